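"""Essential-collective-dynamics descriptors: eigen-oracles, invariants and
parameter recovery on latent-mode trajectories."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from pepdyn import ecd
from pepdyn.model import Trajectory
from pepdyn.synthetic import BackboneSpec, build_peptide, simulate

from conftest import latent_mode_trajectory, rand_index


def power_iteration_eigh(C, d, n_iter=10_000, tol=1e-14):
    """Independent top-d eigensolver: power iteration with deflation.

    Avoids any library eigendecomposition routine so it can serve as a
    second implementation."""
    C = np.array(C, dtype=float)
    n = C.shape[0]
    rng = np.random.default_rng(12345)
    vals, vecs = [], []
    for _ in range(d):
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        lam_old = np.inf
        for _ in range(n_iter):
            w = C @ v
            lam = float(v @ w)
            nrm = np.linalg.norm(w)
            if nrm < 1e-300:
                lam = 0.0
                break
            v = w / nrm
            if abs(lam - lam_old) < tol * max(abs(lam), 1.0):
                break
            lam_old = lam
        vals.append(float(v @ C @ v))
        vecs.append(v.copy())
        C = C - vals[-1] * np.outer(v, v)  # deflate
    return np.array(vals), np.column_stack(vecs)


def toy_trajectory(n_atoms=3, n_frames=100, sd=0.02, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 1, (n_atoms, 3))
    frames = base[None] + rng.normal(0, sd, (n_frames, n_atoms, 3))
    return frames


class TestSegment:
    @staticmethod
    def traj(n_frames, dt):
        s = build_peptide(BackboneSpec("AAA"))
        return Trajectory(s, np.repeat(s.coords[None], n_frames, axis=0), dt=dt)

    def test_20ns_window_gives_100_segments(self):
        traj = self.traj(2001, dt=10.0)  # 0..20000 ps
        segs = ecd.segment(traj, seg_len_ps=200.0, window=(0.0, 20_000.0))
        assert len(segs) == 100

    def test_exactly_one_segment(self):
        traj = self.traj(20, dt=10.0)
        segs = ecd.segment(traj, seg_len_ps=200.0)
        assert len(segs) == 1

    def test_partial_trailing_segment_dropped(self):
        traj = self.traj(30, dt=10.0)  # 1.5 segments
        segs = ecd.segment(traj, seg_len_ps=200.0)
        assert len(segs) == 1

    def test_window_shorter_than_segment_errors(self):
        traj = self.traj(10, dt=10.0)
        with pytest.raises(ValueError, match="segment"):
            ecd.segment(traj, seg_len_ps=200.0)


class TestCovariance:
    def test_identical_frames_zero_matrix(self):
        frames = np.repeat(np.random.default_rng(0).uniform(size=(1, 4, 3)), 10, axis=0)
        C = ecd.covariance(frames, align=False)
        assert np.abs(C).max() < 1e-30  # exact zero up to float subtraction dust

    def test_alignment_removes_rigid_translation(self):
        base = np.random.default_rng(1).uniform(size=(4, 3))
        shifts = np.linspace(0, 1, 20)[:, None, None] * np.array([1.0, 0.5, -0.2])
        frames = base[None] + shifts
        C = ecd.covariance(frames, align=True)
        assert np.abs(C).max() < 1e-10

    def test_matches_explicit_accumulation(self):
        """Eigenvalues equal those of the matrix accumulated by explicit
        python loops over frames and coordinate pairs."""
        frames = toy_trajectory(n_atoms=3, n_frames=100)
        C = ecd.covariance(frames, align=False)
        T, N, _ = frames.shape
        flat = frames.reshape(T, 3 * N)
        mean = flat.mean(axis=0)
        brute = np.zeros((3 * N, 3 * N))
        for t in range(T):
            d = flat[t] - mean
            for a in range(3 * N):
                for b in range(3 * N):
                    brute[a, b] += d[a] * d[b]
        brute /= T
        assert np.abs(C - brute).max() < 1e-12
        assert np.abs(
            np.sort(np.linalg.eigvalsh(C)) - np.sort(np.linalg.eigvalsh(brute))
        ).max() < 1e-10

    def test_trace_equals_total_positional_variance(self):
        frames = toy_trajectory(n_atoms=5, n_frames=200, seed=3)
        C = ecd.covariance(frames, align=False)
        total_var = frames.reshape(len(frames), -1).var(axis=0).sum()
        assert np.trace(C) == pytest.approx(total_var, rel=1e-12)

    def test_single_frame_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            ecd.covariance(np.zeros((1, 4, 3)))


class TestEssentialModes:
    def test_rank_one_matrix(self):
        v = np.random.default_rng(0).standard_normal(12)
        v /= np.linalg.norm(v)
        C = 0.5 * np.outer(v, v)
        modes = ecd.essential_modes(C, d=4)
        assert modes.eigenvalues[0] == pytest.approx(0.5)
        assert np.abs(modes.eigenvalues[1:]).max() < 1e-12
        assert modes.eigenvalues[0] / modes.trace == pytest.approx(1.0)

    def test_isotropic_closed_form(self):
        sigma2 = 0.3
        C = sigma2 * np.eye(12)  # 4 atoms
        modes = ecd.essential_modes(C, d=10)
        assert np.allclose(modes.eigenvalues, sigma2)
        assert modes.cumulative_fraction == pytest.approx(10 / 12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((12, 12))
        C = A @ A.T / 12
        modes = ecd.essential_modes(C, d=6)
        vals, vecs = power_iteration_eigh(C, 6)
        assert np.abs(modes.eigenvalues - vals).max() < 1e-9
        for k in range(6):
            # eigenvectors defined up to sign
            dot = abs(float(modes.eigenvectors[:, k] @ vecs[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-7)

    def test_orthonormality_and_ordering(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((30, 30))
        C = A @ A.T
        modes = ecd.essential_modes(C, d=10)
        G = modes.eigenvectors.T @ modes.eigenvectors
        assert np.abs(G - np.eye(10)).max() < 1e-8
        assert (np.diff(modes.eigenvalues) <= 1e-12).all()

    def test_d_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            ecd.essential_modes(np.eye(6), d=7)


class TestAtomImages:
    def test_immobile_atom_at_origin(self):
        # atom 0 has zero components in every mode
        vecs = np.zeros((6, 2))
        vecs[3, 0] = 1.0
        vecs[4, 1] = 1.0
        modes = ecd.EssentialModes(0, np.array([0.5, 0.25]), vecs, trace=1.0)
        images = ecd.atom_images(modes)
        assert np.allclose(images.images[0], 0.0)

    def test_identical_motion_identical_images(self):
        """Atoms with equal components in every mode map to the same point."""
        vecs = np.zeros((6, 2))
        vecs[[0, 3], 0] = 1 / np.sqrt(2)
        vecs[[1, 4], 1] = 1 / np.sqrt(2)
        modes = ecd.EssentialModes(0, np.array([0.5, 0.25]), vecs, trace=0.75)
        images = ecd.atom_images(modes)
        assert np.allclose(images.images[0], images.images[1])

    def test_group_separation_margin(self, recovery_traj):
        """Disjoint latent modes: inter-group image distance beats 3x the
        max intra-group distance."""
        traj, _, group_of = recovery_traj
        sel = traj.system.ca_selection()
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=10, align=False)
        labels = np.array([group_of[str(traj.system.chain_ids[i])] for i in sel.indices])
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(images[0].images))
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        intra_max = dm[same].max()
        inter_min = dm[~same & (dm > 0)].min()
        assert inter_min > 3 * intra_max


class TestPairCorrelation:
    def test_symmetric_zero_diagonal(self, recovery_traj):
        traj, _, _ = recovery_traj
        sel = traj.system.ca_selection()
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=10, align=False)
        pcm = ecd.pair_correlation(images)
        assert np.allclose(pcm.rho, pcm.rho.T)
        assert np.abs(np.diag(pcm.rho)).max() == 0.0

    def test_block_structure_every_segment(self, recovery_traj):
        traj, _, group_of = recovery_traj
        sel = traj.system.ca_selection()
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=10, align=False)
        labels = np.array([group_of[str(traj.system.chain_ids[i])] for i in sel.indices])
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        for im in images:
            rho = ecd.pair_correlation([im]).rho
            assert rho[same].mean() < rho[~same & (rho > 0)].mean()

    def test_identical_motion_pair_rho_zero(self):
        vecs = np.zeros((6, 2))
        vecs[[0, 3], 0] = 1 / np.sqrt(2)
        vecs[[1, 4], 1] = 1 / np.sqrt(2)
        modes = ecd.EssentialModes(0, np.array([0.4, 0.2]), vecs, trace=0.6)
        pcm = ecd.pair_correlation([ecd.atom_images(modes)])
        assert pcm.rho[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestFlexibility:
    def test_uniform_motion_zero_flexibility(self):
        vecs = np.zeros((9, 1))
        vecs[[0, 3, 6], 0] = 1 / np.sqrt(3)  # all 3 atoms move identically
        modes = ecd.EssentialModes(0, np.array([0.5]), vecs, trace=0.5)
        prof = ecd.flexibility([ecd.atom_images(modes)], ["A"] * 3, np.arange(1, 4))
        assert np.abs(prof.values).max() < 1e-12

    def test_spiked_atom_has_largest_flexibility(self):
        """One atom with extra independent noise tops its chain's profile."""
        s = build_peptide(BackboneSpec("A" * 6, conformation="coil"))
        noise = np.full(s.n_atoms, 0.004)
        ca = s.ca_selection().indices
        spiked = int(ca[2])
        noise[spiked] = 0.05
        traj, _ = simulate(s, noise_sd=noise, n_frames=2000, dt=1.0, seed=5)
        sel = s.ca_selection()
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=10, align=False)
        prof = ecd.flexibility(
            images, ["A"] * len(sel), s.res_ids[sel.indices]
        )
        assert np.argmax(prof.values) == 2

    def test_noise_sd_rank_recovery(self):
        """Per-atom noise SDs over a 5x range: flexibility rank-correlates
        with the injected SD at Spearman >= 0.9."""
        s = build_peptide(BackboneSpec("A" * 6, conformation="coil"))
        rng = np.random.default_rng(21)
        ca = s.ca_selection().indices
        noise = np.full(s.n_atoms, 0.003)
        sds = np.geomspace(0.01, 0.05, len(ca))
        noise[ca] = rng.permutation(sds)
        traj, gt = simulate(s, noise_sd=noise, n_frames=4000, dt=1.0, seed=6)
        sel = s.ca_selection()
        d = min(18, 3 * len(ca))
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=d, align=False)
        prof = ecd.flexibility(images, ["A"] * len(sel), s.res_ids[sel.indices])
        rho = spearmanr(prof.values, gt.noise_sd[sel.indices]).statistic
        assert rho >= 0.9

    def test_c_terminal_value_and_chain_average(self, recovery_traj):
        traj, _, _ = recovery_traj
        sel = traj.system.ca_selection()
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=10, align=False)
        labels = [str(traj.system.chain_ids[i]) for i in sel.indices]
        rids = traj.system.res_ids[sel.indices]
        prof = ecd.flexibility(images, labels, rids)
        mask = np.array([c == "A" for c in labels])
        expected = prof.values[mask][np.argmax(rids[mask])]
        assert prof.c_terminal_value("A") == pytest.approx(expected)


class TestDomains:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.001, (25, 6)), rng.normal(1, 0.001, (25, 6))])
        images = ecd.AtomImages(0, pts, np.arange(50), 1.0)
        dom = ecd.domains(images, threshold=0.05, min_size=5)
        assert dom.n_domains == 2
        assert dom.sizes == [25, 25]

    def test_threshold_below_all_distances_all_off_domain(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (30, 6))
        images = ecd.AtomImages(0, pts, np.arange(30), 1.0)
        dom = ecd.domains(images, threshold=1e-9, min_size=2)
        assert dom.n_domains == 0
        assert (dom.domain_id == 0).all()

    def test_nonpositive_threshold_errors(self):
        images = ecd.AtomImages(0, np.zeros((5, 3)), np.arange(5), 1.0)
        with pytest.raises(ValueError, match="positive"):
            ecd.domains(images, threshold=0.0)

    def test_ground_truth_recovery_rand_index(self, recovery_traj):
        """Threshold from the detected distance gap recovers the latent
        groups exactly (Rand index 1.0)."""
        traj, _, group_of = recovery_traj
        sel = traj.system.ca_selection()
        images = ecd.segment_images(traj, sel, seg_len_ps=200.0, d=10, align=False)
        rho = ecd.pair_correlation(images).rho
        thr = ecd.detect_threshold(rho)
        dom = ecd.domains(rho, threshold=thr, min_size=2)
        truth = [group_of[str(traj.system.chain_ids[i])] for i in sel.indices]
        assert rand_index(truth, dom.domain_id) == 1.0


class TestInvariants:
    def test_rotation_invariance_with_alignment(self, recovery_traj):
        """All image-space descriptors unchanged under a global rigid
        rotation of the input frames when align=True."""
        from scipy.spatial.transform import Rotation

        traj, _, _ = recovery_traj
        sel = traj.system.ca_selection()
        sub = Trajectory(traj.system, traj.frames[:200], dt=traj.dt)
        R = Rotation.random(random_state=np.random.default_rng(3)).as_matrix()
        rotated = Trajectory(traj.system, traj.frames[:200] @ R.T, dt=traj.dt)
        im_a = ecd.segment_images(sub, sel, seg_len_ps=200.0, d=10, align=True)
        im_b = ecd.segment_images(rotated, sel, seg_len_ps=200.0, d=10, align=True)
        rho_a = ecd.pair_correlation(im_a).rho
        rho_b = ecd.pair_correlation(im_b).rho
        assert np.abs(rho_a - rho_b).max() < 1e-6

    def test_variance_capture_with_few_latent_modes(self, recovery_traj):
        """<= 10 latent modes: the 10-mode cumulative fraction exceeds 0.95
        in every segment."""
        traj, _, _ = recovery_traj
        sel = traj.system.ca_selection()
        for a, b in ecd.segment(traj, 200.0):
            C = ecd.covariance(traj.frames[a:b], sel.indices, align=False)
            modes = ecd.essential_modes(C, d=10)
            assert modes.cumulative_fraction > 0.95

    def test_segment_doubling_stability(self, recovery_traj):
        """Descriptors from 2x longer segments of stationary dynamics change
        window-averaged rho and f by < 10%."""
        traj, _, _ = recovery_traj
        sel = traj.system.ca_selection()
        labels = [str(traj.system.chain_ids[i]) for i in sel.indices]
        rids = traj.system.res_ids[sel.indices]
        out = {}
        for seg_len in (200.0, 400.0):
            images = ecd.segment_images(traj, sel, seg_len_ps=seg_len, d=10, align=False)
            rho = ecd.pair_correlation(images).rho
            f = ecd.flexibility(images, labels, rids).values
            out[seg_len] = (rho, f)
        rho_rel = np.abs(out[400.0][0] - out[200.0][0]).mean() / out[200.0][0].mean()
        f_rel = np.abs(out[400.0][1] - out[200.0][1]).mean() / out[200.0][1].mean()
        assert rho_rel < 0.10
        assert f_rel < 0.10
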