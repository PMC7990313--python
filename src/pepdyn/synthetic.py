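"""Synthetic peptide systems and trajectories with known ground truth.

The generator emulates the study design that motivates this package: eight
disordered amyloid-beta chains (40 or 42 residues) mixed with eight small
cyclic peptides (somatostatin-14 or vasopressin mimics) at ~4 mM, sparsely
placed with inter-surface gaps above 0.4 nm, undergoing scripted aggregation
with correlated internal motion.  Because every latent ingredient (mode
shapes, per-atom noise, merge schedule) is recorded as ground truth, each
downstream analysis stage can be validated by parameter recovery.

Peptides are built at backbone resolution (N, CA, C, O, CB for non-Gly, and
idealised aromatic-ring atoms for F/Y/W/H) with ideal bond geometry via NeRF
chain extension.  Internal motion is a sum of Ornstein-Uhlenbeck-driven
latent modes plus isotropic per-atom Gaussian noise; chain groups undergo
rigid random-walk diffusion and scheduled merges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model import (
    AA_1TO3,
    ABETA40_SEQ,
    ABETA42_SEQ,
    AVP_SEQ,
    SST14_SEQ,
    ChainRecord,
    MolecularSystem,
    Species,
    Trajectory,
)

__all__ = [
    "BackboneSpec",
    "LatentModeSpec",
    "MergeEvent",
    "AggregationSchedule",
    "GroundTruth",
    "build_peptide",
    "build_mixture",
    "simulate",
    "SEQUENCES",
    "default_box_nm",
]

# Standard backbone bond lengths (Angstrom) and angles (deg).
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
B_CA_CB = 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O = 120.8
OMEGA = 180.0

MOTIF_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}
# Coil residues draw phi from U(-150, -50) and psi from U(-60, 160) deg: the
# broad upper-left region of the Ramachandran map populated by disordered
# chains.
COIL_PHI_RANGE = (-150.0, -50.0)
COIL_PSI_RANGE = (-60.0, 160.0)

SEQUENCES = {
    Species.ABETA42: ABETA42_SEQ,
    Species.ABETA40: ABETA40_SEQ,
    Species.SST14: SST14_SEQ,
    Species.AVP: AVP_SEQ,
}

# Aromatic ring atoms built for pi-pi geometry (6-membered idealised ring;
# His gets a 5-membered one).
RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "CE2", "CE3", "CZ2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


@dataclass
class BackboneSpec:
    """Sequence plus per-residue (phi, psi) in degrees, or a named motif.

    ``conformation`` may be "helix", "strand", "coil", or an explicit list of
    (phi, psi) pairs of the same length as the sequence.  ``cyclic`` marks
    disulfide-closed peptides (SST14/AVP mimics); the closure only shapes the
    builder's choice of conformation, it is not enforced dynamically.
    """

    sequence: str
    conformation: str | list[tuple[float, float]] = "coil"
    cyclic: bool = False
    seed: int = 0

    def phi_psi(self) -> list[tuple[float, float]]:
        n = len(self.sequence)
        if isinstance(self.conformation, str):
            if self.conformation in MOTIF_PHI_PSI:
                return [MOTIF_PHI_PSI[self.conformation]] * n
            if self.conformation == "coil":
                rng = np.random.default_rng(self.seed)
                return [
                    (rng.uniform(*COIL_PHI_RANGE), rng.uniform(*COIL_PSI_RANGE))
                    for _ in range(n)
                ]
            raise ValueError(f"unknown motif {self.conformation!r}")
        if len(self.conformation) != n:
            raise ValueError("per-residue (phi, psi) list must match sequence length")
        return list(self.conformation)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position d at |cd|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ring_positions(ca, cb, res_name):
    """Idealised flat ring hanging off CB along the CA->CB direction."""
    names = RING_ATOMS[res_name]
    k = 6 if len(names) == 6 else 5
    axis = cb - ca
    axis /= np.linalg.norm(axis)
    # Build an orthonormal frame around the axis.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    r_ring = 1.39 if k == 6 else 1.32  # aromatic C-C / imidazole bond (A)
    radius = r_ring / (2 * np.sin(np.pi / k))
    centre = cb + axis * (1.5 + radius)
    coords = []
    for i in range(k):
        theta = 2 * np.pi * i / k
        coords.append(centre + radius * (np.cos(theta) * u + np.sin(theta) * v))
    return names, coords


def build_peptide(spec: BackboneSpec) -> MolecularSystem:
    """Build a peptide with ideal geometry from a :class:`BackboneSpec`.

    Atoms per residue: N, CA, C, O, CB (non-Gly) and idealised ring atoms for
    F/Y/W/H.  Bond lengths follow the standard values (N-CA 1.458, CA-C
    1.525, C-N 1.329, C=O 1.231 Angstrom).  Coordinates are returned in nm.
    """
    seq = spec.sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have >= 2 residues")
    for letter in seq:
        if letter not in AA_1TO3:
            raise ValueError(f"unknown residue letter {letter!r}")
    phi_psi = spec.phi_psi()

    names: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    coords: list[np.ndarray] = []

    def add(name, resi, pos):
        names.append(name)
        res_ids.append(resi)
        res_names.append(AA_1TO3[seq[resi - 1]])
        coords.append(np.asarray(pos, dtype=float))

    # Residue 1 seeded in a canonical local frame.
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(A_N_CA_C)
    c1 = ca1 + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = {1: {"N": n1, "CA": ca1, "C": c1}}
    for i in range(2, len(seq) + 1):
        prev = backbone[i - 1]
        phi_prev, psi_prev = phi_psi[i - 2]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, B_N_CA, A_C_N_CA, OMEGA)
        phi_i, _ = phi_psi[i - 1]
        c_i = _place_atom(prev["C"], n_i, ca_i, B_CA_C, A_N_CA_C, phi_i)
        backbone[i] = {"N": n_i, "CA": ca_i, "C": c_i}

    for i in range(1, len(seq) + 1):
        bb = backbone[i]
        add("N", i, bb["N"])
        add("CA", i, bb["CA"])
        add("C", i, bb["C"])
        # Carbonyl O: anti to the next amide N (trans peptide), i.e. torsion
        # psi_i + 180 about N-CA-C; the C-terminal O uses psi directly.
        _, psi_i = phi_psi[i - 1]
        o_torsion = psi_i + 180.0 if i < len(seq) else psi_i
        o_i = _place_atom(bb["N"], bb["CA"], bb["C"], B_C_O, A_CA_C_O, o_torsion)
        add("O", i, o_i)
        res3 = AA_1TO3[seq[i - 1]]
        if res3 != "GLY":
            # CB from the standard tetrahedral branch off N-CA-C.
            cb = bb["CA"] + B_CA_CB * _tetrahedral_dir(bb["N"], bb["CA"], bb["C"])
            add("CB", i, cb)
            if res3 in RING_ATOMS:
                ring_names, ring_coords = _ring_positions(bb["CA"], cb, res3)
                for rn, rc in zip(ring_names, ring_coords):
                    add(rn, i, rc)

    coords_arr = np.vstack(coords) / 10.0  # Angstrom -> nm
    elements = np.array([nm[0] for nm in names], dtype=object)
    chain = ChainRecord(label="A", species=_species_for(seq), sequence=seq)
    return MolecularSystem(
        chains=[chain],
        atom_names=np.array(names, dtype=object),
        elements=elements,
        res_ids=np.array(res_ids),
        res_names=np.array(res_names, dtype=object),
        chain_ids=np.array(["A"] * len(names), dtype=object),
        coords=coords_arr,
    )


def _tetrahedral_dir(n, ca, c):
    """Unit vector from CA toward CB for ideal tetrahedral geometry."""
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    bisector = -(u + v)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(v, u)
    perp /= np.linalg.norm(perp)
    # Rotate the bisector out of the N-CA-C plane by the tetrahedral half-angle.
    d = bisector * np.cos(np.deg2rad(54.25)) + perp * np.sin(np.deg2rad(54.25))
    return d / np.linalg.norm(d)


def _species_for(seq: str) -> Species:
    from .model import KNOWN_SEQUENCES

    return KNOWN_SEQUENCES.get(seq, Species.OTHER)


def hairpin_conformation(n_res: int, turn_start: int, turn_len: int = 4) -> list[tuple[float, float]]:
    """(phi, psi) list for strand / turn / strand; the turn uses alternating
    left-handed torsions so the two strands run antiparallel."""
    strand = MOTIF_PHI_PSI["strand"]
    # type-II beta-turn torsions, padded with strand for longer turns
    turn = [(-139.0, 135.0), (-60.0, 120.0), (80.0, 0.0), (-139.0, 135.0)]
    if turn_len <= 2:
        turn = [(-60.0, 120.0), (80.0, 0.0)]
    out = []
    for i in range(n_res):
        if turn_start <= i < turn_start + turn_len:
            out.append(turn[(i - turn_start) % len(turn)])
        else:
            out.append(strand)
    return out


def default_box_nm(n_abeta: int = 8) -> float:
    """Cubic box edge giving ~4 mM for ``n_abeta`` chains (approximation:
    c = n / (N_A * V); 8 chains at 4 mM -> V = 3322 nm^3 -> edge 14.9 nm)."""
    n_av = 6.02214076e23
    volume_l = n_abeta / (n_av * 4e-3)
    return (volume_l * 1e24) ** (1.0 / 3.0)  # 1 L = 1e24 nm^3


def build_mixture(
    n_abeta: int,
    abeta_species: Species = Species.ABETA42,
    n_scp: int = 0,
    scp_species: Species = Species.SST14,
    box: float | None = None,
    min_gap: float = 0.4,
    seed: int = 0,
    max_retries: int = 500,
) -> MolecularSystem:
    """Randomly place Abeta chains (labels A..) and small cyclic peptides
    (labels I..) in a cubic box with all inter-chain surface gaps > ``min_gap``
    nm.  Deterministic under a fixed seed.
    """
    if box is None:
        box = default_box_nm(max(n_abeta, n_scp, 1))
    rng = np.random.default_rng(seed)
    species_list = [abeta_species] * n_abeta + [scp_species] * n_scp
    labels = [chr(ord("A") + i) for i in range(n_abeta)] + [
        chr(ord("I") + i) for i in range(n_scp)
    ]
    templates: dict[Species, MolecularSystem] = {}
    for sp in set(species_list):
        cyclic = sp.is_scp
        conf = "coil"
        if cyclic:
            # Shape the cyclic mimic: pick the canonical conformation that
            # best closes the disulfide (C3-C14 for SST14, C1-C6 for AVP).
            conf = _best_cyclic_conformation(SEQUENCES[sp], sp)
        templates[sp] = build_peptide(
            BackboneSpec(SEQUENCES[sp], conformation=conf, cyclic=cyclic, seed=seed)
        )

    placed_coords: list[np.ndarray] = []
    if n_abeta + n_scp == 1:
        sys0 = templates[species_list[0]]
        centred = sys0.coords - sys0.coords.mean(axis=0) + box / 2.0
        out = _assemble(labels, species_list, templates, [centred], box)
        return out
    for lab, sp in zip(labels, species_list):
        tmpl = templates[sp]
        base = tmpl.coords - tmpl.coords.mean(axis=0)
        ok = False
        for _attempt in range(max_retries):
            rot = Rotation.random(random_state=rng)
            pos = rng.uniform(0.0, box, size=3)
            cand = base @ rot.as_matrix().T + pos
            if np.any(cand < 0.0) or np.any(cand > box):
                continue
            if all(cdist(cand, other).min() > min_gap for other in placed_coords):
                ok = True
                break
        if not ok:
            achieved = min(
                (cdist(cand, other).min() for other in placed_coords), default=np.inf
            )
            raise RuntimeError(
                f"could not place chain {lab} after {max_retries} retries "
                f"(best achieved gap {achieved:.3f} nm < {min_gap} nm); "
                f"increase the box or lower min_gap"
            )
        placed_coords.append(cand)
    return _assemble(labels, species_list, templates, placed_coords, box)


def _best_cyclic_conformation(seq: str, sp: Species) -> list[tuple[float, float]]:
    pairs = {"AGCKNFFWKTFTSC": (3, 14), "CYFENCPRG": (1, 6)}
    i, j = pairs.get(seq, (1, len(seq)))
    best, best_d = None, np.inf
    candidates = [
        [MOTIF_PHI_PSI["helix"]] * len(seq),
        hairpin_conformation(len(seq), turn_start=len(seq) // 2 - 1, turn_len=3),
        hairpin_conformation(len(seq), turn_start=len(seq) // 2 - 2, turn_len=4),
    ]
    for conf in candidates:
        system = build_peptide(BackboneSpec(seq, conformation=conf))
        sel_i = _res_atom_index(system, i, "CA")
        sel_j = _res_atom_index(system, j, "CA")
        d = np.linalg.norm(system.coords[sel_i] - system.coords[sel_j])
        if d < best_d:
            best, best_d = conf, d
    return best


def combine_chains(parts: list[tuple[str, MolecularSystem, np.ndarray]], box: float | None = None) -> MolecularSystem:
    """Assemble single-chain systems (with replacement coordinates) into one
    multi-chain system under new labels."""
    chains, names, elements, res_ids, res_names, chain_ids, coords = (
        [], [], [], [], [], [], []
    )
    for lab, tmpl, xyz in parts:
        chains.append(ChainRecord(label=lab, species=tmpl.chains[0].species,
                                  sequence=tmpl.chains[0].sequence))
        names.extend(tmpl.atom_names)
        elements.extend(tmpl.elements)
        res_ids.extend(tmpl.res_ids)
        res_names.extend(tmpl.res_names)
        chain_ids.extend([lab] * tmpl.n_atoms)
        coords.append(np.asarray(xyz, dtype=float))
    return MolecularSystem(
        chains=chains,
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        coords=np.vstack(coords),
        box=None if box is None else np.array([box] * 3),
    )


def build_two_strand_sheet(n_res: int = 8, sequence: str | None = None) -> MolecularSystem:
    """Two-chain antiparallel beta-sheet fixture (chains A and B).

    Chain B is the 180-degree-rotated copy of an ideal strand, placed by a
    deterministic scan over offset/stagger that maximises the number of
    antiparallel Kabsch-Sander bridges, giving a cleanly registered ladder.
    """
    from . import secstruct  # deferred: secstruct does not import synthetic

    seq = sequence or "A" * n_res
    s1 = build_peptide(BackboneSpec(seq, conformation="strand"))
    X = s1.coords
    ca = X[s1.atom_names == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    _, _, vt = np.linalg.svd(X - X.mean(0), full_matrices=False)
    centre = X.mean(0)
    best = None
    for pvec in (vt[1], vt[2], -vt[1], -vt[2]):
        R = Rotation.from_rotvec(np.pi * pvec).as_matrix()
        for off in np.arange(0.42, 0.54, 0.01):
            for shift in np.arange(-0.4, 0.41, 0.05):
                c2 = (X - centre) @ R.T + centre + off * pvec + shift * axis
                cand = combine_chains([("A", s1, X), ("B", s1, c2)])
                tab = secstruct.residue_table(cand)
                hb = secstruct.backbone_hbond_matrix(cand.coords, cand, tab)
                n_anti = sum(
                    1 for *_, sense in secstruct.find_bridges(hb, tab) if sense == "A"
                )
                if best is None or n_anti > best[0]:
                    best = (n_anti, cand)
    return best[1]


def _res_atom_index(system: MolecularSystem, res_id: int, name: str) -> int:
    idx = np.flatnonzero(
        (system.res_ids == res_id) & (system.atom_names.astype(str) == name)
    )
    return int(idx[0])


def _assemble(labels, species_list, templates, placed_coords, box) -> MolecularSystem:
    chains, names, elements, res_ids, res_names, chain_ids, coords = (
        [], [], [], [], [], [], []
    )
    for lab, sp, xyz in zip(labels, species_list, placed_coords):
        tmpl = templates[sp]
        chains.append(ChainRecord(label=lab, species=sp, sequence=tmpl.chains[0].sequence))
        names.extend(tmpl.atom_names)
        elements.extend(tmpl.elements)
        res_ids.extend(tmpl.res_ids)
        res_names.extend(tmpl.res_names)
        chain_ids.extend([lab] * tmpl.n_atoms)
        coords.append(xyz)
    return MolecularSystem(
        chains=chains,
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        coords=np.vstack(coords),
        box=np.array([box, box, box]),
    )


# -- latent-mode trajectory generation -------------------------------------


@dataclass
class LatentModeSpec:
    """A collective latent mode: unit 3m-shape over ``atoms`` with an
    Ornstein-Uhlenbeck amplitude of stationary SD ``sigma`` (nm) and
    correlation time ``tau`` (ps)."""

    mode_id: str
    atoms: np.ndarray
    shape: np.ndarray
    sigma: float
    tau: float

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=np.intp)
        self.shape = np.asarray(self.shape, dtype=float).reshape(len(self.atoms), 3)
        norm = np.linalg.norm(self.shape)
        if norm <= 0:
            raise ValueError("mode shape must be non-zero")
        self.shape = self.shape / norm
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")

    @classmethod
    def random_for_atoms(cls, mode_id, atoms, sigma, tau, rng) -> "LatentModeSpec":
        """Incoherent mode: an independent random 3-vector per atom."""
        shape = rng.standard_normal((len(atoms), 3))
        return cls(mode_id, atoms, shape, sigma, tau)

    @classmethod
    def coherent(cls, mode_id, atoms, direction, sigma, tau) -> "LatentModeSpec":
        """Coherent mode: every participant moves along the same direction
        (a rigid-translation-like collective motion), which is what a domain
        of correlated motion looks like to the ECD descriptors."""
        direction = np.asarray(direction, dtype=float)
        shape = np.tile(direction / np.linalg.norm(direction), (len(atoms), 1))
        return cls(mode_id, atoms, shape, sigma, tau)


@dataclass(frozen=True)
class MergeEvent:
    time_ps: float
    chains_a: frozenset
    chains_b: frozenset

    @classmethod
    def of(cls, time_ps, a, b) -> "MergeEvent":
        return cls(time_ps, frozenset(a), frozenset(b))


@dataclass
class AggregationSchedule:
    """Scripted rigid-body kinetics: per-group random-walk step SD (nm/frame),
    rotational step SD (deg/frame), and a drift rate (nm/ps) pulling merged
    groups into contact.  Merge times must increase and form a forest."""

    merges: list[MergeEvent] = field(default_factory=list)
    step_sd: float = 0.0
    rot_sd_deg: float = 0.0
    drift_rate: float = 0.05
    contact_dist: float = 0.35

    def __post_init__(self):
        times = [m.time_ps for m in self.merges]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("merge times must be non-decreasing")


@dataclass
class GroundTruth:
    """Latent state recorded by :func:`simulate` for parameter recovery."""

    partitions: list[list[frozenset]]
    mode_amplitudes: dict[str, np.ndarray]
    noise_sd: np.ndarray
    contact_frames: dict[tuple, int]
    seed: int

    def final_partition(self) -> list[frozenset]:
        return self.partitions[-1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "partitions_last": [sorted(g) for g in self.partitions[-1]],
                "contact_frames": {
                    "+".join(sorted(k[0]) + ["|"] + sorted(k[1])): v
                    for k, v in self.contact_frames.items()
                },
                "noise_sd": self.noise_sd.tolist(),
                "modes": {k: {"n_frames": len(v)} for k, v in self.mode_amplitudes.items()},
            },
            indent=2,
        )


def _ou_series(n, dt, sigma, tau, rng):
    """Stationary Ornstein-Uhlenbeck: a(t+dt) = a e^(-dt/tau) + N(0, s2(1-e^(-2dt/tau)))."""
    a = np.empty(n)
    a[0] = rng.normal(0.0, sigma)
    decay = np.exp(-dt / tau)
    innov_sd = sigma * np.sqrt(1.0 - decay**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        a[i] = a[i - 1] * decay + shocks[i - 1]
    return a


def simulate(
    system: MolecularSystem,
    modes: list[LatentModeSpec] | None = None,
    schedule: AggregationSchedule | None = None,
    noise_sd: float | np.ndarray = 0.0,
    n_frames: int = 100,
    dt: float = 1.0,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory: frame(t) = rigid group motion applied to
    (reference + sum_k a_k(t) u_k + noise), with OU amplitudes a_k and the
    scripted merge schedule.  Returns the trajectory and its ground truth.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    modes = modes or []
    schedule = schedule or AggregationSchedule()
    n = system.n_atoms
    for m in modes:
        if np.any(m.atoms >= n) or np.any(m.atoms < 0):
            raise ValueError(f"mode {m.mode_id}: atom indices outside system")
    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n,)).copy()

    ss = np.random.SeedSequence(seed)
    rng_modes, rng_noise, rng_rigid = [np.random.default_rng(s) for s in ss.spawn(3)]

    amplitudes = {
        m.mode_id: _ou_series(n_frames, dt, m.sigma, m.tau, rng_modes) for m in modes
    }

    labels = system.chain_labels
    chain_idx = {lab: system.chain_atom_indices(lab) for lab in labels}
    ref = system.coords.copy()

    # Rigid-group state: map group (frozenset of labels) -> translation.
    groups: list[set] = [{lab} for lab in labels]
    offsets = {lab: np.zeros(3) for lab in labels}  # per-chain translation
    rotations = {lab: np.eye(3) for lab in labels}
    pending = list(schedule.merges)
    active_drifts: list[tuple[str, str]] = []
    contact_frames: dict[tuple, int] = {}
    partitions: list[list[frozenset]] = []

    frames = np.empty((n_frames, n, 3))
    times = dt * np.arange(n_frames)

    def group_of(lab):
        for g in groups:
            if lab in g:
                return g
        raise KeyError(lab)

    for f in range(n_frames):
        t = times[f]
        while pending and pending[0].time_ps <= t:
            ev = pending.pop(0)
            # a merge event starts a drift; the groups fuse at first contact
            active_drifts.append(
                (next(iter(ev.chains_a)), next(iter(ev.chains_b)))
            )

        # Internal coordinates: reference + latent modes + noise.
        x = ref.copy()
        for m in modes:
            x[m.atoms] += amplitudes[m.mode_id][f] * m.shape
        if np.any(noise > 0):
            x += rng_noise.standard_normal((n, 3)) * noise[:, None]

        # Rigid group motion: random walk + rotation about the group centroid.
        for g in groups:
            if schedule.step_sd > 0:
                step = rng_rigid.normal(0.0, schedule.step_sd, size=3)
            else:
                step = np.zeros(3)
            if schedule.rot_sd_deg > 0:
                rotvec = rng_rigid.normal(0.0, np.deg2rad(schedule.rot_sd_deg), size=3)
                rot = Rotation.from_rotvec(rotvec).as_matrix()
            else:
                rot = np.eye(3)
            for lab in g:
                offsets[lab] = offsets[lab] + step
                rotations[lab] = rot @ rotations[lab]

        # Drift scheduled pairs toward each other until their groups fuse.
        still = []
        for la, lb in active_drifts:
            ga, gb = group_of(la), group_of(lb)
            if ga is gb:
                continue
            pa = _transformed(x, ga, ref, chain_idx, offsets, rotations)
            pb = _transformed(x, gb, ref, chain_idx, offsets, rotations)
            dmin = cdist(pa, pb).min()
            direction = pb.mean(axis=0) - pa.mean(axis=0)
            direction /= max(np.linalg.norm(direction), 1e-12)
            shift = min(
                schedule.drift_rate * dt,
                max(dmin - schedule.contact_dist * 0.5, 0.0) / 2,
            )
            for lab in ga:
                offsets[lab] = offsets[lab] + direction * shift
            for lab in gb:
                offsets[lab] = offsets[lab] - direction * shift
            still.append((la, lb))
        active_drifts = still

        # Apply per-chain rigid transforms (rotation about the chain's
        # reference centroid keeps each chain intact).
        for lab in labels:
            idx = chain_idx[lab]
            centre = ref[idx].mean(axis=0)
            frames[f, idx] = (x[idx] - centre) @ rotations[lab].T + centre + offsets[lab]

        # Sticky contact detection between ALL rigid groups: any two groups
        # that touch (min distance <= contact_dist) fuse permanently, whether
        # the contact was scheduled or incidental -- so the recorded partition
        # is exactly what a contact-graph analysis of the frames should find.
        fused = True
        while fused:
            fused = False
            descr = []
            for g in groups:
                gi = np.concatenate([chain_idx[lab] for lab in sorted(g)])
                pts = frames[f, gi]
                c = pts.mean(axis=0)
                r = np.linalg.norm(pts - c, axis=1).max()
                descr.append((g, gi, c, r))
            for a in range(len(descr)):
                for b in range(a + 1, len(descr)):
                    ga, gi_a, ca, ra = descr[a]
                    gb, gi_b, cb, rb = descr[b]
                    if np.linalg.norm(ca - cb) - ra - rb > schedule.contact_dist:
                        continue  # bounding spheres too far apart
                    if cdist(frames[f, gi_a], frames[f, gi_b]).min() <= schedule.contact_dist:
                        contact_frames.setdefault(
                            (frozenset(ga), frozenset(gb)), f
                        )
                        groups.remove(ga)
                        groups.remove(gb)
                        groups.append(ga | gb)
                        fused = True
                        break
                if fused:
                    break

        partitions.append(
            sorted((frozenset(g) for g in groups), key=lambda s: sorted(s))
        )

    traj = Trajectory(system=system, frames=frames, dt=dt, time_origin=0.0)
    gt = GroundTruth(
        partitions=partitions,
        mode_amplitudes=amplitudes,
        noise_sd=noise,
        contact_frames=contact_frames,
        seed=seed,
    )
    return traj, gt


def _transformed(x, group, ref, chain_idx, offsets, rotations):
    """Current coordinates of a rigid group's atoms."""
    parts = []
    for lab in sorted(group):
        ci = chain_idx[lab]
        centre = ref[ci].mean(axis=0)
        parts.append((x[ci] - centre) @ rotations[lab].T + centre + offsets[lab])
    return np.vstack(parts)
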