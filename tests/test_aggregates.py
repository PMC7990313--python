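"""Contact graphs, aggregate components, timelines, exposure, contact types."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pepdyn import aggregates
from pepdyn.model import ChainRecord, MolecularSystem, Species, Trajectory
from pepdyn.synthetic import (
    AggregationSchedule,
    BackboneSpec,
    MergeEvent,
    build_peptide,
    combine_chains,
    simulate,
)


def spaced_chains(offsets, n_res=4, labels=None, species=None):
    tmpl = build_peptide(BackboneSpec("A" * n_res, conformation="strand"))
    labels = labels or [chr(ord("A") + i) for i in range(len(offsets))]
    parts = [
        (lab, tmpl, tmpl.coords + np.asarray(off, float))
        for lab, off in zip(labels, offsets)
    ]
    system = combine_chains(parts)
    if species:
        system.chains = [
            ChainRecord(c.label, sp, c.sequence) for c, sp in zip(system.chains, species)
        ]
    return system


class TestContactGraph:
    def test_far_chains_no_edge(self):
        s = spaced_chains([(0, 0, 0), (5.0, 0, 0)])
        g = aggregates.contact_graph(s.coords, s)
        assert not g.any()

    def test_interface_gives_edge(self):
        s = spaced_chains([(0, 0, 0), (0.0, 0.8, 0.0)])
        # chains are elongated along x; a 0.8 nm y-offset leaves close contacts
        dmin = cdist(
            s.coords[s.chain_atom_indices("A")], s.coords[s.chain_atom_indices("B")]
        ).min()
        g = aggregates.contact_graph(s.coords, s)
        assert g[0, 1] == (dmin <= 0.45)
        assert g[0, 1]

    def test_matches_exhaustive_distance_table(self):
        s = spaced_chains([(0, 0, 0), (1.2, 0.3, 0), (2.0, -0.4, 0.3)])
        for cutoff in (0.2, 0.45, 0.8, 2.0):
            g = aggregates.contact_graph(s.coords, s, cutoff=cutoff)
            for i, a in enumerate(s.chain_labels):
                for j, b in enumerate(s.chain_labels):
                    if i == j:
                        assert not g[i, j]
                        continue
                    dmin = cdist(
                        s.coords[s.chain_atom_indices(a)],
                        s.coords[s.chain_atom_indices(b)],
                    ).min()
                    assert g[i, j] == (dmin <= cutoff)

    def test_monotone_coarsening(self):
        """Raising the cutoff never splits a component."""
        rng = np.random.default_rng(3)
        s = spaced_chains([rng.uniform(0, 3, 3) for _ in range(5)])
        prev = None
        for cutoff in (0.3, 0.6, 1.0, 2.0, 5.0):
            g = aggregates.contact_graph(s.coords, s, cutoff=cutoff)
            state = aggregates.components(g, s)
            if prev is not None:
                for comp in prev.partition:
                    assert any(comp <= bigger for bigger in state.partition)
            prev = state


class TestComponents:
    def test_empty_graph_all_free(self):
        s = spaced_chains([(3.0 * k, 0, 0) for k in range(4)])
        g = np.zeros((4, 4), bool)
        state = aggregates.components(g, s)
        assert state.compositions == []
        assert state.free_chains == ["A", "B", "C", "D"]

    def test_composition_string_formatting(self):
        species_map = dict(
            zip("ABCDEIJ", [Species.ABETA42] * 5 + [Species.SST14] * 2)
        )
        assert (
            aggregates._composition_string(frozenset("ABCIJ"), species_map)
            == "3Ab42+2SST14"
        )
        assert aggregates._composition_string(frozenset("DE"), species_map) == "2Ab42"

    def test_components_partition_and_free(self):
        s = spaced_chains([(3.0 * k, 0, 0) for k in range(7)], labels=list("ABCDEIJ"))
        g = np.zeros((7, 7), bool)
        # component {A,B,C,I,J} and component {D,E}
        for a, b in [(0, 1), (1, 2), (2, 5), (5, 6), (3, 4)]:
            g[a, b] = g[b, a] = True
        state = aggregates.components(g, s)
        assert set(state.partition) == {frozenset("ABCIJ"), frozenset("DE")}
        assert state.free_chains == []
        assert len(state.compositions) == 2

    def test_asymmetric_graph_rejected(self):
        s = spaced_chains([(0, 0, 0), (3.0, 0, 0)])
        g = np.zeros((2, 2), bool)
        g[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            aggregates.components(g, s)


class TestTimeline:
    @staticmethod
    def flicker_trajectory(occupancy, n_frames=20):
        """Dimer in contact for the given fraction of frames."""
        s = spaced_chains([(0, 0, 0), (0.0, 0.8, 0.0)])
        apart = s.coords.copy()
        apart[s.chain_atom_indices("B")] += np.array([0.0, 5.0, 0.0])
        n_contact = int(round(occupancy * n_frames))
        frames = [s.coords if f < n_contact else apart for f in range(n_frames)]
        return Trajectory(s, np.array(frames), dt=1.0)

    def test_persistent_edge_kept(self):
        traj = self.flicker_trajectory(0.6)
        states = aggregates.timeline(traj, window_frames=20, persistence=0.5)
        assert states[0].compositions  # one dimer component

    def test_transient_edge_dropped(self):
        traj = self.flicker_trajectory(0.4)
        states = aggregates.timeline(traj, window_frames=20, persistence=0.5)
        assert states[0].compositions == []
        assert states[0].free_chains == ["A", "B"]

    def test_seventy_percent_dimer_reported(self):
        traj = self.flicker_trajectory(0.7)
        states = aggregates.timeline(traj, window_frames=20, persistence=0.5)
        assert len(states[0].partition) == 1

    def test_scheduled_merges_recover_ground_truth(self, small_mixture):
        sched = AggregationSchedule(
            merges=[
                MergeEvent.of(10.0, {"A"}, {"B"}),
                MergeEvent.of(40.0, {"A"}, {"I"}),
            ],
            drift_rate=0.05,
            contact_dist=0.4,
        )
        traj, gt = simulate(small_mixture, schedule=sched, noise_sd=0.002,
                            n_frames=300, dt=1.0, seed=11)
        states = aggregates.timeline(traj, window_frames=50, persistence=0.5)
        assert set(states[-1].partition) == set(gt.final_partition())


class TestTerminusExposure:
    def test_isolated_chain_surface(self, strand10):
        for which in ("N", "C"):
            assert (
                aggregates.terminus_exposure(strand10.coords, strand10, "A", which)
                == "surface"
            )

    def test_caged_terminus_buried(self):
        """Terminal residue enclosed in a tight cage of atoms is buried."""
        tmpl = build_peptide(BackboneSpec("AAAA", conformation="strand"))
        term_atoms = tmpl.chain_atom_indices("A")[tmpl.res_ids == 4]
        centre = tmpl.coords[term_atoms].mean(axis=0)
        from pepdyn.sasa import sphere_points

        cage = centre + 0.55 * sphere_points(200)
        cage_sys = MolecularSystem(
            chains=[ChainRecord("X", Species.OTHER, "G" * 200)],
            atom_names=["CA"] * 200,
            elements=["C"] * 200,
            res_ids=list(range(1, 201)),
            res_names=["GLY"] * 200,
            chain_ids=["X"] * 200,
            coords=cage,
        )
        combined = combine_chains([("A", tmpl, tmpl.coords)])
        # append the cage atoms manually
        combined = MolecularSystem(
            chains=combined.chains + cage_sys.chains,
            atom_names=np.concatenate([combined.atom_names, cage_sys.atom_names]),
            elements=np.concatenate([combined.elements, cage_sys.elements]),
            res_ids=np.concatenate([combined.res_ids, cage_sys.res_ids]),
            res_names=np.concatenate([combined.res_names, cage_sys.res_names]),
            chain_ids=np.concatenate([combined.chain_ids, cage_sys.chain_ids]),
            coords=np.vstack([combined.coords, cage]),
        )
        assert aggregates.terminus_exposure(combined.coords, combined, "A", "C") == "buried"

    def test_threshold_flip_at_computed_relative_sasa(self, strand10):
        from pepdyn.sasa import compute_sasa

        prof = compute_sasa(strand10.coords, strand10, n_points=480)
        idx = strand10.chain_atom_indices("A")[strand10.res_ids == 10]
        rel = prof.atom_areas[idx].sum() / aggregates.MAX_ASA_NM2["ALA"]
        below = aggregates.terminus_exposure(
            strand10.coords, strand10, "A", "C", rel_threshold=rel - 1e-6
        )
        above = aggregates.terminus_exposure(
            strand10.coords, strand10, "A", "C", rel_threshold=rel + 1e-6
        )
        assert below == "surface" and above == "buried"

    def test_unknown_residue_reference_errors(self):
        tmpl = build_peptide(BackboneSpec("AAAA", conformation="strand"))
        tmpl.res_names = np.array(["UNK"] * tmpl.n_atoms, dtype=object)
        with pytest.raises(ValueError, match="max-SASA"):
            aggregates.terminus_exposure(tmpl.coords, tmpl, "A", "C")


class TestClassifyContacts:
    def test_phenyl_ring_pipi(self):
        tmpl = build_peptide(BackboneSpec("AFA", conformation="strand"))
        # place a second copy so ring centroids sit ~0.4 nm apart
        from pepdyn.synthetic import RING_ATOMS

        ring = np.isin(tmpl.atom_names, RING_ATOMS["PHE"]) & (tmpl.res_ids == 2)
        c1 = tmpl.coords[ring].mean(axis=0)
        shifted = tmpl.coords + (np.array([0.4, 0.0, 0.0]))
        system = combine_chains([("A", tmpl, tmpl.coords), ("B", tmpl, shifted)])
        recs = aggregates.classify_contacts(system.coords, system)
        pipi = [r for r in recs if "aromatic_pipi" in r.types]
        assert any(
            {r.residue_a, r.residue_b} == {("A", 2), ("B", 2)} for r in pipi
        )

    def test_hydrophobic_contact_matches_brute_force(self):
        tmpl = build_peptide(BackboneSpec("LVL", conformation="strand"))
        shifted = tmpl.coords + np.array([0.0, 0.55, 0.0])
        system = combine_chains([("A", tmpl, tmpl.coords), ("B", tmpl, shifted)])
        recs = aggregates.classify_contacts(system.coords, system)
        names = system.atom_names.astype(str)
        backbone = np.isin(names, ["N", "CA", "C", "O"])
        phobic = ~backbone & np.isin(system.elements.astype(str), ["C", "S"])
        for r in recs:
            ia = np.flatnonzero(
                (system.chain_ids == r.residue_a[0]) & (system.res_ids == r.residue_a[1])
            )
            ib = np.flatnonzero(
                (system.chain_ids == r.residue_b[0]) & (system.res_ids == r.residue_b[1])
            )
            pa, pb = ia[phobic[ia]], ib[phobic[ib]]
            expect = (
                len(pa) > 0
                and len(pb) > 0
                and cdist(system.coords[pa], system.coords[pb]).min() <= 0.45
            )
            assert ("hydrophobic" in r.types) == expect

    def test_hydrogen_bond_type_flagged(self, sheet_dimer):
        # rigid ideal-geometry strands put the constructed amide H ~40 deg off
        # the N->O axis, so widen the angle cutoff to the energy-criterion scale
        recs = aggregates.classify_contacts(
            sheet_dimer.coords, sheet_dimer, hb_angle_max=45.0
        )
        hb_pairs = [r for r in recs if "hydrogen_bond" in r.types]
        assert hb_pairs
        # hydrogen-bonded residue pairs are exactly the inter-chain pairs the
        # hbonds module reports at the same cutoffs
        from pepdyn import hbonds

        raw = hbonds.find_hbonds(sheet_dimer.coords, sheet_dimer, angle_max=45.0)
        raw_pairs = {
            frozenset(
                {
                    (r.donor_chain, int(sheet_dimer.res_ids[r.donor])),
                    (r.acceptor_chain, int(sheet_dimer.res_ids[r.acceptor])),
                }
            )
            for r in raw
            if not r.intra
        }
        got_pairs = {frozenset({r.residue_a, r.residue_b}) for r in hb_pairs}
        assert got_pairs <= raw_pairs
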