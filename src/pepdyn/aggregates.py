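"""Chain-level contact graph, connected-component aggregates, aggregation
timeline, terminus exposure and residue-contact classification.

An aggregate is a connected component of the chain contact graph, where two
chains are in contact when their minimum heavy-atom distance is at most the
cutoff (default 0.45 nm).  Components are reported as canonical composition
strings such as "3Ab42+2SST14"; transient detachment/re-adsorption is made
robust by a persistence filter over the reporting window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial.distance import cdist

from . import hbonds as _hbonds
from .model import MolecularSystem, Species, Trajectory
from .synthetic import RING_ATOMS

log = logging.getLogger(__name__)

__all__ = [
    "AggregateState",
    "ContactRecord",
    "MAX_ASA_NM2",
    "contact_graph",
    "components",
    "timeline",
    "terminus_exposure",
    "classify_contacts",
]

# Theoretical maximum accessible surface areas per residue (Tien et al. 2013,
# "theoretical" column), converted from A^2 to nm^2; config-overridable.
MAX_ASA_NM2 = {
    "ALA": 1.29, "ARG": 2.74, "ASN": 1.95, "ASP": 1.93, "CYS": 1.67,
    "GLN": 2.25, "GLU": 2.23, "GLY": 1.04, "HIS": 2.24, "ILE": 1.97,
    "LEU": 2.01, "LYS": 2.36, "MET": 2.24, "PHE": 2.40, "PRO": 1.59,
    "SER": 1.55, "THR": 1.72, "TRP": 2.85, "TYR": 2.63, "VAL": 1.74,
}

SPECIES_ORDER = {
    Species.ABETA42: 0, Species.ABETA40: 0,  # Abeta listed first
    Species.SST14: 1, Species.AVP: 1, Species.OTHER: 2,
}


@dataclass
class AggregateState:
    """Partition of chain labels into aggregates for one frame/window."""

    frame_id: object
    partition: list[frozenset]
    compositions: list[str]  # for components of size >= 2, sorted by size desc
    free_chains: list[str]

    def composition_text(self) -> str:
        parts = list(self.compositions)
        if self.free_chains:
            parts.append(
                "; ".join(f"1 free {c}" for c in self.free_chains)
            )
        return "; ".join(parts) if parts else "(none)"


def contact_graph(
    frame: np.ndarray,
    system: MolecularSystem,
    cutoff: float = 0.45,
) -> np.ndarray:
    """Boolean chain-by-chain contact matrix: edge iff the minimum
    inter-chain heavy-atom distance is <= cutoff (nm)."""
    labels = system.chain_labels
    if len(labels) < 2:
        raise ValueError("contact graph needs >= 2 chains")
    frame = np.asarray(frame, dtype=float)
    heavy = system.elements.astype(str) != "H"
    coords = {
        lab: frame[np.intersect1d(system.chain_atom_indices(lab), np.flatnonzero(heavy))]
        for lab in labels
    }
    n = len(labels)
    graph = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if cdist(coords[labels[i]], coords[labels[j]]).min() <= cutoff:
                graph[i, j] = graph[j, i] = True
    return graph


def _composition_string(chains: frozenset, species_map: dict[str, Species]) -> str:
    counts: dict[Species, int] = {}
    for lab in chains:
        sp = species_map[lab]
        counts[sp] = counts.get(sp, 0) + 1
    parts = [
        f"{counts[sp]}{sp.display}"
        for sp in sorted(counts, key=lambda s: (SPECIES_ORDER[s], s.value))
    ]
    return "+".join(parts)


def components(graph: np.ndarray, system: MolecularSystem, frame_id=None) -> AggregateState:
    """Connected components of the contact graph with canonical composition
    strings (Abeta species first); singletons are listed as free chains."""
    graph = np.asarray(graph)
    if not np.array_equal(graph, graph.T):
        raise ValueError("contact graph must be symmetric")
    labels = system.chain_labels
    n_comp, assignment = _cc(csr_matrix(graph), directed=False)
    species_map = system.species_map()
    comps: list[frozenset] = []
    for c in range(n_comp):
        members = frozenset(labels[i] for i in np.flatnonzero(assignment == c))
        comps.append(members)
    comps.sort(key=lambda s: (-len(s), sorted(s)))
    compositions = [
        _composition_string(c, species_map) for c in comps if len(c) >= 2
    ]
    free = sorted(lab for c in comps if len(c) == 1 for lab in c)
    return AggregateState(
        frame_id=frame_id, partition=comps, compositions=compositions, free_chains=free
    )


def timeline(
    traj: Trajectory,
    cutoff: float = 0.45,
    window_frames: int = 10,
    persistence: float = 0.5,
    stride: int = 1,
) -> list[AggregateState]:
    """Aggregation status per window: an edge is kept when present in at
    least ``persistence`` of the window's frames, making the status robust
    to transient chain detachment/re-adsorption."""
    if window_frames < 2:
        raise ValueError("window must span >= 2 frames")
    n_chains = len(traj.system.chain_labels)
    states = []
    for start in range(0, traj.n_frames - window_frames + 1, window_frames):
        acc = np.zeros((n_chains, n_chains), dtype=float)
        count = 0
        for f in range(start, start + window_frames, stride):
            frame = traj.system.make_whole(traj.frames[f])
            acc += contact_graph(frame, traj.system, cutoff)
            count += 1
        kept = acc / count >= persistence
        states.append(
            components(kept, traj.system, frame_id=(start, start + window_frames - 1))
        )
    return states


def terminus_exposure(
    frame: np.ndarray,
    system: MolecularSystem,
    chain: str,
    which: str = "C",
    rel_threshold: float = 0.25,
    max_asa: dict[str, float] | None = None,
    n_points: int = 480,
) -> str:
    """Classify a chain terminus as "surface" or "buried" by relative SASA
    of the terminal residue against a published per-residue maximum."""
    from .sasa import compute_sasa  # local import avoids a cycle at load time

    max_asa = {**MAX_ASA_NM2, **(max_asa or {})}
    idx = system.chain_atom_indices(chain)
    res_ids = system.res_ids[idx]
    target = int(res_ids.min() if which.upper() == "N" else res_ids.max())
    res_atoms = idx[res_ids == target]
    res_name = str(system.res_names[res_atoms[0]])
    if res_name not in max_asa:
        raise ValueError(f"no reference max-SASA for residue {res_name!r}")
    prof = compute_sasa(np.asarray(frame, float), system, n_points=n_points)
    rel = prof.atom_areas[res_atoms].sum() / max_asa[res_name]
    return "surface" if rel >= rel_threshold else "buried"


@dataclass(frozen=True)
class ContactRecord:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    min_distance: float
    types: frozenset  # subset of {hydrophobic, hydrogen_bond, aromatic_pipi}


def _ring_centroids(frame, system):
    """(chain, res_id) -> ring centroid for aromatic residues with ring atoms."""
    names = system.atom_names.astype(str)
    out = {}
    for lab in system.chain_labels:
        idx = system.chain_atom_indices(lab)
        for r in np.unique(system.res_ids[idx]):
            sub = idx[system.res_ids[idx] == r]
            res3 = str(system.res_names[sub[0]])
            if res3 not in RING_ATOMS:
                continue
            ring = sub[np.isin(names[sub], RING_ATOMS[res3])]
            if len(ring) >= 3:
                out[(lab, int(r))] = frame[ring].mean(axis=0)
    return out


def classify_contacts(
    frame: np.ndarray,
    system: MolecularSystem,
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
    consider_cutoff: float = 0.6,
    hydrophobic_cutoff: float = 0.45,
    pipi_cutoff: float = 0.55,
    hb_d_max: float = 0.35,
    hb_angle_max: float = 30.0,
) -> list[ContactRecord]:
    """Classify residue-residue contacts as hydrophobic, hydrogen-bonded
    and/or aromatic pi-pi.

    hydrophobic: two hydrophobic-classified (C/S) side-chain heavy atoms
    within ``hydrophobic_cutoff``; hydrogen_bond: a geometric hydrogen bond
    between the residues; aromatic_pipi: ring centroids within
    ``pipi_cutoff`` (F/Y/W/H).  Without an explicit pair list, all
    inter-chain residue pairs within ``consider_cutoff`` are examined.
    """
    frame = np.asarray(frame, dtype=float)
    names = system.atom_names.astype(str)
    elements = system.elements.astype(str)
    backbone = np.isin(names, ["N", "CA", "C", "O"])
    sidechain_phobic = ~backbone & np.isin(elements, ["C", "S"]) & (elements != "H")

    res_atoms: dict[tuple[str, int], np.ndarray] = {}
    for lab in system.chain_labels:
        idx = system.chain_atom_indices(lab)
        for r in np.unique(system.res_ids[idx]):
            res_atoms[(lab, int(r))] = idx[system.res_ids[idx] == r]

    if pairs is None:
        keys = list(res_atoms)
        pairs = []
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ka, kb = keys[a], keys[b]
                if ka[0] == kb[0]:
                    continue
                if cdist(frame[res_atoms[ka]], frame[res_atoms[kb]]).min() <= consider_cutoff:
                    pairs.append((ka, kb))

    hb_records = _hbonds.find_hbonds(frame, system, d_max=hb_d_max, angle_max=hb_angle_max)
    hb_pairs = set()
    for r in hb_records:
        ra = (r.donor_chain, int(system.res_ids[r.donor]))
        rb = (r.acceptor_chain, int(system.res_ids[r.acceptor]))
        hb_pairs.add(frozenset((ra, rb)))

    centroids = _ring_centroids(frame, system)
    records = []
    for ka, kb in pairs:
        ia, ib = res_atoms[ka], res_atoms[kb]
        dmin = float(cdist(frame[ia], frame[ib]).min())
        types = set()
        pa = ia[sidechain_phobic[ia]]
        pb = ib[sidechain_phobic[ib]]
        if len(pa) and len(pb) and cdist(frame[pa], frame[pb]).min() <= hydrophobic_cutoff:
            types.add("hydrophobic")
        if frozenset((ka, kb)) in hb_pairs:
            types.add("hydrogen_bond")
        if ka in centroids and kb in centroids:
            if np.linalg.norm(centroids[ka] - centroids[kb]) <= pipi_cutoff:
                types.add("aromatic_pipi")
        records.append(
            ContactRecord(residue_a=ka, residue_b=kb, min_distance=dmin, types=frozenset(types))
        )
    return records


def timeline_table(states: list[AggregateState]) -> pd.DataFrame:
    rows = [
        {
            "window": str(s.frame_id),
            "compositions": "; ".join(s.compositions),
            "free_chains": ",".join(s.free_chains),
        }
        for s in states
    ]
    return pd.DataFrame(rows)
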