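"""Per-frame secondary-structure assignment and occupancy statistics.

The assignment follows the Kabsch-Sander rules: a backbone hydrogen bond
between the N-H of residue a and the C=O of residue b exists when the
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   kcal/mol

(with distances in Angstrom) is below -0.5 kcal/mol.  n-turns, helices
(G/H/I), bridges and ladders (B/E), turns (T) and bends (S) are derived
from the hydrogen-bond pattern; everything else is coil (C).  Amide
hydrogens are constructed geometrically when absent.

Occupancy statistics aggregate the eight DSSP classes into the four-colour
scheme used for amyloid aggregation studies: beta-sheet (E), beta-bridge
(B), helix (H+G+I), turn (T) and coil (C+S).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MolecularSystem, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "ResidueTable",
    "assign_ss",
    "backbone_hbond_matrix",
    "find_bridges",
    "ss_content_series",
    "beta_content",
    "CATEGORIES",
]

CATEGORIES = {
    "sheet": ("E",),
    "bridge": ("B",),
    "helix": ("H", "G", "I"),
    "turn": ("T",),
    "coil": ("C", "S"),
}

Q_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom
E_CUTOFF = -0.5


@dataclass
class ResidueTable:
    """Backbone atom indices per residue, in global residue order."""

    chain_labels: list
    res_ids: np.ndarray
    n_idx: np.ndarray  # -1 where missing
    ca_idx: np.ndarray
    c_idx: np.ndarray
    o_idx: np.ndarray
    is_pro: np.ndarray
    chain_start: np.ndarray  # True at first residue of each chain

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def same_chain(self, i: int, j: int) -> bool:
        return self.chain_labels[i] == self.chain_labels[j]


def residue_table(system: MolecularSystem) -> ResidueTable:
    names = system.atom_names.astype(str)
    chain_labels, res_ids = [], []
    n_idx, ca_idx, c_idx, o_idx, is_pro, chain_start = [], [], [], [], [], []
    for lab in system.chain_labels:
        idx = system.chain_atom_indices(lab)
        rid = system.res_ids[idx]
        for k, r in enumerate(np.unique(rid)):
            sub = idx[rid == r]
            lookup = {names[a]: a for a in sub}
            chain_labels.append(lab)
            res_ids.append(int(r))
            n_idx.append(lookup.get("N", -1))
            ca_idx.append(lookup.get("CA", -1))
            c_idx.append(lookup.get("C", -1))
            o_idx.append(lookup.get("O", -1))
            is_pro.append(system.res_names[sub[0]] == "PRO")
            chain_start.append(k == 0)
    return ResidueTable(
        chain_labels=chain_labels,
        res_ids=np.asarray(res_ids),
        n_idx=np.asarray(n_idx),
        ca_idx=np.asarray(ca_idx),
        c_idx=np.asarray(c_idx),
        o_idx=np.asarray(o_idx),
        is_pro=np.asarray(is_pro),
        chain_start=np.asarray(chain_start),
    )


def _amide_h_positions(frame: np.ndarray, table: ResidueTable) -> np.ndarray:
    """H at 1.0 A from N, anti to the preceding residue's carbonyl O.
    NaN where the residue cannot donate (chain start, Pro, missing atoms)."""
    n_res = table.n_residues
    h = np.full((n_res, 3), np.nan)
    for i in range(n_res):
        if table.chain_start[i] or table.is_pro[i]:
            continue
        prev = i - 1
        if table.n_idx[i] < 0 or table.c_idx[prev] < 0 or table.o_idx[prev] < 0:
            continue
        direction = frame[table.c_idx[prev]] - frame[table.o_idx[prev]]
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            continue
        h[i] = frame[table.n_idx[i]] + 0.10 * direction / nrm
    return h


def backbone_hbond_matrix(
    frame: np.ndarray, system: MolecularSystem, table: ResidueTable | None = None
) -> np.ndarray:
    """Boolean matrix hb[a, b]: N-H of residue a donates to C=O of residue b
    under the Kabsch-Sander energy criterion."""
    frame = np.asarray(frame, dtype=float)
    if table is None:
        table = residue_table(system)
    n_res = table.n_residues
    h = _amide_h_positions(frame, table)
    hb = np.zeros((n_res, n_res), dtype=bool)
    # distances in Angstrom for the energy formula
    A = 10.0
    for a in range(n_res):
        if not np.isfinite(h[a, 0]) or table.n_idx[a] < 0:
            continue
        n_pos, h_pos = frame[table.n_idx[a]] * A, h[a] * A
        for b in range(n_res):
            if a == b:
                continue
            if table.same_chain(a, b) and abs(a - b) < 2:
                continue
            if table.c_idx[b] < 0 or table.o_idx[b] < 0:
                continue
            c_pos, o_pos = frame[table.c_idx[b]] * A, frame[table.o_idx[b]] * A
            r_on = np.linalg.norm(o_pos - n_pos)
            if r_on > 5.2:  # beyond any plausible bonding distance
                continue
            r_ch = np.linalg.norm(c_pos - h_pos)
            r_oh = np.linalg.norm(o_pos - h_pos)
            r_cn = np.linalg.norm(c_pos - n_pos)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry; DSSP treats as no bond
            energy = Q_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < E_CUTOFF:
                hb[a, b] = True
    return hb


def find_bridges(hb: np.ndarray, table: ResidueTable) -> list[tuple[int, int, str]]:
    """Kabsch-Sander bridges: (i, j, sense) with sense 'P' or 'A', i < j."""
    n = table.n_residues

    def valid_triplet(i):
        return (
            0 < i < n - 1
            and table.same_chain(i - 1, i)
            and table.same_chain(i, i + 1)
        )

    bridges = []
    for i in range(n):
        for j in range(i + 1, n):
            if table.same_chain(i, j) and j - i < 3:
                continue
            par = ant = False
            if valid_triplet(i) and valid_triplet(j):
                par = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
                ant = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            elif valid_triplet(i) or valid_triplet(j):
                # chain-terminal partner: only the symmetric antiparallel test
                ant = bool(hb[i, j] and hb[j, i])
            if par:
                bridges.append((i, j, "P"))
            elif ant:
                bridges.append((i, j, "A"))
    return bridges


def assign_ss(
    frame: np.ndarray, system: MolecularSystem, table: ResidueTable | None = None
) -> np.ndarray:
    """One-letter DSSP class per residue for one frame.

    Residues missing backbone atoms are forced to 'C' with a warning.
    Priority of overlapping patterns: H, E, B, G, I, T, S.
    """
    frame = np.asarray(frame, dtype=float)
    if table is None:
        table = residue_table(system)
    n = table.n_residues
    missing = (
        (table.n_idx < 0) | (table.ca_idx < 0) | (table.c_idx < 0) | (table.o_idx < 0)
    )
    if missing.any():
        log.warning("%d residues missing backbone atoms; forced to coil", missing.sum())
    hb = backbone_hbond_matrix(frame, system, table)

    # n-turns: turn_n[i] true when N-H(i+n) -> C=O(i).
    turns = {}
    for nlen in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - nlen):
            if table.same_chain(i, i + nlen) and hb[i + nlen, i]:
                t[i] = True
        turns[nlen] = t

    helix = {4: np.zeros(n, bool), 3: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for nlen in (4, 3, 5):
        t = turns[nlen]
        for i in range(1, n - nlen):
            if t[i - 1] and t[i]:
                helix[nlen][i : i + nlen] = True

    bridges = find_bridges(hb, table)
    bridge_res = np.zeros(n, bool)
    ladder_res = np.zeros(n, bool)
    bset = {(i, j): s for i, j, s in bridges}
    for i, j, s in bridges:
        bridge_res[i] = bridge_res[j] = True
        if s == "P":
            laddered = (i + 1, j + 1) in bset or (i - 1, j - 1) in bset
        else:
            laddered = (i + 1, j - 1) in bset or (i - 1, j + 1) in bset
        if laddered:
            ladder_res[i] = ladder_res[j] = True

    turn_res = np.zeros(n, bool)
    for nlen in (3, 4, 5):
        for i in range(n - nlen):
            if table.same_chain(i, i + nlen) and turns[nlen][i]:
                turn_res[i + 1 : i + nlen] = True

    bend_res = np.zeros(n, bool)
    for i in range(2, n - 2):
        if not (table.same_chain(i - 2, i) and table.same_chain(i, i + 2)):
            continue
        if min(table.ca_idx[i - 2], table.ca_idx[i], table.ca_idx[i + 2]) < 0:
            continue
        u = frame[table.ca_idx[i]] - frame[table.ca_idx[i - 2]]
        v = frame[table.ca_idx[i + 2]] - frame[table.ca_idx[i]]
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom < 1e-12:
            continue
        angle = np.degrees(np.arccos(np.clip(u @ v / denom, -1.0, 1.0)))
        if angle > 70.0:
            bend_res[i] = True

    out = np.full(n, "C", dtype="U1")
    out[bend_res] = "S"
    out[turn_res] = "T"
    out[helix[5]] = "I"
    out[helix[3]] = "G"
    out[bridge_res & ~ladder_res] = "B"
    out[ladder_res] = "E"
    out[helix[4]] = "H"
    out[missing] = "C"
    return out


def ss_content_series(
    traj: Trajectory,
    abeta_only: bool = True,
    stride: int = 1,
) -> pd.DataFrame:
    """Per-frame percentages of the aggregated categories.  The five
    category percentages sum to 100 each frame."""
    table = residue_table(traj.system)
    species = traj.system.species_map()
    if abeta_only:
        res_mask = np.array([species[lab].is_abeta for lab in table.chain_labels])
        if not res_mask.any():
            raise ValueError("no Abeta chains in system")
    else:
        res_mask = np.ones(table.n_residues, dtype=bool)
    total = int(res_mask.sum())
    rows = []
    frame_idx = range(0, traj.n_frames, stride)
    for f in frame_idx:
        frame = traj.system.make_whole(traj.frames[f])
        ss = assign_ss(frame, traj.system, table)[res_mask]
        row = {"time_ps": traj.times[f]}
        for cat, letters in CATEGORIES.items():
            row[cat] = 100.0 * np.isin(ss, letters).sum() / total
        rows.append(row)
    return pd.DataFrame(rows)


def beta_content(
    traj: Trajectory,
    window: tuple[float, float],
    category: str = "sheet",
    abeta_only: bool = True,
    persistence: float | None = None,
    stride: int = 1,
) -> float:
    """Stable secondary-structure percentage over a window.

    Default: time average of the per-frame percentage of Abeta residues in
    the category (E for beta-sheet).  With ``persistence`` (e.g. 0.5) the
    alternative definition is used: percentage of residues assigned the
    category in at least that fraction of the window frames.
    """
    idx = traj.window_frames(window)[::stride]
    table = residue_table(traj.system)
    species = traj.system.species_map()
    if abeta_only:
        res_mask = np.array([species[lab].is_abeta for lab in table.chain_labels])
        if not res_mask.any():
            raise ValueError("no Abeta chains in system")
    else:
        res_mask = np.ones(table.n_residues, dtype=bool)
    letters = CATEGORIES[category]
    hits = []
    for f in idx:
        frame = traj.system.make_whole(traj.frames[f])
        ss = assign_ss(frame, traj.system, table)[res_mask]
        hits.append(np.isin(ss, letters))
    hits = np.asarray(hits)  # (frames, residues)
    if persistence is None:
        return float(100.0 * hits.mean())
    frac = hits.mean(axis=0)
    return float(100.0 * (frac >= persistence).mean())
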