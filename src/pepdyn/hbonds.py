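"""Geometric hydrogen-bond detection and species-pair census.

A bond is recorded when the donor--acceptor heavy-atom distance is at most
``d_max`` (default 0.35 nm) and the hydrogen--donor--acceptor angle is at
most ``angle_max`` (default 30 deg) -- the convention of the GROMACS
analysis ecosystem.  Structures without explicit hydrogens get amide
hydrogens constructed 1.0 Angstrom from N, anti to the preceding carbonyl O.

Per-frame counts are classified by the species of the two chains involved:
Abeta-Abeta (AB_AB), Abeta-SCP (AB_SCP) and SCP-SCP (SCP_SCP), each split
into intra- and inter-molecular contributions.  Chains of species OTHER are
excluded from the classified census.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import MolecularSystem, Species, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "HBondRecord",
    "HBondSeries",
    "donors_and_acceptors",
    "find_hbonds",
    "census",
    "window_means",
    "find_extrema",
    "CLASSES",
]

CLASSES = ("AB_AB", "AB_SCP", "SCP_SCP")


@dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int  # -1 when the hydrogen was constructed geometrically
    acceptor: int
    donor_chain: str
    acceptor_chain: str
    pair_class: str | None  # AB_AB / AB_SCP / SCP_SCP, None when OTHER involved
    intra: bool


@dataclass
class HBondSeries:
    """Per-frame class counts; ``total`` is the sum of the three classes."""

    times: np.ndarray
    counts: pd.DataFrame  # columns: AB_AB, AB_SCP, SCP_SCP, total, intra, inter

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "time_ps", self.times)
        out.to_csv(path, sep="\t", index=False)


def _classify(sp_a: Species, sp_b: Species) -> str | None:
    if sp_a is Species.OTHER or sp_b is Species.OTHER:
        return None
    a_ab, b_ab = sp_a.is_abeta, sp_b.is_abeta
    if a_ab and b_ab:
        return "AB_AB"
    if not a_ab and not b_ab:
        return "SCP_SCP"
    return "AB_SCP"


def donors_and_acceptors(
    system: MolecularSystem, frame: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Identify donors (N/O/S with an attached or constructible H) and
    acceptors (N, O) and return (donor_idx, hydrogen_idx, h_coords, acceptor_idx).

    ``hydrogen_idx`` is -1 where the amide H was constructed geometrically;
    ``h_coords`` holds one hydrogen position per donor (nm).
    """
    elements = system.elements.astype(str)
    names = system.atom_names.astype(str)
    h_mask = elements == "H"
    donors: list[int] = []
    h_idx: list[int] = []
    h_pos: list[np.ndarray] = []

    if h_mask.any():
        # Explicit hydrogens: attach each H to the nearest N/O/S within 0.12 nm.
        heavy_dea = np.flatnonzero(np.isin(elements, ["N", "O", "S"]))
        tree = cKDTree(frame[heavy_dea])
        for h in np.flatnonzero(h_mask):
            dist, j = tree.query(frame[h])
            if dist <= 0.12:
                donors.append(int(heavy_dea[j]))
                h_idx.append(int(h))
                h_pos.append(frame[h])
    else:
        # Construct amide H: 1.0 A from N, anti to the preceding carbonyl O.
        for lab in system.chain_labels:
            idx = system.chain_atom_indices(lab)
            res_ids = system.res_ids[idx]
            for r in range(2, int(res_ids.max()) + 1):
                res3 = system.res_names[idx[res_ids == r][0]]
                if res3 == "PRO":
                    continue
                n_i = idx[(res_ids == r) & (names[idx] == "N")]
                o_prev = idx[(res_ids == r - 1) & (names[idx] == "O")]
                c_prev = idx[(res_ids == r - 1) & (names[idx] == "C")]
                if len(n_i) != 1 or len(o_prev) != 1 or len(c_prev) != 1:
                    continue
                n_xyz = frame[n_i[0]]
                direction = frame[c_prev[0]] - frame[o_prev[0]]
                nrm = np.linalg.norm(direction)
                if nrm < 1e-9:
                    continue
                donors.append(int(n_i[0]))
                h_idx.append(-1)
                h_pos.append(n_xyz + 0.10 * direction / nrm)

    acceptors = np.flatnonzero(np.isin(elements, ["N", "O"]))
    return (
        np.asarray(donors, dtype=int),
        np.asarray(h_idx, dtype=int),
        np.asarray(h_pos, dtype=float).reshape(len(donors), 3),
        acceptors,
    )


def find_hbonds(
    frame: np.ndarray,
    system: MolecularSystem,
    d_max: float = 0.35,
    angle_max: float = 30.0,
) -> list[HBondRecord]:
    """All donor-H...acceptor contacts in one frame satisfying the cutoffs.

    Pairs within the same residue, and the trivially bonded amide pair
    N(i)...O(i-1), are excluded.
    """
    frame = np.asarray(frame, dtype=float)
    donors, h_idx, h_pos, acceptors = donors_and_acceptors(system, frame)
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    species = system.species_map()
    names = system.atom_names.astype(str)

    tree = cKDTree(frame[acceptors])
    neighbour_lists = tree.query_ball_point(frame[donors], r=d_max)
    records: list[HBondRecord] = []
    cos_min = np.cos(np.deg2rad(angle_max))
    for k, neighbours in enumerate(neighbour_lists):
        d = donors[k]
        d_chain = system.chain_ids[d]
        d_res = system.res_ids[d]
        for jj in neighbours:
            a = int(acceptors[jj])
            if a == d:
                continue
            a_chain = system.chain_ids[a]
            a_res = system.res_ids[a]
            if a_chain == d_chain:
                if a_res == d_res:
                    continue
                # exclude the covalently adjacent amide N(i)...O(i-1)
                if names[d] == "N" and names[a] == "O" and a_res == d_res - 1:
                    continue
            hd = h_pos[k] - frame[d]
            ad = frame[a] - frame[d]
            denom = np.linalg.norm(hd) * np.linalg.norm(ad)
            if denom < 1e-12:
                continue
            if hd @ ad / denom < cos_min:  # angle H-D-A > angle_max
                continue
            records.append(
                HBondRecord(
                    donor=int(d),
                    hydrogen=int(h_idx[k]),
                    acceptor=a,
                    donor_chain=str(d_chain),
                    acceptor_chain=str(a_chain),
                    pair_class=_classify(species[d_chain], species[a_chain]),
                    intra=bool(a_chain == d_chain),
                )
            )
    return records


def census(
    traj: Trajectory,
    d_max: float = 0.35,
    angle_max: float = 30.0,
    include_intra: bool = True,
) -> HBondSeries:
    """Per-frame hydrogen-bond counts by species-pair class.

    ``include_intra=False`` drops intra-molecular bonds from the class
    counts (the default keeps them, with intra/inter also reported
    separately).
    """
    rows = []
    for f in range(traj.n_frames):
        frame = traj.system.make_whole(traj.frames[f])
        recs = find_hbonds(frame, traj.system, d_max=d_max, angle_max=angle_max)
        row = {c: 0 for c in CLASSES}
        intra = inter = 0
        for r in recs:
            if r.intra:
                intra += 1
            else:
                inter += 1
            if r.pair_class is None:
                continue
            if r.intra and not include_intra:
                continue
            row[r.pair_class] += 1
        row["total"] = sum(row[c] for c in CLASSES)
        row["intra"] = intra
        row["inter"] = inter
        rows.append(row)
    counts = pd.DataFrame(rows)
    return HBondSeries(times=traj.times, counts=counts)


def window_means(series: HBondSeries, window: tuple[float, float]) -> dict[str, float]:
    """Per-class means over a time window [t0, t1] ps, rounded to 1 decimal."""
    t0, t1 = window
    mask = (series.times >= t0 - 1e-9) & (series.times <= t1 + 1e-9)
    if not mask.any():
        raise ValueError(f"window ({t0}, {t1}) ps contains no frames")
    sub = series.counts.loc[mask, list(CLASSES) + ["total"]]
    return {c: round(float(sub[c].mean()), 1) for c in sub.columns}


def find_extrema(
    values: np.ndarray,
    times: np.ndarray | None = None,
    smooth_window: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima/minima of a moving-average-smoothed series.

    Returns (maxima, minima) as indices into the input (or times when
    given).  Plateau ties are broken by the earliest time.  A constant
    series yields empty results.
    """
    y = np.asarray(values, dtype=float)
    if smooth_window > 1:
        if len(y) <= smooth_window:
            raise ValueError("series must be longer than the smoothing window")
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(y, kernel, mode="valid")
        offset = (smooth_window - 1) // 2
    else:
        smoothed = y
        offset = 0

    maxima, minima = [], []
    i = 1
    n = len(smoothed)
    while i < n - 1:
        j = i
        while j < n - 1 and smoothed[j + 1] == smoothed[j]:
            j += 1  # plateau: compare its ends, report its first point
        left, right = smoothed[i - 1], smoothed[min(j + 1, n - 1)]
        if j >= n - 1:
            break
        if smoothed[i] > left and smoothed[i] > right:
            maxima.append(i + offset)
        elif smoothed[i] < left and smoothed[i] < right:
            minima.append(i + offset)
        i = j + 1
    maxima = np.asarray(maxima, dtype=int)
    minima = np.asarray(minima, dtype=int)
    if times is not None:
        times = np.asarray(times)
        return times[maxima], times[minima]
    return maxima, minima
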