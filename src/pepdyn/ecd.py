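"""Essential Collective Dynamics (ECD) descriptors.

The trajectory is cut into short segments (default 0.2 ns).  For each
segment the covariance matrix of atomic positions (after optional rigid-body
alignment onto the segment mean) is diagonalised, and the leading d
eigenpairs (default d = 10, chosen to capture >= 95% of the total
displacement) define the essential collective coordinates.  Every atom i is
mapped to a point -- its *image* -- in the 3d-dimensional essential space:

    chi_i = ( sqrt(l_1) e^(1)_i, ..., sqrt(l_d) e^(d)_i ) / sqrt(sum_k l_k)

where e^(k)_i is atom i's 3-component block of eigenvector k.  Proximity of
images encodes persistently correlated motion, which yields three
descriptors, each averaged over segments:

* pair correlation map: rho_ij = mean_seg ||chi_i - chi_j|| on the C-alpha
  set (small rho = strong dynamic coupling);
* main-chain flexibility: f_i = mean_seg ||chi_i - chi_bar|| with chi_bar
  the centroid of the main-chain images (large f = independent motion);
* domains of correlated motion: single-linkage clusters of images cut at a
  distance threshold; clusters below a minimum size are off-domain.

The image mapping normalisation is a swappable strategy; the variant above
makes all descriptors dimensionless and comparable across segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .model import Selection, Trajectory, superpose

log = logging.getLogger(__name__)

__all__ = [
    "EssentialModes",
    "AtomImages",
    "PairCorrelationMap",
    "FlexibilityProfile",
    "DomainAssignment",
    "segment",
    "covariance",
    "essential_modes",
    "atom_images",
    "segment_images",
    "pair_correlation",
    "flexibility",
    "domains",
    "detect_threshold",
]


@dataclass
class EssentialModes:
    """Leading eigenpairs of one segment's covariance matrix."""

    segment_id: int
    eigenvalues: np.ndarray  # (d,) nm^2, descending
    eigenvectors: np.ndarray  # (3N, d), orthonormal columns
    trace: float  # total positional variance, nm^2

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        self.eigenvalues = np.clip(lam, 0.0, None)

    @property
    def d(self) -> int:
        return len(self.eigenvalues)

    @property
    def cumulative_fraction(self) -> float:
        """f_d = sum of retained eigenvalues over the trace."""
        if self.trace <= 0:
            return 1.0
        return float(self.eigenvalues.sum() / self.trace)


@dataclass
class AtomImages:
    """Per-atom points chi_i in the 3d-dimensional essential space."""

    segment_id: int
    images: np.ndarray  # (N, 3d), dimensionless
    atom_indices: np.ndarray  # which system atoms the rows correspond to
    normalization: float  # sqrt(total retained variance), nm

    @property
    def n_atoms(self) -> int:
        return self.images.shape[0]


@dataclass
class PairCorrelationMap:
    atom_indices: np.ndarray
    rho: np.ndarray  # symmetric, zero diagonal; small = strongly correlated
    n_segments: int

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.rho).to_csv(path, sep="\t", index=False, header=False)


@dataclass
class FlexibilityProfile:
    chain_labels: list
    res_ids: np.ndarray
    values: np.ndarray  # f_i >= 0, dimensionless
    n_segments: int

    def chain_values(self, label: str) -> np.ndarray:
        mask = np.array([c == label for c in self.chain_labels])
        return self.values[mask]

    def c_terminal_value(self, label: str) -> float:
        mask = np.array([c == label for c in self.chain_labels])
        rid = self.res_ids[mask]
        return float(self.values[mask][np.argmax(rid)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chain": self.chain_labels, "residue": self.res_ids, "flexibility": self.values}
        )


@dataclass
class DomainAssignment:
    atom_indices: np.ndarray
    domain_id: np.ndarray  # 1-based rank by size; 0 = off-domain
    sizes: list[int]  # per domain rank (rank 1 first, largest)

    @property
    def n_domains(self) -> int:
        return len(self.sizes)

    def partition(self) -> list[np.ndarray]:
        return [
            self.atom_indices[self.domain_id == k] for k in range(1, self.n_domains + 1)
        ]


def segment(traj: Trajectory, seg_len_ps: float = 200.0, window: tuple[float, float] | None = None) -> list[tuple[int, int]]:
    """Maximal list of non-overlapping consecutive segment frame-ranges
    [start, stop) covering the window; a trailing partial segment is dropped."""
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    idx = traj.window_frames(window)
    frames_per_seg = int(round(seg_len_ps / traj.dt))
    if frames_per_seg < 2:
        raise ValueError("segment length must span >= 2 frames")
    n_segs = len(idx) // frames_per_seg
    if n_segs == 0:
        raise ValueError(
            f"window of {len(idx)} frames is shorter than one {frames_per_seg}-frame segment"
        )
    return [
        (int(idx[k * frames_per_seg]), int(idx[k * frames_per_seg] + frames_per_seg))
        for k in range(n_segs)
    ]


def covariance(
    frames: np.ndarray,
    selection: Selection | np.ndarray | None = None,
    align: bool = True,
) -> np.ndarray:
    """3N x 3N positional covariance of one segment.

    With ``align`` (default), frames are superposed onto the segment mean,
    the mean recomputed once, and frames re-aligned -- removing rigid-body
    motion so internal fluctuations dominate the leading eigenvalues.
    C = (1/T) sum_t dr dr^T with dr the deviation from the segment mean.
    """
    x = np.asarray(frames, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("covariance needs a (T, N, 3) stack with T >= 2")
    if selection is not None:
        idx = selection.indices if isinstance(selection, Selection) else np.asarray(selection)
        x = x[:, idx, :]
    if align:
        mean = x.mean(axis=0)
        aligned, _ = superpose(x, mean)
        mean = aligned.mean(axis=0)
        aligned, _ = superpose(x, mean)
        x = aligned
    mean = x.mean(axis=0)
    dev = (x - mean).reshape(x.shape[0], -1)  # (T, 3N)
    return dev.T @ dev / x.shape[0]


def essential_modes(C: np.ndarray, d: int = 10, segment_id: int = 0) -> EssentialModes:
    """Top-d eigenpairs of a symmetric PSD covariance matrix.

    Logs a warning when the retained cumulative variance fraction is below
    0.95 (the conventional sufficiency criterion for the mode count).
    """
    C = np.asarray(C, dtype=float)
    n3 = C.shape[0]
    if d > n3:
        raise ValueError(f"d={d} exceeds matrix dimension {n3}")
    lam, vec = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1][:d]
    modes = EssentialModes(
        segment_id=segment_id,
        eigenvalues=lam[order],
        eigenvectors=vec[:, order],
        trace=float(np.trace(C)),
    )
    if modes.cumulative_fraction < 0.95:
        log.warning(
            "segment %d: %d modes capture only %.1f%% of the total displacement",
            segment_id, d, 100 * modes.cumulative_fraction,
        )
    return modes


def atom_images(modes: EssentialModes, atom_indices: np.ndarray | None = None) -> AtomImages:
    """Map each atom to its image chi_i in R^(3d):
    chi_i = (sqrt(l_1) e^(1)_i, ..., sqrt(l_d) e^(d)_i) / sqrt(sum l_k)."""
    n3, d = modes.eigenvectors.shape
    n_atoms = n3 // 3
    total = modes.eigenvalues.sum()
    norm = np.sqrt(total) if total > 0 else 1.0
    blocks = modes.eigenvectors.reshape(n_atoms, 3, d)  # e^(k)_i blocks
    weighted = blocks * np.sqrt(modes.eigenvalues)[None, None, :] / norm
    images = weighted.transpose(0, 2, 1).reshape(n_atoms, 3 * d)
    if atom_indices is None:
        atom_indices = np.arange(n_atoms)
    return AtomImages(
        segment_id=modes.segment_id,
        images=images,
        atom_indices=np.asarray(atom_indices),
        normalization=float(norm),
    )


def segment_images(
    traj: Trajectory,
    selection: Selection | np.ndarray,
    seg_len_ps: float = 200.0,
    window: tuple[float, float] | None = None,
    d: int = 10,
    align: bool = True,
) -> list[AtomImages]:
    """Per-segment atom images for a trajectory selection: the common input
    of the pair-correlation, flexibility and domain descriptors."""
    idx = selection.indices if isinstance(selection, Selection) else np.asarray(selection)
    out = []
    for k, (a, b) in enumerate(segment(traj, seg_len_ps, window)):
        C = covariance(traj.frames[a:b], idx, align=align)
        modes = essential_modes(C, d=min(d, C.shape[0]), segment_id=k)
        out.append(atom_images(modes, atom_indices=idx))
    return out


def pair_correlation(images_per_segment: list[AtomImages]) -> PairCorrelationMap:
    """rho_ij = mean over segments of ||chi_i - chi_j||; symmetric, zero
    diagonal.  Small rho marks strongly correlated motion."""
    if not images_per_segment:
        raise ValueError("need >= 1 segment of images")
    n = images_per_segment[0].n_atoms
    acc = np.zeros((n, n))
    for im in images_per_segment:
        acc += squareform(pdist(im.images))
    return PairCorrelationMap(
        atom_indices=images_per_segment[0].atom_indices,
        rho=acc / len(images_per_segment),
        n_segments=len(images_per_segment),
    )


def flexibility(
    images_per_segment: list[AtomImages],
    chain_labels: list,
    res_ids: np.ndarray,
) -> FlexibilityProfile:
    """f_i = mean over segments of ||chi_i - chi_bar||, chi_bar the centroid
    of the selection's images.  ``chain_labels``/``res_ids`` annotate each
    image row (typically the C-alpha of each residue)."""
    if not images_per_segment:
        raise ValueError("need >= 1 segment of images")
    n = images_per_segment[0].n_atoms
    acc = np.zeros(n)
    for im in images_per_segment:
        centroid = im.images.mean(axis=0)
        acc += np.linalg.norm(im.images - centroid, axis=1)
    return FlexibilityProfile(
        chain_labels=list(chain_labels),
        res_ids=np.asarray(res_ids),
        values=acc / len(images_per_segment),
        n_segments=len(images_per_segment),
    )


def abeta_cterminal_average(profile: FlexibilityProfile, abeta_chains: list) -> float:
    """Mean C-terminal flexibility over the Abeta chains of one trajectory."""
    return float(np.mean([profile.c_terminal_value(c) for c in abeta_chains]))


def domains(
    images: AtomImages | np.ndarray,
    threshold: float = 0.008,
    min_size: int = 20,
) -> DomainAssignment:
    """Domains of correlated motion: single-linkage clustering of images (or
    of a precomputed distance matrix) cut at ``threshold``; clusters smaller
    than ``min_size`` atoms are off-domain; ranks ordered by size."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(images, AtomImages):
        dist = pdist(images.images)
        atom_indices = images.atom_indices
        n = images.n_atoms
    else:
        mat = np.asarray(images, dtype=float)
        dist = squareform(mat, checks=False)
        atom_indices = np.arange(mat.shape[0])
        n = mat.shape[0]
    if n < 2:
        raise ValueError("need >= 2 atoms to cluster")
    Z = linkage(dist, method="single")
    raw = fcluster(Z, t=threshold, criterion="distance")
    sizes = [(c, int((raw == c).sum())) for c in np.unique(raw)]
    kept = [(c, s) for c, s in sizes if s >= min_size]
    kept.sort(key=lambda cs: -cs[1])
    domain_id = np.zeros(n, dtype=int)
    out_sizes = []
    for rank, (c, s) in enumerate(kept, start=1):
        domain_id[raw == c] = rank
        out_sizes.append(s)
    return DomainAssignment(atom_indices=np.asarray(atom_indices), domain_id=domain_id, sizes=out_sizes)


def detect_threshold(images: AtomImages | np.ndarray) -> float:
    """Data-driven clustering threshold: the midpoint of the largest
    multiplicative gap in the sorted single-linkage merge distances.  Useful
    because the image normalisation sets the scale of distances, so a fixed
    literature threshold only transfers between identically normalised
    pipelines."""
    if isinstance(images, AtomImages):
        dist = pdist(images.images)
    else:
        dist = squareform(np.asarray(images, dtype=float), checks=False)
    Z = linkage(dist, method="single")
    merge_d = np.sort(Z[:, 2])
    merge_d = merge_d[merge_d > 0]
    if len(merge_d) < 2:
        return float(merge_d[0] * 0.5) if len(merge_d) else 1e-6
    ratios = merge_d[1:] / merge_d[:-1]
    k = int(np.argmax(ratios))
    return float(np.sqrt(merge_d[k] * merge_d[k + 1]))
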