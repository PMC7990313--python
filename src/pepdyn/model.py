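"""Topology/coordinate data model, selections and rigid-body superposition.

All coordinates are stored in nanometres.  Unit conversion happens only at
format boundaries (:mod:`pepdyn.io`).  Atom indices are 0-based; residue
numbers are 1-based and contiguous within each chain, so that residue names
like K28 or V40 match the conventional amyloid-beta numbering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "ChainRecord",
    "MolecularSystem",
    "Trajectory",
    "Selection",
    "DegenerateSelectionError",
    "kabsch",
    "superpose",
    "AA_3TO1",
    "AA_1TO3",
    "KNOWN_SEQUENCES",
]


class Species(enum.Enum):
    """Peptide species recognised by the analysis pipeline.

    ABETA42/ABETA40 are the 42- and 40-residue amyloid-beta alloforms;
    SST14 is somatostatin-14 and AVP arginine vasopressin, the two small
    cyclic peptides (SCPs).  Anything else is OTHER and is excluded from
    species-classified censuses.
    """

    ABETA42 = "ABETA42"
    ABETA40 = "ABETA40"
    SST14 = "SST14"
    AVP = "AVP"
    OTHER = "OTHER"

    @property
    def expected_length(self) -> int | None:
        return {"ABETA42": 42, "ABETA40": 40, "SST14": 14, "AVP": 9}.get(self.value)

    @property
    def is_abeta(self) -> bool:
        return self in (Species.ABETA42, Species.ABETA40)

    @property
    def is_scp(self) -> bool:
        return self in (Species.SST14, Species.AVP)

    @property
    def display(self) -> str:
        return {
            "ABETA42": "Ab42",
            "ABETA40": "Ab40",
            "SST14": "SST14",
            "AVP": "AVP",
            "OTHER": "other",
        }[self.value]


ABETA42_SEQ = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
ABETA40_SEQ = ABETA42_SEQ[:40]
SST14_SEQ = "AGCKNFFWKTFTSC"
AVP_SEQ = "CYFENCPRG"

KNOWN_SEQUENCES: dict[str, Species] = {
    ABETA42_SEQ: Species.ABETA42,
    ABETA40_SEQ: Species.ABETA40,
    SST14_SEQ: Species.SST14,
    AVP_SEQ: Species.AVP,
}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


@dataclass(frozen=True)
class ChainRecord:
    """One peptide chain: single-letter label, species tag and sequence."""

    label: str
    species: Species
    sequence: str

    def __post_init__(self):
        exp = self.species.expected_length
        if exp is not None and len(self.sequence) != exp:
            raise ValueError(
                f"chain {self.label}: species {self.species.value} requires "
                f"{exp} residues, got {len(self.sequence)}"
            )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Selection:
    """Ordered, unique atom indices plus the expression that produced them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("selection indices must be unique and ascending")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


class DegenerateSelectionError(ValueError):
    """Raised when a superposition selection is collinear or coincident."""


@dataclass
class MolecularSystem:
    """Static description of a peptide mixture: chains, atoms, one coordinate set.

    Parameters
    ----------
    chains : ordered chain records (labels unique).
    atom_names, elements, res_ids, res_names, chain_ids : per-atom annotation
        arrays of equal length N.  ``res_ids`` are 1-based within each chain.
    coords : (N, 3) positions in nm.
    box : optional (3,) orthorhombic box lengths in nm.
    """

    chains: list[ChainRecord]
    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        for arr, name in [
            (self.elements, "elements"), (self.res_ids, "res_ids"),
            (self.res_names, "res_names"), (self.chain_ids, "chain_ids"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        labels = [c.label for c in self.chains]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate chain labels")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chain_labels(self) -> list[str]:
        return [c.label for c in self.chains]

    def chain(self, label: str) -> ChainRecord:
        for c in self.chains:
            if c.label == label:
                return c
        raise KeyError(f"no chain labelled {label!r}")

    def chain_atom_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.chain_ids == label)

    def species_map(self) -> dict[str, Species]:
        return {c.label: c.species for c in self.chains}

    # -- selections --------------------------------------------------------

    def select(
        self,
        chains: str | list[str] | None = None,
        residues: tuple[int, int] | None = None,
        names: set[str] | str | None = None,
        heavy: bool = False,
    ) -> Selection:
        """Select atoms by chain labels, 1-based residue range, atom names
        and/or heavy-atom filter.  Criteria combine conjunctively."""
        mask = np.ones(self.n_atoms, dtype=bool)
        parts = []
        if chains is not None:
            chains = list(chains)
            mask &= np.isin(self.chain_ids.astype(str), chains)
            parts.append(f"chains {''.join(chains)}")
        if residues is not None:
            lo, hi = residues
            mask &= (self.res_ids >= lo) & (self.res_ids <= hi)
            parts.append(f"residues {lo}-{hi}")
        if names is not None:
            if isinstance(names, str):
                names = {names}
            mask &= np.isin(self.atom_names.astype(str), sorted(names))
            parts.append(f"names {sorted(names)}")
        if heavy:
            mask &= self.elements.astype(str) != "H"
            parts.append("heavy")
        return Selection(np.flatnonzero(mask), " and ".join(parts) or "all")

    def ca_selection(self, chains: str | list[str] | None = None) -> Selection:
        return self.select(chains=chains, names="CA")

    # -- geometry helpers --------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def make_whole(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Undo periodic wrapping within each chain by minimum-image shifting
        every atom relative to the chain's first atom.  No-op without a box."""
        x = np.array(self.coords if coords is None else coords, dtype=float)
        if self.box is None:
            return x
        for lab in self.chain_labels:
            idx = self.chain_atom_indices(lab)
            if idx.size == 0:
                continue
            ref = x[idx[0]]
            d = x[idx] - ref
            x[idx] -= np.round(d / self.box) * self.box
        return x


@dataclass
class Trajectory:
    """Time-ordered coordinate frames bound to a :class:`MolecularSystem`.

    ``dt`` is the inter-frame spacing in ps and ``time_origin`` the time of
    frame 0 in ps.
    """

    system: MolecularSystem
    frames: np.ndarray
    dt: float = 1.0
    time_origin: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (T, N, 3) with T >= 1")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != system "
                f"{self.system.n_atoms}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.time_origin + self.dt * np.arange(self.n_frames)

    def window_frames(self, window: tuple[float, float]) -> np.ndarray:
        """Frame indices with time inside [t0, t1] ps (inclusive)."""
        t0, t1 = window
        t = self.times
        idx = np.flatnonzero((t >= t0 - 1e-9) & (t <= t1 + 1e-9))
        if idx.size == 0:
            raise ValueError(f"window ({t0}, {t1}) ps contains no frames")
        return idx


# -- rigid-body superposition ---------------------------------------------


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising RMSD of
    ``mobile @ R.T + t`` onto ``reference`` (Kabsch, via SVD)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _check_not_degenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise DegenerateSelectionError("superposition needs >= 3 atoms")
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1e-12) or s[0] < 1e-12:
        raise DegenerateSelectionError(
            "selection is collinear or coincident; rotation is underdetermined"
        )


def superpose(
    frames: np.ndarray,
    reference: np.ndarray,
    selection: Selection | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose each frame onto ``reference`` by the rigid motion that is
    optimal on ``selection``; returns (aligned frames, per-frame RMSD in nm,
    measured on the selection).

    Accepts a single (N, 3) frame or a (T, N, 3) stack.
    """
    x = np.asarray(frames, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    ref = np.asarray(reference, dtype=float)
    if selection is None:
        idx = np.arange(ref.shape[0])
    else:
        idx = selection.indices if isinstance(selection, Selection) else np.asarray(selection)
    _check_not_degenerate(ref[idx])
    aligned = np.empty_like(x)
    rmsd = np.empty(x.shape[0])
    for i, frame in enumerate(x):
        R, t = kabsch(frame[idx], ref[idx])
        aligned[i] = frame @ R.T + t
        rmsd[i] = float(np.sqrt(np.mean(np.sum((aligned[i][idx] - ref[idx]) ** 2, axis=1))))
    if single:
        return aligned[0], rmsd[0]
    return aligned, rmsd
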