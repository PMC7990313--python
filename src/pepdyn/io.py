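"""Readers/writers for structure and trajectory formats.

PDB (read/write, including multi-MODEL trajectories) and GRO (read) go
through biotite; XTC and DCD coordinate trajectories are adapted through
mdtraj's raw format readers, which need no topology.  All coordinates are
converted to nm at this boundary (biotite and DCD are in Angstrom, XTC and
GRO are natively nm).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .model import (
    AA_3TO1,
    ChainRecord,
    KNOWN_SEQUENCES,
    MolecularSystem,
    Species,
    Trajectory,
)

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
]

ANGSTROM_PER_NM = 10.0

# Standard PDB convention: element from the first alphabetic character of the
# atom name that is not a digit (covers N, CA, CB, OD1, 1HB, ...).
def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    for two in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        if stripped.upper().startswith(two) and len(stripped) > 1:
            return two.capitalize()
    return stripped[:1].upper() if stripped else "X"


class ParseError(ValueError):
    """A structure file failed to parse; the message names the line."""


def _validate_pdb_text(path: Path) -> None:
    """Light pre-scan so malformed coordinate records fail with a line number."""
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise ParseError(f"{path}: file is empty")
    for i, ln in enumerate(lines, start=1):
        if ln.startswith(("ATOM  ", "HETATM")):
            try:
                float(ln[30:38]); float(ln[38:46]); float(ln[46:54])
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}: malformed coordinate record at line {i}: {ln.rstrip()!r}"
                ) from None


def _sequence_of(res_names: list[str]) -> str:
    return "".join(AA_3TO1.get(rn, "X") for rn in res_names)


def _infer_species(sequence: str) -> Species:
    sp = KNOWN_SEQUENCES.get(sequence, Species.OTHER)
    if sp is Species.OTHER:
        log.warning(
            "chain sequence %r does not match any known species; tagged OTHER "
            "and excluded from species-classified censuses", sequence[:20]
        )
    return sp


def _system_from_atom_array(arr: "struc.AtomArray", box: np.ndarray | None) -> MolecularSystem:
    chain_ids = [str(c).strip() for c in arr.chain_id]
    if len(set(chain_ids)) <= 1:
        # Format without chain identifiers (GRO): split chains where the
        # residue numbering restarts.
        labels = []
        label_i = 0
        prev_rid = None
        for rid in arr.res_id:
            if prev_rid is not None and rid < prev_rid:
                label_i += 1
            prev_rid = rid
            labels.append(chr(ord("A") + label_i))
        chain_ids = labels
    elements = [
        str(e).capitalize() if str(e).strip() else _element_from_name(str(n))
        for e, n in zip(arr.element, arr.atom_name)
    ]
    # Renumber residues contiguously from 1 within each chain, preserving order.
    res_ids = np.zeros(arr.array_length(), dtype=int)
    chains: list[ChainRecord] = []
    seen: list[str] = []
    for lab in chain_ids:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        mask = np.array([c == lab for c in chain_ids])
        idx = np.flatnonzero(mask)
        res_names_chain: list[str] = []
        current = None
        num = 0
        for i in idx:
            key = (int(arr.res_id[i]), str(arr.ins_code[i]) if hasattr(arr, "ins_code") else "")
            if key != current:
                current = key
                num += 1
                res_names_chain.append(str(arr.res_name[i]))
            res_ids[i] = num
        seq = _sequence_of(res_names_chain)
        chains.append(ChainRecord(label=lab, species=_infer_species(seq), sequence=seq))
    return MolecularSystem(
        chains=chains,
        atom_names=np.array([str(n) for n in arr.atom_name], dtype=object),
        elements=np.array(elements, dtype=object),
        res_ids=res_ids,
        res_names=np.array([str(r) for r in arr.res_name], dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        coords=np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM,
        box=box,
    )


def _box_from_biotite(arr) -> np.ndarray | None:
    box = getattr(arr, "box", None)
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    if box.ndim == 3:
        box = box[0]
    lengths = np.linalg.norm(box, axis=1) / ANGSTROM_PER_NM
    if np.all(lengths < 1e-9):
        return None
    return lengths


def read_structure(path: str | os.PathLike, format: str | None = None) -> MolecularSystem:
    """Read a PDB or GRO file into a :class:`MolecularSystem`.

    Coordinates are converted to nm; chain species are inferred by exact
    sequence match against the known Abeta42/Abeta40/SST14/AVP sequences,
    anything else becomes OTHER.  Altloc records other than blank/'A' are
    ignored.  The first model of a multi-model PDB is used.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    if fmt == "pdb":
        _validate_pdb_text(path)
        try:
            pdb = PDBFile.read(str(path))
            arr = pdb.get_structure(model=1, altloc="first")
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ParseError(f"{path}: {exc}") from exc
        return _system_from_atom_array(arr, _box_from_biotite(arr))
    if fmt == "gro":
        try:
            gro = GROFile.read(str(path))
            arr = gro.get_structure(model=1)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path}: {exc}") from exc
        return _system_from_atom_array(arr, _box_from_biotite(arr))
    raise ValueError(f"unsupported structure format {fmt!r}")


def _atom_array_from_system(system: MolecularSystem, coords_nm: np.ndarray):
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=np.float32) * ANGSTROM_PER_NM
    arr.chain_id = np.array([str(c) for c in system.chain_ids], dtype="U4")
    arr.res_id = np.asarray(system.res_ids, dtype=int)
    arr.res_name = np.array([str(r) for r in system.res_names], dtype="U5")
    arr.atom_name = np.array([str(a) for a in system.atom_names], dtype="U6")
    arr.element = np.array([str(e).upper() for e in system.elements], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    if system.box is not None:
        arr.box = np.diag(system.box * ANGSTROM_PER_NM)
    return arr


def write_structure(system: MolecularSystem, path: str | os.PathLike) -> None:
    """Write a single-model PDB file (coordinates nm -> Angstrom)."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_system(system, system.coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a trajectory as multi-MODEL PDB or as XTC (nm)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        stack = struc.stack(
            [_atom_array_from_system(traj.system, f) for f in traj.frames]
        )
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
        return
    if fmt == "xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path), "w") as fh:
            box = traj.system.box
            fh.write(
                np.asarray(traj.frames, dtype=np.float32),
                time=np.asarray(traj.times, dtype=np.float32),
                step=np.arange(traj.n_frames),
                box=None if box is None else np.tile(np.diag(box), (traj.n_frames, 1, 1)).astype(np.float32),
            )
        return
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def read_trajectory(
    path: str | os.PathLike,
    system: MolecularSystem,
    format: str | None = None,
    dt: float | None = None,
    time_origin: float = 0.0,
) -> Trajectory:
    """Read a coordinate trajectory bound to ``system``.

    Multi-model PDB is the mandatory format; XTC and DCD are adapters via
    mdtraj's raw readers.  ``dt`` (ps) overrides any file metadata; when the
    file carries none (PDB, DCD) it defaults to 1 ps.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        _validate_pdb_text(path)
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="first")
        coords = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
        frames = coords[None] if coords.ndim == 2 else coords
        file_dt = None
        times = None
    elif fmt == "xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz, times, _step, _box = fh.read()
        frames = np.asarray(xyz, dtype=float)  # XTC is natively nm
        file_dt = float(times[1] - times[0]) if times is not None and len(times) > 1 else None
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _lengths, _angles = fh.read()
        frames = np.asarray(xyz, dtype=float) / ANGSTROM_PER_NM  # DCD is Angstrom
        file_dt = None
        times = None
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    if frames.shape[1] != system.n_atoms:
        raise ValueError(
            f"{path}: atom count mismatch: expected {system.n_atoms}, "
            f"found {frames.shape[1]}"
        )
    eff_dt = dt if dt is not None else (file_dt if file_dt else 1.0)
    origin = time_origin
    if dt is None and times is not None and len(times):
        origin = float(times[0])
    return Trajectory(system=system, frames=frames, dt=eff_dt, time_origin=origin)
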