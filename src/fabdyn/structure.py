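"""Structures, trajectories, residue selections and centers of mass.

Coordinates are held as plain numpy arrays inside :class:`StructureFrame`.
PDB parsing and writing (including the multi-model trajectory format) is
delegated to :mod:`biotite.structure.io.pdb`; everything downstream of the
parser is format-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    TopologyError,
    ValidationError,
)

# Monoisotopic-free standard atomic weights (amu) for the elements that occur
# in protein structures; anything else falls back to biotite's table.
_ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "NA": 22.99, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


def element_mass(element: str, atom_name: str = "") -> float:
    """Mass (amu) for an element symbol, falling back to the atom-name
    leading character when the element field is blank."""
    sym = element.strip().upper()
    if not sym:
        # PDB atom names start with the element for standard protein atoms.
        stripped = atom_name.strip().lstrip("0123456789")
        sym = stripped[:1].upper()
    if sym in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[sym]
    try:
        from biotite.structure.info import mass as _bt_mass

        m = _bt_mass(sym.capitalize(), is_residue=False)
        if m is not None and m > 0:
            return float(m)
    except Exception:
        pass
    raise ValidationError(f"cannot assign a mass to element {element!r} / atom {atom_name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom; mostly a convenience view into a StructureFrame."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    mass: float
    position: np.ndarray

    def __post_init__(self):
        if not self.mass > 0:
            raise ValidationError("atom mass must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError("atom position must be finite")


@dataclass
class StructureFrame:
    """One coordinate frame: parallel per-atom arrays plus frame metadata."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    ins_codes: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    frame_index: int = 0
    time_ps: float = 0.0

    def __post_init__(self):
        n = len(self.chain_ids)
        for arr in (self.res_ids, self.ins_codes, self.res_names,
                    self.atom_names, self.elements, self.masses):
            if len(arr) != n:
                raise ValidationError("inconsistent per-atom array lengths")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValidationError("coords must be (n_atoms, 3)")
        self.masses = np.asarray(self.masses, dtype=float)
        if n and not np.all(self.masses > 0):
            raise ValidationError("all atom masses must be positive")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValidationError("all coordinates must be finite")
        if self.time_ps < 0:
            raise ValidationError("frame time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            chain_id=str(self.chain_ids[i]),
            residue_number=int(self.res_ids[i]),
            insertion_code=str(self.ins_codes[i]),
            residue_name=str(self.res_names[i]),
            atom_name=str(self.atom_names[i]),
            element=str(self.elements[i]),
            mass=float(self.masses[i]),
            position=self.coords[i].copy(),
        )

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None,
                    time_ps: float | None = None) -> "StructureFrame":
        """Copy of this frame with replaced coordinates (same atoms)."""
        return StructureFrame(
            chain_ids=self.chain_ids, res_ids=self.res_ids,
            ins_codes=self.ins_codes, res_names=self.res_names,
            atom_names=self.atom_names, elements=self.elements,
            masses=self.masses, coords=np.asarray(coords, dtype=float),
            frame_index=self.frame_index if frame_index is None else frame_index,
            time_ps=self.time_ps if time_ps is None else time_ps,
        )


def _frame_from_atom_array(arr: bts.AtomArray, frame_index: int,
                           time_ps: float) -> StructureFrame:
    elements = np.asarray(arr.element, dtype="U4")
    names = np.asarray(arr.atom_name, dtype="U6")
    masses = np.array(
        [element_mass(e, a) for e, a in zip(elements, names)], dtype=float
    )
    ins = (np.asarray(arr.ins_code, dtype="U2")
           if "ins_code" in arr.get_annotation_categories()
           else np.full(arr.array_length(), "", dtype="U2"))
    return StructureFrame(
        chain_ids=np.asarray(arr.chain_id, dtype="U4"),
        res_ids=np.asarray(arr.res_id, dtype=int),
        ins_codes=ins,
        res_names=np.asarray(arr.res_name, dtype="U5"),
        atom_names=names,
        elements=elements,
        masses=masses,
        coords=np.asarray(arr.coord, dtype=float),
        frame_index=frame_index,
        time_ps=time_ps,
    )


def _load_pdb(path) -> tuple[PDBFile, int]:
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if n_models == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    return pdb, n_models


def _check_model_order(path) -> None:
    """Warn (do not fail) if MODEL serial numbers are out of order."""
    serials = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                try:
                    serials.append(int(line.split()[1]))
                except (IndexError, ValueError):
                    return
    if serials and any(b <= a for a, b in zip(serials, serials[1:])):
        warnings.warn(
            f"{path}: MODEL numbers are not strictly increasing; "
            "frames are used in file order", stacklevel=3)


def read_models(path, protein_only: bool = False,
                dt_ps: float = 1.0) -> list[StructureFrame]:
    """Read all MODELs of a PDB file as StructureFrames.

    Times are assigned as ``frame_index * dt_ps``; atom order is identical
    across models (guaranteed by the multi-model PDB format).
    """
    pdb, n_models = _load_pdb(path)
    _check_model_order(path)
    frames = []
    for i in range(1, n_models + 1):
        arr = pdb.get_structure(model=i)
        if protein_only:
            arr = arr[bts.filter_amino_acids(arr)]
        if arr.array_length() == 0:
            raise EmptyStructureError(
                f"{path}: model {i} has no atoms"
                + (" after protein-only filtering" if protein_only else ""))
        frames.append(_frame_from_atom_array(arr, i - 1, (i - 1) * dt_ps))
    return frames


def read_structure(path, protein_only: bool = False,
                   model: int | None = None) -> StructureFrame:
    """Read one model of a PDB file (the first, unless ``model`` is given)."""
    pdb, n_models = _load_pdb(path)
    idx = 1 if model is None else model
    if not 1 <= idx <= n_models:
        raise ValidationError(f"model {idx} out of range 1..{n_models}")
    arr = pdb.get_structure(model=idx)
    if protein_only:
        arr = arr[bts.filter_amino_acids(arr)]
    if arr.array_length() == 0:
        raise EmptyStructureError(
            f"{path}: no atoms"
            + (" after protein-only filtering" if protein_only else ""))
    return _frame_from_atom_array(arr, idx - 1, 0.0)


def read_trajectory(topology, traj, dt_ps: float,
                    equilibration_frames_discarded: int = 0,
                    protein_only: bool = False) -> list[StructureFrame]:
    """Read a multi-model PDB trajectory against a (single-model) topology.

    The first ``equilibration_frames_discarded`` frames are dropped and the
    retained frames are re-indexed and re-timed from zero (spectra depend on
    dt only, not on the absolute time origin).
    """
    if not dt_ps > 0:
        raise ValidationError(f"dt must be positive, got {dt_ps}")
    if equilibration_frames_discarded < 0:
        raise ValidationError("equilibration_frames_discarded must be >= 0")
    top = read_structure(topology, protein_only=protein_only)
    frames = read_models(traj, protein_only=protein_only, dt_ps=dt_ps)
    for f in frames:
        if f.n_atoms != top.n_atoms:
            raise TopologyError(
                f"trajectory frame {f.frame_index} has {f.n_atoms} atoms, "
                f"topology has {top.n_atoms}")
    kept = frames[equilibration_frames_discarded:]
    return [
        f.with_coords(f.coords, frame_index=i, time_ps=i * dt_ps)
        for i, f in enumerate(kept)
    ]


def _to_atom_array(frame: StructureFrame) -> bts.AtomArray:
    arr = bts.AtomArray(frame.n_atoms)
    arr.chain_id = frame.chain_ids
    arr.res_id = frame.res_ids
    arr.ins_code = frame.ins_codes
    arr.res_name = frame.res_names
    arr.atom_name = frame.atom_names
    arr.element = frame.elements
    arr.hetero = np.zeros(frame.n_atoms, dtype=bool)
    arr.coord = frame.coords.astype(np.float32)
    return arr


def write_pdb(frames: StructureFrame | Sequence[StructureFrame], path) -> None:
    """Write one frame as a single-model PDB, or several as multi-model."""
    if isinstance(frames, StructureFrame):
        frames = [frames]
    if not frames:
        raise ValidationError("no frames to write")
    stack = bts.stack([_to_atom_array(f) for f in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Residue selections


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive residue-number ranges on one chain.

    Insertion-coded residues sort within their parent number, so residue
    100A is inside the range [100, 101].
    """

    chain_id: str
    ranges: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self):
        if not self.ranges:
            raise ValidationError(f"selection {self.name!r}: no ranges")
        norm = []
        for lo, hi in self.ranges:
            lo, hi = int(lo), int(hi)
            if lo > hi:
                raise ValidationError(
                    f"selection {self.name!r}: inverted range [{lo}, {hi}]")
            norm.append((lo, hi))
        object.__setattr__(self, "ranges", tuple(norm))

    def contains(self, res_id: int) -> bool:
        return any(lo <= res_id <= hi for lo, hi in self.ranges)

    def overlaps(self, other: "ResidueSelection") -> bool:
        if self.chain_id != other.chain_id:
            return False
        return any(
            a_lo <= b_hi and b_lo <= a_hi
            for a_lo, a_hi in self.ranges
            for b_lo, b_hi in other.ranges
        )

    def covers(self, other: "ResidueSelection") -> bool:
        """True if every residue of `other` is inside this selection."""
        if self.chain_id != other.chain_id:
            return False
        return all(
            any(a_lo <= b_lo and b_hi <= a_hi for a_lo, a_hi in self.ranges)
            for b_lo, b_hi in other.ranges
        )

    @property
    def span(self) -> tuple[int, int]:
        return min(lo for lo, _ in self.ranges), max(hi for _, hi in self.ranges)


def resolve_selection(frame: StructureFrame, sel: ResidueSelection) -> np.ndarray:
    """Indices of the frame's atoms matched by the selection, in frame order."""
    if not np.any(frame.chain_ids == sel.chain_id):
        raise EmptySelectionError(
            f"selection {sel.name!r}: chain {sel.chain_id!r} not in frame")
    mask = frame.chain_ids == sel.chain_id
    in_range = np.zeros(frame.n_atoms, dtype=bool)
    for lo, hi in sel.ranges:
        in_range |= (frame.res_ids >= lo) & (frame.res_ids <= hi)
    idx = np.nonzero(mask & in_range)[0]
    if idx.size == 0:
        raise EmptySelectionError(
            f"selection {sel.name!r} ({sel.chain_id} {sel.ranges}) matched no atoms")
    return idx


def center_of_mass(frame: StructureFrame, indices: np.ndarray,
                   weighting: str = "mass") -> np.ndarray:
    """COM of an atom subset: Σmᵢrᵢ/Σmᵢ, or the unweighted mean ("geometric")."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise EmptySelectionError("center of mass of an empty atom subset")
    pos = frame.coords[indices]
    if weighting == "geometric":
        return pos.mean(axis=0)
    if weighting != "mass":
        raise ValidationError(f"unknown COM weighting {weighting!r}")
    m = frame.masses[indices]
    return (m[:, None] * pos).sum(axis=0) / m.sum()
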