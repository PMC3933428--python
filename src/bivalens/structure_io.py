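"""Structures, ensembles, atom selections and PDB input/output.

The in-memory currency of the pipeline is :class:`Structure` — a flat,
ordered table of atom records (identity fields + coordinates in Å + optional
van der Waals radii).  Multi-model PDB files become :class:`Ensemble` objects
whose frames are guaranteed to share an identical atom-identity sequence, so
that downstream superposition and docking can pair atoms by position.

PDB parsing and serialisation are delegated to :mod:`biotite`; this module
adds the identity bookkeeping the pipeline relies on (per-model topology
verification, explicit empty-selection errors, line-numbered parse errors).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptySelectionError,
    FormatError,
    PDBParseError,
    RadiusAssignmentError,
    TopologyError,
)

logger = logging.getLogger(__name__)

#: Standard single-atom van der Waals radii (Å), Bondi-style values.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

#: Residue names treated as water and dropped on read.
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "TIP3", "SOL"})


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """An ordered set of atom records for one model.

    All identity arrays have length ``n_atoms`` and ``coord`` has shape
    ``(n_atoms, 3)`` in Å.  ``radius`` is ``None`` until
    :func:`assign_radii` populates it.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    icode: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    radius: np.ndarray | None = None
    model_id: int = 1

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=np.float64).reshape(-1, 3)
        n = self.coord.shape[0]
        self.serial = np.asarray(self.serial, dtype=np.int64)
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.icode = np.asarray(self.icode, dtype="U1")
        self.element = np.asarray(self.element, dtype="U2")
        for name in ("serial", "atom_name", "res_name", "chain_id",
                     "res_id", "icode", "element"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"field {name!r} length != atom count {n}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinates must be finite")
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=np.float64)
            if self.radius.shape != (n,):
                raise ValueError("radius length != atom count")

    def __len__(self) -> int:
        return self.coord.shape[0]

    # -- identity -----------------------------------------------------------

    def identity(self) -> list[tuple[str, int, str, str]]:
        """(chain_id, res_id, icode, atom_name) per atom, in order."""
        return list(zip(self.chain_id.tolist(), self.res_id.tolist(),
                        self.icode.tolist(), self.atom_name.tolist()))

    def residue_identity(self) -> list[tuple[int, str, str]]:
        """(res_id, icode, atom_name) per atom — identity ignoring chain."""
        return list(zip(self.res_id.tolist(), self.icode.tolist(),
                        self.atom_name.tolist()))

    # -- derived copies -----------------------------------------------------

    def copy(self) -> "Structure":
        return Structure(
            serial=self.serial.copy(), atom_name=self.atom_name.copy(),
            res_name=self.res_name.copy(), chain_id=self.chain_id.copy(),
            res_id=self.res_id.copy(), icode=self.icode.copy(),
            element=self.element.copy(), coord=self.coord.copy(),
            radius=None if self.radius is None else self.radius.copy(),
            model_id=self.model_id,
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=np.intp)
        return Structure(
            serial=self.serial[idx], atom_name=self.atom_name[idx],
            res_name=self.res_name[idx], chain_id=self.chain_id[idx],
            res_id=self.res_id[idx], icode=self.icode[idx],
            element=self.element[idx], coord=self.coord[idx],
            radius=None if self.radius is None else self.radius[idx],
            model_id=self.model_id,
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        out = self.copy()
        out.coord = np.asarray(coord, dtype=np.float64).reshape(len(self), 3)
        return out

    def with_chain_id(self, chain_id: str) -> "Structure":
        out = self.copy()
        out.chain_id = np.full(len(self), chain_id, dtype="U4")
        return out

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element) != "H"


def concat_structures(parts: Sequence[Structure], model_id: int = 1) -> Structure:
    """Concatenate structures in order; serials are renumbered from 1."""
    n = sum(len(p) for p in parts)
    radii = None
    if all(p.radius is not None for p in parts):
        radii = np.concatenate([p.radius for p in parts])
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.concatenate([p.atom_name for p in parts]),
        res_name=np.concatenate([p.res_name for p in parts]),
        chain_id=np.concatenate([p.chain_id for p in parts]),
        res_id=np.concatenate([p.res_id for p in parts]),
        icode=np.concatenate([p.icode for p in parts]),
        element=np.concatenate([p.element for p in parts]),
        coord=np.concatenate([p.coord for p in parts]),
        radius=radii,
        model_id=model_id,
    )


@dataclass
class Ensemble:
    """An ordered sequence of frames sharing identical topology."""

    frames: list[Structure]
    trajectory_id: str = "traj"
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        ref = self.frames[0].identity()
        for k, frame in enumerate(self.frames[1:], start=1):
            if frame.identity() != ref:
                raise TopologyError(
                    f"frame {k} of trajectory {self.trajectory_id!r} has a "
                    "different atom identity sequence than frame 0"
                )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
            if self.frame_times.shape != (len(self.frames),):
                raise ValueError("frame_times length != frame count")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def time_of(self, index: int) -> float:
        if self.frame_times is None:
            return float(index)
        return float(self.frame_times[index])


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Declarative atom selection with intersection semantics.

    A criterion left as ``None`` matches every atom for that field.
    ``residue_ranges`` are inclusive 1-based ``(start, stop)`` intervals in
    PDB author numbering.
    """

    chain_ids: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None

    @staticmethod
    def make(chains: Iterable[str] | None = None,
             residues: Iterable[tuple[int, int]] | None = None,
             atoms: Iterable[str] | None = None) -> "Selection":
        return Selection(
            chain_ids=None if chains is None else frozenset(chains),
            residue_ranges=None if residues is None
            else tuple(tuple(r) for r in residues),
            atom_names=None if atoms is None else frozenset(atoms),
        )

    def mask(self, structure: Structure) -> np.ndarray:
        m = np.ones(len(structure), dtype=bool)
        if self.chain_ids is not None:
            m &= np.isin(structure.chain_id, sorted(self.chain_ids))
        if self.residue_ranges is not None:
            rm = np.zeros(len(structure), dtype=bool)
            for lo, hi in self.residue_ranges:
                rm |= (structure.res_id >= lo) & (structure.res_id <= hi)
            m &= rm
        if self.atom_names is not None:
            m &= np.isin(structure.atom_name, sorted(self.atom_names))
        return m

    def resolve(self, structure: Structure) -> np.ndarray:
        """Strictly increasing atom indices; raises on an empty match."""
        idx = np.flatnonzero(self.mask(structure))
        if idx.size == 0:
            raise EmptySelectionError(f"selection {self} matched no atoms")
        return idx


def resolve_selection(structure: Structure, selection: Selection) -> np.ndarray:
    """Functional alias for :meth:`Selection.resolve`."""
    return selection.resolve(structure)


# ---------------------------------------------------------------------------
# Radii
# ---------------------------------------------------------------------------

def assign_radii(structure: Structure,
                 radius_table: dict[str, float] | None = None,
                 default: float | None = None) -> Structure:
    """Return a copy with van der Waals radii filled in by element.

    An element missing from the table raises unless ``default`` is given,
    in which case the default is used and a warning logged.
    """
    table = {k.upper(): float(v)
             for k, v in (radius_table or DEFAULT_RADII).items()}
    out = structure.copy()
    radii = np.empty(len(structure), dtype=np.float64)
    for i, elem in enumerate(np.char.upper(structure.element)):
        if elem in table:
            radii[i] = table[elem]
        elif default is not None:
            logger.warning("element %r not in radius table; using default %.2f Å",
                           str(elem), default)
            radii[i] = float(default)
        else:
            raise RadiusAssignmentError(
                f"element {str(elem)!r} not in radius table and no default set"
            )
    if np.any(radii <= 0):
        raise RadiusAssignmentError("van der Waals radii must be positive")
    out.radius = radii
    return out


def read_radius_table(source: Union[str, Path, TextIO]) -> dict[str, float]:
    """Read a two-column (element, radius Å) text table; '#' starts a comment."""
    text = _read_text(source)
    table: dict[str, float] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"radius table line {ln}: expected 'ELEMENT RADIUS'")
        table[parts[0].upper()] = float(parts[1])
    return table


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _read_text(source: Union[str, Path, TextIO]) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    return source.read()


def _prescan(text: str) -> None:
    """Validate fixed-column numeric fields so errors can name a line."""
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError("coordinate record shorter than 54 columns", ln)
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"malformed {what} coordinate field {line[lo:hi]!r}", ln
                ) from None


def _from_atom_array(arr: "struc.AtomArray", model_id: int) -> Structure:
    serial = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, arr.array_length() + 1))
    return Structure(
        serial=serial,
        atom_name=arr.atom_name,
        res_name=arr.res_name,
        chain_id=arr.chain_id,
        res_id=arr.res_id,
        icode=arr.ins_code,
        element=arr.element,
        coord=arr.coord,
        model_id=model_id,
    )


def _altloc_keep_mask(arr: "struc.AtomArray") -> np.ndarray:
    """Per-atom alt-loc resolution: highest occupancy, ties to the first.

    Atoms are grouped by (chain, residue, insertion code, atom name); within
    each group the record with the highest occupancy wins and earlier file
    order breaks ties.  Atoms without an alternate location always survive.
    """
    n = arr.array_length()
    if "altloc_id" not in arr.get_annotation_categories():
        return np.ones(n, dtype=bool)
    occupancy = (arr.occupancy if "occupancy"
                 in arr.get_annotation_categories()
                 else np.ones(n))
    best: dict[tuple, int] = {}
    for i in range(n):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]),
               str(arr.ins_code[i]), str(arr.atom_name[i]))
        j = best.get(key)
        if j is None or occupancy[i] > occupancy[j]:
            best[key] = i
    keep = np.zeros(n, dtype=bool)
    keep[list(best.values())] = True
    return keep


def read_pdb(source: Union[str, Path, TextIO],
             model_policy: str = "first",
             include_hetero: bool = False,
             trajectory_id: str = "traj") -> Union[Structure, Ensemble]:
    """Read a PDB file or stream.

    With ``model_policy="first"`` returns the first MODEL as a
    :class:`Structure`; with ``"all"`` returns an :class:`Ensemble` whose
    frames are verified to share identical topology.  HETATM records and
    waters are excluded unless ``include_hetero`` is set (waters are always
    excluded).  Alternate locations are resolved to the highest occupancy,
    ties going to the first encountered.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    text = _read_text(source)
    _prescan(text)
    try:
        pdb = PDBFile.read(io.StringIO(text))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite failure without line info
        raise PDBParseError(str(exc)) from exc
    if n_models == 0:
        raise PDBParseError("no ATOM records found")

    def get_model(i: int) -> Structure:
        arr = pdb.get_structure(model=i, altloc="all",
                                extra_fields=["atom_id", "occupancy"])
        keep = ~np.isin(arr.res_name, sorted(WATER_RESIDUES))
        if not include_hetero:
            keep &= ~arr.hetero
        arr = arr[keep]
        arr = arr[_altloc_keep_mask(arr)]
        if arr.array_length() == 0:
            raise PDBParseError(f"model {i} contains no selected atoms")
        st = _from_atom_array(arr, model_id=i)
        ident = st.identity()
        if len(set(ident)) != len(ident):
            raise PDBParseError(
                f"model {i}: duplicate (chain, residue, insertion code, atom "
                "name) after alt-loc resolution"
            )
        return st

    if model_policy == "first":
        return get_model(1)
    frames = [get_model(i) for i in range(1, n_models + 1)]
    return Ensemble(frames=frames, trajectory_id=trajectory_id)


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _to_atom_array(st: Structure) -> "struc.AtomArray":
    bad = np.char.str_len(st.chain_id) > 1
    if np.any(bad):
        raise FormatError(
            f"chain id {st.chain_id[bad][0]!r} longer than one character"
        )
    if np.any(st.coord >= 10000.0) or np.any(st.coord <= -1000.0):
        raise FormatError("coordinate out of PDB fixed-width range "
                          "(-999.999 … 9999.999 Å)")
    arr = struc.AtomArray(len(st))
    arr.coord = st.coord.astype(np.float32)
    arr.chain_id = st.chain_id.astype("U4")
    arr.res_id = st.res_id.copy()
    arr.res_name = st.res_name.astype("U5")
    arr.atom_name = st.atom_name.astype("U6")
    arr.element = st.element.astype("U2")
    arr.set_annotation("ins_code", st.icode.astype("U1"))
    arr.set_annotation("hetero", np.zeros(len(st), dtype=bool))
    return arr


def write_pdb(obj: Union[Structure, Ensemble],
              sink: Union[str, Path, TextIO]) -> None:
    """Write a Structure (single model) or Ensemble (MODEL/ENDMDL blocks).

    Round-tripping through :func:`read_pdb` reproduces identity fields
    exactly and coordinates to the format precision of 0.001 Å.
    """
    pdb = PDBFile()
    if isinstance(obj, Structure):
        pdb.set_structure(_to_atom_array(obj))
    else:
        arrays = [_to_atom_array(f) for f in obj.frames]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    if isinstance(sink, (str, Path)):
        pdb.write(str(sink))
    else:
        pdb.write(sink)
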