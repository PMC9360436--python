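"""Multi-model PDB structures, atom metadata and atom selections.

The classes here are the carriers shared by every analysis stage: a
:class:`Structure` is one set of coordinates (a crystal structure or a
single trajectory frame), an :class:`Ensemble` is an ordered stack of
frames over a shared topology, and an :class:`AtomSelection` names the
atoms (chain, residue ranges, atom names) that a superposition or a
contact analysis should operate on.

Coordinates are in Angstroms throughout.  Residue numbering is taken
verbatim from the file (author numbering, insertion codes honored);
phosphoresidues such as SEP/TPO arrive as HETATM records and are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "AtomSelection",
    "PDBParseError",
    "TopologyMismatchError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "resolve_selection",
    "match_selections",
]

# Two-letter element symbols that legitimately appear in protein PDB files;
# used only when the element column is blank and the name must be decoded.
_TWO_LETTER_ELEMENTS = {"FE", "ZN", "MG", "MN", "NA", "CL", "BR", "CU", "NI", "CO", "SE", "CD", "HG"}


class PDBParseError(ValueError):
    """Raised for malformed PDB records; message names the line number."""


class TopologyMismatchError(ValueError):
    """Raised when MODEL blocks of one file disagree on their atoms."""


class EmptySelectionError(ValueError):
    """Raised when a selection matches no atoms of a structure."""


@dataclass(frozen=True)
class Atom:
    """One atom's metadata (coordinates live on the Structure/Ensemble)."""

    serial: int
    name: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    element: str
    occupancy: float = 1.0
    record: str = "ATOM"  # "ATOM" or "HETATM"

    def key(self) -> tuple:
        """Identity of the atom within one model (uniqueness invariant)."""
        return (self.chain_id, self.residue_number, self.insertion_code, self.name, self.alt_loc)

    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class Structure:
    """An atom list with one set of 3-D coordinates (Angstrom)."""

    atoms: list[Atom]
    coordinates: np.ndarray  # (n_atoms, 3) float64
    model_id: int = 1
    title: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate block shape {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("structure contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure(list(self.atoms), self.coordinates.copy(), self.model_id, self.title)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        new = self.copy()
        new.coordinates = self.coordinates @ np.asarray(rotation).T + np.asarray(translation)
        return new


@dataclass
class Ensemble:
    """Frames over a shared topology (a trajectory, or a multi-model file)."""

    topology: list[Atom]
    frames: list[np.ndarray]
    run_id: str = ""
    frame_stride_ns: float = 0.0  # 0 = unknown

    def __post_init__(self) -> None:
        if self.frame_stride_ns < 0:
            raise ValueError("frame_stride_ns must be >= 0")
        n = len(self.topology)
        clean = []
        for i, fr in enumerate(self.frames):
            fr = np.asarray(fr, dtype=float)
            if fr.shape != (n, 3):
                raise TopologyMismatchError(
                    f"frame {i} has shape {fr.shape}, expected ({n}, 3)"
                )
            clean.append(fr)
        self.frames = clean

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def get_frame(self, index: int, title: str = "") -> Structure:
        return Structure(self.topology, self.frames[index].copy(), model_id=index + 1, title=title)

    @classmethod
    def from_structure(cls, structure: Structure, run_id: str = "") -> "Ensemble":
        return cls(list(structure.atoms), [structure.coordinates.copy()], run_id=run_id)


@dataclass(frozen=True)
class AtomSelection:
    """Chain + inclusive residue ranges + atom names.

    ``residue_ranges`` is normalized on construction: ranges are sorted,
    merged when overlapping or adjacent-with-overlap, and each must satisfy
    start <= end.  Resolution against a structure is deterministic and
    returns indices in file order.
    """

    residue_ranges: tuple[tuple[int, int], ...]
    chain_id: str | None = None
    atom_names: frozenset[str] = frozenset({"CA"})
    label: str = ""

    def __init__(
        self,
        residue_ranges: Iterable[Sequence[int]],
        chain_id: str | None = None,
        atom_names: Iterable[str] = ("CA",),
        label: str = "",
    ) -> None:
        ranges = []
        for r in residue_ranges:
            start, end = int(r[0]), int(r[1])
            if start > end:
                raise ValueError(f"selection range start {start} > end {end}")
            ranges.append((start, end))
        ranges.sort()
        merged: list[tuple[int, int]] = []
        for start, end in ranges:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        object.__setattr__(self, "residue_ranges", tuple(merged))
        object.__setattr__(self, "chain_id", chain_id)
        object.__setattr__(self, "atom_names", frozenset(str(n) for n in atom_names))
        object.__setattr__(self, "label", label)

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.atom_names and atom.name not in self.atom_names:
            return False
        return any(a <= atom.residue_number <= b for a, b in self.residue_ranges)

    @classmethod
    def from_dict(cls, d: dict) -> "AtomSelection":
        """Build from the YAML/JSON config shape {label, chain, ranges, atoms}."""
        return cls(
            residue_ranges=d["ranges"],
            chain_id=d.get("chain"),
            atom_names=d.get("atoms", ["CA"]),
            label=d.get("label", ""),
        )


def _infer_element(name: str, record: str, residue_name: str) -> str:
    """Best-effort element from the atom-name columns when col 77-78 is blank."""
    stripped = name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit():  # e.g. 1HB2
        return "H"
    upper = stripped.upper()
    if record == "HETATM" and upper[:2] in _TWO_LETTER_ELEMENTS and residue_name.strip() == upper[:2]:
        return upper[:2].capitalize()
    return upper[0]


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than coordinate columns")
    record = line[0:6].strip()
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serials above 99999 are sometimes starred; tolerate
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip()
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed residue number {line[22:26]!r}") from exc
    insertion_code = line[26].strip()
    try:
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate field {line[30:54]!r}") from exc
    try:
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError:
        occupancy = 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name, record, residue_name)
    element = element[0].upper() + element[1:].lower() if len(element) > 1 else element.upper()
    atom = Atom(
        serial=serial,
        name=name,
        alt_loc=alt_loc,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        insertion_code=insertion_code,
        element=element,
        occupancy=min(max(occupancy, 0.0), 1.0),
        record=record,
    )
    return atom, xyz


def _apply_altloc_policy(
    atoms: list[Atom], coords: list[np.ndarray], policy: str
) -> tuple[list[Atom], list[np.ndarray]]:
    """Keep exactly one alternate location per atom site.

    ``first`` keeps the first occurrence in file order; ``highest_occupancy``
    keeps the highest-occupancy location, ties broken by alphabetical alt_loc.
    The surviving atom has its alt_loc cleared so site keys stay unique.
    """
    site_key = lambda a: (a.chain_id, a.residue_number, a.insertion_code, a.name)
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i, a in enumerate(atoms):
        k = site_key(a)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)
    out_atoms: list[Atom] = []
    out_coords: list[np.ndarray] = []
    for k in order:
        idxs = groups[k]
        if len(idxs) == 1:
            pick = idxs[0]
        elif policy == "first":
            pick = idxs[0]
        elif policy == "highest_occupancy":
            pick = min(idxs, key=lambda i: (-atoms[i].occupancy, atoms[i].alt_loc))
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
        out_atoms.append(replace(atoms[pick], alt_loc=""))
        out_coords.append(coords[pick])
    return out_atoms, out_coords


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One frame per MODEL block; a file without MODEL records yields exactly
    one frame.  HETATM residues (SEP, TPO, waters, ligands) are retained.
    Alternate locations are collapsed per ``altloc_policy``
    ("first" or "highest_occupancy", default).
    """
    path = Path(path)
    title = ""
    model_atoms: list[Atom] = []
    model_coords: list[np.ndarray] = []
    models: list[tuple[list[Atom], list[np.ndarray]]] = []
    in_model = False
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_atom_line(line, lineno)
                model_atoms.append(atom)
                model_coords.append(xyz)
            elif rec == "MODEL":
                saw_model_record = True
                in_model = True
                model_atoms, model_coords = [], []
            elif rec == "ENDMDL":
                in_model = False
                models.append((model_atoms, model_coords))
                model_atoms, model_coords = [], []
            elif rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
    if model_atoms or not models:
        if model_atoms:
            models.append((model_atoms, model_coords))
    if not models or not models[0][0]:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    frames: list[np.ndarray] = []
    topology: list[Atom] | None = None
    ref_keys: list[tuple] | None = None
    for i, (atoms, coords) in enumerate(models):
        atoms, coords = _apply_altloc_policy(atoms, coords, altloc_policy)
        keys = [a.key() for a in atoms]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise PDBParseError(f"{path}: duplicate atom sites within one model: {dupes[:5]}")
        if topology is None:
            topology = atoms
            ref_keys = keys
        elif keys != ref_keys:
            raise TopologyMismatchError(
                f"{path}: model {i + 1} has {len(atoms)} atoms / different sites than model 1 "
                f"({len(topology)} atoms)"
            )
        frames.append(np.array(coords))
    assert topology is not None
    # saw_model_record noted for symmetry with the writer; single-frame files
    # round-trip identically either way.
    del saw_model_record
    return Ensemble(topology=topology, frames=frames, run_id=path.stem)


def _format_atom_line(atom: Atom, xyz: np.ndarray, serial: int) -> str:
    if np.any(np.abs(xyz) > 9999.999):
        raise ValueError(
            f"coordinate magnitude {np.abs(xyz).max():.1f} A exceeds the PDB fixed-column "
            "limit of 9999.999"
        )
    name = atom.name
    if len(name) < 4:
        # standard left-padding for short names with 1-letter elements
        name = f" {name}" if len(atom.element) == 1 else name
    record = atom.record if atom.record in ("ATOM", "HETATM") else "ATOM"
    return (
        f"{record:<6}{serial % 100000:>5} {name:<4}{atom.alt_loc or '':1}"
        f"{atom.residue_name:>3} {atom.chain_id or 'A':1}{atom.residue_number:>4}"
        f"{atom.insertion_code or '':1}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )


def write_pdb(ensemble: Ensemble | Structure, path: str | Path) -> None:
    """Write fixed-column PDB; multi-frame ensembles get MODEL/ENDMDL blocks.

    Single-frame output is written without MODEL records (crystal-structure
    convention); multi-frame always with.  Coordinates beyond 9999.999 A in
    magnitude are refused (column overflow).
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble.from_structure(ensemble)
    path = Path(path)
    lines: list[str] = []
    multi = ensemble.n_frames > 1
    for fi, frame in enumerate(ensemble.frames):
        if multi:
            lines.append(f"MODEL     {fi + 1:>4}")
        for ai, atom in enumerate(ensemble.topology):
            lines.append(_format_atom_line(atom, frame[ai], serial=ai + 1))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def resolve_selection(structure: Structure | Ensemble | list[Atom], selection: AtomSelection) -> np.ndarray:
    """Resolve a selection to strictly increasing atom indices.

    Accepts a Structure, an Ensemble (topology is shared by all frames) or a
    bare atom list.  Raises :class:`EmptySelectionError` on zero matches:
    downstream superposition needs at least 3 non-collinear atoms, so an
    empty result is never useful.
    """
    if isinstance(structure, Structure):
        atoms = structure.atoms
    elif isinstance(structure, Ensemble):
        atoms = structure.topology
    else:
        atoms = structure
    idx = np.array([i for i, a in enumerate(atoms) if selection.matches(a)], dtype=int)
    if idx.size == 0:
        raise EmptySelectionError(
            f"selection {selection.label or selection.residue_ranges} matched no atoms"
        )
    return idx


def match_selections(
    atoms_a: list[Atom],
    atoms_b: list[Atom],
    selection: AtomSelection,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve ``selection`` in two structures and pair atoms one-to-one.

    Atoms are matched by (chain, residue number, insertion code, atom name).
    Raises a correspondence error listing the unmatched residues if the two
    structures do not agree on the selection.
    """
    ia = resolve_selection(atoms_a, selection)
    ib = resolve_selection(atoms_b, selection)
    key = lambda a: (a.chain_id, a.residue_number, a.insertion_code, a.name)
    map_b = {key(atoms_b[i]): i for i in ib}
    out_a, out_b = [], []
    missing = []
    for i in ia:
        k = key(atoms_a[i])
        if k in map_b:
            out_a.append(i)
            out_b.append(map_b[k])
        else:
            missing.append(k)
    extra = [key(atoms_b[i]) for i in ib if key(atoms_b[i]) not in {key(atoms_a[i]) for i in ia}]
    if missing or extra:
        raise ValueError(
            f"selection {selection.label!r}: unmatched atoms between structures; "
            f"only in first: {missing[:8]}; only in second: {extra[:8]}"
        )
    return np.array(out_a, dtype=int), np.array(out_b, dtype=int)
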