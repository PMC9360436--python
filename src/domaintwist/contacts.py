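"""Residue contact analysis: salt bridges, hydrogen bonds, polar contacts.

Direct (non-water-mediated) contacts are detected with heavy-atom distance
criteria only — no donor/acceptor angle term, since crystal structures in
scope lack hydrogens.  Atom chemistry is read off names and elements:

* polar atoms: any nitrogen or oxygen (including phosphate oxygens of the
  phosphoresidues SEP/TPO/PTR, in either the O1P/O2P/O3P or OP1/OP2/OP3
  naming dialect);
* cationic atoms: side-chain N of Lys (NZ), Arg (NE/NH1/NH2) and His
  (ND1/NE2, plus the common His tautomer residue names);
* anionic atoms: side-chain carboxylate O of Asp (OD1/OD2) and Glu
  (OE1/OE2), the C-terminal OXT, and phosphate oxygens of phosphoresidues.

Classification precedence per atom pair is salt_bridge > hbond > polar, so
each atom pair yields at most one record.  Unknown residues fall back to
polar-by-element with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Atom, Structure

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "ResidueNetwork",
    "find_contacts",
    "residue_network",
    "compare_networks",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "SEP", "TPO", "PTR", "HOH", "WAT",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}

_HIS_NAMES = {"HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"}
_PHOSPHO_RESIDUES = {"SEP", "TPO", "PTR"}
_PHOSPHATE_OXYGENS = {"O1P", "O2P", "O3P", "OP1", "OP2", "OP3"}

_CATIONIC = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    **{name: {"ND1", "NE2"} for name in _HIS_NAMES},
}
_ANIONIC = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (Angstrom) and residue-pair exclusions.

    The cutoffs are independent criteria, defaults drawn from common
    structural-biology practice: 4.0 A N...O for salt bridges, 3.5 A for
    heavy-atom hydrogen bonds, 3.9 A for weaker polar contacts.
    """

    hbond_max_A: float = 3.5
    saltbridge_max_A: float = 4.0
    polar_max_A: float = 3.9
    exclude_same_residue: bool = True
    exclude_adjacent_residues: bool = False

    def __post_init__(self) -> None:
        for f in ("hbond_max_A", "saltbridge_max_A", "polar_max_A"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond_max_A, self.saltbridge_max_A, self.polar_max_A)


@dataclass(frozen=True, order=True)
class ContactRecord:
    """One typed residue-residue interaction between a pair of heavy atoms."""

    residue_a: tuple[str, int, str]  # (chain, number, name)
    residue_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    distance_A: float
    kind: str  # salt_bridge | hbond | polar

    def pair_key(self) -> tuple:
        """Residue-pair-level identity used by network comparison."""
        return (self.residue_a[:2], self.residue_b[:2], self.kind)


@dataclass
class ResidueNetwork:
    """All contacts involving one focus residue."""

    focus_residue: tuple[str, int, str]
    contacts: list[ContactRecord]


def _is_polar(atom: Atom) -> bool:
    return atom.element in ("N", "O")


def _is_cationic(atom: Atom) -> bool:
    return atom.name in _CATIONIC.get(atom.residue_name, ())


def _is_anionic(atom: Atom) -> bool:
    if atom.name == "OXT":
        return True
    if atom.residue_name in _PHOSPHO_RESIDUES and atom.name in _PHOSPHATE_OXYGENS:
        return True
    return atom.name in _ANIONIC.get(atom.residue_name, ())


def _classify_pair(a: Atom, b: Atom, dist: float, criteria: ContactCriteria) -> str | None:
    ionic = (_is_cationic(a) and _is_anionic(b)) or (_is_anionic(a) and _is_cationic(b))
    if ionic and dist <= criteria.saltbridge_max_A:
        return "salt_bridge"
    if _is_polar(a) and _is_polar(b):
        if dist <= criteria.hbond_max_A:
            return "hbond"
        if dist <= criteria.polar_max_A:
            return "polar"
    return None


def _make_record(a: Atom, b: Atom, dist: float, kind: str) -> ContactRecord:
    ra = (a.chain_id, a.residue_number, a.residue_name)
    rb = (b.chain_id, b.residue_number, b.residue_name)
    # canonical order: a before b by (chain, residue number, atom name)
    if (ra[0], ra[1], a.name) > (rb[0], rb[1], b.name):
        a, b, ra, rb = b, a, rb, ra
    return ContactRecord(
        residue_a=ra,
        residue_b=rb,
        atom_a=a.name,
        atom_b=b.name,
        distance_A=round(float(dist), 4),
        kind=kind,
    )


def find_contacts(structure: Structure, criteria: ContactCriteria | None = None) -> list[ContactRecord]:
    """Enumerate all direct polar contacts of a structure.

    Hydrogens are ignored.  Candidate pairs are gathered with a KD-tree at
    the largest cutoff, then classified; the result is sorted canonically
    and deduplicated per (atom pair, kind).
    """
    criteria = criteria or ContactCriteria()
    atoms = structure.atoms
    unknown = sorted({a.residue_name for a in atoms if a.residue_name not in STANDARD_RESIDUES})
    if unknown:
        warnings.warn(
            f"residues without chemistry classification treated polar-by-element: {unknown}",
            stacklevel=2,
        )
    # only N/O atoms can participate in any of the three contact kinds
    cand = [i for i, a in enumerate(atoms) if _is_polar(a)]
    if len(cand) < 2:
        return []
    coords = structure.coordinates[cand]
    tree = cKDTree(coords)
    records: set[ContactRecord] = set()
    for ii, jj in tree.query_pairs(criteria.max_cutoff):
        a, b = atoms[cand[ii]], atoms[cand[jj]]
        if criteria.exclude_same_residue and a.residue_id() == b.residue_id():
            continue
        if (
            criteria.exclude_adjacent_residues
            and a.chain_id == b.chain_id
            and abs(a.residue_number - b.residue_number) == 1
        ):
            continue
        dist = float(np.linalg.norm(coords[ii] - coords[jj]))
        kind = _classify_pair(a, b, dist, criteria)
        if kind is not None:
            records.add(_make_record(a, b, dist, kind))
    return sorted(records)


def residue_network(
    structure: Structure,
    focus: tuple[str, int],
    criteria: ContactCriteria | None = None,
) -> ResidueNetwork:
    """Contacts involving one focus residue, given as (chain, residue number)."""
    chain, number = focus
    focus_atoms = [
        a for a in structure.atoms if a.chain_id == chain and a.residue_number == number
    ]
    if not focus_atoms:
        raise ValueError(f"residue {number} of chain {chain!r} not found in structure")
    focus_id = (chain, number)
    contacts = [
        rec
        for rec in find_contacts(structure, criteria)
        if rec.residue_a[:2] == focus_id or rec.residue_b[:2] == focus_id
    ]
    return ResidueNetwork(
        focus_residue=(chain, number, focus_atoms[0].residue_name), contacts=contacts
    )


def compare_networks(
    structure_a: Structure,
    structure_b: Structure,
    focus: tuple[str, int],
    criteria: ContactCriteria | None = None,
) -> dict[str, list]:
    """Diff the focus residue's network between two conformations.

    Contacts are keyed at the residue-pair + kind level; the per-side
    atom-level records (with distances) are reported for each key.  Returns
    a dict with sorted ``shared``, ``only_a`` and ``only_b`` lists of
    ``(key, records_a, records_b)`` / ``(key, records)`` tuples.
    """
    net_a = residue_network(structure_a, focus, criteria)
    net_b = residue_network(structure_b, focus, criteria)
    by_key_a: dict[tuple, list[ContactRecord]] = {}
    by_key_b: dict[tuple, list[ContactRecord]] = {}
    for rec in net_a.contacts:
        by_key_a.setdefault(rec.pair_key(), []).append(rec)
    for rec in net_b.contacts:
        by_key_b.setdefault(rec.pair_key(), []).append(rec)
    keys_a, keys_b = set(by_key_a), set(by_key_b)
    return {
        "shared": [(k, by_key_a[k], by_key_b[k]) for k in sorted(keys_a & keys_b)],
        "only_a": [(k, by_key_a[k]) for k in sorted(keys_a - keys_b)],
        "only_b": [(k, by_key_b[k]) for k in sorted(keys_b - keys_a)],
    }


def contacts_to_frame(records: list[ContactRecord]) -> pd.DataFrame:
    """Tabulate contact records in the canonical CSV column layout."""
    return pd.DataFrame(
        [
            {
                "chain_a": r.residue_a[0],
                "res_a": r.residue_a[1],
                "name_a": r.residue_a[2],
                "atom_a": r.atom_a,
                "chain_b": r.residue_b[0],
                "res_b": r.residue_b[1],
                "name_b": r.residue_b[2],
                "atom_b": r.atom_b,
                "distance_A": r.distance_A,
                "kind": r.kind,
            }
            for r in records
        ],
        columns=[
            "chain_a", "res_a", "name_a", "atom_a",
            "chain_b", "res_b", "name_b", "atom_b",
            "distance_A", "kind",
        ],
    )
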