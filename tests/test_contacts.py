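"""Salt-bridge / hydrogen-bond / polar contact detection vs brute force."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from domaintwist import (
    Atom,
    ContactCriteria,
    Structure,
    compare_networks,
    find_contacts,
    residue_network,
)
from domaintwist.contacts import contacts_to_frame, _classify_pair


def atom(name, res_name, res_num, element=None, chain="A"):
    if element is None:
        element = name[0]
    return Atom(0, name, "", res_name, chain, res_num, "", element)


def structure(entries):
    """entries: list of (Atom, xyz)."""
    atoms = [a for a, _ in entries]
    coords = np.array([xyz for _, xyz in entries], dtype=float)
    return Structure(atoms, coords)


def brute_force_contacts(struct, criteria):
    """Independent all-pairs double loop reference implementation."""
    from domaintwist.contacts import _make_record

    records = set()
    n = struct.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            a, b = struct.atoms[i], struct.atoms[j]
            if a.element not in ("N", "O") or b.element not in ("N", "O"):
                continue
            if criteria.exclude_same_residue and a.residue_id() == b.residue_id():
                continue
            if (
                criteria.exclude_adjacent_residues
                and a.chain_id == b.chain_id
                and abs(a.residue_number - b.residue_number) == 1
            ):
                continue
            dist = float(np.linalg.norm(struct.coordinates[i] - struct.coordinates[j]))
            kind = _classify_pair(a, b, dist, criteria)
            if kind is not None:
                records.add(_make_record(a, b, dist, kind))
    return sorted(records)


def random_polar_structure(rng, n_atoms=200, box=25.0):
    """Random mix of charged/polar/apolar atoms in a box."""
    menu = [
        ("NZ", "LYS", "N"), ("NE", "ARG", "N"), ("NH1", "ARG", "N"),
        ("OD1", "ASP", "O"), ("OE1", "GLU", "O"), ("OE2", "GLU", "O"),
        ("N", "ALA", "N"), ("O", "ALA", "O"), ("OG", "SER", "O"),
        ("CA", "ALA", "C"), ("CB", "VAL", "C"), ("OXT", "GLY", "O"),
        ("O1P", "SEP", "O"), ("OP2", "TPO", "O"), ("ND1", "HIS", "N"),
    ]
    entries = []
    for i in range(n_atoms):
        name, res, elem = menu[int(rng.integers(len(menu)))]
        entries.append(
            (atom(name, res, i + 1, elem), rng.uniform(0, box, size=3))
        )
    return structure(entries)


class TestFindContacts:
    def test_lys_glu_salt_bridge(self):
        s = structure(
            [
                (atom("NZ", "LYS", 1), (0.0, 0.0, 0.0)),
                (atom("OE1", "GLU", 5), (3.8, 0.0, 0.0)),
            ]
        )
        records = find_contacts(s)
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "salt_bridge"
        assert rec.distance_A == pytest.approx(3.8)
        assert {rec.atom_a, rec.atom_b} == {"NZ", "OE1"}

    def test_backbone_hbond(self):
        s = structure(
            [
                (atom("N", "ALA", 1), (0.0, 0.0, 0.0)),
                (atom("O", "GLY", 5), (0.0, 3.0, 0.0)),
            ]
        )
        (rec,) = find_contacts(s)
        assert rec.kind == "hbond"

    def test_weak_polar_between_hbond_and_polar_cutoffs(self):
        s = structure(
            [
                (atom("OG", "SER", 1), (0.0, 0.0, 0.0)),
                (atom("O", "GLY", 5), (3.7, 0.0, 0.0)),
            ]
        )
        (rec,) = find_contacts(s)
        assert rec.kind == "polar"

    def test_beyond_all_cutoffs_no_record(self):
        s = structure(
            [
                (atom("O", "SER", 1), (0.0, 0.0, 0.0)),
                (atom("O", "GLY", 5), (4.5, 0.0, 0.0)),
            ]
        )
        assert find_contacts(s) == []

    def test_saltbridge_precedence_over_hbond(self):
        # cationic-anionic pair inside the hbond cutoff is still a salt bridge
        s = structure(
            [
                (atom("NZ", "LYS", 1), (0.0, 0.0, 0.0)),
                (atom("OD1", "ASP", 9), (2.9, 0.0, 0.0)),
            ]
        )
        (rec,) = find_contacts(s)
        assert rec.kind == "salt_bridge"

    def test_phosphate_dialects_are_anionic(self):
        for name in ("O1P", "OP1"):
            s = structure(
                [
                    (atom(name, "SEP", 3), (0.0, 0.0, 0.0)),
                    (atom("NZ", "LYS", 11), (3.2, 0.0, 0.0)),
                ]
            )
            (rec,) = find_contacts(s)
            assert rec.kind == "salt_bridge"

    def test_same_residue_excluded_by_default(self):
        s = structure(
            [
                (atom("N", "SER", 1), (0.0, 0.0, 0.0)),
                (atom("OG", "SER", 1), (3.0, 0.0, 0.0)),
            ]
        )
        assert find_contacts(s) == []
        crit = ContactCriteria(exclude_same_residue=False)
        assert len(find_contacts(s, crit)) == 1

    def test_hydrogens_ignored(self):
        s = structure(
            [
                (atom("HZ1", "LYS", 1, element="H"), (0.0, 0.0, 0.0)),
                (atom("OE1", "GLU", 5), (2.0, 0.0, 0.0)),
            ]
        )
        assert find_contacts(s) == []

    def test_unknown_residue_warns_polar_by_element(self):
        s = structure(
            [
                (atom("N1", "LIG", 1, element="N"), (0.0, 0.0, 0.0)),
                (atom("O", "GLY", 5), (3.0, 0.0, 0.0)),
            ]
        )
        with pytest.warns(UserWarning, match="LIG"):
            (rec,) = find_contacts(s)
        assert rec.kind == "hbond"

    def test_matches_brute_force_on_random_structures(self, rng):
        crit = ContactCriteria()
        for _ in range(10):
            s = random_polar_structure(rng)
            assert find_contacts(s, crit) == brute_force_contacts(s, crit)

    def test_rigid_motion_invariance(self, rng):
        s = random_polar_structure(rng, n_atoms=120)
        moved = s.transformed(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3) * 50)
        recs_a = find_contacts(s)
        recs_b = find_contacts(moved)
        assert [(r.residue_a, r.residue_b, r.kind) for r in recs_a] == [
            (r.residue_a, r.residue_b, r.kind) for r in recs_b
        ]
        for ra, rb in zip(recs_a, recs_b):
            assert ra.distance_A == pytest.approx(rb.distance_A, abs=1e-3)

    def test_cutoff_monotonicity(self, rng):
        s = random_polar_structure(rng, n_atoms=150)
        base = ContactCriteria()
        wider = ContactCriteria(hbond_max_A=3.5, saltbridge_max_A=5.0, polar_max_A=3.9)
        base_sb = {(r.residue_a, r.residue_b, r.atom_a, r.atom_b) for r in find_contacts(s, base) if r.kind == "salt_bridge"}
        wide_sb = {(r.residue_a, r.residue_b, r.atom_a, r.atom_b) for r in find_contacts(s, wider) if r.kind == "salt_bridge"}
        assert base_sb <= wide_sb


class TestResidueNetwork:
    def test_sep_phosphate_lysine_network(self):
        s = structure(
            [
                (atom("O1P", "SEP", 360), (0.0, 0.0, 0.0)),
                (atom("NZ", "LYS", 294), (3.2, 0.0, 0.0)),
                (atom("O", "GLY", 100), (30.0, 0.0, 0.0)),
            ]
        )
        net = residue_network(s, ("A", 360))
        assert net.focus_residue == ("A", 360, "SEP")
        assert len(net.contacts) == 1 and net.contacts[0].kind == "salt_bridge"

    def test_isolated_focus_empty_network(self):
        s = structure(
            [
                (atom("NZ", "LYS", 1), (0.0, 0.0, 0.0)),
                (atom("OE1", "GLU", 9), (50.0, 0.0, 0.0)),
            ]
        )
        assert residue_network(s, ("A", 1)).contacts == []

    def test_missing_residue_error_names_it(self):
        s = structure([(atom("CA", "ALA", 1, element="C"), (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError, match="99"):
            residue_network(s, ("A", 99))

    def test_network_is_subset_of_all_contacts(self, rng):
        s = random_polar_structure(rng, n_atoms=150)
        all_recs = set(find_contacts(s))
        focus = s.atoms[0].residue_number
        net = residue_network(s, ("A", focus))
        assert set(net.contacts) <= all_recs
        assert all(
            rec.residue_a[1] == focus or rec.residue_b[1] == focus for rec in net.contacts
        )


class TestCompareNetworks:
    def test_identical_structures_no_diff(self, rng):
        s = random_polar_structure(rng, n_atoms=100)
        focus = ("A", s.atoms[0].residue_number)
        diff = compare_networks(s, s.copy(), focus)
        assert diff["only_a"] == [] and diff["only_b"] == []

    def test_partner_moved_out_of_range(self):
        entries = [
            (atom("NZ", "LYS", 1), (0.0, 0.0, 0.0)),
            (atom("OE1", "GLU", 5), (3.5, 0.0, 0.0)),
        ]
        a = structure(entries)
        b = a.copy()
        b.coordinates = b.coordinates.copy()
        b.coordinates[1] = (12.0, 0.0, 0.0)
        diff = compare_networks(a, b, ("A", 1))
        assert len(diff["only_a"]) == 1 and diff["only_b"] == []
        key = diff["only_a"][0][0]
        assert key[2] == "salt_bridge"

    def test_matches_independent_set_algebra(self, rng):
        crit = ContactCriteria()
        s_a = random_polar_structure(rng, n_atoms=150)
        s_b = s_a.copy()
        s_b.coordinates = s_a.coordinates + rng.normal(scale=0.8, size=s_a.coordinates.shape)
        focus_num = s_a.atoms[0].residue_number
        focus = ("A", focus_num)
        diff = compare_networks(s_a, s_b, focus, crit)

        def keyset(struct):
            return {
                r.pair_key()
                for r in brute_force_contacts(struct, crit)
                if focus_num in (r.residue_a[1], r.residue_b[1])
            }

        ka, kb = keyset(s_a), keyset(s_b)
        assert {k for k, *_ in diff["shared"]} == ka & kb
        assert {k for k, _ in diff["only_a"]} == ka - kb
        assert {k for k, _ in diff["only_b"]} == kb - ka

    def test_focus_absent_raises(self, rng):
        s = random_polar_structure(rng, n_atoms=20)
        with pytest.raises(ValueError):
            compare_networks(s, s, ("B", 1))


def test_contacts_frame_layout():
    s = structure(
        [
            (atom("NZ", "LYS", 1), (0.0, 0.0, 0.0)),
            (atom("OE1", "GLU", 5), (3.8, 0.0, 0.0)),
        ]
    )
    df = contacts_to_frame(find_contacts(s))
    assert list(df.columns) == [
        "chain_a", "res_a", "name_a", "atom_a",
        "chain_b", "res_b", "name_b", "atom_b",
        "distance_A", "kind",
    ]
    assert len(df) == 1 and df.loc[0, "kind"] == "salt_bridge"
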