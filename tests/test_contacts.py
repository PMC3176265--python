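import numpy as np
import pytest

from ppihotspot.contacts import (
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    atomic_contacts,
    contact_features,
    hydrogen_bonds,
    salt_bridges,
)
from ppihotspot.structure_io import PartnerSpec, read_pdb, split_partners

from conftest import make_structure


def charged_pair(distance, partner_res="GLU", partner_atom="OE1"):
    a = make_structure("sb", {
        "A": [("LYS", 1, {"CA": (0, 0, 0), "CE": (0, 1, 0),
                          "NZ": (0, 2.5, 0)})],
    })
    b = make_structure("sb", {
        "B": [(partner_res, 1, {"CA": (0, 2.5 + distance + 3, 0),
                                partner_atom: (0, 2.5 + distance, 0)})],
    })
    return a, b


def test_salt_bridge_within_cutoff():
    a, b = charged_pair(6.9)
    key = a.chains["A"][0].key
    assert salt_bridges(a, b, key) == 1


def test_salt_bridge_beyond_cutoff():
    a, b = charged_pair(7.1)
    key = a.chains["A"][0].key
    assert salt_bridges(a, b, key) == 0


def test_same_sign_pair_is_not_a_salt_bridge():
    a, b = charged_pair(5.0, partner_res="ARG", partner_atom="NH1")
    key = a.chains["A"][0].key
    assert salt_bridges(a, b, key) == 0


def test_histidine_configurable():
    a = make_structure("his", {
        "A": [("HIS", 1, {"CA": (0, 0, 0), "CG": (0, 1, 0),
                          "ND1": (0, 2, 0)})],
    })
    b = make_structure("his", {
        "B": [("ASP", 1, {"CA": (0, 9, 0), "OD1": (0, 6, 0)})],
    })
    key = a.chains["A"][0].key
    assert salt_bridges(a, b, key) == 1
    assert salt_bridges(a, b, key, exclude_his=True) == 0


def hbond_pair(distance):
    # SER OG donating to a partner backbone O, antecedent CB behind OG
    a = make_structure("hb", {
        "A": [("SER", 1, {"CA": (0, -2, 0), "CB": (0, -1.4, 0),
                          "OG": (0, 0, 0)})],
    })
    b = make_structure("hb", {
        "B": [("GLY", 1, {"CA": (3, distance + 2, 0),
                          "O": (0, distance, 0)})],
    })
    return a, b


def test_hydrogen_bond_geometry():
    a, b = hbond_pair(2.9)
    key = a.chains["A"][0].key
    assert hydrogen_bonds(a, b, key) == 1


def test_hydrogen_bond_too_long():
    a, b = hbond_pair(4.2)
    key = a.chains["A"][0].key
    assert hydrogen_bonds(a, b, key) == 0


def test_hydrogen_bond_angle_rejected():
    # acceptor placed behind the antecedent: angle ~0 degrees
    a = make_structure("hb", {
        "A": [("SER", 1, {"CA": (0, -2, 0), "CB": (0, -1.4, 0),
                          "OG": (0, 0, 0)})],
    })
    b = make_structure("hb", {
        "B": [("GLY", 1, {"CA": (5, -3.0, 0), "O": (0, -3.0, 0)})],
    })
    key = a.chains["A"][0].key
    assert hydrogen_bonds(a, b, key) == 0


def test_no_donor_no_bond():
    # ALA has no side-chain donor/acceptor; backbone too far
    a = make_structure("hb", {
        "A": [("ALA", 1, {"CA": (0, 0, 0), "CB": (0, 1, 0),
                          "N": (-1, -1, 0), "O": (1, -1, 0)})],
    })
    b = make_structure("hb", {
        "B": [("ALA", 1, {"CA": (0, 7, 0), "CB": (0, 6, 0),
                          "N": (-1, 8, 0), "O": (1, 8, 0)})],
    })
    key = a.chains["A"][0].key
    assert hydrogen_bonds(a, b, key) == 0


def test_atomic_contact_vdw_slack():
    a = make_structure("ac", {"A": [("GLY", 1, {"CA": (0, 0, 0)})]})
    b35 = make_structure("ac", {"B": [("GLY", 1, {"CA": (3.5, 0, 0)})]})
    b37 = make_structure("ac", {"B": [("GLY", 1, {"CA": (3.7, 0, 0)})]})
    key = a.chains["A"][0].key
    # carbons: 3.5 < 1.70 + 1.70 + 0.25 = 3.65, 3.7 is not
    assert atomic_contacts(a, b35, key) == 1
    assert atomic_contacts(a, b37, key) == 0


def test_distant_residue_no_contacts(separated_pdb):
    s = read_pdb(separated_pdb)
    spec = PartnerSpec({"A"}, {"B"})
    for res in s.chains["A"]:
        cc = contact_features(s, spec, res.key)
        assert (cc.n_hbonds, cc.n_salt_bridges, cc.n_atomic_contacts) == (0, 0, 0)


def test_engineered_salt_bridge_counted(toy_pdb):
    s = read_pdb(toy_pdb)
    spec = PartnerSpec({"A"}, {"B"})
    lys_key = s.chains["A"][1].key
    cc = contact_features(s, spec, lys_key)
    assert cc.n_salt_bridges == 1
    ser_key = s.chains["A"][4].key
    cc = contact_features(s, spec, ser_key)
    assert cc.n_hbonds >= 1


def _random_two_clouds(rng, n_per_side=15):
    """Random charged/polar residues in two nearby clouds."""
    kinds = [("LYS", "NZ"), ("ARG", "NH1"), ("ASP", "OD1"), ("GLU", "OE1"),
             ("GLY", "CB")]
    def side(chain, offset):
        residues = []
        for i in range(n_per_side):
            resname, extra = kinds[int(rng.integers(len(kinds)))]
            base = rng.uniform(-4, 4, 3) + offset
            atoms = {"CA": tuple(base), extra: tuple(base + rng.uniform(-1.5, 1.5, 3))}
            residues.append((resname, i + 1, atoms))
        return residues
    a = make_structure("rnd", {"A": side("A", np.zeros(3))})
    b = make_structure("rnd", {"B": side("B", np.array([0.0, 6.0, 0.0]))})
    return a, b


def _brute_force_counts(a, b, key, fn_kind):
    """O(n^2) all-pairs oracle for salt bridges / atomic contacts."""
    from ppihotspot.contacts import _charge
    from ppihotspot.sasa import VDW_RADII

    res = a.get_residue(key) if key.chain_id in a.chains else b.get_residue(key)
    other = b if key.chain_id in a.chains else a
    count = 0
    for atom in res.atoms:
        for ores in other.residues():
            for oatom in ores.atoms:
                d = np.linalg.norm(np.array(atom.coord) - np.array(oatom.coord))
                if fn_kind == "salt":
                    q1 = _charge(res.resname, atom.name)
                    q2 = _charge(ores.resname, oatom.name)
                    if q1 * q2 < 0 and d < 7.0:
                        count += 1
                else:
                    r1 = VDW_RADII.get(atom.element.upper(), 1.70)
                    r2 = VDW_RADII.get(oatom.element.upper(), 1.70)
                    if d < r1 + r2 + 0.25:
                        count += 1
    return count


def test_brute_force_oracle_matches(rng):
    """KD-tree-accelerated counts equal the O(n^2) scan on random fixtures."""
    for trial in range(20):
        a, b = _random_two_clouds(rng)
        for res in list(a.residues())[:5]:
            key = res.key
            assert salt_bridges(a, b, key) == _brute_force_counts(a, b, key, "salt")
            assert atomic_contacts(a, b, key) == _brute_force_counts(a, b, key, "atomic")


def test_side_sums_balance(toy_pdb):
    """Each cross pair is counted once from each side."""
    s = read_pdb(toy_pdb)
    spec = PartnerSpec({"A"}, {"B"})
    a, b = split_partners(s, spec)
    for fn in (salt_bridges, hydrogen_bonds, atomic_contacts):
        sum_a = sum(fn(a, b, r.key) for r in a.residues())
        sum_b = sum(fn(a, b, r.key) for r in b.residues())
        assert sum_a == sum_b


def test_rigid_motion_invariance(toy_pdb, rng):
    s = read_pdb(toy_pdb)
    spec = PartnerSpec({"A"}, {"B"})
    # random rotation + translation applied to the whole complex
    q = rng.standard_normal((3, 3))
    rot, _ = np.linalg.qr(q)
    shift = rng.uniform(-20, 20, 3)

    moved = make_structure("mv", {
        cid: [
            (r.resname, r.key.resseq,
             {a.name: tuple(rot @ np.array(a.coord) + shift)
              for a in r.atoms})
            for r in s.chains[cid]
        ]
        for cid in s.chain_ids
    })
    for res in s.chains["A"]:
        orig = contact_features(s, spec, res.key)
        new = contact_features(moved, spec, moved.chains["A"][0].key.__class__(
            "mv", "A", res.key.resseq, "", res.key.aa))
        assert (orig.n_hbonds, orig.n_salt_bridges, orig.n_atomic_contacts) \
            == (new.n_hbonds, new.n_salt_bridges, new.n_atomic_contacts)


def test_counts_monotone_in_cutoff(toy_pdb):
    s = read_pdb(toy_pdb)
    spec = PartnerSpec({"A"}, {"B"})
    a, b = split_partners(s, spec)
    for res in s.chains["A"]:
        prev_sb, prev_ac = -1, -1
        for scale in (0.5, 1.0, 2.0):
            sb = salt_bridges(a, b, res.key, cutoff=7.0 * scale)
            ac = atomic_contacts(a, b, res.key, slack=0.25 * scale)
            assert sb >= prev_sb and ac >= prev_ac
            prev_sb, prev_ac = sb, ac


def test_charged_tables_disjoint():
    assert not POSITIVE_ATOMS & NEGATIVE_ATOMS
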