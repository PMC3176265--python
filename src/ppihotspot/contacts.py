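"""Cross-interface biochemical contacts: hydrogen bonds, salt bridges,
atomic contacts.

All three counters pair one atom from each binding partner; intra-partner
interactions are never counted. Hydrogen bonds use a heavy-atom geometric
criterion (donor-acceptor distance plus donor-antecedent angle) rather
than a hydrogen-placement or network-optimization model, because typical
X-ray structures carry no hydrogens. An "atomic contact" is a heavy-atom
pair closer than the sum of van der Waals radii plus a slack (default
0.25 A), i.e. a vdW-overlap criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .sasa import VDW_RADII
from .structure_io import PartnerSpec, ResidueKey, Structure, split_partners

__all__ = [
    "ContactCounts",
    "POSITIVE_ATOMS",
    "NEGATIVE_ATOMS",
    "DONOR_ATOMS",
    "ACCEPTOR_ATOMS",
    "SALT_BRIDGE_CUTOFF",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_MIN_ANGLE_DEG",
    "ATOMIC_CONTACT_SLACK",
    "salt_bridges",
    "hydrogen_bonds",
    "atomic_contacts",
    "contact_features",
]

SALT_BRIDGE_CUTOFF = 7.0        # A, charged-atom pair across the interface
HBOND_DISTANCE_CUTOFF = 3.5     # A, donor heavy atom to acceptor
HBOND_MIN_ANGLE_DEG = 90.0      # antecedent-donor-acceptor angle
ATOMIC_CONTACT_SLACK = 0.25     # A beyond r_vdw(i) + r_vdw(j)

#: Formally charged side-chain atoms. Histidine is included on the
#: positive side by default (exclude_his removes it).
POSITIVE_ATOMS: set[tuple[str, str]] = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
NEGATIVE_ATOMS: set[tuple[str, str]] = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}

#: Hydrogen-bond donors as (resname, donor atom) -> antecedent atom used
#: for the angle test. Backbone N applies to every residue type ("*").
DONOR_ATOMS: dict[tuple[str, str], str] = {
    ("*", "N"): "CA",
    ("SER", "OG"): "CB",
    ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ",
    ("CYS", "SG"): "CB",
    ("ASN", "ND2"): "CG",
    ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD",
    ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG",
    ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1",
}

#: Hydrogen-bond acceptors as (resname, atom). Backbone O ("*") accepts
#: for every residue type.
ACCEPTOR_ATOMS: set[tuple[str, str]] = {
    ("*", "O"),
    ("*", "OXT"),
    ("SER", "OG"),
    ("THR", "OG1"),
    ("TYR", "OH"),
    ("ASN", "OD1"),
    ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}


@dataclass(frozen=True)
class ContactCounts:
    n_hbonds: int
    n_salt_bridges: int
    n_atomic_contacts: int


def _is_in(table, resname: str, atom_name: str) -> bool:
    return (resname, atom_name) in table or ("*", atom_name) in table


def _charge(resname: str, atom_name: str) -> int:
    if (resname, atom_name) in POSITIVE_ATOMS:
        return +1
    if (resname, atom_name) in NEGATIVE_ATOMS:
        return -1
    return 0


def _partner_atoms(partner: Structure):
    """Flat (residue, atom, coord) arrays for one partner."""
    residues, atoms, coords = [], [], []
    for res in partner.residues():
        for a in res.atoms:
            residues.append(res)
            atoms.append(a)
            coords.append(a.coord)
    return residues, atoms, np.array(coords, dtype=float).reshape(-1, 3)


def _opposite(a: Structure, b: Structure, residue: ResidueKey):
    """(residue object, its partner, the opposite partner)."""
    for own, other in ((a, b), (b, a)):
        try:
            res = own.get_residue(residue)
            return res, own, other
        except KeyError:
            continue
    raise KeyError(f"residue {residue} not found in either partner")


def salt_bridges(
    a: Structure, b: Structure, residue: ResidueKey,
    cutoff: float = SALT_BRIDGE_CUTOFF, exclude_his: bool = False,
) -> int:
    """Count oppositely charged cross-interface atom pairs within cutoff
    that involve ``residue``."""
    res, _, other = _opposite(a, b, residue)

    def charge(resname, atom_name):
        if exclude_his and resname == "HIS":
            return 0
        return _charge(resname, atom_name)

    own = [(atom, charge(res.resname, atom.name)) for atom in res.atoms]
    own = [(atom, q) for atom, q in own if q != 0]
    if not own:
        return 0

    count = 0
    for ores in other.residues():
        for oatom in ores.atoms:
            oq = charge(ores.resname, oatom.name)
            if oq == 0:
                continue
            for atom, q in own:
                if q * oq < 0 and _dist(atom.coord, oatom.coord) < cutoff:
                    count += 1
    return count


def _dist(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


def _angle_deg(p, vertex, q) -> float:
    u = np.asarray(p, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(q, dtype=float) - np.asarray(vertex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 180.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _donor_pairs(res):
    """(donor atom, antecedent atom or None) for one residue."""
    out = []
    for atom in res.atoms:
        ante_name = DONOR_ATOMS.get((res.resname, atom.name)) or \
            DONOR_ATOMS.get(("*", atom.name))
        if ante_name is None:
            continue
        out.append((atom, res.atom(ante_name)))
    return out


def _acceptors(res):
    return [a for a in res.atoms if _is_in(ACCEPTOR_ATOMS, res.resname, a.name)]


def hydrogen_bonds(
    a: Structure, b: Structure, residue: ResidueKey,
    distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    min_angle_deg: float = HBOND_MIN_ANGLE_DEG,
) -> int:
    """Count cross-interface donor-acceptor pairs involving ``residue``.

    Criterion: donor heavy atom within ``distance_cutoff`` of the acceptor
    and antecedent-donor-acceptor angle >= ``min_angle_deg`` (the angle
    test is skipped when the antecedent atom is absent). The residue may
    act as donor or acceptor.
    """
    res, _, other = _opposite(a, b, residue)

    def bonded(donor, antecedent, acceptor) -> bool:
        if _dist(donor.coord, acceptor.coord) > distance_cutoff:
            return False
        if antecedent is None:
            return True
        return _angle_deg(antecedent.coord, donor.coord,
                          acceptor.coord) >= min_angle_deg

    count = 0
    own_donors = _donor_pairs(res)
    own_acceptors = _acceptors(res)
    for ores in other.residues():
        for oacc in _acceptors(ores):
            for donor, ante in own_donors:
                if bonded(donor, ante, oacc):
                    count += 1
        for odon, oante in _donor_pairs(ores):
            for acc in own_acceptors:
                if bonded(odon, oante, acc):
                    count += 1
    return count


def atomic_contacts(
    a: Structure, b: Structure, residue: ResidueKey,
    slack: float = ATOMIC_CONTACT_SLACK,
    radii: dict[str, float] | None = None,
) -> int:
    """Count cross-interface heavy-atom pairs involving ``residue`` with
    distance < r_vdw(i) + r_vdw(j) + slack."""
    radii = VDW_RADII if radii is None else radii
    res, _, other = _opposite(a, b, residue)

    own_coords = res.coords
    own_r = np.array([radii.get(at.element.upper(), 1.70) for at in res.atoms])

    _, oatoms, ocoords = _partner_atoms(other)
    if len(oatoms) == 0:
        return 0
    other_r = np.array([radii.get(at.element.upper(), 1.70) for at in oatoms])

    max_cut = float(own_r.max() + other_r.max() + slack)
    tree = cKDTree(ocoords)
    count = 0
    for i, c in enumerate(own_coords):
        for j in tree.query_ball_point(c, max_cut):
            if _dist(c, ocoords[j]) < own_r[i] + other_r[j] + slack:
                count += 1
    return count


def contact_features(
    complex_structure: Structure,
    spec: PartnerSpec,
    residue: ResidueKey,
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
    hbond_distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    atomic_contact_slack: float = ATOMIC_CONTACT_SLACK,
) -> ContactCounts:
    """All three contact counters for one residue against the opposite
    binding partner."""
    a, b = split_partners(complex_structure, spec)
    return ContactCounts(
        n_hbonds=hydrogen_bonds(a, b, residue,
                                distance_cutoff=hbond_distance_cutoff),
        n_salt_bridges=salt_bridges(a, b, residue,
                                    cutoff=salt_bridge_cutoff),
        n_atomic_contacts=atomic_contacts(a, b, residue,
                                          slack=atomic_contact_slack),
    )
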