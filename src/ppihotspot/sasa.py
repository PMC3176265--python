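"""Solvent-accessible surface area and interface-burial features.

SASA is computed with Shrake-Rupley sphere-point sampling using a
deterministic golden-spiral (Fibonacci) point set, a 1.4 A water probe and
an embedded per-element van der Waals radius table (NACCESS-class
accuracy at the default 960 points/atom).

Derived per-residue features:

* ``delta_asa``      -- ASA_monomer - ASA_complex (A^2), the area a residue
                        buries when the complex forms; clamped at 0 against
                        quadrature noise.
* ``delta_asa_pct``  -- relative surface burial, 100 * delta_asa/ASA_monomer.
* ``rel_asa``        -- complex-state ASA over the residue type's reference
                        area in an extended ALA-x-ALA tripeptide.
* ``is_interface``   -- delta_asa >= 1 A^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import PartnerSpec, ResidueKey, Structure, split_partners

__all__ = [
    "VDW_RADII",
    "REFERENCE_AREAS",
    "SasaResult",
    "AsaFeatures",
    "shrake_rupley",
    "residue_asa_features",
    "reference_areas",
    "sphere_points",
    "INTERFACE_DELTA_ASA",
]

#: Per-element van der Waals radii (A), Bondi-style values as used by
#: common SASA programs. Overridable via the ``radii`` argument.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Reference ASA (A^2) of residue X in an extended ALA-X-ALA tripeptide
#: (theoretical maxima of Tien et al. 2013, the modern tabulation of the
#: ALA-x-ALA convention).
REFERENCE_AREAS = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: A residue burying at least this much area on complexation is an
#: interface residue.
INTERFACE_DELTA_ASA = 1.0

#: Quadrature noise bound: negative delta_asa above this magnitude is an
#: error, below it is clamped to zero.
_NOISE_EPS = 0.1


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


@dataclass
class SasaResult:
    per_atom: np.ndarray              # area per atom, structure atom order
    per_residue: dict[ResidueKey, float]
    probe_radius: float
    n_sphere_points: int


def _atom_radii(s: Structure, radii: dict[str, float]) -> np.ndarray:
    out = []
    for atom in s.atoms():
        r = radii.get(atom.element.upper())
        if r is None:
            raise ValueError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.name})"
            )
        out.append(r)
    return np.array(out, dtype=float)


def shrake_rupley(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Per-atom and per-residue SASA by Shrake-Rupley sampling.

    Deterministic for fixed ``n_points``: the test-point set is a golden
    spiral, not a random sample.
    """
    if s.n_atoms == 0:
        raise ValueError("cannot compute SASA of an empty structure")
    radii = VDW_RADII if radii is None else radii

    coords = s.coord_array()
    ext_r = _atom_radii(s, radii) + probe  # extended (solvent-center) radii
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_ext = float(ext_r.max())
    per_atom = np.empty(len(coords))
    for i in range(len(coords)):
        # any sphere whose extended radius can reach atom i's surface
        nbrs = tree.query_ball_point(coords[i], ext_r[i] + max_ext)
        nbrs = [j for j in nbrs if j != i
                and np.linalg.norm(coords[j] - coords[i]) < ext_r[i] + ext_r[j]]
        pts = coords[i] + ext_r[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= ext_r[j] ** 2
        per_atom[i] = 4.0 * math.pi * ext_r[i] ** 2 * accessible.mean()

    per_residue: dict[ResidueKey, float] = {}
    idx = 0
    for res in s.residues():
        n = len(res.atoms)
        per_residue[res.key] = float(per_atom[idx:idx + n].sum())
        idx += n
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe, n_sphere_points=n_points)


def reference_areas(aa: str) -> float:
    """Extended ALA-x-ALA tripeptide reference area for a residue type."""
    try:
        return REFERENCE_AREAS[aa.upper()]
    except KeyError:
        raise KeyError(f"no tripeptide reference area for residue type {aa!r}")


@dataclass
class AsaFeatures:
    asa_monomer: float
    asa_complex: float
    delta_asa: float
    delta_asa_pct: float | None      # None when asa_monomer == 0 (missing)
    rel_asa: float
    is_interface: bool

    @classmethod
    def from_areas(cls, asa_monomer: float, asa_complex: float,
                   aa: str) -> "AsaFeatures":
        delta = asa_monomer - asa_complex
        if delta < -_NOISE_EPS:
            raise ValueError(
                f"delta_asa {delta:.3f} below quadrature noise bound; "
                "monomer and complex coordinates must be identical"
            )
        delta = max(delta, 0.0)
        pct = None if asa_monomer <= 0.0 else 100.0 * delta / asa_monomer
        return cls(
            asa_monomer=asa_monomer,
            asa_complex=asa_complex,
            delta_asa=delta,
            delta_asa_pct=pct,
            rel_asa=asa_complex / reference_areas(aa),
            is_interface=delta >= INTERFACE_DELTA_ASA,
        )


def residue_asa_features(
    complex_structure: Structure,
    spec: PartnerSpec,
    residue: ResidueKey,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    _cache: dict | None = None,
) -> AsaFeatures:
    """Burial features for one residue: monomer SASA on its isolated
    partner, complex SASA on the full complex (identical coordinates).

    ``_cache`` (a plain dict) lets callers iterating over many residues of
    the same complex reuse the three SASA computations.
    """
    side = spec.side_of(residue.chain_id)
    # canonicalize: match on (chain, resseq, icode) so callers need not
    # supply the aa/pdb_id fields exactly
    res = complex_structure.get_residue(residue)
    residue = res.key

    if _cache is not None and "complex" in _cache:
        res_complex = _cache["complex"]
    else:
        res_complex = shrake_rupley(complex_structure, probe, n_points, radii)
        if _cache is not None:
            _cache["complex"] = res_complex

    if _cache is not None and side in _cache:
        res_monomer = _cache[side]
    else:
        a, b = split_partners(complex_structure, spec)
        monomer = a if side == "a" else b
        res_monomer = shrake_rupley(monomer, probe, n_points, radii)
        if _cache is not None:
            _cache[side] = res_monomer

    if residue not in res_monomer.per_residue:
        raise KeyError(f"residue {residue} not found on partner side {side!r}")
    return AsaFeatures.from_areas(
        asa_monomer=res_monomer.per_residue[residue],
        asa_complex=res_complex.per_residue[residue],
        aa=res.key.aa,
    )
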