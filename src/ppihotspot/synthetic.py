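"""Synthetic fixtures: toy two-chain complexes, mutation tables, MSAs,
PSSM files and feature matrices with planted class structure.

Everything here is generated, deterministic under a fixed seed, and
emitted in the exact dialects the package's readers consume. Toy
complexes use idealized backbone geometry (no rotamer realism): the
geometric features depend only on interatomic distances, which the
generator controls directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .dataset import FEATURE_GROUPS, Dataset, combo_columns
from .seqfeat import AA_ORDER, PSSM_COLUMNS

__all__ = [
    "EngineeredContact",
    "ToyComplexSpec",
    "SyntheticDatasetSpec",
    "make_toy_complex",
    "make_synthetic_dataset",
    "make_synthetic_msa",
    "make_synthetic_pssm",
    "synthetic_training_table",
    "synthetic_bid_table",
]

_RES_SPACING = 3.8  # A between consecutive CA atoms


@dataclass(frozen=True)
class EngineeredContact:
    """A contact placed at an exact distance between the two chains."""

    kind: str                 # "salt_bridge" | "hbond"
    index_a: int              # residue index on chain A (0-based)
    index_b: int              # residue index on chain B
    distance: float           # A between the two contact atoms

    def __post_init__(self):
        if self.kind not in ("salt_bridge", "hbond"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


@dataclass(frozen=True)
class ToyComplexSpec:
    n_residues_per_chain: int = 8
    gap: float = 5.0          # A between the chains' backbone planes
    contacts: tuple[EngineeredContact, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("inter-chain gap must be >= 0")
        for c in self.contacts:
            if not (0 <= c.index_a < self.n_residues_per_chain
                    and 0 <= c.index_b < self.n_residues_per_chain):
                raise ValueError(
                    f"contact indices {c.index_a},{c.index_b} outside chain "
                    f"of length {self.n_residues_per_chain}"
                )


def _backbone(i: int, y: float, sign: float):
    """Idealized glycine backbone for residue i; side `sign` points the
    N/C/O atoms away from the other chain."""
    x = i * _RES_SPACING
    return {
        "N": (x - 1.2, y + sign * 0.8, 0.5),
        "CA": (x, y, 0.0),
        "C": (x + 1.2, y + sign * 0.8, -0.5),
        "O": (x + 1.8, y + sign * 1.8, -0.5),
    }


def make_toy_complex(spec: ToyComplexSpec) -> str:
    """PDB text for a two-chain toy complex.

    Chain A lies along the x axis at y <= 0, chain B parallel at
    y >= gap, so the closest backbone approach is ``spec.gap``.
    Engineered contacts add side-chain atoms at the exact requested
    distances (salt bridge: LYS NZ vs GLU OE1; hydrogen bond: SER OG
    donated to the partner's backbone O).
    """
    n = spec.n_residues_per_chain
    residues: dict[tuple[str, int], dict] = {}
    for i in range(n):
        residues[("A", i)] = {"name": "GLY",
                              "atoms": dict(_backbone(i, 0.0, -1.0))}
        residues[("B", i)] = {"name": "GLY",
                              "atoms": dict(_backbone(i, spec.gap, +1.0))}

    for c in spec.contacts:
        ca_a = np.array(residues[("A", c.index_a)]["atoms"]["CA"])
        ca_b = np.array(residues[("B", c.index_b)]["atoms"]["CA"])
        axis = ca_b - ca_a
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("contact residues coincide; unrealizable")
        u = axis / norm
        if c.kind == "salt_bridge":
            mid = (ca_a + ca_b) / 2.0
            nz = mid - (c.distance / 2.0) * u
            oe1 = mid + (c.distance / 2.0) * u
            ra = residues[("A", c.index_a)]
            ra["name"] = "LYS"
            ra["atoms"]["CE"] = tuple(nz - 1.5 * u)
            ra["atoms"]["NZ"] = tuple(nz)
            rb = residues[("B", c.index_b)]
            rb["name"] = "GLU"
            rb["atoms"]["CD"] = tuple(oe1 + 1.5 * u)
            rb["atoms"]["OE1"] = tuple(oe1)
        else:  # hbond: SER OG on A donates to backbone O of B
            o_b = np.array(residues[("B", c.index_b)]["atoms"]["O"])
            v = ca_a - o_b
            v = v / np.linalg.norm(v)
            og = o_b + c.distance * v
            ra = residues[("A", c.index_a)]
            ra["name"] = "SER"
            ra["atoms"]["OG"] = tuple(og)
            ra["atoms"]["CB"] = tuple(og + 1.4 * v)

    order = []
    for chain in ("A", "B"):
        for i in range(n):
            order.append((chain, i))

    n_atoms = sum(len(residues[k]["atoms"]) for k in order)
    arr = struc.AtomArray(n_atoms)
    idx = 0
    for chain, i in order:
        res = residues[(chain, i)]
        for atom_name, coord in res["atoms"].items():
            arr.chain_id[idx] = chain
            arr.res_id[idx] = i + 1
            arr.res_name[idx] = res["name"]
            arr.atom_name[idx] = atom_name
            arr.element[idx] = atom_name[0]
            arr.hetero[idx] = False
            arr.coord[idx] = coord
            idx += 1
    arr.set_annotation("occupancy", np.ones(n_atoms))
    arr.set_annotation("b_factor", np.zeros(n_atoms))

    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Feature-table generator with a planted standardized mean shift.

    Positives have the columns of ``informative_groups`` shifted by
    ``separation`` standard deviations over unit-variance Gaussian noise.
    """

    n_rows: int = 377
    prevalence: float = 182 / 377
    separation: float = 1.0
    informative_groups: tuple[str, ...] = ("PSSM", "SE")
    seed: int = 0
    fixed_count: bool = True       # exactly round(prevalence*n) positives
    n_complexes: int = 25

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if self.separation < 0:
            raise ValueError("class separation must be >= 0")


def make_synthetic_dataset(spec: SyntheticDatasetSpec) -> tuple[Dataset, dict]:
    """Dataset with planted class structure plus ground-truth metadata."""
    unknown = set(spec.informative_groups) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups {sorted(unknown)}")
    if spec.separation > 0 and not spec.informative_groups:
        import warnings

        warnings.warn("separation > 0 but no informative groups requested")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    if spec.fixed_count:
        n_pos = int(round(spec.prevalence * n))
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=n_pos, replace=False)] = 1
    else:
        labels = (rng.random(n) < spec.prevalence).astype(int)

    combo = tuple(FEATURE_GROUPS)
    cols = combo_columns(combo)
    X = rng.standard_normal((n, len(cols)))
    informative = [c for g in spec.informative_groups
                   for c in FEATURE_GROUPS[g]]
    for j, c in enumerate(cols):
        if c in informative:
            X[labels == 1, j] += spec.separation

    groups = np.array([f"SYN{1 + i % spec.n_complexes:02d}" for i in range(n)])
    ds = Dataset(features=pd.DataFrame(X, columns=cols), labels=labels,
                 groups=groups, combo=combo)
    truth = {
        "informative_groups": tuple(spec.informative_groups),
        "informative_columns": informative,
        "separation": spec.separation,
        "n_pos": int(labels.sum()),
    }
    return ds, truth


def make_synthetic_msa(
    n_seqs: int, length: int = 30, conserved_positions=(), seed: int = 0,
) -> str:
    """Aligned FASTA text: designated columns invariant (alanine), the
    rest drawn uniformly over the 20 amino acids."""
    rng = np.random.default_rng(seed)
    conserved = set(conserved_positions)
    aas = np.array(list(AA_ORDER))
    rows = rng.integers(0, 20, size=(n_seqs, length))
    lines = []
    for s in range(n_seqs):
        seq = [
            "A" if j in conserved else aas[rows[s, j]]
            for j in range(length)
        ]
        lines.append(f">seq{s + 1}")
        lines.append("".join(seq))
    return "\n".join(lines) + "\n"


def make_synthetic_pssm(query: str = "MKVLAGH", seed: int = 0) -> str:
    """PSI-BLAST ASCII PSSM text for a query sequence (scores in the
    typical -10..10 integer range, self-substitution boosted)."""
    rng = np.random.default_rng(seed)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted "
        "observed percentages rounded down, information per position, "
        "and relative weight of gapless real matches to pseudocounts",
        "           " + "  ".join(PSSM_COLUMNS),
    ]
    for i, aa in enumerate(query, start=1):
        scores = rng.integers(-6, 5, size=20)
        if aa.upper() in PSSM_COLUMNS:
            scores[PSSM_COLUMNS.index(aa.upper())] = rng.integers(4, 9)
        lines.append(
            f"{i:5d} {aa.upper()}  " + " ".join(f"{v:3d}" for v in scores)
        )
    return "\n".join(lines) + "\n"


def _spread(rng, n, lo, hi):
    return lo + (hi - lo) * rng.random(n)


def synthetic_training_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the published 25-complex alanine-scanning
    training table (377 interface mutations with measured ddG).

    The ddG values are drawn so that the table reproduces the published
    composition exactly: 84 mutations with ddG >= 2 kcal/mol, 98 with
    1 <= ddG < 2 (182 hot spots at the 1 kcal/mol threshold) and 195
    with ddG < 1. Residue identities and coordinates are invented; only
    the ddG marginals are meaningful.
    """
    rng = np.random.default_rng(seed)
    ddg = np.concatenate([
        _spread(rng, 84, 2.0, 6.5),      # strict hot spots
        _spread(rng, 98, 1.0, 1.99),     # hot at >=1 only
        _spread(rng, 195, -0.8, 0.99),   # non-hot spots
    ])
    n = len(ddg)
    order = rng.permutation(n)
    ddg = np.round(ddg[order], 2)
    # rounding must not cross the thresholds
    ddg[(ddg >= 1.995) & (ddg < 2.0)] = 1.99
    ddg[(ddg >= 0.995) & (ddg < 1.0)] = 0.99

    complexes = [f"SYN{i + 1:02d}" for i in range(25)]
    antibody = set(complexes[:4])
    wt_pool = [a for a in AA_ORDER if a != "A"]
    rows = []
    for i in range(n):
        pdb_id = complexes[i % 25]
        rows.append({
            "pdb_id": pdb_id,
            "chain": "A" if i % 2 == 0 else "B",
            "resseq": 10 + i // 25,
            "icode": "",
            "wt_aa": wt_pool[int(rng.integers(0, len(wt_pool)))],
            "ddg": float(ddg[i]),
            "is_antibody_complex": pdb_id in antibody,
        })
    return pd.DataFrame(rows)


def synthetic_bid_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the published 23-complex BID test table
    (148 mutations with categorical effects, no ddG).

    Composition matches the published counts: 80 hot spots under the
    Strong/Intermediate rule and 68 non-hot spots spread over the four
    remaining categories.
    """
    rng = np.random.default_rng(seed)
    cats = (
        ["Strong"] * 44 + ["Intermediate"] * 36
        + ["Weak"] * 22 + ["Insignificant"] * 24
        + ["Negative-weak"] * 12 + ["Negative-strong"] * 10
    )
    assert len(cats) == 148
    order = rng.permutation(len(cats))
    cats = [cats[i] for i in order]

    complexes = [f"TST{i + 1:02d}" for i in range(23)]
    wt_pool = [a for a in AA_ORDER if a != "A"]
    rows = []
    for i, cat in enumerate(cats):
        rows.append({
            "pdb_id": complexes[i % 23],
            "chain": "A",
            "resseq": 5 + i // 23,
            "icode": "",
            "wt_aa": wt_pool[int(rng.integers(0, len(wt_pool)))],
            "bid_category": cat,
            "is_antibody_complex": False,
        })
    return pd.DataFrame(rows)
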