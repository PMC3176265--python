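"""Hot-spot labeling and feature-matrix assembly.

A mutation is a hot spot when alanine substitution costs at least a
threshold of binding free energy (ddG >= 1 kcal/mol by default; >= 2 is
the stricter convention used by several earlier studies). Mutations
annotated only with a BID effect category are hot spots when the effect
is Strong or Intermediate.

Feature columns are organized into named groups selectable by a combo
mask, matching the feature families used in training:

* ``ASA``  -- 5 burial features (asa_monomer, asa_complex, delta_asa,
  delta_asa_pct, rel_asa)
* ``BC``   -- 3 biochemical-contact counts
* ``Phy``  -- 6 physicochemical constants
* ``PSSM`` -- 20 normalized profile scores
* ``ECS``  -- conservation grade (1)
* ``SE``   -- sequence entropy (1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqfeat import PSSM_COLUMNS

__all__ = [
    "FEATURE_GROUPS",
    "KEY_COLUMNS",
    "BID_CATEGORIES",
    "HOTSPOT_BID_CATEGORIES",
    "MutationRecord",
    "Dataset",
    "label_from_ddg",
    "label_from_bid",
    "load_mutation_table",
    "assemble",
    "balance_lowest_ddg",
    "split_ab",
]

KEY_COLUMNS = ["pdb_id", "chain", "resseq", "icode"]

FEATURE_GROUPS: dict[str, list[str]] = {
    "ASA": ["asa_monomer", "asa_complex", "delta_asa", "delta_asa_pct",
            "rel_asa"],
    "BC": ["n_hbonds", "n_salt_bridges", "n_atomic_contacts"],
    "Phy": ["hydrophobicity", "hydrophilicity", "polarity",
            "polarizability", "propensity", "avg_asa"],
    "PSSM": [f"pssm_{a}" for a in PSSM_COLUMNS],
    "ECS": ["conservation_grade"],
    "SE": ["sequence_entropy"],
}

BID_CATEGORIES = (
    "Strong", "Intermediate", "Weak", "Insignificant",
    "Negative-weak", "Negative-strong",
)
HOTSPOT_BID_CATEGORIES = frozenset({"Strong", "Intermediate"})


def label_from_ddg(ddg: float, threshold: float = 1.0) -> int:
    """1 when ddG >= threshold (kcal/mol), else 0. Inclusive boundary."""
    if ddg is None or (isinstance(ddg, float) and np.isnan(ddg)):
        raise ValueError("cannot label a mutation with missing ddG")
    return int(float(ddg) >= threshold)


def label_from_bid(category: str) -> int:
    """1 for Strong/Intermediate BID effects, 0 for the other four."""
    if category not in BID_CATEGORIES:
        raise ValueError(
            f"unknown BID category {category!r}; expected one of "
            f"{BID_CATEGORIES}"
        )
    return int(category in HOTSPOT_BID_CATEGORIES)


@dataclass(frozen=True)
class MutationRecord:
    pdb_id: str
    chain: str
    resseq: int
    icode: str
    wt_aa: str
    ddg: float | None = None
    bid_category: str | None = None
    is_antibody_complex: bool = False

    def __post_init__(self):
        has_ddg = self.ddg is not None and not (
            isinstance(self.ddg, float) and np.isnan(self.ddg)
        )
        if has_ddg == (self.bid_category is not None):
            raise ValueError(
                "exactly one of ddg / bid_category must be present "
                f"for {self.pdb_id} {self.chain}{self.resseq}"
            )

    def label(self, ddg_threshold: float = 1.0) -> int:
        if self.bid_category is not None:
            return label_from_bid(self.bid_category)
        return label_from_ddg(self.ddg, ddg_threshold)


def load_mutation_table(path) -> pd.DataFrame:
    """Read a mutation CSV with columns (pdb_id, chain, resseq, icode,
    wt_aa, ddg | bid_category[, is_antibody_complex])."""
    df = pd.read_csv(path, dtype={"chain": str, "icode": str})
    missing = {"pdb_id", "chain", "resseq", "wt_aa"} - set(df.columns)
    if missing:
        raise ValueError(f"mutation table lacks columns {sorted(missing)}")
    if "ddg" not in df.columns and "bid_category" not in df.columns:
        raise ValueError("mutation table needs a ddg or bid_category column")
    if "icode" not in df.columns:
        df["icode"] = ""
    df["icode"] = df["icode"].fillna("")
    if "is_antibody_complex" not in df.columns:
        df["is_antibody_complex"] = False
    return df


def table_labels(df: pd.DataFrame, ddg_threshold: float = 1.0) -> np.ndarray:
    """Binary hot-spot labels for a mutation table."""
    labels = np.empty(len(df), dtype=int)
    for i, row in enumerate(df.itertuples(index=False)):
        ddg = getattr(row, "ddg", None)
        has_ddg = ddg is not None and not pd.isna(ddg)
        if has_ddg:
            labels[i] = label_from_ddg(float(ddg), ddg_threshold)
        else:
            labels[i] = label_from_bid(getattr(row, "bid_category"))
    return labels


@dataclass
class Dataset:
    """Feature matrix + labels + per-complex grouping for one experiment."""

    features: pd.DataFrame          # indexed like mutations, named columns
    labels: np.ndarray              # binary
    groups: np.ndarray              # complex id per row
    combo: tuple[str, ...]          # feature groups included
    mutations: pd.DataFrame | None = None
    imputed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.groups = np.asarray(self.groups)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if len(self.groups) != len(self.labels):
            raise ValueError("groups and labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    @property
    def n_hotspots(self) -> int:
        return int(self.labels.sum())

    def subset(self, mask) -> "Dataset":
        mask = np.asarray(mask)
        return Dataset(
            features=self.features.loc[mask].reset_index(drop=True),
            labels=self.labels[mask],
            groups=self.groups[mask],
            combo=self.combo,
            mutations=(None if self.mutations is None
                       else self.mutations.loc[mask].reset_index(drop=True)),
        )

    def with_groups_removed(self, drop: set[str]) -> "Dataset":
        """Drop whole feature groups (for ablation)."""
        keep = tuple(g for g in self.combo if g not in drop)
        if not keep:
            raise ValueError("removing these groups would empty the matrix")
        cols = [c for g in keep for c in FEATURE_GROUPS[g]]
        return Dataset(features=self.features[cols], labels=self.labels,
                       groups=self.groups, combo=keep,
                       mutations=self.mutations)


def combo_columns(combo) -> list[str]:
    combo = tuple(combo)
    if not combo:
        raise ValueError("empty feature combination")
    unknown = set(combo) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(
            f"unknown feature groups {sorted(unknown)}; "
            f"known: {sorted(FEATURE_GROUPS)}"
        )
    return [c for g in combo for c in FEATURE_GROUPS[g]]


def assemble(
    feature_table: pd.DataFrame,
    mutations: pd.DataFrame,
    combo=("Phy", "PSSM", "ECS", "SE"),
    ddg_threshold: float = 1.0,
    interface_only: bool = True,
) -> Dataset:
    """Join a per-residue feature table onto a mutation table and select
    the requested feature groups.

    The feature table must carry KEY_COLUMNS plus the columns of every
    group in ``combo``. Mutations at residues missing from the feature
    table raise; missing feature *values* are imputed with the column
    mean and counted in ``Dataset.imputed``. Rows failing the interface
    filter (is_interface column false) are dropped with a count recorded.
    """
    cols = combo_columns(combo)
    missing_cols = set(cols) - set(feature_table.columns)
    if missing_cols:
        raise ValueError(
            f"feature table lacks columns {sorted(missing_cols)} "
            f"required by combo {tuple(combo)}"
        )

    feats = feature_table.copy()
    muts = mutations.copy()
    for df in (feats, muts):
        df["icode"] = df.get("icode", "").fillna("") if "icode" in df else ""
        df["_key"] = list(zip(df["pdb_id"], df["chain"],
                              df["resseq"], df["icode"]))
    lookup = feats.set_index("_key")
    dup = lookup.index.duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate residue keys in feature table: "
            f"{lookup.index[dup].tolist()[:5]}"
        )
    unresolved = [k for k in muts["_key"] if k not in lookup.index]
    if unresolved:
        raise KeyError(
            f"{len(unresolved)} mutation(s) not resolvable in feature "
            f"table, e.g. {unresolved[:5]}"
        )

    joined = lookup.loc[muts["_key"]].reset_index(drop=True)
    if interface_only and "is_interface" in joined.columns:
        keep = joined["is_interface"].astype(bool).to_numpy()
        if not keep.all():
            muts = muts.loc[keep].reset_index(drop=True)
            joined = joined.loc[keep].reset_index(drop=True)

    X = joined[cols].astype(float)
    imputed = {}
    for c in cols:
        n_missing = int(X[c].isna().sum())
        if n_missing:
            imputed[c] = n_missing
            X[c] = X[c].fillna(X[c].mean())

    labels = table_labels(muts, ddg_threshold)
    return Dataset(
        features=X.reset_index(drop=True),
        labels=labels,
        groups=muts["pdb_id"].to_numpy(),
        combo=tuple(combo),
        mutations=muts.drop(columns=["_key"]),
        imputed=imputed,
    )


def balance_lowest_ddg(ds: Dataset, n: int) -> Dataset:
    """Keep all hot spots plus the ``n`` non-hot spots with smallest ddG
    (ties broken by (pdb_id, chain, resseq))."""
    if ds.mutations is None or "ddg" not in ds.mutations.columns:
        raise ValueError("balancing requires mutation ddG values")
    is_hot = ds.labels.astype(bool)
    non = ds.mutations.loc[~is_hot].copy()
    if n > len(non):
        raise ValueError(
            f"requested {n} non-hot spots but only {len(non)} available"
        )
    non["_order"] = np.arange(len(non))
    non = non.sort_values(
        ["ddg", "pdb_id", "chain", "resseq"], kind="mergesort"
    )
    chosen = set(non.index[:n])
    mask = is_hot | np.array([i in chosen for i in range(len(ds))])
    return ds.subset(mask)


def split_ab(ds: Dataset) -> tuple[Dataset, Dataset]:
    """(Ab+, Ab-) dataset variants: all rows, and rows from complexes not
    flagged antigen-antibody."""
    if ds.mutations is None or "is_antibody_complex" not in ds.mutations:
        raise ValueError("antibody-complex flags missing from mutation table")
    flags = ds.mutations["is_antibody_complex"].astype(bool).to_numpy()
    ab_minus = ds.subset(~flags)
    if len(ab_minus) == 0:
        import warnings

        warnings.warn("all complexes are antigen-antibody; Ab- set is empty")
    return ds, ab_minus
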