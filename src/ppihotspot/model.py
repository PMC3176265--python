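"""RBF-SVM hot-spot classifier with grid search, cross-validation and the
evaluation protocol (precision / recall / F1 / ROC-AUC, feature ablation,
random baseline, group statistics).

The modelling surface follows the Model/Results convention: build a
:class:`HotspotSVM` from a :class:`~ppihotspot.dataset.Dataset` (or plain
arrays), call :meth:`~HotspotSVM.fit` and obtain a
:class:`HotspotSVMResults` carrying the selected hyper-parameters, the
trained decision function and a ``summary()`` table.

Conventions fixed here (surfaced because they affect reported numbers):

* grid-search criterion is mean cross-validated F1, ties resolved toward
  the smallest C then the smallest gamma;
* feature scaling (z-score by default) is fit on training data only and
  refit inside every cross-validation fold;
* a decision score of exactly 0 predicts the positive class;
* cross-validated confusion counts are pooled over folds (fold-averaged
  metrics are also available);
* the two-sample location test defaults to Welch's t (rank-sum optional).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import Dataset, FEATURE_GROUPS

__all__ = [
    "SvmConfig",
    "EvalReport",
    "HotspotSVM",
    "HotspotSVMResults",
    "TrainedModel",
    "metrics",
    "roc_auc",
    "train",
    "predict",
    "cross_validate",
    "self_consistency",
    "ablate",
    "random_baseline",
    "compare_groups",
]

_DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
_DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SvmConfig:
    """Training configuration for the RBF-SVM."""

    C_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA_GRID
    cv_folds: int = 10
    seed: int = 0
    scaling: str = "zscore"          # zscore | minmax | none
    grid_folds: int = 5              # inner folds for hyper-parameter search

    def __post_init__(self):
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("C and gamma grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(
            g <= 0 for g in self.gamma_grid
        ):
            raise ValueError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.scaling not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    degenerate: bool = False         # some ratio had a zero denominator

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_json(self) -> str:
        d = asdict(self)
        d["roc"] = [list(p) for p in d["roc"]]
        return json.dumps(d, indent=2)


def metrics(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    """Precision, recall and F1 from confusion counts.

    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); any ratio with a zero
    denominator is reported as 0 and the report flagged degenerate.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts) or any(int(c) != c for c in counts):
        raise ValueError(f"confusion counts must be non-negative integers, got {counts}")
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return EvalReport(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                      precision=precision, recall=recall, f1=f1,
                      degenerate=degenerate)


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and trapezoidal AUC from decision scores.

    Tied scores are grouped into a single threshold step, which makes the
    trapezoidal area equal to the Mann-Whitney rank statistic
    U / (n+ * n-) with the midrank tie convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # group equal scores into one step
    distinct = np.r_[True, np.diff(s) != 0]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    idx = np.r_[np.nonzero(distinct)[0][1:] - 1, len(s) - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos]
    fpr = np.r_[0.0, fps[idx] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _report_from_predictions(y_true, y_pred, scores=None) -> EvalReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    rep = metrics(tp, fp, tn, fn)
    if scores is not None and len(set(y_true)) == 2:
        rep.roc, rep.auc = roc_auc(scores, y_true)
    return rep


# ---------------------------------------------------------------------------
# scaling

@dataclass
class _Scaler:
    kind: str
    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, kind: str) -> "_Scaler":
        X = np.asarray(X, dtype=float)
        if kind == "zscore":
            center = X.mean(axis=0)
            scale = X.std(axis=0)
        elif kind == "minmax":
            center = X.min(axis=0)
            scale = X.max(axis=0) - center
        else:  # none
            center = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        scale = np.where(scale == 0, 1.0, scale)
        return cls(kind=kind, center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale


# ---------------------------------------------------------------------------
# trained model (persistable decision function)

@dataclass
class TrainedModel:
    """Persistable RBF-SVM decision function.

    The decision function is evaluated from the stored support vectors,
    so a persisted-then-reloaded model reproduces scores bit-identically.
    """

    support_vectors: np.ndarray      # (already scaled feature space)
    dual_coef: np.ndarray
    intercept: float
    C: float
    gamma: float
    scaler: _Scaler
    columns: tuple[str, ...]
    schema_version: int = 1

    def decision_function(self, X) -> np.ndarray:
        X = self._check(X)
        Z = self.scaler.transform(X)
        d2 = (
            np.sum(Z * Z, axis=1)[:, None]
            + np.sum(self.support_vectors ** 2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Labels and decision scores; a score of 0 is the positive class."""
        scores = self.decision_function(X)
        return (scores >= 0).astype(int), scores

    def _check(self, X) -> np.ndarray:
        if isinstance(X, Dataset):
            if tuple(X.features.columns) != self.columns:
                raise ValueError(
                    f"feature columns {tuple(X.features.columns)} do not "
                    f"match training schema {self.columns}"
                )
            return X.X
        if isinstance(X, pd.DataFrame):
            if tuple(X.columns) != self.columns:
                raise ValueError(
                    f"feature columns {tuple(X.columns)} do not match "
                    f"training schema {self.columns}"
                )
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} feature columns, "
                f"got shape {X.shape}"
            )
        return X

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": self.schema_version,
            "C": self.C,
            "gamma": self.gamma,
            "intercept": self.intercept,
            "columns": list(self.columns),
            "scaler": {
                "kind": self.scaler.kind,
                "center": self.scaler.center.tolist(),
                "scale": self.scaler.scale.tolist(),
            },
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            scaler=_Scaler(
                kind=d["scaler"]["kind"],
                center=np.array(d["scaler"]["center"], dtype=float),
                scale=np.array(d["scaler"]["scale"], dtype=float),
            ),
            columns=tuple(d["columns"]),
            schema_version=int(d["schema_version"]),
        )


# ---------------------------------------------------------------------------
# fitting machinery

def _check_trainable(X: np.ndarray, y: np.ndarray):
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def _fit_svc(X, y, C, gamma) -> SVC:
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(X, y)
    return clf


def _cv_f1(X, y, C, gamma, folds, seed, scaling) -> float:
    """Mean F1 over stratified folds at fixed (C, gamma)."""
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    f1s = []
    for tr, te in skf.split(X, y):
        scaler = _Scaler.fit(X[tr], scaling)
        clf = _fit_svc(scaler.transform(X[tr]), y[tr], C, gamma)
        scores = clf.decision_function(scaler.transform(X[te]))
        pred = (scores >= 0).astype(int)
        f1s.append(_report_from_predictions(y[te], pred).f1)
    return float(np.mean(f1s))


def grid_search(X, y, cfg: SvmConfig) -> tuple[float, float, float]:
    """(C, gamma, mean CV F1) maximizing mean CV F1 over the grid.

    Ties go to the smallest C, then the smallest gamma (grids are scanned
    in ascending order and only strict improvements replace the best).
    """
    best = None
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            f1 = _cv_f1(X, y, C, gamma, cfg.grid_folds, cfg.seed, cfg.scaling)
            if best is None or f1 > best[2] + 1e-12:
                best = (C, gamma, f1)
    return best


def train(ds: Dataset, cfg: SvmConfig | None = None) -> TrainedModel:
    """Grid-search (C, gamma) by mean CV F1, then fit on the full set."""
    cfg = cfg or SvmConfig()
    X, y = ds.X, ds.y
    _check_trainable(X, y)
    if len(cfg.C_grid) == 1 and len(cfg.gamma_grid) == 1:
        C, gamma = cfg.C_grid[0], cfg.gamma_grid[0]
    else:
        C, gamma, _ = grid_search(X, y, cfg)
    scaler = _Scaler.fit(X, cfg.scaling)
    clf = _fit_svc(scaler.transform(X), y, C, gamma)
    dual = clf.dual_coef_.ravel().astype(float)
    return TrainedModel(
        support_vectors=clf.support_vectors_.astype(float),
        dual_coef=dual,
        intercept=float(clf.intercept_[0]),
        C=C, gamma=gamma, scaler=scaler,
        columns=tuple(ds.features.columns),
    )


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision scores for new feature rows."""
    return model.predict(X)


def self_consistency(ds: Dataset, cfg: SvmConfig | None = None) -> EvalReport:
    """Train on the full set and evaluate on the same set."""
    model = train(ds, cfg)
    pred, scores = model.predict(ds.features)
    return _report_from_predictions(ds.y, pred, scores)


def cross_validate(
    ds: Dataset, cfg: SvmConfig | None = None,
    params: tuple[float, float] | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Scaling is refit inside every fold. Hyper-parameters are either
    ``params`` (C, gamma), the single grid point when both grids have
    length one, or grid-searched once on the full set (the protocol of
    tuning first, then cross-validating). Fold-averaged metrics are
    attached as ``report.fold_reports``.
    """
    cfg = cfg or SvmConfig()
    X, y = ds.X, ds.y
    _check_trainable(X, y)
    if cfg.cv_folds > len(y):
        raise ValueError(f"{cfg.cv_folds} folds but only {len(y)} rows")
    if params is not None:
        C, gamma = params
    elif len(cfg.C_grid) == 1 and len(cfg.gamma_grid) == 1:
        C, gamma = cfg.C_grid[0], cfg.gamma_grid[0]
    else:
        C, gamma, _ = grid_search(X, y, cfg)

    folds = min(cfg.cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    fold_reports = []
    for tr, te in skf.split(X, y):
        scaler = _Scaler.fit(X[tr], cfg.scaling)
        clf = _fit_svc(scaler.transform(X[tr]), y[tr], C, gamma)
        s = clf.decision_function(scaler.transform(X[te]))
        scores[te] = s
        y_pred[te] = (s >= 0).astype(int)
        fold_reports.append(_report_from_predictions(y[te], y_pred[te]))
    report = _report_from_predictions(y, y_pred, scores)
    report.fold_reports = fold_reports
    return report


def ablate(
    ds: Dataset, cfg: SvmConfig | None = None,
    groups=("SE", "ECS", "PSSM", "Phy"),
) -> pd.DataFrame:
    """Leave-one-feature-group-out table: CV F1 without the group minus
    full-model CV F1 (negative delta = the group helps)."""
    cfg = cfg or SvmConfig()
    groups = [g for g in groups if g in ds.combo]
    if not groups:
        raise ValueError("no requested group is present in the dataset")
    full = cross_validate(ds, cfg)
    rows = []
    for g in groups:
        reduced = ds.with_groups_removed({g})
        rep = cross_validate(reduced, cfg)
        rows.append({
            "excluded": g,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
            "delta_f1": rep.f1 - full.f1,
        })
    return pd.DataFrame(rows)


def random_baseline(
    n_total: int, n_pos: int, replicates: int = 1000, seed: int = 0,
) -> dict:
    """Random-assignment baseline: predict positive a uniformly random
    subset of size ``n_pos`` against fixed labels with ``n_pos``
    positives; report mean precision/recall/F1 over replicates.

    With equal predicted and true positive counts, per-replicate
    P = R = F1 = TP/n_pos, and E[TP] = n_pos^2/n_total.
    """
    if n_pos > n_total:
        raise ValueError("n_pos cannot exceed n_total")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_total, dtype=int)
    labels[:n_pos] = 1
    ps, rs, f1s = [], [], []
    for _ in range(replicates):
        pred_idx = rng.choice(n_total, size=n_pos, replace=False)
        pred = np.zeros(n_total, dtype=int)
        pred[pred_idx] = 1
        rep = _report_from_predictions(labels, pred)
        ps.append(rep.precision)
        rs.append(rep.recall)
        f1s.append(rep.f1)
    return {
        "precision": float(np.mean(ps)) if ps else 0.0,
        "recall": float(np.mean(rs)) if rs else 0.0,
        "f1": float(np.mean(f1s)) if f1s else 0.0,
        "replicates": replicates,
        "n_total": n_total,
        "n_pos": n_pos,
    }


def compare_groups(values_a, values_b, test: str = "welch") -> dict:
    """Two-sample location comparison (hot spots vs non-hot spots).

    Welch's t-test by default; ``test='ranksum'`` uses Mann-Whitney U.
    Returns group means, mean difference and the two-sided p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "ranksum":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "mean_diff": float(a.mean() - b.mean()),
        "statistic": float(stat),
        "p_value": float(p),
        "test": test,
        "n_a": len(a),
        "n_b": len(b),
    }


# ---------------------------------------------------------------------------
# Model / Results surface

class HotspotSVM:
    """Hot-spot classifier model bound to one dataset.

    Parameters
    ----------
    dataset : Dataset
        Feature matrix, binary labels and per-complex grouping.
    config : SvmConfig, optional
        Hyper-parameter grids, fold count, seed and scaling policy.
    """

    def __init__(self, dataset: Dataset, config: SvmConfig | None = None):
        self.dataset = dataset
        self.config = config or SvmConfig()

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, labels, groups=None,
                       combo=None, config: SvmConfig | None = None):
        labels = np.asarray(labels, dtype=int)
        if groups is None:
            groups = np.zeros(len(labels), dtype=int)
        if combo is None:
            combo = tuple(
                g for g, cols in FEATURE_GROUPS.items()
                if set(cols) <= set(features.columns)
            ) or ("custom",)
        ds = Dataset(features=features.reset_index(drop=True), labels=labels,
                     groups=np.asarray(groups), combo=tuple(combo))
        return cls(ds, config)

    def fit(self) -> "HotspotSVMResults":
        model = train(self.dataset, self.config)
        return HotspotSVMResults(self, model)


class HotspotSVMResults:
    """Fit results: selected hyper-parameters, decision function and the
    evaluation protocol (self-consistency, cross-validation, ablation)."""

    def __init__(self, model: HotspotSVM, trained: TrainedModel):
        self.model = model
        self.trained = trained
        self._self_consistency: EvalReport | None = None
        self._cv: EvalReport | None = None

    @property
    def params(self) -> dict:
        return {"C": self.trained.C, "gamma": self.trained.gamma}

    def predict(self, X=None) -> tuple[np.ndarray, np.ndarray]:
        if X is None:
            X = self.model.dataset.features
        return self.trained.predict(X)

    def self_consistency(self) -> EvalReport:
        if self._self_consistency is None:
            pred, scores = self.predict()
            self._self_consistency = _report_from_predictions(
                self.model.dataset.y, pred, scores
            )
        return self._self_consistency

    def cross_validate(self) -> EvalReport:
        if self._cv is None:
            self._cv = cross_validate(
                self.model.dataset, self.model.config,
                params=(self.trained.C, self.trained.gamma),
            )
        return self._cv

    def ablate(self, groups=("SE", "ECS", "PSSM", "Phy")) -> pd.DataFrame:
        return ablate(self.model.dataset, self.model.config, groups)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.trained.to_json())

    def summary(self) -> str:
        ds = self.model.dataset
        sc = self.self_consistency()
        cv = self.cross_validate()
        lines = [
            "RBF-SVM hot-spot classifier",
            "=" * 47,
            f"rows: {len(ds)}   hot spots: {ds.n_hotspots}   "
            f"non-hot spots: {len(ds) - ds.n_hotspots}",
            f"feature groups: {'+'.join(ds.combo)} "
            f"({ds.features.shape[1]} columns)",
            f"selected C = {self.trained.C:g}, "
            f"gamma = {self.trained.gamma:g} "
            f"(scaling: {self.trained.scaler.kind})",
            "-" * 47,
            f"{'test':<18}{'P':>7}{'R':>7}{'F1':>7}{'AUC':>8}",
            f"{'self-consistency':<18}{sc.precision:>7.2f}{sc.recall:>7.2f}"
            f"{sc.f1:>7.2f}{(sc.auc if sc.auc is not None else math.nan):>8.2f}",
            f"{'cross-validation':<18}{cv.precision:>7.2f}{cv.recall:>7.2f}"
            f"{cv.f1:>7.2f}{(cv.auc if cv.auc is not None else math.nan):>8.2f}",
            "=" * 47,
        ]
        return "\n".join(lines)
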