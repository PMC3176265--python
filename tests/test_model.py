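import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ppihotspot.dataset import Dataset
from ppihotspot.model import (
    HotspotSVM,
    SvmConfig,
    TrainedModel,
    _Scaler,
    ablate,
    compare_groups,
    cross_validate,
    grid_search,
    metrics,
    random_baseline,
    roc_auc,
    self_consistency,
    train,
)
from ppihotspot.synthetic import SyntheticDatasetSpec, make_synthetic_dataset

SMALL_CFG = SvmConfig(C_grid=(1.0,), gamma_grid=(1 / 36,), cv_folds=10,
                      seed=0)
GRID_CFG = SvmConfig(C_grid=(0.25, 1.0, 4.0), gamma_grid=(1 / 64, 1 / 8),
                     cv_folds=5, seed=0, grid_folds=3)


def separable_dataset(n=80, seed=0):
    ds, _ = make_synthetic_dataset(SyntheticDatasetSpec(
        n_rows=n, prevalence=0.5, separation=6.0, seed=seed,
        informative_groups=("Phy", "PSSM"),
    ))
    return ds


# -- metrics ------------------------------------------------------------------

def test_metric_worked_examples():
    # receptor-peptide case: 2 TP, 1 FN, 0 FP
    rep = metrics(tp=2, fp=0, tn=1, fn=1)
    assert rep.precision == pytest.approx(1.0)
    assert rep.recall == pytest.approx(2 / 3, abs=0.005)
    assert rep.f1 == pytest.approx(0.8)
    # catenin-APC case: 5 TP, 1 FN, 1 FP
    rep = metrics(tp=5, fp=1, tn=0, fn=1)
    assert rep.precision == pytest.approx(5 / 6)
    assert rep.recall == pytest.approx(5 / 6)
    assert rep.f1 == pytest.approx(5 / 6)


def test_metrics_degenerate_flagged():
    rep = metrics(tp=0, fp=0, tn=3, fn=5)
    assert (rep.precision, rep.recall, rep.f1) == (0.0, 0.0, 0.0)
    assert rep.degenerate


def test_metrics_negative_counts_rejected():
    with pytest.raises(ValueError):
        metrics(-1, 0, 0, 0)


# -- ROC / AUC ----------------------------------------------------------------

def test_auc_perfect_and_tied():
    _, auc = roc_auc([3.0, 2.0, -1.0, -2.0], [1, 1, 0, 0])
    assert auc == pytest.approx(1.0)
    _, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert auc == pytest.approx(0.5)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


def test_auc_equals_rank_statistic(rng):
    """Trapezoidal AUC with tie grouping equals Mann-Whitney U/(n+ n-)."""
    for _ in range(10):
        scores = np.round(rng.standard_normal(50), 1)  # force ties
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            continue
        _, auc = roc_auc(scores, labels)
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
        expected = u / (labels.sum() * (50 - labels.sum()))
        assert auc == pytest.approx(expected, abs=1e-9)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.standard_normal(60)
    labels = rng.integers(0, 2, 60)
    _, auc1 = roc_auc(scores, labels)
    _, auc2 = roc_auc(np.exp(scores / 2), labels)
    assert auc1 == pytest.approx(auc2, abs=1e-12)


def test_roc_monotone_nondecreasing():
    ds = separable_dataset()
    rep = self_consistency(ds, SMALL_CFG)
    fpr = [p[0] for p in rep.roc]
    tpr = [p[1] for p in rep.roc]
    assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
    assert all(a <= b + 1e-12 for a, b in zip(tpr, tpr[1:]))


# -- training and prediction --------------------------------------------------

def test_separable_self_consistency_perfect():
    rep = self_consistency(separable_dataset(), SMALL_CFG)
    assert rep.f1 == pytest.approx(1.0)
    assert rep.n == 80


def test_grid_search_deterministic():
    ds = separable_dataset(n=60)
    r1 = grid_search(ds.X, ds.y, GRID_CFG)
    r2 = grid_search(ds.X, ds.y, GRID_CFG)
    assert r1 == r2


def test_single_class_rejected():
    ds = separable_dataset()
    bad = Dataset(features=ds.features, labels=np.ones(len(ds), dtype=int),
                  groups=ds.groups, combo=ds.combo)
    with pytest.raises(ValueError, match="both classes"):
        train(bad, SMALL_CFG)


def test_nonfinite_features_rejected():
    ds = separable_dataset()
    ds.features.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        train(ds, SMALL_CFG)


def test_predict_rejects_shuffled_columns():
    ds = separable_dataset()
    model = train(ds, SMALL_CFG)
    shuffled = ds.features[list(ds.features.columns[::-1])]
    with pytest.raises(ValueError, match="schema"):
        model.predict(shuffled)


def test_zero_score_is_positive_class():
    model = TrainedModel(
        support_vectors=np.zeros((1, 2)), dual_coef=np.zeros(1),
        intercept=0.0, C=1.0, gamma=1.0,
        scaler=_Scaler("none", np.zeros(2), np.ones(2)),
        columns=("f0", "f1"),
    )
    labels, scores = model.predict(np.zeros((3, 2)))
    assert np.all(scores == 0.0)
    assert np.all(labels == 1)


def test_persisted_model_bit_identical(tmp_path):
    ds = separable_dataset()
    model = train(ds, SMALL_CFG)
    before = model.decision_function(ds.features)
    path = tmp_path / "model.json"
    path.write_text(model.to_json())
    reloaded = TrainedModel.from_json(path.read_text())
    after = reloaded.decision_function(ds.features)
    assert np.array_equal(before, after)


# -- cross-validation ---------------------------------------------------------

def test_cv_separable_near_perfect():
    rep = cross_validate(separable_dataset(), SMALL_CFG)
    assert rep.f1 > 0.95
    assert rep.n == 80          # pooled counts cover every row


def test_cv_same_seed_identical():
    ds = separable_dataset(n=60, seed=3)
    r1 = cross_validate(ds, SMALL_CFG)
    r2 = cross_validate(ds, SMALL_CFG)
    assert (r1.tp, r1.fp, r1.tn, r1.fn) == (r2.tp, r2.fp, r2.tn, r2.fn)
    assert r1.auc == r2.auc


def test_cv_too_many_folds():
    ds = separable_dataset(n=20)
    with pytest.raises(ValueError, match="folds"):
        cross_validate(ds, SvmConfig(C_grid=(1.0,), gamma_grid=(0.1,),
                                     cv_folds=50))


def test_null_data_gives_chance_auc():
    """No class signal: cross-validated AUC hovers around 0.5."""
    aucs = []
    for seed in range(5):
        ds, _ = make_synthetic_dataset(SyntheticDatasetSpec(
            n_rows=120, prevalence=0.5, separation=0.0, seed=seed,
        ))
        aucs.append(cross_validate(ds, SMALL_CFG).auc)
    assert all(0.3 <= a <= 0.7 for a in aucs)
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_self_consistency_beats_cv_in_expectation():
    diffs = []
    for seed in range(10):
        ds, _ = make_synthetic_dataset(SyntheticDatasetSpec(
            n_rows=100, prevalence=0.5, separation=1.0, seed=seed,
        ))
        diffs.append(self_consistency(ds, SMALL_CFG).f1
                     - cross_validate(ds, SMALL_CFG).f1)
    assert np.mean(diffs) >= 0


# -- ablation -----------------------------------------------------------------

def test_ablation_identifies_planted_group():
    ds, truth = make_synthetic_dataset(SyntheticDatasetSpec(
        n_rows=200, prevalence=0.5, separation=1.5, seed=1,
        informative_groups=("SE",),
    ))
    table = ablate(ds, SMALL_CFG, groups=("SE", "ECS", "Phy"))
    assert len(table) == 3
    worst = table.loc[table["delta_f1"].idxmin(), "excluded"]
    assert worst == "SE"
    # ablating pure-noise groups barely moves F1
    noise = table[table["excluded"] != "SE"]["delta_f1"].abs()
    assert (noise < 0.15).all()


def test_ablation_requires_present_group():
    ds = separable_dataset()
    with pytest.raises(ValueError):
        ablate(ds, SMALL_CFG, groups=("NOPE",))


# -- random baseline ----------------------------------------------------------

def test_random_baseline_matches_analytic_mean():
    res = random_baseline(377, 182, replicates=300, seed=7)
    # E[TP] = 182^2/377, and P = R = F1 = TP/182 per replicate
    assert res["f1"] == pytest.approx(182 / 377, abs=0.02)
    assert res["precision"] == pytest.approx(res["recall"], abs=0.02)


def test_random_baseline_closed_forms():
    # predicting everything positive: F1 = 2p/(1+p)
    p = 0.4
    res = random_baseline(100, 100, replicates=5, seed=0)
    assert res["f1"] == pytest.approx(1.0)  # labels have n_pos=100 positives
    res = random_baseline(50, 0, replicates=5, seed=0)
    assert res["f1"] == 0.0
    with pytest.raises(ValueError):
        random_baseline(10, 11)


def test_all_positive_prediction_prevalence_formula():
    """Predicting every residue positive against prevalence-p labels."""
    n, n_pos = 100, 40
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rep_all = metrics(tp=n_pos, fp=n - n_pos, tn=0, fn=0)
    p = n_pos / n
    assert rep_all.f1 == pytest.approx(2 * p / (1 + p))


# -- group statistics ---------------------------------------------------------

def test_compare_groups_identical():
    vals = np.arange(20.0)
    res = compare_groups(vals, vals)
    assert res["mean_diff"] == 0.0
    assert res["p_value"] > 0.9


def test_compare_groups_separated(rng):
    a = rng.normal(0, 1, 50)
    b = rng.normal(3, 1, 50)
    res = compare_groups(a, b)
    assert res["p_value"] < 1e-10
    res_swap = compare_groups(b, a)
    assert res_swap["mean_diff"] == pytest.approx(-res["mean_diff"])
    assert res_swap["p_value"] == pytest.approx(res["p_value"])


def test_compare_groups_small_group_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0], [1.0, 2.0])


def test_compare_groups_ranksum_option(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
    res = compare_groups(a, b, test="ranksum")
    assert res["test"] == "ranksum"
    assert 0 <= res["p_value"] <= 1


# -- Model/Results surface ----------------------------------------------------

def test_results_summary_and_reports():
    ds = separable_dataset()
    results = HotspotSVM(ds, SMALL_CFG).fit()
    text = results.summary()
    assert "self-consistency" in text and "cross-validation" in text
    assert results.params["C"] == 1.0
    sc = results.self_consistency()
    assert sc.tp + sc.fp + sc.tn + sc.fn == len(ds)


def test_from_dataframe_constructor():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((40, 3)),
                     columns=["a", "b", "c"])
    y = (X["a"] * 3 > 0).astype(int)
    results = HotspotSVM.from_dataframe(X, y, config=SMALL_CFG).fit()
    assert results.self_consistency().f1 > 0.9
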