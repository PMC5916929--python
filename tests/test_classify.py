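"""Biomarker selection and the two-step random-forest classifier."""

import numpy as np
import pandas as pd
import pytest

from cagekit.classify import (
    TwoStepClassifier,
    accuracy_vs_feature_count,
    ensemble_consensus,
    evaluate_repeated_cv,
    high_confidence_filter,
    iterative_rf_elimination,
    shuffled_label_null,
    variance_stabilize,
)


def informative_matrix(rng, n_per_group=15, n_informative=10, n_noise=40,
                       shift=2.0):
    """Samples-by-features matrix where the first features separate groups."""
    groups = ["CDa"] * n_per_group + ["UCa"] * n_per_group + ["Ctrl"] * n_per_group
    n = len(groups)
    X = rng.normal(size=(n, n_informative + n_noise))
    # every informative feature gets its own group-center pattern so each
    # carries non-redundant signal (permutation importance stays positive)
    for j in range(n_informative):
        centers = dict(zip(["CDa", "UCa", "Ctrl"],
                           rng.permutation([shift, -shift, 0.0])))
        X[:, j] += np.array([centers[g] for g in groups])
    cols = [f"inf{i}" for i in range(n_informative)] + [f"noise{i}" for i in range(n_noise)]
    return (
        pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)]),
        pd.Series(groups, index=[f"s{i}" for i in range(n)]),
    )


# -- elimination ------------------------------------------------------------


def test_elimination_keeps_informative_features(rng):
    X, y = informative_matrix(rng, n_per_group=12, n_informative=10, n_noise=90)
    survivors = iterative_rf_elimination(
        X, y, subset_size=25, drop_frac=0.2, splits_per_iter=3, stop_below=20,
        trees=101, seed=5, importance_repeats=2,
    )
    informative = [f for f in survivors if f.startswith("inf")]
    # planted informative features dominate the survivor set
    assert len(informative) >= 8


def test_elimination_noop_when_already_below_threshold(rng):
    X, y = informative_matrix(rng, n_per_group=5, n_informative=3, n_noise=3)
    out = iterative_rf_elimination(X, y, stop_below=200, trees=51, seed=1)
    assert out == list(X.columns)  # returned unchanged


def test_elimination_deterministic_under_seed(rng):
    X, y = informative_matrix(rng, n_per_group=8, n_informative=5, n_noise=25)
    kw = dict(subset_size=10, drop_frac=0.25, splits_per_iter=2, stop_below=10,
              trees=51, seed=9, importance_repeats=2)
    assert iterative_rf_elimination(X, y, **kw) == iterative_rf_elimination(X, y, **kw)


def test_elimination_rejects_nonfinite(rng):
    X, y = informative_matrix(rng, n_per_group=4)
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        iterative_rf_elimination(X, y, trees=11, seed=0)


# -- consensus --------------------------------------------------------------


def test_consensus_vote_thresholds():
    ibd_lists = [["a", "b"]] * 9 + [["b"]]
    cduc_lists = [["c"], ["c"], ["d"], [], []]
    selected, prov = ensemble_consensus(
        {"IBD": ibd_lists, "CDUC": cduc_lists},
        {"IBD": 9, "CDUC": 2},
    )
    assert selected == {"a", "b", "c"}  # a:9, b:10, c:2, d:1
    assert prov.loc[(prov.feature == "d") & (prov.group == "CDUC"), "votes"].item() == 1


def test_consensus_empty_and_invalid_threshold():
    selected, _ = ensemble_consensus({"IBD": [[], []]}, {"IBD": 2})
    assert selected == set()
    with pytest.raises(ValueError, match="exceeds"):
        ensemble_consensus({"IBD": [["a"]]}, {"IBD": 2})


# -- high-confidence filter -------------------------------------------------


def test_high_confidence_filter_boundaries():
    tc_table = pd.DataFrame(
        {
            "category": ["canonical"] * 4 + ["novel_antisense"],
            "width": [1, 100, 50, 100, 50],
        },
        index=[f"tc{i}" for i in range(5)],
    )
    tpm = pd.DataFrame(
        {
            "s1": [20, 11, 10, 11, 20],
            "s2": [20, 11, 10, 11, 20],
            "s3": [20, 11, 10, 11, 20],
        },
        index=tc_table.index,
        dtype=float,
    )
    kept = high_confidence_filter(tc_table, tpm)
    assert "tc0" not in kept        # width 1
    assert "tc1" in kept            # width 100, 11 TPM in 3 subjects
    assert "tc2" not in kept        # exactly 10 TPM: strict >
    assert "tc3" in kept
    assert "tc4" not in kept        # disallowed category


# -- two-step classifier ----------------------------------------------------


def test_two_step_separable_data(rng):
    X, y = informative_matrix(rng, n_per_group=10, shift=3.0)
    model = TwoStepClassifier(trees=101, seed=3, params=(2, 3))
    model.fit(X.to_numpy(), y.to_numpy())
    assert (model.predict(X.to_numpy()) == y.to_numpy()).mean() > 0.95


def test_step2_never_overrides_ctrl(rng):
    X, y = informative_matrix(rng, n_per_group=10)
    model = TwoStepClassifier(trees=51, seed=1, params=(2, 2))
    model.fit(X.to_numpy(), y.to_numpy())
    Xa = X.to_numpy()
    step1_pred = model.step1_.predict(Xa)
    final = model.predict(Xa)
    assert (final[step1_pred == "Ctrl"] == "Ctrl").all()
    assert set(final[step1_pred == "IBD"]) <= {"CDa", "UCa"}


def test_grid_search_deterministic(rng):
    X, y = informative_matrix(rng, n_per_group=6, n_informative=4, n_noise=6)
    m1 = TwoStepClassifier(trees=31, seed=11, grid_n=(2, 5), grid_y=(0.5, 2.0))
    m2 = TwoStepClassifier(trees=31, seed=11, grid_n=(2, 5), grid_y=(0.5, 2.0))
    m1.fit(X.to_numpy(), y.to_numpy())
    m2.fit(X.to_numpy(), y.to_numpy())
    assert m1.best_params_ == m2.best_params_


def test_missing_class_rejected(rng):
    X, y = informative_matrix(rng, n_per_group=5)
    y2 = y.replace("UCa", "CDa")
    with pytest.raises(ValueError, match="absent"):
        TwoStepClassifier(trees=11, params=(2, 2)).fit(X.to_numpy(), y2.to_numpy())


# -- evaluation -------------------------------------------------------------


class _ConstantModel:
    """Stub predicting a fixed label."""

    def __init__(self, label):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.label] * len(X))


class _OracleModel:
    """Stub memorizing the full label vector (perfect classifier)."""

    def __init__(self, X_all, y_all):
        self.lookup = {tuple(row): label for row, label in zip(X_all, y_all)}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.lookup[tuple(row)] for row in X])


def test_perfect_stub_scores_one(rng):
    X, y = informative_matrix(rng, n_per_group=8)
    oracle = _OracleModel(X.to_numpy(), y.to_numpy())
    report = evaluate_repeated_cv(lambda s: oracle, X, y, reps=3, seed=0)
    assert report.overall_accuracy == 1.0
    assert (report.per_class["sensitivity"] == 1.0).all()


def test_majority_stub_accuracy_is_class_frequency(rng):
    y = pd.Series(["CDa"] * 40 + ["UCa"] * 30 + ["Ctrl"] * 30)
    X = pd.DataFrame(rng.normal(size=(100, 3)))
    report = evaluate_repeated_cv(lambda s: _ConstantModel("CDa"), X, y, reps=2, seed=0)
    assert report.overall_accuracy == pytest.approx(0.4)


def test_confusion_columns_sum_to_one(rng):
    X, y = informative_matrix(rng, n_per_group=8)
    report = evaluate_repeated_cv(
        lambda s: TwoStepClassifier(trees=21, seed=s, params=(2, 2)), X, y,
        reps=2, seed=1,
    )
    assert np.allclose(report.confusion.sum(axis=0), 1.0)


def test_null_fold_change_is_one_for_majority_stub(rng):
    X, y = informative_matrix(rng, n_per_group=8)
    nul = shuffled_label_null(
        lambda s: _ConstantModel("Ctrl"), X, y, X, y, reps=5, seed=2
    )
    assert nul.fold_change["Ctrl"] == pytest.approx(1.0)
    assert nul.null_accuracy == pytest.approx(nul.actual_accuracy)


def test_accuracy_vs_feature_count_counts_validated(rng):
    X, y = informative_matrix(rng, n_per_group=6, n_informative=3, n_noise=3)
    with pytest.raises(ValueError, match="outside"):
        accuracy_vs_feature_count(lambda s: _ConstantModel("CDa"), X, y, [99])
    curve = accuracy_vs_feature_count(
        lambda s: _ConstantModel("CDa"), X, y, [1, 6], reps=2, seed=0
    )
    assert list(curve["n_features"]) == [1, 6]
    assert np.allclose(curve["accuracy"], 1 / 3, atol=1e-9)


def test_variance_stabilize_monotone(rng):
    counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)).astype(float))
    vst = variance_stabilize(counts)
    col = counts[0].to_numpy()
    order = np.argsort(col)
    assert (np.diff(vst[0].to_numpy()[order]) >= 0).all()
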