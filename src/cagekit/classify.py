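"""Biomarker selection and the two-step random-forest diagnosis model.

Selection: an iterative elimination scheme trains forests on random
even partitions of the features (max 500 per subset, 501 trees, mtry =
(sqrt(x)-1)*2) and drops the features that rank in the bottom 5% of
their subset in every partition of the iteration, until fewer than 200
remain; candidate lists from several rankers are then combined by
consensus voting (e.g. >=9 of 10 lists for IBD-vs-Ctrl, >=2 of 5 for
CD-vs-UC).

Classification: step 1 separates IBD (CDa + UCa) from Ctrl, step 2
separates CDa from UCa and is consulted only when step 1 predicts IBD.
Hyperparameters (min node size n in {2..5}, mtry m = sqrt(x-1)*y for
y in {1/2, 3/4, 1, 6/4, 2}) come from a grid search maximizing mean
overall two-step accuracy under 5-fold cross-validation; accuracy is
reported over 101 repetitions of 5-fold CV with percentile confidence
intervals, against a shuffled-label null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold


def variance_stabilize(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Default VST for CAGE features: log2 counts-per-million.

    Any monotone variance-stabilizing transform may be substituted; the
    classifier contract only needs finite numeric features.
    """
    cpm = counts / counts.sum(axis=0) * 1e6
    return np.log2(cpm + pseudocount)


def _forest(n_features: int, trees: int, seed: int, mtry: int | None = None,
            min_node: int = 1) -> RandomForestClassifier:
    if mtry is None:
        mtry = max(1, round((np.sqrt(n_features) - 1) * 2))
    mtry = int(np.clip(mtry, 1, n_features))
    return RandomForestClassifier(
        n_estimators=trees,
        max_features=mtry,
        min_samples_leaf=min_node,
        random_state=seed,
        n_jobs=1,
    )


# ---------------------------------------------------------------------------
# Iterative elimination


def iterative_rf_elimination(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    subset_size: int = 500,
    drop_frac: float = 0.05,
    splits_per_iter: int = 10,
    stop_below: int = 200,
    trees: int = 501,
    seed: int = 0,
    importance_repeats: int = 3,
) -> list[str]:
    """Iteratively drop uninformative features; return ranked survivors.

    ``matrix`` is samples-by-features.  Per iteration the features are
    randomly split ``splits_per_iter`` times into even subsets of at
    most ``subset_size`` and a forest scores each subset by permutation
    importance, so every feature is scored in several subset contexts;
    the ``drop_frac`` of features with the lowest average importance is
    then removed.  Terminates when fewer than ``stop_below`` remain; the
    output is ordered by a final forest's permutation importance.  With
    ``stop_below`` at or above the feature count the input is returned
    unchanged.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    features = list(matrix.columns)
    if len(features) < stop_below:
        return features
    while len(features) >= stop_below:
        scores = {f: 0.0 for f in features}
        for _ in range(splits_per_iter):
            order = rng.permutation(len(features))
            n_subsets = int(np.ceil(len(features) / subset_size))
            for chunk in np.array_split(order, n_subsets):
                subset = [features[i] for i in chunk]
                imp = _subset_importance(
                    matrix[subset].to_numpy(dtype=float), y, trees,
                    int(rng.integers(2**31)), importance_repeats,
                )
                for f, v in zip(subset, imp):
                    scores[f] += v / splits_per_iter
        k = max(1, int(np.floor(drop_frac * len(features))))
        shuffled = [features[i] for i in rng.permutation(len(features))]
        ranked = sorted(shuffled, key=lambda f: scores[f])  # random tie-break
        features = [f for f in features if f not in set(ranked[:k])]
        if not features:
            raise RuntimeError("elimination removed every feature")
    final_imp = _subset_importance(
        matrix[features].to_numpy(dtype=float), y, trees,
        int(rng.integers(2**31)), importance_repeats,
    )
    return [features[i] for i in np.argsort(final_imp)[::-1]]


def _subset_importance(X: np.ndarray, y: np.ndarray, trees: int, seed: int,
                       repeats: int) -> np.ndarray:
    """Permutation importance on a stratified held-out third.

    A fully grown forest memorizes its training data, so importances
    must be scored on samples the trees did not see (the analogue of the
    out-of-bag accuracy decrease).
    """
    from sklearn.model_selection import train_test_split

    tr, te = train_test_split(
        np.arange(len(y)), test_size=1 / 3, stratify=y, random_state=seed % 2**31
    )
    forest = _forest(X.shape[1], trees, seed)
    forest.fit(X[tr], y[tr])
    res = permutation_importance(
        forest, X[te], y[te], n_repeats=repeats, random_state=seed, n_jobs=1
    )
    return res.importances_mean


def ensemble_consensus(
    candidate_lists: dict[str, list[list[str]]],
    vote_thresholds: dict[str, int],
) -> tuple[set[str], pd.DataFrame]:
    """Vote features across ranker lists, per comparison group.

    Returns the union of features meeting each group's threshold plus a
    provenance table (feature, group, votes, selected).
    """
    rows = []
    selected: set[str] = set()
    for group, lists in candidate_lists.items():
        threshold = vote_thresholds[group]
        if threshold > len(lists):
            raise ValueError(
                f"{group}: threshold {threshold} exceeds list count {len(lists)}"
            )
        votes: dict[str, int] = {}
        for lst in lists:
            for feat in set(lst):
                votes[feat] = votes.get(feat, 0) + 1
        for feat, v in votes.items():
            ok = v >= threshold
            rows.append((feat, group, v, ok))
            if ok:
                selected.add(feat)
    provenance = pd.DataFrame(rows, columns=["feature", "group", "votes", "selected"])
    return selected, provenance


def high_confidence_filter(
    tc_table: pd.DataFrame,
    tpm: pd.DataFrame,
    allowed_categories: tuple[str, ...] = (
        "canonical",
        "known_alternative",
        "novel_intergenic",
    ),
    min_width: int = 2,
    max_width: int = 100,
    min_tpm: float = 10.0,
    min_subjects: int = 3,
) -> pd.Index:
    """High-confidence TCs: allowed category, width in [2, 100] and
    TPM strictly above ``min_tpm`` in at least ``min_subjects``."""
    ok_cat = tc_table["category"].isin(allowed_categories)
    ok_width = tc_table["width"].between(min_width, max_width)
    expressed = (tpm.loc[tc_table.index] > min_tpm).sum(axis=1) >= min_subjects
    keep = ok_cat & ok_width & expressed
    return tc_table.index[keep]


# ---------------------------------------------------------------------------
# Two-step classifier


GRID_N = (2, 3, 4, 5)
GRID_Y = (0.5, 0.75, 1.0, 1.5, 2.0)


class TwoStepClassifier:
    """Two random forests: IBD-vs-Ctrl, then CDa-vs-UCa for IBD calls.

    ``params=(n, m)`` fixes min node size and mtry; otherwise ``fit``
    grid searches (n in grid_n, m = sqrt(x-1)*y for y in grid_y) for the
    combination with the best mean overall two-step accuracy under
    stratified ``cv_folds``-fold cross-validation, then refits both
    forests on all training data.
    """

    def __init__(
        self,
        trees: int = 1001,
        grid_n: tuple[int, ...] = GRID_N,
        grid_y: tuple[float, ...] = GRID_Y,
        cv_folds: int = 5,
        seed: int = 0,
        params: tuple[int, int] | None = None,
    ) -> None:
        self.trees = trees
        self.grid_n = grid_n
        self.grid_y = grid_y
        self.cv_folds = cv_folds
        self.seed = seed
        self.params = params
        self.best_params_: tuple[int, int] | None = params

    def _fit_pair(self, X: np.ndarray, y: np.ndarray, n: int, m: int, seed: int):
        is_ctrl = y == "Ctrl"
        y1 = np.where(is_ctrl, "Ctrl", "IBD")
        step1 = _forest(X.shape[1], self.trees, seed, mtry=m, min_node=n)
        step1.fit(X, y1)
        ibd = ~is_ctrl
        step2 = _forest(X.shape[1], self.trees, seed + 1, mtry=m, min_node=n)
        step2.fit(X[ibd], y[ibd])
        return step1, step2

    @staticmethod
    def _predict_pair(step1, step2, X: np.ndarray) -> np.ndarray:
        pred = step1.predict(X).astype(object)
        ibd = pred == "IBD"
        if ibd.any():
            pred[ibd] = step2.predict(X[ibd])
        return pred.astype(str)

    def fit(self, X: pd.DataFrame | np.ndarray, y) -> "TwoStepClassifier":
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y).astype(str)
        for cls in ("CDa", "UCa", "Ctrl"):
            if (ya == cls).sum() == 0:
                raise ValueError(f"class {cls} absent from training labels")
        if self.best_params_ is None:
            self.best_params_ = self._grid_search(Xa, ya)
        n, m = self.best_params_
        self.step1_, self.step2_ = self._fit_pair(Xa, ya, n, m, self.seed)
        return self

    def _grid_search(self, X: np.ndarray, y: np.ndarray) -> tuple[int, int]:
        x = X.shape[1]
        best, best_acc = None, -1.0
        for n in self.grid_n:
            for yy in self.grid_y:
                m = int(np.clip(round(np.sqrt(max(x - 1, 1)) * yy), 1, x))
                accs = []
                for fold_seed, (tr, te) in enumerate(
                    _stratified_folds(y, self.cv_folds, self.seed)
                ):
                    s1, s2 = self._fit_pair(X[tr], y[tr], n, m, self.seed + fold_seed)
                    pred = self._predict_pair(s1, s2, X[te])
                    accs.append(float(np.mean(pred == y[te])))
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best, best_acc = (n, m), acc
        return best  # type: ignore[return-value]

    def predict(self, X) -> np.ndarray:
        return self._predict_pair(self.step1_, self.step2_, np.asarray(X, dtype=float))


def _stratified_folds(y: np.ndarray, folds: int, seed: int, max_redraws: int = 20):
    """Stratified folds whose training parts contain every class."""
    classes = np.unique(y)
    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(set(classes) <= set(y[tr]) for tr, _ in splits):
            return splits
    raise RuntimeError("could not draw stratified folds containing all classes")


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class CvReport:
    """Repeated-CV metrics: means and percentile 95% CIs across reps."""

    overall_accuracy: float
    overall_ci: tuple[float, float]
    per_class: pd.DataFrame  # accuracy/sensitivity/specificity per class
    confusion: pd.DataFrame  # rows predicted, columns true; columns sum to 1
    accuracies: np.ndarray = field(repr=False, default=None)  # type: ignore

    def summary(self) -> str:
        lines = [
            "Repeated cross-validation report",
            f"  overall accuracy: {self.overall_accuracy:.3f} "
            f"(95% CI {self.overall_ci[0]:.3f}-{self.overall_ci[1]:.3f}, "
            f"{len(self.accuracies)} repetitions)",
            "  per-class (one-vs-rest):",
            self.per_class.round(3).to_string(),
            "  column-normalized confusion (columns = true label):",
            self.confusion.round(3).to_string(),
        ]
        return "\n".join(lines)


def _one_vs_rest_metrics(y_true: np.ndarray, y_pred: np.ndarray, cls: str):
    pos = y_true == cls
    pred_pos = y_pred == cls
    tp = float((pos & pred_pos).sum())
    tn = float((~pos & ~pred_pos).sum())
    fp = float((~pos & pred_pos).sum())
    fn = float((pos & ~pred_pos).sum())
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return acc, sens, spec


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes) -> np.ndarray:
    mat = np.zeros((len(classes), len(classes)))
    for i, pc in enumerate(classes):
        for j, tc in enumerate(classes):
            mat[i, j] = float(((y_pred == pc) & (y_true == tc)).sum())
    return mat


def evaluate_repeated_cv(
    make_model,
    matrix,
    labels,
    folds: int = 5,
    reps: int = 101,
    seed: int = 0,
) -> CvReport:
    """Repeat stratified k-fold CV ``reps`` times for a model factory.

    ``make_model(seed)`` must return an object with fit/predict.  Means
    and percentile 95% CIs are taken across repetitions; per-class
    metrics recast the problem one-vs-rest.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels).astype(str)
    classes = sorted(np.unique(y))
    rng = np.random.default_rng(seed)
    overall, per_class_rows = [], []
    conf_total = np.zeros((len(classes), len(classes)))
    for _rep in range(reps):
        rep_seed = int(rng.integers(2**31))
        y_pred = np.empty(len(y), dtype=object)
        for k, (tr, te) in enumerate(_stratified_folds(y, folds, rep_seed)):
            model = make_model(rep_seed + k)
            model.fit(X[tr], y[tr])
            y_pred[te] = model.predict(X[te])
        y_pred = y_pred.astype(str)
        overall.append(float(np.mean(y_pred == y)))
        per_class_rows.append(
            [m for cls in classes for m in _one_vs_rest_metrics(y, y_pred, cls)]
        )
        conf_total += _confusion(y, y_pred, classes)
    overall_arr = np.array(overall)
    pc = np.array(per_class_rows)
    per_class = pd.DataFrame(
        {
            "accuracy": pc[:, 0::3].mean(axis=0),
            "sensitivity": pc[:, 1::3].mean(axis=0),
            "specificity": pc[:, 2::3].mean(axis=0),
            "sensitivity_lo": np.percentile(pc[:, 1::3], 2.5, axis=0),
            "sensitivity_hi": np.percentile(pc[:, 1::3], 97.5, axis=0),
        },
        index=classes,
    )
    col_sums = conf_total.sum(axis=0)
    confusion = pd.DataFrame(
        conf_total / np.where(col_sums == 0, 1, col_sums)[None, :],
        index=[f"pred_{c}" for c in classes],
        columns=classes,
    )
    return CvReport(
        overall_accuracy=float(overall_arr.mean()),
        overall_ci=(
            float(np.percentile(overall_arr, 2.5)),
            float(np.percentile(overall_arr, 97.5)),
        ),
        per_class=per_class,
        confusion=confusion,
        accuracies=overall_arr,
    )


@dataclass
class NullReport:
    null_accuracy: float
    null_ci: tuple[float, float]
    null_confusion: pd.DataFrame
    actual_accuracy: float
    fold_change: pd.Series  # actual vs null per-class correct fraction
    null_accuracies: np.ndarray = field(repr=False, default=None)  # type: ignore


def shuffled_label_null(
    make_model,
    matrix_train,
    labels_train,
    matrix_test,
    labels_test,
    reps: int = 1001,
    seed: int = 0,
) -> NullReport:
    """Train on permuted labels, predict a held-out cohort, aggregate.

    Reports the null accuracy distribution, the aggregated
    column-normalized null confusion, the actual model's accuracy on the
    same split and the per-class actual/null correct-fraction fold
    change.
    """
    Xtr = np.asarray(matrix_train, dtype=float)
    Xte = np.asarray(matrix_test, dtype=float)
    ytr = np.asarray(labels_train).astype(str)
    yte = np.asarray(labels_test).astype(str)
    classes = sorted(np.unique(np.concatenate([ytr, yte])))
    rng = np.random.default_rng(seed)
    accs = []
    conf = np.zeros((len(classes), len(classes)))
    for _ in range(reps):
        perm = rng.permutation(len(ytr))
        model = make_model(int(rng.integers(2**31)))
        model.fit(Xtr, ytr[perm])
        pred = np.asarray(model.predict(Xte)).astype(str)
        accs.append(float(np.mean(pred == yte)))
        conf += _confusion(yte, pred, classes)
    actual = make_model(seed)
    actual.fit(Xtr, ytr)
    actual_pred = np.asarray(actual.predict(Xte)).astype(str)
    actual_acc = float(np.mean(actual_pred == yte))
    col = conf.sum(axis=0)
    null_conf = pd.DataFrame(
        conf / np.where(col == 0, 1, col)[None, :],
        index=[f"pred_{c}" for c in classes],
        columns=classes,
    )
    null_diag = np.diag(null_conf.to_numpy())
    actual_conf = _confusion(yte, actual_pred, classes)
    actual_col = actual_conf.sum(axis=0)
    actual_diag = np.diag(actual_conf / np.where(actual_col == 0, 1, actual_col)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(null_diag > 0, actual_diag / null_diag, np.nan)
    accs_arr = np.array(accs)
    return NullReport(
        null_accuracy=float(accs_arr.mean()),
        null_ci=(
            float(np.percentile(accs_arr, 2.5)),
            float(np.percentile(accs_arr, 97.5)),
        ),
        null_confusion=null_conf,
        actual_accuracy=actual_acc,
        fold_change=pd.Series(fc, index=classes, name="actual_vs_null"),
        null_accuracies=accs_arr,
    )


def accuracy_vs_feature_count(
    make_model,
    matrix: pd.DataFrame,
    labels,
    counts: list[int],
    reps: int = 11,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV accuracy as a function of the number of (random) features."""
    y = np.asarray(labels).astype(str)
    rng = np.random.default_rng(seed)
    rows = []
    for count in counts:
        if not 1 <= count <= matrix.shape[1]:
            raise ValueError(f"feature count {count} outside [1, {matrix.shape[1]}]")
        accs = []
        for _ in range(reps):
            cols = rng.choice(matrix.shape[1], size=count, replace=False)
            rep = evaluate_repeated_cv(
                make_model, matrix.iloc[:, cols], y, folds=folds, reps=1,
                seed=int(rng.integers(2**31)),
            )
            accs.append(rep.overall_accuracy)
        accs_arr = np.array(accs)
        rows.append(
            (count, float(accs_arr.mean()),
             float(np.percentile(accs_arr, 2.5)), float(np.percentile(accs_arr, 97.5)))
        )
    return pd.DataFrame(rows, columns=["n_features", "accuracy", "ci_lo", "ci_hi"])
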