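"""Classifier-assessment protocol: stratified marker resampling, macro and
per-class F1, quadratic loss, a probabilistic KNN baseline and
cross-classifier contingency comparison.

Markers are repeatedly split into class-stratified train (80%) / test
(20%) partitions; each classifier is trained on the training markers,
predicts class probabilities for the withheld test markers, and is scored
by macro-F1 on the argmax labels and by the quadratic loss
Q2 = sum_i ||q_i - p_i||^2 on the probability vectors (q_i one-hot truth).
The loss rewards calibrated, not merely correct, predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier

from .core import ExpressionMatrix, Hyperparameters, MarkerAnnotation

__all__ = [
    "SplitSpec",
    "EvalResult",
    "stratified_split",
    "f1_scores",
    "quadratic_loss",
    "knn_probabilistic",
    "crossval_compare",
    "contingency_table",
    "pairwise_method_tests",
]


@dataclass(frozen=True)
class SplitSpec:
    """One class-stratified train/test partition of the marker set."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    round_index: int = 0


@dataclass
class EvalResult:
    """Scores of one method on one evaluation round."""

    method: str
    macro_f1: float
    per_class_f1: dict[str, float]
    quadratic_loss: float
    round_index: int = 0


def stratified_split(
    markers: MarkerAnnotation, train_fraction: float, seed: int, round_index: int = 0
) -> SplitSpec:
    """Per class, a seeded shuffle puts round(train_fraction * n_c) markers
    in train and the remainder in test."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    counts = markers.counts()
    for cls, n_c in counts.items():
        if n_c < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 markers; cannot stratify")
    rng = np.random.default_rng([seed, round_index])
    train: list[str] = []
    test: list[str] = []
    by_class: dict[str, list[str]] = {c: [] for c in markers.classes}
    for pid, cls in markers.labels.items():
        by_class[cls].append(pid)
    for cls in markers.classes:
        ids = sorted(by_class[cls])
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both partitions non-empty
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitSpec(
        train_ids=tuple(train), test_ids=tuple(test), seed=seed, round_index=round_index
    )


def f1_scores(
    true_labels, predicted_labels, classes: tuple[str, ...] | None = None
) -> tuple[float, dict[str, float]]:
    """Macro and per-class F1.

    F1 = 2 precision recall / (precision + recall) from per-class tp/fp/fn;
    a class whose precision + recall vanishes contributes 0; the macro
    score is the unweighted mean over the class catalogue.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    if classes is None:
        classes = tuple(sorted(set(true_labels) | set(predicted_labels)))
    per = f1_score(
        true_labels, predicted_labels, labels=list(classes), average=None, zero_division=0
    )
    macro = float(np.mean(per))
    return macro, {c: float(v) for c, v in zip(classes, per)}


def quadratic_loss(true_onehot: np.ndarray, predicted_prob: np.ndarray) -> float:
    """Q2 = sum over proteins of the squared L2 distance between the
    one-hot truth and the predicted probability vector (no averaging)."""
    q = np.asarray(true_onehot, dtype=float)
    p = np.asarray(predicted_prob, dtype=float)
    if q.shape != p.shape:
        raise ValueError(f"shape mismatch: {q.shape} vs {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("predicted probability rows must sum to 1")
    row_ok = np.all((q == 0) | (q == 1)) and np.all(q.sum(axis=1) == 1)
    if not row_ok:
        raise ValueError("true rows must be one-hot")
    return float(np.sum((q - p) ** 2))


def _onehot(labels, classes: tuple[str, ...]) -> np.ndarray:
    idx = {c: k for k, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, idx[lab]] = 1.0
    return out


def knn_probabilistic(
    train_X: np.ndarray,
    train_labels,
    test_X: np.ndarray,
    classes: tuple[str, ...],
    alpha: float = 0.5,
    k_grid: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15),
    cv: int = 5,
) -> np.ndarray:
    """Laplace-smoothed K-nearest-neighbour class probabilities.

    p(z = k | x) = (N_k + alpha d_k C) / (K + alpha C), with N_k the count
    of class-k neighbours among the K nearest, d_k the training incidence
    of class k, C the number of classes and alpha the pseudo-count
    (alpha = 0.5, a Jeffreys-style prior, by default). Rows sum to 1
    because sum_k N_k = K and sum_k d_k = 1. K is chosen by internal
    cross-validated accuracy over ``k_grid``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_labels = np.asarray([str(x) for x in train_labels])
    n_train = train_X.shape[0]
    grid = [k for k in k_grid if k <= n_train]
    if not grid:
        raise ValueError(f"every k in {k_grid} exceeds the training size {n_train}")
    min_class = min(np.sum(train_labels == c) for c in set(train_labels))
    n_folds = max(2, min(cv, int(min_class)))
    if len(grid) > 1 and n_folds >= 2:
        search = GridSearchCV(
            KNeighborsClassifier(), {"n_neighbors": grid}, cv=n_folds, scoring="accuracy"
        )
        search.fit(train_X, train_labels)
        k_best = int(search.best_params_["n_neighbors"])
    else:
        k_best = grid[0]
    knn = KNeighborsClassifier(n_neighbors=k_best).fit(train_X, train_labels)
    _, nbr_idx = knn.kneighbors(test_X)
    C = len(classes)
    d = np.array([np.mean(train_labels == c) for c in classes])
    probs = np.empty((test_X.shape[0], C))
    for i in range(test_X.shape[0]):
        nbr_labels = train_labels[nbr_idx[i]]
        counts = np.array([np.sum(nbr_labels == c) for c in classes], dtype=float)
        probs[i] = (counts + alpha * d * C) / (k_best + alpha * C)
    return probs


def _svm_probabilistic(train_X, train_labels, test_X, classes, seed: int) -> np.ndarray:
    """Off-the-shelf RBF SVM with internal 5-fold search over (gamma, cost)
    and Platt-style probability outputs."""
    from sklearn.svm import SVC

    train_labels = np.asarray([str(x) for x in train_labels])
    min_class = min(np.sum(train_labels == c) for c in set(train_labels))
    n_folds = max(2, min(5, int(min_class)))
    grid = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1, 1.0]}
    search = GridSearchCV(
        SVC(kernel="rbf", probability=True, random_state=seed), grid,
        cv=n_folds, scoring="accuracy",
    )
    search.fit(train_X, train_labels)
    est = search.best_estimator_
    probs = est.predict_proba(test_X)
    order = [list(est.classes_).index(c) for c in classes]
    return probs[:, order]


def _tagm_probabilistic(
    matrix: ExpressionMatrix,
    markers: MarkerAnnotation,
    split: SplitSpec,
    method: str,
    hyper: Hyperparameters | None,
    mcmc_settings: dict | None,
    seed: int,
) -> np.ndarray:
    """Fit TAGM with training markers labelled and the full remainder
    (test markers plus genuinely unlabelled proteins) unlabelled; return
    class-membership probabilities for the test markers."""
    train_set = set(split.train_ids)
    labels = {pid: markers.labels[pid] for pid in split.train_ids}
    sub_markers = MarkerAnnotation(labels=labels, classes=markers.classes)
    test_rows = [matrix.index_of(pid) for pid in split.test_ids]
    if method == "tagm_map":
        from .map_em import TAGMMAPClassifier, fit_map

        result = fit_map(matrix, sub_markers, hyper=hyper)
        clf = TAGMMAPClassifier()
        clf.result_ = result
        clf.classes_ = np.asarray(markers.classes)
        test_mat = ExpressionMatrix(
            values=matrix.values[test_rows],
            protein_ids=tuple(split.test_ids),
            fraction_ids=matrix.fraction_ids,
        )
        return clf.predict_membership_proba(test_mat)
    if method == "tagm_mcmc":
        from .core import default_hyperparameters
        from .mcmc import MCMCSettings, pool_chains, run_chains

        settings = MCMCSettings(**{
            "n_chains": 2, "n_iter": 300, "burn_in": 100, "thin": 5, "seed": seed,
            **(mcmc_settings or {}),
        })
        h = hyper or default_hyperparameters(matrix, sub_markers)
        chains = run_chains(matrix, sub_markers, h, settings)
        pooled = pool_chains(chains)
        probs = pooled.prob_samples  # (T, N_U, K)
        row_sums = probs.sum(axis=2, keepdims=True)
        member = np.divide(
            probs, row_sums, out=np.full_like(probs, 1.0 / probs.shape[2]),
            where=row_sums > 0,
        )
        member_mean = member.mean(axis=0)
        id_row = {pid: i for i, pid in enumerate(pooled.unlabelled_ids)}
        return np.stack([member_mean[id_row[pid]] for pid in split.test_ids])
    raise ValueError(f"unknown TAGM method {method!r}")


def crossval_compare(
    matrix: ExpressionMatrix,
    markers: MarkerAnnotation,
    methods: tuple[str, ...] = ("tagm_map", "knn"),
    rounds: int = 100,
    seed: int = 0,
    train_fraction: float = 0.8,
    hyper: Hyperparameters | None = None,
    mcmc_settings: dict | None = None,
) -> pd.DataFrame:
    """Repeated stratified-split evaluation of the requested classifiers.

    Returns a long-format table (round, method, macro_f1, quadratic_loss,
    one column per class F1). A method that fails on a round is recorded
    with NaN scores and a warning, never silently dropped.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    markers.validate_against(matrix)
    classes = markers.classes
    records = []
    for r in range(rounds):
        split = stratified_split(markers, train_fraction, seed=seed, round_index=r)
        train_rows = [matrix.index_of(pid) for pid in split.train_ids]
        test_rows = [matrix.index_of(pid) for pid in split.test_ids]
        train_X = matrix.values[train_rows]
        test_X = matrix.values[test_rows]
        train_y = [markers.labels[pid] for pid in split.train_ids]
        true_y = [markers.labels[pid] for pid in split.test_ids]
        true_onehot = _onehot(true_y, classes)
        for method in methods:
            try:
                if method in ("tagm_map", "tagm_mcmc"):
                    probs = _tagm_probabilistic(
                        matrix, markers, split, method, hyper, mcmc_settings,
                        seed=seed * 1009 + r,
                    )
                elif method == "knn":
                    probs = knn_probabilistic(train_X, train_y, test_X, classes)
                elif method == "svm":
                    probs = _svm_probabilistic(
                        train_X, train_y, test_X, classes, seed=seed * 1009 + r
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:  # noqa: BLE001 — record, don't drop
                warnings.warn(f"method {method} failed on round {r}: {exc}", stacklevel=2)
                records.append(
                    {"round": r, "method": method, "macro_f1": np.nan,
                     "quadratic_loss": np.nan}
                )
                continue
            pred_labels = [classes[k] for k in np.argmax(probs, axis=1)]
            macro, per_class = f1_scores(true_y, pred_labels, classes=classes)
            loss = quadratic_loss(true_onehot, probs)
            rec = {"round": r, "method": method, "macro_f1": macro, "quadratic_loss": loss}
            rec.update({f"f1_{c}": v for c, v in per_class.items()})
            records.append(rec)
    return pd.DataFrame.from_records(records)


def contingency_table(
    labels_a: dict[str, str],
    labels_b: dict[str, str],
    restrict: set[str] | None = None,
) -> pd.DataFrame:
    """Row-proportion contingency table between two hard labellings.

    Entry (j, k) is the proportion of common proteins labelled j by
    classifier a that classifier b labels k; rows sum to 1. ``restrict``
    optionally limits the comparison to a subset of protein ids (e.g.
    those classifier a labelled above a probability threshold).
    """
    common = set(labels_a) & set(labels_b)
    if restrict is not None:
        common &= set(restrict)
    if not common:
        raise ValueError("no common proteins to compare")
    rows = sorted({labels_a[p] for p in common})
    cols = sorted({labels_b[p] for p in common})
    table = pd.DataFrame(0.0, index=rows, columns=cols)
    for p in common:
        table.loc[labels_a[p], labels_b[p]] += 1.0
    return table.div(table.sum(axis=1), axis=0)


def pairwise_method_tests(
    results: pd.DataFrame, metric: str = "macro_f1", alpha: float = 0.01
) -> pd.DataFrame:
    """Pairwise two-sided unpaired t-tests between methods on a metric with
    Benjamini-Hochberg correction; a reporting utility over the long
    table returned by :func:`crossval_compare`."""
    from itertools import combinations

    from scipy.stats import ttest_ind
    from statsmodels.stats.multitest import multipletests

    methods = sorted(results["method"].unique())
    pairs = list(combinations(methods, 2))
    raw = []
    for a, b in pairs:
        xa = results.loc[results["method"] == a, metric].dropna()
        xb = results.loc[results["method"] == b, metric].dropna()
        stat, p = ttest_ind(xa, xb, equal_var=False)
        raw.append({"method_a": a, "method_b": b, "t": float(stat), "p_raw": float(p)})
    out = pd.DataFrame(raw)
    if len(out):
        rej, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["significant"] = rej
    return out
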