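"""Feature ranking, subset cutting, sparse-support and RFE selection.

Three families of feature selection operate on a labelled
:class:`~dbpkit.features.FeatureTable`:

* filters — per-feature variance, the chi-squared statistic against the
  class label, and the maximal information coefficient (MIC);
* embedded rankings — absolute coefficients of logistic regression or a
  linear SVM, and impurity importances of a random forest, fit on the full
  table; plus the nonzero support of L1/elastic-net regularized linear
  models (Lasso, LassoLars, ElasticNet);
* a wrapper — recursive feature elimination scored by cross-validation
  (RFE-CV), which refits a linear ranker each round, drops the
  lowest-weighted features, and keeps the subset size with the best CV
  accuracy of the evaluation classifier.

Rankings are deterministic: ties are broken by original column order
(stable sort), and any stochastic fit takes an explicit seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.linear_model import ElasticNet, Lasso, LassoLars, LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .errors import ConfigError
from .features import FeatureTable

RANKING_METHODS = ("variance", "chi2", "mic", "lr", "linsvm", "rf")
EMBEDDED_ESTIMATORS = ("lr", "linsvm", "rf")
REGULARIZERS = ("lasso", "lassolars", "elasticnet")

#: Display labels used in selection origins ("LR4", "LinSVM20", ...).
METHOD_LABELS = {
    "variance": "Variance", "chi2": "Chi2", "mic": "MIC",
    "lr": "LR", "linsvm": "LinSVM", "rf": "RF",
}


@dataclass(frozen=True)
class FeatureRanking:
    """Feature names sorted by descending score under one method."""

    method: str
    ordered_names: list[str]
    scores: Mapping[str, float]


@dataclass(frozen=True)
class SelectionResult:
    """A selected feature subset with its provenance."""

    origin: str
    selected_names: list[str]
    provenance: Mapping[str, object] = field(default_factory=dict)


def _rank(method: str, names: Sequence[str],
          scores: np.ndarray) -> FeatureRanking:
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ConfigError(f"{method}: non-finite feature scores")
    order = np.argsort(-scores, kind="stable")  # ties keep column order
    return FeatureRanking(
        method=method,
        ordered_names=[names[j] for j in order],
        scores={name: float(s) for name, s in zip(names, scores)},
    )


# ---------------------------------------------------------------------------
# Filter rankings
# ---------------------------------------------------------------------------

def score_variance(table: FeatureTable) -> FeatureRanking:
    """Rank by population variance of each feature column."""
    if table.n_samples < 2:
        raise ConfigError("variance ranking needs at least 2 samples")
    return _rank("variance", table.names, table.values.var(axis=0))


def score_chi2(table: FeatureTable) -> FeatureRanking:
    """Rank by the chi-squared statistic between feature mass and class.

    Features must be nonnegative (MinMax-normalized input); a feature whose
    total is zero scores 0 by convention.
    """
    if (table.values < 0).any():
        raise ConfigError("chi2 requires nonnegative feature values")
    _check_two_classes(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stats, _ = _sk_chi2(table.values, table.labels)
    return _rank("chi2", table.names, np.nan_to_num(stats, nan=0.0))


# --- MIC -------------------------------------------------------------------
#
# MIC(x, y) is the maximum over all x-bins-by-y-bins grids with
# bins_x * bins_y <= B(n) of the grid mutual information normalized by
# log2(min(bins_x, bins_y)).  Following the published approximation, one
# axis is equipartitioned by rank and the other axis partition is found
# exactly by dynamic programming; both orientations are searched, which
# makes the statistic symmetric.  B(n) = max(n^alpha, 4) so that the
# smallest informative grid (2x2) is always admissible.


def _equipartition_assign(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each point a y-bin index, ~n/n_bins points per bin.

    Equal values always share a bin; bin targets are recomputed from the
    remaining mass so ties cannot starve later bins.  Returned labels are
    contiguous starting at 0 (fewer than ``n_bins`` bins may be used).
    """
    n = len(v)
    order = np.argsort(v, kind="stable")
    sv = v[order]
    # boundaries of tie groups in sorted order
    group_starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
    group_ends = np.r_[group_starts[1:], n]
    assign_sorted = np.empty(n, dtype=np.intp)
    b = 0
    filled = 0           # points in bins before the current one
    in_bin = 0           # points in the current bin
    for start, end in zip(group_starts, group_ends):
        size = end - start
        if in_bin > 0 and b < n_bins - 1:
            target = (n - filled) / (n_bins - b)
            # close the bin if the group fits the next bin better
            if in_bin + size - target > target - in_bin or in_bin >= target:
                b += 1
                filled += in_bin
                in_bin = 0
        assign_sorted[start:end] = b
        in_bin += size
    labels = np.empty(n, dtype=np.intp)
    labels[order] = assign_sorted
    return labels


def _clump_counts(x: np.ndarray, q: np.ndarray, ny: int) -> np.ndarray:
    """Per-x-clump y-bin counts; clumps are runs of equal x after sorting."""
    order = np.argsort(x, kind="stable")
    xs, qs = x[order], q[order]
    new_clump = np.r_[True, xs[1:] != xs[:-1]]
    clump_id = np.cumsum(new_clump) - 1
    m = clump_id[-1] + 1
    counts = np.zeros((m, ny), dtype=float)
    np.add.at(counts, (clump_id, qs), 1.0)
    return counts


def _segment_terms(cnt: np.ndarray) -> np.ndarray:
    """``sum_q c_q log2(c_q / tot)`` per row of a counts matrix."""
    tot = cnt.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = cnt * (np.log2(cnt) - np.log2(tot))
    return np.where(cnt > 0, term, 0.0).sum(axis=-1)


def _optimize_x_axis(x: np.ndarray, q: np.ndarray, ny: int,
                     kmax: int) -> np.ndarray:
    """Exact DP: best unnormalized MI for exactly k x-bins, k = 1..kmax.

    Returns I_k = H(Q) - H(Q|P_k) in bits, where P_k is the optimal
    partition of the x-axis into k bins respecting equal-x clumps.
    """
    n = len(x)
    counts = _clump_counts(x, q, ny)
    m = counts.shape[0]
    cum = np.vstack([np.zeros(ny), np.cumsum(counts, axis=0)])  # (m+1, ny)
    n_q = cum[-1]
    p_q = n_q[n_q > 0] / n
    h_q = float(-(p_q * np.log2(p_q)).sum())

    kmax = min(kmax, m)
    # f_prev[i] = best sum of segment terms splitting clumps [0, i) into k bins
    f_prev = _segment_terms(cum[1:] - cum[0])        # k = 1, i = 1..m
    best = np.full(kmax, -np.inf)
    best[0] = f_prev[-1]
    for k in range(2, kmax + 1):
        f_curr = np.full(m, -np.inf)
        for i in range(k, m + 1):
            # last bin covers clumps [j, i), j = k-1 .. i-1
            j = np.arange(k - 1, i)
            seg = _segment_terms(cum[i] - cum[j])
            f_curr[i - 1] = np.max(f_prev[j - 1] + seg)
        f_prev = f_curr
        best[k - 1] = f_prev[-1]
    return h_q + best / n


def mic_statistic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6) -> float:
    """Maximal information coefficient of two samples, in [0, 1].

    A constant input yields 0 by convention.  ``alpha`` sets the grid bound
    ``B(n) = max(n^alpha, 4)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ConfigError("mic_statistic: x and y lengths differ")
    if n < 4:
        raise ConfigError("mic_statistic needs n >= 4")
    B = max(n ** alpha, 4.0)
    best = 0.0
    for a, b in ((x, y), (y, x)):
        best = max(best, _mic_one_orientation(a, b, B))
    return min(best, 1.0)


def _mic_one_orientation(x: np.ndarray, y: np.ndarray, B: float) -> float:
    """Max normalized MI with y equipartitioned and x optimized by DP."""
    best = 0.0
    seen: set[int] = set()
    for ny in range(2, int(B // 2) + 1):
        q = _equipartition_assign(y, ny)
        ny_eff = int(q.max()) + 1
        if ny_eff < 2 or ny_eff in seen:
            continue
        seen.add(ny_eff)
        kmax = int(B // ny_eff)
        if kmax < 2:
            continue
        i_k = _optimize_x_axis(x, q, ny_eff, kmax)
        running = -np.inf
        for k in range(2, len(i_k) + 1):
            running = max(running, i_k[k - 1])
            denom = math.log2(min(k, ny_eff))
            best = max(best, running / denom)
    return best


def score_mic(table: FeatureTable, alpha: float = 0.6) -> FeatureRanking:
    """Rank features by MIC between each column and the class labels."""
    _check_two_classes(table)
    y = table.labels.astype(float)
    scores = np.array([
        0.0 if np.ptp(col) == 0 else mic_statistic(col, y, alpha=alpha)
        for col in table.values.T
    ])
    return _rank("mic", table.names, scores)


# ---------------------------------------------------------------------------
# Embedded rankings and sparse supports
# ---------------------------------------------------------------------------

def _check_two_classes(table: FeatureTable) -> None:
    if len(np.unique(table.labels)) < 2:
        raise ConfigError("both classes must be present")


def _make_embedded(estimator: str, seed: int):
    if estimator == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if estimator == "linsvm":
        return LinearSVC(max_iter=5000, random_state=seed)
    if estimator == "rf":
        return RandomForestClassifier(random_state=seed)
    raise ConfigError(f"unknown embedded estimator {estimator!r}")


def score_embedded(table: FeatureTable, estimator: str,
                   seed: int = 0) -> FeatureRanking:
    """Rank by |coefficient| (lr, linsvm) or impurity importance (rf).

    The estimator is fit once on the full (already normalized) table, so a
    feature set has a single ranking regardless of later CV folds.
    """
    _check_two_classes(table)
    model = _make_embedded(estimator, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(table.values, table.labels)
    if estimator == "rf":
        scores = model.feature_importances_
    else:
        scores = np.abs(model.coef_).ravel()
    return _rank(estimator, table.names, scores)


def top_percent_count(n_features: int, p: float) -> int:
    """Subset size for a top-``p``-percent cut: ``ceil(p/100 * n)``."""
    if not 0 < p <= 100:
        raise ConfigError(f"percent must be in (0, 100], got {p}")
    return math.ceil(p / 100.0 * n_features)


def select_top_percent(ranking: FeatureRanking, p: float) -> SelectionResult:
    """Keep the top ``ceil(p/100 * n)`` names of a ranking."""
    count = top_percent_count(len(ranking.ordered_names), p)
    label = METHOD_LABELS.get(ranking.method, ranking.method)
    return SelectionResult(
        origin=f"{label}{p:g}",
        selected_names=ranking.ordered_names[:count],
        provenance={"method": ranking.method, "percent": p, "count": count},
    )


def _make_regularizer(method: str, params: Mapping[str, object] | None,
                      seed: int):
    params = dict(params or {})
    if method == "lasso":
        return Lasso(random_state=seed, **params)
    if method == "lassolars":
        return LassoLars(**params)  # LARS path is deterministic
    if method == "elasticnet":
        return ElasticNet(random_state=seed, **params)
    raise ConfigError(f"unknown regularizer {method!r}")


def select_by_regularizer(
    table: FeatureTable,
    method: str,
    params: Mapping[str, object] | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Select the nonzero-coefficient support of a sparse linear model.

    The model regresses the 0/1 labels on the (MinMax-normalized)
    features; ``params`` (e.g. ``{"alpha": 0.01}``) override the
    implementation defaults and are recorded in the provenance.
    Non-convergence is an error carrying the iteration diagnostics.
    """
    _check_two_classes(table)
    model = _make_regularizer(method, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(table.values, table.labels.astype(float))
        except ConvergenceWarning as exc:
            raise ConfigError(
                f"{method} did not converge "
                f"(n_iter={getattr(model, 'n_iter_', 'unknown')}): {exc}"
            ) from None
    support = np.flatnonzero(model.coef_ != 0)
    label = {"lasso": "Lasso", "lassolars": "LassoLars",
             "elasticnet": "ElasticNet"}[method]
    return SelectionResult(
        origin=label,
        selected_names=[table.names[j] for j in support],
        provenance={"method": method, "params": dict(params or {}),
                    "count": int(support.size)},
    )


# ---------------------------------------------------------------------------
# RFE with cross-validation
# ---------------------------------------------------------------------------

def rfe_cv(
    table: FeatureTable,
    start: SelectionResult,
    ranker: str,
    folds: int = 5,
    step: int = 1,
    seed: int = 0,
    classifier: str = "svm-rbf",
) -> SelectionResult:
    """Recursive feature elimination scored by cross-validated accuracy.

    Starting from ``start.selected_names``, each round refits the linear
    ``ranker`` (lr or linsvm) on the current subset and drops the ``step``
    features with the smallest |coefficient|; every visited subset size is
    scored by pooled ``folds``-fold CV accuracy of ``classifier`` (the
    Gaussian-kernel SVM by default).  The subset with the highest accuracy
    wins; on ties the earliest-visited (largest) subset is kept.
    """
    from .evaluation import cross_validate

    if ranker not in ("lr", "linsvm"):
        raise ConfigError(f"rfe ranker must be lr or linsvm, got {ranker!r}")
    if not start.selected_names:
        raise ConfigError("rfe_cv needs a nonempty starting subset")
    if step < 1:
        raise ConfigError("step must be >= 1")

    current = list(start.selected_names)
    best_names, best_acc = None, -1.0
    while True:
        sub = table.subset(current)
        report = cross_validate(sub, classifier, folds=folds, seed=seed)
        if report.pooled.ACC > best_acc:
            best_acc = report.pooled.ACC
            best_names = list(current)
        if len(current) <= 1:
            break
        ranking = score_embedded(sub, ranker, seed=seed)
        n_drop = min(step, len(current) - 1)
        dropped = set(ranking.ordered_names[-n_drop:])
        current = [n for n in current if n not in dropped]
    return SelectionResult(
        origin=f"{start.origin}_RFE",
        selected_names=best_names,
        provenance={"start": start.origin, "ranker": ranker, "step": step,
                    "folds": folds, "seed": seed, "cv_acc": best_acc,
                    "count": len(best_names)},
    )
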