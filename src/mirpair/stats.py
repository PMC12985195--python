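"""Rank statistics shared across the pipeline.

The central identity used throughout is AUC = U / (n1 * n0): the area under
the ROC curve of a score equals the Mann-Whitney U statistic (with midrank
handling of ties) divided by the number of case-control comparisons. AUC is
computed here directly from midranks, which is both exact and O(n log n);
the trapezoidal-ROC and exhaustive pair-counting routes exist as independent
cross-checks in the test suite.

The DeLong variance estimator expresses the AUC as a two-sample U-statistic
and estimates its variance from per-observation structural components
(placement values), giving the standard asymptotic confidence interval
without resampling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    cases, controls = scores[labels], scores[~labels]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    return cases, controls


def midrank_auc(scores, labels) -> float:
    """AUC via midranks: P(case score > control score) + 0.5 P(tie)."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    n1, n0 = cases.size, controls.size
    ranks = sps.rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def midrank_auc_matrix(scores: np.ndarray, labels) -> np.ndarray:
    """Column-wise midrank AUC for an (n_samples, n_features) score matrix."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    ranks = sps.rankdata(scores, axis=0)
    u = ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def mann_whitney(scores, labels, exact_max_comparisons: int = 400) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of case vs control scores.

    Returns ``(U, p)`` with U oriented as "number of case-over-control wins
    plus half-ties". The exact null distribution is used when the comparison
    count n1*n0 is small and the data are tie-free; otherwise the normal
    approximation with tie correction.
    """
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    n1, n0 = cases.size, controls.size
    has_ties = np.unique(np.concatenate([cases, controls])).size < n1 + n0
    method = "exact" if (n1 * n0 <= exact_max_comparisons and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(cases, controls, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def auc_u_identity(scores, labels) -> dict:
    """Compute AUC and U side by side and assert AUC == U/(n1*n0).

    The identity is structural (both are midrank counts of case-over-control
    wins); any deviation beyond machine precision indicates a defect.
    """
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    n1, n0 = cases.size, controls.size
    auc = midrank_auc(scores, labels)
    u, p = mann_whitney(scores, labels)
    if abs(auc - u / (n1 * n0)) > 1e-12:
        raise AssertionError(f"AUC {auc} != U/(n1*n0) {u / (n1 * n0)}")
    return {"auc": auc, "u": u, "p": p, "n_case": n1, "n_control": n0}


def roc_points(scores, labels) -> np.ndarray:
    """ROC polyline as (1 - specificity, sensitivity) rows, (0,0) to (1,1)."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _split(scores, labels)
    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    pts = np.column_stack([fpr, tpr])
    if not np.array_equal(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.array_equal(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    n1, n0 = cases.size, controls.size
    all_ranks = sps.rankdata(np.concatenate([cases, controls]))
    case_ranks = sps.rankdata(cases)
    control_ranks = sps.rankdata(controls)
    # placements: per-case fraction of controls it beats, and vice versa
    v10 = (all_ranks[:n1] - case_ranks) / n0
    v01 = 1.0 - (all_ranks[n1:] - control_ranks) / n1
    auc = float(v10.mean())
    if n1 > 1 and n0 > 1:
        var = float(np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0)
    else:
        var = float("nan")
    return auc, var


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float, bool]:
    """DeLong asymptotic CI for the AUC, truncated to [0, 1].

    Returns ``(auc, low, high, degenerate)``; ``degenerate`` marks a
    zero-variance interval (e.g. perfect separation), where the interval
    collapses to the point estimate.
    """
    auc, var = delong_auc_variance(scores, labels)
    if not np.isfinite(var) or var <= 0.0:
        return auc, auc, auc, True
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half)), False


def bootstrap_auc_ci(
    scores,
    labels,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float, float, bool]:
    """Stratified percentile-bootstrap CI for the AUC (seeded, reproducible)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases, controls = _split(scores, labels)
    rng = np.random.default_rng(seed)
    n1, n0 = cases.size, controls.size
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
    for b in range(n_boot):
        resampled = np.concatenate(
            [rng.choice(cases, n1, replace=True), rng.choice(controls, n0, replace=True)]
        )
        aucs[b] = midrank_auc(resampled, lab)
    alpha = 1.0 - level
    low, high = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    auc = midrank_auc(scores, labels)
    return auc, float(low), float(high), bool(low == high)
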