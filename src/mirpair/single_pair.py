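"""Single-pair classifier evaluation and the AUC gate.

Each delta-Ct pair feature is evaluated as a standalone binary classifier of
case vs control: a univariate logistic regression fitted by maximum
likelihood on the log2-scale feature, with sensitivity / specificity /
accuracy read off in-sample at the probability-0.5 threshold, the midrank
AUC with a DeLong (or stratified-bootstrap) confidence interval, and a
two-sided Mann-Whitney test. Evaluation is deliberately in-sample — the
screening design fits and scores on the same cohort — so the numbers are
discovery-phase metrics, not generalization estimates.

Pairs are oriented so that AUC >= 0.5 (the orientation flag records whether
the raw feature was flipped), and the gate keeps pairs with AUC >= 0.8
(inclusive) for combination building. No multiple-testing adjustment is
applied to the gate; a Benjamini-Hochberg column is available in the results
table for reference only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .pairs import PairFeature, pair_feature_matrix
from .panel import CtMatrix

PROB_THRESHOLD = 0.5  # p >= 0.5 classifies as case


def roc_auc(values, labels) -> tuple[float, np.ndarray]:
    """Midrank AUC plus the ROC polyline for a score vector."""
    return stats.midrank_auc(values, labels), stats.roc_points(values, labels)


def auc_equals_mw(values, labels) -> dict:
    """U statistic alongside the AUC, asserting AUC == U/(n_case*n_control)."""
    return stats.auc_u_identity(values, labels)


def auc_confidence_interval(
    values, labels, method: str = "delong", level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Confidence interval for the AUC of a score vector."""
    if method == "delong":
        _, lo, hi, _ = stats.delong_ci(values, labels, level=level)
    elif method == "bootstrap":
        _, lo, hi, _ = stats.bootstrap_auc_ci(values, labels, level=level, seed=seed)
    else:
        raise ValueError(f"unknown ci method {method!r}")
    return lo, hi


@dataclass
class PairResult:
    """Classifier metrics for one oriented pair."""

    pair_id: str
    mirna_a: str
    mirna_b: str
    orientation: int  # +1: delta_ct used as-is; -1: flipped so AUC >= 0.5
    intercept: float
    slope: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    mw_u: float
    mw_p: float
    n_case: int
    n_control: int
    degenerate: bool = False  # constant feature
    separable: bool = False  # perfect separation; step-rule fallback used
    ci_method: str = "delong"

    def __post_init__(self) -> None:
        if not (self.auc_ci_low - 1e-12 <= self.auc <= self.auc_ci_high + 1e-12):
            raise ValueError("AUC must lie within its confidence interval")
        expected_acc = (
            self.sensitivity * self.n_case + self.specificity * self.n_control
        ) / (self.n_case + self.n_control)
        if abs(self.accuracy - expected_acc) > 1e-12:
            raise ValueError("accuracy must equal the weighted mean of sens/spec")
        if self.auc < 0.5 - 1e-12:
            raise ValueError("oriented AUC must be >= 0.5")


def _confusion_metrics(pred_case: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    labels = labels.astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    sens = float(pred_case[labels].mean()) if n1 else float("nan")
    spec = float((~pred_case[~labels]).mean()) if n0 else float("nan")
    acc = (sens * n1 + spec * n0) / (n1 + n0)
    return sens, spec, acc


def _logistic_mle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Univariate logistic ML fit; returns (intercept, slope, converged)."""
    import statsmodels.api as sm

    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.astype(float), exog).fit(disp=0, maxiter=200)
        except Exception:
            return float("nan"), float("nan"), False
    converged = bool(res.mle_retvals.get("converged", False))
    b0, b1 = (float(v) for v in res.params)
    return b0, b1, converged


def fit_pair_classifier(
    feature: PairFeature,
    labels: Sequence[bool] | np.ndarray,
    ci_method: str = "delong",
    ci_level: float = 0.95,
    seed: int = 0,
    exclude_censored: bool = False,
) -> PairResult:
    """Evaluate one pair feature as a binary case/control classifier.

    The feature is oriented so cases score high (AUC >= 0.5). On perfect
    separation the logistic MLE diverges, so a deterministic step rule at
    the midpoint between the closest case and control is used instead and
    the result flagged ``separable``. A constant feature yields the
    ``degenerate`` result: AUC 0.5, slope 0, every sample called case (a
    fitted probability of exactly 0.5 classifies as case).
    """
    labels = np.asarray(labels, dtype=bool)
    x = feature.delta_ct.copy()
    keep = ~feature.any_censored if exclude_censored else np.ones(x.size, dtype=bool)
    x, y = x[keep], labels[keep]
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per class")

    common = dict(
        pair_id=feature.pair_id,
        mirna_a=feature.mirna_a,
        mirna_b=feature.mirna_b,
        n_case=n1,
        n_control=n0,
        ci_method=ci_method,
    )

    if np.ptp(x) == 0.0:
        # constant feature: probability = case fraction is tuned by the
        # intercept alone; at p >= 0.5 with the balanced default every
        # sample is called case
        p_hat = n1 / (n1 + n0)
        pred = np.full(x.size, p_hat >= PROB_THRESHOLD)
        sens, spec, acc = _confusion_metrics(pred, y)
        return PairResult(
            orientation=1,
            intercept=float(np.log(p_hat / (1 - p_hat))) if 0 < p_hat < 1 else 0.0,
            slope=0.0,
            sensitivity=sens,
            specificity=spec,
            accuracy=acc,
            auc=0.5,
            auc_ci_low=0.5,
            auc_ci_high=0.5,
            mw_u=n1 * n0 / 2.0,
            mw_p=1.0,
            degenerate=True,
            **common,
        )

    auc_raw = stats.midrank_auc(x, y)
    orientation = 1 if auc_raw >= 0.5 else -1
    xo = orientation * x
    auc = max(auc_raw, 1.0 - auc_raw)

    mw_u, mw_p = stats.mann_whitney(xo, y)
    if ci_method == "delong":
        _, lo, hi, _ = stats.delong_ci(xo, y, level=ci_level)
    elif ci_method == "bootstrap":
        _, lo, hi, _ = stats.bootstrap_auc_ci(xo, y, level=ci_level, seed=seed)
    else:
        raise ValueError(f"unknown ci method {ci_method!r}")
    lo, hi = min(lo, auc), max(hi, auc)

    separable = xo[~y].max() < xo[y].min()
    if separable:
        threshold = (xo[~y].max() + xo[y].min()) / 2.0
        pred = xo >= threshold
        intercept, slope = -float(threshold), 1.0  # step rule surrogate
    else:
        intercept, slope, converged = _logistic_mle(xo, y)
        if not converged or not np.isfinite(slope):
            # quasi-separation: fall back to the ROC-optimal (Youden) cut
            separable = True
            threshold = _youden_threshold(xo, y)
            pred = xo >= threshold
            intercept, slope = -float(threshold), 1.0
        else:
            prob = 1.0 / (1.0 + np.exp(-(intercept + slope * xo)))
            pred = prob >= PROB_THRESHOLD

    sens, spec, acc = _confusion_metrics(pred, y)
    return PairResult(
        orientation=orientation,
        intercept=intercept,
        slope=slope,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        mw_u=mw_u,
        mw_p=mw_p,
        separable=separable,
        **common,
    )


def _youden_threshold(x: np.ndarray, y: np.ndarray) -> float:
    """Cut maximizing sensitivity + specificity over observed values."""
    candidates = np.unique(x)
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = x >= t
        sens, spec, _ = _confusion_metrics(pred, y)
        if sens + spec > best_j:
            best_j, best_t = sens + spec, t
    return float(best_t)


def evaluate_all_pairs(
    ct: CtMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
    ci_method: str = "delong",
    ci_level: float = 0.95,
    seed: int = 0,
    exclude_censored: bool = False,
) -> list[PairResult]:
    """Fit and score every pair of a Ct matrix (the full screen)."""
    pairs, delta, cens = pair_feature_matrix(ct, pairs)
    labels = ct.labels
    results = []
    for k, (a, b) in enumerate(pairs):
        feat = PairFeature(mirna_a=a, mirna_b=b, delta_ct=delta[:, k], any_censored=cens[:, k])
        results.append(
            fit_pair_classifier(
                feat,
                labels,
                ci_method=ci_method,
                ci_level=ci_level,
                seed=seed,
                exclude_censored=exclude_censored,
            )
        )
    return results


def results_table(results: Sequence[PairResult]) -> pd.DataFrame:
    """Tabular form of pair results, with a BH-adjusted p column for
    reference (never used for gating)."""
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["mw_p_bh"] = multipletests(df["mw_p"], method="fdr_bh")[1]
    return df


def select_pairs(
    results: Sequence[PairResult], auc_min: float = 0.8
) -> list[PairResult]:
    """Gate: keep pairs with AUC >= auc_min (inclusive), best first.

    Sorted by AUC descending, ties broken by pair id. No multiple-testing
    correction is applied.
    """
    if not results:
        raise ValueError("no pair results to select from")
    gated = [r for r in results if r.auc >= auc_min]
    return sorted(gated, key=lambda r: (-r.auc, r.pair_id))
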