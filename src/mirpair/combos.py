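"""Equal-weight combination classifiers and the exhaustive k-pair search.

A combination classifier averages k oriented pair features with identical
weights and pushes the mean through a sigmoid:

    P(case) = 1 / (1 + exp(-score)),   score = mean_j z_j,

thresholded at p = 0.5 (p >= 0.5 -> case). Two score conventions ship:

* ``standardized_log`` (default): each member's oriented log2 feature is
  centered at the midpoint between its class means and scaled to unit
  pooled within-class SD before averaging. Score 0 then corresponds to the
  decision boundary, making p = 0.5 a meaningful cut.
* ``raw_ratio``: the literal printed convention — the mean of the positive
  2**(Ct_a - Ct_b) ratios through the sigmoid. Since every ratio is
  positive, every score is positive and every sample is classified as a
  case (specificity 0). The mode is retained, flagged with
  ``caveat=True``, purely to document this degeneracy; it is never the
  default.

The search stage evaluates *all* C(n_gated, k) member combinations — no
greedy shortcut — and ranks survivors by AUC, then accuracy, then member
ids. The search is deterministic: same inputs, same ranking, regardless of
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .pairs import PairFeature
from .single_pair import PROB_THRESHOLD, PairResult, _confusion_metrics

MODES = ("standardized_log", "raw_ratio")


@dataclass(frozen=True)
class ComboCriteria:
    """Post-search acceptance thresholds; all default to 0 (no filtering).

    The original screening procedure applied unstated 'predefined criteria'
    to its candidate classifiers, so no defaults are asserted here beyond
    'keep everything'.
    """

    min_sens: float = 0.0
    min_spec: float = 0.0
    min_auc: float = 0.0


@dataclass
class ComboClassifier:
    """A k-pair equal-weight classifier with training-derived constants."""

    members: tuple[str, ...]  # pair ids, sorted
    orientations: np.ndarray  # +1/-1 per member
    centers: np.ndarray  # per-member centering constants
    scales: np.ndarray  # per-member scale constants
    mode: str
    score: np.ndarray  # per-sample equal-weight mean
    prob: np.ndarray  # sigmoid(score)
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    n_case: int
    n_control: int
    caveat: bool = False  # raw_ratio degeneracy flag

    def __post_init__(self) -> None:
        expected = (
            self.sensitivity * self.n_case + self.specificity * self.n_control
        ) / (self.n_case + self.n_control)
        if abs(self.accuracy - expected) > 1e-12:
            raise ValueError("accuracy must equal the weighted mean of sens/spec")


def _pooled_within_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n0 = int(y.sum()), int((~y).sum())
    s1 = np.var(x[y], ddof=1) if n1 > 1 else 0.0
    s0 = np.var(x[~y], ddof=1) if n0 > 1 else 0.0
    pooled = ((n1 - 1) * s1 + (n0 - 1) * s0) / max(n1 + n0 - 2, 1)
    return float(np.sqrt(pooled))


def standardize_members(
    features: Mapping[str, PairFeature],
    results: Sequence[PairResult],
    labels: np.ndarray,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Oriented, centered, scaled member features for combo building.

    Returns (pair_ids, Z, orientations, centers, scales) where column j of
    Z is the standardized oriented log2 feature of gated pair j. Constants
    are training-derived: center = midpoint between class means of the
    oriented feature; scale = pooled within-class SD (unit scale if the
    feature is constant).
    """
    labels = np.asarray(labels, dtype=bool)
    ids, cols, orients, centers, scales = [], [], [], [], []
    for r in results:
        x = features[r.pair_id].delta_ct * r.orientation
        center = (x[labels].mean() + x[~labels].mean()) / 2.0
        scale = _pooled_within_sd(x, labels)
        if scale == 0.0:
            scale = 1.0
        ids.append(r.pair_id)
        cols.append((x - center) / scale)
        orients.append(r.orientation)
        centers.append(center)
        scales.append(scale)
    return (
        ids,
        np.column_stack(cols) if cols else np.empty((labels.size, 0)),
        np.asarray(orients),
        np.asarray(centers, dtype=float),
        np.asarray(scales, dtype=float),
    )


def _score_metrics(score: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float, float, float, float]:
    prob = 1.0 / (1.0 + np.exp(-score))
    pred = prob >= PROB_THRESHOLD
    sens, spec, acc = _confusion_metrics(pred, labels)
    auc = stats.midrank_auc(score, labels)
    return prob, sens, spec, acc, auc


def build_combo(
    members: Sequence[PairResult],
    features: Mapping[str, PairFeature],
    labels: Sequence[bool] | np.ndarray,
    mode: str = "standardized_log",
) -> ComboClassifier:
    """Build one equal-weight combination classifier from gated pairs."""
    labels = np.asarray(labels, dtype=bool)
    if len(members) == 0:
        raise ValueError("a combination needs at least one member pair")
    ids = [m.pair_id for m in members]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate member pairs: {sorted(ids)}")
    if mode not in MODES:
        raise ValueError(f"unknown combo mode {mode!r}")
    if labels.all() or not labels.any():
        raise ValueError("labels contain a single class")

    order = np.argsort(ids)
    members = [members[i] for i in order]
    if mode == "standardized_log":
        ids_s, z, orients, centers, scales = standardize_members(features, members, labels)
        score = z.mean(axis=1)
        caveat = False
    else:  # raw_ratio: literal printed formula, documented degeneracy
        cols = [features[m.pair_id].ratio for m in members]
        score = np.column_stack(cols).mean(axis=1)
        ids_s = [m.pair_id for m in members]
        orients = np.ones(len(members), dtype=int)
        centers = np.zeros(len(members))
        scales = np.ones(len(members))
        caveat = True

    prob, sens, spec, acc, auc = _score_metrics(score, labels)
    return ComboClassifier(
        members=tuple(ids_s),
        orientations=np.asarray(orients),
        centers=centers,
        scales=scales,
        mode=mode,
        score=score,
        prob=prob,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        n_case=int(labels.sum()),
        n_control=int((~labels).sum()),
        caveat=caveat,
    )


def evaluate_combo(combo: ComboClassifier, labels: Sequence[bool] | np.ndarray) -> dict:
    """Re-score a built combo against labels (must be the build samples)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("labels contain a single class")
    if labels.size != combo.score.size:
        raise ValueError("combo was built on a different sample set")
    _, sens, spec, acc, auc = _score_metrics(combo.score, labels)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": auc,
    }


def exhaustive_combo_search(
    gated: Sequence[PairResult],
    features: Mapping[str, PairFeature],
    labels: Sequence[bool] | np.ndarray,
    k: int = 3,
    criteria: ComboCriteria | None = None,
    mode: str = "standardized_log",
    chunk_size: int = 4096,
) -> tuple[pd.DataFrame, int]:
    """Evaluate every C(n_gated, k) equal-weight combination.

    Returns ``(ranked, n_evaluated)``: the combinations meeting ``criteria``
    ranked by AUC descending (ties: accuracy descending, then member ids),
    and the total number of combinations evaluated. The search has no
    randomness and is invariant to the input ordering of ``gated``.
    """
    labels = np.asarray(labels, dtype=bool)
    criteria = criteria or ComboCriteria()
    if not 1 <= k <= 4:
        raise ValueError("k must be between 1 and 4")
    if len(gated) < k:
        raise ValueError(f"need at least k={k} gated pairs, got {len(gated)}")
    if len({r.pair_id for r in gated}) != len(gated):
        raise ValueError("duplicate pair ids among gated results")
    if mode not in MODES:
        raise ValueError(f"unknown combo mode {mode!r}")

    gated = sorted(gated, key=lambda r: r.pair_id)
    if mode == "standardized_log":
        ids, z, *_ = standardize_members(features, gated, labels)
    else:
        ids = [r.pair_id for r in gated]
        z = np.column_stack([features[r.pair_id].ratio for r in gated])

    n_expected = comb(len(gated), k)
    combo_iter = combinations(range(len(gated)), k)
    rows: list[dict] = []
    n_evaluated = 0
    while True:
        chunk = []
        for _ in range(chunk_size):
            nxt = next(combo_iter, None)
            if nxt is None:
                break
            chunk.append(nxt)
        if not chunk:
            break
        idx = np.asarray(chunk)  # (c, k)
        scores = z[:, idx].mean(axis=2)  # (n_samples, c)
        prob = 1.0 / (1.0 + np.exp(-scores))
        pred = prob >= PROB_THRESHOLD
        n1, n0 = int(labels.sum()), int((~labels).sum())
        sens = pred[labels].mean(axis=0)
        spec = (~pred[~labels]).mean(axis=0)
        acc = (sens * n1 + spec * n0) / (n1 + n0)
        auc = stats.midrank_auc_matrix(scores, labels)
        n_evaluated += len(chunk)
        ok = (sens >= criteria.min_sens) & (spec >= criteria.min_spec) & (auc >= criteria.min_auc)
        for c in np.nonzero(ok)[0]:
            members = tuple(ids[j] for j in idx[c])
            rows.append(
                {
                    **{f"pair_{j + 1}": m for j, m in enumerate(members)},
                    "sensitivity": float(sens[c]),
                    "specificity": float(spec[c]),
                    "accuracy": float(acc[c]),
                    "auc": float(auc[c]),
                    "members": members,
                }
            )
    assert n_evaluated == n_expected
    ranked = pd.DataFrame(rows)
    if len(ranked):
        ranked = ranked.sort_values(
            by=["auc", "accuracy", "members"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return ranked, n_evaluated
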