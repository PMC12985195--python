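"""Pairwise Ct-ratio features.

Every unordered pair (a, b) of panel assays yields one candidate biomarker:
the within-sample difference of the two Ct values. Because any per-sample
technical effect (input amount, extraction efficiency, plate offsets) shifts
all of a sample's Cts by the same constant, it cancels exactly in the
difference — this is the entire normalization strategy of the pipeline, and
it is exact by construction rather than approximate.

Orientation conventions, recorded explicitly because they are easy to trip
over:

* ``delta_ct`` (the working, log2-scale feature) is ``Ct_b - Ct_a``. It
  *increases* when assay ``a``'s expression rises relative to ``b`` (more
  template -> lower Ct).
* ``ratio`` is the reported output scale ``2**(Ct_a - Ct_b)``, i.e.
  ``2**(-delta_ct)`` — the conventional printed form for a pair labeled
  "a/b". Note that on this scale the printed exponent runs opposite to
  expression: all downstream statistics therefore operate on ``delta_ct``
  and treat the ratio as output formatting only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import CtMatrix, PanelDefinition, PanelError, canonical_assay_name

PAIR_SEP = "/"


def pair_id(a: str, b: str) -> str:
    return f"{a}{PAIR_SEP}{b}"


@dataclass
class PairFeature:
    """One oriented miRNA pair with its per-sample feature values."""

    mirna_a: str
    mirna_b: str
    delta_ct: np.ndarray  # Ct_b - Ct_a per sample (log2 working scale)
    any_censored: np.ndarray  # True where either member well was censored

    def __post_init__(self) -> None:
        self.delta_ct = np.asarray(self.delta_ct, dtype=float)
        self.any_censored = np.asarray(self.any_censored, dtype=bool)
        if self.mirna_a == self.mirna_b:
            raise PanelError(f"self-pair {self.mirna_a} is not a valid feature")
        if self.delta_ct.shape != self.any_censored.shape:
            raise PanelError("delta_ct / any_censored length mismatch")

    @property
    def pair_id(self) -> str:
        return pair_id(self.mirna_a, self.mirna_b)

    @property
    def log2_ratio(self) -> np.ndarray:
        """log2 of the reported-scale ratio, i.e. Ct_a - Ct_b."""
        return -self.delta_ct

    @property
    def ratio(self) -> np.ndarray:
        """Reported output scale: 2**(Ct_a - Ct_b) == 2**(-delta_ct)."""
        return np.exp2(-self.delta_ct)

    def reversed(self) -> "PairFeature":
        return PairFeature(
            mirna_a=self.mirna_b,
            mirna_b=self.mirna_a,
            delta_ct=-self.delta_ct,
            any_censored=self.any_censored.copy(),
        )


def enumerate_pairs(panel: PanelDefinition | Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered assay pairs, in lexicographic order."""
    ids = panel.mirna_ids if isinstance(panel, PanelDefinition) else list(panel)
    if len(set(ids)) != len(ids):
        raise PanelError("duplicate assay ids")
    if len(ids) < 2:
        raise PanelError("need at least 2 assays to form pairs")
    return list(combinations(sorted(ids), 2))


def compute_pair_feature(ct: CtMatrix, a: str, b: str) -> PairFeature:
    """Per-sample delta-Ct feature for the pair (a, b).

    Samples where either member is censored keep a value (from the
    max-cycles imputation) but are flagged via ``any_censored``.
    """
    a, b = canonical_assay_name(a), canonical_assay_name(b)
    if a == b:
        raise PanelError(f"cannot pair assay {a} with itself")
    ia, ib = ct.assay_index(a), ct.assay_index(b)
    return PairFeature(
        mirna_a=a,
        mirna_b=b,
        delta_ct=ct.ct[:, ib] - ct.ct[:, ia],
        any_censored=ct.censored[:, ia] | ct.censored[:, ib],
    )


def pair_feature_matrix(
    ct: CtMatrix, pairs: Sequence[tuple[str, str]] | None = None
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Vectorized delta-Ct features for many pairs at once.

    Returns ``(pairs, delta, any_censored)`` where ``delta`` is an
    (n_samples, n_pairs) matrix of Ct_b - Ct_a values in the order of
    ``pairs``.
    """
    if pairs is None:
        pairs = enumerate_pairs(ct.assays)
    ia = np.array([ct.assay_index(a) for a, _ in pairs], dtype=int)
    ib = np.array([ct.assay_index(b) for _, b in pairs], dtype=int)
    delta = ct.ct[:, ib] - ct.ct[:, ia]
    cens = ct.censored[:, ia] | ct.censored[:, ib]
    return list(pairs), delta, cens


def pair_feature_frame(ct: CtMatrix, pairs: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Samples x pairs delta-Ct table (pair ids as columns) for export."""
    pairs, delta, _ = pair_feature_matrix(ct, pairs)
    return pd.DataFrame(
        delta, index=ct.samples["sample_id"], columns=[pair_id(a, b) for a, b in pairs]
    )
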