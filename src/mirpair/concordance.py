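"""Plasma vs tumor-tissue expression-profile concordance.

Compares the per-assay mean Ct profile of plasma samples with that of
matched tumor tissue across the shared panel. Tissue generally amplifies
earlier (lower Ct = higher expression), so the mean Ct shift
(tissue - plasma) is typically negative; the *pattern* similarity of the two
profiles is quantified with Spearman and Pearson correlations of the two
per-assay mean vectors. The choice of statistic is the package's own — the
underlying similarity claim is usually made by eye from overlaid profiles —
and outputs are labeled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import CtMatrix, PanelError, align_profiles


@dataclass
class ConcordanceResult:
    n_assays: int
    mean_shift: float  # mean tissue Ct - mean plasma Ct, cycles
    spearman: float
    pearson: float
    per_assay: pd.DataFrame  # assay, mean_ct_plasma, mean_ct_tissue, shift, detected_*
    detectability: dict  # assays detected in both / plasma only / tissue only / neither

    def to_dict(self) -> dict:
        return {
            "n_assays": self.n_assays,
            "mean_shift": self.mean_shift,
            "spearman": self.spearman,
            "pearson": self.pearson,
            "detectability": self.detectability,
        }


def _mean_uncensored(ct: CtMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-assay mean over uncensored wells; NaN where fully censored."""
    masked = np.where(ct.censored, np.nan, ct.ct)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(masked, axis=0)
    detected = ~np.all(ct.censored, axis=0)
    return means, detected


def profile_concordance(plasma: CtMatrix, tissue: CtMatrix) -> ConcordanceResult:
    """Quantify similarity of plasma and tissue per-assay mean Ct profiles.

    Matrices are aligned to their shared assays first. Correlations are
    computed over assays with at least one uncensored well in *both*
    matrices; fewer than 3 such assays is an error (correlation undefined).
    """
    plasma, tissue = align_profiles(plasma, tissue)
    mean_p, det_p = _mean_uncensored(plasma)
    mean_t, det_t = _mean_uncensored(tissue)
    valid = det_p & det_t
    if valid.sum() < 3:
        raise PanelError(
            f"only {int(valid.sum())} shared assays with uncensored wells; need >= 3"
        )
    mp, mt = mean_p[valid], mean_t[valid]
    shift = float(np.mean(mt - mp))
    if np.ptp(mp) == 0 or np.ptp(mt) == 0:
        spearman = pearson = float("nan")
    else:
        spearman = float(sps.spearmanr(mp, mt).statistic)
        pearson = float(sps.pearsonr(mp, mt).statistic)
    per_assay = pd.DataFrame(
        {
            "assay": plasma.assays,
            "mean_ct_plasma": mean_p,
            "mean_ct_tissue": mean_t,
            "shift": mean_t - mean_p,
            "detected_plasma": det_p,
            "detected_tissue": det_t,
        }
    )
    detectability = {
        "both": int((det_p & det_t).sum()),
        "plasma_only": int((det_p & ~det_t).sum()),
        "tissue_only": int((~det_p & det_t).sum()),
        "neither": int((~det_p & ~det_t).sum()),
    }
    return ConcordanceResult(
        n_assays=int(valid.sum()),
        mean_shift=shift,
        spearman=spearman,
        pearson=pearson,
        per_assay=per_assay,
        detectability=detectability,
    )
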