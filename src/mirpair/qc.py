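"""Assay elimination and run-control checks.

Candidate assays are dropped before biomarker screening when they are poorly
detectable (too many censored wells in either cohort), excessively variable
(per-cohort Ct standard deviation too high), or when their plates fail run
controls. The numeric thresholds are package conventions — detect rate >= 0.8
per cohort, per-cohort SD <= 3 Ct cycles — configurable via
:class:`QcThresholds` and echoed into every :class:`QcReport` so a filtered
dataset always carries the rules that produced it.

Spike-in controls (UniSp3/UniSp6) are used strictly as run-quality flags,
never for normalization: normalization happens downstream through pair
ratios, which cancel per-sample technical offsets by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ControlWells, CtMatrix, PanelError


@dataclass(frozen=True)
class QcThresholds:
    """Assay- and plate-level QC rules.

    min_detect_rate: minimum fraction of uncensored wells per assay, enforced
        in each cohort separately.
    max_assay_sd: maximum per-cohort Ct standard deviation (cycles) over
        uncensored wells.
    ntc_max_ct_margin: an uncensored no-template-control well must sit at
        least this many cycles above the plate's sample median, else the
        plate is flagged for contamination.
    spikein_sd_max: maximum across-plate SD (cycles) of each spike-in before
        the batch is flagged for drift.
    """

    min_detect_rate: float = 0.8
    max_assay_sd: float = 3.0
    ntc_max_ct_margin: float = 5.0
    spikein_sd_max: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_detect_rate <= 1.0:
            raise ValueError("min_detect_rate must lie in [0, 1]")
        for name in ("max_assay_sd", "ntc_max_ct_margin", "spikein_sd_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class QcReport:
    """Per-assay verdicts plus the thresholds that produced them."""

    per_assay: pd.DataFrame  # assay, detect_rate_case/control, sd_case/control, passed, reasons
    eliminated_assays: list[str]
    thresholds: QcThresholds
    plate_verdicts: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "thresholds": asdict(self.thresholds),
            "per_assay": self.per_assay.to_dict(orient="records"),
            "eliminated_assays": self.eliminated_assays,
            "plate_verdicts": (
                self.plate_verdicts.to_dict(orient="records")
                if self.plate_verdicts is not None
                else None
            ),
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def assess_assays(ct: CtMatrix, thresholds: QcThresholds | None = None) -> QcReport:
    """Score every assay for detectability and variability, per cohort.

    detect_rate is the fraction of uncensored wells; sd is computed over
    uncensored wells only (censored Cts are imputed placeholders, not
    measurements). An assay fails if either statistic violates its threshold
    in *any* cohort.
    """
    thresholds = thresholds or QcThresholds()
    labels = ct.labels
    for name, mask in (("case", labels), ("control", ~labels)):
        if mask.sum() < 2:
            raise PanelError(f"cohort {name!r} has fewer than 2 samples")

    rows = []
    eliminated = []
    for j, assay in enumerate(ct.assays):
        rec: dict = {"assay": assay}
        reasons = []
        for name, mask in (("case", labels), ("control", ~labels)):
            cens = ct.censored[mask, j]
            vals = ct.ct[mask, j][~cens]
            detect = 1.0 - cens.mean()
            sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan
            rec[f"detect_rate_{name}"] = float(detect)
            rec[f"sd_{name}"] = sd
            if detect < thresholds.min_detect_rate:
                reasons.append(f"detectability ({name})")
            if np.isfinite(sd) and sd > thresholds.max_assay_sd:
                reasons.append(f"variability ({name})")
        rec["passed"] = not reasons
        rec["reasons"] = "; ".join(reasons)
        rows.append(rec)
        if reasons:
            eliminated.append(assay)
    return QcReport(
        per_assay=pd.DataFrame(rows),
        eliminated_assays=eliminated,
        thresholds=thresholds,
    )


def check_run_controls(
    controls: ControlWells,
    thresholds: QcThresholds | None = None,
    sample_medians: float | dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-plate verdicts from NTC and spike-in control wells.

    ``sample_medians`` supplies the per-plate median sample Ct (a mapping
    plate_id -> median, or one scalar for all plates) needed by the NTC
    proximity rule; without it the NTC check degrades to "uncensored NTC at
    all flags the plate". Spike-in drift is a batch-level verdict: if the
    across-plate SD of UniSp3 or UniSp6 exceeds ``spikein_sd_max``, every
    plate is flagged for that spike-in.
    """
    thresholds = thresholds or QcThresholds()
    wells = controls.wells
    plates = sorted(set(wells["plate_id"]))
    if not plates:
        return pd.DataFrame(columns=["plate_id", "ntc_pass", "spikein_pass", "notes"])

    drifting = []
    for spike in ("UniSp3", "UniSp6"):
        sub = wells[(wells["control_type"] == spike) & (~wells["censored"])]
        if len(sub) >= 2:
            sd = float(np.std(sub["ct"], ddof=1))
            if sd > thresholds.spikein_sd_max:
                drifting.append(f"{spike} across-plate sd {sd:.2f}")

    rows = []
    for plate in plates:
        sub = wells[wells["plate_id"] == plate]
        notes = []
        ntc_pass = True
        for _, w in sub[sub["control_type"] == "NTC"].iterrows():
            if w["censored"]:
                continue
            if sample_medians is None:
                ntc_pass = False
                notes.append(f"NTC amplified at Ct {w['ct']:.1f} (no sample median supplied)")
                continue
            med = (
                float(sample_medians)
                if np.isscalar(sample_medians)
                else float(sample_medians.get(plate, np.nan))
            )
            # an amplifying NTC must sit >= margin cycles above the samples
            if not np.isfinite(med) or w["ct"] - med < thresholds.ntc_max_ct_margin:
                ntc_pass = False
                notes.append(f"NTC Ct {w['ct']:.1f} within margin of sample median")
        spikein_pass = not drifting
        notes.extend(drifting)
        rows.append(
            {
                "plate_id": plate,
                "ntc_pass": ntc_pass,
                "spikein_pass": spikein_pass,
                "passed": ntc_pass and spikein_pass,
                "notes": "; ".join(notes),
            }
        )
    return pd.DataFrame(rows)


def apply_elimination(ct: CtMatrix, report: QcReport) -> CtMatrix:
    """Drop eliminated assays; samples and retained Ct values are untouched."""
    reported = set(report.per_assay["assay"])
    if reported != set(ct.assays):
        raise PanelError("QC report was produced from a different assay set")
    keep = [a for a in ct.assays if a not in set(report.eliminated_assays)]
    if not keep:
        raise PanelError("QC eliminated every assay; nothing to analyze")
    return ct.subset_assays(keep)
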