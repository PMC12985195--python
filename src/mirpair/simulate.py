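"""Synthetic two-cohort qPCR data with known ground truth.

The generator emulates the statistical structure the pair-ratio design
assumes, at the level of exported Ct values:

    Ct[s, m] = mu_m + delta_m * [s is case] + u_s + eps[s, m]

where ``mu_m`` is the assay's baseline mean Ct, ``delta_m`` a planted
case-vs-control shift (cycles; negative = higher expression in cases),
``u_s ~ N(0, tau^2)`` a per-sample technical offset shared by every assay of
that sample (input amount, extraction efficiency — exactly what pair ratios
cancel), and ``eps ~ N(0, sigma_m^2)`` per-well noise. Values above the
cycle ceiling are censored at it. Under this model the delta-Ct feature of a
pair (a, b) is normal in each cohort with common variance
``sigma_a^2 + sigma_b^2``, giving the closed-form pair AUC

    AUC(a, b) = Phi(|delta_a - delta_b| / sqrt(2 (sigma_a^2 + sigma_b^2)))

which the emitted :class:`SyntheticTruth` tabulates for recovery tests.

Defaults mirror the study conditions the pipeline targets: 30 cases vs 30
controls, 48 assays with baseline means drawn uniformly on [22, 34] cycles,
per-assay SD 1.0, sample-offset SD 1.5, censoring at 40 cycles, four
samples per plate with pass-by-default control wells. A 61-assay variant
with "killed" low-detectability assays (baseline mean above the ceiling)
supports QC-elimination scenarios. What the generator does *not* emulate:
amplification-efficiency differences, heavy-tailed or correlated assay
noise, hemolysis artifacts, and demographic covariates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import (
    Assay,
    ControlWells,
    CtMatrix,
    PanelDefinition,
    write_controls,
    write_ct_table,
)


@dataclass(frozen=True)
class TissueConfig:
    """Matched-tissue profile: global Ct shift plus per-assay pattern noise."""

    shift: float = -6.0  # tissue amplifies earlier (higher expression)
    pattern_noise_sd: float = 1.5  # cycles, per assay, shared across tissue samples
    n_samples: int = 3  # matched FFPE specimens


@dataclass
class SyntheticConfig:
    """Parameters of the two-cohort qPCR generator; ``seed`` is mandatory."""

    seed: int
    n_case: int = 30
    n_control: int = 30
    n_assays: int = 48
    mu_range: tuple[float, float] = (22.0, 34.0)  # baseline mean Ct draw
    assay_sd: float | Sequence[float] = 1.0  # sigma_m, cycles
    sample_offset_sd: float = 1.5  # tau, cycles
    planted: dict[str, float] = field(default_factory=dict)  # assay -> delta (cycles)
    censor_at: float = 40.0
    killed_assays: int | Sequence[str] = 0  # low-detectability assays
    killed_mu: float = 41.0  # baseline mean for killed assays (mostly censored)
    assay_ids: Sequence[str] | None = None
    samples_per_plate: int = 4
    ntc_contaminated_plates: Sequence[str] = ()
    ntc_contamination_ct: float = 27.0
    spikein_sd: float = 0.15  # across-plate spike-in wobble, cycles
    tissue: TissueConfig = field(default_factory=TissueConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per cohort")
        if self.n_assays < 1:
            raise ValueError("need at least one assay")
        if self.sample_offset_sd < 0:
            raise ValueError("sample_offset_sd must be nonnegative")
        sd = np.atleast_1d(np.asarray(self.assay_sd, dtype=float))
        if np.any(sd < 0):
            raise ValueError("assay_sd must be nonnegative")
        if sd.size not in (1, self.n_assays):
            raise ValueError("assay_sd must be scalar or one value per assay")
        if self.censor_at <= 0:
            raise ValueError("censor_at must be positive")
        if self.assay_ids is not None and len(self.assay_ids) != self.n_assays:
            raise ValueError("assay_ids length must match n_assays")

    def resolve_assay_ids(self) -> list[str]:
        if self.assay_ids is not None:
            return list(self.assay_ids)
        if self.n_assays == 48:
            from .panel import load_default_panel

            return load_default_panel().mirna_ids
        return [f"miR-syn-{i + 1:02d}" for i in range(self.n_assays)]


@dataclass
class SyntheticTruth:
    """The generator's planted parameters, for recovery testing."""

    assays: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    delta: np.ndarray  # case - control Ct shift per assay
    killed: list[str]
    seed: int

    def pair_auc(self, a: str, b: str) -> float:
        """Closed-form AUC of the delta-Ct feature of pair (a, b)."""
        ia, ib = self.assays.index(a), self.assays.index(b)
        sep = abs(self.delta[ia] - self.delta[ib])
        spread = sqrt(2.0 * (self.sigma[ia] ** 2 + self.sigma[ib] ** 2))
        if spread == 0.0:
            return 1.0 if sep > 0 else 0.5
        return float(norm.cdf(sep / spread))

    def differential_pairs(self, tol: float = 0.0) -> list[tuple[str, str]]:
        """Pairs with truly different group shifts (theoretical AUC > 0.5)."""
        out = []
        for i, a in enumerate(self.assays):
            for j in range(i + 1, len(self.assays)):
                if abs(self.delta[i] - self.delta[j]) > tol:
                    out.append((a, self.assays[j]))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "assays": self.assays,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "delta": self.delta.tolist(),
            "killed": self.killed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def make_panel(config: SyntheticConfig) -> PanelDefinition:
    """Panel definition matching the generator's assay ids."""
    ids = config.resolve_assay_ids()
    if config.n_assays == 48 and config.assay_ids is None:
        from .panel import load_default_panel

        return load_default_panel()
    return PanelDefinition(
        assays=tuple(Assay(mirna_id=a, role="context_dependent", brain_enriched=False) for a in ids)
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[CtMatrix, ControlWells, SyntheticTruth]:
    """Draw one two-cohort dataset plus control wells and its truth table.

    Identical configs (same seed) produce bit-identical output; every random
    draw flows from one ``numpy.random.default_rng(seed)`` stream in a fixed
    order.
    """
    rng = np.random.default_rng(config.seed)
    assays = config.resolve_assay_ids()
    n = config.n_case + config.n_control
    m = config.n_assays

    mu = rng.uniform(*config.mu_range, size=m)
    sigma = np.broadcast_to(
        np.atleast_1d(np.asarray(config.assay_sd, dtype=float)), (m,)
    ).copy()

    if isinstance(config.killed_assays, int):
        n_kill = config.killed_assays
        killed = list(rng.choice(assays, size=n_kill, replace=False)) if n_kill else []
    else:
        killed = [a for a in config.killed_assays]
        unknown = set(killed) - set(assays)
        if unknown:
            raise ValueError(f"killed assays not in panel: {sorted(unknown)}")
    for a in killed:
        mu[assays.index(a)] = config.killed_mu

    delta = np.zeros(m)
    for a, d in config.planted.items():
        if a not in assays:
            raise ValueError(f"planted assay {a!r} not in panel")
        delta[assays.index(a)] = d

    labels = np.concatenate([np.ones(config.n_case, bool), np.zeros(config.n_control, bool)])
    u = rng.normal(0.0, config.sample_offset_sd, size=n)
    eps = rng.normal(0.0, 1.0, size=(n, m)) * sigma
    ct = mu + delta * labels[:, None] + u[:, None] + eps
    censored = ct > config.censor_at
    ct = np.where(censored, config.censor_at, ct)
    # floor guard: Ct is a cycle count, keep it positive
    ct = np.maximum(ct, 1.0)

    sample_ids = [f"case-{i + 1:03d}" for i in range(config.n_case)] + [
        f"ctrl-{i + 1:03d}" for i in range(config.n_control)
    ]
    plates = [f"plate-{i // config.samples_per_plate + 1:02d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": np.where(labels, "case", "control"),
            "sample_type": "plasma",
            "plate": plates,
        }
    )
    matrix = CtMatrix(
        samples=samples,
        assays=assays,
        ct=ct,
        censored=censored,
        max_cycles=config.censor_at,
    )

    controls = _generate_controls(config, sorted(set(plates)), rng)
    truth = SyntheticTruth(
        assays=assays, mu=mu, sigma=sigma, delta=delta, killed=killed, seed=config.seed
    )
    return matrix, controls, truth


def _generate_controls(
    config: SyntheticConfig, plates: list[str], rng: np.random.Generator
) -> ControlWells:
    """Pass-by-default control wells; contamination/drift only on request."""
    rows = []
    contaminated = set(config.ntc_contaminated_plates)
    for plate in plates:
        for ctype, base in (("UniSp3", 20.0), ("UniSp6", 21.0), ("PositiveOligo", 24.0)):
            rows.append(
                {
                    "control_type": ctype,
                    "plate_id": plate,
                    "ct": float(base + rng.normal(0.0, config.spikein_sd)),
                    "censored": False,
                }
            )
        rows.append(
            {"control_type": "BlankSpot", "plate_id": plate, "ct": config.censor_at, "censored": True}
        )
        if plate in contaminated:
            rows.append(
                {
                    "control_type": "NTC",
                    "plate_id": plate,
                    "ct": config.ntc_contamination_ct,
                    "censored": False,
                }
            )
        else:
            rows.append(
                {"control_type": "NTC", "plate_id": plate, "ct": config.censor_at, "censored": True}
            )
    return ControlWells(wells=pd.DataFrame(rows))


def generate_matched_tissue(
    plasma: CtMatrix, config: SyntheticConfig | None = None, tissue: TissueConfig | None = None
) -> CtMatrix:
    """Matched tumor-tissue profiles derived from a plasma matrix.

    Each tissue sample's Ct for assay m is the plasma per-assay mean plus
    the configured global shift plus a per-assay pattern perturbation drawn
    once (shared across tissue samples), so the induced profile correlation
    is controlled by ``pattern_noise_sd`` alone.
    """
    if plasma.n_samples == 0:
        raise ValueError("plasma matrix is empty")
    tcfg = tissue or (config.tissue if config is not None else TissueConfig())
    seed = config.seed if config is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    masked = np.where(plasma.censored, np.nan, plasma.ct)
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(masked, axis=0)
    profile = np.where(np.isfinite(profile), profile, plasma.max_cycles)
    pattern = rng.normal(0.0, tcfg.pattern_noise_sd, size=plasma.n_assays)
    ct = np.tile(profile + tcfg.shift + pattern, (tcfg.n_samples, 1))
    ct = np.clip(ct, 1.0, plasma.max_cycles)
    censored = ct >= plasma.max_cycles
    ct = np.where(censored, plasma.max_cycles, ct)
    samples = pd.DataFrame(
        {
            "sample_id": [f"tissue-{i + 1:02d}" for i in range(tcfg.n_samples)],
            "cohort": "case",
            "sample_type": "tissue",
            "plate": "",
        }
    )
    return CtMatrix(
        samples=samples,
        assays=list(plasma.assays),
        ct=ct,
        censored=censored,
        max_cycles=plasma.max_cycles,
    )


def write_dataset(
    config: SyntheticConfig, outdir: str | Path, with_tissue: bool = False
) -> dict[str, Path]:
    """Generate a dataset and write it in the pipeline's own text dialects.

    Emits the long-CSV Ct table, the control-well CSV, the truth JSON, a
    panel TSV, and optionally a matched-tissue Ct table. Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, controls, truth = generate_cohort(config)
    paths = {
        "ct": outdir / "ct_long.csv",
        "controls": outdir / "controls.csv",
        "truth": outdir / "truth.json",
        "panel": outdir / "panel.tsv",
    }
    write_ct_table(matrix, paths["ct"])
    write_controls(controls, paths["controls"])
    truth.to_json(paths["truth"])
    panel = make_panel(config)
    pd.DataFrame(
        {
            "mirna_id": [a.mirna_id for a in panel.assays],
            "role": [a.role for a in panel.assays],
            "brain_enriched": [str(a.brain_enriched).lower() for a in panel.assays],
        }
    ).to_csv(paths["panel"], sep="\t", index=False)
    if with_tissue:
        tissue = generate_matched_tissue(matrix, config)
        paths["tissue"] = outdir / "tissue_long.csv"
        write_ct_table(tissue, paths["tissue"])
    return paths
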