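"""Panel definitions, Ct tables, and run-control wells.

This module is the I/O layer of the pipeline. It reads the miRNA panel
definition (a delimited file with one row per assay), two-cohort Ct tables in
either a *long* dialect (one row per well) or a *wide* dialect (one row per
sample), and run-control well tables (spike-ins, blank spots, no-template
controls). Cycle-threshold (Ct) values are the raw currency of RT-qPCR: the
PCR cycle at which the amplification signal crosses a fixed threshold, so a
lower Ct means higher target abundance. Wells that never amplify within the
instrument's cycle limit ("Undetermined") are imputed at that limit
(default 40 cycles) and flagged as censored rather than dropped, so that
downstream QC — not the parser — decides their fate.

Assay identifiers are harmonized through a packaged synonym table (miRBase
naming drifts; e.g. ``miR-451a`` vs ``miR-451a-5p``) with optional ``hsa-``
prefixes stripped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLES = ("oncomiR", "tumor_suppressor", "context_dependent")

_ROLE_ALIASES = {
    "oncomir": "oncomiR",
    "oncogenic": "oncomiR",
    "tumor_suppressor": "tumor_suppressor",
    "tumor suppressor": "tumor_suppressor",
    "tumour suppressor": "tumor_suppressor",
    "context_dependent": "context_dependent",
    "context dependent": "context_dependent",
    "context-dependent": "context_dependent",
}

COHORTS = ("case", "control")

_COHORT_ALIASES = {
    "case": "case",
    "gbm": "case",
    "tumor": "case",
    "patient": "case",
    "control": "control",
    "ctrl": "control",
    "healthy": "control",
}

SAMPLE_TYPES = ("plasma", "tissue")

CONTROL_TYPES = ("UniSp3", "UniSp6", "BlankSpot", "NTC", "PositiveOligo")

#: Cell values that parse as "no amplification within max cycles".
CENSORED_TOKENS = frozenset({"undetermined", "undet", "na", "n/a", "nan", ""})

DEFAULT_MAX_CYCLES = 40.0

_TRUE_TOKENS = {"true", "t", "yes", "y", "1", "+"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0", "-", "−"}


class PanelError(ValueError):
    """Raised for malformed panel or Ct-table inputs."""


def _load_synonyms() -> dict[str, str]:
    text = resources.files("mirpair.data").joinpath("synonyms.tsv").read_text()
    table = pd.read_csv(io.StringIO(text), sep="\t")
    return dict(zip(table["alias"], table["canonical"]))


_SYNONYMS = _load_synonyms()


def canonical_assay_name(name: str) -> str:
    """Map an assay label to its canonical panel identifier.

    Strips whitespace and a leading ``hsa-`` species prefix, then applies the
    packaged synonym table (e.g. ``miR-451a`` -> ``miR-451a-5p``).
    """
    name = name.strip()
    if name.lower().startswith("hsa-"):
        name = name[4:]
    return _SYNONYMS.get(name, name)


@dataclass(frozen=True)
class Assay:
    mirna_id: str
    role: str
    brain_enriched: bool

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelError(f"unknown assay role {self.role!r} for {self.mirna_id}")


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of assay records; order is stable across reads."""

    assays: tuple[Assay, ...]

    def __post_init__(self) -> None:
        if not self.assays:
            raise PanelError("panel must contain at least one assay")
        seen: set[str] = set()
        for a in self.assays:
            if a.mirna_id in seen:
                raise PanelError(f"duplicate assay identifier: {a.mirna_id}")
            seen.add(a.mirna_id)

    @property
    def mirna_ids(self) -> list[str]:
        return [a.mirna_id for a in self.assays]

    def __len__(self) -> int:
        return len(self.assays)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in set(self.mirna_ids)


def _parse_bool(token: str, context: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise PanelError(f"cannot parse boolean {token!r} in {context}")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; all inputs here are small text tables
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def read_panel(path: str | Path) -> PanelDefinition:
    """Read a panel definition file (columns mirna_id, role, brain_enriched)."""
    table = _read_delimited(path)
    required = {"mirna_id", "role", "brain_enriched"}
    missing = required - set(table.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    assays = []
    for _, row in table.iterrows():
        role_token = str(row["role"]).strip().lower()
        if role_token not in _ROLE_ALIASES:
            raise PanelError(f"unknown role token {row['role']!r} for {row['mirna_id']}")
        assays.append(
            Assay(
                mirna_id=canonical_assay_name(row["mirna_id"]),
                role=_ROLE_ALIASES[role_token],
                brain_enriched=_parse_bool(row["brain_enriched"], f"assay {row['mirna_id']}"),
            )
        )
    return PanelDefinition(assays=tuple(assays))


def load_default_panel() -> PanelDefinition:
    """The packaged 48-assay glioblastoma plasma miRNA panel."""
    text = resources.files("mirpair.data").joinpath("gbm_panel.tsv").read_text()
    table = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    assays = tuple(
        Assay(
            mirna_id=canonical_assay_name(r["mirna_id"]),
            role=_ROLE_ALIASES[r["role"].strip().lower()],
            brain_enriched=_parse_bool(r["brain_enriched"], r["mirna_id"]),
        )
        for _, r in table.iterrows()
    )
    return PanelDefinition(assays=assays)


@dataclass
class CtMatrix:
    """Samples x assays Ct values with cohort labels and censoring flags.

    ``ct`` holds cycle-threshold values; wherever ``censored`` is True the
    stored value equals ``max_cycles`` (the no-amplification imputation).
    """

    samples: pd.DataFrame  # columns: sample_id, cohort, sample_type[, plate]
    assays: list[str]
    ct: np.ndarray
    censored: np.ndarray
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        n, m = len(self.samples), len(self.assays)
        if self.ct.shape != (n, m):
            raise PanelError(f"ct shape {self.ct.shape} != ({n}, {m})")
        if self.censored.shape != (n, m):
            raise PanelError("censored mask shape mismatch")
        if len(set(self.assays)) != m:
            raise PanelError("duplicate assay in CtMatrix")
        if not self.samples["sample_id"].is_unique:
            raise PanelError("duplicate sample_id in CtMatrix")
        bad = set(self.samples["cohort"]) - set(COHORTS)
        if bad:
            raise PanelError(f"unknown cohort labels: {sorted(bad)}")
        if not np.allclose(self.ct[self.censored], self.max_cycles, atol=0, rtol=0):
            raise PanelError("censored entries must hold ct == max_cycles")
        unc = self.ct[~self.censored]
        if unc.size and (np.any(unc <= 0) or np.any(unc > self.max_cycles)):
            raise PanelError("uncensored ct values must lie in (0, max_cycles]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_assays(self) -> int:
        return len(self.assays)

    @property
    def labels(self) -> np.ndarray:
        """Boolean per-sample vector, True for the case cohort."""
        return (self.samples["cohort"] == "case").to_numpy()

    def assay_index(self, mirna_id: str) -> int:
        try:
            return self.assays.index(canonical_assay_name(mirna_id))
        except ValueError:
            raise PanelError(f"assay {mirna_id!r} not in matrix") from None

    def subset_assays(self, keep: Sequence[str]) -> "CtMatrix":
        idx = [self.assay_index(a) for a in keep]
        return CtMatrix(
            samples=self.samples.copy().reset_index(drop=True),
            assays=[self.assays[i] for i in idx],
            ct=self.ct[:, idx].copy(),
            censored=self.censored[:, idx].copy(),
            max_cycles=self.max_cycles,
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in self.samples.iterrows():
            for j, assay in enumerate(self.assays):
                rows.append(
                    {
                        "sample_id": s["sample_id"],
                        "cohort": s["cohort"],
                        "sample_type": s.get("sample_type", "plasma"),
                        "assay": assay,
                        "ct": "Undetermined" if self.censored[i, j] else repr(float(self.ct[i, j])),
                        "plate": s.get("plate", ""),
                    }
                )
        return pd.DataFrame(rows)


def write_ct_table(ct: CtMatrix, path: str | Path) -> None:
    """Write the long-CSV dialect; uncensored values round-trip bit-exactly."""
    ct.to_long_frame().to_csv(path, index=False)


def _parse_ct_cell(token: str) -> float | None:
    """Return the Ct value, or None for a censored cell; raise on garbage."""
    t = str(token).strip()
    if t.lower() in CENSORED_TOKENS:
        return None
    return float(t)  # ValueError propagates to caller


def read_ct_table(
    path: str | Path,
    layout: str = "long",
    panel: PanelDefinition | None = None,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> CtMatrix:
    """Read a Ct table into a :class:`CtMatrix`.

    Long layout: columns ``sample_id, cohort, assay, ct`` plus optional
    ``sample_type, plate, well``; replicate wells for the same (sample, assay)
    are collapsed by median over uncensored wells. Wide layout: one row per
    sample, one column per assay. ``Undetermined``/``NA``/empty cells become
    censored entries imputed at ``max_cycles``.
    """
    if layout not in ("long", "wide"):
        raise PanelError(f"unknown layout {layout!r}")
    table = _read_delimited(path)
    if layout == "long":
        return _from_long(table, panel, max_cycles)
    return _from_wide(table, panel, max_cycles)


def _canonical_cohort(token: str) -> str:
    t = str(token).strip().lower()
    if t not in _COHORT_ALIASES:
        raise PanelError(f"unknown cohort label {token!r}")
    return _COHORT_ALIASES[t]


def _check_assays_in_panel(assays: Iterable[str], panel: PanelDefinition | None) -> None:
    if panel is None:
        return
    offenders = sorted(set(assays) - set(panel.mirna_ids))
    if offenders:
        raise PanelError(f"assays not in panel: {offenders}")


def _from_long(table: pd.DataFrame, panel: PanelDefinition | None, max_cycles: float) -> CtMatrix:
    required = {"sample_id", "cohort", "assay", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise PanelError(f"long Ct table missing columns: {sorted(missing)}")
    table = table.copy()
    table["assay"] = table["assay"].map(canonical_assay_name)
    _check_assays_in_panel(table["assay"], panel)

    parsed: list[float | None] = []
    bad_per_sample: dict[str, int] = {}
    ok_per_sample: dict[str, int] = {}
    for sid, token in zip(table["sample_id"], table["ct"]):
        try:
            parsed.append(_parse_ct_cell(token))
            ok_per_sample[sid] = ok_per_sample.get(sid, 0) + 1
        except ValueError:
            parsed.append(np.nan)  # placeholder; well is unusable
            bad_per_sample[sid] = bad_per_sample.get(sid, 0) + 1
            ok_per_sample.setdefault(sid, 0)
    table["_ct_value"] = [np.nan if v is None else v for v in parsed]
    table["_censored"] = [v is None for v in parsed]
    dead = sorted(s for s, n_ok in ok_per_sample.items() if n_ok == 0)
    if dead:
        raise PanelError(f"samples with zero parseable wells: {dead}")
    # drop individual garbage wells (sample still has parseable ones)
    bad_rows = [
        i
        for i, (v, c) in enumerate(zip(table["_ct_value"], table["_censored"]))
        if (not c) and np.isnan(v)
    ]
    table = table.drop(table.index[bad_rows])

    sample_ids = list(dict.fromkeys(table["sample_id"]))
    if panel is not None:
        assay_order = [a for a in panel.mirna_ids if a in set(table["assay"])]
    else:
        assay_order = list(dict.fromkeys(table["assay"]))
    n, m = len(sample_ids), len(assay_order)
    ct = np.full((n, m), max_cycles)
    censored = np.ones((n, m), dtype=bool)
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    a_idx = {a: j for j, a in enumerate(assay_order)}
    for (sid, assay), grp in table.groupby(["sample_id", "assay"], sort=False):
        vals = grp.loc[~grp["_censored"], "_ct_value"].to_numpy(dtype=float)
        i, j = s_idx[sid], a_idx[assay]
        if vals.size:
            ct[i, j] = float(np.median(vals))
            censored[i, j] = False

    meta_rows = []
    first = table.drop_duplicates("sample_id").set_index("sample_id")
    for sid in sample_ids:
        row = first.loc[sid]
        meta_rows.append(
            {
                "sample_id": sid,
                "cohort": _canonical_cohort(row["cohort"]),
                "sample_type": str(row["sample_type"]).strip().lower()
                if "sample_type" in first.columns and str(row["sample_type"]).strip()
                else "plasma",
                "plate": str(row["plate"]) if "plate" in first.columns else "",
            }
        )
    samples = pd.DataFrame(meta_rows)
    return CtMatrix(samples=samples, assays=assay_order, ct=ct, censored=censored, max_cycles=max_cycles)


def _from_wide(table: pd.DataFrame, panel: PanelDefinition | None, max_cycles: float) -> CtMatrix:
    meta_cols = [c for c in ("sample_id", "cohort", "sample_type", "plate") if c in table.columns]
    if "sample_id" not in meta_cols or "cohort" not in meta_cols:
        raise PanelError("wide Ct table needs sample_id and cohort columns")
    assay_cols = [c for c in table.columns if c not in meta_cols]
    assays = [canonical_assay_name(c) for c in assay_cols]
    _check_assays_in_panel(assays, panel)
    n, m = len(table), len(assays)
    ct = np.full((n, m), max_cycles)
    censored = np.ones((n, m), dtype=bool)
    for i in range(n):
        n_ok = 0
        for j, col in enumerate(assay_cols):
            try:
                v = _parse_ct_cell(table.iloc[i][col])
                n_ok += 1
            except ValueError:
                continue
            if v is not None:
                ct[i, j] = v
                censored[i, j] = False
        if n_ok == 0:
            raise PanelError(
                f"samples with zero parseable wells: [{table.iloc[i]['sample_id']!r}]"
            )
    samples = pd.DataFrame(
        {
            "sample_id": table["sample_id"].astype(str),
            "cohort": [_canonical_cohort(c) for c in table["cohort"]],
            "sample_type": table["sample_type"].astype(str).str.lower()
            if "sample_type" in table.columns
            else "plasma",
            "plate": table["plate"].astype(str) if "plate" in table.columns else "",
        }
    )
    return CtMatrix(samples=samples, assays=assays, ct=ct, censored=censored, max_cycles=max_cycles)


def align_profiles(a: CtMatrix, b: CtMatrix) -> tuple[CtMatrix, CtMatrix]:
    """Restrict two matrices to their shared assays, in identical order."""
    shared = [x for x in a.assays if x in set(b.assays)]
    if len(shared) < 2:
        raise PanelError(f"matrices share only {len(shared)} assays (need >= 2)")
    return a.subset_assays(shared), b.subset_assays(shared)


@dataclass
class ControlWells:
    """Per-plate run-control wells (spike-ins, blanks, NTCs, positive oligos)."""

    wells: pd.DataFrame  # columns: control_type, plate_id, ct, censored

    def __post_init__(self) -> None:
        required = {"control_type", "plate_id", "ct", "censored"}
        missing = required - set(self.wells.columns)
        if missing:
            raise PanelError(f"control wells missing columns: {sorted(missing)}")
        bad = set(self.wells["control_type"]) - set(CONTROL_TYPES)
        if bad:
            raise PanelError(f"unknown control types: {sorted(bad)}")

    def of_type(self, control_type: str) -> pd.DataFrame:
        return self.wells[self.wells["control_type"] == control_type]


def read_controls(path: str | Path, max_cycles: float = DEFAULT_MAX_CYCLES) -> ControlWells:
    """Read a control-well table (columns control_type, plate_id, ct)."""
    table = _read_delimited(path)
    required = {"control_type", "plate_id", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise PanelError(f"control table missing columns: {sorted(missing)}")
    ct_vals, cens = [], []
    for token in table["ct"]:
        v = _parse_ct_cell(token)
        ct_vals.append(max_cycles if v is None else v)
        cens.append(v is None)
    wells = pd.DataFrame(
        {
            "control_type": table["control_type"].astype(str),
            "plate_id": table["plate_id"].astype(str),
            "ct": ct_vals,
            "censored": cens,
        }
    )
    return ControlWells(wells=wells)


def write_controls(controls: ControlWells, path: str | Path) -> None:
    out = controls.wells.copy()
    out["ct"] = [
        "Undetermined" if c else repr(float(v)) for v, c in zip(out["ct"], out["censored"])
    ]
    out.drop(columns=["censored"]).to_csv(path, index=False)
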