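"""End-to-end discovery runs and report assembly.

``run_discovery`` executes the full chain — read panel and Ct table, QC
elimination, pair enumeration, single-pair screening, AUC gate, exhaustive
combination search — and writes a reproducible bundle: the pair-results TSV,
the ranked-combination TSV, ROC point files for the top combinations,
per-pair group summaries, the QC report JSON, the resolved configuration,
and a log carrying seed, version, and config hash. Reports are rendered
strictly from bundle files (never recomputed) so artifacts cannot drift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, stats
from .combos import ComboCriteria, exhaustive_combo_search
from .pairs import PairFeature, enumerate_pairs, pair_feature_matrix
from .panel import CtMatrix, PanelDefinition, load_default_panel, read_ct_table, read_panel
from .qc import QcThresholds, apply_elimination, assess_assays
from .single_pair import evaluate_all_pairs, results_table, select_pairs


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Fully serializable description of one discovery run."""

    ct_path: str
    out_dir: str
    panel_path: str | None = None  # None -> packaged 48-assay panel
    layout: str = "long"
    qc: QcThresholds = field(default_factory=QcThresholds)
    skip_qc: bool = False
    auc_min: float = 0.8
    ci_method: str = "delong"
    seed: int = 0
    k: int = 3
    combo_mode: str = "standardized_log"
    criteria: ComboCriteria = field(default_factory=ComboCriteria)
    top_roc: int = 3  # combos for which ROC point files are written

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_discovery(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns the bundle's artifact paths.

    On any stage failure, partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def emit(path: Path, writer) -> Path:
        writer(path)
        written.append(path)
        return path

    try:
        resolved = config.to_json()
        cfg_hash = hashlib.sha256(resolved.encode()).hexdigest()[:16]
        log_lines.append(f"mirpair {__version__} seed={config.seed} config_hash={cfg_hash}")

        with _stage("panel_io"):
            panel = read_panel(config.panel_path) if config.panel_path else load_default_panel()
            ct = read_ct_table(config.ct_path, layout=config.layout, panel=panel)
            log_lines.append(
                f"panel_io: {len(panel)} panel assays; {ct.n_samples} samples x {ct.n_assays} assays"
            )

        with _stage("qc_filtering"):
            if config.skip_qc:
                log_lines.append("qc_filtering: skipped by config")
            else:
                report = assess_assays(ct, config.qc)
                emit(out / "qc_report.json", lambda p: report.to_json(p))
                ct = apply_elimination(ct, report)
                log_lines.append(
                    f"qc_filtering: eliminated {len(report.eliminated_assays)} assays, "
                    f"{ct.n_assays} retained"
                )

        with _stage("pair_features"):
            pairs = enumerate_pairs(ct.assays)
            _, delta, cens = pair_feature_matrix(ct, pairs)
            log_lines.append(f"pair_features: {len(pairs)} candidate pairs")

        with _stage("single_pair_eval"):
            results = evaluate_all_pairs(ct, pairs, ci_method=config.ci_method, seed=config.seed)
            table = results_table(results)
            emit(out / "pair_results.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
            gated = select_pairs(results, auc_min=config.auc_min)
            log_lines.append(
                f"single_pair_eval: {len(gated)} pairs passed the AUC >= {config.auc_min} gate"
            )
            _write_group_summaries(out, emit, ct, results, top_n=5)

        with _stage("combo_search"):
            if len(gated) < config.k:
                log_lines.append(
                    f"combo_search: skipped — gate holds {len(gated)} pairs, fewer than k={config.k}"
                )
            else:
                features = {
                    f"{a}/{b}": PairFeature(
                        mirna_a=a, mirna_b=b, delta_ct=delta[:, i], any_censored=cens[:, i]
                    )
                    for i, (a, b) in enumerate(pairs)
                }
                ranked, n_eval = exhaustive_combo_search(
                    gated,
                    features,
                    ct.labels,
                    k=config.k,
                    criteria=config.criteria,
                    mode=config.combo_mode,
                )
                combo_out = ranked.drop(columns=["members"]) if len(ranked) else ranked
                emit(
                    out / "combo_results.tsv",
                    lambda p: combo_out.to_csv(p, sep="\t", index=False),
                )
                log_lines.append(
                    f"combo_search: {n_eval} combinations of k={config.k} evaluated, "
                    f"{len(ranked)} met criteria (mode={config.combo_mode})"
                )
                if config.combo_mode == "raw_ratio":
                    log_lines.append(
                        "combo_search: CAVEAT raw_ratio mode — positive ratio means push "
                        "every sigmoid score above 0.5; all samples classified as case"
                    )
                _write_combo_rocs(out, emit, ranked, gated, features, ct, config)

        emit(out / "resolved_config.json", lambda p: p.write_text(resolved))
        emit(out / "log.txt", lambda p: p.write_text("\n".join(log_lines) + "\n"))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return {p.name: p for p in written}


def _write_group_summaries(out, emit, ct: CtMatrix, results, top_n: int) -> None:
    """Per-cohort distribution summaries for the top pairs (box-plot data)."""
    top = select_pairs(results, auc_min=0.0)[:top_n]
    labels = ct.labels
    rows = []
    for r in top:
        ia, ib = ct.assay_index(r.mirna_a), ct.assay_index(r.mirna_b)
        delta = ct.ct[:, ib] - ct.ct[:, ia]
        for name, mask in (("case", labels), ("control", ~labels)):
            q1, med, q3 = np.percentile(delta[mask], [25, 50, 75])
            rows.append(
                {
                    "pair_id": r.pair_id,
                    "cohort": name,
                    "min": float(delta[mask].min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(delta[mask].max()),
                    "mw_p": r.mw_p,
                }
            )
    emit(
        out / "group_summaries.tsv",
        lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False),
    )


def _write_combo_rocs(out, emit, ranked, gated, features, ct: CtMatrix, config: RunConfig) -> None:
    from .combos import build_combo

    by_id = {r.pair_id: r for r in gated}
    for rank in range(min(config.top_roc, len(ranked))):
        members = [by_id[m] for m in ranked.iloc[rank]["members"]]
        combo = build_combo(members, features, ct.labels, mode=config.combo_mode)
        pts = stats.roc_points(combo.score, ct.labels)
        emit(
            out / f"roc_combo_{rank + 1}.csv",
            lambda p, pts=pts: pd.DataFrame(
                pts, columns=["fpr", "sensitivity"]
            ).to_csv(p, index=False),
        )


def make_report(bundle_dir: str | Path) -> str:
    """Render a human-readable summary strictly from bundle files."""
    bundle = Path(bundle_dir)
    required = ["pair_results.tsv", "resolved_config.json", "log.txt"]
    for name in required:
        if not (bundle / name).exists():
            raise FileNotFoundError(f"bundle is missing {name}")
    config = json.loads((bundle / "resolved_config.json").read_text())
    log = (bundle / "log.txt").read_text()
    pair_table = pd.read_csv(bundle / "pair_results.tsv", sep="\t")

    lines = ["# Discovery run report", ""]
    lines.append("## Settings")
    for key in ("auc_min", "ci_method", "k", "combo_mode", "seed", "layout"):
        lines.append(f"- {key}: {config[key]}")
    lines.append(f"- qc thresholds: {config['qc']}")
    lines.append(f"- combo criteria: {config['criteria']}")
    lines.append("")

    qc_path = bundle / "qc_report.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        lines.append("## QC")
        lines.append(f"- eliminated assays ({len(qc['eliminated_assays'])}): "
                     + (", ".join(qc["eliminated_assays"]) or "none"))
        lines.append("")

    lines.append("## Top 5 pairs")
    top5 = pair_table.sort_values(["auc", "pair_id"], ascending=[False, True]).head(5)
    for _, r in top5.iterrows():
        lines.append(
            f"- {r['pair_id']}: AUC {r['auc']:.3f} "
            f"(95% CI {r['auc_ci_low']:.3f}-{r['auc_ci_high']:.3f}), "
            f"sens {r['sensitivity']:.2f}, spec {r['specificity']:.2f}, "
            f"acc {r['accuracy']:.2f}, Mann-Whitney p {r['mw_p']:.2e}"
        )
    lines.append("")

    combo_path = bundle / "combo_results.tsv"
    if combo_path.exists():
        combo = pd.read_csv(combo_path, sep="\t")
        lines.append("## Top 6 combination classifiers")
        member_cols = [c for c in combo.columns if c.startswith("pair_")]
        for _, r in combo.head(6).iterrows():
            members = " + ".join(str(r[c]) for c in member_cols)
            lines.append(
                f"- {members}: AUC {r['auc']:.3f}, sens {r['sensitivity']:.2f}, "
                f"spec {r['specificity']:.2f}, acc {r['accuracy']:.2f}"
            )
        lines.append("")
    else:
        lines.append("## Combination classifiers")
        lines.append("- combo stage skipped (see log)")
        lines.append("")

    if config["combo_mode"] == "raw_ratio":
        lines.append(
            "> CAVEAT: raw_ratio mode averages strictly positive ratios, so the "
            "sigmoid score exceeds 0.5 for every sample and specificity is 0. "
            "This mode documents the literal printed formula; use "
            "standardized_log for a usable classifier."
        )
        lines.append("")

    lines.append("## Log")
    lines.append("```")
    lines.append(log.rstrip())
    lines.append("```")
    return "\n".join(lines) + "\n"
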