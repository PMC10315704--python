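"""End-to-end reproducible runs: configuration, cohort I/O, and the
report combining ROC analyses, paired AUC comparisons, rule-based calls
and PET/MRI concordance accounting."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as dx
from .diagnostics import (
    POD,
    TRC,
    ContingencyTable,
    MetricOrientation,
    ThresholdRules,
    apply_thresholds,
    benjamini_hochberg,
    concordance_summary,
    contingency_metrics,
    format_performance,
    hanley_compare,
    optimal_cutoff,
    roc_curve,
)
from .kinetics import PetMetrics
from .perfusion import PerfusionMetrics
from .simulate import (
    ATDG,
    BM,
    COHORT_COLUMNS,
    Cohort,
    PatientRecord,
    generate_cohort,
    write_cohort,
)

__all__ = [
    "DEFAULT_METRICS",
    "DEFAULT_COMPARISONS",
    "RunConfig",
    "load_cohort_table",
    "run_pipeline",
    "render_report_text",
]

log = logging.getLogger("fetpwi")

#: Metrics analyzed by default, in report order.
DEFAULT_METRICS: tuple[str, ...] = (
    "volume_change_pct",
    "rcbv",
    "ktrans",
    "ve",
    "tbr_slope",
    "tbr_intercept",
    "tbr_max",
    "tbr_mean",
    "suv_slope",
    "suv_intercept",
    "suv_max",
    "suv_mean",
    "ttp_s",
)

#: Default paired AUC comparisons (metric_1 tested for overperformance).
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("tbr_intercept", "rcbv"),
    ("tbr_mean", "rcbv"),
    ("tbr_max", "rcbv"),
    ("tbr_intercept", "ktrans"),
    ("tbr_mean", "ktrans"),
    ("tbr_max", "ktrans"),
    ("ktrans", "rcbv"),
)

_MANDATORY_COLUMNS = ("patient_id", "truth_label", "origin")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: seed, cohort parameters,
    metric list with orientations, threshold rules and comparisons."""

    seed: int = 0
    n: int = 80
    prevalence: float = 42.0 / 80.0
    origin_mix: float = 42.0 / 80.0
    metrics: tuple[str, ...] = DEFAULT_METRICS
    lower_indicates_pod: tuple[str, ...] = ("tbr_slope", "suv_slope", "ttp_s")
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    pet_rules: tuple[tuple[str, str, float], ...] = (("tbr_max", ">", 2.5),)
    mri_rules: tuple[tuple[str, str, float], ...] = (
        ("rcbv", ">", 3.0),
        ("ktrans", ">", 0.26),
    )
    fusion: str = "pet"

    def orientation(self, metric: str) -> MetricOrientation:
        return MetricOrientation(metric, metric not in self.lower_indicates_pod)

    def threshold_rules(self) -> ThresholdRules:
        return ThresholdRules(
            pet_rules=tuple(tuple(r) for r in self.pet_rules),
            mri_rules=tuple(tuple(r) for r in self.mri_rules),
            fusion=self.fusion,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        for key in ("metrics", "lower_indicates_pod"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "comparisons" in kwargs:
            kwargs["comparisons"] = tuple(tuple(p) for p in kwargs["comparisons"])
        for key in ("pet_rules", "mri_rules"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(r) for r in kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Load a cohort CSV into typed records.

    Mandatory columns are ``patient_id``, ``truth_label`` and ``origin``;
    the canonical metric columns are consumed into typed metric blocks,
    and any unknown numeric column is preserved as a passthrough score
    usable as an ROC metric downstream.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path.name} is missing columns: {missing}")
    metric_cols = [c for c in frame.columns if c not in _MANDATORY_COLUMNS]
    records: list[PatientRecord] = []
    for idx, row in frame.iterrows():
        label = str(row["truth_label"])
        if label not in (POD, TRC):
            raise ValueError(
                f"line {idx + 2}: truth_label must be POD or TRC, got {label!r}"
            )
        values: dict[str, float] = {}
        for col in metric_cols:
            raw = row[col]
            try:
                values[col] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"line {idx + 2}: non-numeric value {raw!r} in column {col!r}"
                ) from None
        pet_fields = {
            k: values.pop(k, float("nan"))
            for k in PetMetrics.__dataclass_fields__
        }
        perf_fields = {
            k: values.pop(k, float("nan"))
            for k in PerfusionMetrics.__dataclass_fields__
        }
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                truth_label=label,
                origin=str(row["origin"]),
                pet=PetMetrics(**pet_fields),
                perfusion=PerfusionMetrics(**perf_fields),
                volume_change_pct=values.pop("volume_change_pct", float("nan")),
                extra_scores=values,
            )
        )
    return records


def _metric_analysis(
    frame: pd.DataFrame, metric: str, config: RunConfig
) -> dict | None:
    scores = frame[metric].to_numpy(dtype=float)
    labels = frame["truth_label"].to_numpy()
    keep = ~np.isnan(scores)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("metric %s: dropped %d rows with missing values", metric, n_dropped)
    scores, labels = scores[keep], labels[keep]
    if scores.size == 0 or len(set(labels)) < 2:
        log.warning("metric %s: not analyzable (empty or single-class)", metric)
        return None
    roc = roc_curve(scores, labels, config.orientation(metric), metric=metric)
    cut = optimal_cutoff(roc)
    calls = [cut.call(v) for v in scores]
    table = ContingencyTable.from_calls(calls, labels)
    perf = contingency_metrics(table)
    return {
        "metric": metric,
        "direction": config.orientation(metric).inequality,
        "n_used": int(scores.size),
        "n_dropped": n_dropped,
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "ci95": list(roc.ci95),
        "p_auc_gt_half": roc.p_auc_gt_half,
        "cutoff": {
            "threshold": cut.threshold,
            "direction": cut.direction,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
            "gmean": cut.gmean,
        },
        "contingency": {"tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn},
        "performance": perf,
        "performance_formatted": format_performance(perf),
        "_roc": roc,
    }


def _institutional_block(frame: pd.DataFrame, config: RunConfig) -> dict:
    rules = config.threshold_rules()
    decisions = [
        apply_thresholds(row, rules)
        for row in frame.to_dict("records")
    ]
    truth = frame["truth_label"].to_numpy()
    origin = frame["origin"].to_numpy()
    hybrid = np.array([d.hybrid_call for d in decisions])
    pet = np.array([d.pet_call for d in decisions])
    mri = np.array([d.mri_call for d in decisions])

    def stratum(mask: np.ndarray) -> dict:
        table = ContingencyTable.from_calls(hybrid[mask], truth[mask])
        perf = contingency_metrics(table)
        return {
            "n": int(mask.sum()),
            "contingency": {
                "tp": table.tp,
                "fp": table.fp,
                "tn": table.tn,
                "fn": table.fn,
            },
            "performance": perf,
            "performance_formatted": format_performance(perf),
        }

    conc = concordance_summary(pet, mri, truth)
    return {
        "rules": {
            "pet": [list(r) for r in rules.pet_rules],
            "mri": [list(r) for r in rules.mri_rules],
            "fusion": rules.fusion,
        },
        "overall": stratum(np.ones(len(frame), dtype=bool)),
        "by_origin": {
            ATDG: stratum(origin == ATDG) if (origin == ATDG).any() else None,
            BM: stratum(origin == BM) if (origin == BM).any() else None,
        },
        "concordance": asdict(conc),
        "calls": {
            "pet": pet.tolist(),
            "mri": mri.tolist(),
            "hybrid": hybrid.tolist(),
        },
    }


def run_pipeline(
    config: RunConfig,
    cohort: Cohort | Sequence[PatientRecord] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return the diagnostic report.

    With no ``cohort`` given, a synthetic one is generated from the
    config's seed and cohort parameters. When ``out_dir`` is set the
    cohort table, report JSON, ROC coordinates CSV and a human-readable
    summary are written there, each stamped with the config hash and seed.
    """
    if not config.metrics:
        raise ValueError("no metrics configured")
    if cohort is None:
        log.info("simulating cohort: n=%d seed=%s", config.n, config.seed)
        cohort = generate_cohort(
            config.n,
            prevalence=config.prevalence,
            origin_mix=config.origin_mix,
            seed=config.seed,
        )
    if isinstance(cohort, Cohort):
        frame = cohort.to_frame()
    else:
        frame = Cohort(records=list(cohort)).to_frame()
    if len(frame) == 0:
        raise ValueError("cohort is empty")

    metric_blocks: dict[str, dict] = {}
    for metric in config.metrics:
        if metric not in frame.columns:
            log.warning("metric %s not present in cohort table; skipped", metric)
            continue
        block = _metric_analysis(frame, metric, config)
        if block is not None:
            metric_blocks[metric] = block
    if not metric_blocks:
        raise ValueError("no analyzable metrics in cohort")

    # One Benjamini-Hochberg family across the per-metric AUC > 0.5 tests.
    names = list(metric_blocks)
    adjusted = benjamini_hochberg([metric_blocks[m]["p_auc_gt_half"] for m in names])
    for name, adj in zip(names, adjusted):
        metric_blocks[name]["p_adjusted"] = float(adj)

    # Paired AUC comparisons form their own BH family.
    comparisons = []
    labels = frame["truth_label"].to_numpy()
    for m1, m2 in config.comparisons:
        if m1 not in metric_blocks or m2 not in metric_blocks:
            continue
        s1 = frame[m1].to_numpy(dtype=float)
        s2 = frame[m2].to_numpy(dtype=float)
        keep = ~(np.isnan(s1) | np.isnan(s2))
        cmp = hanley_compare(
            s1[keep],
            s2[keep],
            labels[keep],
            config.orientation(m1),
            config.orientation(m2),
            alternative="greater",
        )
        comparisons.append(
            {
                "metric_1": m1,
                "metric_2": m2,
                "auc_1": cmp.auc_a,
                "auc_2": cmp.auc_b,
                "r": cmp.r,
                "z": cmp.z,
                "p_raw": cmp.p,
            }
        )
    if comparisons:
        adj = benjamini_hochberg([c["p_raw"] for c in comparisons])
        for c, a in zip(comparisons, adj):
            c["p_adjusted"] = float(a)

    institutional = _institutional_block(frame, config)

    roc_frames = []
    for name, block in metric_blocks.items():
        roc = block.pop("_roc")
        roc_frames.append(
            pd.DataFrame(
                {
                    "metric": name,
                    "threshold_transformed": roc.thresholds,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                }
            )
        )
    roc_table = pd.concat(roc_frames, ignore_index=True)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n": int(len(frame)),
        "n_pod": int((labels == POD).sum()),
        "n_trc": int((labels == TRC).sum()),
        "metrics": metric_blocks,
        "comparisons": comparisons,
        "institutional": institutional,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "cohort.csv", index=False)
        roc_table.to_csv(out_dir / "roc_coordinates.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        (out_dir / "report.txt").write_text(render_report_text(report))
        (out_dir / "config.json").write_text(
            json.dumps(
                {"config": config.to_dict(), "hash": config.config_hash()},
                indent=2,
                default=list,
            )
        )
    return report


def render_report_text(report: dict) -> str:
    """Human-readable summary mirroring the clinical table layout."""
    lines = [
        f"fetpwi diagnostic report  (n={report['n']}, POD={report['n_pod']}, "
        f"TRC={report['n_trc']}, seed={report['seed']}, "
        f"config={report['config_hash']})",
        "",
        "Per-metric ROC analysis",
        f"{'metric':18s} {'cutoff':>12s} {'SN':>5s} {'SP':>5s} {'ACC':>5s} "
        f"{'PPV':>5s} {'NPV':>5s} {'AUC':>6s} {'95% CI':>13s} {'adj P':>9s}",
    ]
    for name, b in report["metrics"].items():
        cut = b["cutoff"]
        pf = b["performance_formatted"]
        ci = b["ci95"]
        ci_str = f"{ci[0]:.2f}-{ci[1]:.2f}"
        lines.append(
            f"{name:18s} {cut['direction']}{cut['threshold']:11.3g} "
            f"{pf['sensitivity']:>5s} {pf['specificity']:>5s} {pf['accuracy']:>5s} "
            f"{pf['ppv']:>5s} {pf['npv']:>5s} {b['auc']:6.2f} "
            f"{ci_str:>13s} {b['p_adjusted']:9.2g}"
        )
    lines.append("")
    lines.append("Paired AUC comparisons (metric 1 over metric 2)")
    for c in report["comparisons"]:
        lines.append(
            f"  {c['metric_1']} vs {c['metric_2']}: "
            f"{c['auc_1']:.4f} vs {c['auc_2']:.4f}, adj P={c['p_adjusted']:.3g}"
        )
    inst = report["institutional"]
    overall = inst["overall"]
    pf = overall["performance_formatted"]
    t = overall["contingency"]
    lines += [
        "",
        "Institutional rule-based hybrid calls",
        f"  TP={t['tp']} TN={t['tn']} FP={t['fp']} FN={t['fn']}",
        f"  accuracy {pf['accuracy']}, sensitivity {pf['sensitivity']}, "
        f"specificity {pf['specificity']}, PPV {pf['ppv']}, NPV {pf['npv']}, "
        f"+LR {pf['plr']}, -LR {pf['nlr']}",
    ]
    conc = inst["concordance"]
    if conc["n_concordant"]:
        lines.append(
            f"  concordant PET/MRI: {conc['concordant_correct']}/{conc['n_concordant']} correct"
        )
    if conc["n_discordant"]:
        lines.append(
            f"  discordant: PET correct in {conc['pet_correct_when_discordant_n']}"
            f"/{conc['n_discordant']}, MRI correct in "
            f"{conc['mri_correct_when_discordant_n']}/{conc['n_discordant']}"
        )
    return "\n".join(lines) + "\n"
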