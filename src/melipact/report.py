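"""Pipeline orchestration and table rendering.

``run_audit`` executes generate → reclassify → audit → stats → train as one
reproducible run, writing per-stage artifacts plus a machine-readable
summary.  ``render_tables`` produces descriptive tables in the survey's
column order (N, Means±SD, CI−95, CI+95, Var, Min, Max, Q25, Median, Q75,
letter) with extreme values outside the policy limits flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from .cann import TrainingConfig, train_classifier
from .compliance import Grade, check_sample, grade_verdict, summarize_compliance
from .data_model import (
    PARAMETERS,
    HoneyType,
    SampleTable,
    ThresholdPolicy,
    read_samples,
    write_samples,
)
from .reclassify import reclassify_table
from .stats import describe, pearson_matrix, tukey_hsd
from .synthetic import GeneratorConfig, build_fixture, generate_realistic

__all__ = ["AuditRunConfig", "run_audit", "render_tables"]

log = logging.getLogger("melipact")

ALL_STAGES = ("generate", "reclassify", "audit", "stats", "train")


@dataclass
class AuditRunConfig:
    """One reproducible end-to-end run.

    Exactly one input source applies: a packaged-fixture seed, a CSV path,
    or a realistic-generator seed.
    """

    out_dir: str | Path = "results"
    fixture_seed: int | None = None
    input_csv: str | Path | None = None
    realistic_seed: int | None = None
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        sources = [
            self.fixture_seed is not None,
            self.input_csv is not None,
            self.realistic_seed is not None,
        ]
        if sum(sources) != 1:
            raise ValueError("exactly one of fixture_seed / input_csv / realistic_seed")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown or not self.stages:
            raise ValueError(f"stages must be a non-empty subset of {ALL_STAGES}")


def _dump_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def _load_input(config: AuditRunConfig) -> SampleTable:
    if config.fixture_seed is not None:
        table, manifest = build_fixture(config.fixture_seed)
        _dump_json(manifest.to_dict(), Path(config.out_dir) / "manifest.json")
        return table
    if config.input_csv is not None:
        return read_samples(config.input_csv)
    return generate_realistic(GeneratorConfig(seed=config.realistic_seed))


def run_audit(config: AuditRunConfig) -> dict:
    """Run the configured stages in order; return (and write) the summary.

    Fully deterministic given the seeds; every policy constant in force is
    logged at INFO so a run is self-describing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in fields(config.policy):
        v = getattr(config.policy, f.name)
        if isinstance(v, frozenset):
            v = sorted(t.value for t in v)
        log.info("policy %s = %s", f.name, v)
    log.info(
        "seeds fixture=%s realistic=%s split=%s init=%s",
        config.fixture_seed,
        config.realistic_seed,
        config.training.split_seed,
        config.training.init_seed,
    )

    table = _load_input(config)
    if len(table) == 0:
        raise ValueError("input table has no records")
    summary: dict = {"provenance": table.provenance, "n_records": len(table)}

    if "generate" in config.stages:
        write_samples(table, out / "table.csv")

    if "reclassify" in config.stages:
        table, reclass = reclassify_table(table, config.policy)
        _dump_json(reclass.to_dict(), out / "reclass.json")
        write_samples(table, out / "table_final.csv")
        summary["reclassification"] = {
            "moved": reclass.moved_count,
            "into_honeydew": reclass.in_count,
            "out_of_honeydew": reclass.out_count,
            "final_honeydew": reclass.final_honeydew_count,
        }

    if "audit" in config.stages:
        per_sample = []
        for s in table:
            report = check_sample(s, config.policy)
            verdict = grade_verdict(report)
            per_sample.append(
                {
                    "sample_id": s.sample_id,
                    "codes": sorted(c.value for c in report.codes),
                    "blend_suspect": report.blend_suspect,
                    "grade": verdict.grade.value,
                }
            )
        _dump_json({"samples": per_sample}, out / "audit.json")
        comp = summarize_compliance(table, config.policy)
        summary["compliance"] = {
            "grades": {g.value: n for g, n in comp.grade_counts.items()},
            "nonconforming_pct": comp.nonconforming_pct,
            "codes": {c.value: n for c, n in comp.code_counts.items()},
            "blend_flags": comp.blend_count,
        }

    if "stats" in config.stages:
        render_tables(table, "final_type", config.policy, out / "summary_by_type.csv")
        corr = pearson_matrix(table)
        corr_df = pd.DataFrame(corr.r, index=corr.parameters, columns=corr.parameters)
        corr_df.to_csv(out / "corr.csv", float_format="%.3f")

    if "train" in config.stages:
        model, reports = train_classifier(table, config.training)
        model.to_json(out / "model.json")
        _dump_json(
            {name: rep.to_dict() for name, rep in reports.items()}, out / "eval.json"
        )
        summary["model"] = {
            "train_accuracy": reports["train"].accuracy,
            "test_accuracy": reports["test"].accuracy,
            "test_per_class": reports["test"].per_class_rate,
        }

    _dump_json(summary, out / "run_summary.json")
    return summary


def _extreme_flag(
    parameter: str, value: float, which: str, policy: ThresholdPolicy, honey_type: HoneyType | None
) -> bool:
    """Would this min/max be printed bold (outside the policy limits)?"""
    if parameter == "suc":
        ceiling = policy.sucrose_max(honey_type) if honey_type else policy.sucrose_max_default
        return which == "max" and value > ceiling
    if parameter == "hmf":
        return which == "max" and value > policy.hmf_max
    if parameter == "mc":
        return which == "max" and value > policy.moisture_max
    if parameter == "acid":
        return which == "max" and value > policy.acidity_max
    if parameter == "dia":
        return which == "min" and value < policy.diastase_min
    if parameter == "ins":
        return which == "max" and value > policy.insoluble_max
    if parameter == "econd":
        return which == "min" and value < policy.econd_low_flag
    return False


def render_tables(
    table: SampleTable,
    by: str,
    policy: ThresholdPolicy | None = None,
    out_csv: str | Path | None = None,
    out_md: str | Path | None = None,
) -> pd.DataFrame:
    """Descriptive table grouped by ``by`` (final_type, declared_type,
    region, or year), one row per parameter x group.

    Columns mirror the survey layout; ``letter`` is the Tukey compact
    letter within each parameter; ``min_flag``/``max_flag`` mark extremes
    outside the policy limits (rendered bold in markdown output).  Groups
    with fewer than two records are omitted from the letter computation.
    """
    policy = policy or ThresholdPolicy()
    if by == "final_type":
        key = lambda s: s.effective_type.value
    elif by == "declared_type":
        key = lambda s: s.declared_type.value
    elif by == "region":
        key = lambda s: s.region.value
    elif by == "year":
        key = lambda s: s.year
    else:
        raise ValueError(f"unknown grouping {by!r}")

    groups: dict = {}
    for s in table:
        groups.setdefault(key(s), []).append(s)
    group_names = sorted(groups, key=str)

    rows = []
    for p in PARAMETERS:
        series = [[getattr(s, p) for s in groups[g]] for g in group_names]
        lettered = [g for g, v in zip(group_names, series) if len(v) >= 2]
        try:
            display = tukey_hsd([v for v in series if len(v) >= 2])
            letters = dict(zip(lettered, display.letters))
        except ValueError:
            letters = {}
        for g, values in zip(group_names, series):
            d = describe(values)
            honey_type = HoneyType(g) if by in ("final_type", "declared_type") else None
            rows.append(
                {
                    "parameter": p,
                    "group": g,
                    "N": d.n,
                    "mean": round(d.mean, 2),
                    "sd": round(d.sd, 2),
                    "ci_low": round(d.ci_low, 2),
                    "ci_high": round(d.ci_high, 2),
                    "var": round(d.var, 2),
                    "min": round(d.min, 3),
                    "max": round(d.max, 3),
                    "q25": round(d.q25, 2),
                    "median": round(d.median, 2),
                    "q75": round(d.q75, 2),
                    "letter": letters.get(g, ""),
                    "min_flag": _extreme_flag(p, d.min, "min", policy, honey_type),
                    "max_flag": _extreme_flag(p, d.max, "max", policy, honey_type),
                }
            )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_md is not None:
        md = df.copy()
        md["min"] = [f"**{v}**" if f else str(v) for v, f in zip(md["min"], md["min_flag"])]
        md["max"] = [f"**{v}**" if f else str(v) for v, f in zip(md["max"], md["max_flag"])]
        md = md.drop(columns=["min_flag", "max_flag"])
        header = "| " + " | ".join(md.columns) + " |"
        sep = "| " + " | ".join("---" for _ in md.columns) + " |"
        body = ["| " + " | ".join(str(v) for v in row) + " |" for row in md.itertuples(index=False)]
        Path(out_md).write_text("\n".join([header, sep, *body]) + "\n", encoding="utf-8")
    return df
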