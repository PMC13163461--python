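"""End-to-end pipeline: simulate -> parse -> score -> evaluate.

The pipeline mirrors a report-processing study: reports are "uploaded"
(generated synthetically or read from JSONL), parsed into key metrics,
scored to a BioAGE, filtered for plausibility, and the included patients
are evaluated for MACE discrimination.  Excluded records are never
dropped silently — every patient stays in the per-patient table with its
exclusion reason, and the run manifest's accounting identity

    included = uploaded - parse failures - implausible scores

holds exactly on every run.  Two runs with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioage_scoring import ScoringConfig, compose_bioage
from .errors import ConfigurationError, DegenerateStatisticsError, InputError
from .outcome_eval import EvalSummary, binary_labels, evaluate_cohort
from .synthetic_cohort import (
    CohortConfig,
    PatientRecord,
    build_cohort,
    read_cohort_jsonl,
)
from .report_parsing import parse_report

__all__ = [
    "EvalConfig",
    "RunConfig",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "write_outputs",
    "read_patient_table",
    "PATIENT_TABLE_COLUMNS",
]

PARSE_FAILURE_REASONS = (
    "missing_cac",
    "missing_cadrads",
    "ambiguous_phrasing",
    "missing_function",
    "malformed_number",
)

#: Fixed column order of the per-patient CSV.
PATIENT_TABLE_COLUMNS = [
    "patient_id", "chrono_age", "sex", "report_locale", "followup_years",
    "mace_event", "mace_event_time", "mace_label", "injected_failure",
    "parse_outcome", "parse_failure_reason",
    "cac_au", "cadrads", "vessel_over50", "proximal_lad_over70",
    "soft_plaque_rca_cx_only", "hrp_present", "lvef_percent", "edv_ml",
    "esv_ml", "extracoronary_findings",
    "base_years", "inc_cadrads", "inc_multivessel", "inc_proximal_lad",
    "inc_soft_plaque_rca_cx", "inc_impaired_function", "inc_extracoronary",
    "total_years", "display_years", "deviation_years", "plausible",
    "included", "exclusion_reason",
]

_LEDGER_COLUMNS = {
    "multivessel": "inc_multivessel",
    "proximal_lad": "inc_proximal_lad",
    "soft_plaque_rca_cx": "inc_soft_plaque_rca_cx",
    "impaired_function": "inc_impaired_function",
    "extracoronary": "inc_extracoronary",
}


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation options: cumulative batch sizes for the consistency
    table, the CI/p method, and batch semantics."""

    batch_sizes: Optional[tuple] = None
    ci_method: str = "delong"  # or "mannwhitney_exact"
    cumulative_batches: bool = True

    def validate(self) -> "EvalConfig":
        if self.ci_method not in ("delong", "mannwhitney_exact"):
            raise ConfigurationError(f"unknown ci_method: {self.ci_method!r}")
        return self


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration (cohort + scoring + evaluation)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: Optional[int] = None  # overrides cohort.seed when set
    input_jsonl: Optional[str] = None  # parse an existing cohort instead

    def resolved_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        return dataclasses.replace(self.cohort, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.resolved_cohort()),
            "scoring": dataclasses.asdict(self.scoring),
            "eval": dataclasses.asdict(self.eval),
            "input_jsonl": self.input_jsonl,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, section):
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown {klass.__name__} fields: {sorted(unknown)}"
                )
            for key in ("cadrads_probs", "cac_zero_prob_by_cadrads",
                        "hrp_category_weights", "event_type_probs",
                        "batch_sizes"):
                if key in section and section[key] is not None:
                    section[key] = tuple(
                        tuple(v) if isinstance(v, list) else v
                        for v in section[key]
                    )
            if "cac_lognormal_params" in section:
                section["cac_lognormal_params"] = tuple(
                    tuple(p) for p in section["cac_lognormal_params"]
                )
            return klass(**section)

        return cls(
            cohort=build(CohortConfig, dict(d.get("cohort", {}))),
            scoring=build(ScoringConfig, dict(d.get("scoring", {}))),
            eval=build(EvalConfig, dict(d.get("eval", {}))),
            seed=d.get("seed"),
            input_jsonl=d.get("input_jsonl"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Stage-count accounting for one pipeline run.

    Invariant: ``n_included = n_uploaded - n_parse_failures -
    n_implausible`` and ``success_rate = n_included / n_uploaded``.
    """

    n_uploaded: int
    parse_failures_by_reason: dict
    n_parse_failures: int
    implausible_by_reason: dict
    n_implausible: int
    n_included: int
    success_rate: float
    seed: Optional[int]
    config_hash: str
    version: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    summary: Optional[EvalSummary]
    manifest: RunManifest


def _score_row(record: PatientRecord, scoring: ScoringConfig) -> dict:
    row = {
        "patient_id": record.patient_id,
        "chrono_age": record.chrono_age,
        "sex": record.sex,
        "report_locale": record.report_locale,
        "followup_years": record.followup_time,
        "mace_event": record.mace_event,
        "mace_event_time": record.mace_event_time,
        "injected_failure": record.injected_failure or "",
    }
    result = parse_report(record.report_text, locale=record.report_locale)
    row["parse_outcome"] = result.outcome
    row["parse_failure_reason"] = result.failure_reason or ""
    if not result.parsed:
        row.update(
            {c: np.nan for c in PATIENT_TABLE_COLUMNS
             if c.startswith(("cac_", "inc_", "base_", "total_", "display_",
                              "deviation_", "lvef_", "edv_", "esv_"))}
        )
        row.update(
            {
                "cadrads": "",
                "vessel_over50": "",
                "extracoronary_findings": "",
                "proximal_lad_over70": False,
                "soft_plaque_rca_cx_only": False,
                "hrp_present": False,
                "plausible": False,
            }
        )
        row["included"] = False
        row["exclusion_reason"] = f"parse:{result.failure_reason}"
        return row
    m = result.metrics
    est = compose_bioage(m, record.chrono_age, scoring)
    row.update(
        {
            "cac_au": m.cac_au,
            "cadrads": m.cadrads,
            "vessel_over50": ",".join(sorted(m.vessel_over50)),
            "proximal_lad_over70": m.proximal_lad_over70,
            "soft_plaque_rca_cx_only": m.soft_plaque_rca_cx_only,
            "hrp_present": m.hrp_present,
            "lvef_percent": m.lvef_percent,
            "edv_ml": m.edv_ml,
            "esv_ml": m.esv_ml,
            "extracoronary_findings": ",".join(sorted(m.extracoronary_findings)),
            "base_years": est.base_years,
            "total_years": est.total_years,
            "display_years": est.display_years,
            "deviation_years": est.deviation_years,
            "plausible": est.plausible,
        }
    )
    for col in _LEDGER_COLUMNS.values():
        row[col] = 0.0
    row["inc_cadrads"] = 0.0
    for rule, years in est.increment_ledger:
        if rule.startswith("cadrads_"):
            row["inc_cadrads"] = years
        else:
            row[_LEDGER_COLUMNS[rule]] = years
    if est.plausible:
        row["included"] = True
        row["exclusion_reason"] = ""
    else:
        row["included"] = False
        row["exclusion_reason"] = f"score:{est.failure_reason}"
    return row


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and return the per-patient table, the
    evaluation summary on included patients, and the run manifest.

    Raises :class:`DegenerateStatisticsError` naming the dominant
    exclusion reason when no record survives the filters.
    """
    cohort_cfg = config.resolved_cohort().validate()
    scoring = config.scoring.validate()
    eval_cfg = config.eval.validate()

    if config.input_jsonl is not None:
        records = read_cohort_jsonl(config.input_jsonl)
        if not records:
            raise InputError(f"no records in {config.input_jsonl}")
    else:
        records = build_cohort(cohort_cfg, scoring)

    labels = binary_labels(records)
    rows = []
    for rec, label in zip(records, labels):
        row = _score_row(rec, scoring)
        row["mace_label"] = int(label)
        rows.append(row)
    table = pd.DataFrame(rows, columns=PATIENT_TABLE_COLUMNS)

    n = len(table)
    parse_failed = table["parse_outcome"] == "failed"
    by_reason = {
        r: int((table.loc[parse_failed, "parse_failure_reason"] == r).sum())
        for r in PARSE_FAILURE_REASONS
    }
    implausible = table["exclusion_reason"].str.startswith("score:")
    imp_by_reason = {
        r: int(
            (table.loc[implausible, "exclusion_reason"] == f"score:{r}").sum()
        )
        for r in ("implausible_low", "implausible_high")
    }
    included = table["included"].astype(bool)
    manifest = RunManifest(
        n_uploaded=n,
        parse_failures_by_reason=by_reason,
        n_parse_failures=int(parse_failed.sum()),
        implausible_by_reason=imp_by_reason,
        n_implausible=int(implausible.sum()),
        n_included=int(included.sum()),
        success_rate=float(included.sum() / n),
        seed=cohort_cfg.seed,
        config_hash=config.config_hash(),
        version=__version__,
    )
    assert manifest.n_included == manifest.n_uploaded - manifest.n_parse_failures - manifest.n_implausible

    if manifest.n_included == 0:
        reasons = dict(by_reason)
        reasons.update(imp_by_reason)
        dominant = max(reasons, key=reasons.get)
        raise DegenerateStatisticsError(
            f"no records included; dominant exclusion reason: {dominant}"
        )

    inc = table[included]
    batch_sizes = eval_cfg.batch_sizes
    if batch_sizes is not None:
        # batches index into the *included* set; exclusions shrink the
        # cohort, so cap sizes at the included count (dropping duplicates)
        capped = [min(int(k), len(inc)) for k in batch_sizes]
        batch_sizes = tuple(dict.fromkeys(capped))
    try:
        summary = evaluate_cohort(
            inc["total_years"].to_numpy(float),
            inc["chrono_age"].to_numpy(float),
            inc["mace_label"].to_numpy(int),
            batch_sizes=batch_sizes,
            method=eval_cfg.ci_method,
        )
    except DegenerateStatisticsError:
        summary = None  # too few events to evaluate; table/manifest still valid
    return PipelineResult(table=table, summary=summary, manifest=manifest)


def write_outputs(result: PipelineResult, out_dir) -> dict:
    """Write patients.csv, summary.json, manifest.json and run.log under
    *out_dir*; returns the path map.  Output bytes depend only on the
    config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
        "log": out / "run.log",
    }
    result.table.to_csv(paths["patients"], index=False)
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(
            result.summary.to_dict() if result.summary is not None else None,
            fh, indent=2, sort_keys=True,
        )
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(result.manifest.to_dict(), fh, indent=2, sort_keys=True)
    m = result.manifest
    lines = [
        f"cardioage {m.version} run (config {m.config_hash}, seed {m.seed})",
        f"uploaded reports:      {m.n_uploaded}",
        f"parse failures:        {m.n_parse_failures} {m.parse_failures_by_reason}",
        f"implausible estimates: {m.n_implausible} {m.implausible_by_reason}",
        f"included:              {m.n_included} (success rate {m.success_rate:.3f})",
    ]
    if result.summary is not None:
        s = result.summary
        lines += [
            f"MACE events:           {s.n_events}/{s.n_included} ({s.event_rate:.3f})",
            f"AUC BioAGE:            {s.auc_bioage:.3f} (95% CI {s.ci95_bioage[0]:.3f}-{s.ci95_bioage[1]:.3f}, p={s.p_bioage:.3g})",
            f"AUC chronological age: {s.auc_chrono:.3f} (95% CI {s.ci95_chrono[0]:.3f}-{s.ci95_chrono[1]:.3f}, p={s.p_chrono:.3g})",
            f"|deviation| mean:      {s.deviation.mean:.2f} (median {s.deviation.median:.2f}, IQR {s.deviation.iqr:.2f})",
        ]
    paths["log"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}


def read_patient_table(path) -> pd.DataFrame:
    """Round-trip reader for patients.csv (string columns kept as
    strings, empty cells as '')."""
    df = pd.read_csv(
        path,
        dtype={c: str for c in (
            "patient_id", "sex", "report_locale", "mace_event", "cadrads",
            "vessel_over50", "extracoronary_findings", "injected_failure",
            "parse_outcome", "parse_failure_reason", "exclusion_reason",
        )},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    for c in ("vessel_over50", "extracoronary_findings", "injected_failure",
              "parse_failure_reason", "exclusion_reason", "cadrads"):
        df[c] = df[c].fillna("")
    return df
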