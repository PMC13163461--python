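"""MACE discrimination and deviation statistics.

Discrimination of the binary MACE endpoint by BioAGE versus chronological
age is summarized by the c-statistic (area under the ROC curve) with the
Mann-Whitney estimator — over all (event, non-event) pairs a higher
event score counts 1 and a tie 0.5 — which equals the trapezoidal ROC
area.  Confidence intervals and the two-sided test against AUC = 0.5 use
the DeLong structural-components variance (a Mann-Whitney-exact p-value
is available as an alternative).  The endpoint is binary on censored
follow-up; no time-dependent ROC is attempted.

Deviation statistics summarize |BioAGE - chronological age| (mean, SD,
median, IQR) together with the signed split (fraction with BioAGE above,
below, equal).  The batch-consistency table re-runs the ROC analysis on
cumulative prefixes of the cohort, emulating analysis batches that grow
as reports accrue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateStatisticsError
from .synthetic_cohort import PatientRecord

__all__ = [
    "binary_labels",
    "auc",
    "auc_ci_and_test",
    "deviation_stats",
    "batch_consistency",
    "evaluate_cohort",
    "compare_groups",
    "DeviationStats",
    "EvalSummary",
]

_Z975 = 1.959963984540054


def binary_labels(records: Sequence[PatientRecord]) -> np.ndarray:
    """Per-patient 0/1 MACE labels under right censoring: 1 iff an event
    occurred within the follow-up window.  Any event type counts,
    including non-cardiac death."""
    out = np.zeros(len(records), dtype=int)
    for i, r in enumerate(records):
        if r.mace_event != "none" and r.mace_event_time is not None:
            if 0 < r.mace_event_time <= r.followup_time:
                out[i] = 1
    return out


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return s, y


def auc(scores, labels) -> float:
    """Mann-Whitney c-statistic: P(score_event > score_nonevent) with
    ties counted 0.5; identical to the trapezoidal ROC area.

    Raises :class:`DegenerateStatisticsError` when a class is absent.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatisticsError("AUC undefined: only one class present")
    ranks = stats.rankdata(s)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance) via midrank placements (Sun & Xu)."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n  # placements of events
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    a = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def auc_ci_and_test(
    scores, labels, method: str = "delong"
) -> tuple[float, tuple[float, float], float]:
    """``(auc, (ci_low, ci_high), p)`` — Wald 95% CI from the DeLong
    variance truncated to [0, 1] and a two-sided test of AUC = 0.5.

    ``method="mannwhitney_exact"`` replaces the p-value by the exact
    Mann-Whitney U test (CI stays DeLong).  Requires at least two
    observations per class.
    """
    s, y = _check_scores_labels(scores, labels)
    m, n = int(y.sum()), int((1 - y).sum())
    if m < 2 or n < 2:
        raise DegenerateStatisticsError(
            f"need >= 2 observations per class, got {m} events / {n} non-events"
        )
    a, var = _delong(s, y)
    se = np.sqrt(var)
    ci = (max(0.0, a - _Z975 * se), min(1.0, a + _Z975 * se))
    if method == "delong":
        if se == 0.0:
            p = 1.0 if a == 0.5 else 0.0
        else:
            p = float(2.0 * special.ndtr(-abs(a - 0.5) / se))
    elif method == "mannwhitney_exact":
        p = float(
            stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").pvalue
        )
    else:
        raise ValueError(f"unknown method: {method!r}")
    return a, ci, p


@dataclass(frozen=True)
class DeviationStats:
    """Summary of intra-individual BioAGE-vs-chronological deviations.

    ``mean/sd/median/iqr`` describe the absolute deviation |bio - chrono|
    (SD with n-1 denominator, quantiles by linear interpolation,
    IQR = Q3 - Q1); the fractions give the signed split.
    """

    mean: float
    sd: float
    median: float
    iqr: float
    fraction_higher: float
    fraction_lower: float
    fraction_equal: float
    mean_signed: float


def deviation_stats(bioages, chrono_ages) -> DeviationStats:
    """Deviation summary between paired BioAGE and chronological age."""
    bio = np.asarray(bioages, dtype=float)
    chrono = np.asarray(chrono_ages, dtype=float)
    if bio.shape != chrono.shape or bio.ndim != 1 or len(bio) == 0:
        raise ValueError("bioages and chrono_ages must be equal-length 1-D arrays")
    signed = bio - chrono
    dev = np.abs(signed)
    q1, q3 = np.percentile(dev, [25, 75])  # linear interpolation
    return DeviationStats(
        mean=float(dev.mean()),
        sd=float(dev.std(ddof=1)) if len(dev) > 1 else 0.0,
        median=float(np.median(dev)),
        iqr=float(q3 - q1),
        fraction_higher=float((signed > 0).mean()),
        fraction_lower=float((signed < 0).mean()),
        fraction_equal=float((signed == 0).mean()),
        mean_signed=float(signed.mean()),
    )


def batch_consistency(
    bioages,
    chrono_ages,
    labels,
    batch_sizes: Sequence[int],
    cumulative: bool = True,
    method: str = "delong",
) -> pd.DataFrame:
    """ROC consistency table over analysis batches.

    With ``cumulative=True`` (default) batch k covers the first
    ``batch_sizes[k]`` patients in cohort order, so event counts are
    non-decreasing and the final row reproduces the full-cohort analysis;
    with ``cumulative=False`` the sizes delimit disjoint consecutive
    groups.  A batch with fewer than two observations in either class is
    flagged ``undefined`` (NaN statistics) instead of erroring the table.
    """
    bio, y = _check_scores_labels(bioages, labels)
    chrono, _ = _check_scores_labels(chrono_ages, labels)
    rows = []
    start = 0
    for k in batch_sizes:
        if cumulative:
            lo, hi = 0, int(k)
        else:
            lo, hi = start, start + int(k)
            start = hi
        if hi > len(y):
            raise ValueError(f"batch size {k} exceeds cohort size {len(y)}")
        sl = slice(lo, hi)
        row = {"n": hi - lo, "n_events": int(y[sl].sum())}
        try:
            for name, scores in (("bioage", bio[sl]), ("chrono", chrono[sl])):
                a, ci, p = auc_ci_and_test(scores, y[sl], method=method)
                row[f"auc_{name}"] = a
                row[f"ci_low_{name}"] = ci[0]
                row[f"ci_high_{name}"] = ci[1]
                row[f"p_{name}"] = p
            row["undefined"] = False
        except DegenerateStatisticsError:
            for name in ("bioage", "chrono"):
                row[f"auc_{name}"] = np.nan
                row[f"ci_low_{name}"] = np.nan
                row[f"ci_high_{name}"] = np.nan
                row[f"p_{name}"] = np.nan
            row["undefined"] = True
        rows.append(row)
    cols = [
        "n", "auc_bioage", "ci_low_bioage", "ci_high_bioage", "p_bioage",
        "auc_chrono", "ci_low_chrono", "ci_high_chrono", "p_chrono",
        "n_events", "undefined",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class EvalSummary:
    """Full-cohort evaluation: AUCs with CIs and p-values against 0.5,
    deviation statistics and (optionally) the batch-consistency table."""

    n_included: int
    n_events: int
    event_rate: float
    auc_bioage: float
    ci95_bioage: tuple
    p_bioage: float
    auc_chrono: float
    ci95_chrono: tuple
    p_chrono: float
    deviation: DeviationStats
    batch_table: Optional[pd.DataFrame] = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {
            "n_included": self.n_included,
            "n_events": self.n_events,
            "event_rate": self.event_rate,
            "auc_bioage": self.auc_bioage,
            "ci95_bioage": list(self.ci95_bioage),
            "p_bioage": self.p_bioage,
            "auc_chrono": self.auc_chrono,
            "ci95_chrono": list(self.ci95_chrono),
            "p_chrono": self.p_chrono,
            "deviation": vars(self.deviation).copy(),
        }
        if self.batch_table is not None:
            d["batch_table"] = self.batch_table.to_dict(orient="records")
        return d


def evaluate_cohort(
    bioages,
    chrono_ages,
    labels,
    batch_sizes: Optional[Sequence[int]] = None,
    method: str = "delong",
) -> EvalSummary:
    """Evaluate MACE discrimination of BioAGE vs chronological age on the
    included patients; see module docstring for the statistics used."""
    bio, y = _check_scores_labels(bioages, labels)
    chrono, _ = _check_scores_labels(chrono_ages, labels)
    a_bio, ci_bio, p_bio = auc_ci_and_test(bio, y, method=method)
    a_chr, ci_chr, p_chr = auc_ci_and_test(chrono, y, method=method)
    table = (
        batch_consistency(bio, chrono, y, batch_sizes, method=method)
        if batch_sizes is not None
        else None
    )
    return EvalSummary(
        n_included=len(y),
        n_events=int(y.sum()),
        event_rate=float(y.mean()),
        auc_bioage=a_bio,
        ci95_bioage=ci_bio,
        p_bioage=p_bio,
        auc_chrono=a_chr,
        ci95_chrono=ci_chr,
        p_chrono=p_chr,
        deviation=deviation_stats(bio, chrono),
        batch_table=table,
    )


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two groups (e.g. deviation by sex);
    returns ``(U, p two-sided)``."""
    res = stats.mannwhitneyu(
        np.asarray(values_a, float), np.asarray(values_b, float),
        alternative="two-sided",
    )
    return float(res.statistic), float(res.pvalue)
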