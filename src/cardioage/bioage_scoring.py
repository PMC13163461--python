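"""Heuristic biological cardiovascular age (BioAGE) from CTA report metrics.

The score starts from a calcium-based base age

    base = 39 + 0.1 * CAC  (years, CAC in Agatston units)

and stacks additive increments for stenosis severity and high-risk
anatomy (CAD-RADS 2 +5, 3 +10, 4a +15, 4b/5 +20; three-vessel disease
+15; proximal LAD >=70% +10; RCA/CX soft plaque only +5), impaired LV
function (LVEF < 50% or elevated EDV/ESV, +10 once), and extracoronary
vascular-aging findings (+5 once).  Every applied rule is recorded in an
itemized ledger so ``total_years`` always equals the base plus the ledger
sum exactly.

Totals outside a plausibility window (default 25–105 years) are flagged
as failures (``implausible_low`` / ``implausible_high``) and are meant to
be excluded from downstream evaluation, mirroring how implausible
estimates (e.g. 123 or 17 years) are discarded in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigurationError
from .report_parsing import VESSELS, KeyMetrics, cadrads_rank

__all__ = [
    "ScoringConfig",
    "BioAgeEstimate",
    "cac_component",
    "stenosis_increment",
    "function_increment",
    "extracoronary_increment",
    "compose_bioage",
    "plausibility_check",
]


@dataclass(frozen=True)
class ScoringConfig:
    """All tunable constants of the BioAGE heuristic, in years unless noted.

    Defaults follow the published rule list; values the rule list leaves
    open (EDV/ESV thresholds, the extracoronary increment, the CAD-RADS 5
    increment, plausibility bounds) are package choices and configurable.
    """

    cac_base_intercept: float = 39.0
    cac_slope: float = 0.1  # years per Agatston unit
    increment_cadrads2: float = 5.0
    increment_cadrads3: float = 10.0
    increment_cadrads4a: float = 15.0
    increment_cadrads4b: float = 20.0
    increment_cadrads5: float = 20.0
    increment_multivessel: float = 15.0
    increment_proximal_lad: float = 10.0
    increment_soft_plaque_rca_cx: float = 5.0
    increment_low_lvef_or_elevated_volumes: float = 10.0
    lvef_threshold: float = 50.0  # percent, strict <
    edv_elevated_threshold: float = 200.0  # mL, strict >
    esv_elevated_threshold: float = 90.0  # mL, strict >
    increment_extracoronary: float = 5.0
    plausible_min: float = 25.0
    plausible_max: float = 105.0
    rounding: str = "nearest_integer"  # or "none"

    def validate(self) -> "ScoringConfig":
        for name in (
            "increment_cadrads2", "increment_cadrads3", "increment_cadrads4a",
            "increment_cadrads4b", "increment_cadrads5", "increment_multivessel",
            "increment_proximal_lad", "increment_soft_plaque_rca_cx",
            "increment_low_lvef_or_elevated_volumes", "increment_extracoronary",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.cac_slope >= 0:
            raise ConfigurationError("cac_slope must be >= 0")
        if not self.plausible_min < self.plausible_max:
            raise ConfigurationError("plausible_min must be < plausible_max")
        if self.rounding not in ("none", "nearest_integer"):
            raise ConfigurationError(f"unknown rounding mode: {self.rounding!r}")
        return self

    def category_increment(self, cadrads: str) -> float:
        """Stenosis-severity increment for one CAD-RADS category."""
        return {
            "0": 0.0,
            "1": 0.0,
            "2": self.increment_cadrads2,
            "3": self.increment_cadrads3,
            "4a": self.increment_cadrads4a,
            "4b": self.increment_cadrads4b,
            "5": self.increment_cadrads5,
        }[cadrads]


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class BioAgeEstimate:
    """Itemized BioAGE result for one patient.

    ``total_years = base_years + sum(years for _, years in increment_ledger)``
    holds exactly; ``display_years`` applies the configured rounding;
    ``deviation_years`` is BioAGE minus chronological age (signed) when a
    chronological age was supplied.
    """

    base_years: float
    increment_ledger: tuple = field(default_factory=tuple)
    total_years: float = 0.0
    display_years: float = 0.0
    deviation_years: Optional[float] = None
    plausible: bool = True
    failure_reason: Optional[str] = None  # implausible_low | implausible_high


def cac_component(cac_au: float, config: ScoringConfig = DEFAULT_SCORING) -> float:
    """Calcium-based base age: ``intercept + slope * CAC`` years."""
    if not math.isfinite(cac_au) or cac_au < 0:
        raise ValueError(f"cac_au must be a finite value >= 0, got {cac_au}")
    return config.cac_base_intercept + config.cac_slope * cac_au


def stenosis_increment(
    metrics: KeyMetrics, config: ScoringConfig = DEFAULT_SCORING
) -> tuple[float, tuple]:
    """Stenosis-severity and high-risk-anatomy increments (additively
    stacked), with the ledger of applied rules."""
    ledger: list[tuple[str, float]] = []
    cat = config.category_increment(metrics.cadrads)
    if cat:
        ledger.append((f"cadrads_{metrics.cadrads}", cat))
    if set(VESSELS) <= metrics.vessel_over50:
        ledger.append(("multivessel", config.increment_multivessel))
    if metrics.proximal_lad_over70:
        ledger.append(("proximal_lad", config.increment_proximal_lad))
    if metrics.soft_plaque_rca_cx_only:
        ledger.append(("soft_plaque_rca_cx", config.increment_soft_plaque_rca_cx))
    return sum(y for _, y in ledger), tuple(ledger)


def function_increment(
    metrics: KeyMetrics, config: ScoringConfig = DEFAULT_SCORING
) -> tuple[float, tuple]:
    """+10 years once when LVEF < threshold (strict) or EDV/ESV elevated;
    absent volumes never trigger."""
    impaired = metrics.lvef_percent < config.lvef_threshold
    if metrics.edv_ml is not None and metrics.edv_ml > config.edv_elevated_threshold:
        impaired = True
    if metrics.esv_ml is not None and metrics.esv_ml > config.esv_elevated_threshold:
        impaired = True
    if impaired:
        inc = config.increment_low_lvef_or_elevated_volumes
        return inc, (("impaired_function", inc),)
    return 0.0, ()


def extracoronary_increment(
    metrics: KeyMetrics, config: ScoringConfig = DEFAULT_SCORING
) -> tuple[float, tuple]:
    """One increment when any coded extracoronary finding is present,
    regardless of how many."""
    if metrics.extracoronary_findings:
        inc = config.increment_extracoronary
        return inc, (("extracoronary", inc),)
    return 0.0, ()


def plausibility_check(
    total_years: float, config: ScoringConfig = DEFAULT_SCORING
) -> tuple[bool, Optional[str]]:
    """``(plausible, reason)`` — reason is ``implausible_low`` /
    ``implausible_high`` outside ``[plausible_min, plausible_max]``."""
    if total_years < config.plausible_min:
        return False, "implausible_low"
    if total_years > config.plausible_max:
        return False, "implausible_high"
    return True, None


def _round_display(total: float, config: ScoringConfig) -> float:
    if config.rounding == "nearest_integer":
        # round half away from zero, the convention of printed ages
        return float(math.floor(total + 0.5))
    return total


def compose_bioage(
    metrics: KeyMetrics,
    chrono_age: Optional[float] = None,
    config: ScoringConfig = DEFAULT_SCORING,
) -> BioAgeEstimate:
    """Compose the full BioAGE estimate for one set of parsed metrics.

    Parameters
    ----------
    metrics
        Parsed report metrics (all three key metrics present by type).
    chrono_age
        Chronological age in years; enables ``deviation_years``.
    config
        Scoring constants.

    Returns
    -------
    BioAgeEstimate
        With the exact ledger identity
        ``total_years == base_years + sum(ledger)`` and the plausibility
        verdict evaluated on the continuous total.
    """
    config.validate()
    base = cac_component(metrics.cac_au, config)
    _, sten_ledger = stenosis_increment(metrics, config)
    _, fn_ledger = function_increment(metrics, config)
    _, ex_ledger = extracoronary_increment(metrics, config)
    ledger = sten_ledger + fn_ledger + ex_ledger
    total = base + sum(y for _, y in ledger)
    plausible, reason = plausibility_check(total, config)
    return BioAgeEstimate(
        base_years=base,
        increment_ledger=ledger,
        total_years=total,
        display_years=_round_display(total, config),
        deviation_years=None if chrono_age is None else total - chrono_age,
        plausible=plausible,
        failure_reason=reason,
    )
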