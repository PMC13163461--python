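"""Tests for the synthetic cohort generator, outcome simulator and
parse-failure injection."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import special, stats

from cardioage import (
    CohortConfig,
    auc,
    binary_labels,
    build_cohort,
    calibrate_mace_intercept,
    generate_cohort,
    inject_failures,
    parse_report,
    read_cohort_jsonl,
    simulate_mace,
    write_cohort_jsonl,
)
from cardioage.errors import ConfigurationError
from cardioage.synthetic_cohort import EXPECTED_FAILURE_REASON


def _fractions(values, universe):
    n = len(values)
    return {u: sum(v == u for v in values) / n for u in universe}


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = CohortConfig(n_patients=200, seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert [(r.patient_id, r.report_text, r.true_bioage) for r in a] == [
            (r.patient_id, r.report_text, r.true_bioage) for r in b
        ]

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="female_fraction"):
            generate_cohort(CohortConfig(female_fraction=1.5))
        with pytest.raises(ConfigurationError, match="cadrads_probs"):
            generate_cohort(CohortConfig(cadrads_probs=(1.0,) * 7))

    def test_record_invariants(self):
        cfg = CohortConfig(n_patients=500, seed=9)
        for r in build_cohort(cfg):
            assert cfg.chrono_age_min <= r.chrono_age <= cfg.chrono_age_max
            assert cfg.followup_min <= r.followup_time <= cfg.followup_max
            if r.mace_event == "none":
                assert r.mace_event_time is None
            else:
                assert 0 < r.mace_event_time <= r.followup_time
            r.true_metrics.validate()

    def test_sex_marginal(self, cohort_50k):
        frac = np.mean([r.sex == "female" for r in cohort_50k])
        assert frac == pytest.approx(0.396, abs=0.01)

    def test_cadrads_marginals(self, cohort_50k):
        cfg = CohortConfig()
        fracs = _fractions(
            [r.true_metrics.cadrads for r in cohort_50k],
            ["0", "1", "2", "3", "4a", "4b", "5"],
        )
        assert fracs["0"] == pytest.approx(0.202, abs=0.01)
        n = len(cohort_50k)
        for cat, p in zip(["0", "1", "2", "3", "4a", "4b", "5"], cfg.cadrads_probs):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(fracs[cat] - p) < 3 * se, cat

    def test_hrp_marginal(self, cohort_50k):
        p = CohortConfig().hrp_prevalence
        frac = np.mean([r.true_metrics.hrp_present for r in cohort_50k])
        se = math.sqrt(p * (1 - p) / len(cohort_50k))
        assert abs(frac - p) < 3 * se

    def test_lvef_mean_matches_truncated_normal(self, cohort_50k):
        cfg = CohortConfig()
        a = (cfg.lvef_min - cfg.lvef_mean) / cfg.lvef_sd
        b = (cfg.lvef_max - cfg.lvef_mean) / cfg.lvef_sd
        expected = stats.truncnorm.mean(a, b, loc=cfg.lvef_mean, scale=cfg.lvef_sd)
        lvefs = np.array([r.true_metrics.lvef_percent for r in cohort_50k])
        se = lvefs.std() / math.sqrt(len(lvefs))
        # rounding to integer LVEF adds < 0.05 bias; allow it on top of 3 SE
        assert abs(lvefs.mean() - expected) < 3 * se + 0.05

    def test_severity_increases_with_age(self, cohort_50k):
        from cardioage.report_parsing import cadrads_rank

        ages = np.array([r.chrono_age for r in cohort_50k])
        sev = np.array([cadrads_rank(r.true_metrics.cadrads) for r in cohort_50k])
        assert np.corrcoef(ages, sev)[0, 1] > 0.15

    def test_cac_range_capped(self, cohort_50k):
        cacs = np.array([r.true_metrics.cac_au for r in cohort_50k])
        assert cacs.min() == 0.0
        assert cacs.max() <= CohortConfig().cac_max


class TestSimulateMace:
    def test_flat_model_matches_intercept_rate(self, cohort_50k):
        cfg = dataclasses.replace(
            CohortConfig(),
            n_patients=len(cohort_50k),
            mace_slope_per_bioage_year=0.0,
            mace_intercept=float(special.logit(0.087)),
        )
        labels = binary_labels(simulate_mace(cohort_50k, cfg))
        assert labels.mean() == pytest.approx(0.087, abs=0.005)

    def test_no_signal_gives_chance_auc(self, cohort_50k):
        cfg = dataclasses.replace(
            CohortConfig(),
            mace_slope_per_bioage_year=0.0,
            mace_intercept=float(special.logit(0.087)),
        )
        recs = simulate_mace(cohort_50k, cfg)
        bio = np.array([r.true_bioage for r in recs])
        assert auc(bio, binary_labels(recs)) == pytest.approx(0.5, abs=0.02)

    def test_auto_calibration_hits_target_rate(self, cohort_50k):
        cfg = dataclasses.replace(
            CohortConfig(), target_event_rate=0.10, mace_slope_per_bioage_year=0.06
        )
        bio = np.array([r.true_bioage for r in cohort_50k])
        a = calibrate_mace_intercept(bio, 0.06, 0.10)
        # oracle: the calibrated intercept solves the mean-probability equation
        assert np.mean(special.expit(a + 0.06 * bio)) == pytest.approx(0.10, abs=1e-9)
        labels = binary_labels(simulate_mace(cohort_50k, cfg))
        assert labels.mean() == pytest.approx(0.10, abs=0.005)

    def test_positive_slope_gives_signal_in_bioage(self):
        wins = 0
        for seed in range(30):
            cfg = CohortConfig(n_patients=346, seed=seed)
            recs = simulate_mace(generate_cohort(cfg), cfg)
            y = binary_labels(recs)
            if y.sum() == 0 or y.sum() == len(y):
                continue
            bio = np.array([r.true_bioage for r in recs])
            age = np.array([r.chrono_age for r in recs])
            a_bio, a_age = auc(bio, y), auc(age, y)
            wins += a_bio > max(0.5, a_age)
        assert wins >= 24  # bioage carries the discrimination signal

    def test_nonfinite_intercept_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(mace_intercept=float("nan")).validate()


class TestInjectFailures:
    def test_rate_zero_alters_nothing(self):
        cfg = CohortConfig(n_patients=100, seed=5, parse_failure_rate=0.0)
        recs = generate_cohort(cfg)
        out = inject_failures(recs, cfg)
        assert all(r.injected_failure is None for r in out)
        assert [r.report_text for r in out] == [r.report_text for r in recs]

    def test_altered_fraction_matches_rate(self, cohort_50k):
        cfg = dataclasses.replace(CohortConfig(), parse_failure_rate=0.104)
        out = inject_failures(cohort_50k, cfg)
        frac = np.mean([r.injected_failure is not None for r in out])
        assert frac == pytest.approx(0.104, abs=0.005)

    def test_each_mode_produces_its_failure_reason(self):
        cfg = CohortConfig(n_patients=400, seed=8, parse_failure_rate=0.5, locale_mix=0.5)
        out = inject_failures(generate_cohort(cfg), cfg)
        seen = set()
        for r in out:
            if r.injected_failure is None:
                continue
            res = parse_report(r.report_text, r.report_locale)
            assert not res.parsed
            assert res.failure_reason == EXPECTED_FAILURE_REASON[r.injected_failure]
            seen.add(r.injected_failure)
        assert seen == set(EXPECTED_FAILURE_REASON)  # all three modes exercised


class TestJsonlRoundTrip:
    def test_write_read(self, tmp_path):
        cfg = CohortConfig(n_patients=30, seed=3)
        recs = build_cohort(cfg)
        path = tmp_path / "cohort.jsonl"
        write_cohort_jsonl(recs, path)
        back = read_cohort_jsonl(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.patient_id, a.report_text, a.mace_event) == (
                b.patient_id, b.report_text, b.mace_event,
            )
            assert b.chrono_age == pytest.approx(a.chrono_age)
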