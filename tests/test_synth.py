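"""Synthetic cohort generator: determinism, marginal fidelity, copula recovery,
prevalence calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import sarcoscreen as sc
from sarcoscreen.synth import VARIABLES


def _columns(cohort, sex):
    return np.array([
        [r.age, r.height, r.asmi, r.grip, r.gait_speed, r.calf_circumference]
        for r in cohort if r.sex == sex
    ])


def test_same_seed_is_byte_identical(table1_config):
    a = sc.generate_cohort(table1_config)
    b = sc.generate_cohort(table1_config)
    assert a == b


def test_different_seed_differs(table1_config):
    other = dataclasses.replace(table1_config, seed=table1_config.seed + 1)
    assert sc.generate_cohort(table1_config) != sc.generate_cohort(other)


def test_male_count_within_binomial_band(table1_config):
    cohort = sc.generate_cohort(table1_config)
    n_male = sum(r.sex is sc.Sex.MALE for r in cohort)
    p = table1_config.male_fraction
    sd = np.sqrt(941 * p * (1 - p))
    assert abs(n_male - 941 * p) < 3 * sd


def test_generated_records_pass_validation(table1_config):
    for r in sc.generate_cohort(table1_config):
        assert r.validate() == []


def test_ages_respect_band_support(table1_config):
    ages = np.array([r.age for r in sc.generate_cohort(table1_config)])
    assert ages.min() >= 60.0 and ages.max() <= 92.0


def test_identity_correlation_yields_independence():
    cfg = dataclasses.replace(
        sc.default_config_from_table1(n_total=20_000, seed=3),
        correlation=np.eye(len(VARIABLES)),
    )
    cols = _columns(sc.generate_cohort(cfg), sc.Sex.MALE)
    r = np.corrcoef(cols[:, 3], cols[:, 5])[0, 1]  # grip vs calf circumference
    assert abs(r) < 0.02


def test_marginal_fidelity_three_se():
    """At n=50000 every per-sex sample mean sits within 3 SE of its target."""
    cfg = sc.default_config_from_table1(n_total=50_000, seed=11)
    cohort = sc.generate_cohort(cfg)
    for sex, marg in ((sc.Sex.MALE, cfg.male), (sc.Sex.FEMALE, cfg.female)):
        cols = _columns(cohort, sex)
        n = len(cols)
        for j, var in enumerate(VARIABLES[1:], start=1):
            mean, sd = marg.mean_sd(var)
            se = sd / np.sqrt(n)
            assert abs(cols[:, j].mean() - mean) < 3 * se, (sex, var)


def test_correlation_recovery():
    """Latent copula correlation re-estimated from ranks matches the input."""
    cfg = sc.default_config_from_table1(n_total=50_000, seed=11)
    cohort = sc.generate_cohort(cfg)
    for sex in (sc.Sex.MALE, sc.Sex.FEMALE):
        cols = _columns(cohort, sex)
        rho_s = stats.spearmanr(cols).statistic
        latent = 2 * np.sin(np.pi * rho_s / 6)
        assert np.max(np.abs(latent - np.asarray(cfg.correlation))) < 0.03


def test_age_band_proportions_match_config():
    cfg = sc.default_config_from_table1(n_total=50_000, seed=4)
    cohort = sc.generate_cohort(cfg)
    for sex, marg in ((sc.Sex.MALE, cfg.male), (sc.Sex.FEMALE, cfg.female)):
        ages = _columns(cohort, sex)[:, 0]
        n = len(ages)
        for p_target, (lo, hi) in zip(marg.age_band_probs,
                                      ((60, 65), (65, 70), (70, 80), (80, 92.01))):
            p_hat = np.mean((ages >= lo) & (ages < hi))
            se = np.sqrt(p_target * (1 - p_target) / n)
            assert abs(p_hat - p_target) < 4 * se, (sex, lo, hi)


def test_table1_defaults():
    cfg = sc.default_config_from_table1()
    assert cfg.male.grip == (35.66, 7.52)
    assert cfg.female.asmi == (6.36, 1.27)
    assert cfg.female.age_band_probs[1] == pytest.approx(130 / 479)
    assert cfg.male_fraction == pytest.approx(462 / 941)
    cfg.validate()  # invariants hold


def test_non_positive_definite_correlation_fatal(table1_config):
    bad = np.asarray(table1_config.correlation).copy()
    bad[0, 1] = bad[1, 0] = 0.999
    bad[0, 2] = bad[2, 0] = 0.999
    bad[1, 2] = bad[2, 1] = -0.999
    cfg = dataclasses.replace(table1_config, correlation=bad)
    with pytest.raises(ValueError, match="eigenvalue"):
        sc.generate_cohort(cfg)


class TestCalibration:
    def test_reaches_target(self, calibrated_config):
        cfg = dataclasses.replace(calibrated_config, n_total=50_000, seed=202)
        prev = sc.emergent_prevalence(cfg)
        assert prev == pytest.approx(0.1838, abs=0.01)

    def test_fixed_point_returns_config_unchanged(self, table1_config):
        current = sc.emergent_prevalence(
            dataclasses.replace(table1_config, n_total=50_000))
        out = sc.calibrate_prevalence(table1_config, current, tolerance=0.02)
        assert out == table1_config

    def test_infeasible_target_rejected(self, table1_config):
        with pytest.raises(ValueError):
            sc.calibrate_prevalence(table1_config, 0.0)

    def test_unreachable_target_raises_with_trace(self, table1_config):
        with pytest.raises(sc.CalibrationError) as exc:
            sc.calibrate_prevalence(table1_config, 0.999, tolerance=1e-4,
                                    n_calib=5_000)
        assert exc.value.trace  # search history preserved


def test_emergent_auc_plausibility_envelope(calibrated_config):
    """Ishii score vs emergent AWGS2019 status discriminates at AUC 0.75-0.90."""
    cfg = dataclasses.replace(calibrated_config, n_total=20_000, seed=303)
    cohort = sc.generate_cohort(cfg)
    status = sc.classify_cohort(cohort)
    for sex in (sc.Sex.MALE, sc.Sex.FEMALE):
        idx = [i for i, r in enumerate(cohort) if r.sex == sex]
        truth = np.array([status[i].sarcopenic for i in idx])
        scores = np.array([sc.score_record(cohort[i]) for i in idx])
        auc = sc.auc_mannwhitney(scores, truth)
        assert 0.75 <= auc <= 0.90, sex
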