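"""Synthetic cohort generator: determinism, calibration, recovery."""

import collections
import math

import numpy as np
import pytest

from astraqc import (
    CohortConfig,
    GroupSpec,
    IndicatorModel,
    calibrate_noise_sd,
    default_config,
    generate_cohort,
    generate_components,
    pearson_r,
)
from astraqc.study import REGION_STATS
from astraqc.sweetness import sweetness_table
from astraqc.synthetic import config_from_dict, config_to_dict, load_config, save_config


def single_group_config(n, seed, region="Sx", rho0=0.659, years=5, cultivation="PA"):
    st = REGION_STATS[region]
    return CohortConfig(
        groups=[
            GroupSpec(
                region=region, species="MG", cultivation=cultivation,
                growth_years=years, n=n, means=st.means, sds=st.sds,
            )
        ],
        indicator_models=[
            IndicatorModel("calycosin_glucoside", 0.079, -0.344, rho0),
            IndicatorModel("astragaloside_iv", 0.004, 0.926, 0.412),
            IndicatorModel("polysaccharides", 0.007, 0.090, 0.486),
            IndicatorModel("extracts", -0.003, 0.243, -0.183),
        ],
        seed=seed,
    )


# --- noise calibration -----------------------------------------------------


@pytest.mark.parametrize(
    "a,sigma_x,rho0,expected",
    [
        (0.5, 2.0, 1.0, 0.0),                 # perfect correlation: no noise
        (1.0, 1.0, 1 / math.sqrt(2), 1.0),    # algebraic identity
        (2.0, 3.0, 0.6, 8.0),                 # closed form
        (-2.0, 3.0, -0.6, 8.0),               # sign-symmetric
    ],
)
def test_calibrate_noise_sd_closed_form(a, sigma_x, rho0, expected):
    assert calibrate_noise_sd(a, sigma_x, rho0) == pytest.approx(expected, abs=1e-12)


def test_calibrate_noise_sd_rejects_bad_inputs():
    with pytest.raises(ValueError, match="sign"):
        calibrate_noise_sd(1.0, 1.0, -0.5)
    with pytest.raises(ValueError, match="rho0"):
        calibrate_noise_sd(1.0, 1.0, 0.0)


def test_calibration_hits_target_in_population(rng):
    """corr(X, aX + b + eps) with the calibrated noise equals rho0
    analytically; verify by a large Monte Carlo draw."""
    a, rho0 = 0.079, 0.659
    x = rng.normal(17, 2.2, 200_000)
    sd = calibrate_noise_sd(a, 2.2, rho0)
    y = a * x - 0.344 + rng.normal(0, sd, x.size)
    assert pearson_r(x, y) == pytest.approx(rho0, abs=0.01)


# --- component generation --------------------------------------------------


def test_same_seed_identical_cohorts():
    c1, p1 = generate_cohort(default_config(seed=11))
    c2, p2 = generate_cohort(default_config(seed=11))
    assert all(a == b for a, b in zip(c1, c2))
    assert all(a == b for a, b in zip(p1, p2))


def test_different_seeds_differ():
    c1, _ = generate_cohort(default_config(seed=11))
    c2, _ = generate_cohort(default_config(seed=12))
    assert any(a != b for a, b in zip(c1, c2))


def test_default_config_reproduces_study_structure():
    config = default_config()
    samples = generate_components(config)
    assert len(samples) == 48
    regions = collections.Counter(s.region for s in samples)
    years = collections.Counter(s.growth_years for s in samples)
    assert regions == {"Sx": 17, "Ssx": 7, "Gs": 10, "Nm": 8, "Hlj": 6}
    assert years == {5: 22, 2: 18, 7: 6, 1: 2}
    assert all(s.species == ("MJ" if s.region == "Hlj" else "MG") for s in samples)


def test_large_sample_means_within_clt_bound():
    """n = 5000 draws from the Shanxi parameters: sucrose sample mean
    within 3 standard errors of the configured mean (truncation bias
    negligible when the mean sits many SDs above zero)."""
    config = single_group_config(n=5000, seed=5)
    samples = generate_components(config)
    suc = np.array([s.contents["sucrose"] for s in samples])
    se = 2.3 / math.sqrt(5000)
    assert abs(suc.mean() - 17.5) < 3 * se


def test_rejection_sampling_truncates_at_zero():
    config = CohortConfig(
        groups=[
            GroupSpec(region="Nm", species="MG", cultivation="FA", growth_years=2,
                      n=400, means={"fructose": 0.1, "sucrose": 11.8},
                      sds={"fructose": 0.3, "sucrose": 0.8})
        ],
        indicator_models=[],
        seed=2,
    )
    samples = generate_components(config)
    assert all(s.contents["fructose"] >= 0 for s in samples)
    # heavy truncation shifts the mean upward for this near-zero component
    fru_ug = np.array([s.contents["fructose"] for s in samples]) * 1000
    assert fru_ug.mean() > 0.1


def test_impossible_truncation_errors():
    config = CohortConfig(
        groups=[
            GroupSpec(region="Sx", species="MG", cultivation="PA", growth_years=5,
                      n=1, means={"sucrose": -50.0}, sds={"sucrose": 0.001})
        ],
        indicator_models=[],
        seed=0,
    )
    with pytest.raises(RuntimeError, match="rejection"):
        generate_components(config)


def test_degenerate_zero_sd_with_negative_mean_errors():
    config = CohortConfig(
        groups=[
            GroupSpec(region="Sx", species="MG", cultivation="PA", growth_years=5,
                      n=1, means={"sucrose": -1.0}, sds={"sucrose": 0.0})
        ],
        indicator_models=[],
        seed=0,
    )
    with pytest.raises(ValueError, match="negative mean"):
        generate_components(config)


# --- indicator generation --------------------------------------------------


def test_zero_noise_limit_gives_perfect_correlation():
    config = single_group_config(n=30, seed=9, rho0=1.0)
    samples, panels = generate_cohort(config)
    s = [r.sweetness for r in sweetness_table(samples)]
    y = [p.calycosin_glucoside for p in panels]
    assert pearson_r(s, y) == pytest.approx(1.0, abs=1e-12)
    # with zero noise the indicator is a strictly increasing function of S
    assert np.array_equal(np.argsort(s), np.argsort(y))


def test_empirical_r_near_target_at_large_n():
    config = single_group_config(n=5000, seed=13, rho0=0.66)
    samples, panels = generate_cohort(config)
    s = [r.sweetness for r in sweetness_table(samples)]
    y = [p.calycosin_glucoside for p in panels]
    assert pearson_r(s, y) == pytest.approx(0.66, abs=0.03)


def test_uncoupled_indicator_is_null():
    st = REGION_STATS["Sx"]
    config = CohortConfig(
        groups=[GroupSpec(region="Sx", species="MG", cultivation="PA",
                          growth_years=5, n=5000, means=st.means, sds=st.sds)],
        indicator_models=[
            IndicatorModel("extracts", slope=0.0, intercept=0.2,
                           rho0=None, noise_sd=0.02)
        ],
        seed=21,
    )
    samples, panels = generate_cohort(config)
    s = [r.sweetness for r in sweetness_table(samples)]
    y = [p.extracts for p in panels]
    assert abs(pearson_r(s, y)) < 0.1


def test_indicator_model_validation():
    with pytest.raises(ValueError, match="sign"):
        IndicatorModel("extracts", slope=0.003, intercept=0.2, rho0=-0.2)
    with pytest.raises(ValueError, match="rho0"):
        IndicatorModel("extracts", slope=0.003, intercept=0.2, rho0=0.0)


# --- config persistence ----------------------------------------------------


def test_config_yaml_round_trip(tmp_path):
    config = default_config(seed=42)
    save_config(config, tmp_path / "config.yaml")
    back = load_config(tmp_path / "config.yaml")
    assert back == config
    assert config_from_dict(config_to_dict(config)) == config
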