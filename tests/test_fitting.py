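"""Likelihood, estimation and bootstrap tests.

Controlled-probability fixtures use a unit-slope single-drug surface
(all U50 coefficients zero, exp link, n = 1 at the propofol vertex,
C50p = 1): there E = cp / (1 + cp), so any target probability p is
realized exactly by cp = p / (1 - p).
"""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from nlmaz.fitting import (
    DEFAULT_FROZEN,
    FIT_PARAM_NAMES,
    FitConfig,
    binarize,
    bootstrap_se,
    fit,
    neg2ll,
)
from nlmaz.surface import (
    Link,
    PolynomialCoefficients,
    PotencyTriple,
    SurfaceParameters,
)


def unit_slope_params() -> SurfaceParameters:
    n = PolynomialCoefficients(1.0, 1.0, 1.0, *np.zeros(7))
    return SurfaceParameters(
        potency=PotencyTriple(1.0, 1.0, 1.0),
        u50_coeffs=PolynomialCoefficients.zeros(),
        n_coeffs=n,
        link_u50=Link("exp"),
        link_n=Link("identity"),
    )


def obs_with_probs(probs, responses) -> pd.DataFrame:
    cp = np.asarray(probs) / (1.0 - np.asarray(probs))
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(cp))],
            "time_min": np.arange(len(cp), dtype=float),
            "ce_mid_ng_ml": 0.0,
            "ce_alf_ng_ml": 0.0,
            "ce_prop_ug_ml": cp,
            "lor": list(responses),
        }
    )


@pytest.mark.parametrize(
    "score, flag", [(5, 0), (4, 0), (3, 1), (2, 1), (1, 1), (0, 1)]
)
def test_binarize(score, flag):
    assert binarize(score) == flag


@pytest.mark.parametrize("score", [-1, 6, 2.5])
def test_binarize_rejects_out_of_range(score):
    with pytest.raises(ValueError):
        binarize(score)


def test_neg2ll_hand_example():
    # R=(1,0,1), P=(0.8,0.3,0.9): -2(ln .8 + ln .7 + ln .9)
    obs = obs_with_probs([0.8, 0.3, 0.9], [1, 0, 1])
    expected = -2.0 * (math.log(0.8) + math.log(0.7) + math.log(0.9))
    assert neg2ll(unit_slope_params(), obs) == pytest.approx(expected, rel=1e-10)
    assert expected == pytest.approx(1.370358, abs=5e-6)


def test_neg2ll_closed_form_half_probabilities():
    K = 17
    obs = obs_with_probs([0.5] * K, [1, 0] * 8 + [1])
    assert neg2ll(unit_slope_params(), obs) == pytest.approx(K * 2.0 * math.log(2.0), rel=1e-12)


def test_neg2ll_perfect_prediction_limit():
    obs = obs_with_probs([1 - 1e-9, 1e-9], [1, 0])
    assert neg2ll(unit_slope_params(), obs) < 1e-6


def test_neg2ll_empty_and_inconsistent():
    with pytest.raises(ValueError):
        neg2ll(unit_slope_params(), pd.DataFrame(columns=["ce_mid_ng_ml"]))
    obs = obs_with_probs([0.5], [1])
    obs["moaas"] = [5]  # contradicts lor = 1
    with pytest.raises(ValueError):
        neg2ll(unit_slope_params(), obs)


def test_neg2ll_matches_bruteforce_oracle(normalized_truth):
    """Vectorized objective vs an explicit per-observation loop."""
    from nlmaz.surface import effect

    rng = np.random.default_rng(9)
    from nlmaz.cohort import CohortSpec, generate

    obs, _ = generate(CohortSpec(truth=normalized_truth, n_patients=20, n_observations=80, seed=4))
    total = 0.0
    from nlmaz.surface import DrugState

    for _, row in obs.iterrows():
        p = effect(
            DrugState(row.ce_mid_ng_ml, row.ce_alf_ng_ml, row.ce_prop_ug_ml), normalized_truth
        )
        p = min(max(p, 1e-10), 1 - 1e-10)
        total += row.lor * math.log(p) + (1 - row.lor) * math.log(1 - p)
    assert neg2ll(normalized_truth, obs) == pytest.approx(-2.0 * total, abs=1e-10)


def small_fit_config(**kw) -> FitConfig:
    frozen = dict(DEFAULT_FROZEN)
    frozen.update({"u50_alpha_m": 0.0, "u50_alpha_a": 0.0, "u50_alpha_p": 0.0})
    frozen.update({"u50_gamma_ma": 0.0, "u50_gamma_mp": 0.0, "u50_gamma_ap": 0.0})
    kw.setdefault("frozen", frozen)
    kw.setdefault("n_starts", 6)
    kw.setdefault("n_bootstrap", 8)
    return FitConfig(**kw)


@pytest.fixture(scope="module")
def small_cohort(normalized_truth):
    from nlmaz.cohort import CohortSpec, generate

    obs, _ = generate(
        CohortSpec(truth=normalized_truth, n_patients=40, n_observations=170, seed=12)
    )
    return obs


def test_fit_deterministic_under_seed(small_cohort):
    cfg = small_fit_config(seed=5)
    r1 = fit(small_cohort, cfg)
    r2 = fit(small_cohort, cfg)
    assert r1.estimates == r2.estimates  # bit-identical
    assert r1.neg2ll == r2.neg2ll


def test_fit_invariant_to_observation_order(small_cohort):
    cfg = small_fit_config(seed=5)
    shuffled = small_cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
    r1 = fit(small_cohort, cfg)
    r2 = fit(shuffled, cfg)
    for k in r1.estimates:
        assert r1.estimates[k] == pytest.approx(r2.estimates[k], rel=1e-4, abs=1e-6)
    assert r1.neg2ll == pytest.approx(r2.neg2ll, rel=1e-8)


def test_fit_minimizes_neg2ll(small_cohort, normalized_truth):
    cfg = small_fit_config(seed=5)
    res = fit(small_cohort, cfg)
    assert res.neg2ll <= neg2ll(normalized_truth, small_cohort) + 1e-9
    assert res.converged
    assert res.n_obs == len(small_cohort)
    assert res.n_patients == 40


def test_all_one_class_drives_bounds_and_warns():
    obs = obs_with_probs([0.3] * 12, [0] * 12)  # nobody loses response
    cfg = small_fit_config(seed=1, n_starts=3)
    with pytest.warns(UserWarning, match="one response class"):
        res = fit(obs, cfg)
    # no-LOR data push the propofol potency to its upper bound
    assert res.at_boundary["c50_prop"]


def test_frozen_mask_is_respected(small_cohort):
    cfg = small_fit_config(seed=2)
    cfg.frozen["u50_beta_mp"] = -0.123
    res = fit(small_cohort, cfg)
    assert "u50_beta_mp" not in res.estimates
    assert res.params.u50_coeffs.beta_mp == -0.123


def test_bootstrap_se_and_rse(small_cohort):
    cfg = small_fit_config(seed=5, n_bootstrap=10)
    res = bootstrap_se(small_cohort, cfg)
    assert len(res.bootstrap_table) + res.n_boot_failed == 10
    for name in cfg.free_names:
        assert res.se[name] >= 0.0
        if res.estimates[name] != 0.0:
            assert res.rse[name] == pytest.approx(res.se[name] / abs(res.estimates[name]))
    # reproducible under the same master seed
    res2 = bootstrap_se(small_cohort, cfg)
    pd.testing.assert_frame_equal(res.bootstrap_table, res2.bootstrap_table)


def test_bootstrap_degenerate_single_patient():
    """One patient: every patient-level resample is identical, so SE = 0."""
    obs = obs_with_probs([0.3, 0.6, 0.8, 0.4], [0, 1, 1, 0])
    obs["patient_id"] = "P0"
    cfg = small_fit_config(seed=3, n_starts=2, n_bootstrap=4, n_boot_starts=1)
    res = bootstrap_se(obs, cfg)
    assert all(v == 0.0 for v in res.se.values())


def test_rse_undefined_for_zero_estimate():
    obs = obs_with_probs([0.3, 0.6, 0.8, 0.4], [0, 1, 1, 0])
    cfg = small_fit_config(seed=3, n_starts=2, n_bootstrap=3, n_boot_starts=1)
    point = fit(obs, cfg)
    point.estimates["u50_beta_ma"] = 0.0  # definition edge: estimate exactly 0
    res = bootstrap_se(obs, cfg, point=point)
    assert res.rse["u50_beta_ma"] == math.inf


def test_bootstrap_se_shrinks_with_dataset_size(normalized_truth):
    """SE scales roughly as 1/sqrt(dataset multiplier) (here x4 -> ~1/2)."""
    from nlmaz.cohort import CohortSpec, generate

    # freeze everything except the propofol potency and slope, at truth
    from nlmaz.surface import params_to_dict

    truth_vals = params_to_dict(normalized_truth)
    frozen = {
        name: float(truth_vals[name])
        for name in FIT_PARAM_NAMES
        if name not in ("c50_prop", "n_alpha_p")
    }
    ses = []
    for n_pat, n_obs in ((30, 120), (120, 480)):
        obs, _ = generate(
            CohortSpec(truth=normalized_truth, n_patients=n_pat, n_observations=n_obs, seed=31)
        )
        cfg = FitConfig(frozen=frozen, n_starts=4, n_bootstrap=40, n_boot_starts=1, seed=31)
        ses.append(bootstrap_se(obs, cfg).se["c50_prop"])
    ratio = ses[0] / ses[1]
    assert 1.3 < ratio < 3.2  # Monte-Carlo band around the ideal 2.0
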