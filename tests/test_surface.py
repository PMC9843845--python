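"""Unit and property tests for the response-surface core."""

import math
from dataclasses import replace

import numpy as np
import pytest
import yaml

from conftest import hill, random_admissible_params
from nlmaz.surface import (
    DrugState,
    InadmissibleParametersError,
    Link,
    MixtureFractions,
    PolynomialCoefficients,
    PotencyTriple,
    SurfaceParameters,
    UnitState,
    ZeroAmountError,
    effect,
    effect_many,
    eval_polynomial,
    eval_polynomial_xyz,
    fractions,
    normalize,
    params_from_dict,
    params_to_dict,
    surface_n,
    surface_u50,
)


@pytest.mark.parametrize(
    "state, potency, expected",
    [
        (DrugState(0, 0, 0), PotencyTriple(40.73, 340.84, 1.21), (0.0, 0.0, 0.0)),
        # identity ratio at the propofol potency
        (DrugState(0, 0, 1.21), PotencyTriple(40.73, 340.84, 1.21), (0.0, 0.0, 1.0)),
        # hand division 27 / 340.84
        (DrugState(0, 27.0, 0), PotencyTriple(40.73, 340.84, 1.21), (0.0, 0.07921605, 0.0)),
    ],
)
def test_normalize(state, potency, expected):
    units = normalize(state, potency)
    assert (units.um, units.ua, units.up) == pytest.approx(expected, abs=1e-8)
    assert units.u == units.um + units.ua + units.up


def test_negative_or_nonfinite_concentration_rejected():
    with pytest.raises(ValueError):
        DrugState(-1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        DrugState(float("nan"), 0.0, 0.0)


@pytest.mark.parametrize(
    "units, expected",
    [
        (UnitState(0.2, 0.2, 0.2), (1 / 3, 1 / 3, 1 / 3)),
        (UnitState(0.0, 0.0, 0.5), (0.0, 0.0, 1.0)),
        (UnitState(1.0, 3.0, 0.0), (0.25, 0.75, 0.0)),
    ],
)
def test_fractions(units, expected):
    f = fractions(units)
    assert (f.x, f.y, f.z) == pytest.approx(expected, abs=1e-15)


def test_fractions_zero_amount_signal():
    with pytest.raises(ZeroAmountError):
        fractions(UnitState(0.0, 0.0, 0.0))


def test_fractions_sum_to_one_property():
    rng = np.random.default_rng(11)
    for _ in range(200):
        u = rng.uniform(0.0, 5.0, 3)
        if u.sum() == 0:
            continue
        f = fractions(UnitState(*u))
        assert f.x + f.y + f.z == pytest.approx(1.0, abs=1e-12)


def _bruteforce_polynomial(c: PolynomialCoefficients, x, y, z) -> float:
    """Term-by-term oracle with explicit loops over the index sets."""
    vals = {"m": x, "a": y, "p": z}
    alpha = {"m": c.alpha_m, "a": c.alpha_a, "p": c.alpha_p}
    beta = {("m", "a"): c.beta_ma, ("m", "p"): c.beta_mp, ("a", "p"): c.beta_ap}
    gamma = {("m", "a"): c.gamma_ma, ("m", "p"): c.gamma_mp, ("a", "p"): c.gamma_ap}
    total = 0.0
    for i in ("m", "a", "p"):
        total += alpha[i] * vals[i]
    for pair in (("m", "a"), ("m", "p"), ("a", "p")):
        i, j = pair
        total += beta[pair] * vals[i] * vals[j]
        total += gamma[pair] * vals[i] * vals[j] * (vals[i] - vals[j])
    total += c.delta_map * vals["m"] * vals["a"] * vals["p"]
    return total


def test_polynomial_matches_bruteforce_oracle():
    rng = np.random.default_rng(5)
    for _ in range(300):
        coeffs = PolynomialCoefficients(*rng.uniform(-3, 3, 10))
        w = rng.dirichlet(np.ones(3))
        f = MixtureFractions(*w)
        assert eval_polynomial(coeffs, f) == pytest.approx(
            _bruteforce_polynomial(coeffs, *w), abs=1e-12
        )


def test_polynomial_zero_coefficients():
    f = MixtureFractions(0.3, 0.3, 0.4)
    assert eval_polynomial(PolynomialCoefficients.zeros(), f) == 0.0


def test_polynomial_reference_values(ref_params):
    # vertex value equals the single-drug constant exactly
    assert eval_polynomial(ref_params.u50_coeffs, MixtureFractions(0, 0, 1)) == -0.50
    # centre: sum(alpha)/3 + sum(beta)/9 + delta/27 (gamma terms vanish)
    centre = eval_polynomial(ref_params.u50_coeffs, MixtureFractions(1 / 3, 1 / 3, 1 / 3))
    assert centre == pytest.approx(-0.7207407407, abs=1e-9)


def test_surface_u50_trivial_and_contract(ref_params):
    flat = replace(
        ref_params, u50_coeffs=PolynomialCoefficients.zeros(), link_u50=Link("exp")
    )
    assert surface_u50(flat, MixtureFractions(0.2, 0.3, 0.5)) == 1.0
    bad = replace(ref_params, link_u50=Link("identity"))
    with pytest.raises(InadmissibleParametersError):
        surface_u50(bad, MixtureFractions(0, 0, 1))  # polynomial is negative there


def test_surface_n_reference_values(ref_params):
    assert surface_n(ref_params, MixtureFractions(0, 0, 1)) == pytest.approx(10.66)
    assert surface_n(ref_params, MixtureFractions(1, 0, 0)) == pytest.approx(3.95)
    # interaction-free blend on the alfentanil-propofol edge
    assert surface_n(ref_params, MixtureFractions(0, 0.5, 0.5)) == pytest.approx(12.03)


def test_effect_zero_amount_and_half_maximal(smooth_params):
    assert effect(DrugState(0, 0, 0), smooth_params) == 0.0
    # choose a mixture direction, place U exactly at / above the local U50
    w = np.array([0.2, 0.3, 0.5])
    u50 = surface_u50(smooth_params, MixtureFractions(*w))
    n = surface_n(smooth_params, MixtureFractions(*w))
    pot = smooth_params.potency
    c50 = np.array([pot.c50m, pot.c50a, pot.c50p])
    at_u50 = u50 * w * c50
    assert effect(DrugState(*at_u50), smooth_params) == pytest.approx(0.5, abs=1e-12)
    at_95 = u50 * 19.0 ** (1.0 / n) * w * c50
    assert effect(DrugState(*at_95), smooth_params) == pytest.approx(0.95, abs=1e-9)


def test_effect_monotone_along_rays():
    """Scaling all drugs together always increases the effect.

    This is the model's exact monotonicity guarantee: along a fixed
    composition the fractions (hence U50 and n) are constant and E is a
    strictly increasing Hill curve in U.  Per-drug monotonicity is NOT a
    theorem of the canonical-polynomial surface (moving the composition
    can raise U50 faster than U); see the companion test below.
    """
    rng = np.random.default_rng(21)
    for _ in range(25):
        params = random_admissible_params(rng)
        w = rng.dirichlet(np.ones(3))
        scale = np.linspace(0.01, 4.0, 60)
        c50 = np.array([params.potency.c50m, params.potency.c50a, params.potency.c50p])
        cm, ca, cp = (np.outer(scale, w * c50)).T
        probs = effect_many(cm, ca, cp, params)
        assert np.all(np.diff(probs) > 0)


def test_effect_nearly_monotone_per_drug_reference_set(ref_params):
    """For the reference set, per-drug dips stay below 1e-3 probability."""
    bases = [(0, 0, 0), (10, 0, 0.5), (30, 50, 0.2), (5, 100, 1.0), (80, 20, 0.1)]
    for base in bases:
        for axis, grid_max in ((0, 108.0), (1, 156.0), (2, 2.6)):
            grid = np.linspace(0.0, grid_max, 300)
            cols = [np.full_like(grid, base[i]) for i in range(3)]
            cols[axis] = grid
            probs = effect_many(cols[0], cols[1], cols[2], ref_params)
            assert np.min(np.diff(probs)) > -1e-3


def test_single_drug_slice_is_hill_curve(smooth_params):
    """At a vertex the surface collapses to C50*link(alpha_U), link(alpha_n)."""
    pot = smooth_params.potency
    cases = [
        ("cm", pot.c50m, smooth_params.u50_coeffs.alpha_m, smooth_params.n_coeffs.alpha_m),
        ("ca", pot.c50a, smooth_params.u50_coeffs.alpha_a, smooth_params.n_coeffs.alpha_a),
        ("cp", pot.c50p, smooth_params.u50_coeffs.alpha_p, smooth_params.n_coeffs.alpha_p),
    ]
    for field, c50, alpha_u, alpha_n in cases:
        c50_eff = c50 * float(smooth_params.link_u50(alpha_u))
        slope = float(smooth_params.link_n(alpha_n))
        for conc in np.linspace(0.01, 4.0, 23) * c50:
            state = DrugState(**{"cm": 0.0, "ca": 0.0, "cp": 0.0, field: conc})
            assert effect(state, smooth_params) == pytest.approx(
                hill(conc, c50_eff, slope), abs=1e-12
            )


def test_single_drug_reduction_gives_bare_hill(ref_params):
    """With the reduction the vertex slice uses the drug's own C50."""
    pot = ref_params.potency
    for cp in (0.5, 1.21, 2.0):
        assert effect(DrugState(0, 0, cp), ref_params) == pytest.approx(
            hill(cp, pot.c50p, ref_params.n_coeffs.alpha_p), abs=1e-12
        )


def _swap_mid_alf(params: SurfaceParameters) -> SurfaceParameters:
    def swap(c: PolynomialCoefficients) -> PolynomialCoefficients:
        return PolynomialCoefficients(
            alpha_m=c.alpha_a,
            alpha_a=c.alpha_m,
            alpha_p=c.alpha_p,
            beta_ma=c.beta_ma,
            beta_mp=c.beta_ap,
            beta_ap=c.beta_mp,
            gamma_ma=-c.gamma_ma,  # ordered-pair convention flips sign
            gamma_mp=c.gamma_ap,
            gamma_ap=c.gamma_mp,
            delta_map=c.delta_map,
        )

    return replace(
        params,
        potency=PotencyTriple(params.potency.c50a, params.potency.c50m, params.potency.c50p),
        u50_coeffs=swap(params.u50_coeffs),
        n_coeffs=swap(params.n_coeffs),
    )


def test_permutation_consistency():
    """Relabeling drugs together with their coefficients leaves E unchanged."""
    rng = np.random.default_rng(33)
    for _ in range(10):
        params = random_admissible_params(rng)
        swapped = _swap_mid_alf(params)
        cm, ca, cp = rng.uniform(0.0, 2.0, 3) * np.array(
            [params.potency.c50m, params.potency.c50a, params.potency.c50p]
        )
        assert effect(DrugState(cm, ca, cp), params) == pytest.approx(
            effect(DrugState(ca, cm, cp), swapped), abs=1e-12
        )


def test_parameter_roundtrip(tmp_path, ref_params):
    d = params_to_dict(ref_params)
    back = params_from_dict(d)
    assert back == ref_params
    # scaled_exp link constants survive the flat dialect
    cal = replace(ref_params, link_u50=Link("scaled_exp", a=0.41, b=1.3))
    path = tmp_path / "params.yaml"
    from nlmaz.surface import load_parameters, save_parameters

    save_parameters(cal, path)
    loaded = load_parameters(path)
    assert loaded == cal
    raw = yaml.safe_load(path.read_text())
    assert raw["link_u50"] == "scaled_exp"
    assert raw["link_u50_a"] == 0.41


def test_validate_rejects_inadmissible(ref_params):
    bad = replace(ref_params, link_u50=Link("identity"))
    with pytest.raises(InadmissibleParametersError):
        bad.validate()
    ref_params.validate()  # admissible set passes
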