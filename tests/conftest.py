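from dataclasses import replace

import numpy as np
import pytest

from nlmaz.surface import (
    Link,
    PolynomialCoefficients,
    PotencyTriple,
    SurfaceParameters,
    reference_parameters,
)


@pytest.fixture(scope="session")
def ref_params() -> SurfaceParameters:
    """Packaged moderate-sedation parameter set (exp link, vertex reduction)."""
    return reference_parameters()


@pytest.fixture(scope="session")
def smooth_params(ref_params) -> SurfaceParameters:
    """Reference coefficients without the single-drug reduction.

    A fully continuous surface for properties that probe the polynomial
    link path at and around the vertices.
    """
    return replace(ref_params, single_drug_reduction=False)


@pytest.fixture(scope="session")
def normalized_truth(ref_params) -> SurfaceParameters:
    """Vertex-normalized ground truth for simulation studies.

    alpha_U = 0 (U50 = 1 at each vertex, the identifiable convention);
    interaction structure and potencies as in the reference set.
    """
    return replace(
        ref_params,
        u50_coeffs=replace(ref_params.u50_coeffs, alpha_m=0.0, alpha_a=0.0, alpha_p=0.0),
        link_u50=Link("exp"),
        single_drug_reduction=False,
    )


def random_admissible_params(rng: np.random.Generator) -> SurfaceParameters:
    """A random admissible surface (exp U50 link, identity n link)."""
    u50 = PolynomialCoefficients(*rng.uniform(-1.5, 1.0, 10))
    n_alphas = rng.uniform(1.5, 15.0, 3)
    n = PolynomialCoefficients(*n_alphas, *np.zeros(7))
    return SurfaceParameters(
        potency=PotencyTriple(*np.exp(rng.uniform(np.log(5.0), np.log(400.0), 2)),
                              np.exp(rng.uniform(np.log(0.3), np.log(5.0)))),
        u50_coeffs=u50,
        n_coeffs=n,
        link_u50=Link("exp"),
        link_n=Link("identity"),
    )


def hill(conc, c50, slope):
    """Independent scalar two-parameter Hill curve (test oracle)."""
    r = (conc / c50) ** slope
    return r / (1.0 + r)
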