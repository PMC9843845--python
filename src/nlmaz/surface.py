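"""NLMAZ three-drug response surface.

The model treats a midazolam/alfentanil/propofol combination as a single
virtual drug.  Effect-site concentrations are first normalized by each
drug's potency,

    U_m = C_m / C50_m,   U_a = C_a / C50_a,   U_p = C_p / C50_p,

and summed to a total normalized amount ``U = U_m + U_a + U_p``.  The
composition of the mixture is described by the fractions
``x = U_m/U, y = U_a/U, z = U_p/U`` (which sum to one), and the
probability of loss of response (LOR, MOAA/S < 4) follows a sigmoid Emax
(Hill) curve in ``U``:

    E = (U / U50)^n / (1 + (U / U50)^n)

where both the half-effect amount ``U50`` and the slope ``n`` vary with
the mixture composition through full-cubic Scheffe canonical polynomials
in (x, y, z).  Pairwise (beta) and triple (delta) polynomial terms encode
synergy (negative values bow the U50 surface downward).

Because a Scheffe polynomial is unconstrained in sign while U50 and n
must be positive, the polynomial output is passed through an explicit,
configurable link function; see :class:`Link`.  The "zero amount" in the
model name refers to the convention that the effect is exactly 0 when no
drug is present (U = 0), where the mixture fractions are undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
import numpy as np
import yaml

__all__ = [
    "DrugState",
    "PotencyTriple",
    "UnitState",
    "MixtureFractions",
    "PolynomialCoefficients",
    "Link",
    "SurfaceParameters",
    "ZeroAmountError",
    "InadmissibleParametersError",
    "normalize",
    "fractions",
    "eval_polynomial",
    "eval_polynomial_xyz",
    "surface_u50",
    "surface_n",
    "effect",
    "effect_many",
    "reference_parameters",
    "load_parameters",
    "save_parameters",
]

#: Fixed unit convention: ng/mL for midazolam and alfentanil, ug/mL for
#: propofol.  All potencies, observation files and dosing results use it.
UNITS = {"midazolam": "ng/mL", "alfentanil": "ng/mL", "propofol": "ug/mL"}


class ZeroAmountError(ValueError):
    """Raised where mixture fractions are requested for U = 0."""


class InadmissibleParametersError(ValueError):
    """Raised when a parameter set yields non-positive U50 or n."""


def _check_nonneg(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v) or v < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return v


@dataclass(frozen=True)
class DrugState:
    """Effect-site concentration triple.

    cm: midazolam Ce (ng/mL); ca: alfentanil Ce (ng/mL);
    cp: propofol Ce (ug/mL).
    """

    cm: float
    ca: float
    cp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cm", _check_nonneg("cm", self.cm))
        object.__setattr__(self, "ca", _check_nonneg("ca", self.ca))
        object.__setattr__(self, "cp", _check_nonneg("cp", self.cp))


@dataclass(frozen=True)
class PotencyTriple:
    """Single-drug potencies C50 (same units as :class:`DrugState`)."""

    c50m: float
    c50a: float
    c50p: float

    def __post_init__(self) -> None:
        for name in ("c50m", "c50a", "c50p"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class UnitState:
    """Dimensionless normalized potencies and their total."""

    um: float
    ua: float
    up: float

    @property
    def u(self) -> float:
        return self.um + self.ua + self.up


@dataclass(frozen=True)
class MixtureFractions:
    """Mixture fractions of midazolam (x), alfentanil (y), propofol (z)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        s = self.x + self.y + self.z
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {s!r}")
        if min(self.x, self.y, self.z) < 0 or max(self.x, self.y, self.z) > 1:
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class PolynomialCoefficients:
    """Coefficients of a full-cubic Scheffe canonical polynomial.

    Ten constants: three single-drug terms (alpha, indexed m/a/p), three
    pairwise interaction terms (beta, indexed ma/mp/ap), three pairwise
    asymmetry terms (gamma, same index order) and one triple-interaction
    term (delta).  The gamma term is ``gamma_ij * x_i * x_j * (x_i - x_j)``
    with the *first minus second* convention for the ordered pairs
    (m,a), (m,p), (a,p); this ordering is fixed so serialized sets
    round-trip deterministically.
    """

    alpha_m: float
    alpha_a: float
    alpha_p: float
    beta_ma: float
    beta_mp: float
    beta_ap: float
    gamma_ma: float
    gamma_mp: float
    gamma_ap: float
    delta_map: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.__dataclass_fields__])

    @classmethod
    def zeros(cls) -> "PolynomialCoefficients":
        return cls(*([0.0] * 10))


@dataclass(frozen=True)
class Link:
    """Positivity link applied to a canonical-polynomial value.

    Supported: ``identity`` (requires positive polynomial output),
    ``exp``, ``softplus`` (log(1+exp(P))), and ``scaled_exp`` with two
    parameters (a, b) giving exp(a + b*P).  ``scaled_exp`` exists because
    the published simulation results for the moderate-sedation parameter
    set cannot be matched by any fixed zero-parameter link; its constants
    are obtained by :func:`nlmaz.dosing.calibrate_link`.
    """

    name: str = "exp"
    a: float = 0.0
    b: float = 1.0

    _SUPPORTED = ("identity", "exp", "softplus", "scaled_exp")

    def __post_init__(self) -> None:
        if self.name not in self._SUPPORTED:
            raise ValueError(
                f"unsupported link {self.name!r}; expected one of {self._SUPPORTED}"
            )

    def __call__(self, p):
        p = np.asarray(p, dtype=float)
        if self.name == "identity":
            return p
        if self.name == "exp":
            return np.exp(p)
        if self.name == "softplus":
            return np.logaddexp(0.0, p)
        return np.exp(self.a + self.b * p)


@dataclass(frozen=True)
class SurfaceParameters:
    """A complete NLMAZ surface: potencies, two polynomials, two links.

    ``single_drug_reduction`` selects the zero-amount convention for
    degenerate mixtures in which exactly one drug is present: when True,
    U50 is fixed at 1 there, so the surface reduces to the drug's own
    two-parameter Hill curve (C50, link_n(alpha_n)).  At a vertex the C50
    and the linked alpha term are confounded (only their product is
    identifiable), and the published simulations for the reference
    parameter set behave this way; it is therefore enabled in
    :func:`reference_parameters` and disabled by default elsewhere.
    """

    potency: PotencyTriple
    u50_coeffs: PolynomialCoefficients
    n_coeffs: PolynomialCoefficients
    link_u50: Link = field(default_factory=lambda: Link("exp"))
    link_n: Link = field(default_factory=lambda: Link("identity"))
    single_drug_reduction: bool = False

    def with_link_u50(self, link: Link) -> "SurfaceParameters":
        return replace(self, link_u50=link)

    def validate(self, resolution: int = 40) -> "SurfaceParameters":
        """Check U50 > 0 and n > 0 over a simplex grid; raise otherwise."""
        xs, ys, zs = _simplex_grid(resolution)
        u50 = self.link_u50(eval_polynomial_xyz(self.u50_coeffs, xs, ys, zs))
        n = self.link_n(eval_polynomial_xyz(self.n_coeffs, xs, ys, zs))
        if np.any(u50 <= 0):
            raise InadmissibleParametersError(
                "link_u50(polynomial) is not strictly positive over the simplex"
            )
        if np.any(n <= 0):
            raise InadmissibleParametersError(
                "link_n(polynomial) is not strictly positive over the simplex"
            )
        return self


def _simplex_grid(resolution: int):
    i, j = np.meshgrid(np.arange(resolution + 1), np.arange(resolution + 1))
    keep = (i + j) <= resolution
    x = i[keep] / resolution
    y = j[keep] / resolution
    return x, y, 1.0 - x - y


# ---------------------------------------------------------------------------
# Operations


def normalize(state: DrugState, potency: PotencyTriple) -> UnitState:
    """Normalize concentrations to dimensionless potency units."""
    return UnitState(
        um=state.cm / potency.c50m,
        ua=state.ca / potency.c50a,
        up=state.cp / potency.c50p,
    )


def fractions(units: UnitState) -> MixtureFractions:
    """Mixture fractions x, y, z of the three drugs.

    Undefined at U = 0; raises :class:`ZeroAmountError` there (the effect
    at U = 0 is handled separately and is 0 by convention).
    """
    u = units.u
    if u <= 0:
        raise ZeroAmountError("mixture fractions are undefined at U = 0")
    return MixtureFractions(x=units.um / u, y=units.ua / u, z=units.up / u)


def eval_polynomial_xyz(coeffs: PolynomialCoefficients, x, y, z):
    """Vectorized full-cubic canonical polynomial in raw fraction arrays."""
    c = coeffs
    return (
        c.alpha_m * x
        + c.alpha_a * y
        + c.alpha_p * z
        + c.beta_ma * x * y
        + c.beta_mp * x * z
        + c.beta_ap * y * z
        + c.gamma_ma * x * y * (x - y)
        + c.gamma_mp * x * z * (x - z)
        + c.gamma_ap * y * z * (y - z)
        + c.delta_map * x * y * z
    )


def eval_polynomial(coeffs: PolynomialCoefficients, frac: MixtureFractions) -> float:
    """Raw (unlinked) canonical-polynomial value at one mixture."""
    return float(eval_polynomial_xyz(coeffs, frac.x, frac.y, frac.z))


def _linked(value: float, link: Link, what: str) -> float:
    out = float(link(value))
    if out <= 0:
        raise InadmissibleParametersError(
            f"{what} must be > 0; {link.name} link gave {out!r} "
            f"(polynomial value {value!r})"
        )
    return out


def surface_u50(params: SurfaceParameters, frac: MixtureFractions) -> float:
    """Half-effect normalized amount U50 at a mixture composition."""
    return _linked(eval_polynomial(params.u50_coeffs, frac), params.link_u50, "U50")


def surface_n(params: SurfaceParameters, frac: MixtureFractions) -> float:
    """Hill slope n at a mixture composition."""
    return _linked(eval_polynomial(params.n_coeffs, frac), params.link_n, "n")


def effect(state: DrugState, params: SurfaceParameters) -> float:
    """Probability of loss of response for one concentration triple."""
    return float(effect_many([state.cm], [state.ca], [state.cp], params)[0])


def effect_many(cm, ca, cp, params: SurfaceParameters) -> np.ndarray:
    """Vectorized LOR probability over arrays of concentrations.

    Implements the zero-amount convention (E = 0 at U = 0) and, when
    ``params.single_drug_reduction`` is set, the single-drug reduction
    (U50 = 1 where exactly one drug is present).
    """
    cm = np.asarray(cm, dtype=float)
    ca = np.asarray(ca, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if np.any(~np.isfinite(cm)) or np.any(~np.isfinite(ca)) or np.any(~np.isfinite(cp)):
        raise ValueError("concentrations must be finite")
    if np.any(cm < 0) or np.any(ca < 0) or np.any(cp < 0):
        raise ValueError("concentrations must be >= 0")
    um, ua, up = np.broadcast_arrays(
        cm / params.potency.c50m, ca / params.potency.c50a, cp / params.potency.c50p
    )
    shape = um.shape
    um, ua, up = um.ravel(), ua.ravel(), up.ravel()
    u = um + ua + up
    out = np.zeros(u.shape)
    pos = u > 0
    if not np.any(pos):
        return out.reshape(shape)
    uu = u[pos]
    um_, ua_, up_ = um[pos], ua[pos], up[pos]
    x, y, z = um_ / uu, ua_ / uu, up_ / uu
    u50 = params.link_u50(eval_polynomial_xyz(params.u50_coeffs, x, y, z))
    n = params.link_n(eval_polynomial_xyz(params.n_coeffs, x, y, z))
    if np.any(u50 <= 0) or np.any(n <= 0):
        raise InadmissibleParametersError("non-positive U50 or n encountered")
    if params.single_drug_reduction:
        single = ((um_ > 0).astype(int) + (ua_ > 0).astype(int) + (up_ > 0).astype(int)) == 1
        u50 = np.where(single, 1.0, u50)
    # (U/U50)^n / (1 + (U/U50)^n), computed stably on the log scale
    logr = n * (np.log(uu) - np.log(u50))
    prob = np.where(logr > 0, 1.0 / (1.0 + np.exp(-logr)), np.exp(logr) / (1.0 + np.exp(logr)))
    out[pos] = prob
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# Reference parameter set and (de)serialization

_U50_KEYS = [f"u50_{f}" for f in PolynomialCoefficients.__dataclass_fields__]
_N_KEYS = [f"n_{f}" for f in PolynomialCoefficients.__dataclass_fields__]


def _link_to_dict(prefix: str, link: Link) -> dict:
    d = {prefix: link.name}
    if link.name == "scaled_exp":
        d[f"{prefix}_a"] = float(link.a)
        d[f"{prefix}_b"] = float(link.b)
    return d


def _link_from_dict(prefix: str, d: dict) -> Link:
    name = d.get(prefix, "exp")
    if name == "scaled_exp":
        return Link("scaled_exp", a=float(d[f"{prefix}_a"]), b=float(d[f"{prefix}_b"]))
    return Link(name)


def params_to_dict(params: SurfaceParameters) -> dict:
    """Flat key/value form of a parameter set (serialization dialect)."""
    d = {
        "c50_mid": params.potency.c50m,
        "c50_alf": params.potency.c50a,
        "c50_prop": params.potency.c50p,
    }
    d.update(zip(_U50_KEYS, (float(v) for v in params.u50_coeffs.as_array())))
    d.update(zip(_N_KEYS, (float(v) for v in params.n_coeffs.as_array())))
    d.update(_link_to_dict("link_u50", params.link_u50))
    d.update(_link_to_dict("link_n", params.link_n))
    d["single_drug_reduction"] = bool(params.single_drug_reduction)
    return d


def params_from_dict(d: dict) -> SurfaceParameters:
    return SurfaceParameters(
        potency=PotencyTriple(d["c50_mid"], d["c50_alf"], d["c50_prop"]),
        u50_coeffs=PolynomialCoefficients(*(float(d[k]) for k in _U50_KEYS)),
        n_coeffs=PolynomialCoefficients(*(float(d[k]) for k in _N_KEYS)),
        link_u50=_link_from_dict("link_u50", d),
        link_n=_link_from_dict("link_n", d),
        single_drug_reduction=bool(d.get("single_drug_reduction", False)),
    )


def save_parameters(params: SurfaceParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_parameters(path) -> SurfaceParameters:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def reference_parameters() -> SurfaceParameters:
    """The packaged moderate-sedation (MOAA/S < 4) parameter set.

    Estimated from a gastrointestinal-endoscopy sedation cohort
    (56 patients, 227 pooled observations).  The n-polynomial interaction
    terms were reported only as rounded zeros (magnitude 1e-4 to 1e-7)
    and are carried as exactly zero.  Ships with the plain ``exp`` U50
    link; dosing replication first calibrates a ``scaled_exp`` link
    against the published simulation anchors (see
    :func:`nlmaz.dosing.calibrate_link`).
    """
    ref = resources.files("nlmaz").joinpath("data/moaas_lt4.yaml")
    with ref.open() as fh:
        return params_from_dict(yaml.safe_load(fh))
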