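"""Dosing simulations on a fitted surface: curve shifts, nadirs, ternary grid.

The clinically useful outputs of the surface are (i) the propofol
effect-site concentration needed for a target LOR probability given
fixed companion midazolam/alfentanil concentrations ("curve shift"),
with the 95/50/5% lines read as the LOR threshold, half-effect and
return-of-consciousness conventions, and (ii) the U50 landscape over the
mixture simplex, whose minima (nadirs) locate the strongest interaction.

Companion concentrations for the published replication scenarios are the
printed post-bolus peak Ce values (midazolam 21/52 ng/mL after 1/2 mg,
alfentanil 27/55 ng/mL after 250/500 ug), deliberately decoupling the
pharmacodynamic replication from PK-model uncertainty.

:func:`calibrate_link` resolves the under-specified polynomial-to-U50
transform: it fits the two constants of the ``scaled_exp`` link so that
solved curve-shift concentrations reproduce a set of published anchors
in a least-squares sense (on the log scale).  No zero-parameter link
reproduces the published values, and the anchors are in fact mutually
inconsistent under *any* monotone link, so a least-squares compromise is
the strongest statement the published numbers support; see
docs/methods.md for the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from nlmaz.surface import (
    Link,
    MixtureFractions,
    SurfaceParameters,
    effect_many,
    eval_polynomial_xyz,
)

__all__ = [
    "CurveShiftAnchor",
    "CurveShiftResult",
    "TernarySurface",
    "UnreachableTargetError",
    "REFERENCE_ANCHORS",
    "REFERENCE_COMPANIONS",
    "solve_cp",
    "curve_shift_family",
    "u50_nadir",
    "ternary_grid",
    "calibrate_link",
]


class UnreachableTargetError(ValueError):
    """Target probability cannot be reached at any propofol concentration."""


@dataclass(frozen=True)
class CurveShiftAnchor:
    """A published (companion Ce, target probability, propofol Ce) triple."""

    cm: float  # midazolam Ce, ng/mL
    ca: float  # alfentanil Ce, ng/mL
    target: float  # LOR probability
    cp: float  # published propofol Ce, ug/mL
    label: str = ""


#: Published 95%-LOR curve-shift values for the moderate-sedation set,
#: with companions at the printed post-bolus peak Ce values.
REFERENCE_ANCHORS = (
    CurveShiftAnchor(0.0, 0.0, 0.95, 1.59, "propofol alone"),
    CurveShiftAnchor(21.0, 0.0, 0.95, 0.70, "midazolam 1 mg (21 ng/mL)"),
    CurveShiftAnchor(52.0, 0.0, 0.95, 0.32, "midazolam 2 mg (52 ng/mL)"),
    CurveShiftAnchor(0.0, 27.0, 0.95, 1.12, "alfentanil 250 ug (27 ng/mL)"),
    CurveShiftAnchor(21.0, 27.0, 0.95, 0.54, "midazolam 1 mg + alfentanil 250 ug"),
)

#: Printed peak Ce per companion bolus, keyed by scenario label.
REFERENCE_COMPANIONS = {
    "midazolam 1 mg": (21.0, 0.0),
    "midazolam 2 mg": (52.0, 0.0),
    "alfentanil 250 ug": (0.0, 27.0),
    "alfentanil 500 ug": (0.0, 55.0),
    "midazolam 1 mg + alfentanil 250 ug": (21.0, 27.0),
}


@dataclass
class CurveShiftResult:
    label: str
    cm: float
    ca: float
    target: float
    cp: float  # solved propofol Ce, ug/mL
    curve: pd.DataFrame  # columns cp, probability


@dataclass
class TernarySurface:
    """U50 sampled on a barycentric grid of the mixture simplex."""

    fractions: np.ndarray  # (n_nodes, 3) columns x, y, z
    u50: np.ndarray
    minimum: float
    argmin: MixtureFractions
    flat: bool  # surface constant to numerical precision


def solve_cp(
    target: float,
    cm: float,
    ca: float,
    params: SurfaceParameters,
    cp_max: float = 50.0,
    tol: float = 1e-6,
) -> float:
    """Propofol Ce at which P(LOR) equals ``target`` for fixed companions.

    The effect is strictly increasing in propofol concentration for
    admissible parameter sets, so the root is unique; Brent's method is
    run to an effect tolerance below 1e-6.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target probability must be in (0, 1)")
    if cm < 0 or ca < 0:
        raise ValueError("companion concentrations must be >= 0")

    def f(cp: float) -> float:
        return float(effect_many([cm], [ca], [cp], params)[0]) - target

    if f(0.0) >= 0.0:
        # companions alone already reach the target: the solved propofol
        # requirement is zero only in the limit; report unreachable-from-
        # above explicitly rather than a spurious root.
        raise UnreachableTargetError(
            f"companions alone give P >= {target}; no positive propofol root"
        )
    if f(cp_max) < 0.0:
        raise UnreachableTargetError(
            f"target {target} not reached by cp = {cp_max} ug/mL"
        )
    root = brentq(f, 0.0, cp_max, xtol=1e-12, rtol=8.9e-16)
    if abs(f(root)) >= tol:
        # The crossing is a jump, not a root: under the single-drug
        # reduction the surface is discontinuous where a second drug
        # first appears, and a trial link can push the effect past the
        # target for any positive propofol amount.  The requirement then
        # collapses to an infinitesimal dose; signal it explicitly.
        raise UnreachableTargetError(
            f"effect jumps across the target {target} at cp -> 0+ "
            "(single-drug reduction discontinuity); no positive root"
        )
    return float(root)


def curve_shift_family(
    companions: dict[str, tuple[float, float]] | None,
    params: SurfaceParameters,
    targets: tuple[float, ...] = (0.05, 0.5, 0.95),
    cp_grid_max: float = 4.0,
    cp_grid_step: float = 0.001,
) -> list[CurveShiftResult]:
    """One probability-vs-propofol curve per companion setting.

    ``companions`` maps labels to (midazolam Ce, alfentanil Ce); an empty
    or None mapping yields the propofol-alone curve only.  Each curve is
    tabulated on [0, cp_grid_max] and annotated with the solved propofol
    Ce for each target (root-found analytically, not read off the grid).
    Unreachable targets are recorded as NaN rather than aborting the
    family.
    """
    settings = {"propofol alone": (0.0, 0.0)}
    settings.update(companions or {})
    grid = np.arange(0.0, cp_grid_max + cp_grid_step / 2, cp_grid_step)
    out = []
    for label, (cm, ca) in settings.items():
        probs = effect_many(np.full_like(grid, cm), np.full_like(grid, ca), grid, params)
        curve = pd.DataFrame({"cp": grid, "probability": probs})
        for target in targets:
            try:
                cp = solve_cp(target, cm, ca, params)
            except UnreachableTargetError:
                cp = float("nan")
            out.append(
                CurveShiftResult(label=label, cm=cm, ca=ca, target=target, cp=cp, curve=curve)
            )
    return out


_EDGES = {
    "full": None,
    "mid-alf": ("x", "y"),
    "mid-prop": ("x", "z"),
    "alf-prop": ("y", "z"),
}


def _domain_fractions(restriction: str, resolution: int):
    if restriction == "full":
        i, j = np.meshgrid(np.arange(resolution + 1), np.arange(resolution + 1))
        keep = (i + j) <= resolution
        x = i[keep] / resolution
        y = j[keep] / resolution
        return x, y, 1.0 - x - y
    if restriction not in _EDGES:
        raise ValueError(f"unknown restriction {restriction!r}")
    t = np.linspace(0.0, 1.0, resolution + 1)
    zero = np.zeros_like(t)
    a, b = _EDGES[restriction]
    coords = {"x": zero, "y": zero, "z": zero}
    coords[a] = t
    coords[b] = 1.0 - t
    return coords["x"], coords["y"], coords["z"]


def u50_nadir(
    params: SurfaceParameters, restriction: str = "full", resolution: int = 2000
) -> tuple[float, MixtureFractions, bool]:
    """Minimum of U50 over the simplex or one of its pairwise edges.

    Dense-grid search followed by a local grid refinement around the
    best node; returns (minimum, argmin fractions, flat-surface flag).
    Restrictions: "full", "mid-alf", "mid-prop", "alf-prop".
    """
    res = resolution if restriction != "full" else min(resolution, 600)
    x, y, z = _domain_fractions(restriction, res)
    u50 = np.asarray(params.link_u50(eval_polynomial_xyz(params.u50_coeffs, x, y, z)))
    k = int(np.argmin(u50))
    best = (float(u50[k]), float(x[k]), float(y[k]), float(z[k]))
    # local refinement: shrink a barycentric box around the incumbent
    span = 2.0 / res
    for _ in range(8):
        xs = np.clip(np.linspace(best[1] - span, best[1] + span, 41), 0.0, 1.0)
        ys = np.clip(np.linspace(best[2] - span, best[2] + span, 41), 0.0, 1.0)
        if restriction == "full":
            gx, gy = np.meshgrid(xs, ys)
            keep = gx + gy <= 1.0
            cx, cy = gx[keep], gy[keep]
            cz = 1.0 - cx - cy
        else:
            a, b = _EDGES[restriction]
            t = np.clip(np.linspace(best[{"x": 1, "y": 2, "z": 3}[a]] - span,
                                    best[{"x": 1, "y": 2, "z": 3}[a]] + span, 81), 0.0, 1.0)
            zero = np.zeros_like(t)
            coords = {"x": zero.copy(), "y": zero.copy(), "z": zero.copy()}
            coords[a] = t
            coords[b] = 1.0 - t
            cx, cy, cz = coords["x"], coords["y"], coords["z"]
        vals = np.asarray(params.link_u50(eval_polynomial_xyz(params.u50_coeffs, cx, cy, cz)))
        j = int(np.argmin(vals))
        if vals[j] < best[0]:
            best = (float(vals[j]), float(cx[j]), float(cy[j]), float(cz[j]))
        span /= 4.0
    flat = bool(np.ptp(u50) < 1e-12)
    return best[0], MixtureFractions(best[1], best[2], best[3]), flat


def ternary_grid(params: SurfaceParameters, resolution: int = 100) -> TernarySurface:
    """Barycentric U50 grid with (resolution+1)(resolution+2)/2 nodes."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    x, y, z = _domain_fractions("full", resolution)
    u50 = np.asarray(params.link_u50(eval_polynomial_xyz(params.u50_coeffs, x, y, z)))
    k = int(np.argmin(u50))
    return TernarySurface(
        fractions=np.column_stack([x, y, z]),
        u50=u50,
        minimum=float(u50[k]),
        argmin=MixtureFractions(float(x[k]), float(y[k]), float(z[k])),
        flat=bool(np.ptp(u50) < 1e-12),
    )


def calibrate_link(
    params: SurfaceParameters,
    anchors: tuple[CurveShiftAnchor, ...] = REFERENCE_ANCHORS,
    x0: tuple[float, float] = (0.5, 1.5),
) -> SurfaceParameters:
    """Fit the scaled_exp U50 link to published curve-shift anchors.

    Minimizes the sum of squared log-ratios between solved and published
    propofol concentrations over the anchor set and returns the parameter
    set with ``link_u50 = scaled_exp(a, b)``.  Deterministic (no
    randomness).  Single-drug anchors are insensitive to the link when
    the parameter set uses the single-drug reduction; they then simply
    verify the reduction and do not steer (a, b).
    """

    def residuals(theta):
        trial = params.with_link_u50(Link("scaled_exp", a=float(theta[0]), b=float(theta[1])))
        out = []
        for anchor in anchors:
            try:
                cp = solve_cp(anchor.target, anchor.cm, anchor.ca, trial)
            except UnreachableTargetError:
                cp = 1e-6  # degenerate trial region: large finite residual
            out.append(np.log(cp) - np.log(anchor.cp))
        return out

    sol = least_squares(residuals, x0=np.asarray(x0, dtype=float), method="lm")
    a, b = (float(v) for v in sol.x)
    return params.with_link_u50(Link("scaled_exp", a=a, b=b))
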