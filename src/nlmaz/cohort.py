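"""Synthetic sedation cohorts drawn from a known ground-truth surface.

Emulates the structure of the modeling dataset — about 56 patients with
227 pooled MOAA/S assessments at procedure-critical moments, effect-site
concentrations spanning 0-108 ng/mL midazolam, 0-156 ng/mL alfentanil
and 0-2.6 ug/mL propofol — so that fitting and validation can be
exercised end-to-end without any external data.  Responses are
independent Bernoulli draws with probability given by the ground truth
(matching the pooled likelihood the model assumes); a patient-level
random-shift mode exists only for robustness experiments.

Three concentration-sampling modes are available, none of which involves
the PK engine except the last:

* ``titrate`` (default) — emulates the study's assessment design, in
  which MOAA/S was scored at procedure-critical moments (induction
  transition to LOR, instrumentation, emergence): most observations sit
  near the individual sedation threshold.  A mixture draw places the
  normalized amount U at a random effect level in (0.02, 0.98) given a
  random drug composition, mixed with a 30% mass of plain range-based
  draws.  Range-uniform sampling alone leaves ~90% of responses
  saturated and the binary likelihood nearly uninformative, under which
  no estimator can recover the surface.
* ``direct`` — plain sampling on the stated ranges (log-uniform with a
  zero-dose mass for the two adjuvants, uniform for propofol).
* ``pk`` — generates bolus dose histories and reads Ce off simulated
  trajectories.

Note on identifiability: the reference alfentanil potency (C50 = 340.84
ng/mL) is far above the sampled range (max 156 ng/mL), so C50_alf is
weakly identified by construction — alfentanil alone cannot elicit LOR
within the design.  Recovery experiments should assert only a lower
bound for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nlmaz import pk as pkmod
from nlmaz.surface import (
    SurfaceParameters,
    effect_many,
    eval_polynomial_xyz,
    params_to_dict,
)

__all__ = ["CohortSpec", "generate", "generate_dose_histories"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of a synthetic cohort."""

    truth: SurfaceParameters
    n_patients: int = 56
    n_observations: int = 227
    obs_per_patient: tuple[int, int] = (3, 6)
    age_mean: float = 53.3
    age_sd: float = 13.3
    bmi_mean: float = 23.1
    bmi_sd: float = 3.7
    female_fraction: float = 0.59
    ce_max_mid: float = 108.0
    ce_max_alf: float = 156.0
    ce_max_prop: float = 2.6
    zero_dose_prob: float = 0.1  # per-adjuvant mass at Ce = 0 (direct draws)
    ce_mode: str = "titrate"  # or "direct" or "pk"
    titrate_weight: float = 0.7  # fraction of threshold-targeted draws
    drug_present_prob: tuple[float, float, float] = (0.75, 0.75, 0.95)
    response_mode: str = "independent"  # or "patient_shift"
    patient_shift_sd: float = 0.5  # logit-scale SD, patient_shift mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.obs_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("invalid obs_per_patient range")
        if not lo * self.n_patients <= self.n_observations <= hi * self.n_patients:
            raise ValueError(
                "n_observations incompatible with n_patients and obs_per_patient"
            )
        if min(self.ce_max_mid, self.ce_max_alf, self.ce_max_prop) <= 0:
            raise ValueError("concentration ranges must be positive")
        if self.ce_mode not in ("titrate", "direct", "pk"):
            raise ValueError("ce_mode must be 'titrate', 'direct' or 'pk'")
        if not 0.0 <= self.titrate_weight <= 1.0:
            raise ValueError("titrate_weight must be in [0, 1]")
        if self.response_mode not in ("independent", "patient_shift"):
            raise ValueError("response_mode must be 'independent' or 'patient_shift'")


def _obs_counts(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.obs_per_patient
    counts = rng.integers(lo, hi + 1, size=spec.n_patients)
    # nudge random patients until the pooled total matches exactly
    while counts.sum() != spec.n_observations:
        i = rng.integers(spec.n_patients)
        if counts.sum() < spec.n_observations and counts[i] < hi:
            counts[i] += 1
        elif counts.sum() > spec.n_observations and counts[i] > lo:
            counts[i] -= 1
    return counts


def _demographics(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_patients
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 20.0, 80.0)
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 15.0, 40.0)
    female = rng.random(n) < spec.female_fraction
    height = np.where(female, rng.normal(160.0, 6.0, n), rng.normal(172.0, 7.0, n))
    weight = bmi * (height / 100.0) ** 2
    return pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:03d}" for i in range(n)],
            "age": np.round(age, 1),
            "weight": np.round(weight, 1),
            "height": np.round(height, 1),
            "sex": np.where(female, "F", "M"),
        }
    )


def _sample_ce_direct(spec: CohortSpec, rng: np.random.Generator, n: int):
    def adjuvant(ce_max: float) -> np.ndarray:
        zero = rng.random(n) < spec.zero_dose_prob
        vals = np.exp(rng.uniform(np.log(1.0), np.log(ce_max), n))
        return np.where(zero, 0.0, vals)

    cm = adjuvant(spec.ce_max_mid)
    ca = adjuvant(spec.ce_max_alf)
    cp = rng.uniform(0.0, spec.ce_max_prop, n)
    return cm, ca, cp


def _sample_ce_titrate(spec: CohortSpec, rng: np.random.Generator, n: int):
    """Threshold-concentrated sampling (see module docstring)."""
    pot = spec.truth.potency
    c50 = np.array([pot.c50m, pot.c50a, pot.c50p])
    cmax = np.array([spec.ce_max_mid, spec.ce_max_alf, spec.ce_max_prop])
    present_p = np.asarray(spec.drug_present_prob)
    out = np.zeros((n, 3))
    i = 0
    while i < n:
        if rng.random() < spec.titrate_weight:
            present = rng.random(3) < present_p
            if not present.any():
                continue
            frac = np.zeros(3)
            frac[present] = rng.dirichlet(np.ones(int(present.sum())))
            u50 = spec.truth.link_u50(eval_polynomial_xyz(spec.truth.u50_coeffs, *frac))
            slope = spec.truth.link_n(eval_polynomial_xyz(spec.truth.n_coeffs, *frac))
            e = rng.uniform(0.02, 0.98)
            ce = float(u50) * (e / (1.0 - e)) ** (1.0 / float(slope)) * frac * c50
        else:
            zero = rng.random(2) < spec.zero_dose_prob
            cm = 0.0 if zero[0] else np.exp(rng.uniform(0.0, np.log(spec.ce_max_mid)))
            ca = 0.0 if zero[1] else np.exp(rng.uniform(0.0, np.log(spec.ce_max_alf)))
            ce = np.array([cm, ca, rng.uniform(0.0, spec.ce_max_prop)])
        if (ce <= cmax).all():
            out[i] = ce
            i += 1
    return out[:, 0], out[:, 1], out[:, 2]


def generate(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Observation table plus the hidden ground-truth record.

    Each row is one MOAA/S assessment: concentrations, the Bernoulli LOR
    draw with probability ``effect(Ce, truth)``, and a MOAA/S score
    back-filled consistently with the LOR flag (score < 4 iff lor = 1).
    Deterministic under ``spec.seed``.
    """
    spec.truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10]))
    counts = _obs_counts(spec, rng)
    demo = _demographics(spec, rng)

    pid = np.repeat(demo["patient_id"].to_numpy(), counts)
    times = np.concatenate(
        [np.sort(rng.uniform(0.0, 40.0, c)) for c in counts]
    )
    if spec.ce_mode == "direct":
        cm, ca, cp = _sample_ce_direct(spec, rng, spec.n_observations)
    elif spec.ce_mode == "titrate":
        cm, ca, cp = _sample_ce_titrate(spec, rng, spec.n_observations)
    else:
        cm, ca, cp = _sample_ce_pk(spec, rng, demo, counts, times)

    p = effect_many(cm, ca, cp, spec.truth)
    if spec.response_mode == "patient_shift":
        shift = np.repeat(rng.normal(0.0, spec.patient_shift_sd, spec.n_patients), counts)
        logit = np.log(np.clip(p, 1e-12, 1 - 1e-12)) - np.log1p(-np.clip(p, 1e-12, 1 - 1e-12))
        p = 1.0 / (1.0 + np.exp(-(logit + shift)))
    lor = (rng.random(spec.n_observations) < p).astype(int)
    moaas = np.where(lor == 1, rng.integers(0, 4, spec.n_observations),
                     rng.integers(4, 6, spec.n_observations))

    obs = pd.DataFrame(
        {
            "patient_id": pid,
            "time_min": np.round(times, 2),
            "ce_mid_ng_ml": cm,
            "ce_alf_ng_ml": ca,
            "ce_prop_ug_ml": cp,
            "moaas": moaas,
            "lor": lor,
        }
    )
    truth_record = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "n_observations": spec.n_observations,
        "ce_mode": spec.ce_mode,
        "response_mode": spec.response_mode,
        "truth": params_to_dict(spec.truth),
    }
    return obs, truth_record


# ---------------------------------------------------------------------------
# PK-coupled generation

# Bolus menus; levels chosen so simulated Ce stay inside the cohort's
# stated concentration ranges for the reference PK models.
_MID_DOSES = (0.0, 1.0, 2.0)  # mg, at t=0
_MID_PROBS = (0.25, 0.5, 0.25)
_ALF_DOSES = (0.0, 250.0, 500.0)  # ug, at t=0.5
_ALF_PROBS = (0.25, 0.5, 0.25)


def generate_dose_histories(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bolus dose events and demographics CSV-compatible tables.

    Midazolam and alfentanil are single pre-procedure boluses; propofol
    is an induction bolus followed by a few maintenance boluses, the
    bolus-based pattern of procedural sedation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    demo = _demographics(spec, rng)
    rows = []
    for pid in demo["patient_id"]:
        mid = rng.choice(_MID_DOSES, p=_MID_PROBS)
        alf = rng.choice(_ALF_DOSES, p=_ALF_PROBS)
        if mid > 0:
            rows.append((pid, "midazolam", mid, "mg", 0.0, 0.0))
        if alf > 0:
            rows.append((pid, "alfentanil", alf, "ug", 0.5, 0.0))
        induction = rng.uniform(20.0, 40.0)
        rows.append((pid, "propofol", round(induction, 1), "mg", 1.0, 0.0))
        t = 1.0
        for _ in range(rng.integers(0, 4)):
            t += rng.uniform(3.0, 6.0)
            rows.append((pid, "propofol", round(rng.uniform(10.0, 20.0), 1), "mg", round(t, 2), 0.0))
    doses = pd.DataFrame(
        rows,
        columns=["patient_id", "drug", "amount", "amount_unit", "time_min", "duration_min"],
    )
    return doses, demo


def _sample_ce_pk(spec, rng, demo, counts, times):
    doses, _ = generate_dose_histories(spec)
    cm = np.empty(spec.n_observations)
    ca = np.empty(spec.n_observations)
    cp = np.empty(spec.n_observations)
    start = 0
    for (_, row), c in zip(demo.iterrows(), counts):
        d = pkmod.Demographics(row["age"], row["weight"], row["height"], row["sex"])
        events = [
            pkmod.DoseEvent(r["drug"], r["amount"], r["amount_unit"], r["time_min"], r["duration_min"])
            for _, r in doses[doses["patient_id"] == row["patient_id"]].iterrows()
        ]
        t_obs = times[start : start + c]
        t_end = max(45.0, float(t_obs.max()) + 1.0)
        for drug, target in (("midazolam", cm), ("alfentanil", ca), ("propofol", cp)):
            traj = pkmod.simulate(events, pkmod.build_pk(drug, d), t_end=t_end, dt=0.01)
            target[start : start + c] = np.interp(t_obs, traj.time, traj.ce)
        start += c
    return cm, ca, cp
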