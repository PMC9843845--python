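# nlmaz — three-drug response-surface pharmacodynamics for moderate sedation

`nlmaz` implements the NLMAZ ("nonlinear mixed amount with zero amount")
response-surface model of moderate procedural sedation with **midazolam,
alfentanil and propofol**, for anesthesiologists, pharmacometricians and
educators who want to quantify and simulate three-drug interactions:
which drug combinations reach a target sedation depth, how strongly the
drugs synergize, and how much less propofol is needed once a midazolam
or alfentanil bolus is on board.

Sedation depth is scored with the MOAA/S scale (5 = awake … 0 =
unresponsive to noxious stimuli) and dichotomized at **loss of response
(LOR): MOAA/S < 4**, the operational definition of moderate sedation.

## The model

Effect-site concentrations are normalized by each drug's potency and
summed into a single virtual drug:

```
U_m = C_m / C50_m,   U_a = C_a / C50_a,   U_p = C_p / C50_p
U   = U_m + U_a + U_p
```

The composition of the mixture is captured by fractions
`x = U_m/U, y = U_a/U, z = U_p/U` (x + y + z = 1), and the probability
of LOR follows a sigmoid Emax (Hill) curve in U:

```
E = (U/U50)^n / (1 + (U/U50)^n)
```

Both `U50` (the half-effect amount) and the slope `n` vary with the
composition through full-cubic Scheffé canonical polynomials

```
P(x,y,z) = Σ αᵢ xᵢ + Σ βᵢⱼ xᵢxⱼ + Σ γᵢⱼ xᵢxⱼ(xᵢ−xⱼ) + Σ δᵢⱼₖ xᵢxⱼxₖ
```

whose pairwise (β) and triple (δ) terms encode synergy — negative values
bow the U50 surface downward.  A configurable positive link maps the
polynomial to `U50 > 0`; `E = 0` exactly when no drug is present (the
"zero amount" convention).  The package ships a published
moderate-sedation parameter set (C50: midazolam 40.73 ng/mL, alfentanil
340.84 ng/mL, propofol 1.21 µg/mL, plus 20 polynomial constants) and
calibrates the link against the published simulation results at run time
(see `docs/methods.md` for why the link must be calibrated).

Around the surface the package provides:

- `nlmaz.pk` — three-compartment + effect-site PK (Schnider propofol,
  Maitre alfentanil, Zomorodi midazolam) with exact matrix-exponential
  bolus/infusion simulation;
- `nlmaz.fitting` — pooled binary maximum likelihood (−2LL), multistart
  bounded optimization, patient-level bootstrap SE/RSE;
- `nlmaz.evaluation` — predefined accuracy (|R−P| < 0.5), ROC, AUC with
  DeLong or bootstrap CI;
- `nlmaz.dosing` — curve-shift solving (propofol Ce for a target LOR
  probability given companion drugs), U50 nadirs, ternary surfaces,
  link calibration;
- `nlmaz.cohort` — synthetic cohorts from a known ground truth, so the
  whole pipeline is testable without patient data.

## Worked example

```python
from nlmaz import (REFERENCE_ANCHORS, calibrate_link, solve_cp, u50_nadir)
from nlmaz.surface import reference_parameters

params = calibrate_link(reference_parameters(), REFERENCE_ANCHORS)
for cm, ca, label in [(0, 0, "propofol alone"),
                      (21, 0, "+ midazolam 1 mg (peak Ce 21 ng/mL)"),
                      (21, 27, "+ midazolam 1 mg + alfentanil 250 µg")]:
    cp = solve_cp(0.95, cm, ca, params)
    print(f"{label:<40} {cp:.3f} µg/mL")
print("U50 minimum over the simplex:", round(u50_nadir(params)[0], 3))
```

prints

```
propofol alone                           1.595 µg/mL
+ midazolam 1 mg (peak Ce 21 ng/mL)      0.734 µg/mL
+ midazolam 1 mg + alfentanil 250 µg     0.549 µg/mL
U50 minimum over the simplex: 0.55
```

Read: propofol alone needs ≈1.6 µg/mL at the effect site for a 95%
chance of moderate-sedation LOR; a single 1 mg midazolam bolus halves
that, and adding a 250 µg alfentanil bolus nearly halves it again —
the quantitative case for low-dose triple-drug sedation.  The U50
minimum below 1 shows net synergy: the most synergistic mixture needs
only ~55% of the normalized amount a single drug would need.

## The analysis

The numbered drivers under `analysis/` re-run the full study pipeline on
synthetic data and write their tables under `results/`:

1. `01_build_cohorts.py` — synthetic modeling (56 patients / 227
   observations) and validation cohorts from a known ground truth;
2. `02_fit_surface.py` — maximum-likelihood fit with bootstrap SE/RSE;
3. `03_validate_surface.py` — accuracy, ROC and AUC (with CI) on the
   validation cohorts;
4. `04_replicate_simulations.py` — calibrated curve-shift families,
   ternary U50 surface and nadirs (tables + figures);
5. `05_pk_peaks.py` — bolus PK simulations and peak effect-site
   concentrations.

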