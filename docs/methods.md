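# Methods

This note documents the model, the numerical choices, the synthetic-data
design and the known limitations of `nlmaz`. It states what the package
computes and under which conditions; every number quoted here is
produced by the test suite or the analysis drivers.

## 1. The response-surface model

The NLMAZ model treats a midazolam/alfentanil/propofol combination as a
single virtual drug. Effect-site concentrations (Ce) are divided by the
per-drug potencies C50 and summed into a normalized amount
U = U_m + U_a + U_p; the probability of loss of response
(LOR, MOAA/S < 4) is a Hill curve in U,

E = (U/U50)^n / (1 + (U/U50)^n),

with U50 and n functions of the mixture composition
(x, y, z) = (U_m, U_a, U_p)/U through full-cubic Scheffé canonical
polynomials (3 α single-drug terms, 3 β pairwise, 3 γ pairwise
asymmetry, 1 δ triple, per polynomial). Negative β/δ values bow U50
downward: synergy. Conventions fixed by this package:

- **γ ordering.** γ_ij x_i x_j (x_i − x_j) uses the ordered pairs
  (m,a), (m,p), (a,p) with "first minus second". Serialized parameter
  files record coefficients in this order, so files round-trip exactly.
- **Zero amount.** E = 0 exactly at U = 0, where mixture fractions are
  undefined. Any positive U uses fractions.
- **Units.** ng/mL for midazolam and alfentanil, µg/mL for propofol,
  baked into column names (`ce_mid_ng_ml`, …); unit-less files are
  rejected rather than guessed.

### 1.1 The link function

A Scheffé polynomial is unconstrained in sign, while U50 and n must be
positive. For the packaged moderate-sedation coefficient set the U50
polynomial is negative over the whole simplex, so *some* transform is
required, and the source material for this parameter set does not state
one. The package makes the link explicit and configurable:
`identity` (valid only for positive polynomials), `exp`, `softplus`,
and `scaled_exp(a, b) = exp(a + b·P)` whose two constants are fitted by
`nlmaz.dosing.calibrate_link` — least squares on the log of the solved
curve-shift concentration against a set of published anchor values.
The slope polynomial n uses the identity link: its α values
(3.95–13.40) are already plausible Hill slopes and its interaction
terms are reported only as rounded zeros (magnitude 1e−4 to 1e−7),
which the fixture carries as exactly zero.

Calibration is necessary rather than cosmetic: we verified numerically
that **no zero-parameter link reproduces the published simulation
values, and that those values are mutually inconsistent under any
monotone link at all**. Writing each published 95%-LOR propofol
concentration as an implied (P, U50) pair, the pairs are not monotone
in P (e.g. the midazolam-21 scenario implies U50 = 0.739 at P = −0.524
while the alfentanil-27 scenario implies U50 = 0.767 at the *lower*
P = −0.564), and the published 50%-LOR point implies a U50 24% above
the three-drug 95% point at essentially the same P. A least-squares
link is therefore the strongest statement the published numbers
support. With the calibrated link
(a ≈ 0.410, b ≈ 1.303) four of the five published curve-shift values
are reproduced within 0.01–0.03 µg/mL; the alfentanil-companion value
(published 1.12 µg/mL) comes out at 1.05 µg/mL and cannot be moved
closer without breaking the others — it is reported as-is. The
published U50 nadirs (0.61 at equal thirds; 0.64/0.74/0.69 on the
pairwise edges, all "at equal fractions") are likewise mutually
non-monotone in P and imply a much shallower link than the curve
shifts; under the calibrated link the surface minimum is ≈0.55 and sits
off-centre, and the package reports that honestly rather than tuning
to the printed pair.

### 1.2 Single-drug reduction

At a simplex vertex the potency C50 and the linked single-drug term
link(α) enter the effect only through their product — they are not
separately identifiable. The published propofol-alone simulation value
equals the bare Hill prediction C50_p · 19^(1/n_p) = 1.595 µg/mL to
printed precision, i.e. it was generated with U50 = 1 at the vertex.
The package exposes this as a `single_drug_reduction` flag (U50 := 1
where exactly one drug is present), enabled in the shipped reference
set and disabled by default for generic sets. The cost is a
discontinuity where a second drug first appears; `solve_cp` detects a
target crossed by that jump and raises an explicit signal instead of
returning a spurious root.

### 1.3 Monotonicity

Monotonicity in each *single* drug holding the others fixed is **not**
a theorem of this model family: raising one drug shifts the mixture
composition, which can raise U50 faster than U. Measured violations are
large for arbitrary admissible coefficient sets and below ~2×10⁻⁴
probability for the reference set. What is exact is monotonicity along
rays of fixed composition, and the tests assert exactly that split.

## 2. Estimation

Observations are pooled (no random effects, matching the model's
independent-Bernoulli likelihood): −2LL = −2 Σ [Rᵢ ln Pᵢ +
(1−Rᵢ) ln(1−Pᵢ)] with Rᵢ = 1 ⇔ LOR (MOAA/S ≤ 3). Pᵢ is clamped to
[1e−10, 1−1e−10] as a standard likelihood guard.

- **Optimizer.** L-BFGS-B under bounds (C50_m ∈ [1, 500] ng/mL,
  C50_a ∈ [1, 5000] ng/mL — wide because the alfentanil potency
  exceeds every observable concentration, C50_p ∈ [0.1, 10] µg/mL,
  coefficients ∈ [−10, 10], n-α ∈ [0.5, 40]), with 20 random starts by
  default (log-uniform for potencies) because the likelihood has local
  minima. Rows are put in a canonical sort order before summation so
  estimates do not depend on the row order of the input file.
- **Masking.** Any parameter can be frozen at a fixed value through the
  `FitConfig.frozen` mapping; the default freezes the n-polynomial
  interaction terms at zero (they are reported only as rounded zeros in
  the source parameter table).
- **Identifiability.** Because C50_i and link(α_U,i) are confounded
  (refits preserve C50·exp(α) to ~1% while the individual values move
  freely), the full 23-parameter layout is over-parameterized. The
  recommended estimation configuration — used by the analysis drivers
  and the recovery experiment — is the vertex-normalized form α_U ≡ 0,
  under which U50 = 1 at each vertex and the C50s absorb all
  single-drug potency. The alfentanil C50 remains weakly identified in
  any case, because it lies far above the observable concentration
  range: alfentanil alone cannot produce LOR within the design, and
  recovery experiments assert only a lower bound for it.
- **Bootstrap.** "Uncertainty = bootstrap" with 2000 replicates as the
  reference configuration; replicates resample **patients** with
  replacement (preserving the repeated-measures structure), with
  observation-level resampling available as a config option. Each
  replicate refits from the point estimate plus a small number of
  random starts. SE is the SD of replicate estimates; RSE = SE/|est|,
  reported as infinite for a zero estimate. Failed replicates are
  counted; >20% failures warns.
- **Seeding.** One master seed fans out to the multistart and bootstrap
  streams through `numpy` SeedSequences; identical seeds give
  bit-identical results.

## 3. Validation metrics

Accuracy is the predefined rule: percent of observations with
|Rᵢ − Pᵢ| < 0.5, strict inequality, so a prediction of exactly 0.5 is
inaccurate for both classes. ROC/AUC are computed on the predicted
probabilities (binarized predictions would degenerate the curve); AUC
equals the tie-corrected Mann–Whitney concordance (ties count 1/2) and
agrees with the trapezoid ROC integral to 1e−12 by construction —
both are computed in the tests. The 95% CI uses DeLong's closed-form
variance by default; a patient-level bootstrap CI is available.

## 4. Pharmacokinetics

Each drug is a linear mammillary three-compartment model plus an effect
compartment (ke0). The state is advanced on a uniform grid (default
0.005 min) by the exact matrix exponential of the system; infusions use
the augmented-matrix integral, so there is no ODE-solver error — an
LSODA integration at rtol 1e−11 agrees to <0.1% in the tests. Boluses
are instantaneous central-compartment inputs (the few-mL saline flush
is ignored).

Parameter sets (one annotated constants registry, each entry carrying
its citation): Schnider 1998 for propofol (age/weight/height/LBM
covariates, ke0 0.456 min⁻¹), Maitre 1987 for alfentanil (weight- and
sex-scaled V1, age-adjusted clearance; ke0 from Scott's EEG data,
t½ = 0.9 min), Zomorodi 1998 for midazolam with ke0 from Bührer
(t½ = 4.8 min). The Zomorodi volumes/clearances are **reconstructed
from secondary sources** (the primary table was not available when the
registry was written) and are therefore the least certain entries; with
them a 1 mg midazolam bolus peaks at ≈16.4 ng/mL at the effect site in
the reference adult, within the ±25% band around the published
21 ng/mL that the acceptance suite uses. Note the published midazolam
peaks (21 vs 52 ng/mL for 1 vs 2 mg) are themselves not
dose-proportional, which linear kinetics cannot reproduce; the package
makes no attempt to match the 2 mg value exactly.

Reference demographics for published-simulation work: female, 53.3 yr,
BMI 23.1 (height 160 cm ⇒ weight 59.1 kg) — the only demographic
anchors the modeling cohort provides; exposed as config.

## 5. Synthetic cohorts

`nlmaz.cohort` emulates the modeling dataset's structure: 56 patients,
227 pooled assessments (3–6 per patient at procedure-relevant times),
age ~N(53.3, 13.3²) clipped to 20–80, BMI ~N(23.1, 3.7²), 59% female,
concentrations within 0–108 ng/mL (midazolam), 0–156 ng/mL
(alfentanil), 0–2.6 µg/mL (propofol). Responses are independent
Bernoulli draws with probability given by the ground-truth surface —
exactly the data-generating process the pooled likelihood assumes — and
MOAA/S scores are back-filled consistently (score < 4 iff LOR).

Concentration sampling defaults to a **titration mode**: 70% of draws
pick a random drug composition and place U at a random effect level in
(0.02, 0.98), mimicking assessments clustered around the sedation
threshold (induction, instrumentation, emergence); 30% are plain
range-based draws (log-uniform adjuvants with a 10% zero-dose mass,
uniform propofol). The rationale is statistical as much as clinical:
pure range-uniform sampling leaves ~88% of responses saturated
(true P outside 0.05–0.95) and the binary likelihood close to
uninformative, under which no estimator can recover the surface.
Range-only (`direct`) and PK-driven (`pk`, bolus histories through the
PK engine) modes are available.

The generator does **not** emulate: within-patient correlation (a
logit-shift mode exists only for robustness experiments), time dynamics
of sedation within a procedure (each row is an independent slice),
observer error in MOAA/S scoring, or adverse-event outcomes. Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to their violation.

**Recovery experiment** (the headline full-loop check): 500 patients /
2250 observations from the vertex-normalized truth, balanced mixture
design (equal 0.7 drug-presence probabilities so every pairwise edge is
represented, as in a Scheffé design — under the clinical design with
propofol nearly always present, the midazolam–alfentanil edge carries
~3% of the data and its interaction sign is not reliably estimable at
this size), γ and n-interaction nuisance terms frozen at zero. Under
these conditions the fit recovers C50_p and C50_m within 15%, all three
β_U signs, and the alfentanil C50 as a lower bound.

## 6. Problem sizes and tolerances

Defaults chosen as the package's own working sizes: curve grids
Cp ∈ [0, 4] µg/mL at 0.001; root-finding by Brent to an effect
tolerance < 1e−6 (never read off a grid); nadir search on a dense
barycentric grid (600 per axis on the simplex, 2000 on edges) with
local refinement, matching a brute-force oracle to 1e−3; ternary
export at resolution 100 ((101·102)/2 nodes); PK step 0.005 min;
bootstrap 100 replicates in the analysis driver (2000 is the reference
configuration and a command-line flag away); recovery experiment at
500 patients with 20 optimizer starts.

## 7. Known limitations

- The published simulation quantities are mutually inconsistent
  (§1.1); one curve-shift value and the nadir pair are reported with a
  documented residual rather than reproduced.
- Per-drug monotonicity is only approximate (§1.3), and the single-drug
  reduction introduces a surface discontinuity at the vertices (§1.2).
- C50/α confounding means published-style 23-parameter tables are not
  uniquely estimable from binary data (§2); comparisons of individual
  α/C50 values across fits are not meaningful, only their products.
- The midazolam PK entry is a reconstruction (§4).
- No ordinal MOAA/S modeling (binary LOR only), no time-varying
  pharmacodynamics (hysteresis lives entirely in ke0), no
  respiratory-depression surface, no TCI targeting logic.
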