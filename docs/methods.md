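# Methods

## Scope and intent

`chqdose` is a desk-scale re-implementation of model-informed pediatric
dose selection for chloroquine (CHQ) in COVID-19. The original analysis
used a proprietary whole-body PBPK platform; this package replaces it with
an open, calibrated, physiologically-scaled two-compartment model driven
by the same covariates (age, weight, sex, pathway maturation). The package
therefore claims the *arithmetic* of exposure matching exactly, and the
*qualitative* age pattern of the exposure ratios — not the proprietary
model's absolute numbers.

## Virtual populations

Subjects are sampled independently within an age band:

- **Age**: uniform on the band's half-open interval. The source analysis
  does not state the within-band age distribution of its simulator;
  uniform is the least-informative choice and is the one assumption here
  with no literature anchor.
- **Sex**: Bernoulli with P(female) = 0.5.
- **Weight**: log-normal around the age/sex median of a bundled growth
  table (CV 15% by default; 0 gives deterministic medians for tests). The
  table (`data/growth_reference_synthetic.csv`) is a synthetic
  representative set of medians approximating public growth references —
  it is deliberately not a digitized copy of any single chart, and can be
  replaced by any CSV with columns `age_years, sex, median_weight_kg`.
  Adults use a fixed 75 kg median so the mean adult dose under the
  44 mg/kg schedule is ~3,300 mg.

### Maturation functions

Each elimination pathway carries a fraction-of-adult sigmoid, clamped to
exactly 1.0 from 18 y upward:

| pathway | form | parameters (default) |
|---|---|---|
| CYP3A4 | postnatal-age sigmoid | F_birth 0.11, age50 0.64 y, Hill 1.91 |
| CYP2C8 | postnatal-age sigmoid | F_birth 0.15, age50 0.60 y, Hill 1.2 |
| renal (GFR) | postmenstrual-age sigmoid, term birth (40 wk) assumed | PMA50 47.7 wk, Hill 3.4 |

The CYP3A4 and renal parameters follow widely used in-vivo maturation
estimates. CYP2C8 ontogeny is poorly characterized in vivo; its
parameters were fixed once, at design time, so that the *composite*
clearance maturation (fm-weighted sum of the three sigmoids plus the
mature "other" fraction) reproduces the expected pediatric pattern:
clearance per scaled size immature below ~6 months, near-adult by late
infancy, giving exposure ratios > 1 for 6 mo–12 y, ≈ 1 for 1–6 mo and
< 1 for neonates. They were not adjusted afterwards. All parameters live
in `data/default_config.yaml` and can be overridden.

## Disposition model

Linear mamillary system: absorption depot → central (V1) ⇄ peripheral
(V2), elimination from central.

- **Clearance**: `CL_p = CL_adult · fm_p · maturation_p(age) · (W/70)^0.75`
  per pathway, with fm = 0.15 / 0.20 / 0.56 / 0.09 (CYP3A4 / CYP2C8 /
  renal / other). The unattributed 9% cannot be assigned an ontogeny; it
  is treated as mature from birth (size scaling only) — a documented
  assumption, overridable via the `other_maturation` argument.
  Inter-compartmental clearance Q scales with the same weight^0.75 law;
  volumes scale linearly with weight.
- **Defaults**: Vss 150 L/kg (inside the reported 100–200 L/kg range);
  V1 = 10% of Vss — large enough that central-compartment time constants
  (hours) are well resolved on the default 2-h output grid, consistent
  with CHQ's very large apparent central volume; Q = 200 L/h at the 70-kg
  reference, well above CL so the terminal phase is elimination-limited
  (t½ ≈ ln2·Vss/CL); ka = 0.5 h⁻¹; F = 0.8.
- **Calibration**: `calibrate_adult` solves (Brent's method) for the
  `CL_adult` giving a 14-day terminal half-life in a 75-kg adult,
  estimated by log-linear regression on the 30–70-day tail of a
  single-dose profile; the shipped default (24.22 L/h) is that solution.
  The 70-day AUC window then spans ~5 half-lives, capturing ≳ 97% of
  AUC∞. The half-life target — not an absolute exposure target — anchors
  the model, so simulated absolute AUCs (≈ 101 mg/L·h for the adult
  reference) are on the package's own F/CL scale; exposure *ratios*, which
  drive dose selection, are insensitive to that scale.
- **Solver**: matrix exponential of the 4-state system (depot, central,
  peripheral, cumulative eliminated) propagated step-by-step on the
  uniform grid, with bolus additions of F·dose to the depot at event
  times. This is exact for linear systems: dose-linearity and
  superposition hold to ~1e-9 relative and mass balance to solver
  precision, all asserted in the test suite. Dose times must lie on the
  grid (they do for all shipped schedules).

### AUC

Linear trapezoid on the output grid, with interpolated window endpoints;
additive over interior points. Default window 0–70 days on a 2-h grid
(halving the step moves the 70-day group AUC by < 0.5%, tested);
verification runs use 7 days at 0.5 h. An alternative 0–70 *hour* window
(a reading suggested by one summary of the original analysis, conflicting
with its stated 70-day window) is available via the `auc_window`
argument; the 70-day reading is the default and the one used throughout.

## Regimens

A schedule is (loading₁, loading₂, maintenance) in mg CHQ base/kg: loading
at 0 and 12 h (the licensed 6-h pediatric loading interval is available
but the operative dose tables print 12 h), maintenance at 24–108 h every
12 h. Total = loading sum + 8 × maintenance. Conversions use actual body
weight except for adults, who are dosed for the fixed 75-kg reference. If
the cumulative total exceeds the cap (3,300 mg) every dose is scaled
proportionally — the sources state only a maximum total, so proportional
capping is a package convention, configurable.

Two roundings:

- per-dose maintenance: one decimal, half away from zero on the decimal
  representation;
- final clinical advice: table-driven policy {5.4→5, 5.2→5, 3.7→4,
  2.5→2.5} with nearest-0.5 fallback (ties toward the whole number). No
  closed-form rule reproduces the published mapping, so the policy is an
  explicit, overridable table.

## Dose selection

`run_dose_selection`: 10 trials × 40 subjects per group, 70-day horizon.
The pooled mean AUC forms the ratio (between-trial means are also
retained; the SEM reported is the between-trial SEM of trial means, with a
pooled alternative). Re-verification is **paired** by default: the rebuilt
regimen is re-simulated on the same virtual population as the 44 mg/kg
probe, so under linear kinetics the 5% check can only move through dose
rounding and the (small) schedule-shape difference within the truncated
window — observed deviations are ≲ 1%. Unpaired mode (fresh population,
Monte-Carlo noise in the check) is available via `paired=False`.

## Verification harness

The three published designs are reproduced exactly in structure: adults
10 × 40 with a single 300 mg dose; 6 mo–5 y 4 × 123 and 5–12 y 6 × 76 with
10 mg/kg at 0/24/48 h (30 mg/kg total); 7-day horizon. Observed
concentration ranges are *fixtures* (CSV: study, age_group, time_h,
cmin_mg_per_L, cmax_mg_per_L): the literature comparison data are
digitized from third-party figures and are not bundled.
`make_synthetic_fixture` generates a labelled synthetic stand-in from the
model's own across-subject min/max, with a width-inflation factor
(`max(1, noise)`: 0 leaves the simulated extremes untouched, 2 doubles the
width). Coverage counts an observed range as explained when it intersects
the simulated 1st–99th percentile band at its time; self-generated
fixtures are covered completely by construction, which is tested.
Tablet-strength dose rounding (a plausible source of extra observed
variability) is not emulated by default.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the study — age bands, trial
sizes, sex balance, weight spread, maturation-driven clearance — but not
organ-level anthropometrics, prematurity, disease effects on PK,
ethnicity-specific physiology, metabolite kinetics or absorption
ontogeny. Passing tests therefore demonstrate that the exposure-matching
machinery is correct and that the qualitative age pattern follows from
maturation + allometry; they do not validate the absolute pediatric
exposures against clinical data, which is exactly the role of the
fixture-based verification harness once real digitized ranges are
supplied.

## Numerical choices and degenerate inputs

- Matrix exponentials are computed once per subject per grid step size;
  propagation is a batched 4×4 mat-vec, so a full 5-group selection run
  (2,000 subjects, 70 days) takes seconds on one CPU.
- Weight CV 0 and single-subject trials are supported for deterministic
  oracles; SEM is defined as 0 when only one trial (or subject) exists.
- Empty regimens yield identically zero profiles; negative doses,
  misaligned event times, inverted AUC windows, non-positive AUCs in the
  matching formula, and totals not exceeding the loading sum all raise
  `ValueError`.
- Population sampling is a pure function of its spec (PCG64 generator
  seeded from the spec); group seeds in the selection loop are derived
  deterministically from the run seed.

## Known limitations

- Two-compartment disposition is a deliberate reduction; distribution
  phases of the full physiological model are only mimicked, and lung or
  tissue concentrations are out of scope.
- The 9%-"other" pathway's maturation is unknowable from available
  sources; treating it as mature biases neonatal clearance slightly high.
- The growth table is a synthetic representative reference; users needing
  population-specific anthropometrics should supply their own table.
- Exposure ratios at default parameters reproduce direction and rough
  magnitude of the published values (e.g. 6 mo–5 y runs ~1.4 vs the
  published 1.29); absolute agreement would require the proprietary
  model's organ-level scaling.
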