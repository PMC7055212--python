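# Methods

`betargs` evaluates whether an intraoperative β⁻ probe can discriminate a
pancreatic neuroendocrine tumor remnant from the surrounding healthy
pancreas, given the uptake contrast measured pre-operatively on
⁶⁸Ga-DOTATOC PET and an injection of ⁹⁰Y-DOTATOC before surgery. This note
documents the models, the parameters that matter, the numerical choices and
the limits of what the synthetic tests demonstrate.

## Uptake quantification

The standardized uptake value in a volume of interest (VOI) is

SUV = μ·W / (A_adm · e^(−0.693·Δt/T½)),

with μ the mean activity concentration (kBq/mL), W the patient mass in
grams at unit tissue density (1 g/mL, the standard convention, which makes
SUV dimensionless), A_adm the administered activity (kBq) and the
exponential correcting for tracer decay between injection and scan. The
⁶⁸Ga half-life defaults to 67.71 min and is configurable. The decay
constant is written with 0.693 rather than ln 2, matching the conventional
clinical formula; the difference is below 10⁻⁴ relative.

Lesion VOIs are segmented by a deterministic threshold isocontour: a
hill-climb from a user seed to the lesion's 26-connected local maximum,
then the 26-connected component of voxels at ≥ 50% of that maximum
(fraction configurable). The *local* maximum is used — a bright remote
structure must not set the threshold for a faint lesion; this mirrors how
clinical isocontour tools behave. VOIs are expected to be roughly 100 mm³
for comparability; volumes outside [50, 200] mm³ emit a warning, never an
error, since the target volume is approximate. An explicit-index entry
point (`manual_voi`) covers manually placed background regions. The spread
Δ_SUV is the population standard deviation of member voxels and the error
on the mean SUV is Δ_SUV/√N (the population/sample distinction is
immaterial at N ≈ 100). TNR = SUV_tumor / SUV_healthy, with the relative
errors combined in quadrature.

Voxel indexing is 0-based, physical coordinates refer to voxel centers,
and VOI volumes count whole voxels (no sub-voxel interpolation).

## Activity model

⁹⁰Y is a pure β⁻ emitter: half-life 64 h (mean lifetime 64/ln 2 ≈ 92 h),
endpoint 2.280 MeV, daughter Z = 40. The injection protocol defaults to
1.5 MBq/kg administered 24 h before surgery (105 MBq for a 70 kg patient).
The administered activity is decayed physically over the delay
(105 MBq → ≈ 80.9 MBq at 24 h) before rate prediction; a flag disables
this. Only physical decay is modeled — no biological washout term.

The diagnostic SUV (⁶⁸Ga-DOTATOC at ~60 min) is taken to equal the
⁹⁰Y-DOTATOC SUV at surgery time, the peptide being identical and the
tumor-to-background contrast near its maximum at ~24 h; a multiplicative
`biodistribution_factor` (default 1) is exposed for sensitivity analysis.
The tissue specific activity then follows by inverting the SUV formula:
c = SUV·A/W, numerically kBq/mL = Bq/mm³ at unit density.

## Monte Carlo probe model

Geometry (all coaxial with the probe axis, tissue below the probe face):

| element | dimensions | material, density |
|---|---|---|
| tumor remnant | ⌀ 6 mm × 7 mm, top face under the probe | tissue, 1.0 g/cm³ |
| healthy envelope | ⌀ 20 mm × 10 mm | tissue, 1.0 g/cm³ |
| sensitive element | r 2.55 mm × 3 mm deep | p-terphenyl, 1.23 g/cm³ |
| lateral shield ring | 3 mm thick around the sensitive element | PVC, water-equivalent at 1.4 g/cm³ |

The healthy envelope is deliberately small: electrons of these energies
travel at most ~11 mm in tissue, so decays farther away cannot reach the
detector and enlarging the envelope would only burn CPU.

Decays are generated uniformly in the source region with isotropic
directions. Kinetic energies are drawn (inverse-CDF on a 4096-point table)
from the allowed β spectrum N(T) ∝ p·E·(Q−T)²·F(Z,E) with the
nonrelativistic Coulomb correction F = 2πη/(1−e^(−2πη)), η = ZαE/p. The
spectrum's numeric mean is 0.947 MeV; the sampled mean is tested against
the integral. (⁹⁰Y's decay is first-forbidden unique; the allowed shape
used here is a deliberate first-order simplification, adequate for
feasibility ranking.)

Transport is analog and first-order: straight-line tracks with continuous
slowing down. The collision stopping power of liquid water (ICRU-37
values, 26 points, 10 keV–3 MeV) is log-log interpolated and integrated to
a cumulative CSDA range table (2000-point log grid; the residual range
below the 10 keV table floor, ≈ 2.5 µm, is added analytically). Ranges in
other materials scale inversely with density. The computed range at the
2.28 MeV endpoint is 11.4 mm in water; tests cross-check 0.1, 0.5 and
2 MeV against published CSDA ranges at 3%. Omitted on purpose: multiple
scattering, bremsstrahlung (≈ 0.1% probability at these energies), δ-rays,
and the reference detector's absolute calibration. Because scattering is
ignored, tracks are exact rays: a particle is counted when its ray enters
the sensitive cylinder (front disk or through the lateral shield ring)
with residual energy at or above the detection threshold, after
subtracting the mass thickness of tissue and shield crossed en route.
`probe_standoff` inserts extra tissue between source and probe face
(default 0, contact, for both scenarios — the intraoperative situation).

The detection threshold defaults to 50 keV of residual kinetic energy at
the sensitive-volume entrance (the probe's exact energy threshold is not
public); acceptance-level checks avoid depending on its exact value.

Each region is simulated once (default 10⁶ particles, vectorized numpy)
and the efficiencies ε (counts per decay, binomial error √(ε(1−ε)/n)) are
cached and reusable across a cohort, rates being linear in specific
activity:

R_T = c_T·V_T·ε_tumor + c_H·V_lat·ε_lateral,  R_H = c_H·V_H·ε_healthy,

with volumes in mm³ and c in kBq/mL (≡ Bq/mm³), so R is in counts/s. MC
errors are propagated linearly (the efficiencies are statistically
independent per region but conservatively summed).

Validation anchors: a point-like on-axis source with a monoenergetic beam,
zero threshold and an absorbing shield reproduces the analytic on-axis
disk solid angle Ω/4π = (1 − d/√(d²+R²))/2 within 3 binomial standard
errors at 10⁶ particles; the vectorized transport agrees event-by-event
with an independent scalar per-track tabulation at a fixed seed.

## Detection statistics

Counts in a dwell of t_probe seconds are Poisson, μ_T = R_T·t_probe and
μ_H = R_H·t_probe. At integer count threshold μ_th,

FP = P(X ≥ μ_th | μ_H),  FN = P(X < μ_th | μ_T),

evaluated through scipy's Poisson survival/distribution functions
(regularized incomplete gamma — stable at large μ; term-by-term summation
is kept as a test oracle for μ ≤ 50). Conventions: μ_th = 0 gives FP = 1
and FN = 0 (empty sum); raising μ_th lowers FP and raises FN; and
FP + FN = 1 identically when μ_T = μ_H, which is why a unit TNR can never
satisfy FN < 5% together with FP ≤ 1%.

The minimum probing time scans a grid (default 0.1–60 s in 0.1 s steps)
in ascending order; at each time the threshold is the smallest integer
with FP ≤ 1% — the "approximately 1%" criterion is operationalized as an
upper bound, which makes the search deterministic — and the first time
where additionally FN < 5% (strict, as are all inequalities here) is
returned with the achieved operating point. Infeasibility within the grid
is reported explicitly, never silently dropped.

The ROC at a fixed dwell (default 3 s, the empirical minimum a surgeon
spends per spot) sweeps integer thresholds up to
N_max = ⌈μ + 10√μ + 20⌉ (tails beyond < 10⁻⁹), plotting
TPR(th) = P(X ≥ th | μ_T) against FPR(th) = P(X ≥ th | μ_H), with closed
endpoints (0,0) and (1,1). The AUC is trapezoidal, which for a discrete
ROC equals the Mann–Whitney statistic P(X > Y) + ½P(X = Y); tests verify
agreement to 10⁻¹⁰. A patient is labeled Good iff AUC > 0.95 (strict).

## Synthetic cohort and phantom

Per-patient uptake values are not public; only cohort summaries are:
tumor SUV median 12.4 (IQR 5.5–23.2), healthy pancreas 2.4 (1.9–2.9), TNR
4.9 (2.2–12.2), n = 30. The generator draws tumor SUV and TNR from
lognormal marginals (both quantities are positive and strongly
right-skewed, with tumor SUVs spanning below 2 to above 100) and derives
healthy SUV = tumor SUV / TNR. A two-parameter lognormal reproduces a
median and quartile *ratio* exactly; with asymmetric printed quartiles
the individual quartiles are matched as closely as two parameters allow.

Two calibration subtleties:

* **Visibility truncation.** The cohort contains only PET-visible lesions,
  so TNR draws ≤ 1 are rejected. The printed quantiles describe that
  observed (truncated) population; fitting the plain lognormal and then
  truncating would inflate the generated median by ~18%. The TNR marginal
  is therefore calibrated so that its left-truncation at 1 matches the
  printed median and quartile ratio (`fit_lognormal_truncated`, solved by
  nested bisection). The generated cohort's TNR median is 4.9 by
  construction, and the implied healthy-SUV median lands at ≈ 2.3, within
  10% of the printed 2.4.
* **Independence.** Tumor SUV and TNR are sampled independently by default
  (their joint distribution is not published); a Gaussian-copula rank
  correlation knob is exposed, defaulting to 0. Healthy SUV being derived,
  its distribution is a consequence, checked for consistency, not matched.

Masses are normal (70 ± 12 kg) truncated below 30 kg. Per-patient SUV
errors are assigned at a fixed 5% relative size, emulating the VOI
statistical error scale.

The phantom builder voxelizes a hot sphere in a warm background, then
optionally applies an isotropic Gaussian PSF (FWHM in mm) and Gaussian
noise with variance proportional to the local mean (a common surrogate
for reconstructed-PET noise), clipping negatives. Ground truth (true
SUVs, TNR, lesion mask) is returned alongside. What passing phantom tests
show: the segmentation + quantification chain is unbiased on clean,
plateau-lesion inputs (recovery within 1%). What they do not show:
robustness to partial-volume bias on small lesions, scanner-specific noise
correlations, or reconstruction artifacts — all out of scope.

## Pipeline and reproducibility

`run_feasibility` chains cohort acquisition (CSV or synthetic) → MC
efficiencies → per-patient rates → minimum probing time → ROC/AUC →
summary (medians/IQRs per column; counts and fractions of patients
detectable within configurable cut-offs, default 3 s and 5 s — the
surgeon-reaction-time scale and a comfortable margin). Child seeds for the
cohort and MC stages are spawned from the global seed via numpy's
`SeedSequence`, so stages re-run in isolation reproducibly and reports are
byte-identical across runs at a fixed configuration. Reports are emitted
as CSV rows and a JSON bundle echoing the full configuration.

Default problem sizes: 10⁶ MC particles per region for production runs
(seconds, vectorized); tests and examples use 2×10⁴–10⁶ as appropriate to
the check; the cohort calibration checks use 10⁴ synthetic patients.

## Known limitations

* The MC is first-order (no scattering): efficiencies are geometric upper
  bounds at the few-percent level and the absolute rate scale is not
  calibrated against a physical detector; conclusions should be read as
  feasibility rankings, not absolute count predictions.
* The allowed-spectrum approximation ignores the first-forbidden shape
  correction of ⁹⁰Y (mean energy 0.947 vs 0.934 MeV with the correction).
* The diagnostic-to-therapeutic SUV transfer assumes identical
  biodistribution; the factor is exposed but defaults to 1.
* The cohort generator reproduces marginals, not the unpublished joint
  tumor-SUV/TNR structure; summary statistics driven by the joint (e.g.
  the exact count of slow-to-detect patients) are therefore indicative.
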