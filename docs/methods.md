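# Methods

## Signal model and its assumptions

The package models the steady-state magnitude signal of a spoiled 3-D
gradient-recalled echo (3DT1TFE / SPGR) acquisition as

    S(T1) = k (1 − E) sin θ / (1 − E cos θ),   E = exp(−TR / T1),

with TR in ms, flip angle θ accepted in degrees at every interface
(converted internally), and k a lumped scanner constant absorbing
receiver gain, proton density and coil sensitivity. Assumptions:

- **TE ≪ T2.** TE is stored for provenance but never used; no T2*
  decay term. This holds for the default acquisition (TE = 3.6 ms)
  against brain T2 values of tens of ms.
- **Ideal spoiling, uniform B1.** The nominal flip angle is taken as
  the actual one everywhere; B1 inhomogeneity correction is out of
  scope.
- **Single global k.** Proton-density and coil-sensitivity differences
  between tissues are folded into one constant. The phantom's
  per-class `proton_density_factor` exists to *measure* the bias this
  introduces (set it ≠ 1 and inspect the class recovery error), not to
  correct it.

For 0 < θ ≤ 90° the signal is strictly decreasing in T1, so inversion
is unique and closed-form: u = S/(k sin θ), E = (1 − u)/(1 − u cos θ),
T1 = −TR/ln E, valid when 0 < E < 1. Signals outside that range (zero
or negative intensity, intensities above the T1→0 limit) map to a NaN
sentinel and a False entry in the validity mask. They are never clamped,
because clamping would bias ROI means invisibly; on-disk maps keep the
NaN and ship a saved validity mask alongside.

## Calibration

k is fitted to one or more reference tissues with literature T1 and a
measured mean ROI intensity, minimizing Σᵢ (Sᵢ − k fᵢ)² with
fᵢ = S(T1ᵢ; k = 1); the minimizer is k = Σ Sᵢfᵢ / Σ fᵢ². With the usual
two references (normal-appearing white matter, 810 ms; gray matter /
Heschl gyrus, 1350 ms — 3 T literature values, configurable) the single
scale is overdetermined; the design choice here is a *joint* least
squares rather than per-tissue fits averaged afterwards, because it is
deterministic, symmetric in the references, and reports per-reference
residuals from which model violation (e.g. a genuine proton-density
difference between WM and GM) is visible. With one reference the
residual is exactly zero. Calibration is scale-equivariant: scaling all
intensities by c scales k by c and leaves every inverted T1 unchanged,
which is what makes maps from different sessions of the same protocol
nominally comparable despite arbitrary intensity units.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| TR | ms | 8 | default 3 T 3DT1TFE protocol |
| TE | ms | 3.6 | informational only (TE ≪ T2) |
| flip angle | degrees | 15 | default protocol; any value in (0, 90] |
| WM reference T1 | ms | 810 | 3 T literature value for NAWM |
| GM reference T1 | ms | 1350 | 3 T literature value (Heschl gyrus) |

Reference masks are user input (no segmentation engine in scope),
interpreted as > 0.5 after casting to real so probabilistic masks work.
Masks must be voxel-aligned with the image; no resampling is performed.
ROI SDs use the sample (n − 1) denominator.

## The phantom

`generate_phantom` builds nested ellipsoids — GM shell, WM interior,
CSF core (default 4000 ms, a standard 3 T value), background zero —
with optional spherical lesions (default T1 1040 ms, in the chronic
black-hole range) rejection-sampled wholly inside WM; placement failure
after a bounded number of attempts is an explicit error. The signal is
the exact forward model times the class proton-density factor
(default 1.0), noiseless; `add_noise` then adds Gaussian or Rician
noise at a stated SNR, defined on the noiseless WM class signal for
phantoms. Rician noise is the magnitude of (S + N(0,σ)) + i·N(0,σ),
σ = reference/SNR — positively biased at low signal, which is why noisy
CSF and background recover worst. All randomness flows through
`numpy.random.default_rng(seed)`; seeds are mandatory in specs and
identical specs give bit-identical phantoms.

What the phantom deliberately lacks: anatomy, partial-volume voxels,
bias fields, motion, multi-coil noise correlation. Passing tests
therefore demonstrate the correctness of calibration + inversion and
robustness to independent voxel noise, not robustness to the
segmentation and inhomogeneity errors of real scans.

## Cohort simulation

`simulate_cohort` emulates a two-timepoint longitudinal design:
default n = 20 subjects over a 36.6-month interval, GM volume change
−2.24%, WM −0.34%, thalamus −3.60%, corpus callosum −5.26%, stable T2
lesion volume, GM T1 +6.06% and lesion T1 +2.64%, baseline means and
spreads matching a natalizumab-treated relapsing-remitting MS cohort
(GM ≈ 798,000 mm³, median T2 lesion load ≈ 7.4 cm³, median age ≈ 39.5
years, race mix 50/45/5). PBVC follows the fixed sign convention
*negative = volume loss* and is generated as
intercept + slope·(age − mean age) + noise, default slope −0.05 %/yr
(older subjects lose more volume). Changes are exact when noise is
zero, so generator correctness is testable to machine precision.

## Statistics

Paired Student's t (two-sided) on follow-up − baseline differences;
zero-variance differences return an explicit degenerate flag instead of
an infinite t. Spearman's rank correlation uses average ranks for ties
with the t-approximation p-value; constant inputs are degenerate.
PBVC regression is OLS with intercept and 95% CIs, univariate (each
term separately) or multivariate (jointly); a categorical race column
is encoded as indicator contrasts against the largest category, and a
rank-deficient design raises a collinearity error rather than fitting.
No multiple-testing correction and no automated normality gate are
applied; the `stats` command notes this in its help text. These steps
are delegated to scipy.stats and statsmodels; the test suite
cross-checks them against hand-written textbook formulas (paired-t
ratio, average-rank correlation, normal-equations OLS) to 1e−8.

## Numerical choices

- Inversion is closed-form, not iterative; the suite verifies it
  against a bisection root-finder to < 1e−6 ms over [100, 5000] ms.
- The invalid sentinel is NaN in float maps (with the validity mask
  saved next to the map); in-memory code treats NaN input voxels as
  invalid rather than erroring.
- Problem sizes in tests: 64³ phantoms for end-to-end gates (noiseless
  recovery to < 1e−6 ms; Rician SNR = 40 class means within 2% over 10
  seeds, an internal gate on ROIs ≥ 500 voxels), 32–48³ elsewhere —
  large enough for stable ROI statistics while keeping the whole suite
  in a few seconds.
- Two targets in `scripts/acceptance.py` rerun the calibrate-then-
  invert round trips (single-reference WM with a seed-drawn k; joint
  two-reference fit at k = 100, inverting the GM signal).

## Known limitations

- A single k cannot represent tissue-dependent proton density or
  receive-field variation; the residuals and the phantom's
  proton-density dial quantify, but do not remove, that bias.
- Input volumes are assumed bias-field corrected; no registration
  between timepoints, lesion segmentation, or DICOM ingestion.
- Accuracy inherits everything the reference masks get wrong: a
  contaminated NAWM/NAGM ROI shifts k and hence every voxel's T1.
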