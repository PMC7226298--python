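# Methods

This note records the models, estimator conventions and design choices
behind `hdlflux`, in the spirit of a statistical-methods appendix.  It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Labeling model

### Body water

Body water is a single well-mixed pool of volume `TBW = f_tbw · weight`
(default `f_tbw = 0.35` L/kg, appropriate for an overweight cohort and
configurable) with first-order turnover `r` (default 0.10/day).  Dosing
follows the study protocol: a loading dose of 4.0 mL ²H₂O/kg (70 atom-%
²H₂O) split into five hourly boluses, then daily maintenance doses of 10%
of the loading volume.  Boluses are instantaneous; a dose at time `t_d`
contributes to samples strictly after `t_d`, so the t = 0 draw is a clean
pre-dose baseline.  Maintenance doses are modeled one hour before each
daily draw (the evening dose preceding a fasted morning sample), which
places the daily samples in the observed 0.80–0.90% band.  With
maintenance exactly offsetting turnover, the plateau reduces to the mass
balance `dose · atom fraction / TBW` = 0.80% at the defaults.  Neither
total body water nor water turnover is identifiable from the data the
pipeline sees, so the dose-to-plateau mapping is a calibrated convention,
not a derived quantity; only the plateau itself enters the kinetics.

The "plateau MPE" used downstream is the time-averaged enrichment of all
samples from 5 h (one hour after the last loading dose) onward.

### Peptide spectra

A peptide's baseline spectrum is its natural-abundance mass-isotopomer
distribution (MID), computed by convolving per-element isotope vectors
(IUPAC 2021 abundances, configurable) over the elemental composition,
truncated to 6 peaks and renormalized.  Compositions come from
pyteomics; carbamidomethyl-cysteine (+C2H3NO) is available as the fixed
modification of the workflow.

A newly synthesized molecule incorporates deuterium at `N` effective
exchangeable positions, where `N` is the residue-wise sum of a shipped
incorporation table (Ala 4.0, Gly 2.06, Ser 2.61, …; replaceable by the
user — all N-dependent results reproduce under a supplied table).  The
deuterium-count distribution at water enrichment `p` is a generalized
binomial in the real-valued `N`, so the unlabeled fraction is exactly
`(1−p)^N`; the labeled MID is the baseline convolved with it (truncation
mass is folded into the last peak, keeping rows summing to one without
rescaling M0).  The spectrum at time `t` is the mixture
`(1−f)·baseline + f·labeled` with `f = 1 − e^{−kt}`; the body-water
plateau is used for `p` throughout (the sub-5-hour rise of body water is
ignored — its effect on the earliest, near-zero enrichment points is far
below measurement noise).

Measurement noise is additive Gaussian on M0 (balanced on M1 so rows
still sum to one), with SD expressed as a fraction of the plateau M0
depletion; every time point carries two injection replicates, averaged
with a 2%-agreement flag, as in the protocol.  Between-subject spread of
true rate constants is mean-one lognormal (keeps k > 0), with CV taken
per protein and group from the published half-life SD/mean unless
overridden.

### Enrichment convention

Net labeling is monoisotopic depletion, `E(t) = A0(0) − A0(t)` — the
standard readout for heavy-water proteome dynamics.  Negative noisy
values are retained for fitting; during plateau normalization they are
floored at −0.5·E_as for stability.

## 2. Kinetic estimation

### Exponential (rise-to-plateau) fit

`E(t) = E_as (1 − e^{−kt})` is fitted by bounded nonlinear least squares
(k ∈ (1e-4, 50]/day, E_as ∈ (0, 1]; 2.0 for plateau-normalized protein
curves; 0.5 for cholesterol), with multistart at
`k₀ ∈ {ln2/T_last, ln2/T_mid, ln2/(0.1·T_last)}` and `E_as₀ = max E`.
Unweighted least squares is the default (no weighting is specified for
this assay; noise is approximately homoscedastic on the enrichment
scale).  One outlier pass removes points with |studentized residual| >
2.5 (internally studentized via the local Jacobian's hat matrix; never
more than 20% of points), followed by a single refit.  Fits with final
R² < 0.95 are flagged excluded at the peptide level; protein-level and
cholesterol R² are reported but not used for exclusion.  The 95% CI on k
comes from the Jacobian covariance with a t quantile.

Identifiability is the binding constraint of this design: with the
one-week schedule, the (k, E_as) profile is a ridge once `kT ≲ 1`.  At
k = 0.16/day and 3.5% effective noise the Cramér–Rao bound on sd(k)/k is
~32% (and ~67% at k = 0.1/day); the implementation sits at the bound
(verified by Monte Carlo in the test suite), so reported per-subject
rates at the slow end carry this irreducible spread.  Slower analytes
are not meaningfully fit this way at all, which is what the
precursor–product route is for.

### Peptide → protein aggregation

Each accepted peptide curve is normalized by its own fitted plateau,
normalized curves are averaged per time point, and the exponential model
is refit on the aggregate (plateau expected ≈ 1, bound 2).  A protein
with no accepted peptides is reported unquantified, never silently
dropped.

### Precursor–product (initial-slope) route

For slow proteins the labeling slope from ordinary linear regression of
raw enrichment on time is divided by the linearized asymptote
`A0 · N · p`.  Because the rise curve is concave, a slope over
appreciably labeled points underestimates the rate: on the full one-week
schedule a t½ = 261.6 h protein would be biased ~18% low.  The
regression is therefore restricted iteratively to the quasi-linear
window with estimated cumulative labeling `k·t ≤ 0.1` (at least five
points kept).  For genuinely slow analytes all points satisfy the window
and the estimate is the plain regression slope.  Residual systematic
error is ~3% window curvature plus `(N−1)p/2` from the linearized
asymptote (≈1.5–2% for the low-N peptides used for the PON1-like
protein); both are inside the 15% acceptance band for this route and are
visible in the noiseless round-trip tests.

Method selection: the slope route is chosen when the preliminary
exponential fit indicates a half-life beyond the labeling window
(default 7 days) or an unidentifiable rate (CI spanning zero, or fit
failure).

### Derived quantities

`t½ = 24·ln2/k` hours, residence time `1/k` days — exact identities
asserted to 1e-9.  Cholesterol pool size uses plasma volume = 4.5% of
body weight, giving `pool (mg/kg) = 0.45·[HDL-C] (mg/dL)` and
`PR = pool·FCR` (mg/kg/day; the mass-unit convention of the kinetic
tables).  Protein FCRs on association surfaces are expressed per hour —
the only unit convention under which the published regression slope of
FCR on HbA1c (0.005 per percentage point) is consistent with the group
half-life contrast (ln2/91.9 h → ln2/51.9 h over ≈1 HbA1c point).
Steady state (FCR = FSR) is assumed, not tested.

## 3. Statistics

Group comparisons: Yuen's test on 20%-trimmed means with winsorized
variances and a symmetric percentile bootstrap (2000 replicates, seeded)
for protein half-lives; the unpaired Welch t-test for cholesterol
kinetic parameters — the two conventions of the respective report
tables, configurable per table.  `trim = 0` reduces Yuen's statistic to
Welch's t (bootstrapped), and the empirical size is 0.05 ± 0.02 under a
simulated null (asserted in the acceptance suite).

Associations: Wilcox's percentage-bend correlation (β = 0.2; exactly
Pearson at the β = 0 no-bend limit; p from the t approximation with
n−2 df; case-bootstrap CI) and Theil–Sen regression (median of pairwise
slopes, ties in x skipped, median-residual intercept; case-bootstrap
percentile CI on the slope).  The point estimator is
`scipy.stats.theilslopes(method="joint")`; tests verify it against a
brute-force pairwise-slope median.  HOMA-IR uses the standard fasting
formula glucose·insulin/405.

No multiple-testing correction is applied anywhere (single-contrast
α = 0.05); every report surface carries this note explicitly.

## 4. What the simulator does and does not emulate

The generator reproduces the study's structure: group sizes (8 control /
9 T2D), the 12-point schedule (0–10 h, days 1–7), the body-water
plateau band, duplicate injections, peptide-level intensity and
identification-score QC windows, covariate marginals per group (median,
min, max through a piecewise-linear quantile map under a Gaussian
copula), the configured covariate couplings (HbA1c and insulin on
glucose; LCAT inversely on glucose; CETP inversely on adiponectin within
the T2D arm), and the coupling of ApoA-II/ApoA-IV degradation to HbA1c
as one global linear relation in per-hour FCR.

It does not emulate: chromatographic peak shapes or raw spectra,
isotope fine structure, co-eluting envelope interference, retention-time
drift, heteroscedastic or correlated residuals, missingness beyond an
optional per-timepoint dropout, glycated proteoforms, or real peptide
identities — the shipped peptide sequences are synthetic tryptic-style
stand-ins with realistic compositions (hydrophobic, low-N stand-ins for
PON1), clearly labeled as such in the config.  Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to every artifact of real LC-MS data.

## 5. Numerical and reproducibility choices

* All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; identical configs produce byte-identical
  outputs (asserted).
* MID truncation at 6 peaks; convolution by binary exponentiation;
  enumeration oracle agreement to 1e-9 for small compositions.
* Degenerate inputs raise typed errors (invalid parameter/sequence,
  degenerate calibration or data, missing data) rather than producing
  NaNs; fit failures return a diagnostic result object, never an
  unhandled exception.
* The recovery harness (`hdlflux.recovery`) reports group-level
  quantities as grand means over independent cohort replicates —
  12 cohorts for cholesterol FCR, 6 for protein half-lives — because a
  single 8-subject group mean at k = 0.16/day carries ~11% Monte-Carlo
  SE at the information bound; replicate averaging estimates the same
  expectation with ~3% error.  Group sizes, schedule and noise levels
  are never altered.

## 6. Known limitations

* Free-plateau rate estimates below ~0.3/day are information-limited on
  this schedule (§2); group means of such rates inherit heavy-tailed
  per-subject spread, and mean residence times (1/k) are
  correspondingly upward-biased on noisy data.
* The precursor–product route carries a small deterministic
  underestimate of k (window curvature + linearized asymptote), i.e. a
  few percent overestimate of slow half-lives.
* The R² ≥ 0.95 exclusion is applied at the peptide level only; its
  selection effect under heavy noise slightly tightens apparent
  precision.
* Sex-adjustment of HDL levels is not modeled; report surfaces carry
  unadjusted values.
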