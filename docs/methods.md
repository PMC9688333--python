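# Methods

## Problem setting

Label-free SERS of biofluids produces, per subject, hundreds of mapping
spectra (one per substrate location/spot) over the 700–1800 cm⁻¹ Raman
shift range. Two nuisance structures dominate raw acquisitions: a broad
autofluorescence background that overlaps and often exceeds the Raman
signal, and occasional single-bin cosmic-ray spikes. The analytical task
is binary discrimination of subject groups (cancer vs control) from the
735–1700 cm⁻¹ fingerprint window, plus identification of the wavenumber
bands that carry the discrimination.

## Data model and containers

All analysis runs on a `SpectralDataset`: an (n spectra × p wavenumbers)
matrix on one shared, strictly ascending wavenumber grid, with
per-spectrum subject id, class label and mapping-location annotations.
The canonical grid is 700–1800 cm⁻¹ at 1 cm⁻¹ spacing (1101 points);
instrument exports on other grids are linearly interpolated onto it
(never extrapolated). Linear interpolation is the smallest assumption and
is exact for locally affine intensity profiles at this spacing. The
instrument's native spacing is not standardized across vendors; the
1 cm⁻¹ grid is a package convention, chosen so matrices align across
subjects.

## Preprocessing chain

Per spectrum, in order:

1. **Despike.** Bins whose modified z-score (median/MAD) of the second
   difference exceeds 8 are replaced by linear interpolation of unflagged
   neighbours. Despiking precedes baseline fitting so a spike cannot drag
   the baseline. If more than 5% of bins are flagged the input is
   rejected as pathological rather than spiked. For Gaussian noise the
   modified z of the second difference is approximately standard normal,
   so the default threshold of 8 flags essentially nothing in clean data.
2. **AsLS baseline subtraction.** The baseline z minimizes
   `Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²` with `w_i = p` where `y_i > z_i`
   and `1 − p` otherwise, iterated from uniform weights until the weights
   are stable (relative change < 1e-6) or 15 iterations. Defaults
   λ = 1e5, p = 0.01 — standard magnitudes for Raman autofluorescence:
   λ sets the baseline stiffness relative to a 1 cm⁻¹ grid (larger =
   smoother), and small p makes the baseline hug the lower envelope so
   peaks are preserved. Numerically the pentadiagonal system is solved
   banded (Cholesky) for the *deviation* e = z − y, i.e.
   `(W + λDᵀD) e = −λDᵀD y`, with one iterative-refinement step. The
   deviation form keeps rounding proportional to the peak heights rather
   than the total intensity and reproduces affine inputs exactly (for
   them `DᵀD y = 0`).
3. **Savitzky–Golay smoothing.** Window 11, polynomial order 3 (the
   source protocol does not report its values; these preserve the
   narrowest ~10 cm⁻¹ Lorentzian bands while suppressing bin-level
   noise). Edges use polynomial extrapolation of the terminal windows, so
   polynomials up to the filter order are reproduced exactly everywhere.

Dataset-wise: crop to the closed interval [735, 1700] cm⁻¹ (966 points
on the canonical grid), then divide each spectrum by its own mean
intensity. "Mean normalization" is read as division by the per-spectrum
mean; a no-op alternative (`normalize: none`) is exposed in the config.
Column mean-centering is *not* part of the preprocessing chain: it is
fitted on training folds only, inside cross-validation, and applied to
held-out rows, to avoid information leaking from test subjects into the
training column means.

## PLS-DA

PLS1/NIPALS against a 0/1 response (1 = case group), as single-response
binary problems do not need the multi-response PLS2 machinery. The
centered training matrix and response are deflated component by
component; weights are unit-norm and training scores come out mutually
orthogonal (asserted to 1e-8 in tests). Prediction centers new spectra
with the stored training means, applies `B = W (PᵀW)⁻¹ q` and adds back
the training response mean; the decision threshold is 0.5, the midpoint
of the class codes. At full rank the fit coincides with the
least-squares projection of the response onto the column space — one of
the test oracles.

The number of latent variables A is not a quantity the source protocol
fixes; by default it is selected per training fold by an inner
subject-stratified 5-fold cross-validation over A ∈ 1..10, maximizing
held-out spectrum-level accuracy with ties going to the smallest A. A
fixed A can be supplied instead (the fast path used by most tests).

## VIP scores and bands

The Wold formulation: `VIP_j = sqrt(p · Σ_a SS_a (w_aj)² / Σ_a SS_a)`
with `SS_a = q_a² t_aᵀt_a` the response sum of squares captured by
component a. The identity `mean(VIP²) = 1` makes 1 the natural
importance threshold; discriminative bands are reported as maximal
contiguous grid runs with VIP > 1, as closed intervals at grid
resolution (no sub-bin interpolation), with an optional minimum-width
filter counting a single 1 cm⁻¹ grid point as width 1.

Recovered and injected band sets are compared by Jaccard overlap after
dilating both sets by an edge tolerance (5 cm⁻¹ in the tests), since
band edges are only defined to roughly the linewidth.

## Cross-validation and ROC

Mapping spectra are pseudo-replicates of their subject, so folds are
built over *subjects*, stratified by class (seeded shuffle within class,
round-robin deal; per-fold class counts within ±1 subject of
proportionality), and every spectrum travels with its subject. A
spectrum-level split would place near-copies of the same subject in
training and test and inflate every metric; an assertion in the CV loop
guards against subject leakage on every run. Spectrum-level evaluation
remains available behind a flag for comparison.

Subject-level prediction is the mean of the subject's continuous spectrum
scores (not a majority vote), which stays threshold-compatible with ROC
analysis. Sensitivity is defined with the cancer group as positive. ROC
curves sweep all distinct score thresholds, stepping diagonally through
ties, which makes the trapezoidal AUC equal the tie-corrected
Mann–Whitney statistic (a test oracle). Fold averaging is vertical:
each fold's TPR is interpolated on a fixed FPR grid (0 to 1, step 0.01,
duplicate-FPR points collapsed to their upper envelope) and averaged
point-wise; the mean AUC is the arithmetic mean of fold AUCs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Peaks.** Lorentzian line shapes (the standard Raman profile),
  default fwhm 10–20 cm⁻¹ depending on the band, base amplitudes
  150–600 counts. Class differences are multiplicative per-band factors;
  the lung-vs-control scenario injects factors 1.3–1.6 at the
  discriminative fingerprint bands (1002, 1068, 1168, 1198, 1310, 1398,
  1432, 1558, 1590 cm⁻¹), the all-cancer scenario at its own band set
  (887, 959, 1008, 1078, ~1145, 1222, 1325, 1655 cm⁻¹).
- **Background.** A subject-jittered sum of three Gaussians with fwhm
  ≥ 300 cm⁻¹ and total amplitude ~2000 counts, so autofluorescence
  dominates the Raman signal as it does in raw acquisitions.
- **Noise and spikes.** iid Gaussian noise (sd 20 counts) and
  Poisson-rate cosmic spikes (0.05 per spectrum), single-bin, positive,
  10–50× the noise sd.
- **Subject effect.** A log-normal multiplicative gain per subject
  (log-sd 0.15), because SERS enhancement varies with substrate spot —
  a multiplicative, not additive, phenomenon.
- **Protocol.** Defaults of 500 spectra per subject over 3 mapping
  locations match the acquisition protocol the analysis is designed for;
  tests and examples scale the spectrum counts down (4–50 per subject)
  to keep runs short, which leaves the per-spectrum structure unchanged.

The generator returns the injected effect intervals (center ± fwhm/2) as
ground truth. Intensity units and SNR are package choices — no
calibrated values exist for this setting; what matters for the method's
behaviour is the ratio structure (baseline ≫ peaks ≫ noise).

All randomness is PCG64 seeded from a single integer; identical configs
give bit-identical datasets. In the case-study pipeline every stage seed
derives from the one top-level seed keyed by stage name.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the pipeline recovers known, injected
structure under the assumed noise model: multiplicative class effects on
Lorentzian bands under a smooth dominant background. Real pleural-fluid
SERS differs in ways the generator does not attempt: correlated
biochemical changes across many bands, substrate batch effects,
heteroscedastic detector noise, drift within a mapping session, and
class overlap far larger than the injected effects. The perfect
cross-validated metrics on default scenarios therefore say the machinery
is correct, not that clinical discrimination is this easy; the clinical
headline numbers reported for this kind of study (accuracy ~0.85, AUC
~0.93) come from patient data that are not publicly available and are
not reproduced here.

A second caveat is normalization closure: after per-spectrum mean
normalization the rows sum to a constant, so a genuine intensity
increase at one band necessarily depresses all other signal-bearing
channels of that class. VIP then legitimately flags class-neutral bands
as (anti-)discriminative. The default scenarios place effects on every
simulated band — matching the band tables of the comparisons they
emulate — so ground-truth recovery is well-defined; a dedicated test
documents the closure phenomenon itself.

## Numerical choices

- AsLS: banded Cholesky (`solveh_banded`) on the deviation form with one
  refinement step; stopping by weight stability (tol 1e-6) or 15
  iterations. Baseline roughness is non-increasing in λ (property test).
- Savitzky–Golay: `mode="interp"` edge handling; linearity and
  polynomial reproduction are property-tested.
- PLS: deflation stops with an informative error naming the achievable
  rank if the response covariance is exhausted before the requested A.
- ROC ties: simultaneous TP/FP steps (diagonal segments), giving exact
  Mann–Whitney agreement.
- Degenerate inputs (single-class folds, empty crops, nonpositive row
  means, subjects with conflicting labels) raise errors naming the
  offending unit rather than propagating NaNs.

## Cohort fixture

The subject roster of the emulated study ships as a data fixture:
34 subjects — 15 lung cancer, 7 other cancers (1 breast, 1 ovarian,
1 peritoneal, 2 malignant mesothelioma, 1 multiple myeloma, 1 lymphoma),
12 controls (8 exudate, 4 transudate). The lung-vs-control case study
defaults to 12 lung / 11 control subjects, following the cohort actually
analyzed in that comparison (two figure captions of the source study
disagree with its roster table on this; the package keeps the roster in
the fixture and the 12/11 split in the scenario default). The
all-cancer-vs-control grouping yields 22 cancer vs 12 control subjects.
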