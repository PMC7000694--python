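# Methods

This note documents the models, estimators, numerical choices and known
limitations of `flimspine`, in the spirit of a statistical-software methods
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Decay model

A donor fluorophore population is a two-component mixture: free donor with
lifetime τ_D and donor bound to acceptor (undergoing FRET) with lifetime
τ_AD < τ_D.  The TCSPC histogram of a region is modelled as

F(t) = F0 [ P_D H(t; t0, τ_D, τ_G) + P_AD H(t; t0, τ_AD, τ_G) ],
P_D + P_AD = 1,

where H is a single exponential convolved with a unit-area Gaussian
instrument response of width τ_G:

H(t; t0, τ, τ_G) = ½ exp(τ_G²/(2τ²) − (t−t0)/τ) erfc((τ_G² − τ(t−t0)) / (√2 τ τ_G)).

Properties used throughout (and verified by quadrature in the tests):
∫H dt = τ, and the normalized kernel's mean is t0 + τ.  One widely printed
form of this kernel writes the exponent's decay constant with a stray
subscript ("τ_i"); only reading it as the kernel's own τ makes H equal the
exponential ⊗ Gaussian convolution, so that is what is implemented.

**Numerical stability.** For erfc arguments x ≥ 0 the kernel is evaluated
as ½ erfcx(x) exp(−(t−t0)²/(2τ_G²)), using the identity
exp(τ_G²/(2τ²) − (t−t0)/τ − x²) = exp(−(t−t0)²/(2τ_G²)); this avoids the
overflow of the leading exponential against the underflow of erfc.  For
x < 0 the direct product is safe (erfc ≤ 2, negative exponent).  The kernel
is finite and non-negative for all arguments (property-tested).

## Calibration

τ_D = 2.6 ns (free eGFP) and τ_AD = 1.1 ns (donor bound to acceptor) are
treated as fixed calibration constants; population fits keep them frozen
for stability and only F0, P_AD, t0 and τ_G are free (any subset can be
frozen too).

## Population fit

Expected counts per TCSPC bin are the integral of F over the bin, computed
by a composite midpoint rule with sub-steps ≤ 0.02 ns (ten evaluations per
bin at the default 64 bins / 12.5 ns).  The default objective is the
Poisson negative log-likelihood — the correct noise model for photon
counting — with Neyman-weighted least squares available for comparison.
Because F is linear in F0, the amplitude is profiled out in closed form
(Poisson: F0 = Σk/Σg) and the optimizer (bounded quasi-Newton) works only
on the O(1)-scaled shape parameters, which makes convergence robust and
deterministic.  Initialization is fixed: t0 from the leading-edge
half-maximum of the histogram, τ_G = 0.2 ns, P_AD = 0.2, F0 from the total
count; there are no random restarts, so refitting the same histogram gives
identical results.  Fits below 10³ photons are refused (configurable).
Goodness is the reduced Poisson deviance against the saturated model.

## Mean arrival time, lifetime maps, and the offset t0

Per pixel, ⟨t⟩ is the count-weighted mean of bin centres; the
discretization bias relative to the continuous mean is at most roughly
(bin width)²/(12τ) ≈ 1 ps at the defaults, far below photon noise.  Empty
pixels yield NaN, not errors.  The mean lifetime is ⟨τ⟩ = ⟨t⟩ − t0.

Two offsets are distinguished:

* **model t0** — the fitted arrival-time offset of the excitation pulse;
* **effective t0** — the model-predicted window mean arrival minus the
  model's true mean lifetime, `FitResult.t0_effective`.

The distinction exists because the TCSPC window is finite: at 12.5 ns
(80 MHz repetition rate) about 1.3% of τ_D photons arrive after the window
and are never recorded, which depresses the measured ⟨t⟩ by ≈ 0.15 ns.
Subtracting the *effective* offset cancels this truncation to first order,
so lifetime maps of a free-donor region read ≈ τ_D rather than ≈ 2.45 ns.

## ROI binding fraction

For a spine or dendrite ROI, all photons in the ROI are pooled into one
histogram before inversion.  Pooling-before-inversion equals summing the
ROI's photons (the physically measured quantity) and differs from averaging
per-pixel P_AD when the ROI is heterogeneous; the pooled estimate is the
photon-weighted one and is what this package reports.

The idealized closed-form inversion

P_AD = τ_D (τ_D − ⟨τ⟩) / [(τ_D − τ_AD)(τ_D + τ_AD − ⟨τ⟩)]

is the exact inverse of the intensity-weighted mixture mean
⟨τ⟩ = (P_D τ_D² + P_AD τ_AD²)/(P_D τ_D + P_AD τ_AD), decreasing from 1 to 0
as ⟨τ⟩ runs from τ_AD to τ_D.  Within a finite window [0, T] each component
is observed with kept fraction k_i = 1 − e^(−c/τ_i) (c = T − t0) and
conditional mean arrival μ_i = τ_i − c e^(−c/τ_i)/k_i beyond t0, so the
window-limited mixture mean is A = Σ P_i w_i μ_i / Σ P_i w_i with weights
w_i = τ_i k_i.  Solving for P_AD,

P_AD = w_D (μ_D − A) / [ w_D (μ_D − A) + w_AD (A − μ_AD) ],

which reduces *identically* to the closed form as T → ∞ (w_i = μ_i = τ_i).
`roi_binding_fraction` applies this finite-window inversion by default
(the binning is known from the container metadata); without it, estimates
at the default window would be biased upward by up to ≈ +0.17 at low P_AD —
larger than every effect of interest.  The Gaussian IRF's interaction with
the window edge and the bin-centre discretization contribute a residual
bias of order 10⁻³, measured in the tests.  Raw and [0, 1]-clamped values
are both returned; the pipeline consumes the clamped one, and the inversion
pole at A equal to the two-component crossing raises an explicit error.

ROI estimates below a photon minimum (default 100) return NaN and
propagate as gaps, never silently dropped frames.

## Synthetic experiments

The simulator is the package's ground-truth generator; its defaults are the
study conditions of a wild-type-like single-spine experiment.

**Scene.** A straight dendritic shaft (0.5 µm wide) crosses a 12.8 µm field
(128 px at 0.1 µm/px); spines are disks (radius ≈ 0.3–0.35 µm, ±5% seeded
jitter) attached by a 0.3 µm neck at given arc-length positions, the first
one stimulated and placed so ≥ 4.5 µm of shaft remains for spreading ROIs.
Structures are rendered as hard masks blurred by a 2-D Gaussian
(σ = 0.2 µm) — a lateral point-spread stand-in adequate for
integrated-intensity volume measures; no 3-D PSF is modelled.  Brightness
defaults (1800 photons/px per spine time point, 1400 for the shaft,
2 background; each "frame" being the usual 6-exposure average) put a few
times 10⁴ photons in a spine ROI per time point, the regime in which window
averages of ΔP_AD resolve programmed effects of a few 0.01.

**Program.** At the uncaging onset (a 30-pulse, 0.5 Hz train collapsed to a
single time; pulse-resolved dynamics are far below the frame rate) the
stimulated spine's volume scale jumps to 1 + transient amplitude (default
2.5, i.e. +150%) and relaxes exponentially (τ = 150 s) to 1 + sustained
amplitude (+40%).  The binding fraction follows the same form on top of a
0.12 baseline: ΔP_AD 0.08 transient relaxing (τ = 120 s) to 0.04 sustained.
Dendritic activation is separable: amplitudes scaled by e^(−d/2 µm) with
distance along the shaft from the spine base, onset delayed 120 s.  These
single-exponential and separable forms are the package's modelling choice —
experiments report only windowed means, not functional forms.  Programs
whose P_AD would exceed 1 are rejected at construction.

**Photons.** Pixel counts are Poisson with mean brightness × volume scale.
Each photon picks the bound component with probability
P_AD τ_AD / (P_D τ_D + P_AD τ_AD) — photon yield proportional to lifetime —
which is precisely what makes the photon-weighted mean lifetime equal the
intensity-weighted mixture mean that the closed-form inversion assumes, and
what makes the fitted amplitude fractions equal molecular fractions.
Arrival times are t0 + Exp(τ) + N(0, τ_G), binned into the TCSPC window;
out-of-window photons are dropped (no period wrap-around: the pseudo-
background from fold-back at the defaults is below the other neglected
terms).  Background photons are drawn as free donor (out-of-focus eGFP).
Intensity stacks distribute brightness across 3 z-planes by a normalized
Gaussian axial profile and average 6 independent exposures per plane.

**Randomness.** One root seed; per-frame child streams via seed sequences;
identical (config, seed) gives bit-identical output.  The seed and all
program parameters are recorded in the ground-truth sidecar.

**What the simulator does not emulate.** Drift and motion, detector
afterpulsing/dead time, acceptor photophysics and bleaching, real spine
morphology and 3-D optics, uncaging photochemistry and receptor kinetics.
Passing end-to-end tests therefore demonstrates correctness of the
estimators under the stated photon and geometry model, not robustness to
these instrumental effects.

**Acquisition defaults.** One frame per 30 s from −8 min to +25 min with
the frames during the uncaging train (0–58 s) skipped; 64 TCSPC bins over
12.5 ns; τ_G = 0.2 ns; t0 = 1.2 ns.  Analysis windows: basal [−8, 0] min,
volume transient [1, 3] min, binding-fraction transient [1.5, 3.5] min,
sustained [10, 25] min, all closed intervals on frame timestamps.  The
pre-stimulus baseline span (8 min) and all windows are configurable.

## ROI analysis conventions

Background for volume measurements is the per-plane mean over a user (or
phantom) background mask.  F can be ≤ 0 for pathological input and is then
surfaced to the caller, but a non-positive baseline F0 is an error.
Time courses report both absolute P_AD and ΔP_AD (change from the basal
mean); baseline levels themselves are compared across groups, so the basal
mean is kept on every time course.  Spreading profiles use disks of 1 µm
diameter centred on the dendrite path at arc-length offsets 0–4 µm from the
stimulated spine's attachment point (not its centroid), walking toward the
longer remaining stretch of shaft; pixels of any spine mask are excluded,
and clipping to a dendrite mask is optional.  ROIs are supplied manually or
taken from simulator ground truth — there is no automatic spine
segmentation.

## Exclusion rules and statistics

* **Baseline stability.** The fluctuation metric is the peak-to-peak range
  of the baseline ROI mean lifetime (an SD-based metric is available);
  records above 0.15 ns are excluded before analysis.  Raising the
  threshold can only retain more records (monotonicity is property-tested).
* **ROUT (Q = 1%).** For a column of values (location model, K = 1):
  robust location by iteratively reweighted least squares with Lorentzian
  weights w = 1/(1 + (r/s)²); robust scale RSDR = 68.27th percentile of
  |residuals| × n/(n−K); two-tailed p-values of the residual t-ratios
  (df = n−1); then the values are tested from the largest residual inward
  against α_i = Q·i/n, stopping at the first non-significant one.  The most
  extreme value faces the most stringent threshold, so clean Gaussian data
  are flagged only rarely while gross outliers are removed; decisions are
  invariant under affine maps of the data.  Constant data yield no
  outliers.
* **Health flags.** Subjective exclusions (blebbing, spine collapse) cannot
  be automated and enter as an explicit manual list.
* **Summaries and tests.** Mean ± SEM (SEM = sd/√n, ddof = 1; undefined for
  n = 1); unpaired two-tailed Student's t test with pooled variance
  (df = n₁+n₂−2), Welch by flag.  Two-way ANOVA with multiple-comparison
  correction for grouped spreading data is deliberately left to standard
  statistical software; this package produces its input tables.

## Containers and reproducibility

FLIM stacks live in an open HDF5 layout (schema version attribute; per-frame
count arrays with timestamps in signed seconds, t = 0 at the first uncaging
pulse) — vendor TCSPC formats are proprietary and out of scope.  Intensity
movies are shaped TIFF with JSON metadata, lifetime maps 32-bit float TIFF,
masks labelled integer TIFF, tables UTF-8 CSV with "." decimals.  Every run
writes a manifest with a configuration hash, package version and seeds but
no timestamps, so an unchanged (config, seed) rerun reproduces every output
byte for byte.  Readers reject unknown schema versions and name the missing
metadata field.

## Problem sizes

The shipped scenarios use a 128×128 field, 65 frames and ≈ 7×10⁷ photons
per simulated experiment (the small `smoke_test` scenario is 64×64 with
33 frames).  The validation suite runs ten such experiments end-to-end plus
sixty million-photon population fits; these sizes resolve the programmed
effects several-fold above their standard errors while keeping a full
validation run to a few minutes on one CPU.

## Known limitations

* The finite-window inversion assumes the binning metadata reflects the
  true measurement window and neglects the Gaussian IRF tail at the window
  edges (residual bias ~10⁻³ in P_AD at the defaults).
* Laser-period wrap-around is not modelled in fitting or simulation.
* No background/dark-count term in the decay model by default (the
  simulator's background photons are free-donor-like, a good description of
  out-of-focus eGFP but not of detector dark counts).
* Per-pixel lifetime maps use the idealized offset subtraction and are
  intended for display; quantitative claims should rest on ROI pooling.
* No registration, drift correction, spine tracking, phasor analysis, or
  >2-component decay models.
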