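# Methods

`nanotrack` analyses single-particle imaging of plasma-membrane proteins:
sparse diffraction-limited spots in TIRF-style movies are detected, linked
into trajectories, and summarized as diffusion coefficients, velocities,
dwell times, colocalization fractions, FRAP mobile fractions and FCS-based
surface densities.  Because raw imaging data of this kind is rarely
published, the package carries its own ground-truthed generator; every
estimator is validated by recovering the generator's parameters.

## Synthetic data model

Particles live on a 2D membrane patch and belong to one or more diffusive
populations.  Each population is specified by a lateral diffusion
coefficient `D` (µm²/s), a mixture fraction, a mean membrane dwell time
`τ` (s, exponential; infinite = never leaves), and a per-track integrated
spot intensity (gamma-distributed with given mean and CV).  Motion is pure
Brownian: per-axis increments are N(0, 2 D Δt).

Emitters are simulated on a margin-extended domain (≥ 10 px beyond the
camera frame on every side, configurable) with specular reflection at the
extended boundary.  Reflection preserves both particle number and the
uniform spatial distribution, so the in-frame density is stationary and
free of boundary depletion.  Disappearance (endocytosis) is an exponential
clock per track; appearance is a Poisson birth process with rate
(expected count)/(mean dwell), which keeps the expected population
constant.  Tracks overlapping the movie start or end are flagged censored.

Rendering integrates a symmetric 2D Gaussian PSF exactly over each pixel
(separable erf differences, window ±5σ, truncation error < 10⁻⁴ %), adds a
constant background, then applies Poisson shot noise followed by additive
Gaussian read noise (EMCCD convention: shot first, read second).  Default
calibration is 0.1 µm pixels, 0.1 s frames, PSF σ = 1.3 px — typical of a
100×/1.45 NA TIRF system; all three are config parameters because real
acquisitions vary.

What the generator does *not* emulate: EMCCD gain statistics, chromatic
offsets between channels, evanescent-field depth, blinking/photophysics
beyond a single bleach step, anomalous or confined diffusion, and sample
drift.  Passing tests therefore demonstrate estimator correctness under
the stated model, not robustness to every artifact of real microscopy.

### Two-channel fields

A fraction `f` of channel-B emitters are jittered copies of distinct
channel-A tracks (offset uniform in a 1-px disk); the remaining
`(1 − f)`-share diffuses independently.  `f = 1` makes channel B a
one-to-one copy of A, so a correct object-based colocalization measure
must read 100%; `f = 0` gives two independent fields whose overlap is the
nearest-neighbor chance level.

### FRAP experiments

At the bleach frame, every emitter inside a rectangular ROI goes dark with
probability `bleach_depth`; an `immobile_fraction` of all emitters has
D = 0.  There are no births and no acquisition photobleaching, so recovery
occurs only by lateral exchange of fluorescent mobile emitters into the
ROI — the mechanism the mobile-fraction estimator assumes.

### FCS traces

Particles diffuse in a periodic box (side 8 w₀) through a Gaussian
observation profile W(r) = 2 exp(−2 r²/w₀²) with 1/e² radius w₀
(default 0.25 µm).  The effective observation area is A_eff = π w₀², so
the expected fluctuation amplitude is G(0) = 1/N for N particles in A_eff,
and the decay time is τ_D = w₀²/(4D).  The peak weight 2 makes the trace
mean equal N × brightness.  Counts are Poisson-sampled per time bin.

## Detection

Spot candidates are local maxima of a difference-of-Gaussians band-pass
(σ and 1.6 σ) — the matched filter for a PSF-sized blob.  A candidate's
**SNR is its matched-filter significance**: the band-pass response divided
by the robust (MAD-based) SD of the band-passed image.  Gating on this
smoothed statistic rather than on a per-spot fitted amplitude is what
makes spots near the detection threshold recoverable: the matched-filter
statistic has several-fold less estimation noise than a single-window
amplitude fit, so a threshold equal to the nominal SNR keeps essentially
all true spots while pure-noise frames average ≤ 1 false positive per
512² pixels.  Candidates within 2σ of a stronger candidate are suppressed.

Survivors are refined with a 2D Gaussian least-squares fit (free
amplitude, center, σ, offset) in a (4σ + 1)-px window; background is the
median of the window's border ring.  Localization precision at SNR 5 sits
at the information bound, ≈ 0.18–0.20 px per axis; quoted RMSE values are
per-axis (`sqrt(mean(dx² + dy²)/2)`).  Fits that drift more than 2σ from
their candidate, leave the frame, or fail to converge are dropped.  The
fit window requirement excludes a ~3-px rim of the frame; density
comparisons against ground truth use the effective interior area.
Detection quality figures (F1, RMSE) are quoted for well-dispersed fields
(spot separations ≥ 6 px): closer pairs merge into a single band-pass
maximum and cannot be resolved by any single-emitter fitter — consistent
with the sparse nanodomain imaging this package targets.

Spot size is reported in the field's "n × n pixels" convention as the FWHM
of the fitted Gaussian, s = 2σ√(2 ln 2).

### Voronoi density segmentation

Each spot's local density is the inverse area of its Voronoi cell
(unbounded cells: density 0, always background).  Spots at or above a
density threshold are merged into clusters through Voronoi-cell adjacency;
clusters smaller than `min_cluster_size` are relabeled background.
Densities are scale-covariant (coordinates × c ⇒ densities / c²).

## Tracking

Linking is greedy on ascending distance: all candidate (track-end, spot)
pairs within the search radius are sorted by distance and accepted
first-come, so each accepted pair is the mutual nearest neighbor among
those still unmatched.  A track end may bridge up to `max_gap` missing
frames with a radius growing linearly in the frames elapsed.  The default
search radius is 3·√(4 D_max Δt)/pixel size — three SD of the fastest
expected step.  At nanodomain imaging densities this equals the exhaustive
optimal assignment (verified against a brute-force oracle on ≤ 6
spots/frame); the simplification is deliberate, favouring verifiability
over generality.  Dwell time is (last − first + 1) × Δt; censored tracks
are excluded from dwell statistics by default.

Kymographs sample intensity along an arbitrary line (bilinear
interpolation, averaged over a perpendicular band) with one column per
frame; a laterally stable particle appears as a straight ridge.

## Mobility analysis

Time-averaged MSD uses all ordered point pairs at each frame lag, with
gapped pairs contributing at their true time difference.  D is slope/4 of
an ordinary least-squares line through the first 4 lags (bias/variance
compromise standard in SPT), with a free intercept absorbing localization
noise.  Negative slopes — expected for a fraction of short Brownian
tracks — clamp to D = 0 and are flagged rather than raised; non-positive
values are excluded from population analysis with their count reported.
Velocity is the mean instantaneous speed (mean |Δr|/Δt over consecutive
points); for Brownian motion its expectation is the Rayleigh mean
√(πD/Δt), which ties the velocity scale to D.

**Characteristic peaks (Ĝ).**  Per-track D (or speed) values are log10-
transformed and fitted with Gaussian mixtures of 1 and 2 components
(k-means++ initialization, 10 restarts, fixed seed from config); the model
with the lower BIC is kept.  Each component's Ĝ = 10^mean is the peak
position of the log-binned histogram; its standard error is the
within-component spread / √(weight × n), propagated to the linear scale.
BIC was preferred over AIC as the more conservative choice for the
one-vs-two subpopulation call.  All-identical inputs return a single
degenerate peak with a log10 SD floor of 10⁻³.

**Dwell-time fitting.**  Dwell histograms use bins centered on multiples
of the bin width, so frame-quantized durations fall at centers, and an
exponential A·exp(−t/τ) is least-squares fitted for t ≥ `fit_floor`.
Empty bins inside the observed range are kept (dropping them fattens the
tail and inflates τ) and the half-covered bin below the smallest datum is
excluded.  Because the exponential is memoryless, integration over equal
bins is exactly proportional to exp(−center/τ) — the fit is unbiased with
or without a truncation floor.  The maximum-likelihood mean above the
floor is reported alongside as a cross-check.

## Colocalization

Object-based: detected spot centers in the two channels are paired
one-to-one within a 2-px radius (diffraction-scale, configurable) by
optimal assignment — maximum number of within-radius pairs, minimum total
distance among those.  Unlike nearest-neighbor pairing, clustered spots
cannot shadow each other: whenever a perfect pairing exists it is found,
so a fully colocalized field reads exactly 100%.  Overlap % is the
matched fraction of the reference channel (channel A).  The chance level on a homogeneous field is
100 (1 − exp(−ρ_B π r²)) with ρ_B the other channel's spot density, and a
position-shuffling Monte Carlo reproduces it.  Pixel-correlation
coefficients (Pearson/Manders) are out of scope; line profiles across both
channels are provided for qualitative comparison.

## FRAP

Traces are double-normalized: background-subtracted ROI over
background-subtracted reference, scaled so the pre-bleach mean is 1.  The
reference corrects acquisition photobleaching in real recordings; for
simulator recoveries (which have no acquisition bleaching) a constant
reference is appropriate — an in-frame reference region is transited by
the bleached cloud and distorts mid-recovery values.

Recovery is fitted with the empirical single exponential
F(t) = F0 + (P − F0)(1 − exp(−k t)), t = 0 at the bleach frame, post-bleach
samples only.  By default **F0 is anchored at the normalized bleach-frame
value** (the observed bleach depth) and only P and k are fitted: diffusive
recoveries rise like √t at early times, and a free F0 absorbs that shape
mismatch, biasing the mobile fraction 100(P − F0)/(1 − F0) by ten or more
points.  The free three-parameter fit remains available
(`anchor_f0=False`).  A Soumpasis-style diffusion model was deliberately
not used — the quantity of interest is the recovered fraction, not
D-from-FRAP.  Percent recovery is reported at the last common timepoint by
default.

Sub-ROI analysis splits the bleached square into equal strips (default 3,
along x) sharing one reference; with diffusion-driven recovery the middle
strip's k is smallest, since exchange proceeds from the ROI edges inward.

Validation conditions (recovery experiments): 12×12 px ROI bleached at
full depth in a 44×44 px frame with a 44-px reservoir margin, D = 1 µm²/s,
25 particles/µm², 40 pre-bleach + 240 post-bleach frames at 0.1 s, 16
replicate experiments averaged before fitting.  These sizes keep the three
systematic error sources — reservoir dilution (bleached/total fluorophore
ratio), the unrecovered diffusive tail w²/(4πDt) at the last frame, and
pre-bleach baseline noise (ROI occupancy fluctuations with correlation
time ≈ w²/4D) — each below ~1.5 points of mobile fraction, verified to
recover set immobile fractions {0, 0.25, 0.5, 0.75, 1} within ±5 points.

## FCS

G(τ) = ⟨δF(t) δF(t+τ)⟩/⟨F⟩² is evaluated on a quasi-logarithmic
multiple-tau lag grid (dense first cascade, then doubling spacing), but
each point is computed by the direct estimator on the raw unbinned trace:
the grid thins the lags, nothing is block-averaged, so the curve is
bit-identical to the brute-force definition at every lag.  At these trace
lengths (≤ a few × 10⁴ samples, ≤ ~10² lags) the direct evaluation is
effectively free, and it removes the triangular-averaging distortion of
classic hardware-style binned correlators.  Traces are split into 4
segments by default (matching 20-s acquisitions), G averaged across
segments with its SD.  A constant trace returns G ≡ 0 with a
zero-variance flag.

The 2D membrane model G(τ) = G0/(1 + τ/τ_D) (no triplet term) is fitted by
least squares; N = 1/G0 and density = N/(π w₀²) with the beam waist from
config.  The alternative intensity route density =
(total signal / per-particle brightness)/area is provided as well; the two
agree when the brightness calibration is consistent, and the correlation
route is the default.

## Statistics and pipeline

Condition comparisons use the unpaired two-sample t-test,
pooled-variance by default (Welch behind a flag), with star codes at
0.05/0.01/0.001 and no multiple-testing correction — reports state this.
The pipeline (detect → link → per-track dynamics → peaks) is fully
deterministic for a fixed config: identical inputs give byte-identical
CSVs.  Movie files are multi-page TIFF with a plain-text calibration
sidecar; loading without calibration is a hard error, never a silent
default.

## Validation problem sizes

The test-suite and acceptance-script simulations are sized to hold each
quantity's sampling error comfortably inside its tolerance band: track
ensembles of 500–2000 tracks × 50 steps for diffusion peaks, ≥ 2000
uncensored dwells, 16 replicate bleach experiments, 6–18 FCS traces of
20 s, 20-seed calibrations for bimodality and colocalization chance, and
1000-draw null calibration for the t-test.
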