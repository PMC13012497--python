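# Methods

`dreamdepth` implements the statistical core of a serial-awakening
high-density EEG analysis of subjective sleep depth: how the feeling of
deep N2 sleep relates to cortical activation (spectral band power), to the
presence and phenomenology of dreaming, and to time of night. This note
documents the models, the numerical choices, and what the synthetic
validation does and does not establish.

## The mixed model

Every analysis uses one model family: a Gaussian-identity linear mixed
model with a participant random intercept,

    y_ij = x_ij' beta + b_i + e_ij,  b_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2),

where `y` is a 1–5 Likert rating (perceived sleep depth or sleepiness), a
log band power, or a phenomenology component score, and `x` always carries
the predictor of interest plus experiment (2 levels), night (4 levels,
treatment-coded against night 1) and clock time in decimal hours relative
to midnight (negative before midnight). Modeling Likert outcomes with a
Gaussian identity link is a deliberate simplification: it matches the
symmetric intervals and linear coefficients this kind of analysis reports,
at the cost of ignoring the discreteness of the scale (see Limitations).

The solver profiles the likelihood over the variance ratio
`lambda = tau^2/sigma^2`. With a single grouping factor,
`V = I + lambda Z Z'` is block diagonal, so for any `lambda` the GLS
estimate, the residual quadratic form and `log|V|` have closed forms in
per-group sums; fitting reduces to a bounded 1-D optimization of the
profiled (restricted) likelihood over `log lambda` (Brent search,
`xatol 1e-8`, bracket ±18 with an explicit boundary check at
`lambda -> 0`, which is OLS). Coefficients and standard errors are
reported from REML fits (`sigma^2 = RSS_V/(n-p)`, covariance
`sigma^2 (X'V^-1 X)^-1`); AIC/BIC and likelihood-ratio comparisons always
use an ML refit of the same model. Tests verify agreement with
statsmodels `MixedLM` to ~1e-5 in coefficients and ~1e-4 in ML
log-likelihood (statsmodels' Hessian-based standard errors differ from the
exact GLS covariance by ~0.2%, which the oracle test tolerates).

Per-coefficient inference is Wald-based: `W = (beta/SE)^2` with a
chi-square(1) p-value and 95% CI `beta ± 1.96 SE`.

## Channel-wise fitting and the permutation engine

The channel-wise topographies fit the same model once per electrode, with
the electrode's log band power substituted for the `brain_activity`
placeholder (as predictor, or as outcome for the EEG time-trend models).
The permutation correction needs on the order of 10^5–10^6 refits, so the
engine batches all electrodes: design cross-products are precomputed per
electrode once, and each permutation re-optimizes `log lambda` for every
electrode simultaneously with a vectorized golden-section search (64
iterations over the same bracket as the scalar path). The batched path is
the *same model* as the scalar path — tests require agreement to ~1e-6 —
and is used for both the observed map and every permutation, so the two
are numerically exchangeable.

## Cluster-mass correction

Electrodes with uncorrected `p < 0.005` and a consistent coefficient sign
are grouped into connected clusters on the electrode adjacency graph;
clusters smaller than 3 electrodes are dropped; the cluster mass is the
sum of Wald statistics over members. The outcome is shuffled within
participant-by-experiment strata (participants are nested in experiment,
so this reduces to within-participant; the composite key is kept for
safety), the identical model/clustering runs on each shuffle, and the
maximum absolute cluster mass per shuffle forms the null. Corrected
p-values use the +1 convention `p = (1 + #{null >= mass})/(1 + n_perm)`;
positive and negative clusters are compared against the single max-|mass|
null (two-sided correction). Electrodes whose fit fails are treated as
sub-threshold identically in observed and permuted maps — the only
internally consistent choice. Min-size filtering is likewise applied
identically on both sides.

Adjacency is not dictated by the data format, so it is a constructor
choice: the default is a Delaunay triangulation of the azimuthal (polar)
projection of the electrode positions with edges above the 0.98 length
quantile pruned; a plain distance-threshold graph is available as an
alternative. The construction parameters are recorded on the graph and in
the provenance manifest.

## Spectral features

Per awakening: robust detrend (order-2 polynomial, iteratively reweighted
with Tukey biweights, 3 iterations, 3-robust-SD threshold — the exact
reweighting schedule of the classical robust-detrending routine is not
standardized, so these are configurable), then the 120 s immediately
preceding alarm onset, then a one-sided Welch PSD (4-s Hamming windows,
90% overlap, density scaling, 0.25 Hz resolution), then trapezoidal
integration over delta (0.5–4 Hz) and gamma (25–50 Hz) with the PSD
linearly interpolated onto the exact band edges, which makes the integral
independent of the phasing of the frequency grid. Band powers are
natural-log transformed (any other base rescales coefficients uniformly);
the gamma/delta ratio table is computed as `log gamma − log delta`, so the
log-ratio identity is exact by construction. Integrated powers that are
exactly zero (possible only for silent channels) are floored at machine
epsilon and flagged.

## Report taxonomy, contrasts, PCA

The questionnaire maps to five report levels: CE; CEWR split into rCEWR
(impression of a forgotten rich experience) and sCEWR; NCE split into CESP
(contentless sense of presence) and UNC (full unconsciousness). A missing
follow-up leaves the subtype missing while the three-level class stands.
Report-type effects are estimated with one mixed model per unordered pair
of levels — no ordinal assumption across consciousness levels — with
Benjamini–Hochberg FDR across the 6 pairs of the four-level family
{CE, CEWR, CESP, UNC}; the two-level conscious-vs-not contrast is reported
unadjusted. Participant-wise report proportions are compared with a
Friedman test, and the UNC-vs-CESP and sCEWR-vs-rCEWR splits with Wilcoxon
signed-rank tests on participant-wise shares.

Phenomenology PCA: six features (subjective duration in seconds,
log-transformed with a 1-s floor; vividness; perceptual-vs-thought
content; bizarreness; emotional intensity; dream awareness), z-scored
globally over complete CE records, eigendecomposed; the first two
components are read as perceptual immersion (PC1) and reflective thought
(PC2). Component signs are arbitrary, so each is oriented to make its
largest-|loading| feature positive; scores are standardized to unit
variance, so PC-association coefficients mean "rating change per SD of
the component". Scores are not imputed for records without ratings.

## Time-of-night models

Trends enter raw time powers (orders 1–3) next to the nuisance terms,
with the co-rating as a covariate for the depth/sleepiness models; BIC on
ML fits with identical random-effects structure selects the order, and
the winner is reported from its REML fit. Raw (non-orthogonalized) powers
are the simplest match to reporting a linear-term coefficient; a condition
warning is emitted when the power design is ill-conditioned. The
sleepiness peak is the vertex `-b/(2c)` of the quadratic fixed-effect
polynomial, flagged when curvature is positive (trough) or the vertex
falls outside the observed range. The depth-vs-sleepiness divergence test
stacks both ratings in long format (two rows per awakening), restricts to
`time >= 4.0` h (inclusive), and tests the measure-by-time interaction
with a participant random intercept. "Adjusted" display values are
residuals after removing nuisance fixed effects and BLUP participant
intercepts, recentered to the raw grand mean — a display transform,
never used for inference.

## The synthetic cohort

The generator emulates the study design: 44 participants nested in two
experiments (half each), 4 nights, 4–8 awakenings per night (~1,050
records), report probabilities set to the study mix (CE 432/1024,
CEWR 364/1024 with 70.39% simple, NCE 228/1024 with 50.15% unconscious),
awakening times uniform on [−1, +7.5] h around midnight, a shared
participant intercept (SD 0.5) for both ratings, residual SD 0.8, and
generating coefficients mirroring the study-scale effects (depth time
slope 0.127; immersion/reflective slopes 0.277/−0.195; report-type depth
effects ≈ 0.55/0.59 against the CESP reference; a quadratic sleepiness
trajectory peaking at 3.3 h). Ratings are latent-Gaussian, rounded and
clipped to the 1–5 grid by default. Phenomenology features load on two
latent factors (immersion, reflective thought) so the PCA recovers the
intended structure; the immersion factor drifts with time (slope 0.103).

Band-power tables are generated directly at the statistical level:
baseline + participant offset + a spatially smooth record-level field
(squared-exponential kernel, SD 0.45, length scale 0.10 in head-radius
units of 0.1, plus white noise SD 0.15) + an optional effect topography
coupling a latent cortical-activation variable to the gamma band (and
hence the ratio). The length scale was chosen so that neighboring
electrodes correlate at ~0.8 and null Wald maps have the few effective
spatial degrees of freedom that real high-density band-power topographies
show — the regime max-statistic cluster tests are designed for. Raw EEG
segments (1/f background + band-limited sinusoids) are generated only for
validating the spectral chain; the statistical cohorts use the band-power
tables directly.

Seeding: one master seed; each stage (design, reports, latents, ratings,
features, phenomenology) derives a child stream by stable-hashing the
stage name, so datasets are byte-identical given the config and adding a
stage never perturbs the others.

## Validation design

Desk-scale problem sizes are used throughout: type-I calibration runs 100
global-null cohorts of 16 participants x 32 electrodes with 200
permutations each; power uses 20 replicates with an 8-electrode injected
region (coupling −0.35, topography amplitude 1.0); CI coverage pools 200
fits across the five model forms the pipeline uses.

Two conventions matter for interpreting the recovery tests. First,
coverage is validated on the continuous latent ratings
(`likert=False`): rounding and clipping to the 1–5 grid makes the
Gaussian model deliberately misspecified, which attenuates slopes by a few
percent and is a property of the scale, not of the estimator. Second,
when the fitted regressor is a noisy or estimated proxy of the generating
variable (an electrode's band power standing in for latent activation;
estimated PC scores standing in for the latent immersion factor), the
generating coefficient applies to the latent variable, and the true
conditional coefficient for the regressor actually fitted is the implied
(attenuated) projection slope; recovery tests compare against that
implied slope, computed from the stored latents.

## Limitations

- Gaussian-identity modeling of Likert outcomes ignores discreteness and
  censoring at the scale ends; slopes on rounded data are attenuated by a
  few percent relative to the latent scale.
- The synthetic cohort has stationary Gaussian spatial noise, no artifact
  structure, no missing electrodes, and no sleep-architecture dynamics;
  passing tests demonstrate the statistical machinery is correct and
  calibrated under the assumed data structure, not robustness to real
  recording pathologies.
- Random slopes, crossed random effects, and ordinal/logistic families
  are out of scope by design.
- The sinusoidal EEG fixtures have line spectra; they validate PSD
  scaling and band integration, not broadband sleep EEG morphology.
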