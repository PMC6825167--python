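# Methods

This note documents the models, numerical choices, and limitations of
`alphacond`, in the spirit of a package methods appendix. Everything
quantitative here is computed by the test suite or the scripts; nothing
is quoted from elsewhere.

## Data model

An epoch is channels × time × trials at 500 Hz, −600 ms to 2000 ms
(exclusive) around CS onset: 1,300 samples at 2 ms spacing. Four
conditions are tracked per trial: CS+E, CS+N, CS−E, CS−N (threat vs
safety × extinguished vs non-extinguished). Montages are stored as
unit-sphere Cartesian electrode positions; the standard 64-channel
10-10 layout is loaded from MNE's packaged montage set, re-centred by a
least-squares sphere fit and projected to radius 1.

## Synthetic generator

The generator's purpose is statistical, not biophysical: it produces
data with the paradigm's design structure and the qualitative features
the analysis is sensitive to.

* **Trial schedules** follow the two-day design exactly: habituation
  5 per CS; acquisition 45 per CS with 21 of each CS+ type's trials
  reinforced (uniform random positions within that CS's sequence);
  extinction 40 each for the two "E" cues; recall 60 per CS with no
  reinforcement. Trial order is a seeded interleaving.
* **Alpha oscillation**: a 10 Hz sinusoid with random phase per trial,
  per-trial log-normal amplitude jitter (SD 0.2), and a Gaussian
  topography on the sphere centred at Oz (angular SD 0.6 rad).
* **ERD**: a multiplicative amplitude envelope that ramps linearly from
  1 to 1 − depth between 500 and 700 ms and stays suppressed to the end
  of the epoch. Default depths: 0.5 for CS+ cues, 0.3 for CS− cues.
* **Noise**: per-channel 1/f-power noise, spatially mixed by a
  Gaussian nearest-neighbour kernel (angular SD 0.35 rad) to mimic
  volume conduction; amplitude 1 (nominal µV) against a baseline alpha
  amplitude of 10 at the topography peak.
* **Nuisance structure**: per-channel DC offsets (SD 20) and a
  spatially constant 0.3 Hz drift, so the baseline-subtraction and
  CSD reference-invariance properties are exercised non-trivially.
* **Between-subject variation**: baseline amplitude ~ N(10, 2) and
  independent per-CS depth jitter (SD 0.05). Retained-trial counts per
  CS are drawn from a configurable range (default 16–57).
* **Seeding**: subject *i* of a cohort uses master seed + *i*, so
  cohorts are reproducible piecewise; everything is bit-identical under
  a fixed seed.

A reduced generator (`simulate_roi_subject`) emits a single virtual
occipital-ROI channel with the same temporal statistics. It exists for
calibration studies (type-I error, FWER) that need hundreds of
replicate cohorts; the spatial stage it skips is irrelevant for those
questions, and it feeds the identical time–frequency/summary/
permutation code.

What the generator does **not** emulate: realistic head geometry or
lead fields, non-stationary background rhythms, eye/muscle artefacts,
inter-channel noise-spectrum differences, alpha-frequency variability
across subjects, or ERD recovery before the epoch ends. Passing tests
therefore show the *analysis* is correct and calibrated under the
stated statistical structure, not that it would behave identically on
arbitrary recorded EEG.

### Default effect size

Default depths (0.5 vs 0.3, jitter SD 0.05) produce a subject-level
contrast whose standardized effect is large (d_z ≈ 2). This is a
deliberate parameter-recovery regime: desk-scale cohorts (4–10
subjects) must recover the injected contrast essentially always for
recovery tests to be meaningful. Study-scale effect sizes (η_p² near
0.1) can be emulated by raising `depth_jitter_sd`; nothing in the
analysis depends on the regime.

## Surface Laplacian

Spherical-spline CSD with basis matrices

    g(x) = (1/4π) Σ_{n=1..N} (2n+1)/(n(n+1))^m P_n(x)
    h(x) = (1/4π) Σ_{n=1..N} (2n+1)/(n(n+1))^(m−1) P_n(x)

evaluated at x = cos θ between electrode pairs; defaults m = 4, N = 10,
λ = 10⁻⁵ added to the diagonal of G only. Coefficients solve the
augmented system with an explicit zero-sum constraint row (chosen over
mean-subtraction for numerical clarity), and the output is the
**negative** surface Laplacian H·c/r² (CSD-positive = source), with
head radius 1 so the output is unitless — the analysis endpoint is
percent change, where absolute scale cancels. Since the transform is
linear, a single channels × channels operator is precomputed and
applied to all samples. Duplicate electrode positions are rejected
(singular spline system). N is exposed because other conventions use
larger series degrees.

Verified properties: zero output for spatially constant input,
invariance to reference shifts, linearity, channel-permutation
equivariance, and ≥0.95 pattern correlation with the analytic surface
Laplacian of degree-3 spherical harmonics on the 64-channel montage
(λ = 0 for that check).

## Time–frequency analysis

Epochs are baseline-subtracted (−600…−500 ms mean) and tapered with
cosine-square ramps of 20 samples whose outermost sample is exactly
zero. Complex Morlet wavelets have constant centre-frequency-to-
spectral-SD ratio m_w = f/σ_f = 12 (σ_t = 1/(2πσ_f)), truncated at
±3.5 σ_t and normalized to unit energy — so white noise has equal
expected output power at every centre frequency. Convolution is done
by FFT with a single data transform shared across frequencies.

Numerical consequences worth knowing:

* **Wavelet support vs epoch length.** At 3.8 Hz a ±3.5 σ_t wavelet is
  longer than the 1,300-sample epoch and `morlet_power` refuses to run;
  the analysis band (alpha) is unaffected. Full-grid maps can use a
  2.5 σ_t support bank (98.8 % of energy).
* **Edge attenuation.** Samples within one σ_t of an epoch boundary
  have visibly attenuated power (finite epoch + taper). The default
  baseline window (−400…−200 ms) sits inside this region at the low
  end of the alpha band, which biases raw percent-change levels for
  *both* conditions equally; condition contrasts are essentially
  unaffected. These samples are flagged in an edge mask and summaries
  that touch them warn rather than fail — a hard error would forbid
  the default baseline.
* **Transition splatter.** A step-like amplitude envelope spreads
  broadband energy around the ERD onset. In noiseless or noise-poor
  signals, off-peak bins (near-zero baseline power) can show large
  transient percent *increases* around the transition; a realistic
  noise floor suppresses the artefact. Tests that check pre-onset
  behaviour therefore evaluate the oscillation's own frequency bin.

Baseline normalization divides trial-averaged power by the mean
baseline **power** per frequency and channel (percent change
100·(P/P₀ − 1)); the literal amplitude-domain reading ("mean
amplitude") is available as an option (`amplitude_baseline`). The
stored baseline makes normalization invertible. Condition averaging
precedes normalization, each condition against its own baseline.

Band and window selections use inclusive endpoints; band edges match
grid bins with half-a-step tolerance (the stated 8.1/11.9 Hz edges are
not exact multiples of the 0.38 Hz grid step, so on the default grid
the band covers the 11 bins from 7.98 to 11.78 Hz). The 500–1200 ms
window at 500 Hz selects exactly 351 samples.

## Inference

The 2×2 repeated-measures ANOVA tests each effect against its own
effect-by-subject interaction; η_p² = SS_eff/(SS_eff+SS_err), which
also equals F/(F+df_err). The implementation is a direct sums-of-
squares decomposition validated against a longhand oracle (|ΔF| < 10⁻⁸
over random tables) and cross-checked against pingouin.

Bayes factors use the mixed-model ANOVA construction: all effects get
zero-centred normal priors with per-batch variance g·σ², g ~
InvGamma(1/2, r²/2), with r = 0.5 for the three fixed-effect batches
(±1/2 contrast coding) and r = 1 for the subject batch (orthonormal
sum-to-zero contrast basis); μ and σ² carry Jeffreys priors.
Conditional on g the marginal likelihood is closed-form, and the g
integral is seeded Monte Carlo (default 100,000 draws; a log₁₀ MC
standard error is reported per BF). Exact agreement with other
samplers' BF values is not expected — the integrator differs — but
matched-model **inclusion** BFs are closed-form given the model BFs:
with equal prior model probabilities, BF_incl(C) = (P(C)+P(C+E)) /
(P(null)+P(E)), and BF_incl(C×E) = P(full)/P(C+E). BFs below 1 are
reported in reciprocal form ("1 / x"). Degenerate tables (no
between-subject variability) are rejected.

Within-subject error bars use subject-centred values with the Morey
small-sample correction √(k/(k−1)), k = 4 cells. Distribution checks
report per-cell skewness and excess kurtosis with |skew| ≤ 2,
|kurt| ≤ 7 acceptability flags; constant cells yield NaN moments and a
False flag rather than an error.

The block analysis splits each CS type's retained trials sequentially
into 4 near-equal blocks (remainder to the earliest blocks, all within
±1 trial), averages power within block, normalizes each block against
its own baseline, and reduces to the permutation-derived window (the a
priori window if no window was found). Block × Contingency effects
with a Block term get Greenhouse–Geisser ε (Box's estimate from the
covariance of that effect's repeated measures; ε ≡ 1 for 2-level
factors); per-block paired t-tests are two-sided and uncorrected.

## Permutation testing

The contingency contrast is the per-subject difference of CS+ and CS−
alpha time courses (each the average of its two E/N members). In a
paired design the only exchangeable relabeling is the independent
per-subject condition swap — a sign flip of the whole difference
series. Each of the 1,000 default permutations records the minimum and
maximum of its 1,300-sample t-series; critical values are the 2.5th
percentile of the t_min distribution and the 97.5th of the t_max
distribution (linear interpolation between order statistics — worth
documenting because ±0.05 shifts in t_crit can follow from the
percentile convention). The observed labeling is not forced into the
null by default (`include_identity` adds it). Zero-variance samples
yield flagged non-finite t values, excluded from the extrema with a
warning. Significant windows are maximal contiguous runs of samples
beyond the critical values, reported in ms with inclusive endpoints.

An exhaustive 2ⁿ sign-flip oracle (n ≤ 20) provides the exact null for
validation: Monte-Carlo distributions match it in KS distance, and MC
critical values carry the exact null's nominal tail mass. Note the
exact null is discrete — with few subjects its extreme-tail quantiles
move in visible jumps, so agreement at n = 6 is asserted on the
probability scale.

## Calibration results and problem sizes

All calibration studies use the reduced ROI generator with null
effects (identical depth 0.3 for all CS types, so an ERD exists but no
contrast does):

* **FWER** (`scripts/acceptance.py`): 400 replicate cohorts of 24
  subjects, 8 trials per CS, 1,000 permutations each; the fraction of
  replicates with any significant sample is compared to α = 0.05 with
  binomial tolerance.
* **ANOVA type-I error**: 200 replicate null cohorts of 24 subjects
  through the full summary chain, plus a 400-replicate Gaussian-table
  simulation; both check the Contingency rejection rate against the
  binomial 95% CI of 0.05.
* **Parameter recovery** (full 64-channel pipeline, CSD included):
  50 cohorts of 4 subjects for sign recovery and 20 cohorts of 10
  subjects for window recovery (Jaccard ≥ 0.5 against the injected
  500 ms → epoch-end interval), with retained-trial counts 16–24 as a
  problem-size choice. Ten subjects, not fewer, because the sign-flip
  null under a strong effect is heavily inflated at very small n,
  which costs the t_max test its power there.

## Known limitations

* The CSD constant/λ conventions of proprietary implementations are
  not published; equivalence to them is by construction approximate.
* Bayes factors are Monte-Carlo estimates; at default iterations the
  reported log₁₀ MC error is typically ≲ 0.03 but grows for extreme
  BFs.
* The permutation test assumes within-subject exchangeability of the
  two conditions; it does not address frequency- or channel-dimension
  multiplicity (the analysis band and ROI are fixed a priori).
* Percent-change levels near epoch edges are biased low (edge
  attenuation); contrasts are not.
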