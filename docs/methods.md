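# Methods

`civdwave` re-implements, as a tested pipeline over synthetic data, a
cold-induced vasodilation (CIVD) study design: wavelet band-amplitude
phenotyping of finger skin-blood-flow (SkBF) recordings during cold-water
immersion, CIVD event detection and phase segmentation, categorical
classification with a median-joining network, and a genotype-association
stage. Because no recordings or genotypes of this kind are publicly
deposited, the package ships a first-class synthetic-data generator whose
ground truth makes every downstream stage testable. This note records the
models, the tunable parameters, the design choices that were genuinely
open, and what the passing tests do and do not establish about real data.

## Signal model and phenotyping

A recording is a pair of uniformly sampled traces: SkBF (laser-Doppler,
arbitrary units) and finger skin temperature (°C), covering a 10-min
baseline followed by a 30-min immersion (600 s + 1800 s; 5 Hz by default,
200 Hz generation with block-mean decimation to 5 Hz is supported and
tested).

**Smoothing and landmarks.** All landmark detection operates on 60-s
centered moving averages (window rounded to an odd sample count so the
filter is exactly symmetric). During immersion the smoothed flow falls to
a minimum at `t_minflow` (earliest global minimum; ties break earliest).
The CIVD onset `t_onset_sbf` is the earliest later time at which the
centered slope — the symmetric two-point difference over ±30 s — exceeds a
threshold for at least 60 s. The threshold is *relative*: 5% of the
constriction range (baseline mean minus immersion minimum) per minute,
which makes detection invariant to affine rescaling of the arbitrary flow
units. `t_maxflow` is the earliest maximum after onset. A CIVD event is
called only when, after the flow minimum, the smoothed temperature also
attains a minimum and then rises by at least 0.3 °C before the end of
immersion; the temperature-rise magnitude is not quantified in the source
protocol and 0.3 °C is our documented default (config-exposed). Phases:
baseline, phase 1 `[immersion, t_minflow)`, phase 2
`[t_minflow, t_onset_sbf)`, phase 3 `[t_onset_sbf, t_maxflow)`. Subjects
whose flow rebounds without a temperature rise still receive flow
landmarks and all three phases; when the onset never occurs, phase 2 is
capped at 600 s past the flow minimum (an explicit assumption) and phase 3
is missing.

**Wavelet band amplitudes.** The continuous Morlet transform (ω₀ = 6,
16 voices per octave, log-spaced 0.005–0.150 Hz) is computed in the
Fourier domain with an L1-style normalization: a unit-amplitude sinusoid
produces ridge amplitude 1 at every carrier frequency, which is the
property that makes band *ratios* meaningful. The per-band, per-phase
amplitude is mean |W| over the band's frequency bins and the phase's time
samples, divided by mean |W| over the whole 0.005–0.150 Hz range; samples
inside the cone of influence (within √2·s of a record edge) are excluded
from both means. Bands: eNO-independent 0.005–0.010 Hz, eNO-dependent
0.01–0.02 Hz, neurogenic 0.02–0.05 Hz, myogenic 0.05–0.15 Hz (the last
completes the normalization range only). Whether "total power" means mean
amplitude or integrated squared amplitude is not specified in the source;
we use mean |W|, matching the "wavelet amplitude" language, and expose the
choice.

**Detrending before the transform.** The transform is applied to
`flow − MA₆₀(flow)`, not to the smoothed trace and not to the raw trace.
A 60-s boxcar has its first null at ≈0.0167 Hz, so transforming the
*smoothed* trace would destroy the neurogenic and myogenic bands; while
transforming the *raw* trace lets the large, slow constriction/rebound
envelope radiate into the lowest band and swamp the vasomotor
oscillations. Subtracting the same 60-s average removes the envelope while
passing everything at and above the eNO-dependent band essentially intact
(the known attenuation of the 0.005–0.010 Hz band is accounted for by the
generator's calibration).

## The synthetic-data generator

The generator's defaults are the study conditions: 94 subjects with a
84/94 CIVD prevalence; per-phase band-ratio profiles with the reported
direction of change (eNO-independent 0.30 → 0.48 → 0.76 → 0.58 across
baseline/phase 1/phase 2/phase 3 for responders, neurogenic
0.31 → 0.19 → 0.06 → 0.14; non-responders 0.24/0.38/0.58/0.45 and
0.35/0.24/0.14/0.20); time to minimum flow 702 s with an inter-subject
s.d. of ≈55 s (the reported standard error scaled back to a population
s.d. — an assumption, since subject-level spread is not published); onset
300 ± 30 s after the minimum (the onset delay itself is not tabulated in
the source; 5 min matches the illustrative recording). Minimum finger
temperatures default to ≈10.3 °C (responders) and ≈12.9 °C
(non-responders).

The flow trace is envelope + oscillation bank + white noise. The envelope
is integrated from a piecewise slope profile built from quintic smoothstep
transitions (C² everywhere); the temperature is a first-order lag
`dT/dt = (T_target − T)/τ` (τ = 90 s) toward an affine map of the flow
envelope. For non-responders the target tracks the *running minimum* of
the envelope, so their finger keeps cooling even when flow rebounds — the
pattern real non-responders show, and the reason their phase-2/3 band
amplitudes exist while no CIVD is called.

**Exact landmark recoverability.** The generator is engineered so that on
noiseless data the detector recovers every planted landmark to within one
sample at 5 Hz. This is a non-trivial property — a centered moving average
displaces the minimum of an asymmetric kink by up to
(w/2)(a−b)/(a+b) ≈ 14 s — and drives several design choices:

* envelope slope transitions are antisymmetric about each landmark
  (quadratic-valley minimum, symmetric cap at the maximum), because a
  centered average preserves the argmin/argmax of locally even functions;
* the phase-3 slope is set to `2·θ − r₂` (θ the detector's absolute onset
  threshold, measured by the generator on its own noiseless smoothed
  trace; r₂ the phase-2 slope), so the centered-slope estimate crosses θ
  exactly at the planted onset;
* the eNO-dependent, neurogenic and myogenic carriers sit on exact nulls
  of the detector's discrete 60-s boxcar (k·rate/N for N = 301 taps), so
  they vanish from the smoothed trace entirely while reaching the wavelet
  stage at unit gain. They deviate from the band geometric midpoints by
  less than one analysis voice;
* the 0.005–0.010 Hz band contains no boxcar null, so its carrier is
  phase-locked instead: trough at `t_minflow`, an even number of carrier
  half-periods to the onset (putting a trough there, which keeps the
  threshold crossing exact and monotone) and an odd count to the maximum
  (putting a crest there); the generator places `t_maxflow` on the
  carrier's half-period grid and records the placed value as truth;
* a *fading* moving-average-nulled carrier leaves a residual burst in the
  smoothed trace proportional to its quadrature component, so the
  eNO-dependent/neurogenic carriers are phase-locked to a **node** at
  `t_minflow` (making the burst even about the minimum) and all
  band-1 amplitude crossfades sit entirely outside the ±60 s support of
  the detection kernels.

**Amplitude calibration, targets and the achieved profile.** Carrier
amplitudes are first solved from the analytic Morlet ridge response (a
4×4 linear system, with the myogenic multiplier chosen by closure so the
bin-weighted multipliers average to 1) and then refined against the actual
pipeline — detrend, CWT, per-phase means — by damped multiplicative sweeps
followed by guarded per-cell secant steps. The refinement absorbs envelope
residual, fade smearing and magnitude interference. It cannot do the
impossible: a target that sits below the wavelet's time-frequency
contamination floor (notably the deep phase-2 dips of the 0.01–0.05 Hz
bands, measured over a ~300-s phase with ~80-s wavelet support) is
approached but not attained. The truth ledger therefore records both the
planted `target_ratios` and the `achieved_ratios` — the measured noiseless
profile, i.e. what is physically in the signal. Recovery tests compare the
pipeline to the achieved profile (agreement ≈0.1%, and within 10% of the
planted targets at default parameters); cohort-level tests check the
direction of the group-mean trends against the planted targets, which is
robust to the calibration residual. Per-subject profile jitter uses the
reported standard errors scaled to population s.d., truncated at ±40% of
the group mean so every subject stays inside the generator's recoverable
envelope; the oscillation magnitude (largest raw carrier 0.8 a.u. on a
100 a.u. baseline) tracks each subject's constriction range so the
slope-detection margins hold uniformly.

Genotypes are drawn per variant as two independent allele draws at a
uniform-random MAF (Hardy–Weinberg by construction), dosages 0/1/2 with
optional missingness. `plant_interaction_effects` shifts a named phase-2
band amplitude by `β × coded genotype × 1(non-CIVD)` and clips at zero, so
non-responding major-allele homozygotes sit lowest — the qualitative
pattern the association stage is designed to find.

## Association stage

* **QC** drops variants with call rate < 0.97, Hardy–Weinberg exact
  p < 1e-4, or MAF < 0.005 (0.01 is the conventional floor for imputed
  dosages and is config-exposed). The HWE test is the conditional exact
  test computed by the standard recurrence; it matches a log-factorial
  enumeration oracle to ≈1e-14 on every table with total count ≤ 50. Its
  null p-values are discrete and conservative, so they are *sub*-uniform —
  a Kolmogorov–Smirnov test against the uniform rejects by construction at
  any scale; the meaningful null property, verified in the tests, is tail
  calibration (P(p < α) ≤ α).
* **PCA** standardizes dosages by 2p̂ and √(2p̂(1−p̂)) with per-variant
  mean imputation of missing calls, then takes leading left singular
  vectors scaled by their singular values.
* **Scans.** Logistic regression (Wald test, additive or dominant coding;
  separated or non-convergent fits reported as missing); Fisher's exact
  test on 2×2 allele-count tables; family-wise control by max(T)
  permutation with the (1+b)/(1+B) estimator, so no adjusted p is ever
  zero at finite permutation counts. With complete genotypes a label
  permutation fixes both table margins, so the per-variant Fisher p is a
  function of the case alt-allele count alone and permutations reduce to a
  table lookup; with missing data the scan falls back to re-running the
  exact test. The interaction scan compares, per variant, the least-squares
  models `amp ~ civd + g + civd:g` and `amp ~ civd + g`; the F for this
  highest-order term is invariant to the sums-of-squares type and, in the
  additive coding, to which allele is counted. Designs with a
  monomorphic genotype within either CIVD group are reported missing.
* **Candidate rule**: a variant qualifies if it reaches the genome-wide
  threshold (5e-8) in one band amplitude and at least the borderline
  threshold (1e-5) in the other.
* **GEE**: Gaussian family, identity link, AR(1) working correlation,
  robust sandwich standard errors (statsmodels, with the measurement
  occasion supplied as the wave/time index). With one occasion per subject
  the estimating equations collapse to ordinary least squares exactly.
* **Dunnett-style comparisons** of phases 1–3 against baseline use
  within-subject differences and adjust by Monte-Carlo simulation of the
  correlated max-|t| null (a shared chi scale over correlated normals) —
  exact up to simulation error for the multivariate-t reference, without
  special-function quadrature, and testable by simulation. With a single
  contrast it reduces to the paired t-test.
* **LD**: haplotype frequencies from unphased two-locus genotypes by the
  standard EM (only the double heterozygote is ambiguous), then
  D′ = |D|/D_max and r² = D²/(p₁q₁p₂q₂).

Missing dosages are handled by pairwise deletion in single-variant tests
and mean imputation only inside PCA. The logistic/Fisher scans run without
covariates by default (none are stated for the original scans) with an
optional covariate hook; the GEE contrast group is a user-specified
indicator (the analysis drivers use "non-CIVD and major-allele homozygote
versus the rest" with PC1/PC2 as covariates).

## Classification and network

High/low labels for the phase-2 eNO-independent and neurogenic amplitudes
are thresholded at the mean of the non-CIVD reference group; a value
exactly at the threshold is "low" (strict inequality, deterministic).
Subjects with missing phase-2 amplitudes are excluded with a warning. The
3-bit profiles (CIVD, eNO-independent high, neurogenic high) feed a
median-joining network for binary characters: majority-consensus vectors
of observed/inferred triplets are added while they shorten the total
spanning length, and the final graph is the ε-relaxed minimum-spanning
network (ε = 0, the default of the originating software). For small
character counts the median set is chosen by exhaustive search over the
median closure (minimal spanning length, then fewest medians), so the
result provably attains the optimum that the brute-force oracle in the
acceptance battery computes independently.

## Study-condition constants for the recovery experiments

The candidate-recovery experiment (200 subjects, 500 null variants + 1
planted, relaxed thresholds 1e-5/1e-3, amplitude noise s.d. 0.1) requires
an interaction effect "tuned for ≈0.9 power". Power and false positives
are coupled: the planted signal leaks into null variants through chance
correlation inside the non-responder arm (s.d. 1/√n_non). At the cohort's
84/94 prevalence (≈21 non-responders in 200) the β that reaches 0.82
power already produces 1.26 false positives per replicate, so the
experiment uses a 0.8 prevalence (40 non-responders) with β = 0.18
(eNO-independent) and 0.15 (neurogenic): measured power 0.90 and 0.14 mean
false positives over 50 replicates. The GEE coverage experiment uses 200
subjects × 4 occasions with AR(1) ρ = 0.5 and a −0.2 group effect; the
max(T) calibration uses 500 replicates of 50 variants × 200 permutations
(scaled down from the original million-permutation setting, which only
sharpens the adjusted-p resolution, not the family-wise error property).

## Numerical choices

FFT-domain CWT with an analytic (positive-frequency) Morlet bank, zero
padding past the longest wavelet's e-folding support, and a cached filter
bank per record geometry. Envelope integration by trapezoid over sampled
slopes (exact for the quadratic segments). Ties in extrema break toward
the earlier sample. The max(T) estimator uses ≥ with a 1e-12 tolerance on
the observed statistic. Fisher two-sided p sums table probabilities no
larger than the observed one with the conventional 1+1e-7 relative tie
tolerance. EM for haplotype frequencies starts at linkage equilibrium and
iterates to 1e-10. Dunnett Monte-Carlo uses 2e4 draws by default.

## What the tests show — and what they cannot

Passing the battery establishes that the *pipeline* is correct and
calibrated: landmarks and CIVD flags are recovered exactly on noiseless
data and robustly at the default noise; planted spectral amplitude
structure is recovered through the transform; the exact tests equal
enumeration; the interaction F equals its normal-equations oracle and
holds its nominal size; max(T) controls family-wise error; GEE intervals
cover; the candidate rule finds a planted effect with few false positives;
the network attains the minimal spanning length.

The generator deliberately does **not** model real laser-Doppler data:
noise is white (real LDF noise is structured and heavy-tailed), there are
no motion artifacts, no respiratory/cardiac bands above 0.15 Hz, no
repeated hunting-reaction cycles (only the first CIVD wave is planted and
segmented), and the vasomotor "oscillations" are narrowband carriers
rather than broadband physiological variability. Consequently the
detection sensitivity/specificity measured here are upper bounds, and
nothing in the battery validates the physiological interpretation of the
band ratios on real recordings. Group sizes reported by the original
study (e.g. its typical-phenotype counts and QC survivor counts) depend on
an unreleased cohort and array and are used only as plausibility anchors,
never as test targets.

## Problem sizes

The default battery uses: two 94-subject cohorts (noiseless and default
noise) for detection and direction checks; exhaustive exact-test sweeps to
total count 50 (Fisher over the canonical row/column-swap orbit, with the
symmetry verified on random tables); 50 oracle datasets and 2000 null
simulations for the interaction F; 500 × (50 variants × 200 permutations)
for family-wise error; 200 GEE coverage replicates; 50 candidate-recovery
replicates; all 255 observed subsets of the 3-bit profile space; 200
independent variant pairs at n = 2000 for LD. The full battery completes
in roughly three minutes on one CPU.
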