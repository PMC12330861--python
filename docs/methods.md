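# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the package, in the order the
pipeline runs.

## Synthetic region signals

The generator produces the statistical structure the analysis stack is
built to detect, with every parameter under test control.

**Narrowband alpha.** Gaussian white noise is band-pass filtered at
`iaf ± 2` Hz with a zero-phase windowed-sinc FIR (Hamming; transition
band 25% of the lower edge; applied by centered FFT convolution so the
envelope suffers no phase distortion).  A narrowband Gaussian process
has a Rayleigh envelope, hence exponentially distributed instantaneous
power — the unimodal null of the whole analysis is true by construction.
Note the envelope is autocorrelated with correlation time ≈ 1/bandwidth
(0.25 s at ±2 Hz): a recording of duration T carries only ≈ T × 4 Hz
effectively independent power samples, and empirical-CDF statistics
fluctuate on that scale, not on the raw sample count.

**Aperiodic background.** 1/f^χ noise is synthesized by inverse-FFT
spectral shaping of white noise with uniform random phases: the target
exponent is exact, the cost O(n log n).  The DC bin is zeroed and the
Nyquist bin made real.

**Bimodality.** A two-state continuous-time Markov chain (switching
rates `rate_up`, `rate_down`, exponential holding times, stationary
initial state) multiplies the narrowband component by 1 (low mode) or
`amp_ratio` (high mode).  Multiplying the envelope — rather than adding
bursts — makes the power distribution an exact two-exponential mixture
with mixture weight equal to the high-state occupancy
`rate_up / (rate_up + rate_down)`.  Defaults: rates 0.2 /s (5 s mean
dwell, many switches per 3-minute recording), `amp_ratio` 3 (power
ratio 9, well-separated modes).

**Coupled pairs.** The second signal's narrowband part mixes an
independent component with a phase-shifted copy of the first's
(`sqrt(1−c²)·indep + c·shifted`, shift applied in the analytic domain).
Envelope co-modulation multiplies both envelopes by a shared log-normal
slow modulator (second-order Butterworth low-pass at 2 Hz on the log;
positive by construction).  Because the two carriers fade independently
(Rayleigh, relative variance (4−π)/π ≈ 0.273), the achievable envelope
correlation for independent phases is capped near 0.79; the modulation
depth is solved analytically from the requested target and targets above
0.72 are clamped with a warning.  `gen_power_coupled_pair` additionally
ties the instantaneous mixing fraction to the shared modulator
(`c(t) = strength · logistic(log m)`), planting a genuine
power-coupling relation for the FC analyses.

**What the generator does not emulate.** Sensor-level physics (forward
model, sensor noise), source leakage / volume-conduction mixing between
regions, non-stationary spectral drift, artifacts.  Passing tests
demonstrate correctness of the analysis machinery on data satisfying its
assumptions, not robustness to those real-data complications — in
particular, leakage-induced spurious bimodality is out of scope.

## Spectrum parameterization

The spectrum is the time average of the Morlet TFR (edge-flagged samples
excluded per frequency row).  The model in log10 power is
`offset − log10(knee + f^exponent)` plus Gaussian peaks, fitted over
2–40 Hz:

1. robust aperiodic fit (fit all points, drop positive outliers above
   1 SD of the residual, refit) — candidate peaks must not tilt it;
2. peaks extracted largest-first from the flattened, zero-clipped
   residual until below max(2.0 × residual SD, 0.05 log-units), at most
   6 peaks, Gaussian SD bounded to [0.5, 4] Hz (bandwidth 1–8 Hz),
   followed by a joint least-squares refinement of all peaks;
3. aperiodic refit on the peak-subtracted spectrum; the
   flatten/extract/refit cycle runs twice — the second pass removes the
   tilt left by imperfect first-pass peak subtraction;
4. peaks hugging the fit-range edges (center within one SD of an edge)
   are discarded as flattening artifacts.

Measured recovery: pure power laws χ ∈ {0.5, 1, 2} within 0.05; adding
an alpha bump of 0.6 log-units moves the recovered exponent by < 0.1.
The knee is estimated by default (`aperiodic_mode="knee"`); `"fixed"`
pins it to zero.  The IAF is the center of the highest-power detected
peak with center in 8–12 Hz; with none detected, 10 Hz is used and
flagged (`iaf_defaulted`), matching common practice.

## Alpha-power distribution modeling

The power series is the TFR averaged over `iaf ± 2` Hz.  Samples within
half a wavelet length (`n_cycles / 2f` s) of either recording edge are
excluded.  The optional multiplicative `scale` (1e-19) is pure unit
bookkeeping for empirical MEG inputs; synthetic and simulated data use
scale 1.

Fits are maximum likelihood on the raw samples; the 200-bin equal-width
histogram (spanning [min, max]) is for reporting only — a binned fit
would be inconsistent with the BIC's likelihood definition.

**Exponential MLE** is closed-form (λ = 1/mean, log-likelihood
n(ln λ − 1)).  **Mixture EM** runs in log space (logsumexp) with up to
1000 iterations, relative log-likelihood tolerance 1e-8, and 5 starts: a
symmetric split of the unimodal solution (2λ, λ/2, w = 0.5), a wider
split (4λ, λ/4), and three quantile splits (q = 0.3, 0.5, 0.7).  The
best start by final log-likelihood wins (ties broken by start order).
If every start ends below the unimodal log-likelihood the degenerate
ε-split of the unimodal solution is returned, so the nesting invariant
loglik_bi ≥ loglik_uni holds for every input.  Components are reported
ordered λ₁ > λ₂.

**Model comparison** uses BIC = k ln n − 2 ln L with k = 1 (exponential)
vs 3 (mixture); delta BIC = BIC_uni − BIC_bi, positive favoring the
mixture.  **KS distances** are computed against the fitted CDFs with
p-values from the asymptotic Kolmogorov distribution.  Because the CDF
parameters are estimated from the same data the asymptotic p-value is
biased conservative; every KS result carries an `estimated_params` flag
rather than a (much slower) parametric-bootstrap correction.  Gamma,
Weibull and log-normal alternatives are fitted by `scipy.stats` MLE with
location pinned to zero; non-positive samples are dropped with a warning
(all three supports require x > 0).

**Normalization** divides a power series by its mean ("mean" is the only
method): it makes the exponential MLE rate exactly 1, is idempotent, and
leaves delta BIC and KS distances unchanged (scale family).

**Cross-likelihood** of a series under a reference fit is
Σ ln f_ref(x).  In regime-scoring use the reference is fitted on a
mean-normalized series while the scored (simulated) series enters on its
native scale: under an Exp(1) reference the per-sample score is
−mean(x), so low-power noise-driven regimes score near 0 and
high-power limit-cycle regimes score strongly negative.  Normalizing the
scored series as well would collapse the statistic to exactly −1 for any
input, which is why the asymmetric convention is used.

## Functional connectivity

Windows: 1 s analysis segments with 1 s padding each side, advancing in
0.5 s steps; the first analysis window starts at t = pad.  Each padded
3 s segment is band-passed with a zero-phase windowed-sinc FIR whose
kernel spans exactly the 2 s of padding (so edge contamination never
reaches the analysis second), Hilbert-transformed, and the metric is
evaluated on the central second only.

**ciPLV.** With z the circular mean of the phase differences,
`|Im z| / sqrt(1 − (Re z)²)`.  Perfect real-locking (Re z → ±1) returns
0 (degenerate).  Zero-amplitude samples carry no phase and are excluded
with a warning.  Note the estimator is positively biased under the null
(it is an absolute value): at 1 s windows of alpha-band signal the null
level is ≈ 0.2, which is why analyses compare FC *time courses* rather
than absolute levels.

**cAEC.** Per-sample orthogonalization `y⊥ = Im(y·conj(x)/|x|)`,
Pearson correlation of |x| with |y⊥|, averaged over both directions
(the variant choice — per-sample, symmetrized, plain rather than
log-transformed envelopes — is recorded in the metric name and here).
Instantaneous *real* mixing (the volume-conduction model) is annihilated
exactly; a constant 90° rotation is a genuine lag and deliberately
survives.  Collinear pairs are detected by the relative magnitude of the
orthogonalized residual (< 1e-9 of |y|) and return 0.

**Power-FC coupling.** Normalized alpha power is averaged within each
analysis window; per pair, Spearman's ρ between the pair-mean power and
the FC series; per subject, the mean ρ over pairs; at the group level a
one-sample t-test of subject means against zero ("independent-samples
t-test against a normal distribution centered at zero" admits only this
reading), Cohen's d, and Bonferroni correction over the declared number
of comparisons (bands × metrics × conditions).

## Jansen-Rit simulator

State per node: (y0, y1, y2) — pyramidal, excitatory-interneuron and
inhibitory-interneuron PSP amplitudes (mV) — and their derivatives.
Parameters (units mV, ms, /ms): He = 3.25, Hi = 22, τe = 10, τi = 20,
C_pe = 135, C_ep = 108, C_pi = C_ip = 33.75, e0 = 0.0025, r = 0.56,
v0 = 6, conduction speed 3.9 m/s.  The excitatory feedback loop reads
C_ep·S[C_pe·y0] and the inhibitory decay acts on y2 (the standard
second-order form).  Output is y1 − y2, the pyramidal membrane-potential
proxy.

**Input contract.** η_i(t) ~ N(p, σ) is redrawn independently per node
at every integration step and held constant within the step; there is no
1/sqrt(dt) Wiener scaling, so the effective noise power depends on dt —
σ sweeps must report dt alongside (the default 0.1 ms is used
throughout).  Network input adds `g Σ_j w_ji S[x_j(t − d_ji)]` with
delays `L_ji / s` rounded to the nearest 1 ms (recording-step) multiple;
self-coupling is excluded via the zero weight diagonal.

**Integration.** Stochastic Heun (deterministically 2nd order — verified
against an RK4 reference at 10× finer step), default dt = 0.1 ms,
decimated to 1 kHz recordings; 60 s per run with the first 8 s
discarded.  Initial state: zeros.  Per-node noise streams are spawned
from the run seed (`SeedSequence.spawn`), making a g = 0 network run
bit-identical to the matching single-node runs.  States beyond 1e6 mV
abort with a divergence error.

**Bifurcation scans.** Amplitude = post-transient max − min of y1 − y2.
`continuation` mode walks the p grid reusing the final state (after a
settling run at the starting p); `cold` restarts each cell from zeros.
The two disagree inside the bistable window (hysteresis).
`detect_bifurcations` thresholds at 1 mV: the smallest p on the
downward branch still above threshold (saddle-node side) and the
smallest p on the upward branch below which the amplitude stays
(supercritical side).  Two caveats.  First, threshold sensitivity: at an
abrupt (fold-like) collapse the estimate is threshold-insensitive, but
along the smoothly shrinking oscillation branches actually encountered
(both the low-p end of the alpha cycle and the supercritical decay) the
amplitude crosses any threshold gradually, and the estimate moves by
several grid steps per mV of threshold.  Second, because the amplitude
decays continuously toward the supercritical point, a threshold crossing
systematically precedes the true transition; with the default protocol
the acceptance script locates the crossings at 0.0975 /ms (down) and
0.3100 /ms (up) on the 0.0025 grid.  The model also carries a separate
large-amplitude (~10 mV) cycle on [≈0.115, ≈0.137] reachable from cold
starts in that window; near criticality with low noise, slowly decaying
transients can outlive the 8 s discard (the scan supports longer
discards for that reason).

## Experiments

Sweep cells derive their seeds from the base seed and the cell's grid
index, so results are independent of execution order and reproducible
cell-by-cell.  Per cell (default 60 s / 8 s discard): simulate →
spectral parameterization (IAF, alpha peak power, aperiodic exponent) →
alpha-power series at IAF ± 2 Hz (scale 1) → exponential fits → BIC
metrics, optionally cross-likelihood against a reference.  Failures
(divergence, degenerate series) record NaN.

Friedman's test is implemented natively (rank formula with tie
correction, χ² with k − 1 df) because two-condition designs (k = 2) are
required; it matches `scipy.stats.friedmanchisquare` for k ≥ 3.
Kendall's W = χ² / (n(k − 1)).  Spearman and one-sample t-tests come
from scipy; Bonferroni is min(1, p·m).  The cohort pipeline
(`replicate_empirical_pipeline`) treats subjects as blocks and regions
(or conditions) as the Friedman factor, and correlates region-averaged
spectral characteristics with delta BIC and best-model KS distance.

## Problem sizes used in the test suite

Test simulations use 10–60 s runs; cohort and FC fixtures run at 250 Hz
sampling (the full 2–40 Hz analysis grid fits comfortably under that
Nyquist), 12–24 s per subject; null calibration of the group test uses
500 replicates of the statistical stage on directly generated window
series plus a smaller full-pipeline null; the model-selection study uses
100 seeded runs at n = 1e5 (unimodal) and n = 2e4 (mixture).  These
sizes were chosen so the full suite documents the same effects the
3-minute / 1 kHz defaults produce, at a fraction of the compute.

## Known limitations

- The KS p-values ignore parameter estimation (flagged, see above).
- The cAEC null at 1 s windows is noisy; averaging across windows is
  essential, and absolute cAEC levels are attenuated relative to the
  underlying envelope correlation (orthogonalization removes the
  |sin Δφ| share of the envelope; fading caps the achievable
  correlation).
- Threshold-based bifurcation location inherits the biases described
  above; it is a scan diagnostic, not a root-finding method.
- The simulator's noise convention (no Wiener scaling) matches common
  neural-mass practice but means σ is not dt-invariant.
- Empirical MEG ingestion is limited to region-level matrices
  (delimited text / HDF5); no sensor-space processing is included.
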