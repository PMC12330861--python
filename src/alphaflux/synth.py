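"""Synthetic region time series, coupled pairs, and toy connectomes.

Every analysis stage in this package is exercised against signals with
known ground truth.  The generative model mirrors the statistical
structure assumed for resting-state electrophysiology:

* a narrowband "alpha" component — Gaussian white noise band-pass
  filtered at ``iaf +/- 2`` Hz.  A narrowband Gaussian process has a
  Rayleigh-distributed envelope, so its instantaneous (squared-envelope)
  power is exponentially distributed — the property the distribution
  toolkit is built to detect;
* a ``1/f^chi`` aperiodic background, synthesized by spectral shaping of
  white noise with random phases (exact target exponent, O(n log n));
* optionally a two-state continuous-time Markov chain multiplying the
  narrowband envelope by 1 or ``amp_ratio`` — two amplitude modes of
  alpha, which turn the power distribution into a two-exponential
  mixture (bimodality);
* optionally pairwise coupling: the second signal's narrowband component
  mixes an independent component with a phase-shifted copy of the
  first's, and envelopes can be co-modulated by a shared log-normal slow
  modulator toward a target envelope correlation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import Connectome, RegionTimeSeries

__all__ = [
    "SynthSpec",
    "BimodalSpec",
    "CouplingSpec",
    "ToyConnectomeSpec",
    "gen_unimodal_alpha",
    "gen_bimodal_alpha",
    "gen_coupled_pair",
    "gen_power_coupled_pair",
    "gen_toy_connectome",
    "narrowband_component",
    "aperiodic_background",
]


@dataclass(frozen=True)
class BimodalSpec:
    """Two-state amplitude switching: a continuous-time Markov chain with
    switching rates ``rate_up`` (low->high) and ``rate_down`` (high->low),
    multiplying the alpha envelope by ``amp_ratio`` in the high state.

    The stationary occupancy of the high state is
    ``rate_up / (rate_up + rate_down)``.
    """

    rate_up: float = 0.2    # 1/s
    rate_down: float = 0.2  # 1/s
    amp_ratio: float = 3.0  # > 1

    def __post_init__(self) -> None:
        if self.rate_up <= 0 or self.rate_down <= 0:
            raise ValueError("switching rates must be positive")
        if self.amp_ratio < 1:
            raise ValueError("amp_ratio must be >= 1")


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic region signal.

    Defaults emulate the recordings this package targets: ~3 min of
    resting-state signal at 1 kHz with a ~10 Hz alpha rhythm riding on a
    1/f background of exponent 1.
    """

    duration: float = 180.0        # s
    fs: float = 1000.0             # Hz
    iaf: float = 10.0              # Hz
    alpha_gain: float = 1.0
    aperiodic_exponent: float = 1.0
    aperiodic_gain: float = 1.0
    bimodal: BimodalSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 2 * (self.iaf + 2):
            raise ValueError("fs must exceed twice the alpha band's upper edge")
        if self.alpha_gain < 0 or self.aperiodic_gain < 0:
            raise ValueError("gains must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass(frozen=True)
class CouplingSpec:
    """Pairwise coupling between two generated signals.

    ``coupling_strength`` is the mixing fraction of the phase-shifted
    copy of the first signal's narrowband component inside the second's
    (0 = independent, 1 = fully driven); ``phase_lag`` is applied in the
    analytic domain.  ``envelope_corr`` co-modulates both envelopes with
    a shared log-normal slow modulator toward that Pearson correlation.
    """

    phase_lag: float = 0.0
    coupling_strength: float = 0.0
    envelope_corr: float = 0.0
    band: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if not -1.0 <= self.envelope_corr <= 1.0:
            raise ValueError("envelope_corr must be in [-1, 1]")


@dataclass(frozen=True)
class ToyConnectomeSpec:
    """Random toy structural connectome."""

    n_regions: int = 6
    density: float = 0.5
    length_range: tuple[float, float] = (10.0, 150.0)  # mm
    weight_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if self.length_range[0] < 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")


# ------------------------------------------------------------- components


def _bandpass_fir(fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase windowed-sinc band-pass; transition 25% of each edge."""
    trans = 0.25 * lo
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # Hamming transition rule, odd
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def narrowband_component(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-passed at ``iaf +/- 2`` Hz, unit variance."""
    lo, hi = spec.iaf - 2.0, spec.iaf + 2.0
    taps = _bandpass_fir(spec.fs, lo, hi)
    white = rng.standard_normal(spec.n_samples)
    x = signal.fftconvolve(white, taps, mode="same")
    sd = x.std()
    return x / sd if sd > 0 else x


def aperiodic_background(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """``1/f^chi`` noise by inverse-FFT spectral shaping with random phases.

    Target power spectrum P(f) proportional to ``f**-chi`` (DC excluded),
    output scaled to unit variance before applying ``aperiodic_gain``.
    """
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spec.aperiodic_exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = np.abs(spectrum[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ctmc_path(
    rate_up: float, rate_down: float, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Sampled path of a two-state CTMC (0 = low, 1 = high), initial state
    drawn from the stationary distribution."""
    occ_high = rate_up / (rate_up + rate_down)
    state = int(rng.random() < occ_high)
    path = np.empty(n, dtype=np.int8)
    t_samp = 0
    while t_samp < n:
        rate = rate_down if state else rate_up
        dwell = rng.exponential(1.0 / rate)
        n_dwell = max(1, int(round(dwell * fs)))
        path[t_samp : t_samp + n_dwell] = state
        t_samp += n_dwell
        state = 1 - state
    return path


# ------------------------------------------------------------- generators


def gen_unimodal_alpha(spec: SynthSpec) -> RegionTimeSeries:
    """Narrowband alpha on a 1/f^chi background.

    The squared Hilbert envelope of the (pre-mix) narrowband component is
    exponentially distributed; with ``alpha_gain = 0`` the output is pure
    aperiodic noise with spectral exponent ``chi``.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = narrowband_component(spec, rng)
    background = aperiodic_background(spec, rng)
    data = spec.alpha_gain * alpha + spec.aperiodic_gain * background
    return RegionTimeSeries(
        data[None, :], fs=spec.fs, labels=["synth"],
        meta={"generator": "unimodal", "spec": spec.__dict__ | {"bimodal": None}},
    )


def gen_bimodal_alpha(spec: SynthSpec) -> tuple[RegionTimeSeries, np.ndarray]:
    """Two-mode alpha: the CTMC state path multiplies the narrowband
    envelope by 1 (low) or ``amp_ratio`` (high).

    Returns the signal and the ground-truth state path (0/1 per sample).
    With ``amp_ratio = 1`` the output is sample-identical to the
    unimodal generator at the same seed.
    """
    if spec.bimodal is None:
        raise ValueError("spec.bimodal block is required")
    bm = spec.bimodal
    rng = np.random.default_rng(spec.seed)
    alpha = narrowband_component(spec, rng)
    background = aperiodic_background(spec, rng)
    path = _ctmc_path(bm.rate_up, bm.rate_down, spec.n_samples, spec.fs, rng)
    envelope_gain = np.where(path == 1, bm.amp_ratio, 1.0)
    data = spec.alpha_gain * envelope_gain * alpha + spec.aperiodic_gain * background
    ts = RegionTimeSeries(
        data[None, :], fs=spec.fs, labels=["synth"],
        meta={"generator": "bimodal", "amp_ratio": bm.amp_ratio,
              "rate_up": bm.rate_up, "rate_down": bm.rate_down},
    )
    return ts, path


def _modulator_logs(n: int, fs: float, rng: np.random.Generator,
                    cutoff: float = 2.0) -> np.ndarray:
    """Unit-variance low-passed Gaussian used as a log-envelope modulator.

    The cutoff sits well below the alpha band but high enough that the
    modulation is visible within 1 s analysis windows.
    """
    logm = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    logm = signal.sosfiltfilt(sos, logm)
    return logm / max(logm.std(), 1e-12)


def gen_coupled_pair(
    spec_a: SynthSpec, spec_b: SynthSpec, coupling: CouplingSpec
) -> tuple[RegionTimeSeries, RegionTimeSeries]:
    """Two signals whose narrowband components are phase-coupled.

    Signal B's narrowband part is ``sqrt(1 - c^2) * independent +
    c * shifted(A)`` where ``c = coupling_strength`` and ``shifted``
    applies ``phase_lag`` in the analytic domain (so ``c = 1,
    phase_lag = pi/2`` gives pure quadrature coupling).  A positive
    ``envelope_corr`` multiplies both envelopes by a shared log-normal
    slow modulator, co-modulating them while keeping envelopes positive.
    """
    if spec_a.fs != spec_b.fs or spec_a.n_samples != spec_b.n_samples:
        raise ValueError("both specs must share fs and duration")
    rng_a = np.random.default_rng(spec_a.seed)
    rng_b = np.random.default_rng(spec_b.seed)
    alpha_a = narrowband_component(spec_a, rng_a)
    bg_a = aperiodic_background(spec_a, rng_a)
    alpha_b_indep = narrowband_component(spec_b, rng_b)
    bg_b = aperiodic_background(spec_b, rng_b)

    analytic_a = signal.hilbert(alpha_a)
    shifted = np.real(analytic_a * np.exp(-1j * coupling.phase_lag))
    c = coupling.coupling_strength
    alpha_b = np.sqrt(1.0 - c**2) * alpha_b_indep + c * shifted

    if coupling.envelope_corr > 0:
        # shared log-normal slow modulator on both envelopes (keeps them
        # positive).  The narrowband carriers fade independently
        # (Rayleigh, relative variance v_r = (4 - pi)/pi), which dilutes
        # the shared modulation; the modulation depth is chosen so the
        # resulting envelope correlation hits the target:
        #   corr(envA, envB) = rho_m v_m / (v_r + v_m + v_r v_m)
        # with v_m the modulator's relative variance.  Targets above the
        # fading-imposed ceiling (~0.72 at rho_m = 0.95) are clamped.
        rho_m = 0.95
        v_r = (4.0 - np.pi) / np.pi
        t_max = 0.72
        target = coupling.envelope_corr
        if target > t_max:
            import warnings

            warnings.warn(
                f"envelope_corr {target} exceeds the independent-phase "
                f"fading ceiling; clamped to {t_max}", UserWarning,
            )
            target = t_max
        v_m = target * v_r / (rho_m - target * (1.0 + v_r))
        sig = np.sqrt(np.log1p(v_m))
        # log-domain mixing coefficient giving modulator corr rho_m
        mix = min(1.0, np.log1p(rho_m * v_m) / max(np.log1p(v_m), 1e-12))
        rng_m = np.random.default_rng((spec_a.seed, spec_b.seed, 101))
        z_shared = _modulator_logs(spec_a.n_samples, spec_a.fs, rng_m)
        z_own = _modulator_logs(spec_b.n_samples, spec_b.fs, rng_b)
        alpha_a = alpha_a * np.exp(sig * z_shared - sig**2 / 2.0)
        z_b = mix * z_shared + np.sqrt(1.0 - mix**2) * z_own
        alpha_b = alpha_b * np.exp(sig * z_b - sig**2 / 2.0)

    a = spec_a.alpha_gain * alpha_a + spec_a.aperiodic_gain * bg_a
    b = spec_b.alpha_gain * alpha_b + spec_b.aperiodic_gain * bg_b
    meta = {"coupling": coupling.__dict__}
    return (
        RegionTimeSeries(a[None, :], fs=spec_a.fs, labels=["A"], meta=meta),
        RegionTimeSeries(b[None, :], fs=spec_b.fs, labels=["B"], meta=meta),
    )


def gen_power_coupled_pair(
    spec_a: SynthSpec, spec_b: SynthSpec, coupling: CouplingSpec
) -> tuple[RegionTimeSeries, RegionTimeSeries]:
    """Pair whose phase-coupling strength co-varies with alpha power.

    A shared log-normal modulator ``m(t)`` scales both narrowband
    envelopes AND drives the instantaneous mixing fraction
    ``c(t) = coupling_strength * logistic(log m)``: windows of high
    alpha power are also windows of strong (phase-lagged) coupling.
    This is the planted ground truth for power-FC coupling analyses.
    """
    if spec_a.fs != spec_b.fs or spec_a.n_samples != spec_b.n_samples:
        raise ValueError("both specs must share fs and duration")
    rng_a = np.random.default_rng(spec_a.seed)
    rng_b = np.random.default_rng(spec_b.seed)
    alpha_a = narrowband_component(spec_a, rng_a)
    bg_a = aperiodic_background(spec_a, rng_a)
    alpha_b_indep = narrowband_component(spec_b, rng_b)
    bg_b = aperiodic_background(spec_b, rng_b)

    rng_m = np.random.default_rng((spec_a.seed, spec_b.seed, 202))
    z = _modulator_logs(spec_a.n_samples, spec_a.fs, rng_m)
    sig = 0.7
    m = np.exp(sig * z - sig**2 / 2.0)
    c = coupling.coupling_strength / (1.0 + np.exp(-z))  # in (0, strength)

    shifted = np.real(signal.hilbert(alpha_a) * np.exp(-1j * coupling.phase_lag))
    alpha_b = np.sqrt(1.0 - c**2) * alpha_b_indep + c * shifted

    a = spec_a.alpha_gain * m * alpha_a + spec_a.aperiodic_gain * bg_a
    b = spec_b.alpha_gain * m * alpha_b + spec_b.aperiodic_gain * bg_b
    meta = {"coupling": coupling.__dict__, "power_coupled": True}
    return (
        RegionTimeSeries(a[None, :], fs=spec_a.fs, labels=["A"], meta=meta),
        RegionTimeSeries(b[None, :], fs=spec_b.fs, labels=["B"], meta=meta),
    )


def gen_toy_connectome(spec: ToyConnectomeSpec) -> Connectome:
    """Random symmetric connectome: non-negative weights, zero diagonal,
    symmetric tract lengths in ``length_range`` (mm)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    upper = np.triu_indices(n, k=1)
    present = rng.random(len(upper[0])) < spec.density
    w_vals = rng.gamma(2.0, spec.weight_scale / 2.0, len(upper[0])) * present
    l_vals = rng.uniform(*spec.length_range, len(upper[0])) * present
    W = np.zeros((n, n))
    L = np.zeros((n, n))
    W[upper] = w_vals
    L[upper] = l_vals
    W += W.T
    L += L.T
    return Connectome(W, L, [f"r{i:03d}" for i in range(n)])
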