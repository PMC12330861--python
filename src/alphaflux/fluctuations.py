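"""Alpha-power fluctuation analysis.

From a region signal to a verdict on its alpha-power distribution:

1. Morlet time-frequency representation (7 cycles, 2-40 Hz in 0.25 Hz
   steps) — ``morlet_tfr``;
2. alpha-band power time course: TFR averaged over ``iaf +/- 2`` Hz —
   ``alpha_power_series`` (this is TFR(alpha));
3. distribution modeling of the power values: unimodal exponential
   ``P(x) = lam exp(-lam x)`` vs a two-component exponential mixture
   ``P(x) = w lam1 exp(-lam1 x) + (1-w) lam2 exp(-lam2 x)`` fitted by
   maximum likelihood (EM for the mixture), compared by BIC
   ``k ln(n) - 2 ln(L)`` (k = 1 vs 3) and by Kolmogorov-Smirnov
   distance; gamma / Weibull / log-normal alternatives available;
4. cross-likelihood scoring: the log-likelihood of one (e.g. simulated)
   power series under the exponential model fitted to a (normalized)
   reference series — higher means more plausible under the reference.

Fits use raw samples by MLE; the 200-bin histogram is reporting-only.
Samples within half a wavelet length of either recording edge are
excluded from power-series statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .containers import RegionTimeSeries

__all__ = [
    "TFR",
    "PowerSeries",
    "PowerHistogram",
    "ExpFit",
    "BiExpFit",
    "FitComparison",
    "morlet_tfr",
    "alpha_power_series",
    "power_histogram",
    "fit_exponential",
    "fit_biexponential",
    "bic",
    "ks_distance",
    "fit_alternatives",
    "compare_fits",
    "normalize_power",
    "cross_loglik",
]

#: multiplicative scale applied to empirical MEG band power for unit
#: bookkeeping; synthetic and simulated data use scale 1.
EMPIRICAL_MEG_SCALE = 1e-19


class DegenerateInputError(ValueError):
    """Input carries no usable variation (constant or zero-mean series)."""


# ----------------------------------------------------------------- TFR


@dataclass
class TFR:
    """Time-frequency power: ``power[i, t]`` at ``freqs[i]``, ``times[t]``.

    ``valid[i, t]`` is False within half a wavelet length of either edge
    at that frequency (edge-contaminated samples).
    """

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("TFR power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def morlet_tfr(
    ts: RegionTimeSeries,
    fmin: float = 2.0,
    fmax: float = 40.0,
    fstep: float = 0.25,
    n_cycles: float = 7.0,
    region: int = 0,
) -> TFR:
    """Complex Morlet TFR (power) of one region's signal.

    Uses ``n_cycles`` cycles at every frequency; power is the squared
    magnitude of the wavelet coefficient.  Samples within half a wavelet
    length (``n_cycles / (2 f)`` seconds) of either end are flagged
    invalid per frequency row.
    """
    from mne.time_frequency import tfr_array_morlet

    if ts.fs <= 2.0 * fmax:
        raise ValueError("sampling rate must exceed twice fmax")
    freqs = np.arange(fmin, fmax + fstep / 2.0, fstep)
    longest = n_cycles / fmin  # seconds
    if ts.duration < longest:
        raise ValueError(
            f"signal ({ts.duration:.2f} s) shorter than the longest wavelet "
            f"({longest:.2f} s at {fmin} Hz)"
        )
    x = ts.data[region][None, None, :]
    power = tfr_array_morlet(
        x, sfreq=ts.fs, freqs=freqs, n_cycles=n_cycles, output="power",
        zero_mean=False, verbose="error",
    )[0, 0]
    times = ts.times
    half_len = n_cycles / (2.0 * freqs)  # seconds per row
    valid = (times[None, :] >= half_len[:, None]) & (
        times[None, :] <= times[-1] - half_len[:, None]
    )
    return TFR(freqs=freqs, times=times, power=power, valid=valid, fs=ts.fs)


# --------------------------------------------------------- power series


@dataclass
class PowerSeries:
    """Alpha-band power over time for one region."""

    values: np.ndarray
    dt: float                      # s between samples
    region: str = ""
    band: dict = field(default_factory=dict)   # {"iaf": Hz, "halfwidth": Hz}
    scale_applied: float = 1.0
    normalized: str | None = None  # normalization method, if any

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty power series")
        if np.any(self.values < 0):
            raise ValueError("power values must be non-negative")

    @property
    def n(self) -> int:
        return self.values.size


def alpha_power_series(
    tfr: TFR,
    iaf: float,
    halfwidth: float = 2.0,
    scale: float = 1.0,
    region: str = "",
) -> PowerSeries:
    """Average the TFR across the ``iaf +/- halfwidth`` band, per time point.

    ``scale`` is a unit-bookkeeping factor (``EMPIRICAL_MEG_SCALE`` for
    empirical MEG power; 1 for synthetic/simulated data).  Samples
    edge-flagged in any in-band row are dropped.
    """
    in_band = np.abs(tfr.freqs - iaf) <= halfwidth + 1e-9
    if not in_band.any():
        raise ValueError(f"band {iaf}+/-{halfwidth} Hz not covered by the TFR grid")
    series = tfr.power[in_band].mean(axis=0) * scale
    valid = tfr.valid[in_band].all(axis=0)
    return PowerSeries(
        values=series[valid],
        dt=float(tfr.times[1] - tfr.times[0]) if tfr.times.size > 1 else 1.0 / tfr.fs,
        region=region,
        band={"iaf": iaf, "halfwidth": halfwidth},
        scale_applied=scale,
    )


@dataclass
class PowerHistogram:
    """Equal-width histogram of power values (reporting/visualization)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def power_histogram(ps: PowerSeries, n_bins: int = 200) -> PowerHistogram:
    """Equal-width histogram spanning [min, max] of the series."""
    x = ps.values
    if x.size < n_bins:
        raise ValueError(f"need at least {n_bins} samples for {n_bins} bins")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant power series cannot be histogrammed")
    counts, edges = np.histogram(x, bins=n_bins)
    density, _ = np.histogram(x, bins=n_bins, density=True)
    return PowerHistogram(bin_edges=edges, counts=counts, density=density)


# ------------------------------------------------------------- fitting


@dataclass(frozen=True)
class ExpFit:
    """Unimodal exponential fit: rate ``lam`` = 1/mean (the MLE)."""

    lam: float
    loglik: float
    n: int

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        ok = x >= 0
        out[ok] = np.log(self.lam) - self.lam * x[ok]
        return out

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return np.clip(1.0 - np.exp(-self.lam * np.asarray(x, float)), 0.0, 1.0)


@dataclass(frozen=True)
class BiExpFit:
    """Two-component exponential mixture, components ordered lam1 > lam2."""

    w: float
    lam1: float
    lam2: float
    loglik: float
    n: int
    converged: bool
    n_iter: int

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a = np.log(self.w) + np.log(self.lam1) - self.lam1 * x
        b = np.log1p(-self.w) + np.log(self.lam2) - self.lam2 * x
        out = np.logaddexp(a, b)
        return np.where(x >= 0, out, -np.inf)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.w * (1.0 - np.exp(-self.lam1 * x)) + (1.0 - self.w) * (
            1.0 - np.exp(-self.lam2 * x)
        )
        return np.clip(c, 0.0, 1.0)


def fit_exponential(ps: PowerSeries | np.ndarray) -> ExpFit:
    """Closed-form exponential MLE: lam = 1/mean."""
    x = ps.values if isinstance(ps, PowerSeries) else np.asarray(ps, float)
    if np.any(x < 0):
        raise ValueError("exponential fit requires non-negative values")
    m = x.mean()
    if m <= 0:
        raise DegenerateInputError("zero-mean series cannot be fit")
    lam = 1.0 / m
    n = x.size
    return ExpFit(lam=lam, loglik=n * (np.log(lam) - 1.0), n=n)


def _em_biexp(x, w, l1, l2, tol, max_iter):
    """EM iterations for the 2-exponential mixture; returns params,
    loglik, n_iter, converged."""
    n = x.size
    ll_old = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        la = np.log(w) + np.log(l1) - l1 * x
        lb = np.log1p(-w) + np.log(l2) - l2 * x
        tot = np.logaddexp(la, lb)
        ll = tot.sum()
        r = np.exp(la - tot)  # responsibility of component 1
        s = r.sum()
        if s < 1e-12 or n - s < 1e-12:  # component collapsed
            break
        w = s / n
        l1 = s / max((r * x).sum(), 1e-300)
        l2 = (n - s) / max(((1.0 - r) * x).sum(), 1e-300)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            return (w, l1, l2), ll, it, True
        ll_old = ll
    la = np.log(w) + np.log(l1) - l1 * x
    lb = np.log1p(-w) + np.log(l2) - l2 * x
    return (w, l1, l2), np.logaddexp(la, lb).sum(), it, False


def fit_biexponential(
    ps: PowerSeries | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> BiExpFit:
    """Two-exponential mixture by EM with multiple restarts.

    Restarts include a symmetric split of the unimodal MLE (guaranteeing
    the mixture log-likelihood is never below the unimodal one) and
    quantile-based splits.  Components are ordered ``lam1 > lam2``.
    """
    x = ps.values if isinstance(ps, PowerSeries) else np.asarray(ps, float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a mixture fit")
    uni = fit_exponential(x)
    lam = uni.lam

    starts = [(0.5, 2.0 * lam, 0.5 * lam), (0.5, 4.0 * lam, 0.25 * lam)]
    for q in (0.3, 0.5, 0.7):
        cut = np.quantile(x, q)
        lo, hi = x[x <= cut], x[x > cut]
        if lo.size and hi.size and lo.mean() > 0 and hi.mean() > 0:
            starts.append((q, 1.0 / max(lo.mean(), 1e-300), 1.0 / hi.mean()))
    starts = starts[:n_restarts]

    best = None
    for w0, a0, b0 in starts:
        (w, l1, l2), ll, it, conv = _em_biexp(x, w0, a0, b0, tol, max_iter)
        if best is None or ll > best[1]:
            best = ((w, l1, l2), ll, it, conv)
    (w, l1, l2), ll, it, conv = best

    # nesting guarantee: the mixture can always represent the unimodal fit
    eps = 1e-9
    if ll < uni.loglik:
        w, l1, l2 = 0.5, lam * (1.0 + eps), lam * (1.0 - eps)
        la = np.log(w) + np.log(l1) - l1 * x
        lb = np.log1p(-w) + np.log(l2) - l2 * x
        ll, conv, it = np.logaddexp(la, lb).sum(), True, 0
    if l1 < l2:
        w, l1, l2 = 1.0 - w, l2, l1
    if l1 == l2:
        l1 *= 1.0 + eps
    w = float(np.clip(w, 1e-12, 1.0 - 1e-12))
    return BiExpFit(w=w, lam1=float(l1), lam2=float(l2), loglik=float(ll),
                    n=x.size, converged=bool(conv), n_iter=int(it))


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion ``k ln(n) - 2 loglik`` (lower = better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * np.log(n) - 2.0 * loglik


def ks_distance(ps: PowerSeries | np.ndarray, cdf, estimated_params: bool = True) -> dict:
    """One-sample Kolmogorov-Smirnov distance against a theoretical CDF.

    ``D = sup |F_emp - F|``; the p-value uses the asymptotic Kolmogorov
    distribution.  When the CDF's parameters were estimated from the same
    data (the usual case here) the asymptotic p-value is conservativeness-
    biased; the flag records this caveat.
    """
    x = ps.values if isinstance(ps, PowerSeries) else np.asarray(ps, float)
    n = x.size
    if n < 1:
        raise ValueError("need at least one sample")
    xs = np.sort(x)
    F = np.asarray(cdf(xs), dtype=float)
    if np.any(F < -1e-9) | np.any(F > 1.0 + 1e-9) or np.any(np.isnan(F)):
        raise ValueError("cdf must return values in [0, 1]")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    D = float(max(d_plus, d_minus))
    p = float(special.kolmogorov(np.sqrt(n) * D))
    return {"D": D, "p": p, "n": n, "estimated_params": estimated_params}


def fit_alternatives(ps: PowerSeries | np.ndarray) -> dict:
    """MLE fits and KS distances for gamma, Weibull, and log-normal
    families (location pinned to 0); non-positive values are excluded
    from the log-normal fit with a warning."""
    x = ps.values if isinstance(ps, PowerSeries) else np.asarray(ps, float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series cannot be fit")
    if np.any(x <= 0):
        n_bad = int(np.sum(x <= 0))
        warnings.warn(
            f"dropping {n_bad} non-positive values (gamma/weibull/lognormal "
            "MLE requires x > 0)",
            UserWarning,
        )
        x = x[x > 0]
    out = {}
    spec = {
        "gamma": stats.gamma,
        "weibull": stats.weibull_min,
        "lognormal": stats.lognorm,
    }
    for name, dist in spec.items():
        data = x
        params = dist.fit(data, floc=0)
        frozen = dist(*params)
        out[name] = {
            "params": tuple(float(p) for p in params),
            "loglik": float(frozen.logpdf(data).sum()),
            "ksd": ks_distance(data, frozen.cdf),
        }
    return out


@dataclass
class FitComparison:
    """Unimodal vs bimodal exponential comparison for one power series."""

    uni: ExpFit
    bi: BiExpFit
    bic_uni: float
    bic_bi: float
    ksd_uni: dict
    ksd_bi: dict
    best: str                      # "unimodal" | "bimodal"
    alt_fits: dict | None = None

    @property
    def delta_bic(self) -> float:
        """``bic_uni - bic_bi``: positive favors the bimodal model."""
        return self.bic_uni - self.bic_bi


def compare_fits(ps: PowerSeries | np.ndarray, include_alternatives: bool = False) -> FitComparison:
    """Fit both exponential models, compare by BIC (k = 1 vs 3) and KS."""
    x = ps.values if isinstance(ps, PowerSeries) else np.asarray(ps, float)
    uni = fit_exponential(x)
    bi = fit_biexponential(x)
    b_uni = bic(uni.loglik, 1, uni.n)
    b_bi = bic(bi.loglik, 3, bi.n)
    return FitComparison(
        uni=uni, bi=bi, bic_uni=float(b_uni), bic_bi=float(b_bi),
        ksd_uni=ks_distance(x, uni.cdf),
        ksd_bi=ks_distance(x, bi.cdf),
        best="unimodal" if b_uni <= b_bi else "bimodal",
        alt_fits=fit_alternatives(x) if include_alternatives else None,
    )


def normalize_power(ps: PowerSeries, method: str = "mean") -> PowerSeries:
    """Normalize a power series (default: divide by its mean, making the
    exponential MLE rate exactly 1 for any input scale)."""
    if method != "mean":
        raise ValueError(f"unknown normalization method: {method}")
    m = ps.values.mean()
    if m <= 0:
        raise DegenerateInputError("zero-mean series cannot be normalized")
    return PowerSeries(
        values=ps.values / m, dt=ps.dt, region=ps.region, band=dict(ps.band),
        scale_applied=ps.scale_applied / m, normalized=method,
    )


def cross_loglik(sim: PowerSeries | np.ndarray, ref: ExpFit | BiExpFit) -> float:
    """Log-likelihood of one series under a reference exponential model.

    ``sum_i ln f_ref(x_i)``; higher values mean the series is more
    plausible under the reference distribution.  Values where the
    reference density is zero contribute ``-inf``.
    """
    x = sim.values if isinstance(sim, PowerSeries) else np.asarray(sim, float)
    return float(ref.logpdf(x).sum())
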