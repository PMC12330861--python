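"""Power-spectrum parameterization: aperiodic (1/f-like) component plus
Gaussian periodic peaks, and individual alpha frequency (IAF) selection.

The spectrum (time-averaged from a Morlet time-frequency representation)
is modeled in log10 power as

    log10 P(f) = offset - log10(knee + f^exponent) + sum_k G_k(f)

where each ``G_k`` is a Gaussian in linear frequency (center, height in
log-power units, standard deviation).  The fit is iterative: a robust
aperiodic fit, Gaussian peaks extracted largest-first from the flattened
residual until below a relative threshold, then an aperiodic refit on
the peak-subtracted spectrum.  With ``aperiodic_mode="fixed"`` the knee
is pinned to zero (pure power law).

The IAF is the center frequency of the highest-power detected peak in
the 8-12 Hz alpha band; when no alpha peak is detected the IAF defaults
to 10 Hz and the fit is flagged as defaulted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Spectrum",
    "SpectralPeak",
    "SpectralFit",
    "spectrum_from_tfr",
    "fit_spectral_model",
    "select_iaf",
]

# peak extraction settings: conventional defaults for this kind of model
PEAK_THRESHOLD_SD = 2.0       # relative threshold, in SDs of the flat residual
MAX_N_PEAKS = 6
PEAK_WIDTH_LIMITS = (1.0, 8.0)  # FWHM-like bandwidth limits, Hz
MIN_PEAK_HEIGHT = 0.05          # absolute floor, log10-power units


@dataclass
class Spectrum:
    """Frequency grid (Hz) and positive spectral power."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be 1-D and equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power <= 0):
            raise ValueError("power must be strictly positive for log-log fitting")


@dataclass(frozen=True)
class SpectralPeak:
    center_freq: float          # Hz
    power_over_aperiodic: float  # log10-power units (Gaussian height)
    bandwidth: float            # Hz (2 * Gaussian SD)


@dataclass
class SpectralFit:
    """Parameterized spectrum: aperiodic (offset, exponent, knee) plus peaks."""

    offset: float
    exponent: float
    knee: float
    peaks: list[SpectralPeak]
    iaf: float
    iaf_defaulted: bool
    alpha_peak_power: float | None
    fit_range: tuple[float, float]
    aperiodic_mode: str
    r_squared: float

    def to_json(self, path: str | Path) -> None:
        d = {**self.__dict__, "peaks": [p.__dict__ for p in self.peaks]}
        Path(path).write_text(json.dumps(d, indent=2))


def spectrum_from_tfr(tfr) -> Spectrum:
    """Time-average a time-frequency representation into a spectrum.

    Edge samples flagged invalid in the TFR are excluded from the mean.
    """
    power = np.asarray(tfr.power, dtype=float)
    if power.ndim != 2 or power.shape[1] < 1:
        raise ValueError("TFR must be a freq x time matrix with >= 1 time point")
    valid = getattr(tfr, "valid", None)
    mean = power.mean(axis=1)
    if valid is not None:
        valid = np.asarray(valid, bool)
        if valid.ndim == 1:
            valid = np.broadcast_to(valid, power.shape)
        for i in range(power.shape[0]):  # per-row edge exclusion
            if valid[i].any():
                mean[i] = power[i, valid[i]].mean()
    return Spectrum(np.asarray(tfr.freqs, float), mean)


def _aperiodic(f: np.ndarray, offset: float, knee: float, exponent: float) -> np.ndarray:
    return offset - np.log10(knee + f**exponent)


def _gaussians(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for ctr, hgt, sd in params.reshape(-1, 3):
        out += hgt * np.exp(-((f - ctr) ** 2) / (2.0 * sd**2))
    return out


def _fit_aperiodic(f: np.ndarray, y: np.ndarray, mode: str) -> np.ndarray:
    """Return (offset, knee, exponent); knee fixed at 0 in 'fixed' mode."""
    guess_exp = max((y[0] - y[-1]) / max(np.log10(f[-1] / f[0]), 1e-12), 0.0)
    if mode == "fixed":
        def model(ff, off, expo):
            return off - expo * np.log10(ff)
        p0 = [y[0] + guess_exp * np.log10(f[0]), guess_exp]
        popt, _ = curve_fit(model, f, y, p0=p0, maxfev=5000)
        return np.array([popt[0], 0.0, popt[1]])
    p0 = [y[0] + guess_exp * np.log10(f[0]), 0.0, max(guess_exp, 0.1)]
    bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, 10.0])
    popt, _ = curve_fit(_aperiodic, f, y, p0=p0, bounds=bounds, maxfev=10000)
    return np.asarray(popt)  # (offset, knee, exponent)


def _robust_aperiodic(f: np.ndarray, y: np.ndarray, mode: str) -> np.ndarray:
    """Aperiodic fit down-weighting points that sit above the curve
    (candidate peaks): fit, drop positive outliers, refit."""
    popt = _fit_aperiodic(f, y, mode)
    resid = y - _aperiodic(f, popt[0], popt[1], popt[2])
    sd = resid.std()
    keep = resid <= max(1.0 * sd, 1e-12)
    if keep.sum() >= 6 and keep.sum() < keep.size:
        popt = _fit_aperiodic(f[keep], y[keep], mode)
    return popt


def _extract_peaks(f: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Iterative largest-first Gaussian extraction from the flattened
    (log-power) residual; returns flattened (center, height, sd) triples."""
    sd_lo = PEAK_WIDTH_LIMITS[0] / 2.0
    sd_hi = PEAK_WIDTH_LIMITS[1] / 2.0
    work = flat.copy()
    guesses: list[list[float]] = []
    for _ in range(MAX_N_PEAKS):
        thresh = max(PEAK_THRESHOLD_SD * work.std(), MIN_PEAK_HEIGHT)
        i = int(np.argmax(work))
        height = work[i]
        if height <= thresh:
            break
        ctr = f[i]
        # half-height width estimate on the taller side available
        half = height / 2.0
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < work.size - 1 and work[ri] > half:
            ri += 1
        fwhm = max(f[min(ri, work.size - 1)] - f[max(li, 0)], f[1] - f[0])
        sd_guess = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append([ctr, height, sd_guess])
        work = work - height * np.exp(-((f - ctr) ** 2) / (2.0 * sd_guess**2))
    if not guesses:
        return np.empty(0)
    # joint refinement of all peaks on the original flattened residual
    p0 = np.array(guesses).ravel()
    lo, hi = [], []
    for ctr, height, _sd in guesses:
        lo += [f[0], 0.0, sd_lo]
        hi += [f[-1], np.inf, sd_hi]
    try:
        popt, _ = curve_fit(
            lambda ff, *p: _gaussians(ff, np.asarray(p)), f, flat,
            p0=p0, bounds=(lo, hi), maxfev=10000,
        )
    except RuntimeError:
        popt = p0
    # drop peaks that shrank below the absolute floor during refinement
    triples = popt.reshape(-1, 3)
    return triples[triples[:, 1] >= MIN_PEAK_HEIGHT].ravel()


def fit_spectral_model(
    spectrum: Spectrum,
    fmin: float = 2.0,
    fmax: float = 40.0,
    aperiodic_mode: str = "knee",
) -> SpectralFit:
    """Fit the aperiodic + Gaussian-peaks model over [fmin, fmax] Hz."""
    if aperiodic_mode not in ("knee", "fixed"):
        raise ValueError("aperiodic_mode must be 'knee' or 'fixed'")
    sel = (spectrum.freqs >= fmin) & (spectrum.freqs <= fmax)
    if sel.sum() < 8:
        raise ValueError("fit range must contain at least 8 frequency points")
    f = spectrum.freqs[sel]
    y = np.log10(spectrum.power[sel])

    ap = _robust_aperiodic(f, y, aperiodic_mode)
    peak_params = np.empty(0)
    # two flatten/extract/refit rounds: the second corrects the aperiodic
    # tilt left by imperfect peak subtraction in the first
    for _ in range(2):
        flat = np.clip(y - _aperiodic(f, *ap), 0.0, None)
        peak_params = _extract_peaks(f, flat)
        y_no_peaks = y - (_gaussians(f, peak_params) if peak_params.size else 0.0)
        ap = _fit_aperiodic(f, y_no_peaks, aperiodic_mode)
    # drop peaks hugging the fit edges (artifacts of flattening)
    if peak_params.size:
        triples = peak_params.reshape(-1, 3)
        interior = (triples[:, 0] - triples[:, 2] >= f[0]) & (
            triples[:, 0] + triples[:, 2] <= f[-1]
        )
        peak_params = triples[interior].ravel()

    model = _aperiodic(f, *ap) + (_gaussians(f, peak_params) if peak_params.size else 0.0)
    ss_res = float(np.sum((y - model) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    peaks = [
        SpectralPeak(float(c), float(h), float(2.0 * s))
        for c, h, s in (peak_params.reshape(-1, 3) if peak_params.size else [])
    ]
    peaks.sort(key=lambda p: -p.power_over_aperiodic)

    fit = SpectralFit(
        offset=float(ap[0]), exponent=float(ap[2]), knee=float(ap[1]),
        peaks=peaks, iaf=np.nan, iaf_defaulted=False, alpha_peak_power=None,
        fit_range=(fmin, fmax), aperiodic_mode=aperiodic_mode, r_squared=r2,
    )
    fit.iaf, fit.iaf_defaulted, fit.alpha_peak_power = _alpha_selection(peaks)
    return fit


def _alpha_selection(peaks: list[SpectralPeak]) -> tuple[float, bool, float | None]:
    alpha = [p for p in peaks if 8.0 <= p.center_freq <= 12.0]
    if not alpha:
        return 10.0, True, None
    best = max(alpha, key=lambda p: p.power_over_aperiodic)
    return best.center_freq, False, best.power_over_aperiodic


def select_iaf(fit: SpectralFit) -> float:
    """Individual alpha frequency: center of the highest-power peak in
    8-12 Hz, defaulting to 10 Hz when no alpha peak was detected."""
    iaf, defaulted, power = _alpha_selection(fit.peaks)
    fit.iaf, fit.iaf_defaulted, fit.alpha_peak_power = iaf, defaulted, power
    return iaf
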