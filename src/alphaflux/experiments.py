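"""Parameter-space sweeps, regime scoring, and group statistics.

``run_sweep`` maps out the Jansen-Rit parameter space (any one or two of
p, sigma, g): per cell it simulates, parameterizes the spectrum (IAF,
alpha peak power, aperiodic exponent), extracts the alpha-power time
course, fits the unimodal/bimodal exponential models and records
amplitude, log-likelihoods and the BIC difference — optionally also the
cross-likelihood against a reference exponential model, which scores how
plausible the simulated fluctuations are under empirically-shaped ones.

``replicate_empirical_pipeline`` runs the per-region distribution
analysis over a cohort (subjects x conditions x regions) and the group
statistics: Friedman tests across conditions and across regions (blocks
= subjects) on the BIC differences, and Spearman correlations between
the spectral characteristics and the distribution-modeling outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .containers import Connectome, RegionTimeSeries
from .fluctuations import (
    ExpFit,
    BiExpFit,
    alpha_power_series,
    bic,
    compare_fits,
    cross_loglik,
    morlet_tfr,
    normalize_power,
)
from .jansen_rit import JRParams, SimConfig, SimulationDivergedError, simulate
from .spectral import fit_spectral_model, spectrum_from_tfr

__all__ = [
    "SweepSpec",
    "SweepResult",
    "CellMetrics",
    "analyze_output",
    "run_sweep",
    "friedman_test",
    "spearman_corr",
    "bonferroni",
    "replicate_empirical_pipeline",
]


# --------------------------------------------------------- single cell


@dataclass
class CellMetrics:
    """Spectral and distribution metrics of one simulated (or measured)
    region signal."""

    amplitude: float            # max - min, mV
    iaf: float                  # Hz (10 when defaulted)
    iaf_defaulted: bool
    alpha_peak_power: float     # log10-power units; NaN if no alpha peak
    exponent: float             # aperiodic exponent
    loglik_uni: float
    delta_bic: float            # positive favors bimodal
    cross_loglik: float         # NaN unless a reference was given
    mean_power: float


def analyze_output(
    ts: RegionTimeSeries,
    region: int = 0,
    reference: ExpFit | BiExpFit | None = None,
    fstep: float = 0.25,
) -> CellMetrics:
    """Spectrum parameterization + exponential modeling of one region."""
    tfr = morlet_tfr(ts, fstep=fstep, region=region)
    spec = spectrum_from_tfr(tfr)
    sfit = fit_spectral_model(spec)
    ps = alpha_power_series(tfr, iaf=sfit.iaf, region=str(ts.labels[region]))
    comp = compare_fits(ps)
    x = ts.data[region]
    return CellMetrics(
        amplitude=float(x.max() - x.min()),
        iaf=sfit.iaf,
        iaf_defaulted=sfit.iaf_defaulted,
        alpha_peak_power=(
            float(sfit.alpha_peak_power) if sfit.alpha_peak_power is not None else np.nan
        ),
        exponent=sfit.exponent,
        loglik_uni=comp.uni.loglik,
        delta_bic=comp.delta_bic,
        cross_loglik=(
            cross_loglik(ps, reference) if reference is not None else np.nan
        ),
        mean_power=float(ps.values.mean()),
    )


# --------------------------------------------------------------- sweep


@dataclass(frozen=True)
class SweepSpec:
    """Up to two swept axes over {p, sigma, g} with fixed remaining
    parameters; each cell is simulated with ``seeds_per_cell`` seeds."""

    axes: tuple[str, ...]                  # e.g. ("p",) or ("p", "sigma")
    grids: tuple[np.ndarray, ...]
    params: JRParams = JRParams()
    config: SimConfig = SimConfig(seed=0)
    connectome: Connectome | None = None
    seeds_per_cell: int = 1
    node: int = 0                          # analyzed node for network sweeps
    reference: ExpFit | BiExpFit | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2 or len(self.axes) != len(self.grids):
            raise ValueError("need 1 or 2 axes with matching grids")
        if any(a not in ("p", "sigma", "g") for a in self.axes):
            raise ValueError("axes must be among p, sigma, g")
        if self.seeds_per_cell < 1:
            raise ValueError("seeds_per_cell must be >= 1")


@dataclass
class SweepResult:
    """Grid-shaped metric arrays (seed-averaged); NaN marks failed cells
    or undetected alpha peaks."""

    spec: SweepSpec
    shape: tuple[int, ...]
    metrics: dict[str, np.ndarray]

    def axis_values(self, name: str) -> np.ndarray:
        return self.spec.grids[self.spec.axes.index(name)]


_METRIC_FIELDS = (
    "amplitude", "iaf", "alpha_peak_power", "exponent",
    "loglik_uni", "delta_bic", "cross_loglik", "mean_power",
)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Simulate and analyze every grid cell; fully seeded and cell-order
    independent (each cell derives its seeds from its grid index)."""
    shape = tuple(len(g) for g in spec.grids) + (
        () if spec.seeds_per_cell == 1 else ()
    )
    out = {m: np.full(shape, np.nan) for m in _METRIC_FIELDS}
    base_seed = spec.config.seed if spec.config.seed is not None else 0
    for idx in np.ndindex(*shape):
        overrides = {a: float(spec.grids[k][idx[k]]) for k, a in enumerate(spec.axes)}
        params = replace(spec.params, **overrides)
        cell_vals: dict[str, list[float]] = {m: [] for m in _METRIC_FIELDS}
        for s in range(spec.seeds_per_cell):
            cell_seed = (base_seed + 7919 * s + 104729 * (np.ravel_multi_index(idx, shape) + 1)) % (2**31)
            config = replace(spec.config, seed=int(cell_seed))
            try:
                res = simulate(params, config, connectome=spec.connectome)
                cm = analyze_output(res.output, region=spec.node, reference=spec.reference)
            except (SimulationDivergedError, ValueError):
                continue
            for m in _METRIC_FIELDS:
                cell_vals[m].append(getattr(cm, m))
        for m in _METRIC_FIELDS:
            if cell_vals[m]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    out[m][idx] = np.nanmean(cell_vals[m])
    return SweepResult(spec=spec, shape=shape, metrics=out)


# ----------------------------------------------------------- statistics


def friedman_test(table: np.ndarray) -> dict:
    """Friedman rank test on a blocks x conditions table.

    Rank within each block (average ranks for ties), sum ranks per
    condition, tie-corrected chi-square statistic with k - 1 degrees of
    freedom.  Implemented directly because the two-condition design
    (k = 2) must be supported; agrees with scipy for k >= 3 (tested).
    Returns chi2, df, p, and Kendall's W = chi2 / (n (k - 1)).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 blocks and >= 2 conditions")
    if np.any(np.isnan(table)):
        raise ValueError("missing cells are not supported")
    n, k = table.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    Rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    chi2 = 0.0 if denom <= 0 else chi2 / denom  # all blocks fully tied
    chi2 = float(max(chi2, 0.0))
    return {
        "chi2": chi2,
        "df": k - 1,
        "n": n,
        "p": float(stats.chi2.sf(chi2, k - 1)),
        "kendall_w": chi2 / (n * (k - 1)),
    }


def spearman_corr(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": np.nan, "p": np.nan, "degenerate": True}
    res = stats.spearmanr(x, y)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "degenerate": False}


def bonferroni(p_values, m: int | None = None):
    """Bonferroni correction: ``min(1, p * m)`` (m defaults to len(p))."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size if m is None else m
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------- cohort-level pipeline


@dataclass
class RegionRecord:
    subject: str
    condition: str
    region: str
    iaf: float
    alpha_peak_power: float
    exponent: float
    delta_bic: float
    ksd_best: float


@dataclass
class GroupStats:
    friedman_space: dict | None
    friedman_condition: dict | None
    spearman: dict[str, dict]
    skipped: str | None = None


def _analyze_region(ts: RegionTimeSeries, region: int) -> dict:
    tfr = morlet_tfr(ts, region=region)
    sfit = fit_spectral_model(spectrum_from_tfr(tfr))
    ps = normalize_power(alpha_power_series(tfr, iaf=sfit.iaf))
    comp = compare_fits(ps)
    ksd_best = comp.ksd_uni["D"] if comp.best == "unimodal" else comp.ksd_bi["D"]
    return {
        "iaf": sfit.iaf,
        "alpha_peak_power": (
            sfit.alpha_peak_power if sfit.alpha_peak_power is not None else np.nan
        ),
        "exponent": sfit.exponent,
        "delta_bic": comp.delta_bic,
        "ksd_best": ksd_best,
    }


def replicate_empirical_pipeline(
    dataset: dict[str, dict[str, RegionTimeSeries]],
    alpha_level: float = 0.05,
) -> tuple[list[RegionRecord], GroupStats]:
    """Per-region distribution analysis plus group statistics.

    ``dataset`` maps subject -> condition -> multi-region recording; all
    recordings must share the region set.  Group statistics need >= 2
    subjects and >= 2 conditions; with fewer the group stage is skipped
    with a warning.
    """
    records: list[RegionRecord] = []
    for subject, conds in dataset.items():
        for condition, ts in conds.items():
            for ri, region in enumerate(ts.labels):
                m = _analyze_region(ts, ri)
                records.append(RegionRecord(
                    subject=subject, condition=condition, region=region,
                    iaf=m["iaf"], alpha_peak_power=m["alpha_peak_power"],
                    exponent=m["exponent"], delta_bic=m["delta_bic"],
                    ksd_best=m["ksd_best"],
                ))

    subjects = sorted({r.subject for r in records})
    conditions = sorted({r.condition for r in records})
    regions = sorted({r.region for r in records})
    if len(subjects) < 2 or len(conditions) < 2:
        warnings.warn(
            "group statistics skipped: need >= 2 subjects and >= 2 conditions",
            UserWarning,
        )
        return records, GroupStats(None, None, {}, skipped="insufficient cohort")

    by = {(r.subject, r.condition, r.region): r for r in records}

    # Friedman across regions ("space"), blocks = subjects, values averaged
    # over conditions; and across conditions, values averaged over regions
    space_tbl = np.array([
        [np.mean([by[(s, c, g)].delta_bic for c in conditions]) for g in regions]
        for s in subjects
    ])
    cond_tbl = np.array([
        [np.mean([by[(s, c, g)].delta_bic for g in regions]) for c in conditions]
        for s in subjects
    ])
    fr_space = friedman_test(space_tbl)
    fr_cond = friedman_test(cond_tbl)
    n_tests = 2
    fr_space["p_corr"] = bonferroni(fr_space["p"], n_tests)
    fr_cond["p_corr"] = bonferroni(fr_cond["p"], n_tests)

    # Spearman: spectral characteristics vs delta_bic and vs best-model KSD,
    # over region-level averages (across subjects and conditions)
    region_avg = {
        g: {
            key: np.nanmean([
                getattr(by[(s, c, g)], key) for s in subjects for c in conditions
            ])
            for key in ("iaf", "alpha_peak_power", "exponent", "delta_bic", "ksd_best")
        }
        for g in regions
    }
    spearman: dict[str, dict] = {}
    targets = ("delta_bic", "ksd_best")
    predictors = ("iaf", "alpha_peak_power", "exponent")
    m = len(targets) * len(predictors)
    for tgt in targets:
        for pred in predictors:
            xs = np.array([region_avg[g][pred] for g in regions])
            ys = np.array([region_avg[g][tgt] for g in regions])
            ok = ~(np.isnan(xs) | np.isnan(ys))
            if ok.sum() >= 3:
                res = spearman_corr(xs[ok], ys[ok])
                if not res.get("degenerate"):
                    res["p_corr"] = bonferroni(res["p"], m)
            else:
                res = {"rho": np.nan, "p": np.nan, "degenerate": True}
            spearman[f"{tgt}~{pred}"] = res

    return records, GroupStats(fr_space, fr_cond, spearman)
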