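"""Jansen-Rit neural mass and delay-coupled brain-network simulator.

The Jansen-Rit model describes a cortical column with three interacting
populations — pyramidal cells (``y0``), excitatory interneurons (``y1``)
and inhibitory interneurons (``y2``) — each governed by second-order
synaptic kinetics, with a sigmoidal voltage-to-rate conversion ``S``.
The state of node ``i`` is ``(y0..y5)``, where ``y3..y5`` are the time
derivatives of ``y0..y2`` (units mV and mV/ms; time in ms):

    dy0/dt = y3
    dy1/dt = y4
    dy2/dt = y5
    dy3/dt = (He/tau_e) S[y1 - y2]                - (2/tau_e) y3 - y0/tau_e^2
    dy4/dt = (He/tau_e) (I_i + C_ep S[C_pe y0])   - (2/tau_e) y4 - y1/tau_e^2
    dy5/dt = (Hi/tau_i)  C_ip S[C_pi y0]          - (2/tau_i) y5 - y2/tau_i^2

    S[v]   = 2 e0 / (1 + exp(r (v0 - v)))

The per-node input ``I_i(t) = eta_i(t) + g * sum_j w_ji S[x_j(t - d_ji)]``
combines an intrinsic Gaussian drive ``eta_i ~ N(p, sigma)`` (redrawn each
integration step, held constant within the step) with delayed firing-rate
coupling through the structural connectome, where ``x = y1 - y2`` is the
pyramidal membrane-potential proxy used as each node's output and
``d_ji = L_ji / s`` for tract length ``L`` (mm) and conduction speed
``s`` (m/s).

Integration is stochastic Heun at a configurable step (default 0.1 ms)
with decimation to the recording rate (default 1 kHz).  The module also
provides continuation-style bifurcation scans over the input ``p`` and a
threshold-based locator for the saddle-node (of limit cycles) and
supercritical transitions that delimit the model's oscillatory band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from numba import njit

from .containers import Connectome, RegionTimeSeries

__all__ = [
    "JRParams",
    "SimConfig",
    "SimResult",
    "sigmoid",
    "jr_derivatives",
    "network_input",
    "simulate",
    "downsample_connectome",
    "bifurcation_scan",
    "detect_bifurcations",
]


@dataclass(frozen=True)
class JRParams:
    """Jansen-Rit parameters (units: mV, ms, /ms; speed in m/s).

    Defaults are the standard parameterization producing alpha-band
    oscillations for intrinsic input p roughly in [0.1, 0.33] /ms.
    """

    He: float = 3.25       # excitatory synaptic gain, mV
    Hi: float = 22.0       # inhibitory synaptic gain, mV
    tau_e: float = 10.0    # excitatory time constant, ms
    tau_i: float = 20.0    # inhibitory time constant, ms
    C_pe: float = 135.0    # pyramidal -> excitatory interneurons
    C_ep: float = 108.0    # excitatory interneurons -> pyramidal
    C_pi: float = 33.75    # pyramidal -> inhibitory interneurons
    C_ip: float = 33.75    # inhibitory interneurons -> pyramidal
    e0: float = 0.0025     # half max firing rate, /ms
    r: float = 0.56        # sigmoid steepness, /mV
    v0: float = 6.0        # sigmoid half-activation voltage, mV
    p: float = 0.22        # mean intrinsic input, /ms
    sigma: float = 0.0     # SD of intrinsic input, /ms
    g: float = 0.0         # global coupling factor
    speed: float = 3.9     # conduction speed, m/s

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.e0 <= 0 or self.r <= 0:
            raise ValueError("e0 and r must be positive")
        if self.sigma < 0 or self.g < 0:
            raise ValueError("sigma and g must be non-negative")
        if self.speed <= 0:
            raise ValueError("conduction speed must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Simulation run configuration.

    ``dt`` (ms) must divide the recording period ``1000 / record_fs`` ms;
    the first ``transient`` seconds are discarded from the outputs.
    """

    duration: float = 60.0     # s
    transient: float = 8.0     # s
    record_fs: float = 1000.0  # Hz
    dt: float = 0.1            # ms
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.duration > self.transient:
            raise ValueError("duration must exceed transient")
        rec_period_ms = 1000.0 / self.record_fs
        ratio = rec_period_ms / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("dt must divide the recording period")

    @property
    def record_every(self) -> int:
        return int(round(1000.0 / self.record_fs / self.dt))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


@dataclass
class SimResult:
    """Outputs of one simulation: node x time matrix of ``y1 - y2`` (mV)
    after transient removal, plus the final full state for continuation."""

    output: RegionTimeSeries
    final_state: np.ndarray          # (n_nodes, 6)
    params: JRParams
    config: SimConfig

    @property
    def amplitude(self) -> np.ndarray:
        """Per-node max - min of the post-transient output (mV)."""
        return self.output.data.max(axis=1) - self.output.data.min(axis=1)


# ------------------------------------------------------------------ kernels


def sigmoid(v, params: JRParams):
    """Voltage-to-firing-rate sigmoid, bounded in (0, 2*e0) /ms."""
    v = np.asarray(v, dtype=float)
    return 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - v)))


def jr_derivatives(state: np.ndarray, inputs, params: JRParams) -> np.ndarray:
    """Time derivative of the 6-dimensional state for each node.

    Parameters
    ----------
    state : ndarray (..., 6)
    inputs : scalar or ndarray broadcastable to the node axis
        Total input ``I_i`` in /ms (intrinsic plus network).
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to jr_derivatives")
    y0, y1, y2, y3, y4, y5 = np.moveaxis(state, -1, 0)
    pr = params
    S = lambda v: sigmoid(v, pr)  # noqa: E731
    d = np.empty_like(state)
    d[..., 0] = y3
    d[..., 1] = y4
    d[..., 2] = y5
    d[..., 3] = pr.He / pr.tau_e * S(y1 - y2) - 2.0 / pr.tau_e * y3 - y0 / pr.tau_e**2
    d[..., 4] = (
        pr.He / pr.tau_e * (np.asarray(inputs, dtype=float) + pr.C_ep * S(pr.C_pe * y0))
        - 2.0 / pr.tau_e * y4
        - y1 / pr.tau_e**2
    )
    d[..., 5] = pr.Hi / pr.tau_i * pr.C_ip * S(pr.C_pi * y0) - 2.0 / pr.tau_i * y5 - y2 / pr.tau_i**2
    return d


def network_input(
    history: np.ndarray,
    delay_steps: np.ndarray,
    weights: np.ndarray,
    g: float,
    eta: np.ndarray,
    params: JRParams,
) -> np.ndarray:
    """Total input per node: intrinsic noise plus delayed coupling.

    ``history[j, k]`` holds ``x_j = y1_j - y2_j`` at ``k`` integration
    steps before now (``k = 0`` is the current sample); it must cover the
    maximum delay.  ``eta`` is the per-node intrinsic drive for this step.
    """
    history = np.atleast_2d(history)
    n = history.shape[0]
    lag = np.asarray(delay_steps, dtype=int)
    if lag.max(initial=0) >= history.shape[1]:
        raise ValueError("history buffer shorter than the maximum delay")
    xd = history[np.arange(n)[:, None], lag]  # xd[j, i] = x_j(t - d_ji)
    rates = 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - xd)))
    return np.asarray(eta, dtype=float) + g * np.einsum("ji,ji->i", weights, rates)


@njit(cache=True)
def _heun_loop(y, w, dsteps, hist, noise, use_noise, p, g,
               He, Hi, te, ti, Cpe, Cep, Cpi, Cip, e0, r, v0,
               dt, n_steps, rec_every, out):  # pragma: no cover - jit
    n = y.shape[0]
    hist_len = hist.shape[1]
    coupled = g > 0.0 and n > 1
    dy = np.empty((n, 6))
    dyp = np.empty((n, 6))
    yp = np.empty((n, 6))
    I = np.empty(n)
    for k in range(n_steps):
        pos = k % hist_len
        # input frozen over the step: noise + delayed coupling at time t
        for i in range(n):
            I[i] = noise[k, i] if use_noise else p
        if coupled:
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    if w[j, i] != 0.0:
                        xd = hist[j, (pos - dsteps[j, i]) % hist_len]
                        acc += w[j, i] * (2.0 * e0 / (1.0 + np.exp(r * (v0 - xd))))
                I[i] += g * acc
        # derivative at y
        for i in range(n):
            s_pyr = 2.0 * e0 / (1.0 + np.exp(r * (v0 - (y[i, 1] - y[i, 2]))))
            s_exc = 2.0 * e0 / (1.0 + np.exp(r * (v0 - Cpe * y[i, 0])))
            s_inh = 2.0 * e0 / (1.0 + np.exp(r * (v0 - Cpi * y[i, 0])))
            dy[i, 0] = y[i, 3]
            dy[i, 1] = y[i, 4]
            dy[i, 2] = y[i, 5]
            dy[i, 3] = He / te * s_pyr - 2.0 / te * y[i, 3] - y[i, 0] / (te * te)
            dy[i, 4] = He / te * (I[i] + Cep * s_exc) - 2.0 / te * y[i, 4] - y[i, 1] / (te * te)
            dy[i, 5] = Hi / ti * Cip * s_inh - 2.0 / ti * y[i, 5] - y[i, 2] / (ti * ti)
        # predictor
        for i in range(n):
            for m in range(6):
                yp[i, m] = y[i, m] + dt * dy[i, m]
        # derivative at predictor (same frozen input)
        for i in range(n):
            s_pyr = 2.0 * e0 / (1.0 + np.exp(r * (v0 - (yp[i, 1] - yp[i, 2]))))
            s_exc = 2.0 * e0 / (1.0 + np.exp(r * (v0 - Cpe * yp[i, 0])))
            s_inh = 2.0 * e0 / (1.0 + np.exp(r * (v0 - Cpi * yp[i, 0])))
            dyp[i, 0] = yp[i, 3]
            dyp[i, 1] = yp[i, 4]
            dyp[i, 2] = yp[i, 5]
            dyp[i, 3] = He / te * s_pyr - 2.0 / te * yp[i, 3] - yp[i, 0] / (te * te)
            dyp[i, 4] = He / te * (I[i] + Cep * s_exc) - 2.0 / te * yp[i, 4] - yp[i, 1] / (te * te)
            dyp[i, 5] = Hi / ti * Cip * s_inh - 2.0 / ti * yp[i, 5] - yp[i, 2] / (ti * ti)
        # corrector
        for i in range(n):
            for m in range(6):
                y[i, m] = y[i, m] + 0.5 * dt * (dy[i, m] + dyp[i, m])
            if abs(y[i, 1]) > 1e6 or abs(y[i, 2]) > 1e6:
                return k  # divergence
        # record and advance history with the new state
        npos = (k + 1) % hist_len
        for i in range(n):
            hist[i, npos] = y[i, 1] - y[i, 2]
        if (k + 1) % rec_every == 0:
            ridx = (k + 1) // rec_every - 1
            if ridx < out.shape[1]:
                for i in range(n):
                    out[i, ridx] = y[i, 1] - y[i, 2]
    return -1


class SimulationDivergedError(RuntimeError):
    """Raised when a node's state exceeds the divergence bound (1e6 mV)."""


def _delay_steps(connectome: Connectome | None, params: JRParams, dt: float, n: int) -> np.ndarray:
    if connectome is None:
        return np.zeros((n, n), dtype=np.int64)
    # delays rounded to the nearest recording-step (1 ms) multiple
    d_ms = np.round(connectome.delays(params.speed))
    return np.round(d_ms / dt).astype(np.int64)


def simulate(
    params: JRParams,
    config: SimConfig,
    connectome: Connectome | None = None,
    initial_state: np.ndarray | None = None,
    discard_transient: bool = True,
) -> SimResult:
    """Run a single-node or network Jansen-Rit simulation.

    With ``connectome=None`` a single uncoupled node is simulated.  Noise
    streams are spawned per node from ``config.seed``, so a ``g = 0``
    network run is sample-path identical to the corresponding independent
    single-node runs sharing the same spawned seeds.
    """
    n = 1 if connectome is None else connectome.n_regions
    weights = np.zeros((n, n)) if connectome is None else np.asarray(connectome.weights, float)
    dsteps = _delay_steps(connectome, params, config.dt, n)

    n_steps = config.n_steps
    use_noise = params.sigma > 0
    if use_noise:
        if config.seed is None:
            raise ValueError("a seed is required when sigma > 0")
        children = np.random.SeedSequence(config.seed).spawn(n)
        noise = np.empty((n_steps, n))
        for i, ss in enumerate(children):
            noise[:, i] = np.random.default_rng(ss).normal(params.p, params.sigma, n_steps)
    else:
        noise = np.zeros((1, n))

    y = np.zeros((n, 6)) if initial_state is None else np.array(initial_state, float).reshape(n, 6)
    hist_len = int(dsteps.max()) + 1
    hist = np.tile((y[:, 1] - y[:, 2])[:, None], (1, hist_len))

    n_rec = int(round(config.duration * config.record_fs))
    out = np.empty((n, n_rec))
    bad = _heun_loop(
        y, weights, dsteps, hist, noise, use_noise, params.p, params.g,
        params.He, params.Hi, params.tau_e, params.tau_i,
        params.C_pe, params.C_ep, params.C_pi, params.C_ip,
        params.e0, params.r, params.v0,
        config.dt, n_steps, config.record_every, out,
    )
    if bad >= 0:
        raise SimulationDivergedError(
            f"state exceeded 1e6 mV at t = {bad * config.dt:.1f} ms "
            f"(p={params.p}, g={params.g})"
        )
    n_skip = int(round(config.transient * config.record_fs)) if discard_transient else 0
    labels = None if connectome is None else connectome.labels
    ts = RegionTimeSeries(
        out[:, n_skip:],
        fs=config.record_fs,
        labels=labels,
        meta={"model": "jansen-rit", "p": params.p, "sigma": params.sigma,
              "g": params.g, "dt_ms": config.dt, "transient_s": config.transient},
    )
    return SimResult(output=ts, final_state=y, params=params, config=config)


# ------------------------------------------------------- connectome tools


def downsample_connectome(sc: Connectome, mapping: dict[str, str]) -> Connectome:
    """Aggregate regions into groups by averaging weights and lengths.

    ``mapping`` sends each region label to a group label.  Group-to-group
    weight is the mean of all inter-group weights; group length is the
    mean over the nonzero inter-group lengths; the diagonal is zeroed.
    """
    missing = [lbl for lbl in sc.labels if lbl not in mapping]
    if missing:
        raise KeyError(f"unmapped regions: {missing[:5]}")
    groups = sorted(set(mapping[lbl] for lbl in sc.labels))
    gi = {g: i for i, g in enumerate(groups)}
    idx = np.array([gi[mapping[lbl]] for lbl in sc.labels])
    m = len(groups)
    W = np.zeros((m, m))
    L = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            block_w = sc.weights[np.ix_(idx == a, idx == b)]
            block_l = sc.lengths[np.ix_(idx == a, idx == b)]
            W[a, b] = block_w.mean() if block_w.size else 0.0
            nz = block_l[block_l > 0]
            L[a, b] = nz.mean() if nz.size else 0.0
    return Connectome(W, L, groups)


# ------------------------------------------------------ bifurcation scans


@dataclass
class ScanResult:
    """Amplitude (max - min of y1 - y2, mV) along a scan over p."""

    p_values: np.ndarray
    amplitude: np.ndarray
    mode: str


def bifurcation_scan(
    params: JRParams,
    p_grid: np.ndarray,
    mode: Literal["continuation", "cold"] = "continuation",
    config: SimConfig | None = None,
    init_p: float | None = None,
) -> ScanResult:
    """Scan the input p and record post-transient output amplitude.

    In ``continuation`` mode the grid is traversed in the order given
    (increasing for an upward scan, decreasing for a downward one); the
    final state at each p seeds the next, after an initial settling run
    at ``init_p`` (default: the first grid value).  ``cold`` mode restarts
    every p from the zero state.  Noise-free (sigma forced to 0) unless
    the caller set sigma explicitly in ``params``.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.ndim != 1 or p_grid.size == 0:
        raise ValueError("p_grid must be a non-empty 1-D array")
    config = config or SimConfig()
    amps = np.full(p_grid.size, np.nan)
    state = None
    if mode == "continuation":
        p0 = p_grid[0] if init_p is None else init_p
        settle = simulate(replace(params, p=p0), config)
        state = settle.final_state
    elif mode != "cold":
        raise ValueError(f"unknown scan mode: {mode}")
    for k, p in enumerate(p_grid):
        try:
            res = simulate(
                replace(params, p=float(p)),
                config,
                initial_state=state if mode == "continuation" else None,
            )
        except SimulationDivergedError:
            continue
        amps[k] = res.amplitude[0]
        if mode == "continuation":
            state = res.final_state
    return ScanResult(p_values=p_grid, amplitude=amps, mode=mode)


def detect_bifurcations(
    down: ScanResult,
    up: ScanResult,
    threshold: float = 1.0,
) -> dict:
    """Locate the two transitions bounding the limit-cycle band.

    ``p_saddle`` is the smallest p on the downward continuation branch
    whose amplitude exceeds ``threshold`` (mV): below it the large limit
    cycle has collapsed (saddle-node of limit cycles).  ``p_supercritical``
    is the smallest p on the upward branch at which the amplitude falls
    below ``threshold`` and stays below for all larger p (continuous decay
    of the oscillation into a fixed point).
    """
    out: dict[str, float | None] = {"p_saddle": None, "p_supercritical": None}

    order = np.argsort(down.p_values)
    p_d, a_d = down.p_values[order], down.amplitude[order]
    above = np.isfinite(a_d) & (a_d > threshold)
    if above.any():
        out["p_saddle"] = float(p_d[above][0])

    order = np.argsort(up.p_values)
    p_u, a_u = up.p_values[order], up.amplitude[order]
    below = np.isfinite(a_u) & (a_u < threshold)
    # first index from which the amplitude stays below threshold
    for k in range(p_u.size):
        if below[k] and below[k:].all():
            out["p_supercritical"] = float(p_u[k])
            break
    return out
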