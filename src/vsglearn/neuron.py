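"""Leaky integrate-and-fire dynamics with multi-spike soft reset.

The membrane voltage of a neuron driven by ``N`` afferents is

    V(t) = V_rest + sum_i w_i sum_{t_i^j < t} K(t - t_i^j)
                  - sum_{t_s^j < t} eta(t - t_s^j),

where ``K`` is a double-exponential postsynaptic-potential kernel normalized
to unit peak and ``eta(x) = theta * exp(-x / tau_m)`` implements the
post-spike reset ("soft reset"): each emitted spike subtracts the full
threshold from the voltage and the deficit decays with the membrane time
constant.  Both kernels are causal (zero for ``x <= 0``).

Simulation sweeps a fixed time grid.  The two exponential sums in ``K`` are
computed exactly by first-order recursive filters, so the per-grid-point
voltage equals the analytic expression to floating-point accuracy; threshold
crossings are then resolved sequentially because each crossing feeds back
into the voltage through the reset kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "LIFParams",
    "SpikePattern",
    "VoltageTrace",
    "psp_kernel",
    "psp_kernel_derivative",
    "refractory_kernel",
    "normalize_v0",
    "psp_peak_offset",
    "simulate_neuron",
    "simulate_layer",
    "voltage_slope",
    "voltage_at",
]


def psp_peak_offset(tau_m: float, tau_s: float) -> float:
    """Time offset at which the (unnormalized) PSP kernel peaks."""
    return tau_m * tau_s / (tau_m - tau_s) * math.log(tau_m / tau_s)


def normalize_v0(tau_m: float, tau_s: float) -> float:
    """Normalization coefficient giving the PSP kernel a unit peak.

    Closed form: with ``x* = tau_m tau_s / (tau_m - tau_s) ln(tau_m/tau_s)``,
    ``V0 = 1 / (exp(-x*/tau_m) - exp(-x*/tau_s))``.
    """
    if not (tau_m > tau_s > 0):
        raise ValueError(
            f"require tau_m > tau_s > 0, got tau_m={tau_m}, tau_s={tau_s}"
        )
    x = psp_peak_offset(tau_m, tau_s)
    return 1.0 / (math.exp(-x / tau_m) - math.exp(-x / tau_s))


@dataclass(frozen=True)
class LIFParams:
    """LIF neuron constants.

    tau_m, tau_s : membrane / synaptic time constants (ms), tau_m > tau_s.
    theta        : firing threshold (voltage units).
    v_rest       : resting potential.
    v0           : PSP normalization; derived from the time constants unless
                   given explicitly.
    """

    tau_m: float = 20.0
    tau_s: float = 5.0
    theta: float = 1.0
    v_rest: float = 0.0
    v0: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau_m > self.tau_s > 0):
            raise ValueError("require tau_m > tau_s > 0")
        if not (self.theta > self.v_rest):
            raise ValueError("require theta > v_rest")
        if self.v0 is None:
            object.__setattr__(self, "v0", normalize_v0(self.tau_m, self.tau_s))


def psp_kernel(x, p: LIFParams):
    """Normalized PSP kernel K(x); zero for x <= 0, unit peak."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        p.v0 * (np.exp(-x / p.tau_m) - np.exp(-x / p.tau_s)),
        0.0,
    )
    return out if out.ndim else float(out)


def psp_kernel_derivative(x, p: LIFParams):
    """kappa(x) = dK/dx; zero for x <= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        p.v0 * (np.exp(-x / p.tau_s) / p.tau_s - np.exp(-x / p.tau_m) / p.tau_m),
        0.0,
    )
    return out if out.ndim else float(out)


def refractory_kernel(x, p: LIFParams):
    """Reset kernel eta(x) = theta * exp(-x / tau_m); zero for x <= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, p.theta * np.exp(-x / p.tau_m), 0.0)
    return out if out.ndim else float(out)


@dataclass
class SpikePattern:
    """Multisets of spike times (ms) per afferent over a trial window [0, T).

    ``spikes[i]`` is a strictly increasing float array of the *i*-th
    afferent's spike times.
    """

    n_afferents: int
    duration: float
    spikes: list

    def __post_init__(self) -> None:
        if len(self.spikes) != self.n_afferents:
            raise ValueError("spikes list length must equal n_afferents")
        clean = []
        for i, s in enumerate(self.spikes):
            a = np.asarray(s, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"afferent {i}: spike times must be 1-D")
            if a.size:
                if np.any(np.diff(a) <= 0):
                    raise ValueError(f"afferent {i}: times not strictly increasing")
                if a[0] < 0 or a[-1] >= self.duration:
                    raise ValueError(f"afferent {i}: times outside [0, duration)")
            clean.append(a)
        self.spikes = clean

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes as (times, afferent_indices) arrays."""
        if self.n_spikes == 0:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate([s for s in self.spikes])
        idx = np.concatenate(
            [np.full(len(s), i, dtype=int) for i, s in enumerate(self.spikes)]
        )
        return times, idx

    @classmethod
    def from_flat(
        cls, n_afferents: int, duration: float, times, afferents
    ) -> "SpikePattern":
        times = np.asarray(times, dtype=float)
        afferents = np.asarray(afferents, dtype=int)
        spikes = [np.sort(times[afferents == i]) for i in range(n_afferents)]
        return cls(n_afferents, duration, spikes)


@dataclass
class VoltageTrace:
    """Sampled membrane voltage, slope, and emitted spikes for one trial."""

    grid: np.ndarray
    v: np.ndarray
    dv_dt: np.ndarray
    out_spikes: np.ndarray
    out_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    out_left_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_out(self) -> int:
        return len(self.out_spikes)


def _psp_filter_sums(pattern: SpikePattern, W: np.ndarray, grid: np.ndarray,
                     grid_dt: float, p: LIFParams):
    """Exact exponential sums S_m, S_s (shape n_grid x n_post).

    S_m(t_k) = sum_i W[i, :] sum_{t_i^j < t_k} exp(-(t_k - t_i^j)/tau_m)
    computed with a first-order recursive filter over weighted impulses
    carrying the exact sub-grid phase of each input spike.
    """
    n = len(grid)
    n_post = W.shape[1]
    times, aff = pattern.flat()
    imp_m = np.zeros((n, n_post))
    imp_s = np.zeros((n, n_post))
    if times.size:
        idx = np.searchsorted(grid, times, side="right")  # first grid point > t
        keep = idx < n
        idx, times, aff = idx[keep], times[keep], aff[keep]
        off = grid[idx] - times
        np.add.at(imp_m, idx, W[aff] * np.exp(-off / p.tau_m)[:, None])
        np.add.at(imp_s, idx, W[aff] * np.exp(-off / p.tau_s)[:, None])
    S_m = lfilter([1.0], [1.0, -math.exp(-grid_dt / p.tau_m)], imp_m, axis=0)
    S_s = lfilter([1.0], [1.0, -math.exp(-grid_dt / p.tau_s)], imp_s, axis=0)
    return S_m, S_s


def _detect_spikes(v_free: np.ndarray, dpsp: np.ndarray, grid: np.ndarray,
                   grid_dt: float, p: LIFParams, exact_times: bool):
    """Sequential threshold-crossing detection with soft reset.

    Returns (v, dv, out_times, out_indices).  ``v_free`` is the voltage
    without any reset terms; each detected spike subtracts a decaying
    threshold from all later grid points.
    """
    n = len(grid)
    if not exact_times:
        return _detect_spikes_grid(v_free, dpsp, grid, grid_dt, p)
    R = np.zeros(n)  # accumulated reset sum  sum eta(t - t_s)
    out_times: list[float] = []
    out_idx: list[int] = []
    k = 0
    last_j = -1
    while k < n:
        rel = v_free[k:] - R[k:]
        above = rel >= p.theta
        if not above.any():
            break
        j = k + int(np.argmax(above))
        if exact_times and j > 0 and j != last_j:
            v_prev = v_free[j - 1] - R[j - 1]
            v_cur = v_free[j] - R[j]
            frac = (p.theta - v_prev) / (v_cur - v_prev)
            frac = min(max(frac, 1e-12), 1.0)
            ts = grid[j - 1] + frac * grid_dt
        else:
            ts = grid[j]
        out_times.append(float(ts))
        out_idx.append(j)
        last_j = j
        j0 = int(np.searchsorted(grid, ts, side="right"))  # reset acts for t > ts
        if j0 < n:
            R[j0:] += p.theta * np.exp(-(grid[j0:] - ts) / p.tau_m)
        k = j0 if (exact_times and ts < grid[j]) else j + 1
    v = v_free - R
    dv = dpsp + R / p.tau_m
    return v, dv, np.asarray(out_times), np.asarray(out_idx, dtype=int)


def _detect_spikes_grid(v_free: np.ndarray, dpsp: np.ndarray, grid: np.ndarray,
                        grid_dt: float, p: LIFParams):
    """Grid-time spike detection as a single O(n) sweep.

    The reset sum obeys R(t_k) = R(t_{k-1}) e^{-dt/tau_m}, plus theta * decay
    when a spike was recorded at the previous grid point (strict causality:
    a spike affects only later grid points).
    """
    n = len(grid)
    decay = math.exp(-grid_dt / p.tau_m)
    theta, v_rest_unused = p.theta, p.v_rest
    R = np.empty(n)
    out_idx: list[int] = []
    r = 0.0
    spiked_prev = False
    vf = v_free
    for k in range(n):
        r *= decay
        if spiked_prev:
            r += theta * decay
        R[k] = r
        spiked_prev = vf[k] - r >= theta
        if spiked_prev:
            out_idx.append(k)
    v = v_free - R
    dv = dpsp + R / p.tau_m
    idx = np.asarray(out_idx, dtype=int)
    return v, dv, grid[idx] if len(idx) else np.empty(0), idx


def simulate_layer(pattern: SpikePattern, W: np.ndarray, p: LIFParams,
                   grid_dt: float = 0.1, exact_times: bool = False):
    """Simulate a layer of LIF neurons sharing the input ``pattern``.

    W has shape (n_afferents, n_post).  Returns one VoltageTrace per
    postsynaptic neuron.  With ``exact_times`` the threshold-crossing time is
    located by linear interpolation inside the bracketing grid step (and the
    reset kernel uses that time); otherwise the spike is recorded at the
    first grid point whose voltage reaches threshold.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != pattern.n_afferents:
        raise ValueError("weight matrix shape inconsistent with pattern")
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite weights")
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    n = int(round(pattern.duration / grid_dt))
    if n < 1:
        raise ValueError("empty simulation grid")
    grid = np.arange(n) * grid_dt

    S_m, S_s = _psp_filter_sums(pattern, W, grid, grid_dt, p)
    vpsp = p.v0 * (S_m - S_s)
    dpsp = p.v0 * (S_s / p.tau_s - S_m / p.tau_m)

    traces = []
    for s in range(W.shape[1]):
        v, dv, ts, idx = _detect_spikes(
            p.v_rest + vpsp[:, s], dpsp[:, s], grid, grid_dt, p, exact_times
        )
        if exact_times:
            slopes = np.array([
                voltage_slope(pattern, W[:, s], ts[:f], t, p)
                for f, t in enumerate(ts)
            ])
        else:
            slopes = dv[np.maximum(idx - 1, 0)] if len(idx) else np.empty(0)
        traces.append(VoltageTrace(grid, v, dv, ts, idx, slopes))
    return traces


def simulate_neuron(inputs: SpikePattern, weights, p: LIFParams,
                    grid_dt: float = 0.1, exact_times: bool = False) -> VoltageTrace:
    """Simulate a single LIF neuron; see :func:`simulate_layer`."""
    w = np.asarray(weights, dtype=float).reshape(-1, 1)
    return simulate_layer(inputs, w, p, grid_dt=grid_dt, exact_times=exact_times)[0]


def voltage_at(inputs: SpikePattern, weights, out_spikes, t: float,
               p: LIFParams) -> float:
    """Analytic V(t) by direct kernel summation (spikes strictly before t)."""
    w = np.asarray(weights, dtype=float)
    times, aff = inputs.flat()
    x = t - times
    m = x > 0
    v = p.v_rest + float(np.sum(w[aff[m]] * psp_kernel(x[m], p))) if m.any() \
        else p.v_rest
    ts = np.asarray(out_spikes, dtype=float)
    xs = t - ts
    ms = xs > 0
    if ms.any():
        v -= float(np.sum(refractory_kernel(xs[ms], p)))
    return v


def voltage_slope(inputs: SpikePattern, weights, out_spikes, t: float,
                  p: LIFParams) -> float:
    """Analytic left-limit dV/dt at ``t``:

    dV/dt = sum_i w_i sum_{t_i^j < t} kappa(t - t_i^j)
            + sum_{t_s^f < t} eta(t - t_s^f) / tau_m.

    The reset term enters with a positive sign: after a spike the voltage
    deficit decays, so the voltage recovers toward the PSP sum.
    """
    w = np.asarray(weights, dtype=float)
    times, aff = inputs.flat()
    slope = 0.0
    if times.size:
        x = t - times
        m = x > 0
        if m.any():
            slope += float(np.sum(w[aff[m]] * psp_kernel_derivative(x[m], p)))
    ts = np.asarray(out_spikes, dtype=float)
    if ts.size:
        xs = t - ts
        ms = xs > 0
        if ms.any():
            slope += float(np.sum(refractory_kernel(xs[ms], p))) / p.tau_m
    return slope
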