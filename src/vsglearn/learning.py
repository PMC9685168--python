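"""Voltage-slope-guided (VSG) aggregate-label learning.

The only supervision is a desired total spike count ``N_d`` per output
neuron.  Whenever the actual count ``N_o`` differs, a single *critical time*
``t*`` is selected per update:

* ``N_o < N_d`` (potentiation): the non-spike grid point with the largest
  voltage slope.  Such a point always exists, which is the whole point of
  slope-based selection — subthreshold-*peak* selection (the MPD-AL rule)
  can fail when the voltage rises into every spike without a local maximum.
* ``N_o > N_d`` (depression): the existing output spike crossing the
  threshold with the smallest left-limit slope (the easiest spike to
  remove).

The squared error ``E = (V(t*) - V_tar)^2 / 2`` with target ``theta``
(potentiate) or ``V_rest`` (depress) is minimized by gradient descent on the
synaptic weights.  ``dV(t*)/dw`` is exact up to the standard
linear-threshold-crossing assumption: the sensitivity of a spike time to the
voltage is the negative reciprocal of the voltage slope at the crossing.
Errors backpropagate through multi-layer networks along causal spike chains
only (a hidden spike receives error only from later downstream spikes that
precede ``t*``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .neuron import (
    LIFParams,
    SpikePattern,
    VoltageTrace,
    psp_kernel,
    psp_kernel_derivative,
    simulate_layer,
)

__all__ = [
    "CriticalPoint",
    "Network",
    "LearnConfig",
    "SelectionFailure",
    "select_potentiation_time",
    "select_depression_time",
    "select_last_spike_time",
    "select_mpdal_potentiation_time",
    "error_and_factor",
    "kernel_sums",
    "grad_output_layer",
    "network_gradient",
    "train_step",
    "AdamState",
]

STRATEGIES = ("vsg", "mpdal", "combo_a", "combo_b", "combo_c", "combo_d", "combo_e")


@dataclass
class CriticalPoint:
    """Selected adjustment time t* for one update."""

    t_star: float
    mode: str  # "potentiate" | "depress"
    v_at: float
    v_target: float
    index: int  # grid index of t_star


class SelectionFailure(Exception):
    """Raised when a selection strategy has no admissible critical point.

    For the subthreshold-peak strategy this is a reportable learning
    failure, not a bug; experiments count it as a failed attempt.
    """


def select_potentiation_time(trace: VoltageTrace, p: LIFParams) -> CriticalPoint:
    """Critical time for adding a spike: non-spike point of maximum slope.

    Ties break to the earliest time.  A maximum always exists, so this
    selector is total.

    The grid point immediately before each recorded spike is excluded along
    with the spike itself: the threshold crossing happens inside that grid
    step, so at grid resolution the point is part of the crossing — its
    voltage already sits at the threshold, and potentiating it would only
    shift an existing spike rather than add a new one (with the error
    factor, the vanishing voltage gap would stall learning there).
    """
    mask = np.zeros(len(trace.grid), dtype=bool)
    if len(trace.out_indices):
        mask[trace.out_indices] = True
        mask[np.maximum(trace.out_indices - 1, 0)] = True
    slopes = np.where(mask, -np.inf, trace.dv_dt)
    k = int(np.argmax(slopes))
    return CriticalPoint(float(trace.grid[k]), "potentiate",
                         float(trace.v[k]), p.theta, k)


def select_depression_time(trace: VoltageTrace, p: LIFParams) -> CriticalPoint:
    """Critical time for removing a spike: the output spike whose left-limit
    slope is smallest (weakest upward crossing).  Ties break to the latest
    spike."""
    if trace.n_out == 0:
        raise ValueError("depression requires at least one output spike")
    slopes = trace.out_left_slopes
    rev = slopes[::-1]
    f = len(slopes) - 1 - int(np.argmin(rev))
    k = int(trace.out_indices[f])
    return CriticalPoint(float(trace.out_spikes[f]), "depress",
                         float(trace.v[k]), p.v_rest, k)


def select_last_spike_time(trace: VoltageTrace, p: LIFParams) -> CriticalPoint:
    """Depression variant used by MPD-AL: always the last output spike."""
    if trace.n_out == 0:
        raise ValueError("depression requires at least one output spike")
    f = trace.n_out - 1
    k = int(trace.out_indices[f])
    return CriticalPoint(float(trace.out_spikes[f]), "depress",
                         float(trace.v[k]), p.v_rest, k)


def select_mpdal_potentiation_time(trace: VoltageTrace, p: LIFParams) -> CriticalPoint:
    """Subthreshold-peak potentiation (MPD-AL style).

    Picks the largest interior local maximum of the voltage strictly below
    threshold.  Raises :class:`SelectionFailure` when no such point exists —
    e.g. when dense input drives the voltage monotonically into every spike.
    """
    v = trace.v
    n = len(v)
    if n < 3:
        raise SelectionFailure("trace too short for a local maximum")
    interior = np.zeros(n, dtype=bool)
    interior[1:-1] = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    interior &= v < p.theta
    if len(trace.out_indices):
        interior[trace.out_indices] = False
    idx = np.flatnonzero(interior)
    if idx.size == 0:
        raise SelectionFailure("no subthreshold local maximum of the voltage")
    k = int(idx[np.argmax(v[idx])])
    return CriticalPoint(float(trace.grid[k]), "potentiate",
                         float(v[k]), p.theta, k)


@dataclass
class Network:
    """Fully connected feed-forward spiking network.

    ``layer_sizes = [n_in, ..., n_out]`` with at least input and output
    layers; ``weights[l]`` maps layer ``l`` to layer ``l+1`` with shape
    ``(layer_sizes[l], layer_sizes[l+1])``.
    """

    layer_sizes: list
    weights: list
    params: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("network needs at least input and output layers")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("need one weight matrix per connection")
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        for l, w in enumerate(self.weights):
            want = (self.layer_sizes[l], self.layer_sizes[l + 1])
            if w.shape != want:
                raise ValueError(f"weights[{l}] shape {w.shape} != {want}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    @property
    def n_out(self) -> int:
        return self.layer_sizes[-1]

    @classmethod
    def init(cls, layer_sizes, params: LIFParams | None = None,
             rng: np.random.Generator | None = None,
             w_mean: float = 0.01, w_std: float = 0.01) -> "Network":
        """Gaussian N(w_mean, w_std) weight initialization."""
        rng = rng or np.random.default_rng()
        params = params or LIFParams()
        ws = [
            rng.normal(w_mean, w_std, size=(layer_sizes[l], layer_sizes[l + 1]))
            for l in range(len(layer_sizes) - 1)
        ]
        return cls(list(layer_sizes), ws, params)

    def forward(self, pattern: SpikePattern, grid_dt: float = 0.1,
                exact_times: bool = False):
        """Simulate every layer; returns (traces, patterns).

        ``traces[l]`` (l = 1..L-1) is the list of VoltageTrace per neuron of
        layer l; ``patterns[l]`` is the spike pattern emitted by layer l
        (``patterns[0]`` is the input).
        """
        if pattern.n_afferents != self.layer_sizes[0]:
            raise ValueError("input pattern size mismatch")
        traces: list = [None]
        patterns = [pattern]
        for l, w in enumerate(self.weights):
            layer_traces = simulate_layer(patterns[l], w, self.params,
                                          grid_dt=grid_dt, exact_times=exact_times)
            traces.append(layer_traces)
            patterns.append(SpikePattern(
                len(layer_traces), pattern.duration,
                [t.out_spikes for t in layer_traces]))
        return traces, patterns


@dataclass
class LearnConfig:
    """Hyperparameters of one VSG training run.

    ``selection_strategy`` picks how the critical point is found:
    ``vsg``/``combo_d`` (max slope + min-slope spike), ``mpdal``/``combo_a``
    (subthreshold peak + last spike), ``combo_b`` (peak + min-slope spike),
    ``combo_c`` (max slope + last spike), ``combo_e`` (VSG without the error
    factor, i.e. fixed-size +/- lr * dV/dw steps).

    ``sub_threshold`` enables the dynamic-decoding gate: a potentiation
    update with ``1 <= N_o < N_d`` is discarded unless ``V(t*)`` already
    exceeds this value.
    """

    lr: float = 0.001
    desired_counts: object = 1
    max_iters: int = 2000
    selection_strategy: str = "vsg"
    use_error_factor: bool = True
    optimizer: str = "plain"  # "plain" | "adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    sub_threshold: float | None = None
    grid_dt: float = 0.1
    eps_slope: float = 1e-3
    clip_updates: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.selection_strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.selection_strategy!r}")
        if self.optimizer not in ("plain", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.sub_threshold is not None and not (self.sub_threshold > 0):
            raise ValueError("sub_threshold must be positive when set")

    def desired_vector(self, n_out: int) -> np.ndarray:
        d = np.asarray(self.desired_counts)
        if d.ndim == 0:
            d = np.full(n_out, int(d))
        if len(d) != n_out:
            raise ValueError("desired_counts length mismatch")
        return d.astype(int)

    def selectors(self):
        """(potentiation selector, depression selector, use_error_factor)."""
        strat = self.selection_strategy
        pot = select_mpdal_potentiation_time if strat in ("mpdal", "combo_a", "combo_b") \
            else select_potentiation_time
        dep = select_last_spike_time if strat in ("mpdal", "combo_a", "combo_c") \
            else select_depression_time
        use_err = False if strat == "combo_e" else self.use_error_factor
        return pot, dep, use_err


def error_and_factor(cp: CriticalPoint, cfg: LearnConfig) -> float:
    """Scalar multiplier applied to dV(t*)/dw.

    With the error factor: ``-lr * (V(t*) - V_tar)`` (gradient descent on
    the squared error).  Without it: a fixed ``+lr`` step for potentiation,
    ``-lr`` for depression.
    """
    _, _, use_err = cfg.selectors()
    if use_err:
        return -cfg.lr * (cp.v_at - cp.v_target)
    return cfg.lr if cp.mode == "potentiate" else -cfg.lr


def kernel_sums(pattern: SpikePattern, times, p: LIFParams,
                derivative: bool = False) -> np.ndarray:
    """Per-afferent causal kernel sums at each evaluation time.

    Returns ``(n_afferents, len(times))`` with entry
    ``sum_{t_i^j < t_x} K(t_x - t_i^j)`` (or kappa with ``derivative``).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.zeros((pattern.n_afferents, len(times)))
    t_in, aff = pattern.flat()
    if t_in.size == 0 or len(times) == 0:
        return out
    order = np.argsort(times, kind="stable")
    ts = times[order]
    o_in = np.argsort(t_in, kind="stable")
    t_in, aff = t_in[o_in], aff[o_in]
    # single sweep: the two exponential sums decay between evaluation times
    # and absorb the input spikes that became causal since the last one
    e_m = np.zeros(pattern.n_afferents)
    e_s = np.zeros(pattern.n_afferents)
    bounds = np.searchsorted(t_in, ts, side="left")  # strict u < t
    j = 0
    prev = None
    for f, t in enumerate(ts):
        if prev is not None and t > prev:
            e_m *= np.exp(-(t - prev) / p.tau_m)
            e_s *= np.exp(-(t - prev) / p.tau_s)
        j1 = bounds[f]
        if j1 > j:
            u, a = t_in[j:j1], aff[j:j1]
            np.add.at(e_m, a, np.exp(-(t - u) / p.tau_m))
            np.add.at(e_s, a, np.exp(-(t - u) / p.tau_s))
            j = j1
        if derivative:
            out[:, order[f]] = p.v0 * (e_s / p.tau_s - e_m / p.tau_m)
        else:
            out[:, order[f]] = p.v0 * (e_m - e_s)
        prev = t
    return out


def _clamped(slopes: np.ndarray, eps: float) -> np.ndarray:
    """Floor the crossing slope before inverting (guards gradient blow-up
    when a spike crosses threshold almost tangentially)."""
    return np.maximum(slopes, eps)


def grad_output_layer(inputs: SpikePattern, weights, trace: VoltageTrace,
                      t_star: float, p: LIFParams,
                      eps_slope: float = 1e-3) -> np.ndarray:
    """dV(t*)/dw for one output neuron's incoming weights.

    Direct term: the kernel sum at t*.  Recurrent term: each earlier output
    spike t_s^f < t* shifts under a weight change (linear-crossing
    assumption) and feeds back through the reset kernel,
    ``dV(t*)/dt_s^f = -(theta/tau_m) exp(-(t*-t_s^f)/tau_m)``.
    """
    weights = np.asarray(weights, dtype=float)
    prior = trace.out_spikes < t_star
    ts = trace.out_spikes[prior]
    slopes = _clamped(trace.out_left_slopes[prior], eps_slope)
    times = np.concatenate([ts, [t_star]])
    K = kernel_sums(inputs, times, p)  # (n_aff, F+1)
    F = len(ts)
    grad = K[:, -1].copy()
    if F == 0:
        return grad
    # Total dV(t_x)/dw at each earlier spike, built recursively in time
    # order: a weight change shifts every earlier spike, and each shifted
    # reset changes the voltage at later crossings.  The pairwise reset
    # couplings factor through exp(-t/tau_m), so a single exponentially
    # decaying running sum S_f = sum_{g<f} e^{-(t_f-t_g)/tau_m} D_g/slope_g
    # evaluates the recursion in O(n_afferents * F).
    a = p.theta / p.tau_m
    S = np.zeros(inputs.n_afferents)
    for f in range(F):
        if f:
            S *= math.exp(-(ts[f] - ts[f - 1]) / p.tau_m)
        D_f = K[:, f] + a * S
        S += D_f / slopes[f]
    S *= math.exp(-(t_star - ts[-1]) / p.tau_m)
    grad += a * S
    return grad


def network_gradient(net: Network, traces, patterns, s: int, t_star: float,
                     eps_slope: float = 1e-3):
    """dV_s(t*)/dw for every layer of the network, for output neuron ``s``.

    Returns a list of matrices shaped like ``net.weights``; entries for
    output neurons other than ``s`` are zero.  Hidden-layer gradients follow
    the spike-chain backpropagation: the error of a hidden spike is
    accumulated from strictly later downstream spikes that precede ``t*``,
    each converted through the inverse crossing slope.
    """
    p = net.params
    L = net.n_layers
    grads = [np.zeros_like(w) for w in net.weights]
    out_trace = traces[-1][s]

    grads[-1][:, s] = grad_output_layer(patterns[-2], net.weights[-1][:, s],
                                        out_trace, t_star, p, eps_slope)
    if L == 2:
        return grads

    # deltas[l][j]: dV(t*)/dt for each spike (< t*) of neuron j in layer l
    deltas: dict[int, list[np.ndarray]] = {}

    # Penultimate layer: direct influence on V(t*) plus routing through the
    # output neuron's spikes between the hidden spike and t*.  Routing is
    # chained in spike order: shifting an output spike also shifts every
    # later output spike through the reset kernel.
    l = L - 2
    out_ts = out_trace.out_spikes
    out_sl = _clamped(out_trace.out_left_slopes, eps_slope)
    deltas[l] = []
    for j, tr in enumerate(traces[l]):
        tj = tr.out_spikes
        w_js = net.weights[-1][j, s]
        d = np.zeros(len(tj))
        for m, t in enumerate(tj):
            if t >= t_star:
                break
            val = -w_js * psp_kernel_derivative(t_star - t, p)
            between = np.flatnonzero((out_ts > t) & (out_ts < t_star))
            dts_dtj = {}
            for f in between:
                direct = w_js * psp_kernel_derivative(out_ts[f] - t, p)
                chain = sum(
                    (p.theta / p.tau_m) *
                    np.exp(-(out_ts[f] - out_ts[g]) / p.tau_m) * dts_dtj[g]
                    for g in between if g < f)
                dts_dtj[f] = (direct + chain) / out_sl[f]
                dv_dtsf = -(p.theta / p.tau_m) * \
                    np.exp(-(t_star - out_ts[f]) / p.tau_m)
                val += dv_dtsf * dts_dtj[f]
            d[m] = val
        deltas[l].append(d)

    # Deeper hidden layers: recurse through causal spike pairs.
    for l in range(L - 3, 0, -1):
        deltas[l] = []
        for j, tr in enumerate(traces[l]):
            tj = tr.out_spikes
            d = np.zeros(len(tj))
            for m, t in enumerate(tj):
                if t >= t_star:
                    break
                acc = 0.0
                for k, tr_k in enumerate(traces[l + 1]):
                    tk = tr_k.out_spikes
                    sl_k = _clamped(tr_k.out_left_slopes, eps_slope)
                    sel = (tk > t) & (tk < t_star)
                    for f in np.flatnonzero(sel):
                        acc += deltas[l + 1][k][f] * (1.0 / sl_k[f]) * \
                            net.weights[l][j, k] * \
                            psp_kernel_derivative(tk[f] - t, p)
                d[m] = acc
            deltas[l].append(d)

    # Spike-time-to-weight conversion per hidden neuron.
    for l in range(1, L - 1):
        pat_prev = patterns[l - 1]
        for j, tr in enumerate(traces[l]):
            tj = tr.out_spikes
            if len(tj) == 0:
                continue
            use = tj < t_star
            if not use.any():
                continue
            sl = _clamped(tr.out_left_slopes[use], eps_slope)
            K = kernel_sums(pat_prev, tj[use], p)  # (n_prev, M)
            dts_dw = -K / sl[None, :]
            grads[l - 1][:, j] += dts_dw @ deltas[l][j][use]
    return grads


@dataclass
class AdamState:
    """Per-network Adam moment estimates."""

    m: list
    v: list
    t: int = 0

    @classmethod
    def for_network(cls, net: Network) -> "AdamState":
        return cls([np.zeros_like(w) for w in net.weights],
                   [np.zeros_like(w) for w in net.weights])


@dataclass
class StepReport:
    """Outcome of one train_step: per-output spike counts and what changed."""

    n_out: np.ndarray
    desired: np.ndarray
    updated: list
    gated: list
    selection_failures: list
    critical_points: dict

    @property
    def converged(self) -> bool:
        return bool(np.all(self.n_out == self.desired))


def train_step(net: Network, pattern: SpikePattern, cfg: LearnConfig,
               opt_state: AdamState | None = None) -> StepReport:
    """One VSG update on one input pattern (weights modified in place).

    Every output neuron whose spike count differs from its desired count
    contributes one critical point; gradients are accumulated over all
    mismatched outputs before the weights move.  Neurons already at their
    desired count are untouched.  A selection failure (subthreshold-peak
    strategies) is a logged no-op for that neuron.
    """
    desired = cfg.desired_vector(net.n_out)
    traces, patterns = net.forward(pattern, grid_dt=cfg.grid_dt)
    n_out = np.array([tr.n_out for tr in traces[-1]])
    pot_sel, dep_sel, _ = cfg.selectors()

    report = StepReport(n_out, desired, [], [], [], {})
    total = [np.zeros_like(w) for w in net.weights]
    for s in range(net.n_out):
        if n_out[s] == desired[s]:
            continue
        trace = traces[-1][s]
        try:
            if n_out[s] < desired[s]:
                cp = pot_sel(trace, net.params)
            else:
                cp = dep_sel(trace, net.params)
        except SelectionFailure:
            report.selection_failures.append(s)
            continue
        report.critical_points[s] = cp
        if (cfg.sub_threshold is not None and cp.mode == "potentiate"
                and 1 <= n_out[s] < desired[s]
                and cp.v_at < cfg.sub_threshold):
            report.gated.append(s)
            continue
        mult = error_and_factor(cp, cfg)
        if mult == 0.0:
            continue
        grads = network_gradient(net, traces, patterns, s, cp.t_star,
                                 cfg.eps_slope)
        for g_tot, g in zip(total, grads):
            g_tot += mult * g
        report.updated.append(s)

    if report.updated:
        _apply_update(net, total, cfg, opt_state)
    return report


def _apply_update(net: Network, steps, cfg: LearnConfig,
                  opt_state: AdamState | None) -> None:
    if cfg.optimizer == "adam":
        if opt_state is None:
            raise ValueError("adam optimizer requires an AdamState")
        opt_state.t += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        for l, step in enumerate(steps):
            g = -step / cfg.lr  # surrogate loss gradient
            opt_state.m[l] = b1 * opt_state.m[l] + (1 - b1) * g
            opt_state.v[l] = b2 * opt_state.v[l] + (1 - b2) * g * g
            mhat = opt_state.m[l] / (1 - b1 ** opt_state.t)
            vhat = opt_state.v[l] / (1 - b2 ** opt_state.t)
            delta = -cfg.lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            if cfg.clip_updates:
                delta = np.clip(delta, -10 * cfg.lr, 10 * cfg.lr)
            net.weights[l] += delta
    else:
        for l, step in enumerate(steps):
            delta = np.clip(step, -10 * cfg.lr, 10 * cfg.lr) \
                if cfg.clip_updates else step
            net.weights[l] += delta
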