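# Methods

## Neuron model

Neurons are leaky integrate-and-fire units driven by spike trains from `N`
afferents. The membrane voltage is

    V(t) = V_rest + Σ_i w_i Σ_{t_i^j < t} K(t − t_i^j) − Σ_{t_s^j < t} η(t − t_s^j)

with the normalized double-exponential PSP kernel

    K(x) = V₀ [exp(−x/τ_m) − exp(−x/τ_s)],  x > 0

and the reset kernel `η(x) = ϑ·exp(−x/τ_m), x > 0`. `V₀` is fixed in closed
form so that `max_x K(x) = 1`; with `τ_m = 2 τ_s` it equals exactly 4. Each
threshold crossing subtracts the full threshold ϑ from the voltage (soft
reset); the deficit decays with `τ_m`, and that decaying sum is the entire
refractory mechanism — no hard refractory window.

Defaults: `τ_m = 20 ms`, `τ_s = 5 ms`, `ϑ = 1`, `V_rest = 0`. These are the
standard constants of the multi-spike tempotron lineage; all are
configurable. Times are milliseconds, half-open trial windows `[0, T)`.

### Simulation scheme

The voltage is evaluated on a fixed grid (default `grid_dt = 0.1 ms`). The
two exponential sums in `K` are propagated by first-order recursive filters
whose impulses carry the exact sub-grid phase of each input spike, so grid
values equal the analytic expression to float precision. Crossings are then
resolved in a single causal sweep: a spike is recorded at the first grid
point with `V ≥ ϑ`, and the reset affects strictly later points. A fixed
grid (rather than event-driven root finding) keeps the argmax/argmin slope
selection below well defined; tests assert spike counts are stable under
grid refinement.

For gradient verification only, `exact_times=True` locates each crossing by
linear interpolation inside the bracketing grid step and uses that time in
the reset kernel. This makes spike times continuous in the weights, which a
finite-difference oracle requires; learning itself runs on grid times.

The voltage slope is analytic, not a numerical difference:

    ∂V/∂t = Σ_i w_i Σ κ(t − t_i^j) + Σ η(t − t_s^f)/τ_m,   κ = dK/dx.

The reset term is positive — after a spike the deficit decays, so the
voltage recovers toward the PSP sum.

## Learning rule

Supervision is aggregate: a desired total spike count `N_d` per output
neuron per trial. When the actual count `N_o` differs, one critical time
`t*` is chosen per neuron per iteration:

* `N_o < N_d` — the non-spike grid point with the **largest voltage slope**
  (ties → earliest). Such a point always exists; this is the decisive
  advantage over subthreshold-peak selection, which has no candidate when
  dense drive pushes the voltage monotonically into every spike.
* `N_o > N_d` — the existing output spike with the **smallest left-limit
  slope** (ties → latest), i.e. the weakest crossing, cheapest to remove.

The squared error `E = ½(V(t*) − V_tar)²` with `V_tar = ϑ` (potentiate) or
`V_rest` (depress) is descended in the weights:
`Δw = −lr·(V(t*) − V_tar)·dV(t*)/dw`. A variant drops the error factor and
steps `±lr·dV/dw` directly; both are available (strategy `combo_e`).

**Pre-crossing exclusion.** Besides the recorded spike instants, the grid
point immediately before each spike is excluded from potentiation
selection. The crossing happens inside that grid step, so at grid
resolution that point *is* the crossing: its voltage already sits at ϑ,
the error factor vanishes there, and selecting it would stall learning on a
point that cannot add a spike. This resolves what "except the existing
spike times" means on a discrete grid.

### Spike-time gradients

`dV(t*)/dw` has a direct term (causal kernel sums at `t*`) and a recurrent
term: changing a weight shifts every earlier output spike, and each shifted
reset changes `V(t*)`. Spike-time sensitivity uses the linear
threshold-crossing assumption, `∂t_s/∂V = −(∂V/∂t|_{t_s⁻})⁻¹`, which is
exact in continuous time by the implicit-function theorem. The left-limit
slope at a recorded spike is taken at the last grid point strictly before
it.

The recurrence is evaluated **in full**: the total derivative of the
voltage at each output spike includes the shifts of all earlier spikes.
Because the pairwise reset couplings factor through `exp(−t/τ_m)`, the
whole chain reduces to one exponentially decaying running sum, costing
O(afferents × spikes) instead of O(afferents × spikes²). Finite-difference
oracles confirm agreement to ~1e-3 relative even with a dozen prior spikes;
truncating the chain to first order (direct terms only) leaves 25–45%
errors and occasional sign flips, which is why the full chain is used.

For multi-layer networks, errors propagate along causal spike chains: a
hidden spike at `t_j` receives error only from strictly later downstream
spikes that precede `t*`, each converted through the inverse crossing slope
and the synaptic kernel derivative. Routing through the output neuron's
spike sequence is chained as above. One known approximation remains: a
hidden neuron's own reset coupling between its spikes is not chained
(deliberately, matching the layer-recursion equations as written); toy-net
finite differences agree to ~1e-2 with few spikes per neuron, degrading as
per-neuron spike counts grow.

### Stability guards

* **Slope floor** `ε_slope = 1e-3 ϑ/ms` when inverting the crossing slope;
  near-tangential crossings otherwise explode the gradient.
* **Per-coordinate update clipping** at `10·lr`, off by default in the
  library. The count-learning protocol switches it on: unclipped
  depression under dense 20 Hz drive (hundreds of prior spikes, min-slope
  spike selected precisely because its slope is small) overflows within a
  few iterations at useful learning rates.
* Optimizers: plain gradient descent or Adam (0.9/0.999/1e-8).

## Experiment protocols

### Desired-count learning

One neuron, 500 afferents, 500 ms trial, weights `N(0.01, 0.01)`, one fixed
Poisson input pattern per trial, up to 2,000 single-pattern updates.
Protocol optimizer: Adam at lr 0.01 with clipping. Plain gradient descent
faces a step-size dilemma here: potentiation toward large desired counts
crosses weak-gradient frontiers (the critical point early in the trial has
few contributing input spikes) and needs large steps, while depression
under dense 20 Hz drive has enormous gradients and needs small ones — in a
0.001–0.2 sweep no single plain rate converged on every seed at both
extremes (0.05 left occasional 4 Hz/N_d = 80 trials short of the budget;
0.1 overshot occasional 20 Hz depressions). Adam's per-coordinate scaling
resolves both regimes, converging in at most a few hundred iterations in
every measured condition. A trial whose selection strategy finds no
critical point is recorded as stalled-failed immediately: with a fixed
pattern and unchanged weights the failure is permanent, so burning the
remaining iterations is pointless. Success counts and iteration counts are
reported; wall-clock comparisons are deliberately excluded
(hardware-bound).

### Clue detection

Ten fixed 50 ms clue patterns (4 Hz, 500 afferents) are embedded at random
non-overlapping positions in background streams; clue `i` occurs
`c_i ~ Poisson(P_m)` times per stream and is worth `d_i` output spikes
(`d_i = 0` for distractors). Per-afferent background rates are drawn
uniformly from 0–4 Hz per sample (mean 2 Hz — the stated range and mean fix
a uniform draw). Clue spikes *replace* background spikes inside their
window (embedding, not superposition). Training: 100 streams at
`T_b = 500 ms`, `P_m = 0.5`, per-stream desired total `N_d = Σ c_i d_i`;
testing: fresh streams at `T_b = 2,200 ms`, `P_m = 0.8`. The clue bank is
fixed per run — the task is unlearnable otherwise. Streams that cannot host
all drawn occurrences without overlap are redrawn (the generator itself
raises; the protocol retries with fresh draws).

Training uses deliberately small Adam steps (lr 0.002 for the single-clue
task, 0.0005 for the five-clue decomposition, whose finer credit
assignment oscillates at the larger rate) over up to 40–100 epochs, sample
order reshuffled each epoch. The fixed 100-stream training set makes
memorization a real failure mode: the neuron can satisfy every per-stream
count with idiosyncratic background-driven spikes and then stops updating
(updates fire only on count mismatch), generalizing at chance. Small steps
average the updates across streams, so the only consistently repeated
structure — the effective clue patterns — accumulates while background
contributions cancel; but the memorized fixed point remains reachable from
unlucky initializations. The protocol therefore validates each training
attempt on freshly generated streams *from the training distribution*
(window accuracy ≥ 0.9, at most one stray spike per stream) and restarts
from a new weight initialization on failure, keeping the best-validated
network; memorization is detectable this way without ever touching the
longer test regime. Spike-to-window attribution allows a 15 ms post-window
margin (one PSP rise time).

### Classification

Tabular features are encoded by Gaussian receptive fields: `K` identical
overlapping Gaussians per feature spanning its observed range
(`μ_i = a + (2i−3)/2·(b−a)/(K−2)`, `σ = (1/1.5)·(b−a)/(K−2)`), responses
mapped inversely to first-spike latencies in a 100 ms window, spikes later
than `0.9·T` dropped. Output neurons come in `M`-sized groups per class;
the labeled group is trained toward `N_d = 5` spikes, all others toward
silence. Decoding is spike-count argmax over group sums with a
peak-voltage fallback when nothing fires (ties → lowest class). The
optional dynamic-decoding gate discards a potentiation update when
`1 ≤ N_o < N_d` and `V(t*) < ϑ_s`; with `N_o = 0` the update always
proceeds. Adam is the default optimizer here — GRF patterns are sparse
(≤ 1 spike per afferent) and plain GD needs thousands of passes on what
Adam does in hundreds.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the protocols need:
Poisson afferent spiking, fixed re-occurring clue patterns inside
variable-rate backgrounds, and latency-coded tabular features. They do not
model refractoriness or correlations within input trains, time-varying
background rates, or any sensory front end (e.g. audio filterbanks are out
of scope). Passing tests therefore demonstrate the learning rule's
temporal credit assignment on such stationary synthetic statistics, not
performance on natural recordings.

## Numerical choices and degenerate inputs

* Grid `0.1 ms` for learning; finer grids (≤ 0.005 ms) plus exact crossing
  interpolation for gradient oracles.
* Selection tie-breaks are deterministic (earliest non-spike point, latest
  spike), so runs are bit-reproducible given a seed.
* Empty traces: potentiation on an all-zero trace returns the first grid
  point (slope 0 everywhere); depression on a spikeless trace is an error.
* Coincident Poisson spike times (measure-zero, possible after rounding)
  are collapsed to keep per-afferent times strictly increasing.
* All randomness flows through `numpy` Generators seeded from a single
  user-supplied seed via `SeedSequence` spawning.

## Known limitations

* Gradient fidelity degrades in heavily multi-spike hidden layers (the
  un-chained hidden self-reset term); single-layer gradients are exact up
  to grid resolution.
* The clue task's small-step training is slow by construction (minutes per
  run); large steps are faster when they work but seed-fragile.
* Learning success depends on drive statistics: desired counts far beyond
  what the input mass can sustain (e.g. N_d ≫ rate·T·w_max-budget) will
  exhaust the iteration budget.
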