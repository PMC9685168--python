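# vsglearn

Voltage-slope-guided (VSG) aggregate-label learning for multi-spike leaky
integrate-and-fire (LIF) neurons and feed-forward spiking networks.

## The problem

In aggregate-label learning the only supervision a neuron receives is a
desired **total** number of output spikes per trial — no spike timings, no
per-event labels. The neuron must discover on its own *which* input events
deserve spikes: the temporal credit-assignment problem. The canonical
illustration is clue detection: short, re-occurring spike patterns
("clues") are hidden inside minutes-long streams of distracting background
activity, and a correctly trained neuron fires a prescribed number of
spikes inside every occurrence of an effective clue while staying silent
everywhere else — despite never being told where the clues are.

## The learning rule

The neuron is a multi-spike LIF unit,

    V(t) = V_rest + Σᵢ wᵢ Σ_{tᵢʲ<t} K(t−tᵢʲ) − Σ_{tₛʲ<t} ϑ·e^{−(t−tₛʲ)/τ_m},

with a unit-peak double-exponential PSP kernel `K` and a soft reset that
subtracts the threshold ϑ after every output spike. When the emitted count
`N_o` differs from the desired `N_d`, one critical time `t*` is selected
from the membrane-voltage **slope** ∂V/∂t:

* too few spikes → the non-spike time with the *largest* slope (a new spike
  is cheapest to create where the voltage rises fastest — and such a point
  always exists, unlike a subthreshold voltage peak);
* too many spikes → the output spike with the *smallest* left-limit
  crossing slope (the weakest spike is cheapest to remove).

Weights then descend the squared error `E = ½(V(t*) − V_tar)²` with
`V_tar = ϑ` or `V_rest`. The gradient `dV(t*)/dw` treats spike times as
differentiable through the linear threshold-crossing assumption
(`∂t_s/∂V = −(∂V/∂t|_{t_s⁻})⁻¹`) and chains through the full sequence of
earlier output spikes; for multi-layer networks the error propagates along
causal spike chains between layers. See `docs/methods.md` for the complete
derivation, parameter table, and numerical choices.

## Worked example

Train a single neuron with 500 afferents to emit exactly 10 spikes in
response to one fixed 4 Hz Poisson pattern over 500 ms:

```python
from vsglearn.experiments import run_count_learning

res = run_count_learning(rate=4.0, desired=10, seed=11, n_trials=3)
for i, t in enumerate(res.trials):
    print(f"trial {i}: converged={t.success} after {t.iterations} "
          f"iterations, final count {t.final_count}")
```

prints

```
trial 0: converged=True after 7 iterations, final count 10
trial 1: converged=True after 18 iterations, final count 10
trial 2: converged=True after 17 iterations, final count 10
```

The neuron starts silent (mean drive ≈ 0.3 ϑ) and the rule strengthens
weights until exactly ten threshold crossings appear; with 20 Hz input the
same call starts from dozens of spurious spikes and weakens weights
instead. The clue-detection protocol is one call as well:

```python
from vsglearn.experiments import run_clue_detection

res = run_clue_detection(seed=303)   # one effective clue worth 5 spikes
print(res.eval.window_accuracy(res.spec.effective),
      res.eval.modal_window_count(), max(res.eval.stray_counts))
```

prints `1.0 5 1`: on twenty held-out 2.2 s test streams, every
effective-clue window received exactly the five assigned spikes (modal
count 5) and no stream had more than one stray spike.

A command-line interface mirrors the library:

```bash
vsg train-count --desired 10 --rate 4 --seed 11 --trials 3 --out runs/count
vsg train-clues --seed 303 --out runs/clues
vsg ablation --seed 1 --trials 20 --out runs/ablation
vsg classify train --table features.csv --encoders 10 --out runs/clf
```

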