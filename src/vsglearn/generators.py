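"""Seeded synthetic inputs.

Three families of stimuli exercise the learning rule end-to-end:

* homogeneous Poisson spike patterns (the desired-spike-count task);
* clue-embedding streams: short fixed "clue" patterns hidden at random,
  non-overlapping positions inside variable-rate background activity, with
  the desired total spike count determined by which clues occurred (the
  temporal credit-assignment task);
* Gaussian receptive-field (GRF) population encoding of tabular real-valued
  features into first-spike latencies (the classification path).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neuron import SpikePattern

__all__ = [
    "ClueTaskSpec",
    "GRFEncoderSpec",
    "poisson_pattern",
    "make_clue_bank",
    "make_clue_sample",
    "grf_encode",
    "grf_spec_for_table",
]


def poisson_pattern(n: int, rate: float, duration: float,
                    seed=None) -> SpikePattern:
    """Independent homogeneous Poisson spike trains.

    ``rate`` is in Hz, ``duration`` in ms; the expected total spike count is
    ``n * rate * duration / 1000``.  ``seed`` may be an int or a Generator.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spikes = []
    for _ in range(n):
        count = rng.poisson(rate * duration / 1000.0)
        t = np.sort(rng.uniform(0.0, duration, size=count))
        # strictly increasing: collapse (vanishingly rare) duplicates
        if count > 1:
            t = t[np.concatenate(([True], np.diff(t) > 0))]
        spikes.append(t)
    return SpikePattern(n, duration, spikes)


@dataclass
class ClueTaskSpec:
    """Construction parameters of the clue-detection task.

    ``effective[i]`` is the number of output spikes the trained neuron
    should emit per occurrence of clue ``i`` (0 marks a distractor).  Each
    clue occurs ``c_i ~ Poisson(occurrence_mean)`` times per sample, so the
    per-sample desired total is ``N_d = sum_i c_i * effective[i]``.
    Background activity runs at a per-afferent rate drawn uniformly from
    ``background_rate_range`` (default 0-4 Hz, mean 2 Hz).
    """

    n_afferents: int = 500
    n_clues: int = 10
    clue_duration: float = 50.0
    clue_rate: float = 4.0
    effective: np.ndarray = field(default_factory=lambda: np.array([5] + [0] * 9))
    occurrence_mean: float = 0.5
    background_duration: float = 500.0
    background_rate_range: tuple = (0.0, 4.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.effective = np.asarray(self.effective, dtype=int)
        if len(self.effective) != self.n_clues:
            raise ValueError("effective must list one desired count per clue")
        if np.any(self.effective < 0):
            raise ValueError("per-clue desired counts must be >= 0")

    def test_regime(self, background_duration: float = 2200.0,
                    occurrence_mean: float = 0.8) -> "ClueTaskSpec":
        """The evaluation variant: longer streams, more clue occurrences."""
        return replace(self, background_duration=background_duration,
                       occurrence_mean=occurrence_mean)


def make_clue_bank(spec: ClueTaskSpec, seed=None) -> list:
    """The fixed clue patterns, generated once and reused across samples."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [
        poisson_pattern(spec.n_afferents, spec.clue_rate, spec.clue_duration, rng)
        for _ in range(spec.n_clues)
    ]


def _place_windows(n_windows: int, width: float, total: float,
                   rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """Random non-overlapping window starts in [0, total - width]."""
    if n_windows == 0:
        return np.empty(0)
    if n_windows * width > total:
        raise ValueError(
            f"cannot place {n_windows} windows of {width} ms in {total} ms")
    for _ in range(max_tries):
        starts = np.sort(rng.uniform(0.0, total - width, size=n_windows))
        if n_windows == 1 or np.all(np.diff(starts) >= width):
            return starts
    raise ValueError("failed to place non-overlapping clue windows")


def make_clue_sample(spec: ClueTaskSpec, clue_bank: list, seed=None):
    """One composite stream: clues embedded in background activity.

    Draws per-clue occurrence counts ``c_i ~ Poisson(occurrence_mean)``,
    embeds each occurrence at a random non-overlapping position (clue spikes
    *replace* background spikes inside the window), and returns
    ``(pattern, N_d, windows)`` with ``windows`` a list of
    ``(clue_id, start, end)`` and ``N_d = sum_i c_i * effective[i]``.
    """
    if len(clue_bank) != spec.n_clues:
        raise ValueError("clue bank size mismatch")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(spec.occurrence_mean, size=spec.n_clues)
    order = np.repeat(np.arange(spec.n_clues), counts)
    rng.shuffle(order)
    starts = _place_windows(len(order), spec.clue_duration,
                            spec.background_duration, rng)
    windows = [(int(cid), float(st), float(st + spec.clue_duration))
               for cid, st in zip(order, starts)]

    lo, hi = spec.background_rate_range
    rates = rng.uniform(lo, hi, size=spec.n_afferents)
    spikes = []
    for i in range(spec.n_afferents):
        n_bg = rng.poisson(rates[i] * spec.background_duration / 1000.0)
        t = rng.uniform(0.0, spec.background_duration, size=n_bg)
        keep = np.ones(len(t), dtype=bool)
        for _, st, en in windows:
            keep &= ~((t >= st) & (t < en))
        parts = [t[keep]]
        for cid, st, _ in windows:
            parts.append(clue_bank[cid].spikes[i] + st)
        merged = np.sort(np.concatenate(parts))
        if len(merged) > 1:
            merged = merged[np.concatenate(([True], np.diff(merged) > 0))]
        spikes.append(merged)
    pattern = SpikePattern(spec.n_afferents, spec.background_duration, spikes)
    n_d = int(np.sum(counts * spec.effective))
    return pattern, n_d, windows


@dataclass
class GRFEncoderSpec:
    """Gaussian receptive-field population encoder.

    Each feature is covered by ``n_gaussians`` identical overlapping
    Gaussians spanning its range [a, b]; feeding a value x through Gaussian
    i yields a response y_i in [0, 1] mapped inversely to a first-spike
    latency ``t = (1 - y_i) * window``.  Late spikes (t > late_cutoff *
    window) are dropped, so weakly driven encoders stay silent.
    """

    n_gaussians: int
    feature_ranges: list
    window: float = 100.0
    late_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if self.n_gaussians < 2:
            raise ValueError("need at least 2 Gaussians per feature")
        for a, b in self.feature_ranges:
            if not a < b:
                raise ValueError("each feature range must satisfy a < b")

    @property
    def n_afferents(self) -> int:
        return self.n_gaussians * len(self.feature_ranges)

    def centers_width(self, feat: int):
        """Centers and shared width for one feature.

        mu_i = a + (2i - 3)/2 * (b - a)/(K - 2),  i = 1..K,
        sigma = (1/1.5) * (b - a)/(K - 2)
        — the standard population-coding layout; the outermost centers sit
        just outside [a, b] so boundary values are still covered.
        """
        a, b = self.feature_ranges[feat]
        k = self.n_gaussians
        denom = (b - a) / (k - 2) if k > 2 else (b - a)
        i = np.arange(1, k + 1)
        mu = a + (2 * i - 3) / 2.0 * denom
        sigma = denom / 1.5
        return mu, sigma


def grf_spec_for_table(features: np.ndarray, n_gaussians: int,
                       window: float = 100.0) -> GRFEncoderSpec:
    """Build an encoder spec whose ranges span the observed feature columns."""
    features = np.asarray(features, dtype=float)
    ranges = []
    for c in range(features.shape[1]):
        a, b = float(features[:, c].min()), float(features[:, c].max())
        if a == b:  # constant column still needs a finite interval
            a, b = a - 0.5, b + 0.5
        ranges.append((a, b))
    return GRFEncoderSpec(n_gaussians, ranges, window=window)


def grf_encode(row, spec: GRFEncoderSpec) -> SpikePattern:
    """Encode one feature vector as first-spike latencies.

    Output has ``n_gaussians * n_features`` afferents with at most one spike
    each; a value at a Gaussian's center fires that encoder at t = 0.
    """
    row = np.asarray(row, dtype=float)
    if len(row) != len(spec.feature_ranges):
        raise ValueError("feature count mismatch")
    if not np.all(np.isfinite(row)):
        raise ValueError("non-finite feature value")
    spikes = []
    for f, x in enumerate(row):
        mu, sigma = spec.centers_width(f)
        y = np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))
        t = (1.0 - y) * spec.window
        for ti in t:
            spikes.append(np.array([ti]) if ti <= spec.late_cutoff * spec.window
                          else np.empty(0))
    return SpikePattern(spec.n_afferents, spec.window, spikes)
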