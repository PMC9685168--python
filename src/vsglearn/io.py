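"""File formats, configuration, run manifests, and test fixtures.

All formats are plain text.  Spike patterns use a two-column delimited
format with a header; network checkpoints are versioned JSON (floats
round-trip exactly via the shortest-repr encoding); run configuration is
YAML with fixed sections and strict key checking.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .generators import ClueTaskSpec, GRFEncoderSpec
from .learning import LearnConfig, Network
from .neuron import LIFParams, SpikePattern

__all__ = [
    "read_spike_pattern",
    "write_spike_pattern",
    "save_network",
    "load_network",
    "load_config",
    "RunManifest",
    "JsonlLogger",
    "make_fixtures",
]

_PATTERN_HEADER = "# spike-pattern v1"


def write_spike_pattern(pattern: SpikePattern, path) -> None:
    """Two-column text: afferent index, spike time (>= 10 significant digits)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_PATTERN_HEADER}\n")
        fh.write(f"# n_afferents={pattern.n_afferents} "
                 f"duration={float(pattern.duration)!r}\n")
        for i, times in enumerate(pattern.spikes):
            for t in times:
                fh.write(f"{i}\t{float(t)!r}\n")


def read_spike_pattern(path) -> SpikePattern:
    """Inverse of :func:`write_spike_pattern`; errors name the line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2 or lines[0] != _PATTERN_HEADER:
        raise ValueError(f"{path}: not a spike-pattern file")
    meta = dict(kv.split("=") for kv in lines[1].lstrip("# ").split())
    n_aff = int(meta["n_afferents"])
    duration = float(meta["duration"])
    times, affs = [], []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'afferent time_ms'")
        try:
            a, t = int(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed row") from exc
        if not 0 <= a < n_aff:
            raise ValueError(f"{path}:{ln}: afferent index {a} out of range")
        affs.append(a)
        times.append(t)
    spikes: list = [[] for _ in range(n_aff)]
    for a, t in zip(affs, times):
        if spikes[a] and t <= spikes[a][-1]:
            raise ValueError(f"{path}: afferent {a} times not strictly increasing")
        spikes[a].append(t)
    return SpikePattern(n_aff, duration, [np.asarray(s) for s in spikes])


def save_network(net: Network, path) -> None:
    """Versioned JSON checkpoint; weights round-trip exactly."""
    doc = {
        "format": "vsg-network",
        "version": 1,
        "layer_sizes": list(net.layer_sizes),
        "params": {
            "tau_m": net.params.tau_m,
            "tau_s": net.params.tau_s,
            "theta": net.params.theta,
            "v_rest": net.params.v_rest,
            "v0": net.params.v0,
        },
        "weights": [w.tolist() for w in net.weights],
    }
    Path(path).write_text(json.dumps(doc))


def load_network(path) -> Network:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "vsg-network" or doc.get("version") != 1:
        raise ValueError(f"{path}: not a v1 network checkpoint")
    params = LIFParams(**doc["params"])
    return Network(doc["layer_sizes"],
                   [np.asarray(w) for w in doc["weights"]], params)


_CONFIG_SECTIONS = {
    "lif": LIFParams,
    "learn": LearnConfig,
    "clue_task": ClueTaskSpec,
    "grf": GRFEncoderSpec,
}


def load_config(path) -> dict:
    """YAML config with sections lif / learn / clue_task / grf.

    Unknown sections or keys are errors (typo protection).  Returns a dict
    of instantiated objects keyed by section.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    out = {}
    for section, payload in raw.items():
        if section not in _CONFIG_SECTIONS:
            raise ValueError(f"{path}: unknown section {section!r}")
        cls = _CONFIG_SECTIONS[section]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown keys in [{section}]: {sorted(unknown)}")
        out[section] = cls(**payload)
    return out


@dataclass
class RunManifest:
    """Reproducibility record written next to every experiment's outputs."""

    seed: int
    config: dict = field(default_factory=dict)
    code_version: str = "vsglearn-0.1.0"
    outputs: list = field(default_factory=list)
    failure_flags: dict = field(default_factory=dict)
    created: float = field(default_factory=time.time)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


class JsonlLogger:
    """Append-only log, one JSON record per line."""

    def __init__(self, path):
        self.path = Path(path)

    def log(self, **record) -> None:
        with self.path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")


def make_fixtures(seed: int = 0, outdir=None) -> dict:
    """Deterministic small inputs used throughout the test suite.

    * ``toy_pattern``: 3 afferents with hand-placed spikes (voltage is
      hand-checkable by summing two or three kernels).
    * ``dense_pattern`` / ``dense_weights``: regular dense drive whose
      voltage rises into every spike without a subthreshold local maximum —
      defeats subthreshold-peak selection while slope selection succeeds.
    * ``tabular``: a linearly separable two-cluster feature table.
    * ``mini_clue_spec``: a miniature clue task (3 clues, 1 effective).
    """
    rng = np.random.default_rng(seed)
    toy = SpikePattern(3, 100.0, [np.array([10.0]), np.array([15.0, 40.0]),
                                  np.array([30.0])])

    # 40 afferents firing a staggered regular volley every 1 ms keeps the
    # voltage rising between frequent output spikes
    n_dense = 40
    dense = SpikePattern(
        n_dense, 200.0,
        [np.arange(1.0 + 0.5 * i, 200.0, n_dense * 0.5) for i in range(n_dense)])
    dense_weights = np.full(n_dense, 0.6)

    centers = np.array([[0.0, 0.0], [4.0, 4.0]])
    feats, labels = [], []
    for c, mu in enumerate(centers):
        feats.append(rng.normal(mu, 0.5, size=(30, 2)))
        labels.extend([c] * 30)
    tabular = pd.DataFrame(np.vstack(feats), columns=["f0", "f1"])
    tabular["label"] = labels

    mini_clue = ClueTaskSpec(n_afferents=60, n_clues=3, clue_duration=50.0,
                             clue_rate=8.0, effective=np.array([2, 0, 0]),
                             occurrence_mean=0.7, background_duration=300.0)

    fixtures = {
        "toy_pattern": toy,
        "dense_pattern": dense,
        "dense_weights": dense_weights,
        "tabular": tabular,
        "mini_clue_spec": mini_clue,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spike_pattern(toy, outdir / "toy_pattern.txt")
        write_spike_pattern(dense, outdir / "dense_pattern.txt")
        np.savetxt(outdir / "dense_weights.txt", dense_weights)
        tabular.to_csv(outdir / "tabular.csv", index=False)
        fixtures["files"] = sorted(str(f) for f in outdir.iterdir())
    return fixtures
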