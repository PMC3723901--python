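"""Population spike trains and their plain-text interchange format.

All times are in milliseconds.  The on-disk format is two whitespace-
delimited columns, spike time (ms) then neuron id, one spike per line;
``#``-prefixed header lines carry the duration, neuron count and the
inhibitory ids so a round-trip preserves the population split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeTrain", "read_spike_train", "write_spike_train"]


@dataclass
class SpikeTrain:
    """Time-sorted population spiking record.

    ``times`` are spike times in ms within ``[0, duration]``; ``ids`` the
    corresponding neuron indices.  ``inhibitory_ids`` identifies the
    inhibitory sub-population (empty for excitatory-only networks).
    """

    times: np.ndarray
    ids: np.ndarray
    duration: float  # ms
    n_neurons: int
    inhibitory_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have equal length")
        if len(self.times) and (np.diff(self.times) < 0).any():
            order = np.argsort(self.times, kind="stable")
            self.times, self.ids = self.times[order], self.ids[order]
        if len(self.times) and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValueError("spike times must lie in [0, duration]")
        if len(self.ids) and (self.ids.min() < 0 or self.ids.max() >= self.n_neurons):
            raise ValueError("neuron ids must lie in [0, n_neurons)")
        self.inhibitory_ids = np.asarray(self.inhibitory_ids, dtype=np.int64)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def excitatory_ids(self) -> np.ndarray:
        mask = np.ones(self.n_neurons, dtype=bool)
        mask[self.inhibitory_ids] = False
        return np.flatnonzero(mask)

    @property
    def n_excitatory(self) -> int:
        return self.n_neurons - len(self.inhibitory_ids)

    def excitatory_only(self) -> "SpikeTrain":
        """Restrict to spikes of the excitatory population."""
        if len(self.inhibitory_ids) == 0:
            return self
        keep = ~np.isin(self.ids, self.inhibitory_ids)
        return SpikeTrain(self.times[keep], self.ids[keep], self.duration,
                          self.n_neurons, self.inhibitory_ids, dict(self.meta))

    def drop_transient(self, t0: float = 1000.0) -> "SpikeTrain":
        """Discard the first ``t0`` ms and shift the origin to ``t0``."""
        keep = self.times >= t0
        return SpikeTrain(self.times[keep] - t0, self.ids[keep],
                          max(self.duration - t0, 0.0), self.n_neurons,
                          self.inhibitory_ids, dict(self.meta))

    def write(self, path: str | Path) -> None:
        write_spike_train(self, path)


def write_spike_train(train: SpikeTrain, path: str | Path) -> None:
    lines = [
        f"# duration_ms {train.duration!r}",
        f"# n_neurons {train.n_neurons}",
        "# inhibitory " + " ".join(map(str, train.inhibitory_ids)),
    ]
    for k, v in train.meta.items():
        lines.append(f"# meta {k} {v}")
    lines += [f"{t:.6f} {i}" for t, i in zip(train.times, train.ids)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_train(
    path: str | Path, duration: float | None = None, n_neurons: int | None = None
) -> SpikeTrain:
    """Read the two-column time/neuron-id text format.

    Headerless files from external tools are accepted if ``duration`` and
    ``n_neurons`` are supplied (or inferable from the spikes themselves).
    """
    times, ids, inhib, meta = [], [], [], {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if not parts:
                continue
            if parts[0] == "duration_ms":
                duration = float(parts[1])
            elif parts[0] == "n_neurons":
                n_neurons = int(parts[1])
            elif parts[0] == "inhibitory":
                inhib = [int(x) for x in parts[1:]]
            elif parts[0] == "meta" and len(parts) >= 3:
                meta[parts[1]] = " ".join(parts[2:])
            continue
        t, i = line.split()[:2]
        times.append(float(t))
        ids.append(int(i))
    times = np.asarray(times)
    ids = np.asarray(ids, dtype=np.int64)
    if duration is None:
        duration = float(times.max()) if len(times) else 0.0
    if n_neurons is None:
        n_neurons = int(ids.max()) + 1 if len(ids) else 0
    return SpikeTrain(times, ids, duration, n_neurons,
                      np.asarray(inhib, dtype=np.int64), meta)
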