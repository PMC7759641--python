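"""Shared domain containers for the seizure-network pipeline.

The pipeline moves through three representations: raw multichannel
recordings (:class:`SeizureRecording`), instantaneous phases
(:class:`PhaseSeries`), and edgewise functional-connectivity time series
(:class:`FCSeries`).  A patient's full dataset is a list of per-seizure FC
matrices sharing one edge index (:class:`MultiSeizureDataset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SeizureRecording:
    """Multichannel signal for one seizure.

    Parameters
    ----------
    samples
        ``(n_channels, n_timepoints)`` array, microvolts.
    sampling_rate_hz
        Sampling rate in Hz.
    channel_labels
        One label per channel; on depth electrodes these encode the rod
        letter and contact number (``"A1"``, ``"A2"``, ...).
    seizure_id
        Free-form identifier.
    onset_sample
        Sample index of clinical seizure onset, if known.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    seizure_id: str = ""
    onset_sample: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class PhaseSeries:
    """Instantaneous phase per channel, radians in (-pi, pi]."""

    phases: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str] = field(default_factory=list)
    degenerate_channels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")


@dataclass
class EdgeIndex:
    """Bijection between edge index l and the channel pair (i, j), i < j.

    Pairs are in lexicographic order so that ``l = index_of(i, j)`` is a
    deterministic flattening of the upper triangle.
    """

    n_channels: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = [
            (i, j)
            for i in range(self.n_channels)
            for j in range(i + 1, self.n_channels)
        ]
        if not self.pairs:
            self.pairs = expected
        elif self.pairs != expected:
            raise ValueError("pairs must be the lexicographic upper triangle")

    @classmethod
    def from_n_channels(cls, n_channels: int) -> "EdgeIndex":
        return cls(n_channels=n_channels)

    @property
    def L(self) -> int:
        return self.n_channels * (self.n_channels - 1) // 2

    def index_of(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        if i == j:
            raise ValueError("edges connect distinct channels")
        # offset of row i in the flattened upper triangle
        return i * (2 * self.n_channels - i - 1) // 2 + (j - i - 1)

    def edge_labels(self, channel_labels: list[str]) -> list[str]:
        return [f"{channel_labels[i]}|{channel_labels[j]}" for i, j in self.pairs]


@dataclass
class FCSeries:
    """Edge-by-window functional connectivity matrix for one seizure.

    ``values[l, t]`` is the phase-locking value of edge ``l`` in window
    ``t``; entries lie in [0, 1].
    """

    values: np.ndarray
    edge_index: EdgeIndex
    window_length_s: float
    window_step_s: float
    seizure_id: str = ""
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (edges x windows)")
        if self.values.shape[0] != self.edge_index.L:
            raise ValueError(
                f"{self.values.shape[0]} rows but edge index has "
                f"L={self.edge_index.L}"
            )
        if self.values.shape[1] < 1:
            raise ValueError("need at least one window")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("FC values must lie in [0, 1]")
        if self.window_length_s <= 0 or self.window_step_s <= 0:
            raise ValueError("window parameters must be positive")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiSeizureDataset:
    """All seizures of one patient: FC matrices sharing a single edge index."""

    seizures: list[FCSeries]

    def __post_init__(self) -> None:
        if not self.seizures:
            raise ValueError("need at least one seizure")
        ref = self.seizures[0].edge_index
        for fc in self.seizures[1:]:
            if fc.edge_index.n_channels != ref.n_channels:
                raise ValueError("all seizures must share one edge index")

    @property
    def S(self) -> int:
        return len(self.seizures)

    @property
    def L(self) -> int:
        return self.seizures[0].L

    @property
    def edge_index(self) -> EdgeIndex:
        return self.seizures[0].edge_index

    @property
    def durations(self) -> list[int]:
        return [fc.T for fc in self.seizures]

    def __iter__(self):
        return iter(self.seizures)

    def __len__(self) -> int:
        return len(self.seizures)
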