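"""Shared in-memory containers used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NetworkTimeseriesSet:
    """Per-subject, per-session network time-series.

    Parameters
    ----------
    subjects
        Mapping of subject id to a list of session arrays, each of shape
        ``(T, N)`` (timepoints x networks). All sessions of all subjects
        must share the same number of networks ``N``.
    tr
        Sampling interval in seconds.
    node_labels
        Names of the ``N`` networks; defaults to ``n000, n001, ...``.
    """

    subjects: dict[str, list[np.ndarray]]
    tr: float
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        n = self.n_nodes
        for sid, sessions in self.subjects.items():
            for k, arr in enumerate(sessions):
                arr = np.asarray(arr, dtype=float)
                if arr.ndim != 2:
                    raise ValueError(f"subject {sid} session {k}: expected 2-D array")
                if arr.shape[1] != n:
                    raise ValueError(
                        f"subject {sid} session {k}: {arr.shape[1]} networks, expected {n}"
                    )
                sessions[k] = arr
        if not self.node_labels:
            self.node_labels = [f"n{i:03d}" for i in range(n)]
        elif len(self.node_labels) != n:
            raise ValueError("node_labels length must match number of networks")

    @property
    def n_nodes(self) -> int:
        for sessions in self.subjects.values():
            for arr in sessions:
                return np.asarray(arr).shape[1]
        return 0

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)


def standardize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Z-score along ``axis``; constant slices are returned de-meaned."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd
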