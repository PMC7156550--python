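"""Containers for observed label time courses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelingDataset"]


@dataclass(frozen=True)
class LabelingDataset:
    """(day, fraction-labeled) observations with optional subject/cell-type metadata.

    Fractions are not clipped: additive measurement noise may push individual
    points slightly outside [0, 1].
    """

    times: np.ndarray
    fraction_labeled: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fraction_labeled, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and fraction_labeled must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_labeled", y)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)
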