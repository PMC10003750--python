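"""Uniformly sampled concentration time series (the FSCV data container)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """A time/concentration series on a uniform grid.

    times in seconds, values in uM. FSCV background-subtracted signals can
    dip below zero, so values are not sign-restricted; they must be finite.
    ``meta`` carries protocol/model/parameter provenance for synthetic
    traces and round-trips through the on-disk header.
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("trace contains non-finite entries")
        steps = np.diff(self.times)
        dt = steps[0]
        if dt <= 0:
            raise ValueError("times must be strictly increasing")
        bad = np.nonzero(np.abs(steps - dt) > 1e-6 * max(dt, 1.0))[0]
        if bad.size:
            raise ValueError(
                f"non-uniform sampling: first offending interval at index {int(bad[0])}"
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "da_uM": self.values})

    def __eq__(self, other) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
            and self.meta == other.meta
        )
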