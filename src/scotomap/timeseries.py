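"""Shared container for per-unit BOLD time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeriesSet"]


@dataclass(frozen=True)
class TimeSeriesSet:
    """Per-unit BOLD series (percent signal change) with repetition time.

    ``data`` is a (units, T) array; a single series may be passed 1-D and is
    promoted to one row.
    """

    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError("data must be a (units, T) array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series must be finite")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]
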