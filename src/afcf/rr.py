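"""RR-interval series: the beat-to-beat substrate of all HRV features.

An :class:`RRSeries` holds one record's sequence of RR intervals in
milliseconds.  Onset times are derived as prefix sums, so features depend
only on the interval sequence, never on absolute start time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RRSeries", "FeatureLengthError", "read_rr_csv", "write_rr_csv"]


class FeatureLengthError(ValueError):
    """Raised when a series is too short for a requested feature."""

    def __init__(self, feature: str, needed: int, got: int):
        self.feature = feature
        super().__init__(
            f"feature {feature!r} needs at least {needed} RR intervals, got {got}"
        )


@dataclass(frozen=True)
class RRSeries:
    """One record's RR intervals in milliseconds.

    Invariants: every interval is positive and finite, and the series has
    at least 2 intervals.  Individual features state stricter minima via
    :class:`FeatureLengthError`.
    """

    record_id: str
    intervals: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intervals must be a 1-D sequence")
        if arr.size < 2:
            raise ValueError(
                f"record {self.record_id!r}: need >= 2 RR intervals, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(
                f"record {self.record_id!r}: RR intervals must be positive and finite"
            )
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def onset_times(self) -> np.ndarray:
        """Cumulative beat-onset times in seconds (prefix sums of intervals)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    def require(self, feature: str, n_min: int) -> np.ndarray:
        if len(self) < n_min:
            raise FeatureLengthError(feature, n_min, len(self))
        return self.intervals


def read_rr_csv(path) -> list[RRSeries]:
    """Read RR series from CSV, auto-detecting long or wide layout.

    Long format: columns ``record_id,beat_index,rr_ms`` (one beat per row).
    Wide format: columns ``record_id,rr_ms_list`` with semicolon-joined
    intervals.  The header row is mandatory.
    """
    df = pd.read_csv(path, dtype={"record_id": str})
    cols = set(df.columns)
    if {"record_id", "beat_index", "rr_ms"} <= cols:
        out = []
        for rid, grp in df.groupby("record_id", sort=False):
            grp = grp.sort_values("beat_index")
            out.append(RRSeries(str(rid), grp["rr_ms"].to_numpy(dtype=float)))
        return out
    if {"record_id", "rr_ms_list"} <= cols:
        return [
            RRSeries(str(row.record_id),
                     np.array([float(x) for x in str(row.rr_ms_list).split(";")]))
            for row in df.itertuples(index=False)
        ]
    raise ValueError(
        "unrecognized RR CSV layout: expected columns "
        "(record_id,beat_index,rr_ms) or (record_id,rr_ms_list); "
        f"got {sorted(cols)}"
    )


def write_rr_csv(series: list[RRSeries], path, layout: str = "wide") -> None:
    if layout == "wide":
        df = pd.DataFrame(
            {
                "record_id": [s.record_id for s in series],
                "rr_ms_list": [";".join(f"{v:g}" for v in s.intervals) for s in series],
            }
        )
    elif layout == "long":
        rows = [
            (s.record_id, i, v)
            for s in series
            for i, v in enumerate(s.intervals)
        ]
        df = pd.DataFrame(rows, columns=["record_id", "beat_index", "rr_ms"])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    df.to_csv(path, index=False)
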