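"""Persistence-based escape detection and escape-time statistics.

A tracked ligand is considered to have escaped when its distance to the
binding-site centre stays above a channel-length threshold for at least a
persistence time (default 16.31 A and 2 ns).  The escape time is the start
of the first qualifying excursion; ligands with no qualifying window are
censored — counted among the tracked molecules but excluded from the mean
escape time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError
from .trajectory import DistanceSeries

#: Mean length of the escape channels, used as the default escape threshold.
DEFAULT_THRESHOLD_A = 16.31
#: Minimum duration a supra-threshold excursion must last to count.
DEFAULT_PERSISTENCE_NS = 2.0


@dataclass(frozen=True)
class EscapeCriterion:
    threshold_A: float = DEFAULT_THRESHOLD_A
    persistence_ns: float = DEFAULT_PERSISTENCE_NS

    def __post_init__(self) -> None:
        if self.threshold_A <= 0 or self.persistence_ns <= 0:
            raise DataError("threshold and persistence must be positive")

    def window_frames(self, frame_interval_ns: float) -> int:
        w = int(round(self.persistence_ns / frame_interval_ns))
        if w < 1:
            raise DataError(
                "persistence shorter than half a frame interval; window empty")
        return w


@dataclass
class EscapeEvent:
    ligand_id: str
    replicate_id: str
    variant_label: str
    escape_time_ns: float
    escape_frame: int
    channel_id: str | None = None


@dataclass
class EscapeSummary:
    variant_label: str
    n_tracked: int
    n_escaped: int
    mean_escape_time_ns: float | None
    escape_times: list[float] = field(default_factory=list)


def detect_escape(series: DistanceSeries, crit: EscapeCriterion) -> EscapeEvent | None:
    """First frame opening a window of ``persistence_ns`` entirely above threshold.

    Returns ``None`` when the ligand is censored (no qualifying window).
    Excursions shorter than the persistence window — re-entries — do not
    count, and nothing after the first qualifying window matters.
    """
    w = crit.window_frames(series.frame_interval_ns)
    n = series.n_frames
    if w > n:
        raise NumericalError(
            f"persistence window of {w} frames exceeds series length {n}; "
            "escape persistence unverifiable")
    above = series.values > crit.threshold_A
    # rolling count of above-threshold frames over each length-w window
    run = np.convolve(above.astype(np.intp), np.ones(w, dtype=np.intp), "valid")
    hits = np.nonzero(run == w)[0]
    if len(hits) == 0:
        return None
    t = int(hits[0])
    return EscapeEvent(
        ligand_id=series.ligand_id,
        replicate_id=series.replicate_id,
        variant_label=series.variant_label,
        escape_time_ns=t * series.frame_interval_ns,
        escape_frame=t,
    )


def summarize_escapes(events: list[EscapeEvent | None],
                      variant_label: str) -> EscapeSummary:
    """Escape counts and the mean escape time over escapers only."""
    if len(events) == 0:
        raise DataError("no tracked ligands to summarize")
    escaped = [e for e in events if e is not None]
    times = [e.escape_time_ns for e in escaped]
    return EscapeSummary(
        variant_label=variant_label,
        n_tracked=len(events),
        n_escaped=len(escaped),
        mean_escape_time_ns=(float(np.mean(times)) if times else None),
        escape_times=times,
    )


def cumulative_escape_curve(events: list[EscapeEvent | None],
                            time_grid_ns: np.ndarray) -> np.ndarray:
    """Number of escapes at or before each grid time (non-decreasing)."""
    grid = np.asarray(time_grid_ns, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise DataError("time grid must be strictly increasing")
    times = np.sort([e.escape_time_ns for e in events if e is not None])
    return np.searchsorted(times, grid, side="right")


@dataclass
class DistanceHistogram:
    bin_edges_A: np.ndarray
    counts: np.ndarray
    n_frames: int
    n_below_threshold: int
    threshold_A: float


def distance_histogram(series_list: list[DistanceSeries],
                       bin_width_A: float = 3.0,
                       threshold_A: float = DEFAULT_THRESHOLD_A) -> DistanceHistogram:
    """Pooled histogram of analysis-frame distances for a variant.

    Also reports how many frames sit below the channel-length threshold
    (the "bound" portion of the distance traces).
    """
    if bin_width_A <= 0:
        raise DataError("bin width must be positive")
    pooled = np.concatenate([s.values for s in series_list]) if series_list \
        else np.array([])
    if pooled.size:
        top = float(np.ceil(pooled.max() / bin_width_A) * bin_width_A)
        top = max(top, bin_width_A)
        edges = np.arange(0.0, top + bin_width_A / 2, bin_width_A)
        counts, edges = np.histogram(pooled, bins=edges)
    else:
        edges = np.array([0.0, bin_width_A])
        counts = np.zeros(1, dtype=np.intp)
    return DistanceHistogram(
        bin_edges_A=edges,
        counts=counts,
        n_frames=int(pooled.size),
        n_below_threshold=int(np.sum(pooled < threshold_A)),
        threshold_A=threshold_A,
    )


def events_to_frame(events: list[EscapeEvent | None],
                    labels: list[tuple[str, str, str]] | None = None) -> pd.DataFrame:
    """Events TSV table; censored ligands get an empty escape time.

    ``labels`` supplies (variant, replicate, ligand) for censored entries,
    aligned with ``events``; without it censored rows are dropped.
    """
    rows = []
    for i, e in enumerate(events):
        if e is not None:
            rows.append((e.variant_label, e.replicate_id, e.ligand_id,
                         e.escape_time_ns, e.channel_id or ""))
        elif labels is not None:
            v, r, l = labels[i]
            rows.append((v, r, l, np.nan, ""))
    return pd.DataFrame(rows, columns=["variant", "replicate", "ligand",
                                       "escape_time_ns", "channel"])
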