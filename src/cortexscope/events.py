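"""Calcium-event detection on z-scored region traces and amplitude statistics.

A calcium event is a local maximum of the median-filtered, session-z-scored
region trace whose peak value exceeds 2 SD; its amplitude is the peak's
topographic prominence (height above the higher of the two flanking minima
separating it from any higher peak).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .preprocess import RegionTraces

#: default amplitude bin edges (SD units); the final bin is open above
DEFAULT_EDGES: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
DETECTION_HEIGHT = 2.0
MEDIAN_KERNEL = 5


@dataclass(frozen=True)
class CalciumEvent:
    region: str
    frame: int
    time_s: float
    amplitude: float  # prominence, SD units


@dataclass
class AmplitudeHistogram:
    """Per-cell event-amplitude histogram with half-open bins and an open top bin."""

    bin_edges: np.ndarray  # the final listed interval is open above
    counts: np.ndarray
    relative_freq: np.ndarray  # NaN-flagged when there are no events
    subject: int | None = None
    region: str | None = None
    condition: str | None = None


def zscore_trace(trace: np.ndarray) -> np.ndarray:
    """Session z-score: (x - mean) / population SD."""
    x = np.asarray(trace, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("trace has zero standard deviation")
    return (x - x.mean()) / sd


def median_filter(trace: np.ndarray, kernel: int = MEDIAN_KERNEL) -> np.ndarray:
    """Sliding median with reflected edges; kernel must be odd."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 1")
    return ndimage.median_filter(np.asarray(trace, dtype=float), size=kernel, mode="reflect")


def detect_events(
    trace: np.ndarray,
    fps: float,
    region: str = "",
    height: float = DETECTION_HEIGHT,
) -> list[CalciumEvent]:
    """Find local maxima above ``height`` SD; amplitude = topographic prominence.

    The prominence window is unbounded (whole trace).  The input is assumed to
    be in SD units already (z-scored and median-filtered upstream).
    """
    x = np.asarray(trace, dtype=float)
    peaks, props = signal.find_peaks(x, height=height, prominence=(0, None))
    return [
        CalciumEvent(region=region, frame=int(f), time_s=float(f / fps), amplitude=float(p))
        for f, p in zip(peaks, props["prominences"])
    ]


def detect_events_traces(
    traces: RegionTraces,
    height: float = DETECTION_HEIGHT,
    kernel: int = MEDIAN_KERNEL,
    zscore: bool = True,
) -> pd.DataFrame:
    """Full detection pipeline per region: z-score, median filter, find peaks.

    Returns a long-format frame (region, frame, time_s, amplitude) plus any
    session metadata carried by the traces.
    """
    rows = []
    for i, region in enumerate(traces.region_names):
        x = traces.values[i]
        if zscore:
            x = zscore_trace(x)
        x = median_filter(x, kernel)
        for ev in detect_events(x, traces.fps, region=region, height=height):
            rows.append(
                {"region": ev.region, "frame": ev.frame, "time_s": ev.time_s, "amplitude": ev.amplitude}
            )
    df = pd.DataFrame(rows, columns=["region", "frame", "time_s", "amplitude"])
    for key, val in traces.meta.items():
        df[key] = val
    return df


def event_frequency(events, duration_s: float) -> float:
    """Events per minute."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    return n * 60.0 / duration_s


def bin_amplitudes(
    amplitudes: np.ndarray,
    edges=DEFAULT_EDGES,
    subject: int | None = None,
    region: str | None = None,
    condition: str | None = None,
) -> AmplitudeHistogram:
    """Histogram amplitudes into half-open bins [e_i, e_{i+1}) plus an open top bin.

    Relative frequencies are normalized within this cell; with zero events
    they are NaN-flagged.  Amplitudes below the first edge cannot occur given
    the detection threshold and are excluded with a warning.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with at least two entries")
    a = np.asarray(amplitudes, dtype=float)
    below = a < edges[0]
    if below.any():
        warnings.warn(f"excluding {below.sum()} amplitudes below the first edge")
        a = a[~below]
    # the final listed interval is open above: n_bins = len(edges) - 1
    full_edges = np.append(edges[:-1], np.inf)
    counts, _ = np.histogram(a, bins=full_edges)
    total = counts.sum()
    rel = counts / total if total > 0 else np.full(len(counts), np.nan)
    return AmplitudeHistogram(
        bin_edges=edges, counts=counts, relative_freq=rel,
        subject=subject, region=region, condition=condition,
    )


def ks_two_sample(amplitudes_a: np.ndarray, amplitudes_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p, effective n = nm/(n+m))."""
    a = np.asarray(amplitudes_a, dtype=float)
    b = np.asarray(amplitudes_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def amplitude_histogram_table(
    events: pd.DataFrame, edges=DEFAULT_EDGES, by=("subject", "region", "condition")
) -> pd.DataFrame:
    """Long-format per-bin relative frequencies, one row per (cell, bin)."""
    edges = np.asarray(edges, dtype=float)
    labels = [f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(edges[:-2], edges[1:-1])] + [f">={edges[-2]:.1f}"]
    rows = []
    for keys, grp in events.groupby(list(by)):
        hist = bin_amplitudes(grp["amplitude"].to_numpy(), edges)
        for k, label in enumerate(labels):
            row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
            row.update({"bin": label, "bin_index": k,
                        "count": int(hist.counts[k]), "relative_freq": hist.relative_freq[k]})
            rows.append(row)
    return pd.DataFrame(rows)
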