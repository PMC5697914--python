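"""Dendritic calcium trace analysis.

Traces are detrended with a rolling low-percentile baseline (8th percentile
in a +/-15 s window) and expressed as %dF/F0.  Branchpoint pairs are
compared by total activity (time integral of the %dF/F0 signal), Pearson
correlation and mutual information; calcium transients present in one
branch of a pair but absent in its sibling are flagged as branch-specific
and summarized as a fraction of total activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BranchPairRecording",
    "CalciumEvent",
    "detrend_dff",
    "activity_integral",
    "pair_similarity",
    "detect_events",
    "detect_branch_specific",
    "branch_specific_fraction",
]

ROIS = ("branch1", "branch2", "within_branch1", "different_cell")


@dataclass
class BranchPairRecording:
    """Raw fluorescence traces for a branchpoint pair plus control ROIs.

    ``traces`` maps ROI name -> raw fluorescence array; the canonical ROIs
    are branch1 and branch2 (sharing a branchpoint), within_branch1 (a
    region 10 um away on branch 1) and different_cell.
    """

    traces: dict[str, np.ndarray]
    rate_hz: float

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.traces = {k: np.asarray(v, dtype=float) for k, v in self.traces.items()}
        lengths = {v.size for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must have equal length")

    @property
    def n_frames(self) -> int:
        return next(iter(self.traces.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz


@dataclass
class CalciumEvent:
    roi: str
    onset: int            # frame index
    offset: int           # frame index (inclusive)
    peak: float           # %dF/F0
    integral: float       # %dF/F0 * s
    branch_specific: bool = False

    def to_dict(self) -> dict:
        return {"roi": self.roi, "onset": self.onset, "offset": self.offset,
                "peak": self.peak, "integral": self.integral,
                "branch_specific": self.branch_specific}


def detrend_dff(raw: np.ndarray, rate_hz: float, window_s: float = 15.0,
                percentile: float = 8.0) -> np.ndarray:
    """Rolling-percentile detrending to %dF/F0.

    The baseline F0(t) is the ``percentile``-th percentile of the raw
    fluorescence in a +/-``window_s`` window (truncated at the edges); the
    output is 100 * (F - F0) / F0.
    """
    raw = np.asarray(raw, dtype=float)
    half = int(round(window_s * rate_hz))
    if raw.size <= 2 * half:
        raise ValueError(
            f"trace of {raw.size} frames is too short for a +/-{window_s} s window"
        )
    f0 = (pd.Series(raw)
          .rolling(window=2 * half + 1, center=True, min_periods=1)
          .quantile(percentile / 100.0)
          .to_numpy())
    if np.any(f0 <= 0):
        bad = int(np.argmax(f0 <= 0))
        raise ValueError(
            f"non-positive baseline F0={f0[bad]:.3g} at frame {bad}; "
            "raw fluorescence must stay positive for a %dF/F0 signal"
        )
    return 100.0 * (raw - f0) / f0


def activity_integral(dff: np.ndarray, rate_hz: float) -> float:
    """Time integral of the %dF/F0 signal (rectangle rule), in %*s."""
    dff = np.asarray(dff, dtype=float)
    return float(dff.sum() / rate_hz)


def pair_similarity(trace_a: np.ndarray, trace_b: np.ndarray,
                    mi_bins: int = 10) -> tuple[float, float]:
    """Pearson r and plug-in mutual information (bits) between two signals.

    MI uses a joint histogram with ``mi_bins`` equal-width bins per axis
    spanning each signal's observed range.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance trace: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    joint, _, _ = np.histogram2d(a, b, bins=mi_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())
    return r, mi


def detect_events(dff: np.ndarray, rate_hz: float, roi: str = "",
                  threshold_pct: float = 15.0) -> list[CalciumEvent]:
    """Find contiguous supra-threshold calcium transients in one trace.

    An event starts where the signal crosses ``threshold_pct`` and ends at
    the first frame falling below half the threshold after the peak; its
    integral is the rectangle-rule integral of the signal over that span.
    """
    dff = np.asarray(dff, dtype=float)
    events: list[CalciumEvent] = []
    i = 0
    n = dff.size
    off_level = threshold_pct / 2.0
    while i < n:
        if dff[i] >= threshold_pct:
            onset = i
            j = i
            while j + 1 < n and dff[j + 1] >= off_level:
                j += 1
            seg = dff[onset : j + 1]
            events.append(CalciumEvent(
                roi=roi, onset=onset, offset=j,
                peak=float(seg.max()),
                integral=float(seg.sum() / rate_hz)))
            i = j + 1
        else:
            i += 1
    return events


def detect_branch_specific(pair: BranchPairRecording, threshold_pct: float = 15.0,
                           simultaneity_window_s: float = 0.5,
                           window_s: float = 15.0,
                           percentile: float = 8.0) -> list[CalciumEvent]:
    """Detect events in both branches of a pair and flag branch-specific ones.

    An event in one branch is branch-specific iff the partner branch has no
    supra-threshold frame within ``simultaneity_window_s`` of the event's
    span.
    """
    out: list[CalciumEvent] = []
    dffs = {roi: detrend_dff(pair.traces[roi], pair.rate_hz, window_s, percentile)
            for roi in ("branch1", "branch2")}
    pad = int(round(simultaneity_window_s * pair.rate_hz))
    supra = {roi: dffs[roi] >= threshold_pct for roi in dffs}
    for roi, partner in (("branch1", "branch2"), ("branch2", "branch1")):
        for ev in detect_events(dffs[roi], pair.rate_hz, roi, threshold_pct):
            lo = max(0, ev.onset - pad)
            hi = min(pair.n_frames, ev.offset + 1 + pad)
            ev.branch_specific = not bool(supra[partner][lo:hi].any())
            out.append(ev)
    return out


def event_summary(events: list[CalciumEvent], duration_s: float) -> dict:
    """Frequency (events/min) and mean peak, overall and branch-specific."""
    bs = [e for e in events if e.branch_specific]
    minutes = duration_s / 60.0
    return {
        "n_events": len(events),
        "n_branch_specific": len(bs),
        "frequency_per_min": len(events) / minutes,
        "bs_frequency_per_min": len(bs) / minutes,
        "mean_peak_pct": float(np.mean([e.peak for e in events])) if events else float("nan"),
        "bs_mean_peak_pct": float(np.mean([e.peak for e in bs])) if bs else float("nan"),
    }


def branch_specific_fraction(pair: BranchPairRecording, threshold_pct: float = 15.0,
                             simultaneity_window_s: float = 0.5,
                             window_s: float = 15.0,
                             percentile: float = 8.0) -> dict:
    """Percent of each branch's activity attributable to branch-specific events.

    Per branch: 100 * (sum of branch-specific event integrals) / (total
    activity integral).  The pair difference is |BS1 - BS2| expressed as a
    percentage of the mean of the two branches' total activity integrals.
    """
    events = detect_branch_specific(pair, threshold_pct, simultaneity_window_s,
                                    window_s, percentile)
    totals = {}
    bs_int = {}
    for roi in ("branch1", "branch2"):
        dff = detrend_dff(pair.traces[roi], pair.rate_hz, window_s, percentile)
        totals[roi] = activity_integral(dff, pair.rate_hz)
        bs_int[roi] = sum(e.integral for e in events
                          if e.roi == roi and e.branch_specific)
    if totals["branch1"] == 0 or totals["branch2"] == 0:
        raise ValueError("zero total activity: branch-specific fraction undefined")
    frac = {roi: 100.0 * bs_int[roi] / totals[roi] for roi in totals}
    mean_total = 0.5 * (totals["branch1"] + totals["branch2"])
    diff = 100.0 * abs(bs_int["branch1"] - bs_int["branch2"]) / mean_total
    return {
        "fraction_branch1_pct": frac["branch1"],
        "fraction_branch2_pct": frac["branch2"],
        "pair_difference_pct": diff,
        "bs_integral_branch1": bs_int["branch1"],
        "bs_integral_branch2": bs_int["branch2"],
        "total_integral_branch1": totals["branch1"],
        "total_integral_branch2": totals["branch2"],
        "events": events,
    }
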