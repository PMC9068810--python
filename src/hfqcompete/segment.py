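"""Trace idealisation: bound/unbound intervals, flow detection, step counting.

Binding analysis runs on each channel's own excited-frame timebase (0.2 s
effective resolution while the lasers alternate).  Frames brighter than
``background + k * SD`` are "on"; runs of at least ``min_frames`` on-frames
form bound intervals and dark gaps up to ``gap_frames`` (blinking) are
bridged.  Interval times are reported in seconds on the global movie clock,
half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FlowStepError
from .traces import IntensityTrace

__all__ = [
    "BoundInterval",
    "detect_flow_time",
    "segment_trace",
    "estimate_unit_intensity",
    "unit_from_plateaus",
    "quantize_stoichiometry",
    "intervals_from_counts",
    "intervals_to_frame",
    "lowest_mode",
]


@dataclass
class BoundInterval:
    """Half-open interval [t_start, t_end) with a fluorophore bound.

    ``stoichiometry`` is the maximum concurrent fluorophore count in the
    interval; ``segments`` (optional) lists ``(t0, t1, count)`` pieces from
    stepwise intensity changes.  Censoring flags mark intervals touching the
    movie boundaries, whose true dwell exceeds the recorded one.
    """

    channel: str
    t_start: float
    t_end: float
    stoichiometry: int = 1
    left_censored: bool = False
    right_censored: bool = False
    segments: list | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise DataError("interval must have t_end > t_start")
        if self.stoichiometry < 1:
            raise DataError("stoichiometry must be >= 1")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def intervals_from_counts(
    counts: np.ndarray,
    frame_indices: np.ndarray,
    frame_interval: float,
    n_frames: int,
    channel: str,
    min_frames: int = 2,
    gap_frames: int = 1,
) -> list[BoundInterval]:
    """Turn per-excited-frame occupancy counts into :class:`BoundInterval` s.

    ``counts`` is an integer array over the channel's excited frames (global
    indices ``frame_indices``).  Zero-count gaps of at most ``gap_frames``
    samples are bridged (the gap inherits the preceding count) and runs
    shorter than ``min_frames`` are discarded.
    """
    counts = np.asarray(counts, dtype=int)
    frame_indices = np.asarray(frame_indices, dtype=int)
    if counts.shape != frame_indices.shape:
        raise DataError("counts and frame_indices must align")
    on = counts >= 1
    # order matters: runs shorter than min_frames are noise and must be
    # dropped *before* gap bridging, or two isolated noise frames straddling
    # a bridged gap would fabricate an interval
    padded = np.concatenate([[False], on, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = [(lo, hi) for lo, hi in zip(edges[::2], edges[1::2]) if hi - lo >= min_frames]
    on = np.zeros_like(on)
    for lo, hi in runs:
        on[lo:hi] = True
    if gap_frames > 0 and runs:
        filled = counts.copy()
        merged = [list(runs[0])]
        for lo, hi in runs[1:]:
            if lo - merged[-1][1] <= gap_frames:
                filled[merged[-1][1] : lo] = filled[merged[-1][1] - 1]
                on[merged[-1][1] : lo] = True
                merged[-1][1] = hi
            else:
                merged.append([lo, hi])
        counts = filled
        runs = [tuple(r) for r in merged]

    movie_end = n_frames * frame_interval
    intervals: list[BoundInterval] = []
    for lo, hi in runs:  # on-runs, samples [lo, hi)
        t_start = frame_indices[lo] * frame_interval
        t_end = frame_indices[hi] * frame_interval if hi < counts.size else movie_end
        run = counts[lo:hi]
        # piecewise-constant stoichiometry segments within the run
        change = np.flatnonzero(np.diff(run)) + 1
        bounds = np.concatenate([[0], change, [run.size]])
        segs = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            s0 = frame_indices[lo + a] * frame_interval
            s1 = frame_indices[lo + b] * frame_interval if lo + b < counts.size else movie_end
            segs.append((s0, s1, int(run[a])))
        intervals.append(
            BoundInterval(
                channel=channel,
                t_start=t_start,
                t_end=t_end,
                stoichiometry=int(run.max()),
                left_censored=lo == 0,
                right_censored=hi == counts.size,
                segments=segs,
            )
        )
    return intervals


# ---------------------------------------------------------------------------
# background and flow-step estimation


def lowest_mode(values: np.ndarray, n_bins: int = 64, rel_height: float = 0.25):
    """Locate the lowest-intensity mode of a sample; returns (level, sd).

    Used to estimate the unbound background level of a trace whose dark
    periods form the dimmest cluster of the intensity histogram.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("no samples for background estimation")
    if np.ptp(v) == 0:
        return float(v[0]), 0.0
    hist, edges = np.histogram(v, bins=n_bins)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    floor = rel_height * smooth.max()
    peaks = [
        i
        for i in range(len(smooth))
        if smooth[i] >= floor
        and (i == 0 or smooth[i] >= smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] >= smooth[i + 1])
    ]
    p = peaks[0] if peaks else int(np.argmax(smooth))
    lo, hi = p, p
    while lo > 0 and smooth[lo - 1] >= 0.5 * smooth[p]:
        lo -= 1
    while hi < len(smooth) - 1 and smooth[hi + 1] >= 0.5 * smooth[p]:
        hi += 1
    sel = (v >= edges[lo]) & (v <= edges[hi + 1])
    cluster = v[sel] if sel.any() else v
    level = float(np.median(cluster))
    sd = float(1.4826 * np.median(np.abs(cluster - level)))
    return level, sd


def _best_split(v: np.ndarray, mask: np.ndarray):
    """Best two-constant change point over masked samples.

    Returns (split_index, sse_two, sse_one, mean_left, mean_right); the split
    is the first index of the right segment, chosen to minimise the summed
    squared error of per-side constant fits restricted to ``mask``.
    """
    w = mask.astype(float)
    x = v * w
    cw = np.cumsum(w)
    cx = np.cumsum(x)
    cx2 = np.cumsum(x * v)
    n, sx, sx2 = cw[-1], cx[-1], cx2[-1]
    if n < 4:
        raise FlowStepError("too few background samples for a change point")
    sse_one = sx2 - sx**2 / n
    nl, xl, x2l = cw[:-1], cx[:-1], cx2[:-1]
    nr, xr, x2r = n - nl, sx - xl, sx2 - x2l
    valid = (nl >= 2) & (nr >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = (x2l - xl**2 / nl) + (x2r - xr**2 / nr)
    sse[~valid] = np.inf
    j = int(np.argmin(sse))
    split = j + 1
    return split, float(sse[j]), float(sse_one), float(cx[j] / cw[j]), float((sx - cx[j]) / (n - cw[j]))


def detect_flow_time(trace: IntensityTrace, min_improvement: float = 0.05, n_iter: int = 5) -> float:
    """Time of competitor addition from the Cy5 background step.

    Fits a two-level constant model to the trace's background samples
    (binding pulses are iteratively masked out as high outliers) and returns
    the change-point time on the global movie clock.  Raises
    :class:`FlowStepError` when the step improves the one-level fit by less
    than ``min_improvement`` (no detectable flow event).
    """
    v = trace.intensity.astype(float)
    mask = np.ones(v.size, dtype=bool)
    for _ in range(n_iter):
        split, *_ = _best_split(v, mask)
        # robust per-side background levels; binding pulses are high outliers
        new_mask = mask
        sides = [(slice(0, split),), (slice(split, v.size),)]
        levels = np.empty(v.size)
        sds = np.empty(v.size)
        for (sl,) in sides:
            vals = v[sl][mask[sl]]
            if vals.size == 0:
                vals = v[sl]
            med, sd = lowest_mode(vals)
            levels[sl], sds[sl] = med, sd
        new_mask = v <= levels + 4.0 * np.maximum(sds, 1e-12)
        if new_mask.sum() < 4 or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= 4 else mask
            break
        mask = new_mask
    split, sse2, sse1, mu_l, mu_r = _best_split(v, mask)
    if sse1 <= 0:
        raise FlowStepError("constant background: no flow step present")
    if (sse1 - sse2) / sse1 < min_improvement:
        raise FlowStepError("no detectable Cy5 background step; supply flow_time manually")
    return split * trace.frame_interval


# ---------------------------------------------------------------------------
# segmentation


def _background_model(trace, background, noise_sd, flow_time, background_post):
    """Per-excited-frame background level and noise SD."""
    idx = trace.excited_frames
    t = idx * trace.frame_interval
    if background is None:
        level, sd = lowest_mode(trace.intensity[idx])
        bg = np.full(idx.size, level)
        if flow_time is not None and background_post is not None:
            bg = np.where(t >= flow_time, background_post, level)
    else:
        bg = np.full(idx.size, float(background))
        if flow_time is not None and background_post is not None:
            bg = np.where(t >= flow_time, background_post, background)
        sd = None
    if noise_sd is not None:
        sd = float(noise_sd)
    elif sd is None:
        _, sd = lowest_mode(trace.intensity[idx])
    return bg, sd


def segment_trace(
    trace: IntensityTrace,
    threshold_k: float = 2.5,
    min_frames: int = 2,
    gap_frames: int = 1,
    background: float | None = None,
    noise_sd: float | None = None,
    flow_time: float | None = None,
    background_post: float | None = None,
) -> list[BoundInterval]:
    """Threshold a trace into bound intervals on its excited-frame timebase.

    ``background``/``noise_sd`` default to a per-trace lowest-histogram-mode
    estimate; pipelines that know the acquisition background (or can pool
    many traces) should pass explicit values.  For Cy5 traces the post-flow
    background level can be supplied via ``flow_time``/``background_post``.
    """
    idx = trace.excited_frames
    if idx.size < 10:
        raise DataError("trace has fewer than 10 excited frames")
    bg, sd = _background_model(trace, background, noise_sd, flow_time, background_post)
    on = trace.intensity[idx] > bg + threshold_k * sd
    return intervals_from_counts(
        on.astype(int),
        frame_indices=idx,
        frame_interval=trace.frame_interval,
        n_frames=trace.n_frames,
        channel=trace.channel,
        min_frames=min_frames,
        gap_frames=gap_frames,
    )


# ---------------------------------------------------------------------------
# fluorophore unit intensity and stoichiometry


def _interval_samples(trace: IntensityTrace, interval: BoundInterval, background, flow_time, background_post):
    idx = trace.excited_frames
    t = idx * trace.frame_interval
    sel = (t >= interval.t_start) & (t < interval.t_end)
    bg, _ = _background_model(trace, background, 0.0, flow_time, background_post)
    return t[sel], trace.intensity[idx][sel] - bg[sel]


def unit_from_plateaus(plateaus: np.ndarray) -> float:
    """Single-fluorophore intensity from the lowest mode of interval plateaus."""
    p = np.sort(np.asarray(plateaus, dtype=float))
    if p.size < 20:
        raise DataError("need at least 20 intervals to estimate the unit intensity")
    rough = np.percentile(p, 25.0)
    kept = p[(p >= 0.5 * rough) & (p < 1.5 * rough)]
    if kept.size == 0:
        kept = p
    return float(np.median(kept))


def estimate_unit_intensity(
    items,
    background: float | None = None,
    flow_time: float | None = None,
    background_post: float | None = None,
) -> float:
    """Median background-subtracted plateau of single-fluorophore intervals.

    ``items`` iterates over ``(trace, intervals)`` pairs; plateaus falling in
    the lowest mode of the plateau distribution are taken as one fluorophore.
    """
    plateaus = []
    for trace, intervals in items:
        for iv in intervals:
            _, v = _interval_samples(trace, iv, background, flow_time, background_post)
            if v.size:
                plateaus.append(float(np.median(v)))
    return unit_from_plateaus(np.asarray(plateaus))


def quantize_stoichiometry(
    interval: BoundInterval,
    trace: IntensityTrace,
    unit: float,
    background: float | None = None,
    flow_time: float | None = None,
    background_post: float | None = None,
) -> list[tuple]:
    """Count fluorophores per stepwise segment of a bound interval.

    Each excited frame's background-subtracted intensity is divided by
    ``unit`` and rounded to the nearest count, which detects every internal
    step of at least ``0.5 * unit``; frames rounding to zero (bridged
    blinking gaps) inherit the neighbouring count, or are clamped to 1 with
    a warning when the whole interval rounds to zero.  Runs of equal count
    become the interval's ``segments``; its ``stoichiometry`` is the maximum
    segment count.
    """
    if unit <= 0:
        raise ConfigurationError("unit intensity must be positive")
    t, v = _interval_samples(trace, interval, background, flow_time, background_post)
    if v.size == 0:
        raise DataError("interval contains no excited frames")
    counts = np.rint(v / unit).astype(int)
    counts[counts < 0] = 0
    if (counts == 0).all():
        warnings.warn("interval intensity rounds to 0 fluorophores; clamped to 1", stacklevel=2)
        counts[:] = 1
    elif (counts == 0).any():  # bridged dark frames inherit the previous count
        nz = counts != 0
        idx = np.maximum.accumulate(np.where(nz, np.arange(counts.size), -1))
        first = np.flatnonzero(nz)[0]
        idx[idx < 0] = first
        counts = counts[idx]
    change = np.flatnonzero(np.diff(counts)) + 1
    bounds = [0, *change.tolist(), counts.size]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        s0 = t[a] if a > 0 else interval.t_start
        s1 = t[b] if b < counts.size else interval.t_end
        segments.append((float(s0), float(s1), int(counts[a])))
    interval.segments = segments
    interval.stoichiometry = max(c for _, _, c in segments)
    return segments


# ---------------------------------------------------------------------------
# I/O


def intervals_to_frame(intervals_by_molecule: dict) -> pd.DataFrame:
    """Flatten {molecule_id: {channel: [BoundInterval...]}} into a table."""
    rows = []
    for mol, by_channel in intervals_by_molecule.items():
        for channel, ivs in by_channel.items():
            for iv in ivs:
                rows.append(
                    {
                        "molecule_id": mol,
                        "channel": channel,
                        "t_start_s": iv.t_start,
                        "t_end_s": iv.t_end,
                        "stoichiometry": iv.stoichiometry,
                        "left_censored": iv.left_censored,
                        "right_censored": iv.right_censored,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id",
            "channel",
            "t_start_s",
            "t_end_s",
            "stoichiometry",
            "left_censored",
            "right_censored",
        ],
    )
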