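"""Pairwise correlations between simultaneously recorded cells.

Temporal: lag-0 Pearson of the two binned spike trains after a centered
25 ms moving average. Spatial: masked Pearson of the two rate maps at every
offset, read out at zero offset, plus the angle to the nearest non-central
peak. Time-windowed: 2D histograms of partner-spike displacements relative
to each reference spike, restricted to +/- w seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import (
    ArenaSpec,
    Autocorrelogram,
    RateMap,
    SpikeTrain,
    Trajectory,
    masked_sliding_correlation,
    nan_pearson,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_NBINS,
)
from .scoring import detect_fields

DEFAULT_BIN_WIDTH = 0.001  # s
DEFAULT_SMOOTH_WINDOW = 0.025  # s


@dataclass
class TemporalCorrResult:
    r: float
    bin_width: float
    smooth_window: float
    lag: float = 0.0


@dataclass
class SpatialXCorrResult:
    correlogram: Autocorrelogram
    value_at_zero: float
    nearest_peak_angle: float  # degrees or NaN


@dataclass
class WindowedMap:
    counts: np.ndarray  # (2*nbins-1, 2*nbins-1) partner-spike displacement counts
    window_halfwidth: float
    bin_size: float
    ref_cell: str = ""
    partner_cell: str = ""

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())


def bin_spike_counts(
    train: SpikeTrain, bin_width: float = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    """Spike counts on the train's own condition clock."""
    n = int(np.ceil(train.duration / bin_width))
    idx = np.floor((train.times - train.t_start) / bin_width).astype(int)
    idx = np.clip(idx, 0, n - 1)
    counts = np.zeros(n)
    np.add.at(counts, idx, 1.0)
    return counts


def moving_average(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered boxcar; edge bins average over the truncated window.

    Matches ``np.convolve(x, ones(w), 'same') / np.convolve(ones, ...)``
    but runs in O(n) via cumulative sums.
    """
    x = np.asarray(x, dtype=float)
    w = int(window_bins)
    if w <= 1:
        return x
    n = x.size
    half_hi = (w - 1) // 2  # trailing extent of the centered window
    half_lo = w - 1 - half_hi
    cs = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    hi = np.minimum(idx + half_hi + 1, n)
    lo = np.maximum(idx - half_lo, 0)
    return (cs[hi] - cs[lo]) / (hi - lo)


def smoothed_counts(
    train: SpikeTrain,
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
) -> np.ndarray:
    w = max(1, int(round(smooth_window / bin_width)))
    return moving_average(bin_spike_counts(train, bin_width), w)


def temporal_correlation(
    a: SpikeTrain,
    b: SpikeTrain,
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
) -> TemporalCorrResult:
    """Lag-0 Pearson correlation of the smoothed binned spike trains.

    NaN when either train is empty or has zero variance after smoothing.
    Both trains must span the same condition window.
    """
    if abs(a.t_start - b.t_start) > bin_width or abs(a.t_stop - b.t_stop) > bin_width:
        raise ValueError("trains must span the same condition window")
    if a.n_spikes == 0 or b.n_spikes == 0:
        return TemporalCorrResult(float("nan"), bin_width, smooth_window)
    xa = smoothed_counts(a, bin_width, smooth_window)
    xb = smoothed_counts(b, bin_width, smooth_window)
    n = min(xa.size, xb.size)
    r = nan_pearson(xa[:n], xb[:n], min_overlap=2)
    return TemporalCorrResult(r, bin_width, smooth_window)


def spatial_cross_correlation(
    map_a: RateMap, map_b: RateMap, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SpatialXCorrResult:
    """Masked Pearson of two rate maps at every offset, read out at [0,0]."""
    if map_a.rate.shape != map_b.rate.shape:
        raise ValueError("rate maps must share binning")
    xc = masked_sliding_correlation(map_a.rate, map_b.rate, min_overlap)
    xc.bin_size = map_a.bin_size
    center = xc.center
    # the zero-offset readout is the headline value: compute it exactly
    r0 = nan_pearson(map_a.rate, map_b.rate, min_overlap=min_overlap)
    if not np.isnan(r0):
        xc.values[center] = r0
    return SpatialXCorrResult(
        correlogram=xc,
        value_at_zero=r0,
        nearest_peak_angle=nearest_peak_angle(xc),
    )


def nearest_peak_angle(
    xcorr: Autocorrelogram | SpatialXCorrResult, min_prominence: float = 0.1
) -> float:
    """Angle (degrees CCW from +x) to the nearest non-central peak.

    Peaks are the detected fields of the (already aggregated) correlogram;
    the central field (the one containing the zero offset) is skipped.
    Returns NaN when no non-central peak exists. Row index maps to +y.
    """
    ac = xcorr.correlogram if isinstance(xcorr, SpatialXCorrResult) else xcorr
    fields = detect_fields(ac, min_prominence=min_prominence)
    center = ac.center
    cands = [f for f in fields if not f.is_central]
    if not cands:
        return float("nan")
    nearest = min(cands, key=lambda f: f.distance_from(center))
    dy, dx = nearest.centroid_offset(center)
    return float(np.rad2deg(np.arctan2(dy, dx)) % 360.0)


def windowed_relative_map(
    ref: SpikeTrain,
    partner: SpikeTrain,
    traj: Trajectory,
    arena: ArenaSpec,
    window_halfwidth: float,
    nbins: int = DEFAULT_NBINS,
) -> WindowedMap:
    """Partner-spike displacements around each reference spike.

    For each reference spike at position p and time t, every partner spike
    with |t_partner - t| <= w (closed window) adds one count at the
    displacement (partner_pos - p). The map spans +/- the arena side at
    2*nbins - 1 bins.
    """
    if ref.n_spikes == 0:
        raise ValueError("empty reference train")
    side = arena.side_length
    bin_size = side / nbins
    size = 2 * nbins - 1
    counts = np.zeros((size, size))
    rx, ry = traj.interpolate(ref.times)
    px, py = traj.interpolate(partner.times)
    pt = partner.times
    lo = np.searchsorted(pt, ref.times - window_halfwidth, side="left")
    hi = np.searchsorted(pt, ref.times + window_halfwidth, side="right")
    for i in range(ref.n_spikes):
        if hi[i] <= lo[i]:
            continue
        dx = px[lo[i]:hi[i]] - rx[i]
        dy = py[lo[i]:hi[i]] - ry[i]
        # displacements at the extreme +/- side fall half a bin outside the
        # grid; clamp them into the edge bins so every pair counts once
        cols = np.clip(np.floor(dx / bin_size).astype(int) + (nbins - 1), 0, size - 1)
        rows = np.clip(np.floor(dy / bin_size).astype(int) + (nbins - 1), 0, size - 1)
        np.add.at(counts, (rows, cols), 1.0)
    return WindowedMap(
        counts=counts,
        window_halfwidth=window_halfwidth,
        bin_size=bin_size,
        ref_cell=ref.cell_id,
        partner_cell=partner.cell_id,
    )


def windowed_map_correlation(
    map_x: WindowedMap, map_y: WindowedMap, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Masked Pearson of two aggregated displacement maps."""
    if map_x.counts.shape != map_y.counts.shape:
        raise ValueError("windowed maps must share binning")
    if map_x.window_halfwidth != map_y.window_halfwidth:
        raise ValueError("windowed maps must share the window halfwidth")
    return nan_pearson(map_x.counts, map_y.counts, min_overlap=min_overlap)
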