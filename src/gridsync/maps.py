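"""Spatial binning of trajectories and spike trains.

Converts tracked positions and spike times into occupancy maps, firing-rate
maps, and masked (NaN-aware) normalized 2D spatial autocorrelograms.

Conventions
-----------
* Arenas are square, ``nbins`` x ``nbins`` (default 50x50) equally sized bins.
* Row index follows y, column index follows x; bin edges are half-open
  ``[lo, hi)`` with the final edge closed.
* Undefined (unvisited / insufficient-overlap) entries are marked ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d, fftconvolve

DEFAULT_NBINS = 50
#: minimum number of jointly defined bins for any masked correlation
DEFAULT_MIN_OVERLAP = 20


@dataclass(frozen=True)
class ArenaSpec:
    """Square open-field arena."""

    side_length: float  # cm

    def __post_init__(self) -> None:
        if not self.side_length > 0:
            raise ValueError(f"side_length must be > 0, got {self.side_length}")

    def bin_size(self, nbins: int = DEFAULT_NBINS) -> float:
        return self.side_length / nbins


@dataclass
class Trajectory:
    """Uniformly sampled animal path: time, position and head direction.

    ``hd`` is in degrees, [0, 360).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = np.asarray(self.hd, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.hd.size == n):
            raise ValueError("t, x, y, hd must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValueError("need >= 2 samples to infer dt")
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt) if self.t.size >= 2 else 0.0

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        """Samples with t0 <= t < t1, timestamps kept on the original clock."""
        m = (self.t >= t0) & (self.t < t1)
        return Trajectory(self.t[m], self.x[m], self.y[m], self.hd[m])

    def interpolate(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of position at arbitrary times.

        Times up to one sampling interval outside the sampled span are
        clamped to the end samples; anything further out is an error.
        """
        times = np.asarray(times, dtype=float)
        if times.size and (
            times.min() < self.t[0] - self.dt or times.max() > self.t[-1] + self.dt
        ):
            raise ValueError("requested times outside trajectory span")
        xi = np.interp(times, self.t, self.x)
        yi = np.interp(times, self.t, self.y)
        return xi, yi

    def interpolate_hd(self, times: np.ndarray) -> np.ndarray:
        """Head direction at arbitrary times, interpolated on the circle."""
        times = np.asarray(times, dtype=float)
        rad = np.deg2rad(self.hd)
        s = np.interp(times, self.t, np.sin(rad))
        c = np.interp(times, self.t, np.cos(rad))
        return np.rad2deg(np.arctan2(s, c)) % 360.0


@dataclass
class SpikeTrain:
    """Sorted spike times of one cell within one condition window."""

    times: np.ndarray
    t_start: float
    t_stop: float
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and not np.all(np.diff(self.times) >= 0):
            raise ValueError("spike times must be sorted")
        if not self.t_stop > self.t_start:
            raise ValueError("t_stop must exceed t_start")
        if self.times.size and (
            self.times[0] < self.t_start or self.times[-1] > self.t_stop
        ):
            raise ValueError("spike times outside the condition span")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration

    def shifted_to_zero(self) -> "SpikeTrain":
        return SpikeTrain(
            self.times - self.t_start, 0.0, self.duration, self.cell_id, self.condition
        )


@dataclass
class OccupancyMap:
    """Dwell time (s) per spatial bin."""

    dwell: np.ndarray  # (nbins, nbins), seconds
    bin_size: float  # cm
    arena: ArenaSpec

    @property
    def total_time(self) -> float:
        return float(self.dwell.sum())


@dataclass
class RateMap:
    """Binned firing rate (Hz); NaN marks unvisited bins."""

    rate: np.ndarray
    bin_size: float
    arena: ArenaSpec
    n_spikes: int = 0

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rate)


@dataclass
class Autocorrelogram:
    """Masked spatial autocorrelogram; (2n-1) x (2n-1) for an n x n map.

    ``values[i, j]`` is the correlation at offset
    ``(dy, dx) = (i - n + 1, j - n + 1)`` bins; the center entry is the
    zero-offset correlation (1 by construction).
    """

    values: np.ndarray
    overlap: np.ndarray  # jointly defined bin count per offset
    bin_size: float = 1.0

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def _bin_indices(coords: np.ndarray, side: float, nbins: int) -> np.ndarray:
    """Half-open binning [lo, hi); the final edge is closed."""
    idx = np.floor(coords / side * nbins).astype(int)
    return np.clip(idx, 0, nbins - 1)


def bin_occupancy(
    traj: Trajectory, arena: ArenaSpec, nbins: int = DEFAULT_NBINS
) -> OccupancyMap:
    """Accumulate per-sample dwell time into spatial bins.

    Each trajectory sample contributes its sampling interval to exactly one
    bin, so the map total equals the tracked duration.
    """
    if traj.n_samples == 0:
        raise ValueError("empty trajectory")
    if traj.n_samples == 1:
        raise ValueError("cannot infer dwell from a single sample")
    dt = traj.dt
    rows = _bin_indices(traj.y, arena.side_length, nbins)
    cols = _bin_indices(traj.x, arena.side_length, nbins)
    dwell = np.zeros((nbins, nbins))
    np.add.at(dwell, (rows, cols), dt)
    return OccupancyMap(dwell, arena.bin_size(nbins), arena)


def compute_rate_map(
    spikes: SpikeTrain,
    traj: Trajectory,
    arena: ArenaSpec,
    nbins: int = DEFAULT_NBINS,
) -> RateMap:
    """Spike count map divided element-wise by the occupancy map.

    Bins never visited are NaN. Spike positions come from linear
    interpolation of the trajectory at spike times.
    """
    occ = bin_occupancy(traj, arena, nbins)
    sx, sy = traj.interpolate(spikes.times)
    counts = np.zeros((nbins, nbins))
    if spikes.n_spikes:
        rows = _bin_indices(sy, arena.side_length, nbins)
        cols = _bin_indices(sx, arena.side_length, nbins)
        np.add.at(counts, (rows, cols), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = counts / occ.dwell
    rate[occ.dwell == 0] = np.nan
    return RateMap(rate, occ.bin_size, arena, n_spikes=spikes.n_spikes)


def nan_pearson(
    a: np.ndarray, b: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Pearson correlation over entries where both inputs are defined.

    Returns NaN when fewer than ``min_overlap`` entries are jointly defined
    or when either side has zero variance on the overlap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    m = ~(np.isnan(a) | np.isnan(b))
    n = int(m.sum())
    if n < max(min_overlap, 2):
        return float("nan")
    av = a[m]
    bv = b[m]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    if denom == 0:
        return float("nan")
    r = float((av * bv).sum() / denom)
    return min(1.0, max(-1.0, r))


def masked_sliding_correlation(
    a: np.ndarray,
    b: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    method: str = "fft",
) -> Autocorrelogram:
    """Masked Pearson correlation of ``a`` against ``b`` at every 2D offset.

    Entry at offset (dy, dx) correlates ``a`` with ``b`` shifted by
    (dy, dx) bins, over the jointly defined region, as :func:`nan_pearson`
    would on the overlapping sub-matrices. The default path evaluates the
    per-offset sums with FFT convolutions (agrees with the direct
    evaluation to ~1e-9); ``method='direct'`` recomputes every offset
    explicitly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share shape")
    if np.all(np.isnan(a)) or np.all(np.isnan(b)):
        raise ValueError("all-undefined input map")
    if method == "fft":
        return _masked_sliding_correlation_fft(a, b, min_overlap)
    n_r, n_c = a.shape
    out = np.full((2 * n_r - 1, 2 * n_c - 1), np.nan)
    counts = np.zeros_like(out, dtype=int)
    for dy in range(-(n_r - 1), n_r):
        # overlapping row windows of a and b for this vertical offset
        if dy >= 0:
            ra = slice(dy, n_r)
            rb = slice(0, n_r - dy)
        else:
            ra = slice(0, n_r + dy)
            rb = slice(-dy, n_r)
        for dx in range(-(n_c - 1), n_c):
            if dx >= 0:
                ca = slice(dx, n_c)
                cb = slice(0, n_c - dx)
            else:
                ca = slice(0, n_c + dx)
                cb = slice(-dx, n_c)
            sub_a = a[ra, ca]
            sub_b = b[rb, cb]
            m = ~(np.isnan(sub_a) | np.isnan(sub_b))
            cnt = int(m.sum())
            counts[dy + n_r - 1, dx + n_c - 1] = cnt
            if cnt < max(min_overlap, 2):
                continue
            av = sub_a[m]
            bv = sub_b[m]
            av = av - av.mean()
            bv = bv - bv.mean()
            denom = np.sqrt((av * av).sum() * (bv * bv).sum())
            if denom == 0:
                continue
            out[dy + n_r - 1, dx + n_c - 1] = min(
                1.0, max(-1.0, float((av * bv).sum() / denom))
            )
    return Autocorrelogram(out, counts)


def _masked_sliding_correlation_fft(
    a: np.ndarray, b: np.ndarray, min_overlap: int
) -> Autocorrelogram:
    """All-offsets masked Pearson via FFT cross-correlation of the sums.

    For each offset the masked Pearson needs six sums over the jointly
    defined overlap (count, both sums, both sums of squares, cross sum);
    each is a full 2D cross-correlation of masked inputs, evaluated here
    with ``fftconvolve``.
    """
    mask_a = (~np.isnan(a)).astype(float)
    mask_b = (~np.isnan(b)).astype(float)
    va = np.where(np.isnan(a), 0.0, a)
    vb = np.where(np.isnan(b), 0.0, b)

    def xcorr(x, y):
        return fftconvolve(x, y[::-1, ::-1], mode="full")

    n = xcorr(mask_a, mask_b)
    sa = xcorr(va, mask_b)
    sb = xcorr(mask_a, vb)
    saa = xcorr(va * va, mask_b)
    sbb = xcorr(mask_a, vb * vb)
    sab = xcorr(va, vb)

    counts = np.rint(n).astype(int)
    nf = counts.astype(float)
    var_a = nf * saa - sa * sa
    var_b = nf * sbb - sb * sb
    # FFT round-off can leave tiny residuals where the true variance is 0
    scale_a = float(np.max(np.abs(va), initial=1.0)) ** 2
    scale_b = float(np.max(np.abs(vb), initial=1.0)) ** 2
    tol_a = 1e-9 * nf * scale_a
    tol_b = 1e-9 * nf * scale_b
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (nf * sab - sa * sb) / np.sqrt(
            np.clip(var_a, 0.0, None) * np.clip(var_b, 0.0, None)
        )
    bad = (
        (counts < max(min_overlap, 2))
        | (var_a <= tol_a)
        | (var_b <= tol_b)
        | ~np.isfinite(r)
    )
    r = np.clip(r, -1.0, 1.0)
    r[bad] = np.nan
    counts[counts < 0] = 0
    return Autocorrelogram(r, counts)


def spatial_autocorrelogram(
    rate_map: RateMap, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> Autocorrelogram:
    """Masked normalized 2D spatial autocorrelation of a rate map.

    The center entry (zero offset) is 1 and the result is point-symmetric
    about the center wherever defined.
    """
    ac = masked_sliding_correlation(rate_map.rate, rate_map.rate, min_overlap)
    c = ac.center
    if not np.isnan(ac.values[c]):
        ac.values[c] = 1.0
    ac.bin_size = rate_map.bin_size
    return ac


def _gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    xs = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (xs / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(m: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Masked (normalized-convolution) Gaussian smoothing.

    NaN entries contribute neither to the numerator nor to the kernel mass;
    the output is defined wherever at least one defined input falls inside
    the kernel support.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    m = np.asarray(m, dtype=float)
    if sigma == 0:
        return m.copy()
    k1 = _gaussian_kernel_1d(sigma)
    kernel = np.outer(k1, k1)
    mask = (~np.isnan(m)).astype(float)
    filled = np.where(np.isnan(m), 0.0, m)
    num = convolve2d(filled, kernel, mode="same", boundary="fill")
    den = convolve2d(mask, kernel, mode="same", boundary="fill")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den <= 1e-12] = np.nan
    return out
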