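"""Grid score via annulus rotation of the smoothed autocorrelogram, and
head-direction selectivity via the Rayleigh vector of the tuning curve.

The grid score is the masked correlation of the annulus-restricted
autocorrelogram with its 60-degree rotation minus the correlation with its
30-degree rotation, so scores live in [-2, 2]. Cells whose smoothed
autocorrelogram does not yield six distinct non-central firing fields get
the default score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .maps import (
    Autocorrelogram,
    RateMap,
    SpikeTrain,
    Trajectory,
    gaussian_smooth,
    nan_pearson,
    spatial_autocorrelogram,
    DEFAULT_MIN_OVERLAP,
)

EIGHT_CONN = np.ones((3, 3), dtype=int)

#: minimum peak prominence (value units) for a detected field
DEFAULT_MIN_PROMINENCE = 0.1
#: head-direction tuning curve resolution: 60 bins of 6 degrees
DEFAULT_HD_NBINS = 60


@dataclass
class FiringField:
    """One connected region of elevated autocorrelogram values."""

    bins: np.ndarray  # (k, 2) array of (row, col) member pixels
    peak_rc: tuple[int, int]
    peak_value: float
    level: float  # highest threshold at which the region is distinct
    centroid: tuple[float, float]  # (row, col), fractional
    mean_radius: float  # bins
    is_central: bool = False

    def centroid_offset(self, center: tuple[int, int]) -> tuple[float, float]:
        """(dy, dx) of the centroid relative to the autocorrelogram center."""
        return (self.centroid[0] - center[0], self.centroid[1] - center[1])

    def distance_from(self, center: tuple[int, int]) -> float:
        dy, dx = self.centroid_offset(center)
        return float(np.hypot(dy, dx))


@dataclass(frozen=True)
class AnnulusSpec:
    """Ring about the autocorrelogram center, radii in bins."""

    inner_radius: float
    outer_radius: float

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")


@dataclass
class GridScoreResult:
    score: float
    corr60: float = float("nan")
    corr30: float = float("nan")
    fields: list = field(default_factory=list)
    annulus: AnnulusSpec | None = None
    defaulted: bool = False


@dataclass
class RayleighResult:
    score: float
    preferred_angle: float  # degrees in [0, 360)


class AnnulusUnavailable(Exception):
    """Fewer than six distinct non-central fields: no annulus, default score."""


def _field_persistence(values: np.ndarray) -> list[dict]:
    """Union-find persistence of local maxima of a masked image.

    Pixels are merged in descending value order; when two growing regions
    meet, the one born at the lower peak dies (elder rule). Each peak's
    record carries its birth value, death value (the merge level; -inf for
    the global maximum) and final root for membership assignment.
    """
    defined = ~np.isnan(values)
    order = np.argsort(values[defined])[::-1]
    coords = np.argwhere(defined)[order]
    vals = values[defined][order]

    parent: dict[tuple[int, int], tuple[int, int]] = {}
    birth: dict[tuple[int, int], float] = {}  # root peak -> birth value
    death: dict[tuple[int, int], float] = {}
    n_r, n_c = values.shape

    def find(p):
        root = p
        while parent[root] != root:
            root = parent[root]
        while parent[p] != root:
            parent[p], p = root, parent[p]
        return root

    for (r, c), v in zip(map(tuple, coords), vals):
        neighbor_roots = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                q = (r + dr, c + dc)
                if q != (r, c) and q in parent:
                    neighbor_roots.add(find(q))
        parent[(r, c)] = (r, c)
        if not neighbor_roots:
            birth[(r, c)] = v  # new local maximum
            continue
        roots = sorted(neighbor_roots, key=lambda q: birth[q], reverse=True)
        elder = roots[0]
        parent[(r, c)] = elder
        for other in roots[1:]:
            death[other] = v
            parent[other] = elder

    peaks = []
    for p, b in birth.items():
        peaks.append(
            {
                "peak_rc": p,
                "birth": b,
                "death": death.get(p, float("-inf")),
            }
        )
    return peaks


def detect_fields(
    smoothed_acorr: Autocorrelogram | np.ndarray,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[FiringField]:
    """Detect distinct firing fields of a smoothed autocorrelogram.

    A field is an 8-connected region around a local maximum that is a
    distinct component at its bounding threshold — every exterior boundary
    pixel sits below that threshold. Candidate regions come from the
    persistence decomposition (a peak lives from its birth value down to
    the saddle where it merges with a stronger region); peaks with
    prominence below ``min_prominence`` are discarded as ripples. Member
    pixels are the connected component above the half-prominence level
    (midpoint of peak and merge saddle), raised if necessary until the
    component contains no other accepted peak, which keeps field extents
    compact when saddles are deep.
    """
    values = (
        smoothed_acorr.values
        if isinstance(smoothed_acorr, Autocorrelogram)
        else np.asarray(smoothed_acorr, dtype=float)
    )
    if np.all(np.isnan(values)):
        return []
    center = (values.shape[0] // 2, values.shape[1] // 2)
    peaks = _field_persistence(values)

    finite_min = float(np.nanmin(values))
    accepted = []
    for p in peaks:
        death = p["death"] if np.isfinite(p["death"]) else finite_min
        if p["birth"] - death >= min_prominence:
            accepted.append((p, death))
    if not accepted:
        return []

    peak_set = {p["peak_rc"] for p, _ in accepted}
    fields: list[FiringField] = []
    filled = np.where(np.isnan(values), float("-inf"), values)
    for p, death in accepted:
        level = 0.5 * (p["birth"] + death)
        member = np.array([p["peak_rc"]])
        for _ in range(40):
            lab, _ = ndimage.label(filled > level, structure=EIGHT_CONN)
            region_id = lab[p["peak_rc"]]
            if region_id == 0:  # peak exactly at level; take the peak pixel
                member = np.array([p["peak_rc"]])
                break
            member = np.argwhere(lab == region_id)
            others = peak_set & set(map(tuple, member))
            others.discard(p["peak_rc"])
            if not others:
                break
            level = 0.5 * (level + p["birth"])
        w = values[member[:, 0], member[:, 1]] - level
        w = np.clip(w, 0.0, None)
        if w.sum() > 0:
            centroid = tuple((member * w[:, None]).sum(axis=0) / w.sum())
        else:
            centroid = tuple(member.mean(axis=0))
        d = np.hypot(member[:, 0] - centroid[0], member[:, 1] - centroid[1])
        fields.append(
            FiringField(
                bins=member,
                peak_rc=p["peak_rc"],
                peak_value=float(values[p["peak_rc"]]),
                level=float(level),
                centroid=(float(centroid[0]), float(centroid[1])),
                mean_radius=float(d.mean()),
            )
        )

    # label the field containing (or nearest to) the center offset
    on_center = [
        f
        for f in fields
        if (f.bins == np.array(center)).all(axis=1).any()
    ]
    if on_center:
        on_center[0].is_central = True
    elif fields:
        min(fields, key=lambda f: f.distance_from(center)).is_central = True
    return fields


def make_annulus(
    fields: list[FiringField], center: tuple[int, int]
) -> AnnulusSpec:
    """Ring covering the six non-central fields closest to the center.

    Inner radius: smallest (centroid distance - mean radius) over the six,
    floored at one bin. Outer radius: largest (centroid distance + mean
    radius). Raises :class:`AnnulusUnavailable` with < 6 candidate fields.
    """
    candidates = [f for f in fields if not f.is_central]
    if len(candidates) < 6:
        raise AnnulusUnavailable(
            f"need >= 6 non-central fields, found {len(candidates)}"
        )
    candidates.sort(key=lambda f: (f.distance_from(center), -f.peak_value))
    six = candidates[:6]
    inner = max(1.0, min(f.distance_from(center) - f.mean_radius for f in six))
    outer = max(f.distance_from(center) + f.mean_radius for f in six)
    if outer <= inner:
        outer = inner + 1.0
    return AnnulusSpec(inner, outer)


def _annulus_mask(shape: tuple[int, int], annulus: AnnulusSpec) -> np.ndarray:
    center = (shape[0] // 2, shape[1] // 2)
    rr, cc = np.indices(shape)
    d = np.hypot(rr - center[0], cc - center[1])
    return (d >= annulus.inner_radius) & (d <= annulus.outer_radius)


def _rotate_masked(values: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the array center with bilinear interpolation.

    NaNs propagate: any output pixel whose interpolation stencil touches an
    undefined or out-of-bounds pixel becomes NaN.
    """
    if angle % 360.0 == 0.0:
        return values.copy()
    mask = (~np.isnan(values)).astype(float)
    filled = np.where(np.isnan(values), 0.0, values)
    rot_vals = ndimage.rotate(filled, angle, reshape=False, order=1, cval=0.0)
    rot_mask = ndimage.rotate(mask, angle, reshape=False, order=1, cval=0.0)
    out = np.where(rot_mask > 1.0 - 1e-9, rot_vals, np.nan)
    return out


def rotation_correlation(
    acorr: Autocorrelogram | np.ndarray,
    annulus: AnnulusSpec,
    angle: float,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Masked Pearson correlation of the annulus ring with its rotation."""
    values = (
        acorr.values if isinstance(acorr, Autocorrelogram) else np.asarray(acorr)
    )
    ring = np.where(_annulus_mask(values.shape, annulus), values, np.nan)
    rotated = _rotate_masked(ring, angle)
    return nan_pearson(ring, rotated, min_overlap=min_overlap)


def grid_score_from_acorr(
    acorr: Autocorrelogram,
    sigma: float = 2.0,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> GridScoreResult:
    """Grid score of a (raw) autocorrelogram.

    Smooths with a masked Gaussian (sigma in bins), detects fields, builds
    the annulus from the six closest non-central fields, and returns
    corr(60 deg) - corr(30 deg). Degenerate inputs yield the default score
    0 with ``defaulted=True``.
    """
    smoothed = gaussian_smooth(acorr.values, sigma=sigma)
    sm = Autocorrelogram(smoothed, acorr.overlap, acorr.bin_size)
    fields = detect_fields(sm, min_prominence=min_prominence)
    try:
        annulus = make_annulus(fields, sm.center)
    except AnnulusUnavailable:
        return GridScoreResult(score=0.0, fields=fields, defaulted=True)
    c60 = rotation_correlation(sm, annulus, 60.0)
    c30 = rotation_correlation(sm, annulus, 30.0)
    if np.isnan(c60) or np.isnan(c30):
        return GridScoreResult(
            score=0.0, fields=fields, annulus=annulus, defaulted=True
        )
    return GridScoreResult(
        score=float(c60 - c30),
        corr60=c60,
        corr30=c30,
        fields=fields,
        annulus=annulus,
    )


def grid_score(rate_map: RateMap, sigma: float = 2.0) -> GridScoreResult:
    """Grid score of a rate map (autocorrelate, then score)."""
    acorr = spatial_autocorrelogram(rate_map)
    return grid_score_from_acorr(acorr, sigma=sigma)


def hd_tuning_curve(
    spikes: SpikeTrain,
    traj: Trajectory,
    nbins: int = DEFAULT_HD_NBINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy-normalized head-direction tuning curve.

    Returns (bin_center_angles_deg, rate_per_bin); bins with zero HD
    occupancy are NaN.
    """
    dt = traj.dt
    edges = np.linspace(0.0, 360.0, nbins + 1)
    occ_idx = np.clip((traj.hd / 360.0 * nbins).astype(int), 0, nbins - 1)
    occ = np.zeros(nbins)
    np.add.at(occ, occ_idx, dt)
    counts = np.zeros(nbins)
    if spikes.n_spikes:
        shd = traj.interpolate_hd(spikes.times)
        sidx = np.clip((shd / 360.0 * nbins).astype(int), 0, nbins - 1)
        np.add.at(counts, sidx, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = counts / occ
    rate[occ == 0] = np.nan
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, rate


def rayleigh_from_curve(
    angles_deg: np.ndarray, weights: np.ndarray
) -> RayleighResult:
    """Mean resultant vector of a weighted angular distribution."""
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.asarray(weights, dtype=float)
    m = ~np.isnan(w)
    w = w[m]
    angles = angles[m]
    total = w.sum()
    if total <= 0 or w.size == 0:
        return RayleighResult(float("nan"), float("nan"))
    z = (w * np.exp(1j * angles)).sum() / total
    return RayleighResult(float(np.abs(z)), float(np.rad2deg(np.angle(z)) % 360.0))


def rayleigh_score(
    spikes: SpikeTrain,
    traj: Trajectory,
    nbins: int = DEFAULT_HD_NBINS,
) -> RayleighResult:
    """Head-direction Rayleigh score in [0, 1] from the tuning curve.

    The score is the mean resultant vector length of the
    occupancy-normalized tuning curve treated as a weight over bin-center
    angles; 0 for a flat curve, 1 for all mass in one bin.
    """
    if spikes.n_spikes == 0:
        return RayleighResult(float("nan"), float("nan"))
    centers, rate = hd_tuning_curve(spikes, traj, nbins)
    return rayleigh_from_curve(centers, rate)
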