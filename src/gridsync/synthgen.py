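"""Synthetic session generator.

Produces recordings with the statistical structure the downstream analysis
assumes: a wall-respecting foraging trajectory, hexagonally tuned cells
(three-cosine model), phenomenological pairwise coupling via a shared
log-normal gain, and an "inactivation" condition in which a single
session-wide random-walk drift of every cell's spatial phase destroys each
cell's time-averaged map while exactly preserving relative phases (and hence
pairwise coupling). Optionally, designated cells swap their spatial tuning
for von Mises head-direction tuning during inactivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .maps import ArenaSpec, SpikeTrain, Trajectory

CONDITIONS = ("pre", "during", "post")

#: spike-thinning resolution, well below the 25 ms analysis smoothing
THINNING_DT = 0.001


@dataclass(frozen=True)
class GridCellParams:
    """Hexagonal spatial tuning: three plane-wave cosines, rectified."""

    spacing: float  # cm between neighboring field centers
    orientation: float = 0.0  # degrees in [0, 60)
    phase: tuple[float, float] = (0.0, 0.0)  # cm offset of a field center
    peak_rate: float = 8.0  # Hz at a field center
    baseline_rate: float = 0.0  # Hz floor
    cell_id: str = ""
    hd_switch: bool = False  # becomes HD-tuned during inactivation

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if not self.peak_rate > self.baseline_rate >= 0:
            raise ValueError("need peak_rate > baseline_rate >= 0")


@dataclass(frozen=True)
class HDCellParams:
    """Von Mises head-direction tuning."""

    preferred_angle: float  # degrees in [0, 360)
    concentration: float = 4.0  # kappa >= 0
    peak_rate: float = 8.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Phenomenological pairwise rate coupling.

    A session-wide log-normal gain with standard deviation
    ``shared_gain_sd`` (log scale) and OU timescale ``gain_timescale``
    multiplies every cell's rate, producing positive lag-0 correlations
    that survive the loss of spatial tuning. ``phase_offset`` is the
    relative spatial phase a coupled pair should carry.
    """

    shared_gain_sd: float = 0.5
    gain_timescale: float = 1.0  # s
    phase_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shared_gain_sd < 0:
            raise ValueError("shared_gain_sd must be >= 0")
        if not self.gain_timescale > 0:
            raise ValueError("gain_timescale must be > 0")


@dataclass(frozen=True)
class InactivationSpec:
    """What 'inactivation' does to the generative law."""

    rate_scale: float = 0.5  # multiplicative rate reduction
    drift_sd: float = 3.0  # cm/sqrt(s) shared phase random walk
    hd_switch: bool = False  # let flagged cells become HD-tuned
    hd_mean_angle: float = 37.0  # degrees; common preferred-angle bias
    hd_angle_sd: float = 10.0
    hd_kappa: float = 4.0
    # grid-turned-HD cells keep their drifted-phase rate modulation on top
    # of the HD tuning (they stay part of the coupled network); smaller
    # baseline -> deeper residual modulation
    hd_grid_mix_baseline: float = 0.3
    # one drift path for the whole session preserves relative phases;
    # per-cell paths destroy them (a decoupled control condition)
    shared_drift: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rate_scale <= 1:
            raise ValueError("rate_scale must be in (0, 1]")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")


@dataclass
class SessionRecording:
    """One synthetic (or loaded) session: trajectories and spike trains."""

    session_id: str
    arena: ArenaSpec
    trajectories: dict[str, Trajectory]  # per condition
    spikes: dict[str, dict[str, SpikeTrain]]  # cell_id -> condition -> train
    rat_id: str = ""
    room: str = ""

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.spikes.keys())

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if c in self.trajectories]


def simulate_trajectory(
    arena: ArenaSpec,
    duration: float,
    mean_speed: float = 25.0,
    turn_sd: float = 2.0,
    dt: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Smoothed random walk with reflecting walls.

    Heading diffuses with standard deviation ``turn_sd * sqrt(dt)`` per
    step; speed is constant. Head direction equals the instantaneous
    heading. With duration >= 1200 s and defaults, at least 95% of the
    50x50 bins are visited.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    side = arena.side_length
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    # start away from walls, random heading
    x[0] = side * (0.25 + 0.5 * rng.random())
    y[0] = side * (0.25 + 0.5 * rng.random())
    heading[0] = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.normal(0.0, turn_sd * math.sqrt(dt), size=n - 1)
    step = mean_speed * dt
    eps = 1e-9
    h = heading[0]
    for i in range(1, n):
        h = h + turns[i - 1]
        nx = x[i - 1] + step * math.cos(h)
        ny = y[i - 1] + step * math.sin(h)
        if nx < 0 or nx > side:
            nx = min(max(-nx if nx < 0 else 2 * side - nx, eps), side - eps)
            h = math.pi - h
        if ny < 0 or ny > side:
            ny = min(max(-ny if ny < 0 else 2 * side - ny, eps), side - eps)
            h = -h
        x[i] = nx
        y[i] = ny
        heading[i] = h
    hd = np.rad2deg(heading) % 360.0
    return Trajectory(t, x, y, hd)


def _wave_vectors(spacing: float, orientation_deg: float) -> np.ndarray:
    """Three wave vectors at 60-degree intervals for the given lattice."""
    k = 4.0 * math.pi / (math.sqrt(3.0) * spacing)
    angles = np.deg2rad(orientation_deg + np.array([0.0, 60.0, 120.0]))
    return k * np.column_stack([np.cos(angles), np.sin(angles)])


def grid_rate(params: GridCellParams, position: np.ndarray) -> np.ndarray:
    """Firing rate of the three-cosine hexagonal model at position(s).

    ``position`` is a 2-vector or an (n, 2) array in cm. The rate is
    ``baseline + (peak - baseline) * max(0, sum_of_cosines) / 3`` so the
    maximum (attained at every lattice point of the hexagonal lattice
    through ``phase``) equals ``peak_rate``.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    kvecs = _wave_vectors(params.spacing, params.orientation)
    rel = pos - np.asarray(params.phase)
    s = np.cos(rel @ kvecs.T).sum(axis=1)
    u = np.clip(s, 0.0, None) / 3.0
    rate = params.baseline_rate + (params.peak_rate - params.baseline_rate) * u
    return rate[0] if np.asarray(position).ndim == 1 else rate


def hd_rate(params: HDCellParams, hd_deg: np.ndarray) -> np.ndarray:
    """Von Mises head-direction rate, peaking at ``peak_rate``."""
    delta = np.deg2rad(np.asarray(hd_deg, dtype=float) - params.preferred_angle)
    return params.peak_rate * np.exp(params.concentration * (np.cos(delta) - 1.0))


def generate_spikes(
    rate: np.ndarray,
    t: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning.

    ``rate`` gives the intensity (Hz) sampled at times ``t``; it is
    interpolated to candidate spike times. Candidates are homogeneous
    Poisson at the maximum rate and accepted with probability
    rate(t)/rate_max.
    """
    rate = np.asarray(rate, dtype=float)
    t = np.asarray(t, dtype=float)
    if rate.shape != t.shape:
        raise ValueError("rate and t must align")
    if not np.all(np.isfinite(rate)):
        raise ValueError("rate must be bounded")
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate_max = float(rate.max(initial=0.0))
    if rate_max == 0.0:
        return np.empty(0)
    t0, t1 = float(t[0]), float(t[-1])
    span = t1 - t0
    n_cand = rng.poisson(rate_max * span)
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    lam = np.interp(cand, t, rate)
    keep = rng.random(n_cand) < lam / rate_max
    return cand[keep]


def _ou_path(
    n: int, dt: float, timescale: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck path sampled at dt."""
    a = math.exp(-dt / timescale)
    b = math.sqrt(1.0 - a * a)
    z = np.empty(n)
    z[0] = rng.normal()
    noise = rng.normal(size=n - 1)
    for i in range(1, n):
        z[i] = a * z[i - 1] + b * noise[i - 1]
    return z


def _resolve_coupling(
    coupling, n_cells: int
) -> CouplingSpec:
    """Accept a single spec or a per-pair list (validated for length)."""
    if coupling is None:
        return CouplingSpec(shared_gain_sd=0.0)
    if isinstance(coupling, CouplingSpec):
        return coupling
    n_pairs = n_cells * (n_cells - 1) // 2
    if len(coupling) != n_pairs:
        raise ValueError(
            f"coupling list length {len(coupling)} != n_pairs {n_pairs}"
        )
    sd = float(np.mean([c.shared_gain_sd for c in coupling]))
    ts = float(np.mean([c.gain_timescale for c in coupling]))
    return CouplingSpec(shared_gain_sd=sd, gain_timescale=ts)


def simulate_session(
    cells: list[GridCellParams],
    coupling: CouplingSpec | list[CouplingSpec] | None,
    inact: InactivationSpec,
    arena: ArenaSpec,
    durations: dict[str, float],
    seed: int = 0,
    session_id: str = "synth",
    mean_speed: float = 25.0,
    dt: float = 0.02,
) -> SessionRecording:
    """Simulate one session with pre / during / post conditions.

    During inactivation every cell's spatial phase follows the same
    random-walk drift path (relative phases preserved), mean rates are
    scaled by ``inact.rate_scale``, and flagged cells emit head-direction
    tuned spikes instead. All cells share one log-normal gain, which
    carries the pairwise temporal coupling.
    """
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    spec = _resolve_coupling(coupling, len(cells))
    rng = np.random.default_rng(seed)

    hd_assign: dict[int, HDCellParams] = {}
    if inact.hd_switch:
        for i, c in enumerate(cells):
            if c.hd_switch:
                ang = rng.normal(inact.hd_mean_angle, inact.hd_angle_sd) % 360.0
                hd_assign[i] = HDCellParams(
                    preferred_angle=float(ang),
                    concentration=inact.hd_kappa,
                    peak_rate=c.peak_rate,
                )

    trajectories: dict[str, Trajectory] = {}
    spikes: dict[str, dict[str, SpikeTrain]] = {
        c.cell_id or f"c{i}": {} for i, c in enumerate(cells)
    }
    offset = 0.0
    for cond in CONDITIONS:
        if cond not in durations:
            continue
        dur = float(durations[cond])
        traj = simulate_trajectory(
            arena, dur, mean_speed=mean_speed, dt=dt, seed=rng
        )
        n = traj.n_samples
        gain = np.ones(n)
        if spec.shared_gain_sd > 0:
            z = _ou_path(n, dt, spec.gain_timescale, rng)
            gain = np.exp(
                spec.shared_gain_sd * z - 0.5 * spec.shared_gain_sd**2
            )
        def drift_path() -> np.ndarray:
            d = np.zeros((n, 2))
            if cond == "during" and inact.drift_sd > 0:
                steps = rng.normal(
                    0.0, inact.drift_sd * math.sqrt(dt), size=(n - 1, 2)
                )
                d[1:] = np.cumsum(steps, axis=0)
            return d

        shared = drift_path()
        pos = np.column_stack([traj.x, traj.y])
        for i, c in enumerate(cells):
            drift = shared if inact.shared_drift else drift_path()
            cid = c.cell_id or f"c{i}"
            if cond == "during" and i in hd_assign:
                lam = hd_rate(hd_assign[i], traj.hd) * inact.rate_scale
                # residual drifted-grid modulation preserves pair coupling
                # without restoring spatial tuning (the drift keeps the
                # time-averaged map flat)
                f = grid_rate(c, pos - drift) / c.peak_rate
                b = inact.hd_grid_mix_baseline
                lam = lam * (b + f) / (b + f.mean())
            elif cond == "during":
                lam = grid_rate(c, pos - drift) * inact.rate_scale
            else:
                lam = grid_rate(c, pos)
            lam = lam * gain
            times = generate_spikes(lam, traj.t, seed=rng)
            spikes[cid][cond] = SpikeTrain(
                times + offset,
                t_start=offset,
                t_stop=offset + dur,
                cell_id=cid,
                condition=cond,
            )
        trajectories[cond] = Trajectory(
            traj.t + offset, traj.x, traj.y, traj.hd
        )
        offset += dur
    return SessionRecording(
        session_id=session_id,
        arena=arena,
        trajectories=trajectories,
        spikes=spikes,
    )


def simulate_study(
    arena: ArenaSpec,
    n_sessions: int = 8,
    cells_per_session: int = 5,
    hd_sessions: tuple[int, ...] = (0, 3, 6),
    seed: int = 0,
    durations: dict[str, float] | None = None,
    gain_sd_range: tuple[float, float] = (0.15, 0.78),
    drift_sd: float = 3.0,
    rate_scale: float = 0.5,
) -> list[SessionRecording]:
    """Simulate a multi-session study with the cohort structure the
    selection pipeline expects.

    Shared-gain coupling strength is laddered across sessions (this is
    what makes pair correlations heterogeneous across the cohort, so the
    correlation-of-correlations is informative), and the sessions listed
    in ``hd_sessions`` contain grid-turned head-direction cells.
    """
    durations = durations or {"pre": 900.0, "during": 1800.0, "post": 900.0}
    lo, hi = gain_sd_range
    step = (hi - lo) / max(n_sessions - 1, 1)
    sessions = []
    for s in range(n_sessions):
        hd = s in hd_sessions
        cells = default_grid_cohort(
            cells_per_session, arena, seed=seed * 1000 + s,
            hd_switch_frac=1.0 if hd else 0.0,
        )
        sessions.append(
            simulate_session(
                cells,
                CouplingSpec(shared_gain_sd=lo + step * s, gain_timescale=1.0),
                InactivationSpec(
                    rate_scale=rate_scale,
                    drift_sd=drift_sd,
                    hd_switch=hd,
                    hd_kappa=2.5,
                    hd_angle_sd=6.0,
                    hd_grid_mix_baseline=0.2,
                ),
                arena,
                durations=durations,
                seed=seed * 1000 + 500 + s,
                session_id=f"synth-{seed}-{s}",
            )
        )
    return sessions


def default_grid_cohort(
    n_cells: int,
    arena: ArenaSpec,
    seed: int,
    spacing: float | None = None,
    peak_rate: float = 8.0,
    hd_switch_frac: float = 0.0,
) -> list[GridCellParams]:
    """Cells sharing one lattice (spacing/orientation) with random phases.

    Shared lattice plus distinct phases is what a module of comonotonic
    grid cells looks like; pairwise phase offsets then set the sign and
    size of spatial/temporal correlations.
    """
    rng = np.random.default_rng(seed)
    if spacing is None:
        spacing = 0.35 * arena.side_length
    orientation = float(rng.uniform(0.0, 60.0))
    n_hd = int(round(hd_switch_frac * n_cells))
    cells = []
    for i in range(n_cells):
        phase = tuple(rng.uniform(0.0, spacing, size=2))
        cells.append(
            GridCellParams(
                spacing=spacing,
                orientation=orientation,
                phase=phase,
                peak_rate=peak_rate,
                cell_id=f"c{i}",
                hd_switch=i < n_hd,
            )
        )
    return cells
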