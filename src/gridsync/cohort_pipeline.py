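"""Session I/O, cohort selection and the cross-pair summary statistics.

A session lives in a directory holding ``manifest.json`` (ids, arena side,
condition spans, cell list), one ``position_<cond>.csv`` per condition
(columns t,x,y,hd) and one ``spikes_<cell>_<cond>.txt`` per cell and
condition (one spike time per line). All times are on one session clock.

The selection procedure keeps cells whose grid score is at least
``min_grid_pre`` before and at most ``max_grid_during`` during
inactivation, removes duplicate cells by spike-time overlap, restricts the
during condition to a fixed time window, and enumerates all within-session
pairs. The headline statistic is the correlation-of-correlations: across
pairs, the Pearson correlation between each pair's correlation in one
condition and the same pair's correlation in another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .maps import ArenaSpec, SpikeTrain, Trajectory, compute_rate_map, nan_pearson
from .paircorr import (
    spatial_cross_correlation,
    temporal_correlation,
    windowed_map_correlation,
    windowed_relative_map,
)
from .scoring import grid_score, rayleigh_score
from .shuffletest import ShuffleConfig, shuffle_null
from .synthgen import CONDITIONS, SessionRecording

DEFAULT_DURING_WINDOW = (15.0 * 60.0, 45.0 * 60.0)


@dataclass(frozen=True)
class SelectionCriteria:
    min_grid_pre: float = 0.5
    max_grid_during: float = 0.2
    overlap_window: float = 0.001  # s
    max_overlap_frac: float = 0.05
    during_window: tuple[float, float] = DEFAULT_DURING_WINDOW
    hd_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not self.min_grid_pre > self.max_grid_during:
            raise ValueError("min_grid_pre must exceed max_grid_during")
        if not 0 < self.max_overlap_frac < 1:
            raise ValueError("max_overlap_frac must be in (0, 1)")


# ---------------------------------------------------------------------------
# session I/O


class SessionFormatError(ValueError):
    pass


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session directory in the neutral text format."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spans = {}
    for cond in session.conditions:
        traj = session.trajectories[cond]
        spans[cond] = [float(traj.t[0]), float(traj.t[-1] + traj.dt)]
        pd.DataFrame(
            {"t": traj.t, "x": traj.x, "y": traj.y, "hd": traj.hd}
        ).to_csv(path / f"position_{cond}.csv", index=False, float_format="%.6f")
    manifest = {
        "session_id": session.session_id,
        "rat_id": session.rat_id,
        "room": session.room,
        "arena_side": session.arena.side_length,
        "conditions": spans,
        "cells": session.cell_ids,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for cid in session.cell_ids:
        for cond, train in session.spikes[cid].items():
            lines = "\n".join(f"{t:.6f}" for t in train.times)
            (path / f"spikes_{cid}_{cond}.txt").write_text(lines + "\n")
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read and validate a session directory.

    Raises :class:`SessionFormatError` naming the offending file (and line
    where applicable) for missing manifests, unsorted or out-of-span spike
    times, and out-of-arena positions.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise SessionFormatError(f"missing manifest: {mpath}")
    manifest = json.loads(mpath.read_text())
    arena = ArenaSpec(float(manifest["arena_side"]))
    trajectories: dict[str, Trajectory] = {}
    for cond, span in manifest["conditions"].items():
        fpath = path / f"position_{cond}.csv"
        if not fpath.exists():
            raise SessionFormatError(f"missing position file: {fpath}")
        df = pd.read_csv(fpath)
        for col in ("t", "x", "y", "hd"):
            if col not in df.columns:
                raise SessionFormatError(f"{fpath}: missing column {col!r}")
        bad = np.flatnonzero(
            (df["x"] < 0)
            | (df["x"] > arena.side_length)
            | (df["y"] < 0)
            | (df["y"] > arena.side_length)
        )
        if bad.size:
            raise SessionFormatError(
                f"{fpath}: position outside arena at line {bad[0] + 2}"
            )
        try:
            trajectories[cond] = Trajectory(
                df["t"].to_numpy(),
                df["x"].to_numpy(),
                df["y"].to_numpy(),
                df["hd"].to_numpy(),
            )
        except ValueError as e:
            raise SessionFormatError(f"{fpath}: {e}") from e
    spikes: dict[str, dict[str, SpikeTrain]] = {}
    for cid in manifest["cells"]:
        spikes[cid] = {}
        for cond, span in manifest["conditions"].items():
            fpath = path / f"spikes_{cid}_{cond}.txt"
            if not fpath.exists():
                raise SessionFormatError(f"missing spike file: {fpath}")
            text = fpath.read_text().split()
            times = np.array([float(v) for v in text]) if text else np.empty(0)
            if times.size and np.any(np.diff(times) < 0):
                k = int(np.flatnonzero(np.diff(times) < 0)[0])
                raise SessionFormatError(f"{fpath}: unsorted spikes at line {k + 2}")
            lo, hi = float(span[0]), float(span[1])
            if times.size and (times[0] < lo or times[-1] > hi):
                bad = np.flatnonzero((times < lo) | (times > hi))[0]
                raise SessionFormatError(
                    f"{fpath}: spike outside condition span at line {bad + 1}"
                )
            spikes[cid][cond] = SpikeTrain(times, lo, hi, cid, cond)
    return SessionRecording(
        session_id=manifest["session_id"],
        arena=arena,
        trajectories=trajectories,
        spikes=spikes,
        rat_id=manifest.get("rat_id", ""),
        room=manifest.get("room", ""),
    )


# ---------------------------------------------------------------------------
# pre-processing


def clip_during_window(
    session: SessionRecording, window: tuple[float, float] = DEFAULT_DURING_WINDOW
) -> SessionRecording:
    """Restrict the during condition to ``window`` relative to its start."""
    if "during" not in session.trajectories:
        return session
    traj = session.trajectories["during"]
    start = float(traj.t[0])
    lo, hi = start + window[0], start + window[1]
    if traj.t[-1] <= lo:
        raise ValueError("during condition shorter than the window start")
    new_traj = traj.slice_time(lo, hi)
    new_spikes = {}
    for cid, conds in session.spikes.items():
        new_conds = dict(conds)
        tr = conds.get("during")
        if tr is not None:
            hi_eff = min(hi, tr.t_stop)
            m = (tr.times >= lo) & (tr.times <= hi_eff)
            new_conds["during"] = SpikeTrain(tr.times[m], lo, hi_eff, cid, "during")
        new_spikes[cid] = new_conds
    trajectories = dict(session.trajectories)
    trajectories["during"] = new_traj
    return replace(session, trajectories=trajectories, spikes=new_spikes)


def spike_overlap_fraction(a: SpikeTrain, b: SpikeTrain, window: float = 0.001) -> float:
    """Fraction of the smaller train's spikes with a partner within +/- window/2."""
    small, big = (a, b) if a.n_spikes <= b.n_spikes else (b, a)
    if small.n_spikes == 0:
        return 0.0
    half = window / 2.0
    lo = np.searchsorted(big.times, small.times - half, side="left")
    hi = np.searchsorted(big.times, small.times + half, side="right")
    return float((hi > lo).sum()) / small.n_spikes


def exclude_duplicates(
    session: SessionRecording, window: float = 0.001, max_frac: float = 0.05
) -> tuple[SessionRecording, list[str]]:
    """Drop suspected duplicate cells by spike-time overlap.

    For each pair, overlap is measured over all conditions pooled; when it
    exceeds ``max_frac`` the lower-mean-rate cell is removed. Returns the
    cleaned session and the dropped cell ids.
    """
    ids = session.cell_ids

    def pooled(cid):
        trains = [session.spikes[cid][c] for c in session.conditions if c in session.spikes[cid]]
        times = np.sort(np.concatenate([t.times for t in trains])) if trains else np.empty(0)
        t0 = min(t.t_start for t in trains)
        t1 = max(t.t_stop for t in trains)
        return SpikeTrain(times, t0, t1, cid)

    pooled_trains = {cid: pooled(cid) for cid in ids}
    dropped: set[str] = set()
    for i, ca in enumerate(ids):
        for cb in ids[i + 1 :]:
            if ca in dropped or cb in dropped:
                continue
            frac = spike_overlap_fraction(pooled_trains[ca], pooled_trains[cb], window)
            if frac > max_frac:
                loser = min((ca, cb), key=lambda c: pooled_trains[c].mean_rate)
                dropped.add(loser)
    spikes = {cid: s for cid, s in session.spikes.items() if cid not in dropped}
    return replace(session, spikes=spikes), sorted(dropped)


# ---------------------------------------------------------------------------
# scoring and selection


def score_cells(session: SessionRecording, nbins: int = 50) -> pd.DataFrame:
    """Per-cell, per-condition grid score, Rayleigh score and mean rate."""
    rows = []
    for cond in session.conditions:
        traj = session.trajectories[cond]
        for cid in session.cell_ids:
            train = session.spikes[cid].get(cond)
            if train is None:
                continue
            rmap = compute_rate_map(train, traj, session.arena, nbins)
            gs = grid_score(rmap)
            ray = rayleigh_score(train, traj)
            rows.append(
                {
                    "session": session.session_id,
                    "cell": cid,
                    "condition": cond,
                    "grid_score": gs.score,
                    "defaulted": gs.defaulted,
                    "rayleigh": ray.score,
                    "preferred_angle": ray.preferred_angle,
                    "mean_rate": train.mean_rate,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    sessions: dict[str, SessionRecording]
    kept_cells: dict[str, list[str]]  # session id -> cell ids
    scores: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return sum(len(v) for v in self.kept_cells.values())

    def pairs(self) -> list[tuple[str, str, str]]:
        out = []
        for sid, cells in self.kept_cells.items():
            for i, a in enumerate(cells):
                for b in cells[i + 1 :]:
                    out.append((sid, a, b))
        return out


def _selected_cells(scores: pd.DataFrame, criteria: SelectionCriteria) -> pd.DataFrame:
    wide = scores.pivot_table(
        index=["session", "cell"], columns="condition", values="grid_score"
    )
    ok = (wide.get("pre") >= criteria.min_grid_pre) & (
        wide.get("during") <= criteria.max_grid_during
    )
    return wide[ok.fillna(False)].reset_index()[["session", "cell"]]


def select_cohort(
    sessions: list[SessionRecording],
    criteria: SelectionCriteria = SelectionCriteria(),
    scores: pd.DataFrame | None = None,
) -> Cohort:
    """Apply the during-window clip, duplicate removal and score thresholds.

    ``scores`` may be supplied to skip recomputation (it must then match
    the clipped, deduplicated sessions).
    """
    prepared: dict[str, SessionRecording] = {}
    for s in sessions:
        s2 = clip_during_window(s, criteria.during_window) if "during" in s.trajectories else s
        s2, _ = exclude_duplicates(s2, criteria.overlap_window, criteria.max_overlap_frac)
        prepared[s2.session_id] = s2
    if scores is None:
        parts = [score_cells(s) for s in prepared.values()]
        scores = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    kept = _selected_cells(scores, criteria) if len(scores) else pd.DataFrame(columns=["session", "cell"])
    kept_cells: dict[str, list[str]] = {}
    for sid, grp in kept.groupby("session"):
        cells = sorted(c for c in grp["cell"] if c in prepared[sid].spikes)
        if cells:
            kept_cells[sid] = cells
    return Cohort(sessions=prepared, kept_cells=kept_cells, scores=scores)


def classify_hd_clusters(
    scores: pd.DataFrame, threshold: float = 0.4
) -> pd.DataFrame:
    """Label cells grid-turned-HD / non-HD / unclassified by Rayleigh score."""
    wide = scores.pivot_table(
        index=["session", "cell"], columns="condition", values="rayleigh"
    )
    pre = wide.get("pre")
    during = wide.get("during")
    label = np.where(
        (pre < threshold) & (during > threshold),
        "grid_turned_hd",
        np.where((pre < threshold) & (during < threshold), "non_hd", "unclassified"),
    )
    out = wide.reset_index()[["session", "cell"]]
    out["hd_label"] = label
    return out


# ---------------------------------------------------------------------------
# pair statistics


def compute_pair_stats(
    cohort: Cohort,
    shuffle_config: ShuffleConfig | None = None,
    run_shuffles: bool = True,
    nbins: int = 50,
) -> pd.DataFrame:
    """Temporal and spatial correlations (and shuffle verdicts) per pair."""
    rows = []
    for sid, ca, cb in cohort.pairs():
        session = cohort.sessions[sid]
        for cond in session.conditions:
            ta = session.spikes[ca].get(cond)
            tb = session.spikes[cb].get(cond)
            if ta is None or tb is None:
                continue
            traj = session.trajectories[cond]
            tr = temporal_correlation(ta, tb)
            ma = compute_rate_map(ta, traj, session.arena, nbins)
            mb = compute_rate_map(tb, traj, session.arena, nbins)
            sx = spatial_cross_correlation(ma, mb)
            row = {
                "session": sid,
                "cell_a": ca,
                "cell_b": cb,
                "condition": cond,
                "temporal_r": tr.r,
                "spatial_r0": sx.value_at_zero,
                "nearest_peak_angle": sx.nearest_peak_angle,
            }
            if run_shuffles:
                cfg = shuffle_config or ShuffleConfig()
                res = shuffle_null(ta, tb, config=cfg)
                row["significant"] = res.significant
                row["sign"] = res.sign
            rows.append(row)
    return pd.DataFrame(rows)


def windowed_pair_correlations(
    cohort: Cohort,
    halfwidths: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 10.0),
    nbins: int = 50,
) -> pd.DataFrame:
    """Pre-vs-during and pre-vs-post correlations of windowed relative maps."""
    rows = []
    for sid, ca, cb in cohort.pairs():
        session = cohort.sessions[sid]
        maps = {}
        for cond in session.conditions:
            ta = session.spikes[ca].get(cond)
            tb = session.spikes[cb].get(cond)
            if ta is None or tb is None or ta.n_spikes == 0:
                continue
            traj = session.trajectories[cond]
            maps[cond] = {
                w: windowed_relative_map(ta, tb, traj, session.arena, w, nbins)
                for w in halfwidths
            }
        for w in halfwidths:
            row = {"session": sid, "cell_a": ca, "cell_b": cb, "window": w}
            if "pre" in maps and "during" in maps:
                row["pre_vs_during"] = windowed_map_correlation(
                    maps["pre"][w], maps["during"][w]
                )
            if "pre" in maps and "post" in maps:
                row["pre_vs_post"] = windowed_map_correlation(
                    maps["pre"][w], maps["post"][w]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def cross_session_control_pairs(
    cohort: Cohort, conditions: tuple[str, str] = ("pre", "during")
) -> tuple[pd.DataFrame, float]:
    """Pseudo-pairs across sessions and their correlation-of-correlations.

    Every cohort cell is paired with every cohort cell from a different
    session; both trains are re-referenced to their own condition start and
    truncated to the shorter common duration before the temporal
    correlation. Returns the per-pair table and the Pearson correlation of
    the two conditions' correlations across pseudo-pairs.
    """
    if len(cohort.kept_cells) < 2:
        raise ValueError("need cells from >= 2 sessions for control pairs")
    from .paircorr import DEFAULT_BIN_WIDTH, DEFAULT_SMOOTH_WINDOW, moving_average, smoothed_counts

    entries = [
        (sid, cid) for sid, cells in cohort.kept_cells.items() for cid in cells
    ]

    # per-cell smoothed signals are reused across the O(cells^2) pair loop
    cache: dict[tuple[str, str, str], np.ndarray] = {}
    w_bins = max(1, int(round(DEFAULT_SMOOTH_WINDOW / DEFAULT_BIN_WIDTH)))

    def signal(sid: str, cid: str, cond: str) -> np.ndarray | None:
        key = (sid, cid, cond)
        if key not in cache:
            train = cohort.sessions[sid].spikes[cid].get(cond)
            cache[key] = (
                None if train is None or train.n_spikes == 0
                else smoothed_counts(train.shifted_to_zero())
            )
        return cache[key]

    rows = []
    for i, (sa, ca) in enumerate(entries):
        for sb, cb in entries[i + 1 :]:
            if sa == sb:
                continue
            row = {"session_a": sa, "cell_a": ca, "session_b": sb, "cell_b": cb}
            for cond in conditions:
                xa = signal(sa, ca, cond)
                xb = signal(sb, cb, cond)
                if xa is None or xb is None:
                    row[f"temporal_r_{cond}"] = float("nan")
                    continue
                n = min(xa.size, xb.size)
                row[f"temporal_r_{cond}"] = nan_pearson(xa[:n], xb[:n], min_overlap=2)
            rows.append(row)
    df = pd.DataFrame(rows)
    a = df[f"temporal_r_{conditions[0]}"].to_numpy()
    b = df[f"temporal_r_{conditions[1]}"].to_numpy()
    r = nan_pearson(a, b, min_overlap=3)
    return df, r


# ---------------------------------------------------------------------------
# summary


def rayleigh_uniformity_test(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (R_bar, p)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    a = a[~np.isnan(a)]
    n = a.size
    if n < 3:
        return float("nan"), float("nan")
    rbar = float(np.abs(np.exp(1j * a).mean()))
    z = n * rbar**2
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - (n * rbar) ** 2)) - (1 + 2 * n))
    return rbar, min(p, 1.0)


def _corr_of_corrs(df: pd.DataFrame, value: str, cond_a: str, cond_b: str):
    wide = df.pivot_table(
        index=["session", "cell_a", "cell_b"], columns="condition", values=value
    )
    if cond_a not in wide.columns or cond_b not in wide.columns:
        return float("nan"), float("nan"), 0
    sub = wide[[cond_a, cond_b]].dropna()
    if len(sub) < 3:
        return float("nan"), float("nan"), len(sub)
    r, p = stats.pearsonr(sub[cond_a], sub[cond_b])
    return float(r), float(p), len(sub)


def summarize(
    pair_stats: pd.DataFrame,
    hd_labels: pd.DataFrame | None = None,
) -> dict:
    """Cohort summary: correlation-of-correlations, significance
    proportions with sign breakdown, HD-cluster breakdowns, paired tests
    and the nearest-peak-angle uniformity tests."""
    n_pairs = pair_stats.groupby(["session", "cell_a", "cell_b"]).ngroups
    if n_pairs < 3:
        raise ValueError("need >= 3 pairs to summarize")
    out: dict = {"n_pairs": int(n_pairs)}
    for value, tag in (("temporal_r", "temporal"), ("spatial_r0", "spatial")):
        for ca, cb in (("pre", "during"), ("pre", "post")):
            r, p, n = _corr_of_corrs(pair_stats, value, ca, cb)
            out[f"{tag}_{ca}_vs_{cb}"] = {"r": r, "p": p, "n": n}

    if "significant" in pair_stats.columns:
        props = {}
        for cond, grp in pair_stats.groupby("condition"):
            total = len(grp)
            sig = grp["significant"].fillna(False)
            props[cond] = {
                "significant": float(sig.mean()),
                "positive": float(((grp["sign"] == "positive") & sig).sum() / total),
                "negative": float(((grp["sign"] == "negative") & sig).sum() / total),
                "n": total,
            }
        out["significance_proportions"] = props
        g = pair_stats.dropna(subset=["significant"]).groupby("condition")["significant"]
        sig_counts = g.sum().astype(float).to_numpy()
        totals = g.count().astype(float).to_numpy()
        try:
            tbl = np.column_stack([sig_counts, totals - sig_counts])
            chi2, p = stats.chi2_contingency(tbl)[:2]
            out["significance_chi2"] = {"chi2": float(chi2), "p": float(p)}
        except ValueError:
            out["significance_chi2"] = {"chi2": float("nan"), "p": float("nan")}

    # paired distribution comparison, pre vs during temporal correlations
    wide = pair_stats.pivot_table(
        index=["session", "cell_a", "cell_b"], columns="condition", values="temporal_r"
    )
    if {"pre", "during"}.issubset(wide.columns):
        sub = wide[["pre", "during"]].dropna()
        if len(sub) >= 5 and not np.allclose(sub["pre"], sub["during"]):
            w, p = stats.wilcoxon(sub["pre"], sub["during"])
            out["wilcoxon_pre_vs_during"] = {"statistic": float(w), "p": float(p)}

    # nearest-peak-angle differences across conditions
    if "nearest_peak_angle" in pair_stats.columns:
        ang = pair_stats.pivot_table(
            index=["session", "cell_a", "cell_b"],
            columns="condition",
            values="nearest_peak_angle",
        )
        for ca, cb in (("pre", "during"), ("pre", "post")):
            if ca in ang.columns and cb in ang.columns:
                diff = ((ang[cb] - ang[ca]).dropna().to_numpy() + 180.0) % 360.0 - 180.0
                rbar, p = rayleigh_uniformity_test(diff)
                out[f"angle_diff_{ca}_vs_{cb}"] = {"rbar": rbar, "p": p}

    if hd_labels is not None and len(hd_labels):
        lab = hd_labels.set_index(["session", "cell"])["hd_label"]

        def pair_label(row):
            try:
                la = lab.loc[(row["session"], row["cell_a"])]
                lb = lab.loc[(row["session"], row["cell_b"])]
            except KeyError:
                return "unclassified"
            if la == lb == "grid_turned_hd":
                return "grid_turned_hd"
            if la == lb == "non_hd":
                return "non_hd"
            return "unclassified"

        keys = pair_stats.apply(pair_label, axis=1)
        groups = {}
        for glabel in ("grid_turned_hd", "non_hd"):
            grp = pair_stats[keys == glabel]
            if not len(grp):
                continue
            entry = {}
            for value, tag in (("temporal_r", "temporal"), ("spatial_r0", "spatial")):
                r, p, n = _corr_of_corrs(grp, value, "pre", "during")
                slope = float("nan")
                widef = grp.pivot_table(
                    index=["session", "cell_a", "cell_b"],
                    columns="condition",
                    values=value,
                )
                if {"pre", "during"}.issubset(widef.columns):
                    sub = widef[["pre", "during"]].dropna()
                    if len(sub) >= 3 and sub["pre"].std() > 0:
                        slope = float(
                            np.polyfit(sub["pre"], sub["during"], 1)[0]
                        )
                entry[f"{tag}_pre_vs_during"] = {"r": r, "p": p, "n": n, "slope": slope}
            groups[glabel] = entry
        out["hd_clusters"] = groups
    return out


def threshold_sweep(
    all_pair_stats: pd.DataFrame,
    scores: pd.DataFrame,
    pre_thresholds: np.ndarray,
    during_thresholds: np.ndarray,
) -> pd.DataFrame:
    """Pre-vs-during temporal correlation-of-correlations across grid-score
    threshold combinations, from a pair table computed over all cells."""
    wide = scores.pivot_table(
        index=["session", "cell"], columns="condition", values="grid_score"
    )
    rows = []
    for tp in pre_thresholds:
        for td in during_thresholds:
            if not tp > td:
                continue
            ok = (wide.get("pre") >= tp) & (wide.get("during") <= td)
            kept = set(wide[ok.fillna(False)].index)

            def in_cohort(row):
                return (
                    (row["session"], row["cell_a"]) in kept
                    and (row["session"], row["cell_b"]) in kept
                )

            sub = all_pair_stats[all_pair_stats.apply(in_cohort, axis=1)]
            r, p, n = (
                _corr_of_corrs(sub, "temporal_r", "pre", "during")
                if len(sub)
                else (float("nan"), float("nan"), 0)
            )
            rows.append(
                {"min_grid_pre": tp, "max_grid_during": td, "r": r, "p": p, "n_pairs": n}
            )
    return pd.DataFrame(rows)
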