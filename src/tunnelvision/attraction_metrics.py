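"""Trajectory-based attraction statistics.

The core quantification: trajectories at least 90 frames (1.5 s at 60 fps)
long are scored by the time they spend inside "fictive volumes" — axis-
aligned 14 x 14 x 4 cm boxes anchored over the visual objects — yielding a
per-trajectory preference index

    PI = (t_test - t_control) / (t_test + t_control)

with +1 for exclusive investigation of the test object and -1 for the evenly
reflecting control. Trajectories that enter neither volume are excluded (only
a fraction of trajectories ever approach an object). The cohort mean PI gets
a percentile bootstrap CI from resampling individual trajectories 500 times.

Also here: relative flight activity between phases, mean flight velocities,
occupancy (residency) maps on 0.3 cm^2 cells, per-minute investigation time
courses, the randomly-placed control volume, and volume-size sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import (
    ArenaLayout,
    PhaseSchedule,
    TrajectoryTable,
    ValidationError,
    VisualObjectSpec,
    clip_to_phase,
)

__all__ = [
    "FictiveVolume",
    "PreferenceSummary",
    "OccupancyMap",
    "ActivityResult",
    "FilterReport",
    "filter_trajectories",
    "time_in_volume",
    "preference_index",
    "score_trial",
    "bootstrap_mean_ci",
    "relative_activity",
    "mean_flight_velocity",
    "occupancy_map",
    "pool_occupancy",
    "investigation_timecourse",
    "random_volume_control",
    "volume_sensitivity",
    "volumes_for_layout",
]

MIN_FRAMES_DEFAULT = 90  # 1.5 s at 60 fps


@dataclass(frozen=True)
class FictiveVolume:
    """Axis-aligned box defining "investigation" of a visual object.

    Default footprint 14 x 14 cm, height 4 cm from the floor, centered over
    the object crosswind and shifted slightly (2 cm) downwind. Membership is
    half-open [lo, hi) on every axis.
    """

    anchor: tuple[float, float]  # object center (x, y) on the floor
    footprint: tuple[float, float] = (14.0, 14.0)
    height: float = 4.0
    downwind_shift: float = 2.0
    label: str = ""
    role: str = "test"

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        fx, fy = self.footprint
        cx = self.anchor[0] + self.downwind_shift
        cy = self.anchor[1]
        return (
            (cx - fx / 2.0, cx + fx / 2.0),
            (cy - fy / 2.0, cy + fy / 2.0),
            (0.0, self.height),
        )

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) position array."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        (xl, xh), (yl, yh), (zl, zh) = self.bounds
        return (
            (xyz[:, 0] >= xl) & (xyz[:, 0] < xh)
            & (xyz[:, 1] >= yl) & (xyz[:, 1] < yh)
            & (xyz[:, 2] >= zl) & (xyz[:, 2] < zh)
        )

    def scaled(self, factor: float) -> "FictiveVolume":
        """Volume with footprint and height scaled about the same anchor."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        fx, fy = self.footprint
        return replace(
            self, footprint=(fx * factor, fy * factor), height=self.height * factor
        )


def volumes_for_layout(
    layout: ArenaLayout, downwind_shift: float = 2.0, **kw
) -> tuple[FictiveVolume, FictiveVolume]:
    """(test, control) fictive volumes for a standard two-object layout."""
    test_obj = layout.object_by_role("test")
    ctrl_obj = layout.object_by_role("control")
    mk = lambda o: FictiveVolume(
        anchor=o.center, downwind_shift=downwind_shift, label=o.label, role=o.role, **kw
    )
    return mk(test_obj), mk(ctrl_obj)


@dataclass
class FilterReport:
    n_kept: int
    n_dropped: int


def filter_trajectories(
    table: TrajectoryTable, min_frames: int = MIN_FRAMES_DEFAULT
) -> tuple[TrajectoryTable, FilterReport]:
    """Keep tracks with at least ``min_frames`` recorded frames.

    The default 90 frames corresponds to 1.5 s at 60 fps; an 89-frame track
    is dropped, a 90-frame track kept.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if len(table) == 0:
        return table, FilterReport(0, 0)
    lengths = table.track_lengths()
    keep_ids = lengths.index[lengths >= min_frames]
    kept = table.data[table.data["track_id"].isin(keep_ids)]
    report = FilterReport(n_kept=len(keep_ids), n_dropped=int((lengths < min_frames).sum()))
    return TrajectoryTable(kept, frame_rate=table.frame_rate), report


def time_in_volume(
    track: pd.DataFrame | TrajectoryTable,
    volume: FictiveVolume,
    frame_rate: float | None = None,
) -> float:
    """Seconds a single track spends inside a fictive volume.

    Counted as (number of member frames) / frame_rate with the half-open box
    membership test; a point exactly on an upper bound is outside.
    """
    if isinstance(track, TrajectoryTable):
        frame_rate = frame_rate or track.frame_rate
        df = track.data
    else:
        if frame_rate is None:
            raise ValueError("frame_rate required when passing a raw DataFrame")
        df = track
    if len(df) == 0:
        return 0.0
    inside = volume.contains(df[["x", "y", "z"]].to_numpy())
    return float(inside.sum()) / frame_rate


def preference_index(t_test: float, t_control: float) -> float | None:
    """(t_test - t_control) / (t_test + t_control), or None when the
    trajectory entered neither volume (excluded from scoring)."""
    if t_test < 0 or t_control < 0:
        raise ValueError("in-volume times must be non-negative")
    total = t_test + t_control
    if total == 0:
        return None
    return (t_test - t_control) / total


@dataclass
class PreferenceSummary:
    """Per-trajectory preference indices with a bootstrap CI of the mean."""

    pi_values: np.ndarray
    n_scored: int
    n_excluded: int
    mean: float
    ci_lo: float
    ci_hi: float
    n_boot: int = 500
    ci_level: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_scored:
            assert -1.0 <= self.mean <= 1.0
            assert self.ci_lo <= self.mean + 1e-12 and self.mean - 1e-12 <= self.ci_hi


def bootstrap_mean_ci(
    values: Sequence[float],
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean by resampling individual values.

    Returns (mean, lo, hi); deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def _per_track_pi(
    table: TrajectoryTable,
    test_volume: FictiveVolume,
    control_volume: FictiveVolume,
) -> tuple[np.ndarray, int]:
    """Vectorized per-track preference indices; returns (pi_values, n_excluded)."""
    if len(table) == 0:
        return np.empty(0), 0
    df = table.data
    xyz = df[["x", "y", "z"]].to_numpy()
    in_test = test_volume.contains(xyz)
    in_ctrl = control_volume.contains(xyz)
    t_test = pd.Series(in_test, index=df.index).groupby(df["track_id"]).sum()
    t_ctrl = pd.Series(in_ctrl, index=df.index).groupby(df["track_id"]).sum()
    total = (t_test + t_ctrl).to_numpy(dtype=float)
    scored = total > 0
    pi = (t_test.to_numpy(dtype=float) - t_ctrl.to_numpy(dtype=float))[scored] / total[scored]
    return pi, int((~scored).sum())


def score_trial(
    table: TrajectoryTable,
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    phase: str,
    volumes: tuple[FictiveVolume, FictiveVolume] | None = None,
    seed: int | None = None,
    min_frames: int = MIN_FRAMES_DEFAULT,
    n_boot: int = 500,
    ci_level: float = 0.95,
) -> PreferenceSummary:
    """Full scoring pipeline for one trial and phase.

    clip to phase -> length filter -> per-track PI over the (test, control)
    fictive volumes -> percentile bootstrap of the mean. Tracks that enter
    neither volume are counted as excluded, not scored.
    """
    if volumes is None:
        volumes = volumes_for_layout(layout)
    test_volume, control_volume = volumes
    if control_volume.role != "control":
        raise ValidationError("second volume must have role 'control'")
    clipped = clip_to_phase(table, schedule, phase)
    filtered, _ = filter_trajectories(clipped, min_frames=min_frames)
    pi, n_excluded = _per_track_pi(filtered, test_volume, control_volume)
    if pi.size == 0:
        return PreferenceSummary(
            pi_values=pi, n_scored=0, n_excluded=n_excluded,
            mean=float("nan"), ci_lo=float("nan"), ci_hi=float("nan"),
            n_boot=n_boot, ci_level=ci_level, seed=seed,
        )
    mean, lo, hi = bootstrap_mean_ci(pi, n_boot=n_boot, level=ci_level, seed=seed)
    return PreferenceSummary(
        pi_values=pi, n_scored=pi.size, n_excluded=n_excluded,
        mean=mean, ci_lo=lo, ci_hi=hi, n_boot=n_boot, ci_level=ci_level, seed=seed,
    )


@dataclass
class ActivityResult:
    """Per-phase trajectory counts and consecutive-phase ratios.

    ``ratios[k]`` is count(phase k+1) / count(phase k); None where the
    denominator phase recorded no trajectories.
    """

    phase_names: tuple[str, ...]
    counts: tuple[int, ...]
    ratios: tuple[float | None, ...]


def relative_activity(
    table: TrajectoryTable,
    schedule: PhaseSchedule,
    min_frames: int = MIN_FRAMES_DEFAULT,
) -> ActivityResult:
    """Relative flight activity: trajectory count per phase divided by the
    count in the previous phase (after length filtering within each phase)."""
    if len(schedule.phases) < 2:
        raise ValueError("need at least two phases")
    counts = []
    for name in schedule.names:
        clipped = clip_to_phase(table, schedule, name)
        filtered, rep = filter_trajectories(clipped, min_frames=min_frames)
        counts.append(rep.n_kept)
    ratios = tuple(
        (counts[i + 1] / counts[i]) if counts[i] > 0 else None
        for i in range(len(counts) - 1)
    )
    return ActivityResult(schedule.names, tuple(counts), ratios)


def mean_flight_velocity(
    track: pd.DataFrame | TrajectoryTable, frame_rate: float | None = None
) -> float:
    """Mean speed (cm/s) of a single track from central-difference position
    derivatives (one-sided at the ends)."""
    if isinstance(track, TrajectoryTable):
        frame_rate = frame_rate or track.frame_rate
        df = track.data
    else:
        if frame_rate is None:
            raise ValueError("frame_rate required when passing a raw DataFrame")
        df = track
    if len(df) < 3:
        raise ValueError("need at least 3 frames to estimate velocity")
    t = df["t"].to_numpy()
    xyz = df[["x", "y", "z"]].to_numpy()
    v = np.gradient(xyz, t, axis=0)
    return float(np.mean(np.linalg.norm(v, axis=1)))


@dataclass
class OccupancyMap:
    """Grid of residency percentages over a 2D projection of the arena."""

    view: Literal["top", "side"]
    edges_a: np.ndarray  # bin edges along the first projected axis (x)
    edges_b: np.ndarray  # second axis (y for top view, z for side view)
    percent: np.ndarray  # (na, nb) percentages summing to 100
    n_records: int

    def compatible(self, other: "OccupancyMap") -> bool:
        return (
            self.view == other.view
            and self.percent.shape == other.percent.shape
            and np.allclose(self.edges_a, other.edges_a)
            and np.allclose(self.edges_b, other.edges_b)
        )


def occupancy_map(
    table: TrajectoryTable,
    layout: ArenaLayout,
    view: Literal["top", "side"] = "top",
    cell_area: float = 0.3,
    cell_side: float | None = None,
) -> OccupancyMap:
    """Residency map: the arena projection is tiled with small squares
    (default area 0.3 cm^2, i.e. side sqrt(0.3) ~ 0.548 cm); per-cell
    occurrence counts are normalized to percentages summing to 100.

    ``cell_side`` overrides the area reading for those who interpret the
    cell spec as a side length.
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an occupancy map with no records")
    side = float(cell_side) if cell_side is not None else float(np.sqrt(cell_area))
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = layout.bounds
    if view == "top":
        (alo, ahi), (blo, bhi) = (xlo, xhi), (ylo, yhi)
        a = table.data["x"].to_numpy()
        b = table.data["y"].to_numpy()
    elif view == "side":
        (alo, ahi), (blo, bhi) = (xlo, xhi), (zlo, zhi)
        a = table.data["x"].to_numpy()
        b = table.data["z"].to_numpy()
    else:
        raise ValueError("view must be 'top' or 'side'")
    na = int(np.ceil((ahi - alo) / side))
    nb = int(np.ceil((bhi - blo) / side))
    edges_a = alo + side * np.arange(na + 1)
    edges_b = blo + side * np.arange(nb + 1)
    counts, _, _ = np.histogram2d(a, b, bins=[edges_a, edges_b])
    percent = 100.0 * counts / counts.sum()
    return OccupancyMap(view, edges_a, edges_b, percent, n_records=len(table))


def pool_occupancy(maps: Iterable[OccupancyMap]) -> OccupancyMap:
    """Pool replicate trials: unweighted mean of the per-trial percentage
    maps, so each trial contributes equally regardless of its record count."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to pool")
    first = maps[0]
    for m in maps[1:]:
        if not first.compatible(m):
            raise ValueError("occupancy maps have mismatched grids")
    stacked = np.stack([m.percent for m in maps])
    return OccupancyMap(
        view=first.view,
        edges_a=first.edges_a,
        edges_b=first.edges_b,
        percent=stacked.mean(axis=0),
        n_records=int(sum(m.n_records for m in maps)),
    )


def investigation_timecourse(
    table: TrajectoryTable,
    volumes: Sequence[FictiveVolume],
    schedule: PhaseSchedule,
    bin_s: float = 60.0,
) -> pd.DataFrame:
    """Percent of tracked time spent investigating the visual objects, per
    time bin (default one minute) across the whole trial.

    Returns a DataFrame with columns ``bin_start_s, bin_end_s, phase,
    percent, n_frames``; bins with no tracked frames have NaN percent.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    t_start = schedule.phases[0][1]
    t_end = schedule.phases[-1][2]
    edges = np.arange(t_start, t_end + bin_s, bin_s)
    edges = edges[edges <= t_end + 1e-9]
    if edges[-1] < t_end:
        edges = np.append(edges, t_end)
    df = table.data
    t = df["t"].to_numpy()
    if len(df):
        xyz = df[["x", "y", "z"]].to_numpy()
        inside = np.zeros(len(df), dtype=bool)
        for vol in volumes:
            inside |= vol.contains(xyz)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        phase = next(
            (n for n, s, e in schedule.phases if s <= lo < e), schedule.names[-1]
        )
        if len(df):
            in_bin = (t >= lo) & (t < hi)
            n = int(in_bin.sum())
            pct = 100.0 * inside[in_bin].sum() / n if n else np.nan
        else:
            n, pct = 0, np.nan
        rows.append(
            {"bin_start_s": lo, "bin_end_s": hi, "phase": phase,
             "percent": pct, "n_frames": n}
        )
    return pd.DataFrame(rows)


def random_volume_control(
    table: TrajectoryTable,
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    control_volume: FictiveVolume,
    phase: str = "co2",
    seed: int | None = None,
    object_volumes: Sequence[FictiveVolume] | None = None,
    max_retries: int = 100,
    **score_kw,
) -> tuple[PreferenceSummary, FictiveVolume]:
    """Preference of a randomly placed 14 x 14 x 4 cm volume against the
    object volume.

    The random volume is drawn uniformly inside the arena (rejecting overlap
    with the object volumes) and scored as the "test" side, the real object
    volume as "control" — so genuine attraction to the object drives the mean
    PI toward -1. Returns (summary, the random volume used).
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    avoid = list(object_volumes) if object_volumes is not None else [control_volume]
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = layout.bounds
    fx, fy = control_volume.footprint
    h = control_volume.height
    for _ in range(max_retries):
        cx = rng.uniform(xlo + fx / 2, xhi - fx / 2)
        cy = rng.uniform(ylo + fy / 2, yhi - fy / 2)
        cz = rng.uniform(zlo, zhi - h)
        candidate = _box_volume(cx, cy, cz, fx, fy, h)
        if not any(_boxes_overlap(candidate.bounds, v.bounds) for v in avoid):
            break
    else:
        raise RuntimeError("could not place a non-overlapping random volume")
    # the object volume is the reference side of this comparison whatever
    # its role in the main analysis
    reference = replace(control_volume, role="control")
    summary = score_trial(
        table, layout, schedule, phase,
        volumes=(candidate, reference),
        seed=int(rng.integers(2**31)),
        **score_kw,
    )
    return summary, candidate


@dataclass(frozen=True)
class _FreeBox(FictiveVolume):
    """A fictive volume floated anywhere in the arena (z not floor-anchored)."""

    z_lo: float = 0.0

    @property
    def bounds(self):
        (xl, xh), (yl, yh), _ = super().bounds
        return ((xl, xh), (yl, yh), (self.z_lo, self.z_lo + self.height))


def _box_volume(cx, cy, z_lo, fx, fy, h) -> FictiveVolume:
    return _FreeBox(
        anchor=(cx, cy), footprint=(fx, fy), height=h,
        downwind_shift=0.0, label="random", role="test", z_lo=z_lo,
    )


def _boxes_overlap(b1, b2) -> bool:
    return all(lo1 < hi2 and lo2 < hi1 for (lo1, hi1), (lo2, hi2) in zip(b1, b2))


def volume_sensitivity(
    table: TrajectoryTable,
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    phase: str,
    volumes: tuple[FictiveVolume, FictiveVolume] | None = None,
    scale_factors: Sequence[float] = (0.75, 1.0, 1.25, 1.5),
    seed: int | None = None,
    min_frames: int = MIN_FRAMES_DEFAULT,
) -> pd.DataFrame:
    """Stability of the mean PI under scaling of the fictive-volume size.

    Returns one row per scale factor with columns ``scale, n_scored,
    n_excluded, mean_pi, capture_fraction``.
    """
    if any(s <= 0 for s in scale_factors):
        raise ValueError("scale factors must be positive")
    if volumes is None:
        volumes = volumes_for_layout(layout)
    test_volume, control_volume = volumes
    rng = np.random.default_rng(seed if seed is not None else 0)
    rows = []
    for s in scale_factors:
        summary = score_trial(
            table, layout, schedule, phase,
            volumes=(test_volume.scaled(s), control_volume.scaled(s)),
            seed=int(rng.integers(2**31)),
            min_frames=min_frames,
        )
        total = summary.n_scored + summary.n_excluded
        rows.append(
            {
                "scale": s,
                "n_scored": summary.n_scored,
                "n_excluded": summary.n_excluded,
                "mean_pi": summary.mean,
                "capture_fraction": summary.n_scored / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
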