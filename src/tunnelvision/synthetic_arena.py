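"""Seeded agent-based simulator of odor-gated mosquito flight in a wind tunnel.

The simulator is the stand-in for raw multi-camera tracking data: it emits
:class:`~tunnelvision.trajectory_io.TrajectoryTable` objects with the same
statistical texture the downstream pipeline expects — three experimental
phases (pre / CO2 / post), a roughly twofold jump in flight activity when the
CO2 plume turns on, object-directed hovering a few cm downwind of the floor
circles, and trajectory fragmentation from tracking identity loss.

The CO2 plume is a two-parameter exponential above ambient with a Gaussian
cross-section; its defaults are calibrated so the centerline concentration
passes through the two measured anchors (~1700 ppm at 20 cm and ~1500 ppm at
30 cm downwind of the source, over an ambient of ~400 ppm).

Behavior is a four-state machine (resting, wall-exploring, plume-tracking,
object-investigating) stepped at the camera frame rate. The states and their
transition rates are a modeling invention: the biology fixes the *outcomes*
(activation doubling, hover offset, 5-10 min persistence of sensitization),
not the mechanism, so every rate is exposed in :class:`AgentParams`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .trajectory_io import (
    ArenaLayout,
    PhaseSchedule,
    TrajectoryTable,
    write_trajectories,
)

__all__ = [
    "PlumeParams",
    "AgentParams",
    "PRESETS",
    "calibrate_plume",
    "plume_concentration",
    "simulate_trial",
    "simulate_replicates",
    "fragment_tracks",
    "generate_cohort",
]

# Measured centerline anchors used to calibrate the default plume.
_ANCHOR_NEAR = (20.0, 1700.0)  # (cm downwind, ppm)
_ANCHOR_FAR = (30.0, 1500.0)
_AMBIENT_PPM = 400.0


def calibrate_plume(
    ambient_ppm: float = _AMBIENT_PPM,
    anchor_near: tuple[float, float] = _ANCHOR_NEAR,
    anchor_far: tuple[float, float] = _ANCHOR_FAR,
) -> tuple[float, float]:
    """Solve for (amplitude A, decay length lambda) of the centerline model
    ``C(d) = ambient + A * exp(-d / lambda)`` through two (distance, ppm)
    anchors. Closed form of the 2x2 system.
    """
    d1, c1 = anchor_near
    d2, c2 = anchor_far
    if not (c1 > c2 > ambient_ppm):
        raise ValueError("anchors must decrease toward (but stay above) ambient")
    lam = (d2 - d1) / math.log((c1 - ambient_ppm) / (c2 - ambient_ppm))
    amplitude = (c1 - ambient_ppm) * math.exp(d1 / lam)
    return amplitude, lam


_DEFAULT_A, _DEFAULT_LAMBDA = calibrate_plume()


@dataclass(frozen=True)
class PlumeParams:
    """Exponential-decay CO2 plume with Gaussian cross-section.

    ``C(d, r) = ambient + A exp(-d/lambda) exp(-r^2 / (2 sigma(d)^2))`` with
    ``sigma(d) = cross_sigma0 (1 + cross_spread_rate * d)``; d is downwind
    distance from the source, r the radial offset from the centerline.
    cross_sigma0 defaults to 0.375 cm so the near-source plume diameter
    (~4 sigma) is ~1.5 cm.
    """

    ambient_ppm: float = _AMBIENT_PPM
    amplitude: float = _DEFAULT_A
    decay_length: float = _DEFAULT_LAMBDA
    cross_sigma0: float = 0.375
    cross_spread_rate: float = 0.05


def plume_concentration(
    position: np.ndarray, layout: ArenaLayout, params: PlumeParams | None = None
) -> np.ndarray | float:
    """CO2 concentration (ppm) at one or many positions.

    ``position`` is (3,) or (N, 3) in arena coordinates. Positions upwind of
    the source (or on it) return ambient; the far field decays to ambient.
    """
    params = params or PlumeParams()
    pos = np.asarray(position, dtype=float)
    scalar = pos.ndim == 1
    pos = np.atleast_2d(pos)
    sx, sy, sz = layout.source_position
    d = pos[:, 0] - sx
    r2 = (pos[:, 1] - sy) ** 2 + (pos[:, 2] - sz) ** 2
    sigma = params.cross_sigma0 * (1.0 + params.cross_spread_rate * np.maximum(d, 0.0))
    with np.errstate(over="ignore"):
        excess = (
            params.amplitude
            * np.exp(-np.maximum(d, 0.0) / params.decay_length)
            * np.exp(-r2 / (2.0 * sigma**2))
        )
    conc = params.ambient_ppm + np.where(d > 0, excess, 0.0)
    return float(conc[0]) if scalar else conc


@dataclass(frozen=True)
class AgentParams:
    """Per-cohort behavioral parameters.

    The headline knobs mirror the biology: ``activation_factor`` multiplies
    the per-second take-off rate once an agent has sensed CO2 ("the number of
    flying mosquitoes more than doubled"); ``co2_sensing=False`` models a
    CO2-receptor knockout (Gr3-/-); ``visual_gain=0`` models the long-
    wavelength opsin double knockout (no object attraction despite intact
    CO2 responses); ``attraction_weights`` maps object labels to relative
    attractiveness; ``hover_offset_cm`` places the hover point downwind of
    the object center (observed ~3-5 cm).

    Mechanism rates (take-off, bout length, filament encounters, dwell) are
    simulator inventions, exposed for sweeps.
    """

    n_agents: int = 50
    mean_speed: float = 25.0  # cm/s
    speed_sd: float = 5.0
    turn_persistence: float = 0.95  # per-frame heading memory, 0-1
    activation_factor: float = 2.0
    co2_threshold_ppm: float = 500.0
    co2_sensing: bool = True
    visual_gain: float = 1.0
    attraction_weights: Mapping[str, float] | None = None
    hover_offset_cm: float = 4.0
    dropout_prob: float = 0.01  # per-frame identity-loss probability
    frame_rate: float = 60.0
    # mechanism parameters
    base_takeoff_rate: float = 0.003  # per s, resting -> flight
    mean_bout_s: float = 6.0  # mean flight bout duration
    sense_radius_cm: float = 20.0  # horizontal radius for object detection
    investigate_rate: float = 1.0  # per s within radius, per unit weight
    mean_investigate_s: float = 4.0  # mean hover dwell before excursion
    activation_decay_s: float = 300.0  # persistence of CO2 sensitization
    filament_encounter_rate: float = 0.3  # per s while CO2 is released
    surge_gain: float = 0.4  # upwind bias while inside the plume
    hover_height_cm: float = 2.0
    hover_sd_cm: float = 2.0  # stationary sd of hovering noise
    hover_theta: float = 2.0  # mean reversion rate of hovering (1/s)

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 0.0 <= self.turn_persistence <= 1.0:
            raise ValueError("turn_persistence must lie in [0, 1]")
        if self.activation_factor < 1.0:
            raise ValueError("activation_factor must be >= 1")
        if self.visual_gain < 0.0:
            raise ValueError("visual_gain must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        for name in ("base_takeoff_rate", "mean_bout_s", "investigate_rate",
                     "mean_investigate_s", "filament_encounter_rate"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and non-negative")

    def weight_for(self, label: str, role: str | None = None) -> float:
        """Attraction weight for an object, looked up by its label with a
        fallback to its role ('test'/'control') so presets apply to any
        layout's labels."""
        if self.attraction_weights is None:
            return 1.0
        if label in self.attraction_weights:
            return float(self.attraction_weights[label])
        if role is not None and role in self.attraction_weights:
            return float(self.attraction_weights[role])
        return 1.0

    def replace(self, **kw) -> "AgentParams":
        return dataclasses.replace(self, **kw)


#: Genotype/species presets; they differ only in attraction weights,
#: visual gain and CO2 sensing, which is the level this simulator models.
PRESETS: dict[str, dict] = {
    "ae_aegypti_wt": {"attraction_weights": {"test": 3.0, "control": 1.0}},
    "gr3_ko": {"attraction_weights": {"test": 3.0, "control": 1.0}, "co2_sensing": False},
    "opsin_dko": {"attraction_weights": {"test": 3.0, "control": 1.0}, "visual_gain": 0.0},
    "an_stephensi": {"attraction_weights": {"test": 2.0, "control": 1.0}},
    "cx_quinquefasciatus": {"attraction_weights": {"test": 1.5, "control": 1.0}},
}


def agent_params_for_preset(name: str, **overrides) -> AgentParams:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return AgentParams(**{**PRESETS[name], **overrides})


# state codes
_REST, _EXPLORE, _SURGE, _INVESTIGATE = 0, 1, 2, 3


def simulate_trial(
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    agents: AgentParams | None = None,
    plume: PlumeParams | None = None,
    seed: int | None = None,
    fragment: bool = True,
) -> TrajectoryTable:
    """Simulate one trial cohort and return its (fragmented) trajectory table.

    Per-agent discrete-time state machine at dt = 1/frame_rate:

    * resting -> flight with base take-off rate, multiplied by
      ``activation_factor`` while the agent's CO2-activation flag is fresh;
    * flight is a correlated random walk with specular wall reflection;
      while the local concentration exceeds ``co2_threshold_ppm`` the agent
      surges upwind (plume tracking) and refreshes its activation flag;
    * while CO2 is released, agents (flying or resting) also encounter
      dispersed plume filaments as a Poisson process, the mechanism by which
      resting animals become activated;
    * an activated agent within ``sense_radius_cm`` of a visual object starts
      investigating with probability proportional to
      ``visual_gain * attraction_weight``, hovering with mean-reverting noise
      around the point ``hover_offset_cm`` downwind of the object center,
      with brief excursions between dwells;
    * the activation flag decays ``activation_decay_s`` after the last
      supra-threshold encounter.

    The raw bout-level tracks are passed through :func:`fragment_tracks` to
    emulate tracking identity loss (disable with ``fragment=False``).
    """
    return simulate_replicates(
        layout, schedule, agents, plume, seed=seed, n_reps=1, fragment=fragment
    )[0]


def simulate_replicates(
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    agents: AgentParams | None = None,
    plume: PlumeParams | None = None,
    seed: int | None = None,
    n_reps: int = 1,
    fragment: bool = True,
) -> list[TrajectoryTable]:
    """Simulate ``n_reps`` independent replicate trials in one vectorized
    pass (agents of all replicates stacked), returning one table per trial.

    Statistically identical to ``n_reps`` calls of :func:`simulate_trial`
    with independent seeds, but much faster for parameter sweeps because the
    per-timestep cost is amortized over the whole batch. The random streams
    differ from per-trial simulation, so a batch with seed s is its own
    reproducible object, not a concatenation of ``simulate_trial(seed=s)``
    outputs.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ap = agents or AgentParams()
    pp = plume or PlumeParams()
    dt = 1.0 / ap.frame_rate
    if dt <= 0:
        raise ValueError("frame_rate must be positive")
    rng = np.random.default_rng(seed)
    fragment_seeds = [int(s) for s in rng.integers(2**31, size=n_reps)]

    n = ap.n_agents * n_reps
    rep_of = np.repeat(np.arange(n_reps, dtype=np.int64), ap.n_agents)
    t0 = schedule.phases[0][1]
    n_steps = int(round(schedule.total_duration * ap.frame_rate))
    co2_windows = [(s, e) for name, s, e in schedule.phases if name == "co2"]

    (xlo, xhi), (ylo, yhi), (zlo, zhi) = layout.bounds
    lo = np.array([xlo, ylo, zlo])
    hi = np.array([xhi, yhi, zhi])

    objs = layout.objects
    m = len(objs)
    if m:
        obj_xy = np.array([o.center for o in objs], dtype=float)
        weights = np.array([ap.weight_for(o.label, o.role) for o in objs], dtype=float)
        hover_pts = np.column_stack(
            [
                obj_xy[:, 0] + ap.hover_offset_cm,
                obj_xy[:, 1],
                np.full(m, ap.hover_height_cm),
            ]
        )
        p_enter = ap.investigate_rate * ap.visual_gain * weights * dt  # per object
        sense_r2 = ap.sense_radius_cm**2
    # initial rest positions: random points on the walls/ceiling
    pos = _random_surface_points(rng, lo, hi, n)
    heading = _unit(rng.standard_normal((n, 3)))
    speed = np.clip(rng.normal(ap.mean_speed, ap.speed_sd, n), 5.0, None)
    state = np.full(n, _REST, dtype=np.int8)
    last_enc = np.full(n, -np.inf)
    track_id = np.full(n, -1, dtype=np.int64)
    next_id = 0
    target = np.zeros(n, dtype=np.int64)
    dwell_end = np.zeros(n)

    rec_tid: list[np.ndarray] = []
    rec_rep: list[np.ndarray] = []
    rec_frame: list[np.ndarray] = []
    rec_xyz: list[np.ndarray] = []

    p_land = dt / ap.mean_bout_s
    p_takeoff_base = ap.base_takeoff_rate * dt
    p_filament = ap.filament_encounter_rate * dt
    ou_noise_scale = ap.hover_sd_cm * math.sqrt(2.0 * ap.hover_theta * dt)
    sx, sy, sz = layout.source_position

    # chunked randomness: cap the pre-drawn block at a few hundred MB
    chunk = int(min(4096, max(64, 2_000_000 // max(n, 1))))
    for base in range(0, n_steps, chunk):
        steps_here = min(chunk, n_steps - base)
        # one block of randomness per chunk; rows: takeoff / landing /
        # filament / investigate / dwell-length
        U = rng.random((steps_here, 5, n))
        NORM = rng.standard_normal((steps_here, n, 3))
        for j in range(steps_here):
            step = base + j
            tnow = t0 + step * dt
            co2_on = any(s <= tnow < e for s, e in co2_windows)
            u = U[j]
            norm_j = NORM[j]
            activated = (tnow - last_enc) < ap.activation_decay_s

            # --- resting -> take-off --------------------------------------
            resting = state == _REST
            if resting.any():
                p_takeoff = np.where(activated, ap.activation_factor, 1.0) * p_takeoff_base
                takeoff = resting & (u[0] < p_takeoff)
                k = int(takeoff.sum())
                if k:
                    state[takeoff] = _EXPLORE
                    track_id[takeoff] = next_id + np.arange(k)
                    next_id += k
                    heading[takeoff] = _unit(norm_j[takeoff])

            flying = state != _REST
            any_flying = bool(flying.any())

            # --- odor sensing ---------------------------------------------
            if ap.co2_sensing and co2_on:
                if any_flying:
                    d = pos[:, 0] - sx
                    sig = pp.cross_sigma0 * (1.0 + pp.cross_spread_rate * np.maximum(d, 0.0))
                    r2 = (pos[:, 1] - sy) ** 2 + (pos[:, 2] - sz) ** 2
                    conc = pp.ambient_ppm + np.where(
                        d > 0,
                        pp.amplitude
                        * np.exp(-np.maximum(d, 0.0) / pp.decay_length
                                 - r2 / (2.0 * sig**2)),
                        0.0,
                    )
                    in_plume = flying & (conc > ap.co2_threshold_ppm)
                    last_enc[in_plume] = tnow
                    state[in_plume & (state == _EXPLORE)] = _SURGE
                    state[~in_plume & (state == _SURGE)] = _EXPLORE
                # dispersed filaments reach agents anywhere in the section
                filament = u[2] < p_filament
                last_enc[filament] = tnow
                activated = (tnow - last_enc) < ap.activation_decay_s
            elif not co2_on:
                state[state == _SURGE] = _EXPLORE

            # --- start investigating --------------------------------------
            if m and ap.visual_gain > 0 and any_flying and activated.any():
                cand = ((state == _EXPLORE) | (state == _SURGE)) & activated
                if cand.any():
                    d2 = (
                        (pos[:, 0, None] - obj_xy[None, :, 0]) ** 2
                        + (pos[:, 1, None] - obj_xy[None, :, 1]) ** 2
                    )  # (n, m)
                    probs = np.where(
                        cand[:, None] & (d2 < sense_r2), p_enter[None, :], 0.0
                    )
                    cum = np.cumsum(probs, axis=1)
                    enter = u[3] < cum[:, -1]
                    if enter.any():
                        chosen = (u[3][:, None] >= cum).sum(axis=1)
                        state[enter] = _INVESTIGATE
                        target[enter] = chosen[enter]
                        dwell_end[enter] = tnow - ap.mean_investigate_s * np.log(
                            u[4][enter]
                        )

            if any_flying:
                # --- movement ---------------------------------------------
                cruising = (state == _EXPLORE) | (state == _SURGE)
                if cruising.any():
                    h = ap.turn_persistence * heading + (1 - ap.turn_persistence) * _unit(norm_j)
                    h[:, 0] -= ap.surge_gain * (state == _SURGE)
                    h = _unit(h)
                    heading = np.where(cruising[:, None], h, heading)
                    pos = np.where(
                        cruising[:, None],
                        pos + heading * (speed[:, None] * dt),
                        pos,
                    )

                investigating = state == _INVESTIGATE
                if investigating.any():
                    hp = hover_pts[target]
                    ou = pos + ap.hover_theta * (hp - pos) * dt + ou_noise_scale * norm_j
                    pos = np.where(investigating[:, None], ou, pos)
                    state[investigating & (tnow >= dwell_end)] = _EXPLORE

                # specular reflection at the walls
                below = pos < lo
                if below.any():
                    pos = np.where(below, 2 * lo - pos, pos)
                    heading = np.where(below, np.abs(heading), heading)
                above = pos > hi
                if above.any():
                    pos = np.where(above, 2 * hi - pos, pos)
                    heading = np.where(above, -np.abs(heading), heading)
                if below.any() or above.any():
                    np.clip(pos, lo, hi, out=pos)

                # record this frame
                fly_idx = np.flatnonzero(state != _REST)
                rec_tid.append(track_id[fly_idx])
                rec_rep.append(rep_of[fly_idx])
                rec_frame.append(np.full(fly_idx.size, step, dtype=np.int64))
                rec_xyz.append(pos[fly_idx])

                # --- landing ----------------------------------------------
                landing = flying & (u[1] < p_land)
                if landing.any():
                    state[landing] = _REST
                    track_id[landing] = -1

    if rec_tid:
        all_tid = np.concatenate(rec_tid)
        all_rep = np.concatenate(rec_rep)
        all_frame = np.concatenate(rec_frame)
        all_xyz = np.concatenate(rec_xyz)
    else:
        all_tid = all_rep = all_frame = np.empty(0, dtype=np.int64)
        all_xyz = np.empty((0, 3))
    tables: list[TrajectoryTable] = []
    for r in range(n_reps):
        sel = all_rep == r
        if sel.any():
            table = TrajectoryTable.from_records(
                all_tid[sel], all_frame[sel], all_xyz[sel], frame_rate=ap.frame_rate
            )
        else:
            table = TrajectoryTable.empty(frame_rate=ap.frame_rate)
        if fragment and ap.dropout_prob > 0:
            table = fragment_tracks(table, ap.dropout_prob, seed=fragment_seeds[r])
        tables.append(table)
    return tables


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def _random_surface_points(rng, lo, hi, n) -> np.ndarray:
    """Random resting positions on the four walls + ceiling (not the floor)."""
    pts = lo + rng.random((n, 3)) * (hi - lo)
    # faces: 0/1 -> y walls, 2/3 -> x ends, 4 -> ceiling
    face = rng.integers(0, 5, n)
    pts[face == 0, 1] = lo[1]
    pts[face == 1, 1] = hi[1]
    pts[face == 2, 0] = lo[0]
    pts[face == 3, 0] = hi[0]
    pts[face == 4, 2] = hi[2]
    return pts


def fragment_tracks(
    table: TrajectoryTable, dropout_prob: float, seed: int | None = None
) -> TrajectoryTable:
    """Emulate tracking identity loss.

    At each frame the current track ends with probability ``dropout_prob``
    and a fresh track id begins at the next frame; positions are untouched.
    The first fragment of each track keeps the original id (so
    ``dropout_prob=0`` is the identity); later fragments receive fresh ids
    above the current maximum. Fragment lengths are geometric with mean
    ``1/dropout_prob`` frames (censored by the original track length).
    """
    if not 0.0 <= dropout_prob <= 1.0:
        raise ValueError("dropout_prob must lie in [0, 1]")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if dropout_prob == 0.0 or len(table) == 0:
        return TrajectoryTable(table.data, frame_rate=table.frame_rate)
    rng = np.random.default_rng(seed)
    df = table.data
    tid = df["track_id"].to_numpy()
    breaks = rng.random(len(df)) < dropout_prob
    # a break ends the track *after* the current frame; never break across
    # original track boundaries (they are already separate tracks)
    new_track_start = np.zeros(len(df), dtype=bool)
    new_track_start[1:] = breaks[:-1]
    track_boundary = np.zeros(len(df), dtype=bool)
    track_boundary[1:] = tid[1:] != tid[:-1]
    new_track_start &= ~track_boundary
    frag_index = np.zeros(len(df), dtype=np.int64)
    np.add.at(frag_index, np.flatnonzero(new_track_start), 1)
    # cumulative fragment index within each original track
    frag_index = _segment_cumsum(frag_index, track_boundary)
    is_tail = frag_index > 0
    new_ids = tid.copy()
    if is_tail.any():
        # dense ids for (original id, fragment>0) pairs, above current max
        key = tid.astype(np.float64) * 1e9 + frag_index  # unique composite
        tail_keys = key[is_tail]
        uniq, inverse = np.unique(tail_keys, return_inverse=True)
        new_ids[is_tail] = tid.max() + 1 + inverse
    out = df.copy()
    out["track_id"] = new_ids
    return TrajectoryTable(out, frame_rate=table.frame_rate)


def _segment_cumsum(increments: np.ndarray, reset_at: np.ndarray) -> np.ndarray:
    """Cumulative sum of ``increments`` that restarts at every True in
    ``reset_at``. Vectorized via offset subtraction."""
    cs = np.cumsum(increments)
    seg_id = np.cumsum(reset_at)
    # value of cs just before each segment start
    starts = np.flatnonzero(np.concatenate(([True], reset_at[1:])))
    base = cs[starts] - increments[starts]
    return cs - base[seg_id]


def generate_cohort(
    out_dir: str | Path,
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    agents: AgentParams | None = None,
    plume: PlumeParams | None = None,
    n_trials: int = 6,
    seed: int | None = None,
    format: str = "csv",
) -> tuple[list[Path], Path]:
    """Simulate ``n_trials`` replicate trials and write them plus a manifest.

    Deterministic given ``seed``: per-trial seeds are spawned from a seed
    sequence and recorded in the manifest (JSON) together with the agent and
    plume parameters, so any trial can be regenerated in isolation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    ap = agents or AgentParams()
    pp = plume or PlumeParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_seeds = _distinct_seeds(seed, n_trials)
    suffix = ".csv" if format == "csv" else ".h5"
    paths: list[Path] = []
    for i, s in enumerate(trial_seeds):
        table = simulate_trial(layout, schedule, ap, pp, seed=s)
        path = out_dir / f"trial_{i:03d}{suffix}"
        write_trajectories(table, path, format=format)
        paths.append(path)
    manifest = {
        "seed": int(seed),
        "n_trials": int(n_trials),
        "trial_seeds": [int(s) for s in trial_seeds],
        "trial_files": [p.name for p in paths],
        "format": format,
        "agents": _params_dict(ap),
        "plume": dataclasses.asdict(pp),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths, manifest_path


def _params_dict(ap: AgentParams) -> dict:
    d = dataclasses.asdict(ap)
    if d["attraction_weights"] is not None:
        d["attraction_weights"] = dict(d["attraction_weights"])
    return d


def _distinct_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
    while len(set(seeds)) < n:  # astronomically unlikely; regenerate tail
        ss = ss.spawn(1)[0]
        seeds = [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
    return seeds
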