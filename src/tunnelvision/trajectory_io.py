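"""Data model and readers/writers for wind-tunnel trajectory tables.

The pipeline's universal currency is the :class:`TrajectoryTable`: time-ordered
3D positions grouped by track id, as produced by a real-time multi-camera
insect tracking system. Identity loss is expected — one animal typically
contributes many short track ids — so nothing here assumes a track is an
individual.

Coordinate convention: origin at the upwind end of the working section, on the
floor, on the tunnel centerline. x increases downwind, y crosswind, z upward;
all lengths in cm, time in seconds, frame 0 at t = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrajectoryTable",
    "ArenaLayout",
    "VisualObjectSpec",
    "PhaseSchedule",
    "SchemaError",
    "ValidationError",
    "read_trajectories",
    "write_trajectories",
    "clip_to_phase",
    "load_trial_config",
    "save_trial_config",
]

#: canonical column order of the on-disk trajectory schema
COLUMNS = ["track_id", "frame", "t", "x", "y", "z"]

DEFAULT_FRAME_RATE = 60.0
#: |t - frame/frame_rate| must not exceed this (seconds)
TIME_TOL = 1e-9


class SchemaError(ValueError):
    """The file does not match the documented trajectory column schema."""


class ValidationError(ValueError):
    """Structurally readable data that violates a table invariant."""


@dataclass(frozen=True)
class VisualObjectSpec:
    """A visual stimulus on the arena floor (or wall, for the cage assay).

    ``center`` is (x, y) on the floor for the wind tunnel, (y, z) on the
    window wall for the cage. Exactly one object per trial carries
    ``role='control'`` (the evenly reflecting object).
    """

    label: str
    center: tuple[float, float]
    diameter: float = 3.0
    role: Literal["test", "control"] = "test"
    spectrum_id: str | None = None


@dataclass(frozen=True)
class ArenaLayout:
    """Geometry of the behavioral arena.

    Defaults describe the wind-tunnel working section: 224 cm long, 61 cm
    wide, 61 cm high with laminar flow at 40 cm/s. The odor source sits at
    the immediate upwind end on the centerline at 20 cm height; the two
    visual objects sit on the floor 33 cm downwind of it, 18 cm apart.
    """

    length_x: float = 224.0
    width_y: float = 61.0
    height_z: float = 61.0
    wind_speed: float = 40.0
    source_position: tuple[float, float, float] = (0.0, 0.0, 20.0)
    objects: tuple[VisualObjectSpec, ...] = ()
    arena_kind: Literal["wind_tunnel", "cage"] = "wind_tunnel"

    def __post_init__(self) -> None:
        if min(self.length_x, self.width_y, self.height_z) <= 0:
            raise ValidationError("arena dimensions must be positive")
        roles = [o.role for o in self.objects]
        if self.objects and roles.count("control") != 1:
            raise ValidationError(
                f"expected exactly one control object, found {roles.count('control')}"
            )

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        """((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)) of the working section."""
        half_w = self.width_y / 2.0
        return ((0.0, self.length_x), (-half_w, half_w), (0.0, self.height_z))

    def object_by_role(self, role: str) -> VisualObjectSpec:
        matches = [o for o in self.objects if o.role == role]
        if len(matches) != 1:
            raise ValidationError(f"expected exactly one {role!r} object")
        return matches[0]


def default_two_object_layout(
    test_label: str = "red", control_label: str = "white"
) -> ArenaLayout:
    """Standard two-circle arrangement: 3 cm circles, 18 cm apart crosswind,
    33 cm downwind of the source."""
    return ArenaLayout(
        objects=(
            VisualObjectSpec(label=test_label, center=(33.0, 9.0), role="test"),
            VisualObjectSpec(label=control_label, center=(33.0, -9.0), role="control"),
        )
    )


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous experimental phases (pre / co2 / post).

    Intervals are half-open [start_s, end_s), so concatenating all phases
    partitions the trial timeline with no record counted twice.
    """

    phases: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for name, start, end in self.phases:
            if end <= start:
                raise ValidationError(f"phase {name!r} has end <= start")
            if prev_end is not None and abs(start - prev_end) > TIME_TOL:
                raise ValidationError("phases must be contiguous and ordered")
            prev_end = end

    @classmethod
    def equal_phases(cls, duration_s: float, names=("pre", "co2", "post")) -> "PhaseSchedule":
        return cls(
            tuple(
                (name, i * duration_s, (i + 1) * duration_s)
                for i, name in enumerate(names)
            )
        )

    @classmethod
    def wind_tunnel_default(cls) -> "PhaseSchedule":
        """1 h of filtered air, 1 h CO2, 1 h post (3600 s each)."""
        return cls.equal_phases(3600.0)

    @classmethod
    def cage_default(cls) -> "PhaseSchedule":
        """8 min per phase, as in the cage assay."""
        return cls.equal_phases(480.0)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.phases)

    def interval(self, phase_name: str) -> tuple[float, float]:
        for name, start, end in self.phases:
            if name == phase_name:
                return (start, end)
        raise KeyError(f"unknown phase {phase_name!r}; have {self.names}")

    @property
    def total_duration(self) -> float:
        return self.phases[-1][2] - self.phases[0][1]


@dataclass
class TrajectoryTable:
    """Validated table of 3D tracking records.

    ``data`` holds one row per (track_id, frame) with columns
    ``track_id, frame, t, x, y, z``; rows are sorted by track then frame.
    Within a track, frames strictly increase and t = frame / frame_rate.
    """

    data: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.data = canonicalize(self.data)

    @classmethod
    def empty(cls, frame_rate: float = DEFAULT_FRAME_RATE) -> "TrajectoryTable":
        return cls(
            pd.DataFrame(
                {
                    "track_id": pd.Series(dtype="int64"),
                    "frame": pd.Series(dtype="int64"),
                    "t": pd.Series(dtype="float64"),
                    "x": pd.Series(dtype="float64"),
                    "y": pd.Series(dtype="float64"),
                    "z": pd.Series(dtype="float64"),
                }
            ),
            frame_rate=frame_rate,
        )

    @classmethod
    def from_records(
        cls,
        track_id: Sequence[int],
        frame: Sequence[int],
        xyz: np.ndarray,
        frame_rate: float = DEFAULT_FRAME_RATE,
    ) -> "TrajectoryTable":
        frame = np.asarray(frame, dtype=np.int64)
        xyz = np.asarray(xyz, dtype=float)
        df = pd.DataFrame(
            {
                "track_id": np.asarray(track_id, dtype=np.int64),
                "frame": frame,
                "t": frame / frame_rate,
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
            }
        )
        return cls(df, frame_rate=frame_rate)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def iter_tracks(self) -> Iterable[tuple[int, pd.DataFrame]]:
        yield from self.data.groupby("track_id", sort=True)

    def track_lengths(self) -> pd.Series:
        """Number of frames per track id."""
        return self.data.groupby("track_id", sort=True).size()

    def validate(self, layout: ArenaLayout | None = None) -> None:
        """Check table invariants; raise ValidationError with offenders named."""
        df = self.data
        if df.empty:
            return
        grouped = df.groupby("track_id", sort=False)["frame"]
        bad = [tid for tid, frames in grouped if np.any(np.diff(frames.to_numpy()) <= 0)]
        if bad:
            raise ValidationError(
                f"non-monotone frame sequence within track(s) {bad[:5]}"
            )
        dt_err = np.abs(df["t"].to_numpy() - df["frame"].to_numpy() / self.frame_rate)
        if np.any(dt_err > TIME_TOL):
            rows = np.flatnonzero(dt_err > TIME_TOL)
            raise ValidationError(
                f"t does not equal frame/frame_rate at rows {rows[:5].tolist()}"
            )
        if layout is not None:
            (xlo, xhi), (ylo, yhi), (zlo, zhi) = layout.bounds
            pos = df[["x", "y", "z"]].to_numpy()
            lo = np.array([xlo, ylo, zlo])
            hi = np.array([xhi, yhi, zhi])
            oob = np.any((pos < lo) | (pos > hi), axis=1)
            if np.any(oob):
                rows = np.flatnonzero(oob)
                raise ValidationError(
                    f"{oob.sum()} record(s) outside the arena bounding box, "
                    f"first at rows {rows[:5].tolist()}"
                )

    def equals(self, other: "TrajectoryTable") -> bool:
        return (
            self.frame_rate == other.frame_rate
            and self.data.shape == other.data.shape
            and bool(
                np.all(self.data["track_id"].to_numpy() == other.data["track_id"].to_numpy())
            )
            and bool(np.all(self.data["frame"].to_numpy() == other.data["frame"].to_numpy()))
            and np.allclose(
                self.data[["t", "x", "y", "z"]].to_numpy(),
                other.data[["t", "x", "y", "z"]].to_numpy(),
                rtol=0,
                atol=0,
                equal_nan=True,
            )
        )


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and impose the canonical (track_id, frame) sort order."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}; expected {COLUMNS}")
    df = df[COLUMNS].copy()
    df["track_id"] = df["track_id"].astype(np.int64)
    df["frame"] = df["frame"].astype(np.int64)
    for c in ("t", "x", "y", "z"):
        df[c] = df[c].astype(np.float64)
    if np.any(df["frame"].to_numpy() < 0):
        raise ValidationError("negative frame numbers")
    df = df.sort_values(["track_id", "frame"], kind="mergesort", ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Readers / writers

def read_trajectories(
    path: str | Path,
    format: Literal["csv", "hdf"] | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    layout: ArenaLayout | None = None,
) -> TrajectoryTable:
    """Read a trajectory table from CSV or an HDF5 container.

    ``format=None`` infers from the suffix (.csv / .h5 / .hdf5). The returned
    table is validated: non-monotone frames within a track or out-of-bounds
    positions (when ``layout`` is given) raise :class:`ValidationError` naming
    the offending tracks/rows rather than being silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise SchemaError(f"malformed CSV {path}: {exc}") from exc
        if list(df.columns) != COLUMNS:
            raise SchemaError(
                f"{path}: header {list(df.columns)} does not match {COLUMNS}"
            )
        table = TrajectoryTable(df, frame_rate=frame_rate)
    elif fmt == "hdf":
        with h5py.File(path, "r") as h5:
            if "trajectories" not in h5:
                raise SchemaError(f"{path}: no /trajectories group")
            grp = h5["trajectories"]
            cols = {}
            for c in COLUMNS:
                if c not in grp:
                    raise SchemaError(f"{path}: /trajectories missing dataset {c!r}")
                cols[c] = grp[c][...]
            frame_rate = float(grp.attrs.get("frame_rate", frame_rate))
            table = TrajectoryTable(pd.DataFrame(cols), frame_rate=frame_rate)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    table.validate(layout=layout)
    return table


def write_trajectories(
    table: TrajectoryTable,
    path: str | Path,
    format: Literal["csv", "hdf"] | None = None,
) -> Path:
    """Write a table to disk; bit-stable given identical input.

    Rows go out in canonical (track_id, frame) order. CSV uses the header
    ``track_id,frame,t,x,y,z``, UTF-8, '.' decimal, shortest round-trip float
    repr. HDF stores one dataset per column under /trajectories with
    frame_rate as a group attribute.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        table.data.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "hdf":
        with h5py.File(path, "w") as h5:
            grp = h5.create_group("trajectories")
            for c in COLUMNS:
                grp.create_dataset(c, data=table.data[c].to_numpy())
            grp.attrs["frame_rate"] = table.frame_rate
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf", ".hdf5"):
        return "hdf"
    raise ValueError(f"cannot infer trajectory format from suffix {suffix!r}")


def clip_to_phase(
    table: TrajectoryTable, schedule: PhaseSchedule, phase_name: str
) -> TrajectoryTable:
    """Restrict a table to one experimental phase.

    Keeps exactly the records with start_s <= t < end_s. Tracks straddling a
    phase boundary are split; the fragment inside the phase keeps its
    track_id, so clipping over all phases partitions every record once.
    """
    start, end = schedule.interval(phase_name)
    t = table.data["t"].to_numpy()
    mask = (t >= start) & (t < end)
    return TrajectoryTable(table.data.loc[mask], frame_rate=table.frame_rate)


# ---------------------------------------------------------------------------
# Trial configuration (plain-text YAML)

def _layout_to_dict(layout: ArenaLayout) -> dict:
    d = dataclasses.asdict(layout)
    d["source_position"] = list(layout.source_position)
    d["objects"] = [
        {**dataclasses.asdict(o), "center": list(o.center)} for o in layout.objects
    ]
    return d


def _layout_from_dict(d: dict) -> ArenaLayout:
    objects = tuple(
        VisualObjectSpec(
            label=o["label"],
            center=tuple(o["center"]),
            diameter=o.get("diameter", 3.0),
            role=o.get("role", "test"),
            spectrum_id=o.get("spectrum_id"),
        )
        for o in d.get("objects", [])
    )
    return ArenaLayout(
        length_x=d.get("length_x", 224.0),
        width_y=d.get("width_y", 61.0),
        height_z=d.get("height_z", 61.0),
        wind_speed=d.get("wind_speed", 40.0),
        source_position=tuple(d.get("source_position", (0.0, 0.0, 20.0))),
        objects=objects,
        arena_kind=d.get("arena_kind", "wind_tunnel"),
    )


def save_trial_config(
    path: str | Path,
    layout: ArenaLayout,
    schedule: PhaseSchedule,
    extra: dict | None = None,
) -> Path:
    """Serialize arena + phase schedule (+ free-form parameter blocks) to YAML."""
    doc = {
        "arena": _layout_to_dict(layout),
        "phases": [
            {"name": n, "start_s": float(s), "end_s": float(e)}
            for n, s, e in schedule.phases
        ],
    }
    if extra:
        doc.update(extra)
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_trial_config(path: str | Path) -> tuple[ArenaLayout, PhaseSchedule, dict]:
    """Load a YAML trial config; returns (layout, schedule, remaining blocks)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "arena" not in doc or "phases" not in doc:
        raise SchemaError(f"{path}: trial config needs 'arena' and 'phases' blocks")
    layout = _layout_from_dict(doc["arena"])
    schedule = PhaseSchedule(
        tuple((p["name"], float(p["start_s"]), float(p["end_s"])) for p in doc["phases"])
    )
    rest = {k: v for k, v in doc.items() if k not in ("arena", "phases")}
    return layout, schedule, rest
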