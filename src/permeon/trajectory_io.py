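"""Reading, writing and basic transforms of single-file ion trajectories.

A trajectory is a tidy table with one row per (frame, ion) observation and
columns ``frame``, ``time_ps``, ``ion_id``, ``z``.  The axial coordinate ``z``
is measured in Angstrom along the pore axis and increases toward the
extracellular side.  Frames with no tracked ion simply have no rows; the frame
grid is still uniform and is reconstructed from the observed (frame, time)
pairs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .errors import EmptyTrajectoryError, FormatError, ValidationError

REQUIRED_COLUMNS = ("frame", "time_ps", "ion_id", "z")

_POINT_COLUMNS = ("frame", "time_ps", "ion_id", "x", "y", "z")


@dataclasses.dataclass(frozen=True)
class AxisDefinition:
    """Pore axis defined by two 3-D reference points.

    ``origin`` is the intracellular anchor (maps to z = 0) and ``tip`` the
    extracellular anchor; the unit vector points from origin to tip.
    """

    origin: np.ndarray
    tip: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        if np.allclose(origin, tip):
            raise ValidationError("degenerate axis: origin and tip coincide")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "tip", tip)

    @property
    def unit(self) -> np.ndarray:
        vec = self.tip - self.origin
        return vec / np.linalg.norm(vec)

    @classmethod
    def from_reference_atoms(
        cls, inner_oxygens: np.ndarray, outer_oxygens: np.ndarray
    ) -> "AxisDefinition":
        """Build an axis from the carbonyl-oxygen positions of the four
        subunits: origin = centroid of the inner ring, tip = centroid of the
        outer ring."""
        inner = np.asarray(inner_oxygens, dtype=float).reshape(-1, 3)
        outer = np.asarray(outer_oxygens, dtype=float).reshape(-1, 3)
        return cls(origin=inner.mean(axis=0), tip=outer.mean(axis=0))


@dataclasses.dataclass
class IonTrajectory:
    """Validated, time-ordered table of axial ion positions.

    Attributes
    ----------
    frames:
        DataFrame with columns ``frame``, ``time_ps``, ``ion_id``, ``z``,
        sorted by (frame, ion_id).
    frame_interval:
        Spacing of the frame grid in ps (0.0 for a single-frame trajectory).
    frame_range:
        Optional (first, last) frame of the full grid when it extends beyond
        the observed rows (frames with an empty pore carry no rows).  Known
        for generated trajectories; a plain table file cannot record it.
    """

    frames: pd.DataFrame
    frame_interval: float
    frame_range: tuple[int, int] | None = None

    def _grid(self) -> tuple[int, int, float]:
        """(first frame, last frame, time of first frame) of the full grid."""
        f_obs = int(self.frames["frame"].min())
        t_obs = float(self.frames["time_ps"].min())
        if self.frame_range is None:
            return f_obs, int(self.frames["frame"].max()), t_obs
        f0, f1 = self.frame_range
        return int(f0), int(f1), t_obs - (f_obs - int(f0)) * self.frame_interval

    @property
    def start_time(self) -> float:
        return self._grid()[2]

    @property
    def end_time(self) -> float:
        f0, f1, t0 = self._grid()
        return t0 + (f1 - f0) * self.frame_interval

    @property
    def duration(self) -> float:
        """Total analyzed span in ps (last grid frame time minus first)."""
        return self.end_time - self.start_time

    @property
    def n_frames(self) -> int:
        f0, f1, _ = self._grid()
        return f1 - f0 + 1

    @property
    def ions(self) -> list:
        return sorted(self.frames["ion_id"].unique().tolist())

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "IonTrajectory":
        frames, interval = _validate_table(table)
        return cls(frames=frames, frame_interval=interval)


def _validate_table(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if len(table) == 0:
        raise EmptyTrajectoryError("trajectory table has no rows")
    df = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["frame"] = df["frame"].astype(np.int64)
    df["time_ps"] = df["time_ps"].astype(float)
    df["z"] = df["z"].astype(float)

    dup = df.duplicated(subset=["frame", "ion_id"])
    if dup.any():
        rows = df.loc[dup, ["frame", "ion_id"]].head(3).to_dict("records")
        raise ValidationError(f"duplicate (frame, ion_id) rows, e.g. {rows}")

    grid = df.drop_duplicates("frame").sort_values("frame")
    times = grid["time_ps"].to_numpy()
    frames = grid["frame"].to_numpy()
    if np.any(np.diff(times) <= 0):
        raise ValidationError("frame times are not strictly increasing")
    interval = 0.0
    if len(grid) > 1:
        # Frames with an empty pore carry no rows, so the observed frame
        # numbers may have gaps; times must still sit on one uniform grid.
        span_f = frames - frames[0]
        interval = float(np.min(np.diff(times) / np.diff(frames)))
        expected = times[0] + span_f * interval
        if not np.allclose(times, expected, rtol=1e-6, atol=1e-6):
            raise ValidationError("frame times are not evenly spaced")
    return df.sort_values(["frame", "ion_id"]).reset_index(drop=True), interval


def _sep_for(path: Union[str, Path], fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise FormatError(f"unsupported trajectory format: {fmt!r}")
    return "," if fmt == "csv" else "\t"


def read_trajectory(path: Union[str, Path], fmt: str | None = None) -> IonTrajectory:
    """Read a trajectory table from a TSV/CSV file and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path, sep=_sep_for(path, fmt))
    except pd.errors.ParserError as exc:  # pragma: no cover - depends on file
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return IonTrajectory.from_table(table)


def write_trajectory(
    traj: IonTrajectory, path: Union[str, Path], fmt: str | None = None
) -> None:
    """Write the trajectory table; lossless round-trip with read_trajectory."""
    traj.frames.to_csv(path, sep=_sep_for(path, fmt), index=False)


def project_to_axis(
    points: pd.DataFrame,
    axis: Union[AxisDefinition, Mapping[int, AxisDefinition]],
) -> IonTrajectory:
    """Project 3-D ion coordinates onto the pore axis.

    Parameters
    ----------
    points:
        Table with columns ``frame``, ``time_ps``, ``ion_id``, ``x``, ``y``,
        ``z`` (laboratory coordinates in Angstrom).
    axis:
        Either one fixed :class:`AxisDefinition` or a mapping frame -> axis
        when the reference atoms move (per-frame axis).

    The axial coordinate of a point p is ``dot(p - origin, unit)``; the
    origin maps to 0 and the tip to ``|tip - origin|``.
    """
    missing = [c for c in _POINT_COLUMNS if c not in points.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    xyz = points[["x", "y", "z"]].to_numpy(dtype=float)
    if isinstance(axis, AxisDefinition):
        proj = (xyz - axis.origin) @ axis.unit
    else:
        proj = np.empty(len(points), dtype=float)
        for i, (frame, row) in enumerate(zip(points["frame"].to_numpy(), xyz)):
            try:
                ax = axis[int(frame)]
            except KeyError as exc:
                raise ValidationError(f"no axis defined for frame {frame}") from exc
            proj[i] = (row - ax.origin) @ ax.unit
    out = points[["frame", "time_ps", "ion_id"]].copy()
    out["z"] = proj
    return IonTrajectory.from_table(out)


def trim_equilibration(traj: IonTrajectory, t_cut: float) -> IonTrajectory:
    """Drop all frames with ``time_ps`` < ``t_cut`` (equilibration period)."""
    if t_cut < 0:
        raise ValidationError("t_cut must be non-negative")
    if t_cut == 0:
        return traj
    kept = traj.frames[traj.frames["time_ps"] >= t_cut]
    if len(kept) == 0:
        raise EmptyTrajectoryError(
            f"t_cut = {t_cut} ps removes every frame "
            f"(trajectory ends at {traj.end_time} ps)"
        )
    frame_range = None
    if traj.frame_range is not None and traj.frame_interval > 0:
        f0, f1, t0 = traj._grid()
        new_f0 = f0 + int(np.ceil((t_cut - t0) / traj.frame_interval))
        frame_range = (max(f0, new_f0), f1)
    return IonTrajectory(
        frames=kept.reset_index(drop=True),
        frame_interval=traj.frame_interval,
        frame_range=frame_range,
    )


def voltage_from_field(e_field: float, l_z: float) -> float:
    """Membrane voltage V = L_z * E for a constant applied field.

    ``e_field`` in mV/Angstrom, ``l_z`` (simulation-cell length along the
    pore axis) in Angstrom; result in mV.
    """
    if l_z <= 0:
        raise ValidationError("cell length L_z must be positive")
    return l_z * e_field
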