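"""Recording data model and file I/O.

The pipeline works on three in-memory objects:

``GrfRecording``
    The anteroposterior ground reaction force (AP-GRF) of the two treadmill
    belts, one channel per force plate, in newtons.  The sign convention is
    anterior-positive: the propulsive lobe of the stance curve is positive,
    the braking lobe negative.  Sources that export posterior-positive
    forces are flipped at read time via the dialect.
``MarkerSet``
    Anteroposterior and mediolateral coordinates (metres) of the foot
    markers (calcaneus = heel, second metatarsal head = toe) and a pelvis
    reference (mean of the iliac-spine markers).  Only these landmarks are
    needed for stance estimation and crossover detection.
``ConditionSchedule``
    The list of belt-speed conditions a participant walked, with durations
    following the protocol rule (speed > 0.4 m/s: 120 s, else 180 s), plus
    participant metadata (group, paretic side, comfortable walking speed,
    body mass).

CSV dialects are explicit configuration, never sniffed: treadmill exports
vary too much in column naming, units, and sign conventions for
auto-detection to be safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError, UnsupportedFileError

#: Marker labels the pipeline requires (AP and ML coordinate per label).
REQUIRED_MARKERS = ("l_heel", "r_heel", "l_toe", "r_toe", "pelvis")


@dataclass
class GrfRecording:
    """Per-plate AP-GRF time series for one gait-speed condition.

    Parameters
    ----------
    ap_left, ap_right
        AP-GRF of the left and right belt's force plate, newtons,
        anterior (propulsive) positive.
    fs_force
        Sampling rate in Hz (native 1000).
    body_mass_kg
        Participant body mass, used for normalization to N/kg.
    condition_id
        Identifier linking the recording to a schedule entry.
    v_left, v_right
        Optional vertical force channels (newtons), not used by the
        propulsion analysis itself.
    """

    ap_left: np.ndarray
    ap_right: np.ndarray
    fs_force: float
    body_mass_kg: float
    condition_id: str = ""
    v_left: Optional[np.ndarray] = None
    v_right: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ap_left = np.asarray(self.ap_left, dtype=float)
        self.ap_right = np.asarray(self.ap_right, dtype=float)
        if self.ap_left.shape != self.ap_right.shape or self.ap_left.ndim != 1:
            raise ParameterError("plate channels must be 1-D and of equal length")
        if not self.fs_force > 0:
            raise ParameterError("fs_force must be positive")
        if not self.body_mass_kg > 0:
            raise ParameterError("body_mass_kg must be positive")

    @property
    def n_samples(self) -> int:
        return self.ap_left.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_force


@dataclass
class MarkerSet:
    """Foot and pelvis marker trajectories.

    ``ap`` and ``ml`` map marker labels (see :data:`REQUIRED_MARKERS`) to
    1-D arrays in metres, all of equal length, sampled at ``fs_marker`` Hz
    (native 100).  The AP axis is the belt travel axis (anterior positive);
    the ML axis is used only for crossover detection, with the left belt on
    the negative side of the configured midline.
    """

    ap: dict
    ml: dict
    fs_marker: float

    def __post_init__(self) -> None:
        for name in REQUIRED_MARKERS:
            if name not in self.ap or name not in self.ml:
                missing = [m for m in REQUIRED_MARKERS if m not in self.ap or m not in self.ml]
                raise FormatError(f"marker set is missing required labels: {missing}")
        self.ap = {k: np.asarray(v, dtype=float) for k, v in self.ap.items()}
        self.ml = {k: np.asarray(v, dtype=float) for k, v in self.ml.items()}
        lengths = {v.size for v in self.ap.values()} | {v.size for v in self.ml.values()}
        if len(lengths) != 1:
            raise ParameterError("all marker trajectories must share one length")
        if not self.fs_marker > 0:
            raise ParameterError("fs_marker must be positive")

    @property
    def n_samples(self) -> int:
        return next(iter(self.ap.values())).size


@dataclass
class ConditionEntry:
    condition_id: str
    belt_speed: float
    duration_s: float
    is_cws: bool = False


@dataclass
class ParticipantMeta:
    participant_id: str
    group: str  # "stroke" | "control"
    paretic_side: str  # "left" | "right" | "none"
    cws: float
    body_mass_kg: float


@dataclass
class ConditionSchedule:
    """Ordered speed conditions for one participant, with metadata."""

    meta: ParticipantMeta
    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.belt_speed > 0:
                raise ParameterError(f"{e.condition_id}: belt speed must be > 0")
            expected = 180.0 if e.belt_speed <= 0.4 else 120.0
            if abs(e.duration_s - expected) > 1e-9:
                raise ParameterError(
                    f"{e.condition_id}: duration {e.duration_s} s violates the "
                    f"protocol rule ({expected} s for speed {e.belt_speed} m/s)"
                )

    def cws_entry(self) -> Optional[ConditionEntry]:
        for e in self.entries:
            if e.is_cws:
                return e
        return None


# ---------------------------------------------------------------------------
# CSV dialect and readers
# ---------------------------------------------------------------------------

@dataclass
class CsvDialect:
    """Column mapping for delimited treadmill exports.

    ``force_scale`` converts stored force values to newtons (1000.0 for a
    kilonewton export); ``marker_scale`` converts marker coordinates to
    metres (0.001 for millimetres).  ``anterior_positive=False`` flips the
    force sign so propulsion is positive in memory.
    """

    time_col: str = "time"
    ap_left_col: str = "ap_left"
    ap_right_col: str = "ap_right"
    force_scale: float = 1.0
    anterior_positive: bool = True
    marker_scale: float = 1.0
    # marker files: "<label>_ap" / "<label>_ml" columns by default
    marker_ap_suffix: str = "_ap"
    marker_ml_suffix: str = "_ml"

    @classmethod
    def from_yaml(cls, path) -> "CsvDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        bad = set(raw) - known
        if bad:
            raise FormatError(f"unknown dialect fields: {sorted(bad)}")
        return cls(**raw)


def _fs_from_time(time: np.ndarray, path) -> float:
    dt = np.diff(time)
    if time.size < 2 or np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise FormatError(f"{path}: time column is not uniformly sampled")
    return float(1.0 / dt.mean())


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mapped column(s) {missing}")


def read_recording_csv(
    path,
    dialect: CsvDialect,
    *,
    body_mass_kg: float = 1.0,
    condition_id: str = "",
    marker_path=None,
) -> tuple:
    """Read a force CSV (and optionally a marker CSV) into memory.

    The force file must contain the dialect's time column and one AP-GRF
    column per plate; the optional marker file must contain a time column
    and ``<label>_ap`` / ``<label>_ml`` columns for every required marker.
    Force and marker files may be sampled at different rates.

    Returns ``(GrfRecording, MarkerSet | None)``.
    """
    df = pd.read_csv(path)
    _require_columns(df, [dialect.time_col, dialect.ap_left_col, dialect.ap_right_col], path)
    fs = _fs_from_time(df[dialect.time_col].to_numpy(dtype=float), path)
    sign = 1.0 if dialect.anterior_positive else -1.0
    rec = GrfRecording(
        ap_left=sign * dialect.force_scale * df[dialect.ap_left_col].to_numpy(dtype=float),
        ap_right=sign * dialect.force_scale * df[dialect.ap_right_col].to_numpy(dtype=float),
        fs_force=fs,
        body_mass_kg=body_mass_kg,
        condition_id=condition_id,
    )
    markers = None
    if marker_path is not None:
        mdf = pd.read_csv(marker_path)
        need = [dialect.time_col]
        for label in REQUIRED_MARKERS:
            need += [label + dialect.marker_ap_suffix, label + dialect.marker_ml_suffix]
        _require_columns(mdf, need, marker_path)
        fs_m = _fs_from_time(mdf[dialect.time_col].to_numpy(dtype=float), marker_path)
        s = dialect.marker_scale
        markers = MarkerSet(
            ap={m: s * mdf[m + dialect.marker_ap_suffix].to_numpy(dtype=float) for m in REQUIRED_MARKERS},
            ml={m: s * mdf[m + dialect.marker_ml_suffix].to_numpy(dtype=float) for m in REQUIRED_MARKERS},
            fs_marker=fs_m,
        )
    return rec, markers


def write_recording_csv(rec: GrfRecording, markers, force_path, marker_path=None,
                        dialect: CsvDialect = None) -> None:
    """Write a recording (and optionally markers) in the default dialect."""
    dialect = dialect or CsvDialect()
    t = np.arange(rec.n_samples) / rec.fs_force
    pd.DataFrame({
        dialect.time_col: t,
        dialect.ap_left_col: rec.ap_left,
        dialect.ap_right_col: rec.ap_right,
    }).to_csv(force_path, index=False)
    if markers is not None and marker_path is not None:
        tm = np.arange(markers.n_samples) / markers.fs_marker
        cols = {dialect.time_col: tm}
        for m in REQUIRED_MARKERS:
            cols[m + dialect.marker_ap_suffix] = markers.ap[m]
            cols[m + dialect.marker_ml_suffix] = markers.ml[m]
        pd.DataFrame(cols).to_csv(marker_path, index=False)


# ---------------------------------------------------------------------------
# C3D (optional backend)
# ---------------------------------------------------------------------------

def _require_ezc3d():
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional extra
        raise UnsupportedFileError(
            "C3D support requires the optional dependency ezc3d "
            "(install gaitprop[c3d]); use the CSV reader otherwise"
        ) from exc
    return ezc3d


def read_recording_c3d(path, *, body_mass_kg: float = 1.0, condition_id: str = "",
                       ap_axis: int = 1, anterior_positive: bool = True,
                       marker_map: dict = None):  # pragma: no cover - optional extra
    """Read a C3D file with >=2 force platforms into (GrfRecording, MarkerSet).

    ``marker_map`` maps the pipeline's labels to the file's point labels;
    the AP axis index within the lab frame is configuration, not
    auto-detected.
    """
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d(str(path), extract_forceplat_data=True)
    plats = c3d["data"]["platform"]
    if len(plats) < 2:
        raise UnsupportedFileError(f"{path}: need >=2 force platforms, found {len(plats)}")
    sign = 1.0 if anterior_positive else -1.0
    rec = GrfRecording(
        ap_left=sign * np.asarray(plats[0]["force"][ap_axis], dtype=float),
        ap_right=sign * np.asarray(plats[1]["force"][ap_axis], dtype=float),
        fs_force=float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0]),
        body_mass_kg=body_mass_kg,
        condition_id=condition_id,
    )
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    marker_map = marker_map or {m: m for m in REQUIRED_MARKERS}
    missing = [v for v in marker_map.values() if v not in labels]
    if missing:
        raise FormatError(f"{path}: required marker labels absent: {missing}")
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames), millimetres
    ml_axis = 0 if ap_axis != 0 else 1
    ap, ml = {}, {}
    for ours, theirs in marker_map.items():
        i = labels.index(theirs)
        ap[ours] = sign * pts[ap_axis, i, :] * 0.001
        ml[ours] = pts[ml_axis, i, :] * 0.001
    markers = MarkerSet(ap=ap, ml=ml,
                        fs_marker=float(c3d["parameters"]["POINT"]["RATE"]["value"][0]))
    return rec, markers


# ---------------------------------------------------------------------------
# Observation table
# ---------------------------------------------------------------------------

#: Stable column order of the long-format observation table (one row per
#: participant x condition x leg).
OBSERVATION_COLUMNS = [
    "participant_id", "group", "condition_id", "speed", "is_cws", "leg",
    "peak", "impulse", "n_steps",
    "peak_symmetry", "impulse_symmetry",
    "peak_symmetry_at_cws", "impulse_symmetry_at_cws",
]


def write_observation_table(rows, path) -> None:
    """Write observation rows (dataclasses or dicts) as a long-format CSV."""
    rows = list(rows)
    if not rows:
        raise ParameterError("refusing to write an empty observation table")
    dicts = [r if isinstance(r, dict) else vars(r) for r in rows]
    schemas = {tuple(sorted(d)) for d in dicts}
    if len(schemas) != 1:
        raise ParameterError("observation rows have mixed schemas")
    df = pd.DataFrame(dicts)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"observation rows lack required fields {missing}")
    df[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_observation_table(path) -> pd.DataFrame:
    """Read an observation table written by :func:`write_observation_table`."""
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: not an observation table (missing {missing})")
    return df[OBSERVATION_COLUMNS]
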