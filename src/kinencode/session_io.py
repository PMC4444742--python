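"""Session data model and plain-text I/O.

A recording session is a triplet: a 2D head-tracking series (LED position in
mm at a nominal 30 frames/s), per-unit spike timestamp lists with metadata,
and task event timestamps (cue onsets, outcome deliveries, optional
optogenetic stimulation trains).  Everything is stored as CSV/JSON so that
sessions — real or synthetic — round-trip losslessly through text files.

Conventions
-----------
* All times are seconds as floats; a session nominally starts at t = 0.
* Positions are mm in the animal's frame: x increases rightward, y upward.
  Data digitised from a camera facing the animal can be flipped at load with
  ``camera_mirrored_x=True``.
* Tracking gaps longer than three nominal frame intervals are treated as
  dropouts and masked out of all downstream correlation analysis rather than
  interpolated across.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kinencode")

FLOAT_FMT = "%.12g"  # fixed text formatting => byte-stable, <1e-9 rel round-trip

OUTCOME_TYPES = ("sucrose", "airpuff")
HEMISPHERES = ("left", "right", "unknown")
CELL_CLASSES = ("DA", "GABA", "unknown")


class SessionValidationError(ValueError):
    """An invariant of the session data model was violated."""


class SessionParseError(ValueError):
    """A session file could not be parsed."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SessionValidationError(f"{name} must be 1-dimensional")
    return arr


@dataclass
class TrackingSeries:
    """Timestamped 2D head position in mm.

    ``t`` must be strictly increasing; ``x``/``y`` finite; at least two
    samples.  ``frame_rate_nominal`` is the nominal camera rate in Hz used to
    detect dropout gaps.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate_nominal: float = 30.0

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.validate()

    def validate(self) -> None:
        if len(self.t) < 2:
            raise SessionValidationError("tracking requires length >= 2")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise SessionValidationError("t, x, y must have equal length")
        if not np.all(np.isfinite(self.t)):
            raise SessionValidationError("t must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise SessionValidationError("t strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise SessionValidationError("x,y must be finite")
        if self.frame_rate_nominal <= 0:
            raise SessionValidationError("frame_rate_nominal must be > 0")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def dropout_intervals(self, gap_factor: float = 3.0) -> list[tuple[float, float]]:
        """Intervals between samples separated by more than ``gap_factor``
        nominal frame intervals.  Kinematics inside them are masked."""
        max_gap = gap_factor / self.frame_rate_nominal
        dt = np.diff(self.t)
        idx = np.nonzero(dt > max_gap)[0]
        return [(float(self.t[i]), float(self.t[i + 1])) for i in idx]

    def mirrored_x(self) -> "TrackingSeries":
        """Flip the x axis (camera-facing-animal convention -> animal frame)."""
        return TrackingSeries(self.t.copy(), -self.x, self.y.copy(),
                              self.frame_rate_nominal)


@dataclass
class SessionEvents:
    """Task events: per-trial cue onset / outcome time / outcome type, plus
    optional optogenetic stimulation trains as (onset, offset, frequency_hz)."""

    cue_onsets: np.ndarray
    outcome_times: np.ndarray
    outcome_types: list[str]
    stim_trains: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cue_onsets = _as_float_array(self.cue_onsets, "cue_onsets")
        self.outcome_times = _as_float_array(self.outcome_times, "outcome_times")
        self.outcome_types = list(self.outcome_types)
        self.stim_trains = [tuple(map(float, tr)) for tr in self.stim_trains]
        self.validate()

    def validate(self) -> None:
        n = len(self.cue_onsets)
        if not (len(self.outcome_times) == len(self.outcome_types) == n):
            raise SessionValidationError("per-trial event arrays must align")
        if np.any(self.outcome_times <= self.cue_onsets):
            raise SessionValidationError("each outcome_time > its paired cue_onset")
        for ot in self.outcome_types:
            if ot not in OUTCOME_TYPES:
                raise SessionValidationError(f"unknown outcome_type {ot!r}")
        trains = sorted(self.stim_trains)
        for (on, off, f) in trains:
            if off <= on:
                raise SessionValidationError("stim train offset must exceed onset")
            if f <= 0:
                raise SessionValidationError("stim frequency must be > 0")
        for (_, off_a, _), (on_b, _, _) in zip(trains, trains[1:]):
            if on_b < off_a:
                raise SessionValidationError("stim trains must be non-overlapping")

    @property
    def n_trials(self) -> int:
        return len(self.cue_onsets)

    def all_times(self) -> np.ndarray:
        parts = [self.cue_onsets, self.outcome_times]
        for on, off, _ in self.stim_trains:
            parts.append(np.array([on, off]))
        return np.concatenate(parts) if parts else np.empty(0)


@dataclass
class UnitRecording:
    """One sorted single unit: spike timestamps plus recording metadata.

    ``spike_width_fwhm`` is the waveform full width at half maximum in ms;
    it may be ``None`` when no waveform metadata was kept (such units cannot
    be cell-type classified).  ``isolation_snr`` is pass-through metadata
    (signal-to-noise of the sorted waveform); it is never computed here.
    """

    unit_id: str
    spike_times: np.ndarray
    hemisphere: str = "unknown"
    mean_rate: float = 0.0
    spike_width_fwhm: float | None = None
    putative_class: str = "unknown"
    isolation_snr: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = _as_float_array(self.spike_times, "spike_times")
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.spike_times) < 0):
            raise SessionValidationError("spike_times sorted")
        if len(self.spike_times) and self.spike_times[0] < 0:
            raise SessionValidationError("spike_times non-negative")
        if self.hemisphere not in HEMISPHERES:
            raise SessionValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.putative_class not in CELL_CLASSES:
            raise SessionValidationError(f"unknown putative_class {self.putative_class!r}")
        if self.mean_rate < 0:
            raise SessionValidationError("mean_rate >= 0")
        if self.spike_width_fwhm is not None and self.spike_width_fwhm <= 0:
            raise SessionValidationError("fwhm > 0 when present")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class SessionBundle:
    """A complete session: tracking + events + units + provenance metadata."""

    tracking: TrackingSeries
    events: SessionEvents
    units: list[UnitRecording]
    provenance: dict = field(default_factory=dict)
    spike_span_tolerance: float = 1.0  # s of slack allowed beyond tracking span

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.tracking.span
        ev = self.events.all_times()
        if ev.size and (ev.min() < lo or ev.max() > hi):
            raise SessionValidationError("all event times within tracking time span")
        tol = self.spike_span_tolerance
        for u in self.units:
            if u.n_spikes and (u.spike_times[0] < lo - tol or u.spike_times[-1] > hi + tol):
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike times within tracking span +/- tolerance")

    def unit(self, unit_id: str) -> UnitRecording:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise SessionParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed rows, bad encoding, ...
        raise SessionParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionParseError(f"{path}: missing columns {missing}")
    for col in required:
        if col in ("outcome_type",):
            continue
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise SessionParseError(
                f"{path}: line {int(bad[0]) + 2}: non-numeric value in column {col!r}")
    return df


def read_session(directory: str | Path, camera_mirrored_x: bool = False) -> SessionBundle:
    """Load a session from ``directory`` (schemas in the module docstring).

    Raises :class:`SessionParseError` for malformed files and
    :class:`SessionValidationError` for invariant violations.
    """
    d = Path(directory)
    trk = _read_csv(d / "tracking.csv", ["t", "x", "y"])
    meta = {}
    prov_path = d / "provenance.json"
    if prov_path.exists():
        meta = json.loads(prov_path.read_text())
    tracking = TrackingSeries(
        trk["t"].to_numpy(float), trk["x"].to_numpy(float), trk["y"].to_numpy(float),
        frame_rate_nominal=float(meta.get("frame_rate_nominal", 30.0)))
    if camera_mirrored_x:
        tracking = tracking.mirrored_x()

    ev = _read_csv(d / "events.csv", ["trial", "cue_onset", "outcome_time", "outcome_type"])
    stim: list[tuple[float, float, float]] = []
    stim_path = d / "stim.csv"
    if stim_path.exists():
        sdf = _read_csv(stim_path, ["onset", "offset", "frequency_hz"])
        stim = [(float(r.onset), float(r.offset), float(r.frequency_hz))
                for r in sdf.itertuples()]
    events = SessionEvents(
        ev["cue_onset"].to_numpy(float), ev["outcome_time"].to_numpy(float),
        [str(v) for v in ev["outcome_type"]], stim)

    units: list[UnitRecording] = []
    units_dir = d / "units"
    if units_dir.exists():
        umeta = json.loads((units_dir / "meta.json").read_text())
        for unit_id in sorted(umeta):
            m = umeta[unit_id]
            spikes = _read_csv(units_dir / f"{unit_id}.csv", ["spike_time"])
            fwhm = m.get("fwhm_ms")
            units.append(UnitRecording(
                unit_id=unit_id,
                spike_times=spikes["spike_time"].to_numpy(float),
                hemisphere=m.get("hemisphere", "unknown"),
                mean_rate=float(m.get("mean_rate", 0.0)),
                spike_width_fwhm=None if fwhm is None else float(fwhm),
                putative_class=m.get("putative_class", "unknown"),
                isolation_snr=m.get("isolation_snr"),
            ))
    return SessionBundle(tracking, events, units, provenance=meta.get("provenance", meta))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_session(bundle: SessionBundle, directory: str | Path) -> list[Path]:
    """Write ``bundle`` to ``directory``; returns the files written.

    ``read_session(write_session(b))`` reproduces ``b`` to <=1e-9 relative
    float round-trip; output bytes are deterministic for a given bundle.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    trk = pd.DataFrame({"t": bundle.tracking.t, "x": bundle.tracking.x,
                        "y": bundle.tracking.y})
    _write_csv(trk, d / "tracking.csv")
    written.append(d / "tracking.csv")

    ev = bundle.events
    _write_csv(pd.DataFrame({
        "trial": np.arange(ev.n_trials, dtype=int),
        "cue_onset": ev.cue_onsets,
        "outcome_time": ev.outcome_times,
        "outcome_type": ev.outcome_types,
    }), d / "events.csv")
    written.append(d / "events.csv")

    if ev.stim_trains:
        _write_csv(pd.DataFrame(ev.stim_trains,
                                columns=["onset", "offset", "frequency_hz"]),
                   d / "stim.csv")
        written.append(d / "stim.csv")

    units_dir = d / "units"
    units_dir.mkdir(exist_ok=True)
    meta = {}
    for u in bundle.units:
        _write_csv(pd.DataFrame({"spike_time": u.spike_times}),
                   units_dir / f"{u.unit_id}.csv")
        written.append(units_dir / f"{u.unit_id}.csv")
        meta[u.unit_id] = {
            "hemisphere": u.hemisphere,
            "mean_rate": u.mean_rate,
            "fwhm_ms": u.spike_width_fwhm,
            "putative_class": u.putative_class,
            "isolation_snr": u.isolation_snr,
        }
    (units_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(units_dir / "meta.json")

    prov = {"frame_rate_nominal": bundle.tracking.frame_rate_nominal,
            "provenance": bundle.provenance}
    (d / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    written.append(d / "provenance.json")
    return written


def write_report(results: Iterable, population: dict, directory: str | Path) -> list[Path]:
    """Write per-unit classifications (CSV) and population statistics (JSON).

    ``results`` is an iterable of ``EncodingResult``.  Regenerating the report
    from the same inputs yields identical bytes.
    """
    from .encoding_analysis import EncodingResult  # local import: no cycle at module load

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        assert isinstance(res, EncodingResult)
        rows.append({
            "unit_id": res.unit_id,
            "class_variable": res.class_quantity,
            "direction": res.class_direction,
            "sign": res.sign,
            "best_lag_s": res.class_lag_s,
            "r": res.class_r,
            "p": res.class_p,
        })
    if not rows:
        raise ValueError("write_report requires non-empty results")
    df = pd.DataFrame(rows, columns=["unit_id", "class_variable", "direction",
                                     "sign", "best_lag_s", "r", "p"])
    _write_csv(df, d / "classifications.csv")

    pop = dict(population)
    if not any(r["class_variable"] != "uncorrelated" for r in rows):
        pop["note"] = "no classified units"
    (d / "population.json").write_text(
        json.dumps(pop, indent=2, sort_keys=True, default=_json_default))
    return [d / "classifications.csv", d / "population.json"]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
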