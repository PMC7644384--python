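"""Canonical data model for pen recordings and the on-disk session format.

A session is a set of trials recorded on one device. On disk two dialects are
supported: a long-format CSV (one row per pen sample, trial metadata repeated
on every row, device metadata on a ``#device`` first line) and a nested JSON
document. After reading, coordinates are always millimetres in a y-up frame
(origin at the canvas bottom-left) regardless of the on-disk convention, so
speeds and lengths are comparable across devices.

Trials that violate an invariant are quarantined with reasons on
``SessionData.invalid`` — reported, never silently dropped.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import EmptyTrialError, SchemaError, ValidationError

GROUPS = ("kindergarten", "primary")
GAMES = ("copy", "tunnel")
ITEMS = ("word_mele", "circle", "square", "triangle", "sequence", "word_ele")
MODALITIES = ("spontaneous", "big", "small", "fast", "slow")

CSV_COLUMNS = [
    "subject_id", "group", "game", "item", "modality", "geometry_id",
    "trial_index", "t", "x", "y", "pen_down", "pressure",
]


@dataclass(frozen=True)
class PenSample:
    """One timestamped pen sample in canonical units (seconds, mm, y-up)."""

    t: float
    x: float
    y: float
    pen_down: bool
    pressure: float | None = None


@dataclass
class DeviceInfo:
    """On-disk coordinate convention of the recording device.

    ``canvas_height_px`` is required only when ``y_axis == "down"`` (the flip
    needs a reference height). Canonical sessions use ``pixels_per_mm=1``,
    ``y_axis="up"``.
    """

    pixels_per_mm: float = 1.0
    y_axis: str = "up"  # "up" | "down"
    canvas_height_px: float | None = None

    def to_dict(self) -> dict:
        d = {"pixels_per_mm": self.pixels_per_mm, "y_axis": self.y_axis}
        if self.canvas_height_px is not None:
            d["canvas_height_px"] = self.canvas_height_px
        return d


@dataclass
class TrialRecording:
    """One pen execution: sample columns plus trial metadata.

    Samples are stored as parallel numpy arrays for efficiency; ``samples``
    yields :class:`PenSample` rows. ``truth`` carries generator ground truth
    on synthetic trials and is never serialized.
    """

    subject_id: str
    group: str
    game: str
    item: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pen_down: np.ndarray
    pressure: np.ndarray | None = None
    modality: str | None = None
    geometry_id: str | None = None
    trial_index: int = 0
    manual_boundaries: list[int] | None = None
    truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pen_down = np.asarray(self.pen_down, dtype=bool)
        if self.pressure is not None:
            self.pressure = np.asarray(self.pressure, dtype=float)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> list[PenSample]:
        press = self.pressure if self.pressure is not None else [None] * len(self)
        return [
            PenSample(float(t), float(x), float(y), bool(d),
                      None if p is None or np.isnan(p) else float(p))
            for t, x, y, d, p in zip(self.t, self.x, self.y, self.pen_down, press)
        ]

    def key(self) -> tuple:
        return (self.subject_id, self.game, self.item, self.modality,
                self.geometry_id, self.trial_index)


@dataclass
class Stroke:
    """A maximal contiguous run of pen-down samples within a trial."""

    start: int  # index of first sample in the parent trial
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SessionData:
    """A device header plus validated trials (invalid ones quarantined)."""

    device: DeviceInfo = field(default_factory=DeviceInfo)
    trials: list[TrialRecording] = field(default_factory=list)
    invalid: list[tuple[TrialRecording, list[str]]] = field(default_factory=list)


def validate_trial(trial: TrialRecording) -> list[str]:
    """Return the list of invariant violations for *trial* (empty if valid)."""
    reasons: list[str] = []
    who = f"subject={trial.subject_id} trial={trial.trial_index}"
    if trial.group not in GROUPS:
        reasons.append(f"{who}: unknown group {trial.group!r}")
    if trial.game not in GAMES:
        reasons.append(f"{who}: unknown game {trial.game!r}")
    if trial.item not in ITEMS:
        reasons.append(f"{who}: unknown item {trial.item!r}")
    n = len(trial)
    arrays = [trial.x, trial.y, trial.pen_down]
    if any(len(a) != n for a in arrays):
        reasons.append(f"{who}: ragged sample columns")
        return reasons
    if int(trial.pen_down.sum()) < 2:
        reasons.append(f"{who}: fewer than 2 pen-down samples")
    if n and not np.all(np.isfinite(trial.t)):
        reasons.append(f"{who}: non-finite timestamps")
    elif n > 1 and not np.all(np.diff(trial.t) > 0):
        reasons.append(f"{who}: timestamps not strictly increasing")
    if n and not (np.all(np.isfinite(trial.x)) and np.all(np.isfinite(trial.y))):
        reasons.append(f"{who}: non-finite coordinates")
    if trial.pressure is not None and len(trial.pressure):
        p = trial.pressure[~np.isnan(trial.pressure)]
        if p.size and (p.min() < 0 or p.max() > 1):
            reasons.append(f"{who}: pressure outside [0, 1]")
    if trial.game == "copy":
        if trial.modality not in MODALITIES:
            reasons.append(f"{who}: copy trial without a valid modality")
        if trial.geometry_id:
            reasons.append(f"{who}: copy trial carries a geometry_id")
        if trial.item == "word_ele":
            reasons.append(f"{who}: word_ele is a tunnel-only item")
    elif trial.game == "tunnel":
        if not trial.geometry_id:
            reasons.append(f"{who}: tunnel trial without geometry_id")
        if trial.modality:
            reasons.append(f"{who}: tunnel trial carries a modality")
        if trial.item in ("word_mele", "sequence"):
            reasons.append(f"{who}: {trial.item} is a copy-only item")
        if trial.item == "triangle":
            reasons.append(f"{who}: triangle is not steered in the tunnel game")
    return reasons


def split_strokes(trial: TrialRecording) -> list[Stroke]:
    """Split a trial into maximal pen-down runs, in temporal order.

    The first and last pen-down frames of a run delimit a stroke; the
    concatenation of all strokes is exactly the pen-down samples.
    """
    down = trial.pen_down
    if not down.any():
        raise EmptyTrialError(
            f"trial {trial.subject_id}/{trial.trial_index} has no pen-down samples")
    padded = np.concatenate(([False], down, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [
        Stroke(int(a), trial.t[a:b], trial.x[a:b], trial.y[a:b])
        for a, b in zip(starts, stops)
    ]


# ---------------------------------------------------------------------------
# canonicalization

def _canonicalize(trial: TrialRecording, device: DeviceInfo) -> TrialRecording:
    ppm = device.pixels_per_mm
    if ppm <= 0:
        raise SchemaError("device.pixels_per_mm must be > 0")
    x = trial.x / ppm
    if device.y_axis == "down":
        if device.canvas_height_px is None:
            raise SchemaError("device.y_axis='down' requires canvas_height_px")
        y = (device.canvas_height_px - trial.y) / ppm
    elif device.y_axis == "up":
        y = trial.y / ppm
    else:
        raise SchemaError(f"device.y_axis must be 'up' or 'down', got {device.y_axis!r}")
    return replace(trial, x=x, y=y)


# ---------------------------------------------------------------------------
# CSV dialect

def _bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise SchemaError(f"unparseable pen_down value {v!r}")


def _read_csv(path: Path) -> tuple[DeviceInfo, list[TrialRecording]]:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        device = DeviceInfo()
        if first.startswith("#device"):
            try:
                device = DeviceInfo(**json.loads(first[len("#device"):].strip()))
            except (json.JSONDecodeError, TypeError) as exc:
                raise SchemaError(f"bad #device header: {exc}") from exc
            header_line = fh.readline()
        else:
            header_line = first
        header = next(csv.reader([header_line])) if header_line else []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required CSV column(s): {', '.join(missing)}")
        reader = csv.DictReader(fh, fieldnames=header)
        groups: dict[tuple, dict] = {}
        order: list[tuple] = []
        for lineno, row in enumerate(reader, start=3):
            try:
                key = (row["subject_id"], row["game"], row["item"],
                       row["modality"] or None, row["geometry_id"] or None,
                       int(row["trial_index"]))
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"line {lineno}: bad trial metadata ({exc})") from exc
            if key not in groups:
                groups[key] = {"group": row["group"], "t": [], "x": [], "y": [],
                               "pen_down": [], "pressure": []}
                order.append(key)
            g = groups[key]
            try:
                g["t"].append(float(row["t"]))
                g["x"].append(float(row["x"]))
                g["y"].append(float(row["y"]))
            except ValueError as exc:
                raise SchemaError(f"line {lineno}: non-numeric sample ({exc})") from exc
            g["pen_down"].append(_bool(row["pen_down"]))
            g["pressure"].append(float(row["pressure"]) if row["pressure"] else np.nan)
    trials = []
    for key in order:
        g = groups[key]
        subject_id, game, item, modality, geometry_id, trial_index = key
        press = np.array(g["pressure"])
        trials.append(TrialRecording(
            subject_id=subject_id, group=g["group"], game=game, item=item,
            t=np.array(g["t"]), x=np.array(g["x"]), y=np.array(g["y"]),
            pen_down=np.array(g["pen_down"]),
            pressure=None if np.isnan(press).all() else press,
            modality=modality, geometry_id=geometry_id, trial_index=trial_index))
    return device, trials


def _write_csv(session: SessionData, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("#device " + json.dumps(session.device.to_dict()) + "\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for trial in session.trials:
            press = trial.pressure
            for i in range(len(trial)):
                p = "" if press is None or np.isnan(press[i]) else repr(float(press[i]))
                writer.writerow([
                    trial.subject_id, trial.group, trial.game, trial.item,
                    trial.modality or "", trial.geometry_id or "",
                    trial.trial_index, repr(float(trial.t[i])),
                    repr(float(trial.x[i])), repr(float(trial.y[i])),
                    int(trial.pen_down[i]), p,
                ])


# ---------------------------------------------------------------------------
# JSON dialect

_META_FIELDS = ("subject_id", "group", "game", "item", "modality",
                "geometry_id", "trial_index")


def _read_json(path: Path) -> tuple[DeviceInfo, list[TrialRecording]]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "trials" not in doc:
        raise SchemaError("JSON session must be an object with a 'trials' field")
    try:
        device = DeviceInfo(**doc.get("device", {}))
    except TypeError as exc:
        raise SchemaError(f"bad device object: {exc}") from exc
    trials = []
    for i, tr in enumerate(doc["trials"]):
        missing = [f for f in ("subject_id", "group", "game", "item", "samples")
                   if f not in tr]
        if missing:
            raise SchemaError(f"trial #{i}: missing field(s) {', '.join(missing)}")
        arr = np.asarray([row[:4] for row in tr["samples"]], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise SchemaError(f"trial #{i}: samples must be [t,x,y,pen_down,pressure?] rows")
        press = np.array([
            np.nan if len(row) < 5 or row[4] is None else float(row[4])
            for row in tr["samples"]])
        trials.append(TrialRecording(
            subject_id=tr["subject_id"], group=tr["group"], game=tr["game"],
            item=tr["item"], t=arr[:, 0], x=arr[:, 1], y=arr[:, 2],
            pen_down=arr[:, 3] > 0.5,
            pressure=None if np.isnan(press).all() else press,
            modality=tr.get("modality"), geometry_id=tr.get("geometry_id"),
            trial_index=int(tr.get("trial_index", 0)),
            manual_boundaries=tr.get("manual_boundaries")))
    return device, trials


def _write_json(session: SessionData, path: Path) -> None:
    doc = {"device": session.device.to_dict(), "trials": []}
    for trial in session.trials:
        press = trial.pressure
        samples = []
        for i in range(len(trial)):
            row = [float(trial.t[i]), float(trial.x[i]), float(trial.y[i]),
                   int(trial.pen_down[i]),
                   None if press is None or np.isnan(press[i]) else float(press[i])]
            samples.append(row)
        entry = {f: getattr(trial, f) for f in _META_FIELDS}
        entry = {k: v for k, v in entry.items() if v is not None}
        if trial.manual_boundaries is not None:
            entry["manual_boundaries"] = trial.manual_boundaries
        entry["samples"] = samples
        doc["trials"].append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# public API

def read_session(path: str | Path, strict: bool = False) -> SessionData:
    """Read a session file (CSV or JSON by extension) into canonical units.

    Invalid trials are quarantined on ``SessionData.invalid`` with reasons;
    with ``strict=True`` the first violation raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such session file: {path}")
    if path.suffix.lower() == ".json":
        device, raw = _read_json(path)
    else:
        device, raw = _read_csv(path)
    session = SessionData(device=DeviceInfo())  # canonical after conversion
    for trial in raw:
        trial = _canonicalize(trial, device)
        reasons = validate_trial(trial)
        if reasons:
            if strict:
                raise ValidationError("; ".join(reasons))
            session.invalid.append((trial, reasons))
        else:
            session.trials.append(trial)
    return session


def write_session(session: SessionData, path: str | Path) -> None:
    """Write *session* (assumed canonical) so that it round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_json(session, path)
    else:
        _write_csv(session, path)
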