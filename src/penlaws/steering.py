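"""Tunnel-game analysis: geometry, movement time, and the steering law.

The steering law predicts a linear speed–accuracy tradeoff for constrained
paths: MT = a + b*ID with ID = A/W, where A is the gesture amplitude
(perimeter for symbols, path length for words, measured at the tunnel
center) and W the border-to-border tunnel width. Per-subject ordinary least
squares of movement time on ID yields R², RMSE, the slope significance, and
— for significant fits with a positive slope — the index of performance
IP = 1/b.

Movement time is measured on the central section of the trace: for two-lap
symbol trials the central full lap (progress 0.5P -> 1.5P along the center
path), for word trials the span between the first crossing of the start
gate and the last crossing of the end gate. Trials with more than 40% of
their traced arc length outside the borders are excluded (strict
inequality: exactly 40% is retained).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import stats as sps
from shapely.geometry import LineString

from .errors import ConfigError, IncompleteTrialError, TooShortError
from .io import TrialRecording
from .templates import make_template

#: Fraction of traced arc length outside the borders above which a trial is
#: discarded (strict inequality).
EXCLUSION_THRESHOLD = 0.40

#: Hysteresis for lap unwrapping: a projection jump above this fraction of
#: the perimeter between consecutive samples is treated as aliasing noise.
MAX_PROGRESS_JUMP = 0.25


@dataclass
class TunnelGeometry:
    """A tunnel path: center polyline, width W, amplitude A, and ID = A/W."""

    geometry_id: str
    item: str  # circle | square | word_ele
    center_path: np.ndarray
    W: float
    A: float
    laps_required: int
    gates: tuple[float, float] | None = None  # absolute arc positions, words only
    _line: LineString | None = field(default=None, repr=False, compare=False)

    @property
    def ID(self) -> float:
        return self.A / self.W

    @property
    def closed(self) -> bool:
        return self.item in ("circle", "square")

    @property
    def line(self) -> LineString:
        if self._line is None:
            self._line = LineString(self.center_path)
        return self._line


def make_geometry(item: str, A: float, W: float, geometry_id: str | None = None,
                  gates: tuple[float, float] | None = None) -> TunnelGeometry:
    """Construct the center polyline for *item* scaled to amplitude ``A``.

    ``gates`` (word only) are arc-length fractions of the path; the default
    comes from the word template's lead-in/lead-out dips.
    """
    if A <= 0 or W <= 0:
        raise ConfigError(f"A and W must be positive, got A={A}, W={W}")
    if item in ("circle", "square"):
        tpl = make_template(item)
        xy = tpl.xy * A
        laps, gate_pos = 2, None
    elif item == "word_ele":
        tpl = make_template("word_ele_tunnel")
        xy = tpl.xy * A
        fr = gates if gates is not None else tpl.gates
        gate_pos = (fr[0] * A, fr[1] * A)
        laps = 1
    else:
        raise ConfigError(f"unsupported tunnel item {item!r}")
    gid = geometry_id or f"{item}_A{A:g}_W{W:g}"
    return TunnelGeometry(geometry_id=gid, item=item, center_path=xy,
                          W=W, A=A, laps_required=laps, gates=gate_pos)


@dataclass
class SteeringTrial:
    """Per-trial steering outcome: accuracy, exclusion flag, movement time."""

    subject_id: str
    item: str
    geometry_id: str
    ID: float
    outside_fraction: float
    excluded: bool
    MT: float | None
    note: str = ""


@dataclass
class SteeringFit:
    """Per-subject steering-law regression MT = a + b*ID."""

    subject_id: str
    item: str
    n: int
    a: float
    b: float
    b_se: float
    R2: float
    RMSE: float
    p: float
    IP: float | None
    global_MT: float


def _pen_down_xy(trial: TrialRecording) -> np.ndarray:
    idx = np.flatnonzero(trial.pen_down)
    if idx.size < 2:
        raise TooShortError("tunnel trial needs >=2 pen-down samples")
    return idx


def outside_fraction(trial: TrialRecording, geom: TunnelGeometry) -> float:
    """Fraction of traced arc length whose segments lie outside the borders.

    A segment is outside when its midpoint is farther than W/2 from the
    center path.
    """
    idx = _pen_down_xy(trial)
    x, y = trial.x[idx], trial.y[idx]
    seg = np.hypot(np.diff(x), np.diff(y))
    total = seg.sum()
    if total <= 0:
        raise TooShortError("zero trace length")
    mx, my = (x[:-1] + x[1:]) / 2.0, (y[:-1] + y[1:]) / 2.0
    dist = shapely.distance(geom.line, shapely.points(np.column_stack([mx, my])))
    return float(seg[dist > geom.W / 2.0].sum() / total)


def _progress(trial: TrialRecording, geom: TunnelGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped arc-length progress of the trace projection onto the path."""
    idx = _pen_down_xy(trial)
    pts = shapely.points(np.column_stack([trial.x[idx], trial.y[idx]]))
    proj = shapely.line_locate_point(geom.line, pts)
    t = trial.t[idx]
    if not geom.closed:
        return t, proj
    P = geom.line.length
    delta = np.diff(proj)
    delta = (delta + P / 2.0) % P - P / 2.0  # minimal signed wrap
    delta[np.abs(delta) > MAX_PROGRESS_JUMP * P] = 0.0  # aliasing hysteresis
    return t, proj[0] + np.concatenate(([0.0], np.cumsum(delta)))


def _cross_times(t: np.ndarray, prog: np.ndarray, level: float) -> np.ndarray:
    """Interpolated times at which ``prog`` crosses ``level``."""
    below = prog < level
    hits = np.flatnonzero(below[:-1] != below[1:])
    if hits.size == 0:
        exact = np.flatnonzero(prog == level)
        return t[exact]
    frac = (level - prog[hits]) / (prog[hits + 1] - prog[hits])
    return t[hits] + frac * (t[hits + 1] - t[hits])


def movement_time(trial: TrialRecording, geom: TunnelGeometry) -> float:
    """Movement time of the measured central section of a steering trial.

    Symbols (two laps, total progress ~2P): time from progress 0.5P to
    1.5P — the central full lap after discarding the lead-in and lead-out
    half-laps (circle) or double-sides (square). Words: time from the first
    start-gate crossing to the last end-gate crossing. Crossing times are
    linearly interpolated between samples.
    """
    t, prog = _progress(trial, geom)
    if geom.closed:
        P = geom.line.length
        prog = prog - prog[0]  # trials start at the path origin
        lo, hi = 0.5 * P, 1.5 * P
        t_lo = _cross_times(t, prog, lo)
        t_hi = _cross_times(t, prog, hi)
        if t_lo.size == 0 or t_hi.size == 0:
            raise IncompleteTrialError(
                f"progress reached {prog.max() / P:.2f} laps; central lap landmarks not crossed")
        return float(t_hi[0] - t_lo[0])
    if geom.gates is None:
        raise ConfigError("word geometry without gates")
    s1, s2 = geom.gates
    t1 = _cross_times(t, prog, s1)
    t2 = _cross_times(t, prog, s2)
    if t1.size == 0 or t2.size == 0:
        raise IncompleteTrialError("word trace never crossed both gates")
    mt = float(t2[-1] - t1[0])
    if mt <= 0:
        raise IncompleteTrialError("end gate crossed before start gate")
    return mt


def evaluate_trial(trial: TrialRecording, geom: TunnelGeometry,
                   threshold: float = EXCLUSION_THRESHOLD) -> SteeringTrial:
    """Apply the exclusion rule, then measure MT on retained trials."""
    of = outside_fraction(trial, geom)
    excluded = of > threshold
    mt, note = None, ""
    if excluded:
        note = f"outside_fraction {of:.3f} > {threshold:g}"
    else:
        try:
            mt = movement_time(trial, geom)
        except IncompleteTrialError as exc:
            note = f"incomplete: {exc}"
    return SteeringTrial(subject_id=trial.subject_id, item=trial.item,
                         geometry_id=geom.geometry_id, ID=geom.ID,
                         outside_fraction=of, excluded=excluded, MT=mt, note=note)


def fit_steering(trials: list[SteeringTrial] | list[tuple[float, float]],
                 alpha: float = 0.05, subject_id: str = "", item: str = "") -> SteeringFit:
    """OLS of MT on ID over non-excluded measured trials.

    Accepts :class:`SteeringTrial` lists or raw ``(ID, MT)`` pairs. The
    slope p-value comes from the F(1, n-2) test (equivalently the slope
    t-test); IP = 1/b is reported only for significant positive slopes;
    global MT is the median MT across all retained trials.
    """
    if trials and isinstance(trials[0], SteeringTrial):
        usable = [tr for tr in trials if not tr.excluded and tr.MT is not None]
        ids = np.array([tr.ID for tr in usable])
        mts = np.array([tr.MT for tr in usable])
        subject_id = subject_id or (usable[0].subject_id if usable else "")
        item = item or (usable[0].item if usable else "")
    else:
        ids = np.array([p[0] for p in trials], dtype=float)
        mts = np.array([p[1] for p in trials], dtype=float)
    n = len(ids)
    if n < 3:
        raise TooShortError(f"need >=3 measured trials for a fit, got {n}")
    if np.unique(ids).size < 2:
        raise ConfigError("all trials share one ID: degenerate regression design")
    res = sps.linregress(ids, mts)
    pred = res.intercept + res.slope * ids
    ss_res = float(np.sum((mts - pred) ** 2))
    ss_tot = float(np.sum((mts - mts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rmse = float(np.sqrt(ss_res / n))
    p = float(res.pvalue)
    ip = float(1.0 / res.slope) if (p < alpha and res.slope > 0) else None
    return SteeringFit(subject_id=subject_id, item=item, n=n,
                       a=float(res.intercept), b=float(res.slope),
                       b_se=float(res.stderr), R2=r2, RMSE=rmse, p=p, IP=ip,
                       global_MT=float(np.median(mts)))


def critical_r2(df: int, alpha: float = 0.05) -> float:
    """Minimal R² at which a simple linear regression with ``df`` residual
    degrees of freedom is significant at ``alpha``: F/(F+df) with the
    F(1, df) upper-alpha quantile."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    F = sps.f.ppf(1.0 - alpha, 1, df)
    return float(F / (F + df))


# ---------------------------------------------------------------------------
# geometry catalog IO

def write_geometries(geoms: list[TunnelGeometry], path: str | Path) -> None:
    doc = [{"geometry_id": g.geometry_id, "item": g.item, "A": g.A, "W": g.W,
            **({"gates": [gf / g.A for gf in g.gates]} if g.gates else {})}
           for g in geoms]
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_geometries(path: str | Path) -> dict[str, TunnelGeometry]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {}
    for entry in doc:
        g = make_geometry(entry["item"], entry["A"], entry["W"],
                          geometry_id=entry["geometry_id"],
                          gates=tuple(entry["gates"]) if "gates" in entry else None)
        out[g.geometry_id] = g
    return out
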