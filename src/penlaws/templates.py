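"""Unit-scale shape templates for symbols and cursive-like words.

Every template is a polyline normalized to arc length 1. Cursive words are
built from sinusoidal arches (letter bodies) joined by shallow dips below
the baseline (connecting strokes); the dip minima are the construction
ground truth for letter transitions, recorded as arc-length fractions in
``boundaries``. The tunnel word template adds a lead-in and lead-out around
the "ele" core and records gate positions at the dips bounding the first
and last "e".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUPPORTED = ("circle", "square", "triangle", "word_mele", "word_ele",
             "word_ele_tunnel", "sequence")

#: Depth of the inter-letter connecting dip, as a fraction of x-extent units.
DIP_DEPTH = 0.12

_PTS_PER_BUMP = 48


@dataclass
class ShapeTemplate:
    """A unit-arc-length polyline plus element annotations.

    ``boundaries``: arc-length fractions of letter transitions (words).
    ``gates``: arc-length fractions of the word-tunnel measurement gates.
    ``parts``: for ``sequence``, the member symbol templates with layout
    offsets (in units of the member's own scale).
    """

    item: str
    xy: np.ndarray
    closed: bool
    boundaries: tuple[float, ...] = ()
    gates: tuple[float, float] | None = None
    parts: list[tuple["ShapeTemplate", np.ndarray]] = field(default_factory=list)

    @property
    def arc(self) -> np.ndarray:
        d = np.hypot(*np.diff(self.xy, axis=0).T)
        return np.concatenate(([0.0], np.cumsum(d)))

    def at_arc(self, s: np.ndarray) -> np.ndarray:
        """Points at arc positions ``s`` (same units as the polyline)."""
        arc = self.arc
        x = np.interp(s, arc, self.xy[:, 0])
        y = np.interp(s, arc, self.xy[:, 1])
        return np.column_stack([x, y])


def _normalize(xy: np.ndarray, marks: list[float]) -> tuple[np.ndarray, list[float]]:
    d = np.hypot(*np.diff(xy, axis=0).T)
    arc = np.concatenate(([0.0], np.cumsum(d)))
    total = arc[-1]
    return xy / total, [m / total for m in marks]


def _bump_chain(bumps: list[tuple[float, float]],
                mark_after: set[int]) -> tuple[np.ndarray, list[float]]:
    """Concatenate sinusoid bumps (width, height); height<0 digs a dip.

    ``mark_after`` holds bump indices whose minimum (dips) or end (bumps)
    is recorded as a mark; for dips the mark sits at the dip's midpoint.
    Returns the polyline and the marks as raw arc-length positions.
    """
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    x0 = 0.0
    mark_x: list[float] = []
    for i, (w, h) in enumerate(bumps):
        u = np.linspace(0.0, 1.0, _PTS_PER_BUMP, endpoint=False)
        xs.append(x0 + u * w)
        ys.append(h * np.sin(np.pi * u))
        if i in mark_after:
            mark_x.append(x0 + w / 2.0)
        x0 += w
    xs.append(np.array([x0]))
    ys.append(np.array([0.0]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    xy = np.column_stack([x, y])
    # convert mark x-positions to arc-length positions
    d = np.hypot(*np.diff(xy, axis=0).T)
    arc = np.concatenate(([0.0], np.cumsum(d)))
    marks = [float(np.interp(mx, x, arc)) for mx in mark_x]
    return xy, marks


def _word(bumps: list[tuple[float, float]], dip_idx: set[int],
          gate_idx: tuple[int, int] | None = None):
    xy, marks = _bump_chain(bumps, dip_idx | (set(gate_idx) if gate_idx else set()))
    order = sorted(dip_idx | (set(gate_idx) if gate_idx else set()))
    xy, marks = _normalize(xy, marks)
    by_idx = dict(zip(order, marks))
    boundaries = tuple(by_idx[i] for i in sorted(dip_idx))
    gates = (by_idx[gate_idx[0]], by_idx[gate_idx[1]]) if gate_idx else None
    return xy, boundaries, gates


# bump tables: (width, height); dips are (width, -DIP_DEPTH)
_MELE_BUMPS = [
    (0.40, 0.55), (0.40, 0.60), (0.40, 0.55),      # m: three arches
    (0.22, -DIP_DEPTH),                            # m|e
    (0.45, 0.50),                                  # e
    (0.22, -DIP_DEPTH),                            # e|l
    (0.40, 1.00),                                  # l: tall loop
    (0.22, -DIP_DEPTH),                            # l|e
    (0.45, 0.50),                                  # e
]
_MELE_DIPS = {3, 5, 7}

_ELE_BUMPS = _MELE_BUMPS[4:]                       # e dip l dip e
_ELE_DIPS = {1, 3}

_ELE_TUNNEL_BUMPS = [(0.45, 0.30), (0.22, -DIP_DEPTH), *_ELE_BUMPS,
                     (0.22, -DIP_DEPTH), (0.45, 0.30)]
_ELE_TUNNEL_DIPS = {3, 5}
_ELE_TUNNEL_GATES = (1, 7)


def make_template(item: str) -> ShapeTemplate:
    """Build the unit-arc-length template for *item*."""
    if item == "circle":
        th = np.linspace(-np.pi / 2.0, 1.5 * np.pi, 257)
        xy = np.column_stack([np.cos(th), np.sin(th)])
        chord = np.hypot(*np.diff(xy, axis=0).T).sum()
        xy /= chord  # polyline (chord-sum) arc length exactly 1
        return ShapeTemplate("circle", xy, closed=True)
    if item == "square":
        side = 0.25
        corners = np.array([[0, 0], [side, 0], [side, side], [0, side], [0, 0]])
        pts = [np.linspace(corners[i], corners[i + 1], 33)[:-1] for i in range(4)]
        xy = np.vstack(pts + [corners[-1:]])
        return ShapeTemplate("square", xy, closed=True)
    if item == "triangle":
        side = 1.0 / 3.0
        h = side * np.sqrt(3) / 2.0
        corners = np.array([[0, 0], [side, 0], [side / 2.0, h], [0, 0]])
        pts = [np.linspace(corners[i], corners[i + 1], 33)[:-1] for i in range(3)]
        xy = np.vstack(pts + [corners[-1:]])
        return ShapeTemplate("triangle", xy, closed=True)
    if item == "word_mele":
        xy, boundaries, _ = _word(_MELE_BUMPS, _MELE_DIPS)
        return ShapeTemplate("word_mele", xy, closed=False, boundaries=boundaries)
    if item == "word_ele":
        xy, boundaries, _ = _word(_ELE_BUMPS, _ELE_DIPS)
        return ShapeTemplate("word_ele", xy, closed=False, boundaries=boundaries)
    if item == "word_ele_tunnel":
        xy, boundaries, gates = _word(_ELE_TUNNEL_BUMPS, _ELE_TUNNEL_DIPS,
                                      _ELE_TUNNEL_GATES)
        return ShapeTemplate("word_ele_tunnel", xy, closed=False,
                             boundaries=boundaries, gates=gates)
    if item == "sequence":
        members = [make_template(s) for s in ("circle", "square", "triangle")]
        offsets = [np.array([0.0, 0.0]), np.array([0.45, -0.1]),
                   np.array([0.85, -0.05])]
        # the sequence template itself is the concatenation for reference
        xy = np.vstack([m.xy + o for m, o in zip(members, offsets)])
        tpl = ShapeTemplate("sequence", xy, closed=False,
                            parts=list(zip(members, offsets)))
        return tpl
    raise ValueError(f"unsupported template item {item!r}")
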