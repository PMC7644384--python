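"""Seedable synthetic pen recordings with controllable motor-law compliance.

The generator emulates 50 Hz tablet recordings of the two exercises the
analysis pipeline expects:

* **copy game** — a word or symbol traced under one of five modalities
  (spontaneous, big, small, fast, slow). Speed scales with executed size as
  ``size_ratio ** beta`` where ``beta`` is the isochrony exponent (1 = full
  compliance: bigger is proportionally faster, duration constant; 0 = no
  modulation). Element durations follow a fraction template (homothety),
  perturbed by multiplicative noise and renormalized. Within each element
  the pen follows a minimum-jerk bell speed profile — the standard kinematic
  stand-in for rapid aimed strokes.
* **tunnel game** — steering along a tunnel geometry at constant speed,
  with the target movement time of the measured central section drawn from
  the steering law MT* = a + b*ID + noise, and an Ornstein–Uhlenbeck
  lateral offset of configurable stationary sd. Programmed excursions push
  a contiguous arc fraction outside the borders to exercise the exclusion
  rule.

All randomness flows from explicit integer seeds; identical (config, seed)
pairs give byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import SessionData, TrialRecording
from .steering import TunnelGeometry, make_geometry
from .templates import ShapeTemplate, make_template

FS_HZ = 50.0

#: (size factor, speed factor) per copy-game modality.
MODALITY_FACTORS: dict[str, tuple[float, float]] = {
    "spontaneous": (1.0, 1.0),
    "big": (2.0, 1.0),
    "small": (0.5, 1.0),
    "fast": (1.0, 1.5),
    "slow": (1.0, 0.6),
}

SEQUENCE_ITEMS = ("circle", "square", "triangle")


@dataclass
class MotorProfile:
    """Per-subject generative parameters.

    ``isochrony_exponent`` (beta) in [0, 1.5]; ``base_speed`` in mm/s at the
    spontaneous size; ``fraction_template`` per-element time fractions
    (None = proportional to element arc length); ``steering_a``/``b`` in
    seconds and seconds per ID unit; noise sds in their natural units.
    """

    isochrony_exponent: float = 1.0
    base_speed: float = 50.0
    fraction_template: tuple[float, ...] | None = None
    fraction_noise_sd: float = 0.03
    steering_a: float = 0.8
    steering_b: float = 0.12
    mt_noise_sd: float = 0.1
    lateral_noise_sd: float = 0.3
    lift_duration: float = 0.4
    excursion_prob: float = 0.0
    excursion_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.isochrony_exponent <= 1.5:
            raise ConfigError("isochrony_exponent must be in [0, 1.5]")
        for name in ("fraction_noise_sd", "mt_noise_sd", "lateral_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.fraction_template is not None:
            if abs(sum(self.fraction_template) - 1.0) > 1e-9:
                raise ConfigError("fraction_template must sum to 1")


def _min_jerk_s(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk normalized arc progress s(tau) = 10t^3 - 15t^4 + 6t^5."""
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def min_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """Closed-form normalized minimum-jerk speed ds/dtau (peak 1.875)."""
    return 30.0 * tau ** 2 * (1.0 - tau) ** 2


def _element_plan(template: ShapeTemplate, item: str,
                  profile: MotorProfile, rng: np.random.Generator):
    """Element labels, unit arc spans and time fractions for *item*."""
    if item == "sequence":
        labels = list(SEQUENCE_ITEMS)
        spans = None  # each part has unit arc length of its own
        base = (profile.fraction_template if profile.fraction_template is not None
                else (1.0 / 3.0,) * 3)
    elif item in ("word_mele", "word_ele"):
        cuts = (0.0, *template.boundaries, 1.0)
        spans = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
        labels = [f"letter_{i + 1}" for i in range(len(spans))]
        base = (profile.fraction_template if profile.fraction_template is not None
                else tuple(b - a for a, b in spans))
    else:  # single symbol
        labels, spans, base = [item], [(0.0, 1.0)], (1.0,)
    fractions = np.asarray(base, dtype=float)
    if profile.fraction_noise_sd > 0:
        fractions = fractions * np.exp(
            rng.normal(0.0, profile.fraction_noise_sd, size=fractions.size))
    fractions = fractions / fractions.sum()
    return labels, spans, fractions


def generate_copy_trial(profile: MotorProfile, item: str, modality: str,
                        size_mm: float = 120.0, seed: int | None = 0,
                        subject_id: str = "synthetic", group: str = "primary",
                        trial_index: int = 0, fs: float = FS_HZ) -> TrialRecording:
    """One copy-game execution of *item* under *modality*.

    ``size_mm`` is the spontaneous-modality traced arc length; the modality
    size factor rescales it, and the executed speed is
    ``base_speed * size_factor**beta * speed_factor``. The returned trial
    carries generator ground truth in ``trial.truth`` (element boundary
    times and arc fractions, programmed fractions and speed).
    """
    if modality not in MODALITY_FACTORS:
        raise ConfigError(f"unknown modality {modality!r}")
    size_f, speed_f = MODALITY_FACTORS[modality]
    rng = np.random.default_rng(seed)
    template = make_template(item)
    labels, spans, fractions = _element_plan(template, item, profile, rng)

    L = size_mm * size_f
    speed = profile.base_speed * size_f ** profile.isochrony_exponent * speed_f
    total_T = L / speed  # pen-down time
    durations = fractions * total_T
    dt = 1.0 / fs

    t_parts: list[np.ndarray] = []
    x_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    down_parts: list[np.ndarray] = []
    truth_bounds: list[float] = []

    if item == "sequence":
        # per-symbol scale: equal symbol sizes, laid out left to right
        sym_scale = L / 3.0
        t0 = 0.0
        parts = make_template("sequence").parts
        for k, (tpl, offset) in enumerate(parts):
            dur = durations[k]
            n = max(int(np.round(dur * fs)), 4)
            tk = t0 + np.arange(n + 1) * dt
            tau = np.clip((tk - t0) / dur, 0.0, 1.0)
            s = _min_jerk_s(tau)  # unit template arc
            pts = tpl.at_arc(s * tpl.arc[-1]) * sym_scale + offset * sym_scale
            t_parts.append(tk)
            x_parts.append(pts[:, 0])
            y_parts.append(pts[:, 1])
            down_parts.append(np.ones(n + 1, dtype=bool))
            truth_bounds.append(t0 + dur)
            t_end = tk[-1]
            if k < len(parts) - 1:  # pen-up hover to the next symbol
                lift = profile.lift_duration
                m = max(int(np.round(lift * fs)) - 1, 1)
                tl = t_end + np.arange(1, m + 1) * dt
                nxt_tpl, nxt_off = parts[k + 1]
                start_xy = nxt_tpl.at_arc(np.array([0.0]))[0] * sym_scale + nxt_off * sym_scale
                end_xy = pts[-1]
                frac = (tl - t_end) / (lift + dt)
                x_parts.append(end_xy[0] + (start_xy[0] - end_xy[0]) * frac)
                y_parts.append(end_xy[1] + (start_xy[1] - end_xy[1]) * frac)
                t_parts.append(tl)
                down_parts.append(np.zeros(m, dtype=bool))
                t0 = tl[-1] + dt
    else:
        scaled = template.xy * L  # unit arc length -> L
        tpl_scaled = ShapeTemplate(item, scaled, template.closed)
        n_total = max(int(np.round(total_T * fs)), 8)
        t = np.arange(n_total + 1) * dt
        cum_T = np.concatenate(([0.0], np.cumsum(durations)))
        s = np.empty_like(t)
        cuts = np.concatenate(([0.0], np.cumsum([(b - a) for a, b in spans]))) * L
        for k, dur in enumerate(durations):
            lo, hi = cum_T[k], cum_T[k + 1]
            sel = (t >= lo) & (t <= hi) if k == len(durations) - 1 else (t >= lo) & (t < hi)
            tau = np.clip((t[sel] - lo) / dur, 0.0, 1.0)
            s[sel] = cuts[k] + _min_jerk_s(tau) * (cuts[k + 1] - cuts[k])
        s[t > cum_T[-1]] = cuts[-1]
        pts = tpl_scaled.at_arc(s)
        t_parts, x_parts, y_parts = [t], [pts[:, 0]], [pts[:, 1]]
        down_parts = [np.ones(len(t), dtype=bool)]
        truth_bounds = list(cum_T[1:-1])
        sample_arc_fractions = s / L

    t = np.concatenate(t_parts)
    x = np.concatenate(x_parts)
    y = np.concatenate(y_parts)
    down = np.concatenate(down_parts)
    if profile.lateral_noise_sd > 0:
        x = x + rng.normal(0.0, profile.lateral_noise_sd, size=x.size)
        y = y + rng.normal(0.0, profile.lateral_noise_sd, size=y.size)

    truth = {
        "speed": speed, "fractions": fractions.tolist(),
        "element_labels": labels, "element_end_times": truth_bounds,
        "boundary_arc_fractions": list(template.boundaries),
        "arc_length": L, "pen_down_duration": total_T,
    }
    if item != "sequence":
        # true (pre-noise) arc position of every sample, as path fraction
        truth["sample_arc_fractions"] = sample_arc_fractions
    return TrialRecording(subject_id=subject_id, group=group, game="copy",
                          item=item, t=t, x=x, y=y, pen_down=down,
                          modality=modality, trial_index=trial_index,
                          truth=truth)


def generate_tunnel_trial(profile: MotorProfile, geom: TunnelGeometry,
                          seed: int | None = 0, subject_id: str = "synthetic",
                          group: str = "primary", trial_index: int = 0,
                          fs: float = FS_HZ,
                          force_excursion: bool | None = None) -> TrialRecording:
    """One tunnel-game steering execution along *geom*.

    The programmed movement time of the measured central section is
    MT* = a + b*ID + N(0, mt_noise_sd), redrawn while nonpositive (bounded
    retries); the pen moves at the implied constant speed over the whole
    trace (two laps for symbols, the full path for words). With probability
    ``excursion_prob`` (or when ``force_excursion``) a contiguous
    ``excursion_fraction`` of the trace is offset laterally by W, landing it
    outside the borders.
    """
    rng = np.random.default_rng(seed)
    mt_star = profile.steering_a + profile.steering_b * geom.ID
    if profile.mt_noise_sd > 0:
        for _ in range(100):
            cand = mt_star + rng.normal(0.0, profile.mt_noise_sd)
            if cand > 0.05:
                mt_star_n = cand
                break
        else:
            raise ConfigError("could not draw a positive movement time")
    else:
        mt_star_n = mt_star
    if mt_star_n <= 0:
        raise ConfigError("nonpositive programmed movement time")

    P = float(geom.line.length)
    if geom.closed:
        central = P  # one full lap measured out of two
        total_arc = geom.laps_required * P
    else:
        s1, s2 = geom.gates
        central = s2 - s1
        total_arc = P
    v = central / mt_star_n
    T = total_arc / v
    n = int(np.ceil(T * fs))
    t = np.arange(n + 1) / fs
    s = np.minimum(v * t, total_arc)
    s_path = np.mod(s, P) if geom.closed else s
    # avoid a duplicate wrap point exactly at P
    pts = np.column_stack([
        np.interp(s_path, *_arc_table(geom, 0)),
        np.interp(s_path, *_arc_table(geom, 1)),
    ])

    # unit normals from path tangents
    grad = np.gradient(pts, axis=0)
    norm = np.hypot(grad[:, 0], grad[:, 1])
    norm[norm == 0] = 1.0
    normals = np.column_stack([-grad[:, 1] / norm, grad[:, 0] / norm])

    offset = np.zeros(n + 1)
    if profile.lateral_noise_sd > 0:
        tau_c = 0.15  # OU correlation time, s
        phi = np.exp(-1.0 / (fs * tau_c))
        sd = profile.lateral_noise_sd
        offset[0] = rng.normal(0.0, sd)
        innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
        for i in range(n):
            offset[i + 1] = phi * offset[i] + innov[i]

    excursion = (force_excursion if force_excursion is not None
                 else rng.random() < profile.excursion_prob)
    if excursion:
        frac = profile.excursion_fraction
        lo = (1.0 - frac) / 2.0 * total_arc
        hi = (1.0 + frac) / 2.0 * total_arc
        offset = offset + np.where((s > lo) & (s < hi), geom.W, 0.0)

    xy = pts + normals * offset[:, None]
    truth = {"MT": mt_star_n, "speed": v, "excursion": bool(excursion),
             "ID": geom.ID}
    return TrialRecording(subject_id=subject_id, group=group, game="tunnel",
                          item=geom.item, t=t, x=xy[:, 0], y=xy[:, 1],
                          pen_down=np.ones(n + 1, dtype=bool),
                          geometry_id=geom.geometry_id,
                          trial_index=trial_index, truth=truth)


def _arc_table(geom: TunnelGeometry, col: int) -> tuple[np.ndarray, np.ndarray]:
    xy = geom.center_path
    d = np.hypot(*np.diff(xy, axis=0).T)
    arc = np.concatenate(([0.0], np.cumsum(d)))
    return arc, xy[:, col]


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class GroupConfig:
    """Distributional parameters of one age group's motor profiles."""

    n_subjects: int
    base_speed_mean: float = 50.0
    base_speed_cv: float = 0.15
    isochrony_exponent: float = 1.0
    fraction_noise_sd: float = 0.03
    steering_a_mean: float = 0.8
    steering_a_sd: float = 0.10
    steering_b_mean: float = 0.12
    steering_b_sd: float = 0.02
    mt_noise_sd: float = 0.1
    lateral_noise_sd: float = 0.3
    excursion_prob: float = 0.05
    copy_word: bool = True


@dataclass
class CohortConfig:
    """Study-protocol configuration mirrored from the validation cohort.

    Defaults: 15 primary-school children (copy word + symbols) and 19
    kindergartners (symbols only); tunnel circles/squares at five symbol
    IDs and the word at five word IDs, 14 trials per item (5 IDs with
    repeats 3/3/3/3/2, residual df 12). Kindergarten steering parameters
    are scaled (slope x1.8, MT noise x2, lateral noise x1.5) to mirror the
    reported developmental direction (longer MT, higher RMSE, lower IP).
    """

    primary: GroupConfig = field(default_factory=lambda: GroupConfig(n_subjects=15))
    kindergarten: GroupConfig = field(default_factory=lambda: GroupConfig(
        n_subjects=19, steering_a_mean=1.0, steering_a_sd=0.15,
        steering_b_mean=0.216, steering_b_sd=0.036, mt_noise_sd=0.2,
        lateral_noise_sd=0.45, excursion_prob=0.15, copy_word=False))
    copy_items_word: tuple[str, ...] = ("word_mele",)
    copy_items_symbols: tuple[str, ...] = ("circle", "square", "triangle", "sequence")
    copy_size_mm: float = 120.0
    symbol_ids: tuple[float, ...] = (8.0, 12.0, 18.0, 27.0, 40.0)
    word_ids: tuple[float, ...] = (6.0, 9.0, 14.0, 21.0, 32.0)
    symbol_A_mm: float = 150.0
    word_A_mm: float = 180.0
    trials_per_item: int = 14


def default_geometries(config: CohortConfig | None = None) -> dict[str, TunnelGeometry]:
    """The tunnel geometry catalog implied by a cohort config."""
    config = config or CohortConfig()
    geoms: dict[str, TunnelGeometry] = {}
    for item, ids, A in (("circle", config.symbol_ids, config.symbol_A_mm),
                         ("square", config.symbol_ids, config.symbol_A_mm),
                         ("word_ele", config.word_ids, config.word_A_mm)):
        for i, id_val in enumerate(ids):
            g = make_geometry(item, A=A, W=A / id_val,
                              geometry_id=f"{item}_id{i + 1}")
            geoms[g.geometry_id] = g
    return geoms


def _draw_profile(gc: GroupConfig, rng: np.random.Generator) -> MotorProfile:
    sigma = np.sqrt(np.log(1.0 + gc.base_speed_cv ** 2))
    return MotorProfile(
        isochrony_exponent=gc.isochrony_exponent,
        base_speed=float(gc.base_speed_mean * np.exp(rng.normal(-sigma ** 2 / 2, sigma))),
        fraction_noise_sd=gc.fraction_noise_sd,
        steering_a=float(max(rng.normal(gc.steering_a_mean, gc.steering_a_sd), 0.1)),
        steering_b=float(max(rng.normal(gc.steering_b_mean, gc.steering_b_sd), 0.01)),
        mt_noise_sd=gc.mt_noise_sd,
        lateral_noise_sd=gc.lateral_noise_sd,
        excursion_prob=gc.excursion_prob,
    )


def _id_schedule(ids: tuple[float, ...], n_trials: int) -> list[int]:
    """Indices into ``ids`` repeating as evenly as possible to n_trials."""
    reps = [n_trials // len(ids) + (1 if i < n_trials % len(ids) else 0)
            for i in range(len(ids))]
    sched: list[int] = []
    for i, r in enumerate(reps):
        sched.extend([i] * r)
    return sched


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> tuple[SessionData, dict[str, TunnelGeometry]]:
    """Generate the full two-group session (copy + tunnel trials).

    Word copying appears only for groups with ``copy_word`` (primary by
    default); all groups steer circles, squares and the tunnel word.
    Deterministic given (config, seed).
    """
    config = config or CohortConfig()
    geoms = default_geometries(config)
    root = np.random.SeedSequence(seed)
    session = SessionData()
    group_specs = (("primary", config.primary), ("kindergarten", config.kindergarten))
    subj_seeds = root.spawn(sum(gc.n_subjects for _, gc in group_specs))
    si = 0
    for group, gc in group_specs:
        for j in range(gc.n_subjects):
            ss = subj_seeds[si]
            si += 1
            rng = np.random.default_rng(ss)
            profile = _draw_profile(gc, rng)
            subject_id = f"{group[:4]}{j + 1:02d}"
            trial_index = 0
            items = ((config.copy_items_word if gc.copy_word else ())
                     + config.copy_items_symbols)
            for item in items:
                for modality in MODALITY_FACTORS:
                    trial = generate_copy_trial(
                        profile, item, modality, size_mm=config.copy_size_mm,
                        seed=int(rng.integers(2 ** 31)), subject_id=subject_id,
                        group=group, trial_index=trial_index)
                    session.trials.append(trial)
                    trial_index += 1
            for item, ids in (("circle", config.symbol_ids),
                              ("square", config.symbol_ids),
                              ("word_ele", config.word_ids)):
                for gi in _id_schedule(ids, config.trials_per_item):
                    geom = geoms[f"{item}_id{gi + 1}"]
                    trial = generate_tunnel_trial(
                        profile, geom, seed=int(rng.integers(2 ** 31)),
                        subject_id=subject_id, group=group,
                        trial_index=trial_index)
                    session.trials.append(trial)
                    trial_index += 1
    return session, geoms
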