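"""End-to-end cohort analysis and report rendering.

``run_analysis`` executes the study's statistical battery on a session:

1. **compliance** — Wilcoxon matched-pairs on traced length, big vs small,
   per group and copy item (children must actually scale their gestures);
2. **isochrony** — Friedman over the five modalities on per-execution mean
   speed, per group and item, with Bonferroni pairwise post-hoc when the
   omnibus is significant;
3. **developmental trend** — Mann–Whitney on spontaneous-modality speed
   between groups, per symbol item;
4. **homothety** — per element, Friedman over modalities on fraction time;
5. **steering** — per-trial exclusion (>40% outside) and movement time,
   per-subject steering-law fits, then group (Mann–Whitney) and item
   (Friedman) contrasts on global MT, RMSE and IP.

Every input trial is accounted for exactly once in results, the exclusion
log, or the validation log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (DegenerateError, MismatchError, PenlawsError,
                     SegmentationError, TooShortError)
from .io import MODALITIES, SessionData
from .kinematics import mean_speed, path_length
from .segmentation import fraction_times, segment_sequence, segment_word
from .stats import StatResult, friedman, mann_whitney, posthoc_pairs
from .steering import SteeringFit, SteeringTrial, TunnelGeometry, evaluate_trial, fit_steering
from .synthetic import SEQUENCE_ITEMS

WORD_LETTERS = {"word_mele": ["m", "e1", "l", "e2"]}


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    trim_fraction: float = 0.05
    lowpass_cutoff_hz: float = 10.0
    filter_order: int = 4
    include_pen_up: bool = False
    exclusion_threshold: float = 0.40


@dataclass
class CohortResult:
    """All result surfaces of one cohort run."""

    compliance: dict[tuple, StatResult] = field(default_factory=dict)
    isochrony: dict[tuple, StatResult] = field(default_factory=dict)
    developmental: dict[str, StatResult] = field(default_factory=dict)
    homothety: dict[tuple, StatResult] = field(default_factory=dict)
    steering_trials: list[SteeringTrial] = field(default_factory=list)
    steering_fits: list[SteeringFit] = field(default_factory=list)
    group_contrasts: dict[tuple, StatResult] = field(default_factory=dict)
    item_contrasts: dict[tuple, StatResult] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _log(result: CohortResult, stage: str, message: str, **kw) -> None:
    result.log.append({"stage": stage, "message": message, **kw})


def _copy_measure_table(trials, config, result, measure) -> pd.DataFrame:
    rows = []
    for trial in trials:
        try:
            value = measure(trial)
        except PenlawsError as exc:
            _log(result, "copy", f"measurement failed: {exc}",
                 subject=trial.subject_id, trial=trial.trial_index)
            continue
        rows.append({"group": trial.group, "item": trial.item,
                     "subject": trial.subject_id, "modality": trial.modality,
                     "value": value})
    return pd.DataFrame(rows)


def _modality_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Subjects x modalities matrix (NaN for missing cells), modality order fixed."""
    pivot = df.pivot_table(index="subject", columns="modality", values="value",
                           aggfunc="mean")
    pivot = pivot.reindex(columns=list(MODALITIES))
    return pivot.to_numpy(), list(pivot.index)


def run_analysis(session: SessionData,
                 geometries: dict[str, TunnelGeometry] | None = None,
                 config: AnalysisConfig | None = None) -> CohortResult:
    """Run the full cohort analysis; see the module docstring for stages."""
    config = config or AnalysisConfig()
    result = CohortResult()
    alpha = config.alpha
    copy_trials = [t for t in session.trials if t.game == "copy"]
    tunnel_trials = [t for t in session.trials if t.game == "tunnel"]
    result.counts = {"input": len(session.trials),
                     "invalid": len(session.invalid),
                     "copy": len(copy_trials), "tunnel": len(tunnel_trials)}
    if not session.trials:
        _log(result, "session", "empty session: nothing to analyze")
        return result

    # ---- copy game: compliance (big vs small traced length) ----
    lengths = _copy_measure_table(copy_trials, config, result, path_length)
    if not lengths.empty:
        for (group, item), df in lengths.groupby(["group", "item"]):
            mat, _ = _modality_matrix(df)
            big = mat[:, MODALITIES.index("big")]
            small = mat[:, MODALITIES.index("small")]
            ok = ~np.isnan(big) & ~np.isnan(small)
            try:
                res = _wilcoxon_pair(big[ok], small[ok])
                result.compliance[(group, item)] = res
            except DegenerateError as exc:
                _log(result, "compliance", str(exc), group=group, item=item)

    # ---- copy game: isochrony (Friedman on mean speed over modalities) ----
    speeds = _copy_measure_table(
        copy_trials, config, result,
        lambda tr: mean_speed(tr, config.trim_fraction,
                              config.lowpass_cutoff_hz, config.filter_order))
    if not speeds.empty:
        for (group, item), df in speeds.groupby(["group", "item"]):
            mat, _ = _modality_matrix(df)
            incomplete = int(np.isnan(mat).any(axis=1).sum())
            if incomplete:
                _log(result, "isochrony",
                     f"{incomplete} subject(s) dropped (missing modality)",
                     group=group, item=item)
            try:
                res = friedman(mat)
            except DegenerateError as exc:
                _log(result, "isochrony", str(exc), group=group, item=item)
                continue
            if res.p < alpha:
                res.posthoc = posthoc_pairs(mat, alpha=alpha,
                                            labels=list(MODALITIES))
            result.isochrony[(group, item)] = res

        # ---- developmental trend: spontaneous speed between groups ----
        spont = speeds[speeds.modality == "spontaneous"]
        for item, df in spont.groupby("item"):
            by_group = {g: d.groupby("subject")["value"].mean().to_numpy()
                        for g, d in df.groupby("group")}
            if len(by_group) == 2:
                try:
                    result.developmental[item] = mann_whitney(
                        by_group["primary"], by_group["kindergarten"])
                except DegenerateError as exc:
                    _log(result, "developmental", str(exc), item=item)

    # ---- homothety: fraction times per element ----
    frac_rows = []
    for trial in copy_trials:
        if trial.item not in ("word_mele", "sequence"):
            continue
        try:
            if trial.item == "sequence":
                bounds = segment_sequence(trial, expected=list(SEQUENCE_ITEMS))
            else:
                labels = WORD_LETTERS[trial.item]
                bounds = segment_word(trial, n_letters=len(labels))
                bounds.element_labels = labels
            ft = fraction_times(bounds, trial, include_pen_up=config.include_pen_up)
        except (SegmentationError, MismatchError, TooShortError, PenlawsError) as exc:
            _log(result, "homothety", f"segmentation failed: {exc}",
                 subject=trial.subject_id, trial=trial.trial_index)
            continue
        for label, frac in zip(ft.element_labels, ft.fractions):
            frac_rows.append({"group": trial.group, "item": trial.item,
                              "subject": trial.subject_id,
                              "modality": trial.modality,
                              "element": label, "value": float(frac)})
    fracs = pd.DataFrame(frac_rows)
    if not fracs.empty:
        for (group, item, element), df in fracs.groupby(["group", "item", "element"]):
            mat, _ = _modality_matrix(df)
            try:
                res = friedman(mat)
            except DegenerateError as exc:
                _log(result, "homothety", str(exc), group=group, item=item,
                     element=element)
                continue
            if res.p < alpha:
                res.posthoc = posthoc_pairs(mat, alpha=alpha,
                                            labels=list(MODALITIES))
            result.homothety[(group, item, element)] = res

    # ---- tunnel game: per-trial evaluation and per-subject fits ----
    if tunnel_trials and geometries is None:
        _log(result, "steering", "tunnel trials present but no geometry catalog given")
    elif tunnel_trials:
        for trial in tunnel_trials:
            geom = geometries.get(trial.geometry_id)
            if geom is None:
                _log(result, "steering", f"unknown geometry {trial.geometry_id}",
                     subject=trial.subject_id, trial=trial.trial_index)
                continue
            st = evaluate_trial(trial, geom, threshold=config.exclusion_threshold)
            result.steering_trials.append(st)
        by_subject: dict[tuple, list[SteeringTrial]] = {}
        for st in result.steering_trials:
            by_subject.setdefault((st.subject_id, st.item), []).append(st)
        group_of = {t.subject_id: t.group for t in tunnel_trials}
        for (subject, item), sts in sorted(by_subject.items()):
            try:
                fit = fit_steering(sts, alpha=alpha, subject_id=subject, item=item)
            except (TooShortError, PenlawsError) as exc:
                _log(result, "steering", f"fit skipped: {exc}",
                     subject=subject, item=item)
                continue
            result.steering_fits.append(fit)

        # ---- contrasts on global MT, RMSE, IP ----
        fits = pd.DataFrame([{**asdict(f), "group": group_of.get(f.subject_id)}
                             for f in result.steering_fits])
        if not fits.empty:
            for metric in ("global_MT", "RMSE", "IP"):
                sub = fits.dropna(subset=[metric])
                for item, df in sub.groupby("item"):
                    g1 = df[df.group == "primary"][metric].to_numpy()
                    g2 = df[df.group == "kindergarten"][metric].to_numpy()
                    if len(g1) >= 3 and len(g2) >= 3:
                        try:
                            result.group_contrasts[(metric, item)] = mann_whitney(g1, g2)
                        except DegenerateError as exc:
                            _log(result, "contrasts", str(exc), metric=metric, item=item)
                for group, df in sub.groupby("group"):
                    pivot = df.pivot_table(index="subject_id", columns="item",
                                           values=metric)
                    if pivot.shape[1] >= 3:
                        try:
                            res = friedman(pivot.to_numpy())
                        except (DegenerateError, ValueError) as exc:
                            _log(result, "contrasts", str(exc), metric=metric,
                                 group=group)
                            continue
                        if res.p < alpha:
                            res.posthoc = posthoc_pairs(
                                pivot.to_numpy(), alpha=alpha,
                                labels=list(pivot.columns))
                        result.item_contrasts[(metric, group)] = res

    n_excluded = sum(st.excluded for st in result.steering_trials)
    result.counts.update({
        "tunnel_excluded": n_excluded,
        "tunnel_measured": sum(st.MT is not None for st in result.steering_trials),
    })
    return result


def _wilcoxon_pair(a: np.ndarray, b: np.ndarray) -> StatResult:
    from .stats import wilcoxon_matched
    return wilcoxon_matched(a, b)


# ---------------------------------------------------------------------------
# rendering

def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _stat_rows(d: dict, key_names: list[str]) -> list[dict]:
    rows = []
    for key, res in d.items():
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(key_names, key))
        row.update({"test": res.test_name, "statistic": res.statistic,
                    "p": res.p, "n": res.n, "method": res.method})
        rows.append(row)
    return rows


def _posthoc_rows(d: dict, key_names: list[str]) -> list[dict]:
    rows = []
    for key, res in d.items():
        if not res.posthoc:
            continue
        key = key if isinstance(key, tuple) else (key,)
        for ph in res.posthoc:
            row = dict(zip(key_names, key))
            row.update({"pair": "|".join(ph["pair"]), "raw_p": ph["raw_p"],
                        "adjusted_p": ph["adjusted_p"],
                        "significant": ph["significant"],
                        "median_diff": ph["median_diff"]})
            rows.append(row)
    return rows


def render_report(result: CohortResult, out_dir: str | Path) -> list[Path]:
    """Write CSV tables and a JSON summary of *result*; returns the paths.

    Float formatting is fixed at 6 significant digits so re-runs on the
    same inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def table(name: str, rows: list[dict]) -> None:
        path = out / name
        df = pd.DataFrame(rows)
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    table("compliance.csv", _stat_rows(result.compliance, ["group", "item"]))
    table("isochrony.csv", _stat_rows(result.isochrony, ["group", "item"]))
    table("isochrony_posthoc.csv", _posthoc_rows(result.isochrony, ["group", "item"]))
    table("developmental.csv", _stat_rows(result.developmental, ["item"]))
    table("homothety.csv",
          _stat_rows(result.homothety, ["group", "item", "element"]))
    table("homothety_posthoc.csv",
          _posthoc_rows(result.homothety, ["group", "item", "element"]))
    table("steering_fits.csv", [asdict(f) for f in result.steering_fits])
    table("steering_trials.csv", [asdict(t) for t in result.steering_trials])
    table("group_contrasts.csv", _stat_rows(result.group_contrasts, ["metric", "item"]))
    table("item_contrasts.csv", _stat_rows(result.item_contrasts, ["metric", "group"]))

    summary = {
        "counts": result.counts,
        "log": result.log,
        "n_steering_fits": len(result.steering_fits),
        "significant_fits": sum(f.IP is not None for f in result.steering_fits),
    }
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=1, default=_fmt), encoding="utf-8")
    written.append(spath)
    return written
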