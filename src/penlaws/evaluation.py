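"""Monte-Carlo evaluation of the pipeline under the generative model.

These drivers answer calibration questions about the whole measurement
chain — generator through statistics — by repeated seeded simulation:

* does the isochrony Friedman test detect compliant speed modulation, and
  stay silent when the modulation is absent?
* is the per-element homothety Friedman test calibrated (false-rejection
  rate near the nominal alpha) on compliant cohorts?
* does the steering-law fit recover the generating slope within its own
  standard error?
* does valley-based word segmentation recover the programmed letter
  transitions under amplitude noise?

Each driver takes an explicit seed and returns plain dicts of rates, so
the same code backs both the test suite and the reporting script.
"""

from __future__ import annotations

import numpy as np

from .errors import SegmentationError
from .kinematics import mean_speed
from .segmentation import fraction_times, segment_sequence, segment_word
from .stats import friedman, posthoc_pairs
from .steering import evaluate_trial, fit_steering, make_geometry
from .synthetic import (MODALITY_FACTORS, GroupConfig, MotorProfile,
                        generate_copy_trial, generate_tunnel_trial)

MODALITIES_ORDER = tuple(MODALITY_FACTORS)


def _subject_profile(gc: GroupConfig, rng: np.random.Generator,
                     beta: float) -> MotorProfile:
    sigma = np.sqrt(np.log(1.0 + gc.base_speed_cv ** 2))
    return MotorProfile(
        isochrony_exponent=beta,
        base_speed=float(gc.base_speed_mean * np.exp(rng.normal(-sigma ** 2 / 2, sigma))),
        fraction_noise_sd=gc.fraction_noise_sd,
        lateral_noise_sd=gc.lateral_noise_sd)


def _speed_matrix(n_subjects: int, beta: float, item: str,
                  rng: np.random.Generator) -> np.ndarray:
    gc = GroupConfig(n_subjects=n_subjects)
    mat = np.empty((n_subjects, len(MODALITIES_ORDER)))
    for i in range(n_subjects):
        profile = _subject_profile(gc, rng, beta)
        for j, modality in enumerate(MODALITIES_ORDER):
            trial = generate_copy_trial(profile, item, modality,
                                        seed=int(rng.integers(2 ** 31)))
            mat[i, j] = mean_speed(trial)
    return mat


def _pair_significant(posthoc: list[dict], a: str, b: str) -> tuple[bool, float]:
    for ph in posthoc:
        if set(ph["pair"]) == {a, b}:
            sign = 1.0 if ph["pair"] == (a, b) else -1.0
            return ph["significant"], sign * ph["median_diff"]
    return False, 0.0


def isochrony_power(n_reps: int = 200, beta: float = 1.0,
                    n_subjects: int = 15, item: str = "circle",
                    alpha: float = 0.05, seed: int = 0) -> dict:
    """Detection rates of the isochrony battery over seeded cohorts.

    Returns the fraction of replicates where the Friedman omnibus on mean
    speed is significant with both big>small and fast>slow post-hoc
    contrasts (``power``), and the fraction where the big-vs-small
    post-hoc alone is significant (``big_small_rate``) — the latter is the
    quantity expected to vanish when ``beta = 0``.
    """
    root = np.random.SeedSequence(seed)
    full_hits = 0
    big_small_hits = 0
    for ss in root.spawn(n_reps):
        rng = np.random.default_rng(ss)
        mat = _speed_matrix(n_subjects, beta, item, rng)
        res = friedman(mat)
        omnibus = res.p < alpha
        ph = posthoc_pairs(mat, alpha=alpha, labels=list(MODALITIES_ORDER))
        bs_sig, bs_diff = _pair_significant(ph, "big", "small")
        fs_sig, fs_diff = _pair_significant(ph, "fast", "slow")
        if omnibus and bs_sig and bs_diff > 0 and fs_sig and fs_diff > 0:
            full_hits += 1
        if omnibus and bs_sig:
            big_small_hits += 1
    return {"power": full_hits / n_reps,
            "big_small_rate": big_small_hits / n_reps,
            "n_reps": n_reps, "beta": beta, "n_subjects": n_subjects}


def homothety_false_rejection(n_reps: int = 500, n_subjects: int = 15,
                              alpha: float = 0.05, seed: int = 0) -> dict:
    """Per-element Friedman rejection rate on homothety-compliant cohorts.

    Fraction times are exchangeable across modalities under the generator
    (fractions perturbed identically regardless of modality), so the null
    holds and the rate estimates the test's actual size.
    """
    root = np.random.SeedSequence(seed)
    rejections = 0
    tests = 0
    gc = GroupConfig(n_subjects=n_subjects)
    for ss in root.spawn(n_reps):
        rng = np.random.default_rng(ss)
        mats = np.empty((n_subjects, len(MODALITIES_ORDER), 3))
        for i in range(n_subjects):
            profile = _subject_profile(gc, rng, beta=1.0)
            for j, modality in enumerate(MODALITIES_ORDER):
                trial = generate_copy_trial(profile, "sequence", modality,
                                            seed=int(rng.integers(2 ** 31)))
                ft = fraction_times(segment_sequence(trial, 3), trial)
                mats[i, j] = ft.fractions
        for e in range(3):
            res = friedman(mats[:, :, e])
            rejections += res.p < alpha
            tests += 1
    return {"false_rejection_rate": rejections / tests, "n_tests": tests,
            "n_reps": n_reps}


def slope_recovery(n_reps: int = 500, true_a: float = 0.8,
                   true_b: float = 0.08, mt_noise_sd: float = 0.1,
                   n_trials: int = 14,
                   ids: tuple[float, ...] = (8.0, 12.0, 18.0, 27.0, 40.0),
                   seed: int = 0) -> dict:
    """Coverage of the generating slope by the fit's +/-3 SE interval.

    Each replicate steers ``n_trials`` noisy tunnel trials through the full
    measurement chain (trajectory synthesis, exclusion check, movement-time
    extraction, OLS) and asks whether the true slope lies within three
    standard errors of the estimate.
    """
    geoms = [make_geometry("circle", A=150.0, W=150.0 / i) for i in ids]
    schedule = [i % len(ids) for i in range(n_trials)]
    profile_kw = dict(steering_a=true_a, steering_b=true_b,
                      mt_noise_sd=mt_noise_sd, lateral_noise_sd=0.3)
    root = np.random.SeedSequence(seed)
    hits = 0
    b_err = []
    for ss in root.spawn(n_reps):
        rng = np.random.default_rng(ss)
        profile = MotorProfile(**profile_kw)
        sts = [evaluate_trial(
            generate_tunnel_trial(profile, geoms[g],
                                  seed=int(rng.integers(2 ** 31))), geoms[g])
            for g in schedule]
        fit = fit_steering(sts)
        b_err.append(fit.b - true_b)
        if abs(fit.b - true_b) <= 3.0 * fit.b_se:
            hits += 1
    return {"coverage_3se": hits / n_reps, "n_reps": n_reps,
            "mean_abs_b_error": float(np.mean(np.abs(b_err)))}


def segmentation_recovery(n_words: int = 100, noise_fraction: float = 0.02,
                          tolerance: float = 0.02, seed: int = 0) -> dict:
    """Fraction of noisy cursive words whose letter transitions are all
    recovered within ``tolerance`` of the programmed arc-length positions.

    ``noise_fraction`` scales the additive coordinate noise to the word's
    letter amplitude (its vertical extent).
    """
    from .templates import make_template
    tpl = make_template("word_mele")
    size_mm = 120.0
    height = (tpl.xy[:, 1].max() - tpl.xy[:, 1].min()) * size_mm
    rng = np.random.default_rng(seed)
    ok = 0
    failures = 0
    for _ in range(n_words):
        profile = MotorProfile(lateral_noise_sd=noise_fraction * height,
                               fraction_noise_sd=0.03)
        trial = generate_copy_trial(profile, "word_mele", "spontaneous",
                                    size_mm=size_mm,
                                    seed=int(rng.integers(2 ** 31)))
        try:
            bounds = segment_word(trial, n_letters=4)
        except SegmentationError:
            failures += 1
            continue
        # judge the chosen samples at their true (pre-noise) arc positions
        arc = np.asarray(trial.truth["sample_arc_fractions"])
        found = np.array([arc[b] for _, b in bounds.intervals[:-1]])
        truth = np.asarray(trial.truth["boundary_arc_fractions"])
        if np.all(np.abs(found - truth) <= tolerance):
            ok += 1
    return {"success_rate": ok / n_words, "n_words": n_words,
            "hard_failures": failures}
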