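"""Optogenetic inactivation statistics.

Three analyses around scanning/pulsed laser experiments:

* the site-wise inactivation effect — the change in the proportion of a
  choice type between laser and non-laser trials (equal non-zero contrast
  trials by default), averaged across sessions — with a session-stratified
  permutation test (laser/control labels shuffled within each session);
* pulse-timing accuracy curves: boxcar-smoothed accuracy as a function of
  laser onset time relative to stimulus, with Clopper-Pearson 95% binomial
  confidence intervals and a per-bin chi-squared test against control trials;
* the correlation between a site's inactivation effect and how strongly
  activity near that site encodes the relevant variable (decoding auROC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .session_data import (
    REGION_COORDS_MM,
    Session,
    TrialRecord,
    is_correct,
)

__all__ = [
    "SiteEffect",
    "laser_effect_statistic",
    "permutation_test",
    "pulse_time_course",
    "effect_vs_encoding_correlation",
    "equal_nonzero_contrast",
]


@dataclass
class SiteEffect:
    """Inactivation effect at one laser site.

    ``statistic`` is the across-session mean of (laser - control) proportion
    of ``choice_type`` responses, in [-1, 1]."""

    site: str | tuple[float, float]
    choice_type: str
    statistic: float
    n_laser_trials: int
    n_control_trials: int
    n_sessions: int
    p_value: float | None = None
    per_session: tuple[float, ...] = ()


def equal_nonzero_contrast(trial: TrialRecord) -> bool:
    """Default trial filter: equal non-zero contrast on the two screens."""
    return trial.contrast_left == trial.contrast_right and trial.contrast_left > 0


def _site_coord(site) -> tuple[float, float] | None:
    if isinstance(site, str):
        return REGION_COORDS_MM.get(site)
    return (float(site[0]), float(site[1]))


def _at_site(trial: TrialRecord, site, tol_mm: float = 0.25) -> bool:
    if isinstance(site, str) and trial.laser_region is not None:
        return trial.laser_region == site
    coord = _site_coord(site)
    if coord is None or trial.laser_coord is None:
        return False
    return (
        abs(trial.laser_coord[0] - coord[0]) <= tol_mm
        and abs(trial.laser_coord[1] - coord[1]) <= tol_mm
    )


def _choice_indicator(choice_type: str) -> Callable[[TrialRecord], bool]:
    ct = choice_type.capitalize() if choice_type.lower() != "go" else "Go"
    if ct == "Go":
        return lambda t: t.choice != "NoGo"
    if ct in {"Left", "Right", "Nogo"}:
        target = "NoGo" if ct == "Nogo" else ct
        return lambda t: t.choice == target
    raise ValueError(f"unknown choice type {choice_type!r}")


def _session_masks(session, site, trial_filter):
    """Boolean (is_laser_at_site, indicator) arrays over filtered trials."""
    rows = []
    for t in session.trials:
        if not trial_filter(t):
            continue
        if t.laser_on and not _at_site(t, site):
            continue  # laser trial at a different site: not a control
        rows.append(t)
    return rows


def laser_effect_statistic(
    sessions: Sequence[Session],
    site,
    choice_type: str,
    trial_filter: Callable[[TrialRecord], bool] = equal_nonzero_contrast,
) -> SiteEffect:
    """Across-session mean change in choice-type proportion (laser - control).

    Sessions lacking either a laser trial at the site or a control trial
    (after filtering) are skipped.  Raises if no session qualifies.
    """
    indicator = _choice_indicator(choice_type)
    deltas, n_laser, n_control = [], 0, 0
    for session in sessions:
        rows = _session_masks(session, site, trial_filter)
        laser = [t for t in rows if t.laser_on]
        control = [t for t in rows if not t.laser_on]
        if not laser or not control:
            continue
        p_laser = np.mean([indicator(t) for t in laser])
        p_control = np.mean([indicator(t) for t in control])
        deltas.append(float(p_laser - p_control))
        n_laser += len(laser)
        n_control += len(control)
    if not deltas:
        raise ValueError(f"no session has both laser and control trials at {site!r}")
    return SiteEffect(
        site, choice_type, float(np.mean(deltas)),
        n_laser, n_control, len(deltas), per_session=tuple(deltas),
    )


def permutation_test(
    sessions: Sequence[Session],
    site,
    choice_type: str,
    n_perm: int = 10000,
    seed: int = 0,
    trial_filter: Callable[[TrialRecord], bool] = equal_nonzero_contrast,
) -> SiteEffect:
    """Session-stratified permutation test of the inactivation effect.

    The null distribution is built by shuffling laser/control identities
    within each session (per-session counts preserved — trials never mix
    across sessions), recomputing the across-session mean difference each
    time.  Two-sided p with the add-one convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = laser_effect_statistic(sessions, site, choice_type, trial_filter)
    indicator = _choice_indicator(choice_type)
    rng = np.random.default_rng(seed)

    per_session = []
    for session in sessions:
        rows = _session_masks(session, site, trial_filter)
        n_l = sum(t.laser_on for t in rows)
        if n_l == 0 or n_l == len(rows):
            continue
        y = np.array([indicator(t) for t in rows], dtype=float)
        per_session.append((y, n_l))

    null = np.zeros(n_perm)
    for y, n_l in per_session:
        n = len(y)
        # vectorised within-session shuffles: first n_l of a random order
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        lasered = np.take(y, order[:, :n_l]).mean(axis=1)
        controls = np.take(y, order[:, n_l:]).mean(axis=1)
        null += lasered - controls
    null /= len(per_session)
    exceed = np.sum(np.abs(null) >= abs(observed.statistic) - 1e-12)
    p = (1.0 + float(exceed)) / (n_perm + 1.0)
    return SiteEffect(
        observed.site, observed.choice_type, observed.statistic,
        observed.n_laser_trials, observed.n_control_trials,
        observed.n_sessions, p_value=p, per_session=observed.per_session,
    )


# ---------------------------------------------------------------------------
# Pulse-timing accuracy curves
# ---------------------------------------------------------------------------


def _laser_hemisphere(trial: TrialRecord) -> str | None:
    """'L' or 'R' from the laser site (named region suffix or ML sign)."""
    if trial.laser_region is not None:
        if trial.laser_region.endswith("_L"):
            return "L"
        if trial.laser_region.endswith("_R"):
            return "R"
    if trial.laser_coord is not None:
        return "L" if trial.laser_coord[1] < 0 else "R"
    return None


def contra_gt_ipsi(trial: TrialRecord) -> bool:
    """Contralateral (to the laser site) contrast exceeds ipsilateral."""
    hemi = _laser_hemisphere(trial)
    if hemi is None:
        return trial.contrast_left != trial.contrast_right
    contra, ipsi = (
        (trial.contrast_right, trial.contrast_left)
        if hemi == "L"
        else (trial.contrast_left, trial.contrast_right)
    )
    return contra > ipsi


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def pulse_time_course(
    trials: Sequence[TrialRecord],
    grid_step: float = 0.01,
    window: float = 0.1,
    t_min: float = -0.3,
    t_max: float = 0.3,
    accuracy_definition: Callable[[TrialRecord], bool] = is_correct,
    trial_filter: Callable[[TrialRecord], bool] = contra_gt_ipsi,
):
    """Accuracy vs laser-pulse onset time, boxcar smoothed.

    For each grid time t, accuracy pools the laser trials whose onset lies in
    [t - window/2, t + window/2] (a ``window``-wide boxcar).  Per bin:
    Clopper-Pearson 95% CI and a chi-squared test of the 2x2
    correct/incorrect x laser/control table against the (time-independent)
    control trials.  Empty bins are reported as NaN.

    Trials default-filtered to contralateral > ipsilateral contrast; controls
    are the filtered non-laser trials (filter applied with no laser
    hemisphere: unequal contrasts).

    Returns a dict of arrays: 'time', 'accuracy', 'ci_lo', 'ci_hi',
    'n_trials', 'chi2_p', plus scalars 'control_accuracy', 'n_control'.
    """
    laser = [
        t for t in trials
        if t.laser_on and math.isfinite(t.laser_onset_s) and trial_filter(t)
    ]
    control = [t for t in trials if not t.laser_on and trial_filter(t)]
    if not laser:
        raise ValueError("no laser trials with onset times after filtering")
    if not control:
        raise ValueError("no control trials after filtering")
    onsets = np.array([t.laser_onset_s for t in laser])
    correct = np.array([accuracy_definition(t) for t in laser], dtype=bool)
    ctrl_k = int(sum(accuracy_definition(t) for t in control))
    ctrl_n = len(control)

    grid = np.arange(t_min, t_max + grid_step / 2, grid_step)
    acc = np.full(grid.size, np.nan)
    lo = np.full(grid.size, np.nan)
    hi = np.full(grid.size, np.nan)
    n_in = np.zeros(grid.size, dtype=int)
    chi2_p = np.full(grid.size, np.nan)
    half = window / 2.0
    for i, t0 in enumerate(grid):
        in_bin = (onsets >= t0 - half) & (onsets <= t0 + half)
        n = int(in_bin.sum())
        n_in[i] = n
        if n == 0:
            continue
        k = int(correct[in_bin].sum())
        acc[i] = k / n
        lo[i], hi[i] = _clopper_pearson(k, n)
        table = np.array([[k, n - k], [ctrl_k, ctrl_n - ctrl_k]])
        if np.all(table.sum(axis=0) > 0):
            chi2_p[i] = float(stats.chi2_contingency(table, correction=False)[1])
    return {
        "time": grid,
        "accuracy": acc,
        "ci_lo": lo,
        "ci_hi": hi,
        "n_trials": n_in,
        "chi2_p": chi2_p,
        "control_accuracy": ctrl_k / ctrl_n,
        "n_control": ctrl_n,
    }


# ---------------------------------------------------------------------------
# Effect vs encoding correlation
# ---------------------------------------------------------------------------


def effect_vs_encoding_correlation(
    site_effects: Sequence[SiteEffect],
    encoding_coords: np.ndarray,
    encoding_aurocs: Sequence[float],
    radius_mm: float = 0.5,
    signed: bool = False,
):
    """Pearson correlation between inactivation effects and local encoding.

    Each site's encoding value is the mean decoding auROC over map entries
    within ``radius_mm`` of the site coordinate.  Effects enter as |effect|
    unless ``signed``.  Returns dict with 'r', 'p', 'slope', 'intercept',
    'effects', 'encoding'.
    """
    if len(site_effects) < 3:
        raise ValueError("need at least three sites")
    encoding_coords = np.asarray(encoding_coords, dtype=float).reshape(-1, 2)
    encoding_aurocs = np.asarray(encoding_aurocs, dtype=float)
    effects, encoding = [], []
    for se in site_effects:
        coord = _site_coord(se.site)
        if coord is None:
            raise ValueError(f"no coordinate for site {se.site!r}")
        d = np.hypot(
            encoding_coords[:, 0] - coord[0], encoding_coords[:, 1] - coord[1]
        )
        near = d <= radius_mm
        if not near.any():
            raise ValueError(f"no encoding-map entries within {radius_mm} mm of {se.site!r}")
        encoding.append(float(encoding_aurocs[near].mean()))
        effects.append(se.statistic if signed else abs(se.statistic))
    effects = np.asarray(effects)
    encoding = np.asarray(encoding)
    if np.ptp(effects) == 0.0 or np.ptp(encoding) == 0.0:
        raise ValueError("zero variance in effects or encoding; correlation undefined")
    r, p = stats.pearsonr(encoding, effects)
    slope, intercept = np.polyfit(encoding, effects, 1)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(slope),
        "intercept": float(intercept),
        "effects": effects,
        "encoding": encoding,
    }
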