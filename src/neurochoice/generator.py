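"""Synthetic 2AUC session generator.

Emulates the statistical structure of the visual discrimination task that
the downstream analyses assume: 16 contrast-pair conditions (4 levels per
screen side) weighted towards easy trials, choices drawn from the
psychometric or neurometric generative models with session- and
subject-level parameter variation, and region activity carrying
contralateral-stimulus coding, bilateral pre-movement (Go vs NoGo) coding,
choice (Left vs Right) coding, and additive Gaussian noise.  Laser trials
attenuate the targeted region's activity before choices are drawn.

The default condition weights encode the task's trial-type frequencies:
zero-zero trials ~31%, single-side high- and medium-vs-zero trials ~24%
combined, equal non-zero contrast trials ~12%, and the remaining eight
comparison conditions uniformly share the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .neurometric import NeuroSessionParams, neurometric_decision_variables
from .psychometric import (
    N_FLOOR,
    PsychSessionParams,
    choice_probabilities,
    decision_variables,
)
from .session_data import (
    CHOICES,
    REGIONS,
    ActivityMatrix,
    Session,
    TrialRecord,
    rewarded_choices,
)

__all__ = [
    "DEFAULT_CONTRAST_LEVELS",
    "GeneratorConfig",
    "CodingGains",
    "LaserDesign",
    "default_condition_weights",
    "sample_trials",
    "simulate_choices",
    "simulate_region_activity",
    "simulate_inactivation_session",
    "sample_psych_hierarchy",
    "generate_psych_dataset",
]

DEFAULT_CONTRAST_LEVELS = (0.0, 0.25, 0.5, 1.0)

#: Default activity window (s post-stimulus) attached to generated activity.
DEFAULT_WINDOW = (0.075, 0.175)


def default_condition_weights(
    levels: Sequence[float] = DEFAULT_CONTRAST_LEVELS,
    p_zero: float = 0.31,
    p_easy_single: float = 0.24,
    p_equal: float = 0.12,
) -> dict[tuple[float, float], float]:
    """Per-condition sampling probabilities over the 16 contrast pairs.

    ``p_easy_single`` is the combined mass of the four single-side high- and
    medium-vs-zero conditions; ``p_equal`` the combined mass of the three
    equal non-zero conditions; all other comparison conditions split the
    remainder uniformly.
    """
    levels = tuple(sorted(levels))
    if len(levels) != 4 or levels[0] != 0.0:
        raise ValueError("expected four contrast levels including 0")
    high, medium = levels[3], levels[2]
    weights: dict[tuple[float, float], float] = {}
    easy_single = {(high, 0.0), (0.0, high), (medium, 0.0), (0.0, medium)}
    equal_nonzero = {(c, c) for c in levels[1:]}
    other = [
        (a, b)
        for a in levels
        for b in levels
        if (a, b) != (0.0, 0.0) and (a, b) not in easy_single and (a, b) not in equal_nonzero
    ]
    p_rest = 1.0 - p_zero - p_easy_single - p_equal
    if p_rest < 0:
        raise ValueError("trial-type masses exceed 1")
    weights[(0.0, 0.0)] = p_zero
    for cond in easy_single:
        weights[cond] = p_easy_single / len(easy_single)
    for cond in equal_nonzero:
        weights[cond] = p_equal / len(equal_nonzero)
    for cond in other:
        weights[cond] = p_rest / len(other)
    return weights


@dataclass
class CodingGains:
    """Per-region coding gains for synthetic activity.

    value(region, trial) = stim * (contralateral contrast)^q
                         + exec * 1[choice != NoGo]
                         + select * (+1 contraversive / -1 ipsiversive choice)
                         + N(0, noise_sd)

    Contralateral mapping is fixed: right-hemisphere regions (VISp_R, MOs_R)
    load on the left-screen contrast and vice versa.
    """

    stim: Mapping[str, float] = field(
        default_factory=lambda: {"VISp_L": 1.0, "VISp_R": 1.0, "MOs_L": 0.5, "MOs_R": 0.5}
    )
    exec_: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.5 for r in REGIONS}
    )
    select: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REGIONS}
    )
    noise_sd: float = 0.5
    contrast_exponent: float = 1.0

    def __post_init__(self) -> None:
        for name, table in (("stim", self.stim), ("exec", self.exec_)):
            for region, g in table.items():
                if g < 0:
                    raise ValueError(f"{name} gain for {region} must be >= 0, got {g}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LaserDesign:
    """Optogenetic design: which regions, how often, and how strongly."""

    sites: tuple[str, ...] = ("VISp_L", "VISp_R", "MOs_L", "MOs_R")
    fraction: float = 0.25
    power_mw: float = 1.5
    attenuation: float = 0.0  # multiplies target-region activity; 0 = silencing
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("laser fraction must lie in [0, 1]")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        for site in self.sites:
            if site not in REGIONS:
                raise ValueError(f"laser site {site!r} not in region list {REGIONS}")


@dataclass
class GeneratorConfig:
    n_trials: int = 500
    n_sessions: int = 4
    n_subjects: int = 6
    contrast_levels: tuple[float, ...] = DEFAULT_CONTRAST_LEVELS
    condition_weights: dict[tuple[float, float], float] | None = None
    gains: CodingGains = field(default_factory=CodingGains)
    laser: LaserDesign | None = None
    rt_median_s: float = 0.25
    rt_sigma_log: float = 0.3

    def weights(self) -> dict[tuple[float, float], float]:
        w = self.condition_weights or default_condition_weights(self.contrast_levels)
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"condition weights must sum to 1, got {total}")
        return w


# ---------------------------------------------------------------------------
# Trial sampling and choice simulation
# ---------------------------------------------------------------------------


def sample_trials(
    config: GeneratorConfig,
    seed: int,
    session_id: str = "s0",
    subject_id: str = "m0",
) -> list[TrialRecord]:
    """Draw i.i.d. stimulus conditions for one session (choices unset)."""
    weights = config.weights()
    conditions = list(weights)
    probs = np.array([weights[c] for c in conditions])
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(conditions), size=config.n_trials, p=probs)
    trials = []
    for i, k in enumerate(idx):
        cL, cR = conditions[k]
        trials.append(
            TrialRecord(
                trial_id=i,
                session_id=session_id,
                subject_id=subject_id,
                contrast_left=cL,
                contrast_right=cR,
                choice=None,
            )
        )
    return trials


def _draw_choices_and_rts(p_matrix: np.ndarray, config: GeneratorConfig, rng):
    """Vectorised categorical draw + log-normal reaction times for Go."""
    n = p_matrix.shape[0]
    u = rng.random(n)
    cum = np.cumsum(p_matrix, axis=1)
    y = (u[:, None] > cum).sum(axis=1)  # 0 Left, 1 Right, 2 NoGo
    rts = rng.lognormal(math.log(config.rt_median_s), config.rt_sigma_log, size=n)
    rts[y == 2] = math.nan
    return y, rts


def _finalise_trial(trial: TrialRecord, choice: str, rt: float, rng) -> TrialRecord:
    rewarded = rewarded_choices(trial.contrast_left, trial.contrast_right)
    if choice in rewarded:
        # equal-contrast trials reward Left/Right with 50% probability
        reward = 1.0 if len(rewarded) == 1 or rng.random() < 0.5 else 0.0
    else:
        reward = 0.0
    return replace(trial, choice=choice, reaction_time=rt, reward=reward)


def simulate_choices(
    trials: Sequence[TrialRecord],
    psych: PsychSessionParams,
    seed: int,
    config: GeneratorConfig | None = None,
) -> list[TrialRecord]:
    """Draw choices from the psychometric softmax; attach RTs and rewards."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    cL = np.array([t.contrast_left for t in trials])
    cR = np.array([t.contrast_right for t in trials])
    pL, pR, p0 = choice_probabilities(*decision_variables(psych, cL, cR))
    y, rts = _draw_choices_and_rts(np.stack([pL, pR, p0], axis=1), config, rng)
    return [
        _finalise_trial(t, CHOICES[yi], rt, rng)
        for t, yi, rt in zip(trials, y, rts)
    ]


# ---------------------------------------------------------------------------
# Region activity
# ---------------------------------------------------------------------------


def _stimulus_component(trials, gains: CodingGains) -> np.ndarray:
    cL = np.array([t.contrast_left for t in trials])
    cR = np.array([t.contrast_right for t in trials])
    q = gains.contrast_exponent
    contra = {  # contralateral contrast per region
        "VISp_L": cR, "MOs_L": cR, "VISp_R": cL, "MOs_R": cL,
    }
    cols = [gains.stim.get(r, 0.0) * contra[r] ** q for r in REGIONS]
    return np.stack(cols, axis=1)


def simulate_region_activity(
    trials: Sequence[TrialRecord],
    gains: CodingGains | None = None,
    seed: int = 0,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> ActivityMatrix:
    """Synthesize per-trial region activity from trials *with* choices."""
    gains = gains or CodingGains()
    if any(t.choice is None for t in trials):
        raise ValueError("trials must have choices; run simulate_choices first")
    rng = np.random.default_rng(seed)
    values = _stimulus_component(trials, gains)
    go = np.array([t.choice != "NoGo" for t in trials], dtype=float)
    left = np.array([t.choice == "Left" for t in trials], dtype=float)
    right = np.array([t.choice == "Right" for t in trials], dtype=float)
    # contraversive choice: Left choice for right-hemisphere regions
    select_sign = {
        "VISp_L": right - left, "MOs_L": right - left,
        "VISp_R": left - right, "MOs_R": left - right,
    }
    for j, r in enumerate(REGIONS):
        values[:, j] += gains.exec_.get(r, 0.0) * go
        values[:, j] += gains.select.get(r, 0.0) * select_sign[r]
    values += rng.normal(0.0, gains.noise_sd, size=values.shape)
    return ActivityMatrix(
        np.array([t.trial_id for t in trials]), REGIONS, (window,), values[:, :, None]
    )


# ---------------------------------------------------------------------------
# Inactivation sessions (neurometric generative model)
# ---------------------------------------------------------------------------


def simulate_inactivation_session(
    config: GeneratorConfig,
    neuro: NeuroSessionParams,
    seed: int,
    session_id: str = "s0",
    subject_id: str = "m0",
) -> tuple[Session, ActivityMatrix]:
    """One session whose choices are generated by the neurometric model.

    Activity is stimulus coding plus noise (choices cannot feed back into the
    activity that generates them); on laser trials the targeted region's
    activity is multiplied by the design's attenuation factor *before* the
    choice is drawn, emulating optogenetic silencing.
    """
    if config.laser is None:
        raise ValueError("config.laser must be set for inactivation sessions")
    rng = np.random.default_rng(seed)
    trials = sample_trials(config, int(rng.integers(2**31)), session_id, subject_id)
    gains = config.gains
    values = _stimulus_component(trials, gains)
    values += rng.normal(0.0, gains.noise_sd, size=values.shape)

    n = len(trials)
    laser_on = rng.random(n) < config.laser.fraction
    site_idx = rng.integers(len(config.laser.sites), size=n)
    sites = [config.laser.sites[k] if on else None for k, on in zip(site_idx, laser_on)]
    perceived = values.copy()
    for i, site in enumerate(sites):
        if site is not None:
            perceived[i, REGIONS.index(site)] *= config.laser.attenuation

    ZL, ZR = neurometric_decision_variables(neuro, perceived)
    pL, pR, p0 = choice_probabilities(ZL, ZR)
    y, rts = _draw_choices_and_rts(np.stack([pL, pR, p0], axis=1), config, rng)

    out_trials = []
    for t, yi, rt, site in zip(trials, y, rts, sites):
        t = _finalise_trial(t, CHOICES[yi], rt, rng)
        if site is not None:
            t = replace(
                t,
                laser_on=True,
                laser_region=site,
                laser_power_mw=config.laser.power_mw,
                laser_onset_s=config.laser.onset_s,
            )
        out_trials.append(t)
    session = Session(session_id, subject_id, out_trials)
    activity = ActivityMatrix(
        np.array([t.trial_id for t in out_trials]),
        REGIONS,
        (DEFAULT_WINDOW,),
        values[:, :, None],  # recorded (pre-attenuation) activity
    )
    return session, activity


# ---------------------------------------------------------------------------
# Hierarchical ground-truth sampling (for recovery studies)
# ---------------------------------------------------------------------------


def sample_psych_hierarchy(
    grand: PsychSessionParams,
    n_subjects: int,
    n_sessions: int,
    seed: int,
    subject_sd: Sequence[float] = (0.15, 0.15, 0.3, 0.3, 0.05),
    session_sd: Sequence[float] = (0.15, 0.15, 0.3, 0.3, 0.05),
) -> list[list[PsychSessionParams]]:
    """Subject means around the grand mean, session params around each
    subject; the contrast exponent is clipped into its (0, 1] domain."""
    rng = np.random.default_rng(seed)
    g = grand.as_array()
    subject_sd = np.asarray(subject_sd, float)
    session_sd = np.asarray(session_sd, float)
    out = []
    for _ in range(n_subjects):
        mu_m = g + rng.normal(0.0, subject_sd)
        sessions = []
        for _ in range(n_sessions):
            theta = mu_m + rng.normal(0.0, session_sd)
            theta[4] = float(np.clip(theta[4], N_FLOOR, 1.0))
            sessions.append(PsychSessionParams.from_array(theta))
        out.append(sessions)
    return out


def generate_psych_dataset(
    grand: PsychSessionParams,
    config: GeneratorConfig,
    seed: int,
    subject_sd: Sequence[float] = (0.15, 0.15, 0.3, 0.3, 0.05),
    session_sd: Sequence[float] = (0.15, 0.15, 0.3, 0.3, 0.05),
) -> list[Session]:
    """Full multi-subject, multi-session behavioral dataset from known
    grand-truth psychometric parameters."""
    rng = np.random.default_rng(seed)
    hierarchy = sample_psych_hierarchy(
        grand, config.n_subjects, config.n_sessions, int(rng.integers(2**31)),
        subject_sd, session_sd,
    )
    sessions = []
    for m, subject_sessions in enumerate(hierarchy):
        for d, params in enumerate(subject_sessions):
            sid, mid = f"m{m}_s{d}", f"m{m}"
            trials = sample_trials(config, int(rng.integers(2**31)), sid, mid)
            trials = simulate_choices(trials, params, int(rng.integers(2**31)), config)
            sessions.append(Session(sid, mid, trials))
    return sessions
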