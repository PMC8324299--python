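"""Neurometric model: choices from cortical population activity.

Decision variables are weighted sums of estimated population firing rates in
four regions (left/right primary visual cortex VISp and left/right secondary
motor cortex MOs), with hemispheric weight symmetry:

    ZL = alphaL + vc*VR + vi*VL + mc*MR + mi*ML
    ZR = alphaR + vi*VR + vc*VL + mi*MR + mc*ML

where vc/vi (mc/mi) are weights from contralateral/ipsilateral visual
(frontal) cortex.  Choice probabilities follow the same three-way softmax as
the psychometric model.  Because widefield dF/F has no meaningful baseline,
fluorescence is first calibrated to electrophysiologically measured firing
rates by per-region linear regression over the 16 contrast conditions
(activity windows: VISp 75-125 ms, MOs 125-175 ms post-stimulus; fluorescence
taken 30 ms later to allow for slower indicator kinetics).

Inactivation of a region is modelled by zeroing the corresponding element of
the rate vector f before evaluating the decision variables; the prediction
uses no inactivation data, so it constitutes an out-of-sample test of the
fitted weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from ._hier import (
    HierarchicalModel,
    PosteriorDraws,
    SamplerConfig,
    fit_map,
    fit_mcmc,
)
from .psychometric import choice_probabilities
from .session_data import REGIONS, ActivityMatrix, Session, rewarded_choices

__all__ = [
    "NeuroSessionParams",
    "CalibrationFit",
    "PARAM_NAMES",
    "DEFAULT_WINDOWS",
    "calibrate_fluorescence",
    "neurometric_decision_variables",
    "fit_neurometric",
    "refit_offsets",
    "predict_inactivation",
    "aggregate_unilateral",
]

PARAM_NAMES = ("alphaL", "alphaR", "vc", "vi", "mc", "mi")

#: Electrophysiology alignment windows (s post-stimulus) per region family,
#: and the fluorescence lag accounting for indicator kinetics.
DEFAULT_WINDOWS: Mapping[str, tuple[float, float]] = {
    "VISp": (0.075, 0.125),
    "MOs": (0.125, 0.175),
}
DEFAULT_FLUORESCENCE_LAG_S = 0.030


@dataclass(frozen=True)
class NeuroSessionParams:
    """Session-level neurometric parameters.

    Offsets are log-odds; weights are log-odds per (spikes/s).  The weight
    vectors over the fixed region order (VISp_L, VISp_R, MOs_L, MOs_R) follow
    from the hemispheric symmetry constraint.
    """

    alphaL: float = 0.0
    alphaR: float = 0.0
    vc: float = 0.0
    vi: float = 0.0
    mc: float = 0.0
    mi: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"parameters must be finite: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alphaL, self.alphaR, self.vc, self.vi, self.mc, self.mi])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "NeuroSessionParams":
        return cls(*(float(v) for v in a))

    @property
    def wL(self) -> np.ndarray:
        return np.array([self.vi, self.vc, self.mi, self.mc])

    @property
    def wR(self) -> np.ndarray:
        return np.array([self.vc, self.vi, self.mc, self.mi])


def neurometric_decision_variables(params: NeuroSessionParams, f):
    """(ZL, ZR) for rate vectors ``f`` of shape (..., 4) in region order."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != len(REGIONS):
        raise ValueError(f"rate vector must have length {len(REGIONS)}")
    if not np.all(np.isfinite(f)):
        raise ValueError("rate vector must be finite")
    ZL = params.alphaL + f @ params.wL
    ZR = params.alphaR + f @ params.wR
    return ZL, ZR


# ---------------------------------------------------------------------------
# Fluorescence-to-rate calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationFit:
    """Per-region linear map from fluorescence units to spikes/s."""

    slope: dict[str, float]
    intercept: dict[str, float]
    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    fluorescence_lag_s: float = DEFAULT_FLUORESCENCE_LAG_S

    def apply(self, region: str, fluorescence) -> np.ndarray:
        return self.slope[region] * np.asarray(fluorescence, float) + self.intercept[region]

    def apply_matrix(self, fluor: np.ndarray, regions: Sequence[str] = REGIONS) -> np.ndarray:
        out = np.empty_like(np.asarray(fluor, dtype=float))
        for j, region in enumerate(regions):
            out[..., j] = self.apply(region, fluor[..., j])
        return out


def calibrate_fluorescence(
    wf_condition_means: Mapping[str, Sequence[float]],
    ephys_condition_means: Mapping[str, Sequence[float]],
    condition_labels: Sequence | None = None,
) -> CalibrationFit:
    """Ordinary least-squares rate-vs-fluorescence fit per region.

    Both inputs map region name -> 16 per-condition means (or mappings with
    identical condition labels).  Raises on mismatched labels or a region
    whose fluorescence means have zero variance (degenerate regressor).
    """
    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    if set(wf_condition_means) != set(ephys_condition_means):
        raise ValueError("region sets differ between fluorescence and ephys inputs")
    for region in wf_condition_means:
        x = wf_condition_means[region]
        y = ephys_condition_means[region]
        if isinstance(x, Mapping) or isinstance(y, Mapping):
            if set(x) != set(y):
                raise ValueError(f"condition labels differ for region {region}")
            labels = sorted(x)
            x = [x[k] for k in labels]
            y = [y[k] for k in labels]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"condition count mismatch for region {region}")
        if np.ptp(x) == 0.0:
            raise ValueError(
                f"fluorescence means for region {region} have zero variance"
            )
        slope, intercept = np.polyfit(x, y, 1)
        slopes[region] = float(slope)
        intercepts[region] = float(intercept)
    return CalibrationFit(slopes, intercepts)


# ---------------------------------------------------------------------------
# Hierarchical fitting
# ---------------------------------------------------------------------------

_CHOICE_INDEX = {"Left": 0, "Right": 1, "NoGo": 2}


@dataclass
class _NeuroSessionData:
    F: np.ndarray  # (n_trials, 4) rates, region order
    y: np.ndarray  # 0 Left, 1 Right, 2 NoGo


class _NeuroModel(HierarchicalModel):
    param_names = PARAM_NAMES
    transforms = (None,) * 6
    mu0 = np.zeros(6)
    sigma0 = np.full(6, 4.0)

    def loglik_grad(self, theta: np.ndarray, data: _NeuroSessionData):
        params = NeuroSessionParams.from_array(theta)
        F, y = data.F, data.y
        ZL, ZR = neurometric_decision_variables(params, F)
        pL, pR, p0 = choice_probabilities(ZL, ZR)
        probs = np.stack([pL, pR, p0], axis=-1)
        p_obs = np.maximum(probs[np.arange(len(y)), y], 1e-300)
        ll = float(np.sum(np.log(p_obs)))
        dL = (y == 0).astype(float) - pL
        dR = (y == 1).astype(float) - pR
        fVL, fVR, fML, fMR = F[:, 0], F[:, 1], F[:, 2], F[:, 3]
        grad = np.array(
            [
                np.sum(dL),
                np.sum(dR),
                np.sum(dL * fVR + dR * fVL),  # vc
                np.sum(dL * fVL + dR * fVR),  # vi
                np.sum(dL * fMR + dR * fML),  # mc
                np.sum(dL * fML + dR * fMR),  # mi
            ]
        )
        return ll, grad


def _session_rates(session: Session, activity: ActivityMatrix, include_laser: bool):
    trials = [t for t in session.trials if include_laser or not t.laser_on]
    ids = [t.trial_id for t in trials]
    try:
        F = activity.for_trials(ids)
    except ValueError as err:
        raise ValueError(f"session {session.session_id}: {err}") from err
    y = np.array([_CHOICE_INDEX[t.choice] for t in trials], dtype=int)
    return _NeuroSessionData(F, y)


def fit_neurometric(
    sessions: Sequence[Session],
    activities: Sequence[ActivityMatrix],
    seed: int = 0,
    method: str = "map",
    sampler: SamplerConfig | None = None,
    n_draws: int = 1000,
    include_laser: bool = False,
) -> PosteriorDraws:
    """Hierarchical fit of {alphaL, alphaR, vc, vi, mc, mi} across sessions.

    Hemispheric symmetry is built into the parameterisation (the same four
    weights enter ZL and ZR mirrored).  The hierarchy over sessions and
    subjects mirrors the psychometric model; grand means carry N(0, 4^2)
    priors.
    """
    if len(sessions) != len(activities):
        raise ValueError("need one ActivityMatrix per session")
    if not sessions:
        raise ValueError("at least one session is required")
    subject_ids = list(dict.fromkeys(s.subject_id for s in sessions))
    session_ids = [s.session_id for s in sessions]
    subject_of = [subject_ids.index(s.subject_id) for s in sessions]
    datasets = [
        _session_rates(s, a, include_laser) for s, a in zip(sessions, activities)
    ]
    model = _NeuroModel()
    if method == "map":
        return fit_map(
            model, datasets, subject_of, subject_ids, session_ids,
            seed=seed, n_draws=n_draws,
        )
    if method == "mcmc":
        return fit_mcmc(
            model, datasets, subject_of, subject_ids, session_ids,
            seed=seed, sampler=sampler,
        )
    raise ValueError(f"unknown method {method!r}; use 'map' or 'mcmc'")


# ---------------------------------------------------------------------------
# Inactivation prediction
# ---------------------------------------------------------------------------


def refit_offsets(
    params: NeuroSessionParams,
    F: np.ndarray,
    choices: Sequence[str],
) -> NeuroSessionParams:
    """Re-estimate (alphaL, alphaR) by maximum likelihood, weights frozen.

    Used when transferring the model to sessions whose overall response
    tendency differs from the sessions the weights were fitted on.
    """
    F = np.asarray(F, dtype=float)
    y = np.array([_CHOICE_INDEX[c] for c in choices], dtype=int)
    base_L = F @ params.wL
    base_R = F @ params.wR

    def neg(a):
        ZL = a[0] + base_L
        ZR = a[1] + base_R
        pL, pR, p0 = choice_probabilities(ZL, ZR)
        probs = np.stack([pL, pR, p0], axis=-1)
        p_obs = np.maximum(probs[np.arange(len(y)), y], 1e-300)
        dL = (y == 0).astype(float) - pL
        dR = (y == 1).astype(float) - pR
        return -float(np.sum(np.log(p_obs))), -np.array([dL.sum(), dR.sum()])

    res = optimize.minimize(neg, np.array([params.alphaL, params.alphaR]), jac=True)
    return NeuroSessionParams(
        float(res.x[0]), float(res.x[1]), params.vc, params.vi, params.mc, params.mi
    )


def _zeroed(F: np.ndarray, target_region: str | None, attenuation: float = 0.0):
    if target_region is None:
        return F
    if target_region not in REGIONS:
        raise ValueError(f"unknown region {target_region!r}; expected one of {REGIONS}")
    F = np.array(F, dtype=float, copy=True)
    F[..., REGIONS.index(target_region)] *= attenuation
    return F


def predict_inactivation(
    params_or_draws,
    condition_rates: np.ndarray,
    target_region: str | None = None,
    attenuation: float = 0.0,
    refit_trials: tuple[np.ndarray, Sequence[str]] | None = None,
):
    """Per-condition choice probabilities under simulated inactivation.

    Parameters
    ----------
    params_or_draws : a :class:`NeuroSessionParams` (point prediction) or
        :class:`PosteriorDraws` from :func:`fit_neurometric` (grand-level
        draws; zeroing is applied per draw and 95% credible intervals are
        returned).
    condition_rates : (n_conditions, 4) mean rate vectors f per contrast
        condition, region order (VISp_L, VISp_R, MOs_L, MOs_R).
    target_region : region whose rate is attenuated (default factor 0.0 =
        full silencing); None leaves activity untouched.
    refit_trials : optional (F, choices) of non-laser trials on which the
        offsets are re-fit with weights frozen before predicting.

    Returns
    -------
    dict with 'mean' (n_conditions, 3) probabilities ordered
    (pLeft, pRight, pNoGo); with draws also 'lo'/'hi' 95% interval bounds.
    """
    condition_rates = np.asarray(condition_rates, dtype=float)
    if condition_rates.ndim != 2 or condition_rates.shape[1] != len(REGIONS):
        raise ValueError("condition_rates must have shape (n_conditions, 4)")
    Fz = _zeroed(condition_rates, target_region, attenuation)

    def point(params: NeuroSessionParams):
        if refit_trials is not None:
            params = refit_offsets(params, refit_trials[0], refit_trials[1])
        pL, pR, p0 = choice_probabilities(*neurometric_decision_variables(params, Fz))
        return np.stack([pL, pR, p0], axis=-1)

    if isinstance(params_or_draws, NeuroSessionParams):
        return {"mean": point(params_or_draws)}
    draws: PosteriorDraws = params_or_draws
    preds = np.stack(
        [point(NeuroSessionParams.from_array(row)) for row in draws.grand]
    )
    lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
    return {"mean": preds.mean(axis=0), "lo": lo, "hi": hi, "draws": preds}


def aggregate_unilateral(
    probs: np.ndarray, conditions: Sequence[tuple[float, float]]
) -> dict[str, float]:
    """Average (pLeft, pRight, pNoGo) over unilateral-stimulus conditions into
    Correct / Incorrect / Miss probabilities.

    A condition is unilateral when exactly one side has non-zero contrast;
    Correct is the choice toward that side, Incorrect the opposite wheel turn,
    Miss the NoGo response.
    """
    probs = np.asarray(probs, dtype=float)
    rows = {"Correct": [], "Incorrect": [], "Miss": []}
    for p, (cL, cR) in zip(probs, conditions):
        if (cL > 0) == (cR > 0):
            continue
        rewarded = rewarded_choices(cL, cR)[0]
        if rewarded == "Left":
            rows["Correct"].append(p[0]); rows["Incorrect"].append(p[1])
        else:
            rows["Correct"].append(p[1]); rows["Incorrect"].append(p[0])
        rows["Miss"].append(p[2])
    if not rows["Correct"]:
        raise ValueError("no unilateral conditions supplied")
    return {k: float(np.mean(v)) for k, v in rows.items()}
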