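"""Hierarchical multinomial psychometric model of 2AUC choice behavior.

Each trial's decision variables are a saturating function of screen contrast,

    ZL = bL + sL * cL^n        ZR = bR + sR * cR^n

with session-level bias (bL, bR), sensitivity (sL, sR) and a shared contrast
exponent n in (0, 1].  Choice probabilities follow a three-way logistic
(softmax):

    P(Left) = e^ZL / (1 + e^ZL + e^ZR)
    P(Right) = e^ZR / (1 + e^ZL + e^ZR)
    P(NoGo) = 1 / (1 + e^ZL + e^ZR)

Session parameter vectors theta_d = (bL, bR, sL, sR, n) are drawn from a
subject-level Gaussian, subject means from a grand Gaussian; covariance
matrices carry LKJ(2) correlation and HalfCauchy(0, 1) scale priors, and the
grand mean a weakly informative N((0, 0, 5, 5, 0.5),
diag(2, 2, 2, 2, 0.25^2)) hyperprior.  See :mod:`neurochoice._hier` for the
fitting machinery (MAP + Laplace fast path; ensemble MCMC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._hier import (
    HierarchicalModel,
    Interval,
    PosteriorDraws,
    SamplerConfig,
    fit_map,
    fit_mcmc,
)
from .session_data import Session

__all__ = [
    "PsychSessionParams",
    "PARAM_NAMES",
    "decision_variables",
    "choice_probabilities",
    "session_log_likelihood",
    "fit_hierarchical",
    "posterior_predict",
    "PosteriorDraws",
    "SamplerConfig",
]

PARAM_NAMES = ("bL", "bR", "sL", "sR", "n")

#: Lower bound on the contrast exponent; n = 0 would make 0^0 ill-defined.
N_FLOOR = 1e-3


@dataclass(frozen=True)
class PsychSessionParams:
    """Session-level psychometric parameters (log-odds scale)."""

    bL: float = 0.0
    bR: float = 0.0
    sL: float = 0.0
    sR: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.bL, self.bR, self.sL, self.sR, self.n)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"parameters must be finite: {vals}")
        if not 0.0 < self.n <= 1.0:
            raise ValueError(f"contrast exponent n must lie in (0, 1], got {self.n}")

    def as_array(self) -> np.ndarray:
        return np.array([self.bL, self.bR, self.sL, self.sR, self.n])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "PsychSessionParams":
        return cls(*(float(v) for v in a))


def _pow0(c: np.ndarray, n: float) -> np.ndarray:
    """c^n with the convention 0^n = 0 for all allowed n."""
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    nz = c > 0
    out[nz] = c[nz] ** n
    return out


def decision_variables(params: PsychSessionParams, cL, cR):
    """Log-odds decision variables (ZL, ZR) for contrasts in [0, 1]."""
    cL = np.asarray(cL, dtype=float)
    cR = np.asarray(cR, dtype=float)
    if np.any((cL < 0) | (cL > 1) | (cR < 0) | (cR > 1)):
        raise ValueError("contrasts must lie in [0, 1]")
    ZL = params.bL + params.sL * _pow0(cL, params.n)
    ZR = params.bR + params.sR * _pow0(cR, params.n)
    return ZL, ZR


def choice_probabilities(ZL, ZR):
    """(pLeft, pRight, pNoGo) from the three-way softmax, numerically stable."""
    ZL = np.asarray(ZL, dtype=float)
    ZR = np.asarray(ZR, dtype=float)
    if not (np.all(np.isfinite(ZL)) and np.all(np.isfinite(ZR))):
        raise ValueError("decision variables must be finite")
    # softmax over (ZL, ZR, 0) with max subtraction
    m = np.maximum(np.maximum(ZL, ZR), 0.0)
    eL = np.exp(ZL - m)
    eR = np.exp(ZR - m)
    e0 = np.exp(-m)
    denom = eL + eR + e0
    return eL / denom, eR / denom, e0 / denom


_CHOICE_INDEX = {"Left": 0, "Right": 1, "NoGo": 2}


def session_log_likelihood(
    session: Session, params: PsychSessionParams, include_laser: bool = False
) -> float:
    """Sum over trials of the log probability of the observed choice.

    Laser trials are excluded by default (the model describes unperturbed
    behavior).  A choice assigned probability exactly zero yields -inf with a
    warning rather than an exception.
    """
    trials = [t for t in session.trials if include_laser or not t.laser_on]
    if not trials:
        return 0.0
    cL = np.array([t.contrast_left for t in trials])
    cR = np.array([t.contrast_right for t in trials])
    y = np.array([_CHOICE_INDEX[t.choice] for t in trials])
    p = np.stack(choice_probabilities(*decision_variables(params, cL, cR)), axis=-1)
    p_obs = p[np.arange(len(trials)), y]
    if np.any(p_obs == 0.0):
        warnings.warn("some observed choices have probability 0; returning -inf")
        return -math.inf
    return float(np.sum(np.log(p_obs)))


# ---------------------------------------------------------------------------
# Hierarchical fitting
# ---------------------------------------------------------------------------


@dataclass
class _SessionArrays:
    cL: np.ndarray
    cR: np.ndarray
    y: np.ndarray  # 0 Left, 1 Right, 2 NoGo
    logcL: np.ndarray  # log contrast, 0 where contrast == 0 (masked)
    logcR: np.ndarray
    mL: np.ndarray  # contrast > 0 masks
    mR: np.ndarray


def _session_arrays(session: Session, include_laser: bool, excluded: set[int]) -> _SessionArrays:
    trials = [
        t
        for t in session.trials
        if (include_laser or not t.laser_on) and t.trial_id not in excluded
    ]
    cL = np.array([t.contrast_left for t in trials])
    cR = np.array([t.contrast_right for t in trials])
    y = np.array([_CHOICE_INDEX[t.choice] for t in trials], dtype=int)
    mL, mR = cL > 0, cR > 0
    logcL = np.where(mL, np.log(np.where(mL, cL, 1.0)), 0.0)
    logcR = np.where(mR, np.log(np.where(mR, cR, 1.0)), 0.0)
    return _SessionArrays(cL, cR, y, logcL, logcR, mL, mR)


class _PsychModel(HierarchicalModel):
    param_names = PARAM_NAMES
    transforms = (None, None, None, None, Interval(N_FLOOR, 1.0))
    mu0 = np.array([0.0, 0.0, 5.0, 5.0, 0.5])
    sigma0 = np.array([np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0), 0.25])

    def loglik_grad(self, theta: np.ndarray, data: _SessionArrays):
        bL, bR, sL, sR, n = theta
        pL_c = np.where(data.mL, np.exp(n * data.logcL), 0.0)  # cL^n with 0^n=0
        pR_c = np.where(data.mR, np.exp(n * data.logcR), 0.0)
        ZL = bL + sL * pL_c
        ZR = bR + sR * pR_c
        pL, pR, p0 = choice_probabilities(ZL, ZR)
        probs = np.stack([pL, pR, p0], axis=-1)
        idx = np.arange(len(data.y))
        p_obs = np.maximum(probs[idx, data.y], 1e-300)
        ll = float(np.sum(np.log(p_obs)))
        dL = (data.y == 0).astype(float) - pL
        dR = (data.y == 1).astype(float) - pR
        grad = np.array(
            [
                np.sum(dL),
                np.sum(dR),
                np.sum(dL * pL_c),
                np.sum(dR * pR_c),
                np.sum(dL * sL * pL_c * data.logcL + dR * sR * pR_c * data.logcR),
            ]
        )
        return ll, grad


def _prepare(sessions, include_laser, apply_exclusions):
    from .session_data import validate_session

    if not sessions:
        raise ValueError("at least one session is required")
    subject_ids = list(dict.fromkeys(s.subject_id for s in sessions))
    session_ids = [s.session_id for s in sessions]
    subject_of = [subject_ids.index(s.subject_id) for s in sessions]
    datasets = []
    for s in sessions:
        excluded = (
            validate_session(s).excluded_ids if apply_exclusions else set()
        )
        arr = _session_arrays(s, include_laser, excluded)
        if arr.y.size == 0:
            raise ValueError(f"session {s.session_id} has no usable trials")
        datasets.append(arr)
    return datasets, subject_of, subject_ids, session_ids


def fit_hierarchical(
    sessions: Sequence[Session],
    seed: int = 0,
    method: str = "map",
    sampler: SamplerConfig | None = None,
    n_draws: int = 1000,
    include_laser: bool = False,
    apply_exclusions: bool = False,
) -> PosteriorDraws:
    """Fit the hierarchical psychometric model to a set of sessions.

    ``method='map'`` (default) returns Laplace draws around the joint MAP;
    ``method='mcmc'`` runs the ensemble sampler (4 chains x 500 warmup +
    500 sampling by default, mirroring the reference sampler settings).
    """
    datasets, subject_of, subject_ids, session_ids = _prepare(
        sessions, include_laser, apply_exclusions
    )
    model = _PsychModel()
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
# Posterior prediction
# ---------------------------------------------------------------------------


def posterior_predict(
    draws: PosteriorDraws,
    cL,
    cR,
    level: str = "grand",
    index: int = 0,
):
    """Per-condition choice probabilities with mean and central 95% interval.

    Parameters
    ----------
    draws : posterior draws from :func:`fit_hierarchical`.
    cL, cR : contrast grids (broadcastable 1-d arrays).
    level : 'grand' (default), 'subject', or 'session'; ``index`` selects the
        subject/session when applicable.

    Returns
    -------
    dict with keys 'mean', 'lo', 'hi', each (n_conditions, 3) arrays ordered
    (pLeft, pRight, pNoGo).
    """
    if draws.n_draws == 0:
        raise ValueError("no posterior draws supplied")
    cL = np.atleast_1d(np.asarray(cL, dtype=float))
    cR = np.atleast_1d(np.asarray(cR, dtype=float))
    cL, cR = np.broadcast_arrays(cL, cR)
    if level == "grand":
        theta = draws.grand
    elif level == "subject":
        theta = draws.subject[:, index, :]
    elif level == "session":
        theta = draws.session[:, index, :]
    else:
        raise ValueError(f"unknown level {level!r}")
    preds = np.empty((draws.n_draws, cL.size, 3))
    for i, row in enumerate(theta):
        params = PsychSessionParams.from_array(row)
        pL, pR, p0 = choice_probabilities(*decision_variables(params, cL, cR))
        preds[i] = np.stack([pL, pR, p0], axis=-1)
    lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
    return {"mean": preds.mean(axis=0), "lo": lo, "hi": hi, "draws": preds}
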