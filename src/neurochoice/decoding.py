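"""Condition-controlled binary decoding (pooled choice probability).

The decoder measures how well a scalar activity signal predicts one task
variable while holding the others constant, generalising choice-probability
analysis.  Trials are divided into groups within which the nuisance
variables are constant; within each group a Mann-Whitney U statistic counts
pairs where the positive-label trial had more activity (ties credited 0.5);
U values and pair counts are summed over groups and their ratio is the
pooled auROC (0.5 = chance).

Variables:

* ``execution`` (Go vs NoGo): 16 groups, one per stimulus condition.
* ``vision_l`` (non-zero vs zero left contrast): 12 groups, one per
  (choice x right-contrast) combination; ``vision_r`` mirrored.
* ``selection`` (Left vs Right choice): 16 stimulus-condition groups,
  NoGo trials excluded.

Significance is assessed either by within-group label shuffling (2000
shuffles by default; single-neuron electrophysiology) or, across sessions,
by a nested ANOVA with sessions nested within subjects (widefield).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .session_data import TrialRecord

__all__ = [
    "ConditionGrouping",
    "DecodingResult",
    "build_grouping",
    "pooled_auroc",
    "shuffle_null_pvalue",
    "session_significance",
    "assign_pseudo_movement_times",
]

VARIABLES = ("vision_l", "vision_r", "execution", "selection")


@dataclass
class ConditionGrouping:
    """Trial groups with binary labels; nuisance variables constant within
    each group.  ``indices[k]`` are positions into the trial list that the
    grouping was built from; ``labels[k]`` the matching boolean labels
    (True = positive class)."""

    variable: str
    indices: list[np.ndarray]
    labels: list[np.ndarray]
    descriptions: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.indices)

    @property
    def n_labeled_trials(self) -> int:
        return int(sum(len(ix) for ix in self.indices))


@dataclass
class DecodingResult:
    u_total: float
    pair_total: int
    variable: str
    p_value: float | None = None
    window: tuple[float, float] | None = None

    @property
    def defined(self) -> bool:
        return self.pair_total >= 1

    @property
    def auroc(self) -> float:
        """U_total / pair_total; NaN (not 0.5) when no pairs exist."""
        if not self.defined:
            return math.nan
        return self.u_total / self.pair_total


def _normalise_variable(variable: str) -> str:
    v = variable.lower().replace("-", "_")
    aliases = {
        "vision_left": "vision_l", "vision_right": "vision_r",
        "action_execution": "execution", "go_nogo": "execution",
        "action_selection": "selection", "choice": "selection",
    }
    v = aliases.get(v, v)
    if v not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    return v


def build_grouping(
    trials: Sequence[TrialRecord], variable: str, conditioned: bool = True
) -> ConditionGrouping:
    """Group trials and assign binary labels for one decoded variable.

    With ``conditioned=False`` all labelled trials form a single group (the
    naive, unconditioned auROC) — useful only as a contrast to show why the
    conditioning matters.
    """
    v = _normalise_variable(variable)
    cL = np.array([t.contrast_left for t in trials])
    cR = np.array([t.contrast_right for t in trials])
    choice = np.array([t.choice for t in trials], dtype=object)

    if v == "execution":
        keys = list(zip(cL, cR))
        labels = choice != "NoGo"
        valid = np.ones(len(trials), dtype=bool)
        describe = lambda k: f"cL={k[0]},cR={k[1]}"
    elif v == "selection":
        keys = list(zip(cL, cR))
        labels = choice == "Left"
        valid = choice != "NoGo"
        describe = lambda k: f"cL={k[0]},cR={k[1]}"
    elif v == "vision_l":
        keys = list(zip(choice, cR))
        labels = cL > 0
        valid = np.ones(len(trials), dtype=bool)
        describe = lambda k: f"choice={k[0]},cR={k[1]}"
    else:  # vision_r
        keys = list(zip(choice, cL))
        labels = cR > 0
        valid = np.ones(len(trials), dtype=bool)
        describe = lambda k: f"choice={k[0]},cL={k[1]}"

    if not conditioned:
        ix = np.flatnonzero(valid)
        return ConditionGrouping(v, [ix], [labels[ix]], ["all trials pooled"])

    groups: dict = {}
    for i in np.flatnonzero(valid):
        groups.setdefault(keys[i], []).append(i)
    indices, labs, descs = [], [], []
    for key in sorted(groups, key=str):
        ix = np.array(groups[key], dtype=int)
        indices.append(ix)
        labs.append(labels[ix])
        descs.append(describe(key))
    return ConditionGrouping(v, indices, labs, descs)


def _group_u(activity: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Mann-Whitney U (mid-rank tie convention) and pair count for one group."""
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return 0.0, 0
    ranks = stats.rankdata(activity)
    u = float(ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
    return u, n_pos * n_neg


def pooled_auroc(
    activity: Sequence[float],
    grouping: ConditionGrouping,
    window: tuple[float, float] | None = None,
) -> DecodingResult:
    """Pool per-group U statistics and pair counts into one auROC.

    ``activity`` is aligned to the trial list the grouping was built from.
    Groups with no label variation contribute zero to both numerator and
    denominator; if no group has pairs the result is flagged undefined
    (``auroc`` = NaN).
    """
    activity = np.asarray(activity, dtype=float)
    u_total, pair_total = 0.0, 0
    for ix, labels in zip(grouping.indices, grouping.labels):
        if np.any(np.isnan(activity[ix])):
            raise ValueError("activity undefined for some labelled trials")
        u, pairs = _group_u(activity[ix], labels)
        u_total += u
        pair_total += pairs
    return DecodingResult(u_total, pair_total, grouping.variable, window=window)


def shuffle_null_pvalue(
    activity: Sequence[float],
    grouping: ConditionGrouping,
    n_shuffles: int = 2000,
    seed: int = 0,
) -> DecodingResult:
    """Two-sided permutation p-value for the pooled auROC.

    Labels are shuffled *within* each group independently per shuffle,
    preserving the conditioning structure; p uses the add-one convention
    p = (1 + #{|A_shuffled - 0.5| >= |A_observed - 0.5|}) / (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    activity = np.asarray(activity, dtype=float)
    observed = pooled_auroc(activity, grouping)
    if not observed.defined:
        raise ValueError("pooled auROC undefined (no comparable pairs)")
    rng = np.random.default_rng(seed)

    u_null = np.zeros(n_shuffles)
    pair_total = 0
    for ix, labels in zip(grouping.indices, grouping.labels):
        n_pos = int(labels.sum())
        n = len(ix)
        if n_pos == 0 or n_pos == n:
            continue
        ranks = stats.rankdata(activity[ix])
        # each shuffle: a fresh random assignment of which trials are positive
        order = np.argsort(rng.random((n_shuffles, n)), axis=1)[:, :n_pos]
        u_null += np.take(ranks, order).sum(axis=1) - n_pos * (n_pos + 1) / 2.0
        pair_total += n_pos * (n - n_pos)
    a_null = u_null / pair_total
    obs_dev = abs(observed.auroc - 0.5)
    exceed = np.sum(np.abs(a_null - 0.5) >= obs_dev - 1e-12)
    p = (1.0 + float(exceed)) / (n_shuffles + 1.0)
    return DecodingResult(
        observed.u_total, observed.pair_total, grouping.variable, p_value=p
    )


def session_significance(
    aurocs: Sequence[float],
    subject_ids: Sequence[str],
    null_value: float = 0.5,
) -> tuple[float, float]:
    """Nested-ANOVA test of mean auROC against chance across sessions.

    Sessions are nested within subjects: the grand mean of (auroc - 0.5) is
    tested against the between-subject mean square, F with (1, M - 1)
    degrees of freedom.  With a single subject the test degrades to a
    one-sample t-test across its sessions (F = t^2), with a warning.

    Returns (F, p).
    """
    y = np.asarray(aurocs, dtype=float) - null_value
    subjects = np.asarray(subject_ids)
    if y.size < 2:
        raise ValueError("need at least two sessions")
    uniq = list(dict.fromkeys(subjects.tolist()))
    M = len(uniq)
    if M == 1:
        warnings.warn("single subject: falling back to a one-sample t-test")
        t, p = stats.ttest_1samp(y, 0.0)
        return float(t * t), float(p)
    grand = y.mean()
    ms_mean = y.size * grand * grand  # 1 df
    ms_subj = 0.0
    for m in uniq:
        ym = y[subjects == m]
        ms_subj += len(ym) * (ym.mean() - grand) ** 2
    ms_subj /= M - 1
    if ms_mean == 0.0:
        return 0.0, 1.0
    if ms_subj == 0.0:
        return math.inf, 0.0
    F = ms_mean / ms_subj
    p = float(stats.f.sf(F, 1, M - 1))
    return float(F), p


def assign_pseudo_movement_times(
    nogo_trials: Sequence[TrialRecord],
    go_reaction_times: Sequence[float],
    seed: int = 0,
) -> np.ndarray:
    """Sample a pseudo movement time per NoGo trial from the empirical
    correct-Go reaction-time pool (with replacement).

    Needed to align NoGo trials to a 'movement' for movement-locked decoding.
    """
    pool = np.asarray([rt for rt in go_reaction_times if math.isfinite(rt)], float)
    if pool.size == 0:
        raise ValueError("empty reaction-time pool")
    rng = np.random.default_rng(seed)
    return pool[rng.integers(pool.size, size=len(nogo_trials))]
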