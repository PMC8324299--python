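import numpy as np
import pytest

from neurochoice.session_data import Session, TrialRecord


def make_trial(
    trial_id=0,
    session_id="s0",
    subject_id="m0",
    cL=0.0,
    cR=0.0,
    choice="NoGo",
    rt=float("nan"),
    **kw,
):
    if choice != "NoGo" and not np.isfinite(rt):
        rt = 0.25
    return TrialRecord(
        trial_id=trial_id,
        session_id=session_id,
        subject_id=subject_id,
        contrast_left=cL,
        contrast_right=cR,
        choice=choice,
        reaction_time=rt,
        **kw,
    )


def make_session(rows, session_id="s0", subject_id="m0"):
    """rows: iterable of (cL, cR, choice) or (cL, cR, choice, kwargs)."""
    trials = []
    for i, row in enumerate(rows):
        kw = row[3] if len(row) > 3 else {}
        trials.append(
            make_trial(i, session_id, subject_id, row[0], row[1], row[2], **kw)
        )
    return Session(session_id, subject_id, trials)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
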