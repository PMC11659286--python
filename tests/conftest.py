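"""Shared fixtures: compact synthetic sessions reused across tests."""

import numpy as np
import pandas as pd
import pytest

import pneumotrace as pt


@pytest.fixture(scope="session")
def short_protocol() -> pt.AdultProtocol:
    """Five-period adult gas protocol compressed to 6 min per period and a
    small chamber so washout completes quickly."""
    return pt.AdultProtocol(
        epochs=[
            ("room_air_1", 0.2095, 0.0004, 360.0),
            ("hypercapnia", 0.21, 0.05, 360.0),
            ("room_air_2", 0.2095, 0.0004, 360.0),
            ("hypoxia", 0.10, 0.0004, 360.0),
            ("room_air_3", 0.2095, 0.0004, 360.0),
        ],
        chamber_volume=100.0,
    )


@pytest.fixture(scope="session")
def adult_session(short_protocol):
    meta = pt.AnimalMeta(id="a1", group="GF", sex="F", weight=25.0,
                         temp_pre=37.2, temp_post=36.8, age=49)
    rec, gt = pt.generate_adult_session(protocol=short_protocol,
                                        programmed_vo2=0.9, seed=4,
                                        animal=meta)
    return rec, gt


@pytest.fixture(scope="session")
def adult_breaths(adult_session):
    rec, _ = adult_session
    br = pt.detect_breaths(rec)
    return pt.select_calm_breaths(br, rec=rec)


@pytest.fixture(scope="session")
def neonate_session():
    trials = [
        pt.AutoresusTrialParams(recovers=True),
        pt.AutoresusTrialParams(recovers=True),
        pt.AutoresusTrialParams(induction_time_true=25.0,
                                gasp_intervals_true=[15.0, 9.0, 8.0],
                                recovers=False),
    ]
    meta = pt.AnimalMeta(id="p1", group="SPF", sex="M", weight=4.5, age=7)
    rec, gt = pt.generate_autoresus_session(trials, seed=3, animal=meta)
    return rec, gt


def match_onsets(detected: np.ndarray, truth: np.ndarray, tol: float) -> int:
    """1-to-1 greedy matching of two sorted onset lists within ``tol`` s."""
    detected = np.sort(np.asarray(detected))
    truth = np.sort(np.asarray(truth))
    i = j = tp = 0
    while i < len(detected) and j < len(truth):
        d = detected[i] - truth[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return tp


def metronome_breaths(n: int = 50, tt: float = 0.4, amp: float = 1.0,
                      calm: bool = True) -> pd.DataFrame:
    """Synthetic per-breath table with constant timing/amplitude."""
    onsets = np.arange(n) * tt
    if n == 0:
        return pd.DataFrame({c: [] for c in
                             ["onset_s", "insp_end_s", "offset_s", "ti_s",
                              "te_s", "tt_s", "amp", "integ_insp", "ibi_s",
                              "calm"]})
    return pd.DataFrame({
        "onset_s": onsets,
        "insp_end_s": onsets + 0.35 * tt,
        "offset_s": onsets + tt,
        "ti_s": 0.35 * tt,
        "te_s": 0.65 * tt,
        "tt_s": tt,
        "amp": amp,
        "integ_insp": amp * 0.2,
        "ibi_s": np.append(np.diff(onsets), np.nan),
        "calm": calm,
    })
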