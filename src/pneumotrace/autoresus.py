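"""Neonatal autoresuscitation scoring.

A neonatal session is a baseline followed by repeated anoxic challenges
(markers ``anoxia:k``), each scored for:

* **induction length** — anoxic exposure needed to induce apnea (offset
  of the last breath followed by a ``terminal_apnea_gap`` of silence);
* **gasp latency / inter-gasp interval** — the gasp train after apnea;
* **recovery latencies** — time from the first gasp (the start of the
  recovery period) until heart rate / ventilatory frequency first reach
  a fraction of their baseline values (HR 63%, VF 50% by convention;
  all four combinations are computed);
* **decoupling** — HR(63%) latency minus VF(50%) latency;
* **survival** — both reported latencies defined before the next
  challenge.

VF is tracked continuously as 60 / interbreath interval (gasps
included), linearly interpolated onto the same uniform grid as HR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TraceRecording
from .breaths import (SegmentationConfig, HeartbeatConfig, BeatSeries,
                      detect_breaths, detect_heartbeats, select_calm_breaths)

log = logging.getLogger(__name__)

__all__ = [
    "AutoresusConfig",
    "TrialMetrics",
    "SessionSummary",
    "score_baseline",
    "detect_apnea_onset",
    "detect_gasps",
    "recovery_latency",
    "score_session",
]


@dataclass
class AutoresusConfig:
    terminal_apnea_gap: float = 10.0   # s without breaths defining apnea
    gasp_amp_factor: float = 0.5       # x baseline mean amplitude
    gasp_isolation: float = 1.0        # s of quiescence before a gasp
    baseline_window: float = 120.0     # s before the first switch
    grid_hz: float = 10.0              # HR/VF recovery grid
    hr_fraction: float = 0.63          # reported HR recovery fraction
    vf_fraction: float = 0.50          # reported VF recovery fraction
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    heartbeat: HeartbeatConfig = field(default_factory=HeartbeatConfig)


@dataclass
class TrialMetrics:
    """Scores of one anoxic challenge (times in seconds; NaN = undefined)."""

    trial_index: int
    switch_s: float
    induction_length_s: float = float("nan")
    apnea_onset_s: float = float("nan")
    gasp_times_s: list[float] = field(default_factory=list)
    gasp_latency_s: float = float("nan")
    inter_gasp_s: float = float("nan")
    gasps_per_min: float = float("nan")     # reciprocal reading of inter-gasp
    lat_hr63_s: float = float("nan")
    lat_hr50_s: float = float("nan")
    lat_vf63_s: float = float("nan")
    lat_vf50_s: float = float("nan")
    decoupling_s: float = float("nan")      # lat_hr63 - lat_vf50
    survived: bool = False
    scoreable: bool = True
    notes: str = ""


@dataclass
class SessionSummary:
    animal_id: str
    baseline_vf: float          # breaths/min
    baseline_vt: float          # mL (or signal units if uncalibrated)
    baseline_ve: float          # mL/min
    baseline_hr: float          # beats/min
    episodes_survived: int
    trials: list[TrialMetrics]

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "animal_id": self.animal_id, "trial_index": t.trial_index,
                "induction_s": t.induction_length_s,
                "gasp_latency_s": t.gasp_latency_s,
                "inter_gasp_s": t.inter_gasp_s,
                "gasps_per_min": t.gasps_per_min,
                "lat_hr63_s": t.lat_hr63_s, "lat_vf50_s": t.lat_vf50_s,
                "lat_hr50_s": t.lat_hr50_s, "lat_vf63_s": t.lat_vf63_s,
                "decoupling_s": t.decoupling_s, "survived": t.survived,
            })
        return pd.DataFrame(rows)

    def averages(self) -> dict:
        """Across-trial means of each metric (NaNs ignored)."""
        df = self.trial_table()
        cols = ["induction_s", "gasp_latency_s", "inter_gasp_s",
                "lat_hr63_s", "lat_vf50_s", "decoupling_s"]
        return {c: float(df[c].mean()) for c in cols}


def _switch_times(rec: TraceRecording) -> list[float]:
    out = sorted(t for t, label in rec.markers if label.startswith("anoxia:"))
    if not out:
        raise ValueError("session has no anoxic-switch markers")
    return out


def score_baseline(rec: TraceRecording, breaths: pd.DataFrame,
                   beats: BeatSeries, cfg: AutoresusConfig | None = None,
                   ) -> tuple[float, float, float, float]:
    """Baseline (Vf, VT, VE, HR) over the window preceding the first
    anoxic switch — means over calm breaths and defined HR samples."""
    if cfg is None:
        cfg = AutoresusConfig()
    t_first = _switch_times(rec)[0]
    t0 = max(0.0, t_first - cfg.baseline_window)
    if t_first <= 0:
        raise ValueError("no pre-challenge baseline in recording")
    sel = breaths[(breaths["onset_s"] >= t0) & (breaths["onset_s"] < t_first)
                  & breaths["calm"]]
    if len(sel) == 0:
        raise ValueError("no calm baseline breaths")
    vf = 60.0 / float(sel["tt_s"].mean())
    vt = float(sel["vt_ml"].mean()) if "vt_ml" in sel else float(sel["amp"].mean())
    hr = beats.mean_hr(t0, t_first)
    if not np.isfinite(hr):
        log.warning("HR undefined throughout baseline; HR metrics disabled")
    return vf, vt, vf * vt, hr


def detect_apnea_onset(breaths: pd.DataFrame, t_switch: float, t_end: float,
                       terminal_apnea_gap: float = 10.0) -> float:
    """Apnea onset within one trial: the offset of the last breath that is
    followed by at least ``terminal_apnea_gap`` seconds without a breath,
    searching forward from the anoxic switch.  NaN when breathing never
    ceases (trial unscoreable)."""
    sub = breaths[(breaths["onset_s"] >= t_switch) & (breaths["onset_s"] < t_end)]
    if len(sub) == 0:
        # breathing stopped before/at the switch; treat switch as onset
        return t_switch
    offsets = sub["offset_s"].to_numpy()
    next_onsets = np.append(sub["onset_s"].to_numpy()[1:], t_end)
    gaps = next_onsets - offsets
    qual = np.flatnonzero(gaps >= terminal_apnea_gap)
    if len(qual) == 0:
        return float("nan")
    return float(offsets[qual[0]])


def detect_gasps(breaths: pd.DataFrame, apnea_onset: float, t_end: float,
                 baseline_amp: float, gasp_amp_factor: float = 0.5,
                 gasp_isolation: float = 1.0) -> list[float]:
    """Gasps: isolated breath-like deflections after apnea onset with
    amplitude >= gasp_amp_factor x baseline mean amplitude, preceded by
    >= gasp_isolation seconds of quiescence."""
    sub = breaths[(breaths["onset_s"] > apnea_onset) & (breaths["onset_s"] < t_end)]
    if len(sub) == 0:
        return []
    onsets = sub["onset_s"].to_numpy()
    offsets = sub["offset_s"].to_numpy()
    amps = sub["amp"].to_numpy()
    prev_off = np.append(apnea_onset, offsets[:-1])
    quiet = onsets - prev_off >= gasp_isolation
    big = amps >= gasp_amp_factor * baseline_amp
    return [float(t) for t in onsets[quiet & big]]


def recovery_latency(times: np.ndarray, series: np.ndarray, baseline_value: float,
                     fraction: float, t0: float,
                     t_limit: float | None = None) -> float:
    """Smallest ``t - t0`` with ``series(t) >= fraction x baseline_value``.

    The first crossing is found on the grid and refined by linear
    interpolation between samples; NaN when no crossing occurs before
    ``t_limit`` (or the end of the series).  NaN samples (undefined HR)
    never qualify.
    """
    if baseline_value <= 0:
        raise ValueError("baseline_value must be positive")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    thr = fraction * baseline_value
    sel = times >= t0
    if t_limit is not None:
        sel &= times < t_limit
    tt = times[sel]
    yy = series[sel]
    if len(tt) == 0:
        return float("nan")
    ok = np.isfinite(yy) & (yy >= thr)
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    if i == 0 or not np.isfinite(yy[i - 1]):
        return float(tt[i] - t0)
    # linear interpolation of the crossing between i-1 and i
    y0, y1 = yy[i - 1], yy[i]
    frac = (thr - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]) - t0)


def _vf_series(breaths: pd.DataFrame, duration: float, grid_hz: float,
               gap_max: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous ventilatory frequency (breaths/min) from interbreath
    intervals on a uniform grid; zero during long breathless gaps."""
    grid = np.arange(int(duration * grid_hz)) / grid_hz
    onsets = breaths["onset_s"].to_numpy()
    if len(onsets) < 2:
        return grid, np.zeros_like(grid)
    ibis = np.diff(onsets)
    mid = 0.5 * (onsets[:-1] + onsets[1:])
    vf = 60.0 / ibis
    out = np.interp(grid, mid, vf)
    # inside a gap longer than gap_max the animal is apneic: rate ~ 0
    idx = np.searchsorted(onsets, grid)
    left = onsets[np.clip(idx - 1, 0, len(onsets) - 1)]
    right = onsets[np.clip(idx, 0, len(onsets) - 1)]
    gap = np.minimum(np.abs(grid - left), np.abs(grid - right))
    out[gap > gap_max] = 0.0
    return grid, out


def score_session(rec: TraceRecording, cfg: AutoresusConfig | None = None,
                  breaths: pd.DataFrame | None = None,
                  beats: BeatSeries | None = None) -> SessionSummary:
    """Score a full neonatal session.

    Runs segmentation and heartbeat detection (unless precomputed tables
    are passed), scores the baseline, then every anoxic trial.  Survival
    requires both the HR and the VF recovery latency to be defined before
    the next challenge.
    """
    if cfg is None:
        cfg = AutoresusConfig()
    if breaths is None:
        breaths = detect_breaths(rec, cfg.segmentation)
        breaths = select_calm_breaths(breaths, cfg.segmentation, rec)
    if beats is None:
        beats = detect_heartbeats(rec, cfg.heartbeat)

    switches = _switch_times(rec)
    vf0, vt0, ve0, hr0 = score_baseline(rec, breaths, beats, cfg)
    base_amp = float(breaths.loc[breaths["calm"], "amp"].mean())

    vf_t, vf_y = _vf_series(breaths, rec.duration, cfg.grid_hz,
                            gap_max=cfg.terminal_apnea_gap * 3)

    trials: list[TrialMetrics] = []
    bounds = switches + [rec.duration]
    for k, (t_sw, t_next) in enumerate(zip(switches, bounds[1:]), start=1):
        tm = TrialMetrics(trial_index=k, switch_s=t_sw)
        apnea_onset = detect_apnea_onset(breaths, t_sw, t_next,
                                         cfg.terminal_apnea_gap)
        if not np.isfinite(apnea_onset):
            tm.scoreable = False
            tm.notes = "breathing never ceased"
            trials.append(tm)
            continue
        tm.apnea_onset_s = apnea_onset
        tm.induction_length_s = apnea_onset - t_sw
        gasps = detect_gasps(breaths, apnea_onset, t_next, base_amp,
                             cfg.gasp_amp_factor, cfg.gasp_isolation)
        tm.gasp_times_s = gasps
        if gasps:
            tm.gasp_latency_s = gasps[0] - apnea_onset
            if len(gasps) > 1:
                tm.inter_gasp_s = gasps[1] - gasps[0]
                tm.gasps_per_min = 60.0 / tm.inter_gasp_s
            t0 = gasps[0]
            if np.isfinite(hr0):
                tm.lat_hr63_s = recovery_latency(beats.hr_times, beats.hr, hr0,
                                                 0.63, t0, t_next)
                tm.lat_hr50_s = recovery_latency(beats.hr_times, beats.hr, hr0,
                                                 0.50, t0, t_next)
            tm.lat_vf63_s = recovery_latency(vf_t, vf_y, vf0, 0.63, t0, t_next)
            tm.lat_vf50_s = recovery_latency(vf_t, vf_y, vf0, 0.50, t0, t_next)
            tm.decoupling_s = tm.lat_hr63_s - tm.lat_vf50_s
        tm.survived = bool(np.isfinite(tm.lat_hr63_s) and np.isfinite(tm.lat_vf50_s))
        trials.append(tm)

    return SessionSummary(
        animal_id=rec.animal.id if rec.animal else "",
        baseline_vf=vf0, baseline_vt=vt0, baseline_ve=ve0, baseline_hr=hr0,
        episodes_survived=sum(t.survived for t in trials),
        trials=trials,
    )
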