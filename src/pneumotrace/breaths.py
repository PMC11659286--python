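"""Breath and heartbeat segmentation of raw traces.

Breaths are delimited by signed zero crossings of the band-pass-filtered
breath signal, with a hysteresis pair of thresholds (±h, h relative to
the typical breath amplitude) so that low-amplitude noise and cardiac
bleed-through never split a cycle.  Onsets and inspiratory ends are
refined to sub-sample precision by linear interpolation of the zero
crossing.  Heartbeats are peaks of the band-passed cardiac oscillation;
the instantaneous heart rate series is built from median-filtered
inter-beat intervals on a uniform grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import TraceRecording, AnimalMeta

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "HeartbeatConfig",
    "BeatSeries",
    "detect_breaths",
    "select_calm_breaths",
    "detect_heartbeats",
    "calibrate_tidal_volume",
    "drorbaugh_fenn_factor",
    "water_vapor_pressure_mmhg",
]

BREATH_COLUMNS = ["onset_s", "insp_end_s", "offset_s", "ti_s", "te_s", "tt_s",
                  "amp", "integ_insp", "ibi_s", "calm"]


@dataclass
class SegmentationConfig:
    """Breath-detector configuration.

    All amplitude thresholds are relative to the typical detected lobe
    amplitude, so detection is invariant to uniform channel gain.
    """

    channel: str = "breath"
    sign: float = 1.0              # +1: inspiration = positive lobe
    highpass_hz: float = 0.1
    lowpass_hz: float = 20.0
    hyst_frac: float = 0.25        # hysteresis threshold / reference amplitude
    amp_floor_frac: float = 0.25   # discard cycles with peak below this x ref
    min_tt_s: float = 0.1          # merge cycles shorter than this
    # calm-breath selection
    calm_window: int = 21          # rolling window, breaths
    calm_factor: float = 2.0       # TT and amp must lie in [1/k, k] x window median
    artifact_factor: float = 3.0   # local RMS > this x session median RMS
    artifact_win_s: float = 0.5


@dataclass
class HeartbeatConfig:
    channel: str | None = None     # default: 'cardiac' if present else 'breath'
    band_hz: tuple[float, float] = (4.0, 12.0)   # 240-720 beats/min
    refractory_frac: float = 0.6   # x running median inter-beat interval
    min_prominence_frac: float = 0.5  # x median band-passed envelope
    hr_grid_hz: float = 10.0
    hr_gap_max_s: float = 5.0      # gaps longer than this leave hr undefined
    median_filter_beats: int = 5   # interval median filter (artifact rejection)


@dataclass
class BeatSeries:
    """Detected heartbeats and the derived instantaneous heart rate."""

    beat_times: np.ndarray            # s
    hr_times: np.ndarray              # s, uniform grid
    hr: np.ndarray                    # beats/min, NaN where undefined

    def mean_hr(self, start: float | None = None, end: float | None = None) -> float:
        sel = np.ones_like(self.hr_times, dtype=bool)
        if start is not None:
            sel &= self.hr_times >= start
        if end is not None:
            sel &= self.hr_times < end
        vals = self.hr[sel]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else float("nan")


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase band-pass.

    The high-pass stage subtracts a centered moving-average baseline of
    width ``1/lo`` (a zero-phase FIR high-pass with no IIR edge
    transients — a 0.1 Hz Butterworth ringing over ~10 s would corrupt
    the first and last breaths of a recording); the low-pass stage is a
    4th-order zero-phase Butterworth.
    """
    from scipy.ndimage import uniform_filter1d
    if lo > 0:
        w = max(int(round(fs / lo)), 1)
        baseline = uniform_filter1d(x, size=w, mode="reflect")
        x = x - baseline
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos_lp = sps.butter(4, hi / nyq, btype="lowpass", output="sos")
    return sps.sosfiltfilt(sos_lp, x)


def _interp_zero_cross(x: np.ndarray, j: int, rising: bool) -> float:
    """Sub-sample zero-crossing location between samples j and j+1."""
    x0, x1 = x[j], x[j + 1]
    if x1 == x0:
        return float(j)
    return j + (0.0 - x0) / (x1 - x0)


def _interp_level_cross(x: np.ndarray, i: int, level: float) -> float:
    """Sub-sample location where x rises through ``level`` between
    samples i-1 and i (x[i] is the first sample at or above level)."""
    if i == 0:
        return 0.0
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(i)
    return (i - 1) + (level - x0) / (x1 - x0)


def _fit_edge_onset(x: np.ndarray, i: int, h: float, fallback: float) -> float:
    """Onset of a lobe emerging from baseline silence.

    Zero crossings near a silent baseline are located by noise, so
    instead the inspiratory rise between h/2 and the lobe peak (samples
    with high signal-to-noise) is fit with a half-sine — the classic
    model of inspiratory flow — and the onset is the fitted foot.
    ``i`` is the first index at or above the hysteresis threshold h.
    """
    from scipy.optimize import curve_fit
    n = len(x)
    # forward to the lobe peak
    j = i
    while j + 1 < n and x[j + 1] >= x[j]:
        j += 1
    i_pk = j
    # backward to the base of the edge
    j = i - 1
    while j > 0 and x[j] >= 0.5 * h:
        j -= 1
    lo = j + 1
    idx = np.arange(lo, i_pk + 1).astype(float)
    if len(idx) < 4:
        return fallback
    xpk = x[i_pk]

    def half_sine(t, a, t0, ti):
        return a * np.sin(np.pi * np.clip(t - t0, 0.0, None) / ti)

    p0 = [xpk, float(fallback), 2.0 * (i_pk - fallback)]
    lb = [0.3 * xpk, lo - 12.0, 2.0]
    ub = [3.0 * xpk, lo + 2.0, 10.0 * max(i_pk - lo, 2.0)]
    p0 = [min(max(v, l), u) for v, l, u in zip(p0, lb, ub)]
    try:
        popt, _ = curve_fit(half_sine, idx, x[idx.astype(int)], p0=p0,
                            bounds=(lb, ub), maxfev=400)
    except Exception:
        return fallback
    onset = float(popt[1])
    if not (lo - 10.0 <= onset <= lo + 2.0):
        return fallback
    return onset


def _reference_amplitude(peaks: np.ndarray) -> float:
    """Typical breath-lobe amplitude, robust to a large population of
    small (cardiac / noise) lobes: median of the peaks above one quarter
    of the 99th percentile."""
    if len(peaks) == 0:
        return 0.0
    hi = np.percentile(peaks, 99)
    big = peaks[peaks >= 0.25 * hi]
    return float(np.median(big)) if len(big) else float(np.median(peaks))


def detect_breaths(rec: TraceRecording, cfg: SegmentationConfig | None = None,
                   ) -> pd.DataFrame:
    """Detect breaths on a recording; returns the per-breath table.

    Columns: onset_s, insp_end_s, offset_s, ti_s, te_s, tt_s, amp,
    integ_insp (uncalibrated inspired volume, signal·s), ibi_s (onset to
    next onset; NaN for the last breath), calm (set later by
    :func:`select_calm_breaths`; initialized True).

    A flat (zero-variance) channel yields an empty table with a warning;
    a missing channel raises ``KeyError``.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    if cfg.channel not in rec.channels:
        raise KeyError(f"channel {cfg.channel!r} not in recording "
                       f"(has {sorted(rec.channels)})")
    fs = rec.sample_rate
    if rec.duration < 2.0:
        raise ValueError("recording must be at least 2 s long")

    x = cfg.sign * rec.channels[cfg.channel]
    if np.ptp(x) == 0.0:
        warnings.warn("breath channel has zero variance; no breaths detected")
        return pd.DataFrame(columns=BREATH_COLUMNS)
    x = _bandpass(x, fs, cfg.highpass_hz, cfg.lowpass_hz)

    # --- pass 1: provisional lobes from raw zero crossings ---------------
    pos = x > 0
    up = np.flatnonzero(~pos[:-1] & pos[1:])       # last index before crossing
    if len(up) < 2:
        warnings.warn("no oscillation found on breath channel")
        return pd.DataFrame(columns=BREATH_COLUMNS)
    peaks = np.array([x[a + 1:b + 1].max() for a, b in zip(up[:-1], up[1:])])
    ref_amp = _reference_amplitude(peaks)
    if ref_amp <= 0:
        warnings.warn("no positive breath lobes found")
        return pd.DataFrame(columns=BREATH_COLUMNS)
    h = cfg.hyst_frac * ref_amp

    # --- pass 2: hysteresis state machine over threshold crossings -------
    above = x >= h
    below = x <= -h
    cross_up = np.flatnonzero(~above[:-1] & above[1:]) + 1   # first idx >= +h
    cross_dn = np.flatnonzero(~below[:-1] & below[1:]) + 1   # first idx <= -h
    events = sorted([(i, +1) for i in cross_up] + [(i, -1) for i in cross_dn])

    onsets_i: list[float] = []       # fractional sample indices
    insp_ends_i: list[float] = []
    state = -1                        # start armed for an onset
    pending_onset: float | None = None
    last_below = 0                    # last index with x <= -h
    for i, kind in events:
        if kind == +1 and state == -1:
            t_h = _interp_level_cross(x, i, h)
            # how long ago was the signal last in an expiratory lobe?
            jb = i - 1
            while jb > last_below and x[jb] > -h:
                jb -= 1
            silence_gap = t_h - jb
            # edge steepness: samples to rise from h/2 to h
            j2 = i - 1
            while j2 > 0 and x[j2] >= 0.5 * h:
                j2 -= 1
            t_h2 = _interp_level_cross(x, j2 + 1, 0.5 * h)
            edge = max(t_h - t_h2, 0.5)
            if silence_gap <= 6.0 * edge + 2.0:
                # contiguous breathing: the onset is the zero crossing
                # between the expiratory tail and the inspiratory rise
                j = i - 1
                while j > 0 and x[j] > 0:
                    j -= 1
                if x[j] > 0:
                    pending_onset = 0.0   # record starts mid-inspiration
                else:
                    pending_onset = _interp_zero_cross(x, j, rising=True)
            else:
                # onset out of silence (post-apnea, gasp): zero crossings
                # near the baseline are noise-located, so fit the rising
                # edge up to the lobe peak and extrapolate to zero
                pending_onset = _fit_edge_onset(x, i, h, fallback=2 * t_h2 - t_h)
            state = +1
        elif kind == -1:
            if state == +1:
                j = i - 1
                while j > 0 and x[j] < 0:
                    j -= 1
                if x[j] >= 0 and pending_onset is not None:
                    onsets_i.append(pending_onset)
                    insp_ends_i.append(_interp_zero_cross(x, j, rising=False))
                    pending_onset = None
                state = -1
            last_below = i
    n_b = len(onsets_i)
    if n_b == 0:
        warnings.warn("no breaths passed the amplitude threshold")
        return pd.DataFrame(columns=BREATH_COLUMNS)

    onsets = np.asarray(onsets_i) / fs
    insp_ends = np.asarray(insp_ends_i) / fs

    # --- merge cycles shorter than min_tt --------------------------------
    keep = [0]
    for k in range(1, n_b):
        if onsets[k] - onsets[keep[-1]] >= cfg.min_tt_s:
            keep.append(k)
    onsets = onsets[keep]
    insp_ends = insp_ends[keep]
    n_b = len(onsets)

    # --- offsets: end of the expiratory lobe ------------------------------
    # After insp_end the signal is negative; the offset is the zero
    # crossing where it durably returns to baseline: the first upward
    # crossing of -h after insp_end, refined to the following zero cross.
    offsets = np.empty(n_b)
    next_onset_i = np.append((onsets[1:] * fs).astype(int), len(x) - 1)
    for k in range(n_b):
        i0 = int(insp_ends[k] * fs) + 1
        i1 = next_onset_i[k]
        seg_end = i1
        j = i0
        off = None
        # first index where signal rises to >= -h after having been below
        was_below = False
        while j < seg_end:
            if x[j] <= -h:
                was_below = True
            elif was_below and x[j] >= -h:
                break
            j += 1
        if was_below and j < seg_end:
            # refine to the next zero crossing (or cap at next onset)
            jj = j
            while jj < seg_end and x[jj] < 0:
                jj += 1
            if jj < seg_end and jj > 0 and x[jj] >= 0:
                off = _interp_zero_cross(x, jj - 1, rising=True) / fs
        if off is None or off <= insp_ends[k]:
            off = i1 / fs if k < n_b - 1 else min(i1 / fs, insp_ends[k] + (
                insp_ends[k] - onsets[k]) * 2.0)
        off = min(off, i1 / fs) if k < n_b - 1 else off
        # contiguous breathing: the expiration runs into the next onset,
        # and any residual gap is noise in the shallow tail — absorb it
        # unless it is a genuine pause
        if k < n_b - 1:
            gap = onsets[k + 1] - off
            if gap < 0.5 * (off - onsets[k]):
                off = onsets[k + 1]
        offsets[k] = off

    amps = np.empty(n_b)
    integ = np.empty(n_b)
    for k in range(n_b):
        i0, i1 = int(np.ceil(onsets[k] * fs)), max(int(insp_ends[k] * fs), 1)
        i1 = max(i1, i0 + 1)
        seg = x[i0:i1 + 1]
        amps[k] = seg.max() if len(seg) else 0.0
        integ[k] = np.trapezoid(np.clip(seg, 0, None), dx=1.0 / fs)

    ibi = np.append(np.diff(onsets), np.nan)
    df = pd.DataFrame({
        "onset_s": onsets,
        "insp_end_s": insp_ends,
        "offset_s": offsets,
        "ti_s": insp_ends - onsets,
        "te_s": offsets - insp_ends,
        "tt_s": offsets - onsets,
        "amp": amps,
        "integ_insp": integ,
        "ibi_s": ibi,
        "calm": True,
    })
    # drop any malformed cycles (should not occur on sane input)
    df = df[(df.ti_s > 0) & (df.te_s > 0)].reset_index(drop=True)
    return df


def _artifact_mask(rec: TraceRecording, cfg: SegmentationConfig) -> tuple[np.ndarray, float]:
    """Boolean per-sample movement-artifact mask from local RMS."""
    x = rec.channels[cfg.channel]
    fs = rec.sample_rate
    w = max(int(cfg.artifact_win_s * fs), 1)
    sq = pd.Series(x ** 2).rolling(w, center=True, min_periods=1).mean().to_numpy()
    rms = np.sqrt(sq)
    med = np.median(rms)
    return rms > cfg.artifact_factor * med, float(med)


def select_calm_breaths(breaths: pd.DataFrame,
                        cfg: SegmentationConfig | None = None,
                        rec: TraceRecording | None = None) -> pd.DataFrame:
    """Flag 'calm' breaths: within a centered rolling window of
    ``calm_window`` breaths, TT and amplitude must each lie within
    ``[1/k, k]`` times the window median (k = ``calm_factor``), and the
    breath must not fall in a movement-artifact span (local RMS above
    ``artifact_factor`` times the session median RMS; skipped when no
    recording is supplied).  Returns a copy with the ``calm`` column set.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    if len(breaths) == 0:
        raise ValueError("empty breath table")
    out = breaths.copy()
    w = cfg.calm_window
    if len(out) < w:
        log.info("fewer breaths (%d) than calm window (%d); using whole-session "
                 "medians", len(out), w)
        med_tt = np.full(len(out), out["tt_s"].median())
        med_amp = np.full(len(out), out["amp"].median())
    else:
        med_tt = out["tt_s"].rolling(w, center=True, min_periods=1).median().to_numpy()
        med_amp = out["amp"].rolling(w, center=True, min_periods=1).median().to_numpy()
    k = cfg.calm_factor
    calm = ((out["tt_s"].to_numpy() >= med_tt / k) & (out["tt_s"].to_numpy() <= med_tt * k)
            & (out["amp"].to_numpy() >= med_amp / k) & (out["amp"].to_numpy() <= med_amp * k))
    if rec is not None and np.isfinite(cfg.artifact_factor):
        mask, _ = _artifact_mask(rec, cfg)
        idx = np.clip((out["onset_s"].to_numpy() * rec.sample_rate).astype(int),
                      0, len(mask) - 1)
        calm &= ~mask[idx]
    out["calm"] = calm
    return out


def detect_heartbeats(rec: TraceRecording, cfg: HeartbeatConfig | None = None,
                      ) -> BeatSeries:
    """Detect heartbeats and derive the instantaneous HR series.

    The cardiac channel (``cardiac`` if present, else the breath channel,
    else as named in cfg) is band-pass filtered to the cardiac band,
    peaks are picked with a refractory period of ``refractory_frac``
    times the running median inter-beat interval, and peak times are
    refined by parabolic interpolation.  The HR series is 60 / the
    median-filtered inter-beat interval, linearly interpolated onto a
    uniform grid; grid points farther than ``hr_gap_max_s`` from any
    beat are NaN.
    """
    if cfg is None:
        cfg = HeartbeatConfig()
    chan = cfg.channel or ("cardiac" if "cardiac" in rec.channels else "breath")
    if chan not in rec.channels:
        raise KeyError(f"channel {chan!r} not in recording")
    fs = rec.sample_rate
    x = rec.channels[chan]
    n_grid = int(rec.duration * cfg.hr_grid_hz)
    grid = np.arange(n_grid) / cfg.hr_grid_hz

    if np.ptp(x) == 0.0:
        warnings.warn("cardiac channel has zero variance; no beats detected")
        return BeatSeries(np.empty(0), grid, np.full(n_grid, np.nan))

    lo, hi = cfg.band_hz
    y = _bandpass(x, fs, lo, hi)
    env = np.abs(y)
    scale = np.median(env) * np.sqrt(2.0)   # ~sinusoid amplitude
    if scale <= 0:
        warnings.warn("no cardiac oscillation found")
        return BeatSeries(np.empty(0), grid, np.full(n_grid, np.nan))

    # initial pass: refractory from the top of the band
    d0 = max(int(cfg.refractory_frac * fs / hi), 1)
    pk, _ = sps.find_peaks(y, distance=d0,
                           prominence=cfg.min_prominence_frac * scale)
    if len(pk) < 3:
        warnings.warn("no cardiac oscillation found")
        return BeatSeries(np.empty(0), grid, np.full(n_grid, np.nan))
    med_ibi = np.median(np.diff(pk)) / fs
    d1 = max(int(cfg.refractory_frac * med_ibi * fs), 1)
    pk, _ = sps.find_peaks(y, distance=d1,
                           prominence=cfg.min_prominence_frac * scale)

    # parabolic sub-sample refinement of peak times
    times = pk.astype(float)
    inner = (pk > 0) & (pk < len(y) - 1)
    a = y[pk[inner] - 1]
    b = y[pk[inner]]
    c = y[pk[inner] + 1]
    denom = a - 2 * b + c
    shift = np.where(denom != 0, 0.5 * (a - c) / denom, 0.0)
    times[inner] = pk[inner] + np.clip(shift, -0.5, 0.5)
    beat_times = times / fs

    ibis = np.diff(beat_times)
    if cfg.median_filter_beats > 1 and len(ibis) >= cfg.median_filter_beats:
        k = cfg.median_filter_beats | 1
        ibis_f = sps.medfilt(ibis, kernel_size=k)
    else:
        ibis_f = ibis
    mid = 0.5 * (beat_times[:-1] + beat_times[1:])
    hr_inst = 60.0 / ibis_f

    hr = np.interp(grid, mid, hr_inst, left=np.nan, right=np.nan)
    # undefined where no beat within hr_gap_max
    if len(beat_times):
        nearest = np.searchsorted(beat_times, grid)
        left = beat_times[np.clip(nearest - 1, 0, len(beat_times) - 1)]
        right = beat_times[np.clip(nearest, 0, len(beat_times) - 1)]
        gap = np.minimum(np.abs(grid - left), np.abs(grid - right))
        hr[gap > cfg.hr_gap_max_s] = np.nan
    return BeatSeries(beat_times=beat_times, hr_times=grid, hr=hr)


# ---------------------------------------------------------------------------
# tidal volume calibration (barometric plethysmography)
# ---------------------------------------------------------------------------

def water_vapor_pressure_mmhg(temp_c: float | np.ndarray) -> float | np.ndarray:
    """Saturated water vapor pressure (mmHg) via the Antoine equation,
    valid ~1-100 °C."""
    return 10.0 ** (8.07131 - 1730.63 / (233.426 + np.asarray(temp_c, dtype=float)))


def drorbaugh_fenn_factor(body_temp_c: float | np.ndarray, chamber_temp_c: float,
                          pressure_mmhg: float = 760.0) -> float | np.ndarray:
    """Temperature/humidity correction relating chamber pressure
    deflections to tidal volume in whole-body barometric plethysmography.

    C = TB (PB - Pc) / [ TB (PB - Pc) - TC (PB - Pb) ]

    with TB, TC body and chamber temperature (K); Pb, Pc saturated water
    vapor pressure (mmHg) at body and chamber temperature; PB barometric
    pressure (mmHg).  Chamber gas is assumed saturated (unrestrained
    animal humidifies the chamber); body gas is saturated at body
    temperature.
    """
    tb = np.asarray(body_temp_c, dtype=float) + 273.15
    tc = chamber_temp_c + 273.15
    pb = water_vapor_pressure_mmhg(body_temp_c)
    pc = water_vapor_pressure_mmhg(chamber_temp_c)
    num = tb * (pressure_mmhg - pc)
    den = tb * (pressure_mmhg - pc) - tc * (pressure_mmhg - pb)
    return num / den


def calibrate_tidal_volume(breaths: pd.DataFrame,
                           calibration: tuple[float, float] | None,
                           animal: AnimalMeta | None = None,
                           chamber_temp_c: float = 30.0,
                           pressure_mmhg: float = 760.0,
                           session_duration_s: float | None = None,
                           correction: bool = True) -> pd.DataFrame:
    """Attach a tidal volume column (``vt_ml``) to the breath table.

    ``calibration`` is ``(inject_volume_ml, inject_deflection)`` from a
    known-volume injection;  VT = inject_volume x (breath deflection /
    inject deflection) x C, with C the Drorbaugh-Fenn correction
    evaluated at the breath's body temperature, linearly interpolated
    between the pre- and post-session rectal temperatures.  Without a
    calibration the uncalibrated deflection is copied to ``vt_ml`` and
    ``vt_calibrated`` is False.
    """
    out = breaths.copy()
    if calibration is None:
        out["vt_ml"] = out["amp"]
        out["vt_calibrated"] = False
        log.warning("no volume calibration supplied; vt_ml is in signal units")
        return out
    inject_volume, inject_deflection = calibration
    if inject_deflection <= 0:
        raise ValueError("calibration deflection must be positive")

    if animal is not None and correction:
        t_pre, t_post = animal.temp_pre, animal.temp_post
        dur = session_duration_s or max(float(out["offset_s"].max()), 1.0)
        frac = np.clip(out["onset_s"].to_numpy() / dur, 0.0, 1.0)
        body_temp = t_pre + (t_post - t_pre) * frac
        c = drorbaugh_fenn_factor(body_temp, chamber_temp_c, pressure_mmhg)
    else:
        c = 1.0
    out["vt_ml"] = inject_volume * (out["amp"] / inject_deflection) * c
    out["vt_calibrated"] = True
    return out
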