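"""Synthetic cardiorespiratory trace generation with known ground truth.

Two acquisition paradigms are emulated:

* **Adult whole-body plethysmography** — a five-period gas protocol
  (room air, 5% CO2 hypercapnia, room air, 10% O2 hypoxia, room air) with
  programmable breath rate/amplitude, sigh and apnea events, and
  first-order chamber gas washout with an O2 sink for metabolism.
* **Neonatal pneumotachography** — repeated anoxic challenges with a
  programmable apnea-induction time, gasp train, exponential heart-rate
  and ventilatory-frequency recovery, and a terminal failed trial.

Every generated recording carries a :class:`GroundTruth` with the exact
breath onsets, event log, and analytic per-trial metrics so detectors and
scorers can be validated against construction rather than against another
algorithm.

Breath waveform
---------------
A cycle is a positive half-sine inspiration followed by a stretched-sine
expiratory lobe ``-c * sin(pi * u**k)`` (u = fraction of expiration
elapsed) whose amplitude ``c`` and stretch ``k`` are solved so that the
cycle integrates to zero (inspired volume = expired volume, as in an
AC-coupled flow signal) and the signal slope is continuous through the
breath onset.  Zero-mean, slope-continuous cycles give breath onsets
that are unbiased zero crossings under any zero-phase filtering.  Sighs
replace a breath's amplitude with
``amp_mean * sigh_amp_factor``; apneas append a quiescent pause after a
breath so its onset-to-onset interval equals ``apnea_ibi_factor`` times
its own cycle length.  Event counts are exact per-session quotas
(``round(rate/100 * n_breaths)``); positions are random.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnimalMeta, TraceRecording

__all__ = [
    "BreathModelParams",
    "AdultProtocol",
    "AutoresusTrialParams",
    "CohortDesign",
    "GroundTruth",
    "generate_breathing_trace",
    "generate_gas_channels",
    "generate_adult_session",
    "generate_autoresus_session",
    "generate_cohort",
    "simulate_outcome_table",
    "adult_breath_defaults",
    "neonate_breath_defaults",
]

ROOM_AIR_O2 = 0.2095
ROOM_AIR_CO2 = 0.0004

# Fraction of the cycle spent in inspiration; mouse Ti/TT is ~1/3.
TI_FRACTION = 0.35


def _lobe_integral(k: float, n: int = 2000) -> float:
    """Integral of sin(pi * u**k) over u in [0, 1] (composite Simpson)."""
    u = np.linspace(0.0, 1.0, n + 1)
    from scipy.integrate import simpson
    return float(simpson(np.sin(math.pi * u ** k), x=u))


def _solve_expiration_shape(ti_frac: float = TI_FRACTION) -> tuple[float, float]:
    """Stretch ``k`` and amplitude ratio ``c/amp`` of the expiratory lobe
    ``-c sin(pi u**k)`` enforcing (i) slope continuity through the breath
    onset, c*pi*k/Te = amp*pi/Ti, and (ii) lobe area balance,
    c*Te*I(k) = amp*(2/pi)*Ti."""
    from scipy.optimize import brentq
    r = ti_frac / (1.0 - ti_frac)          # Ti / Te
    target = (2.0 / math.pi) * r ** 2      # required I(k)/k
    k = brentq(lambda kk: _lobe_integral(kk) / kk - target, 1.05, 25.0)
    return k, (1.0 / r) / k                # c/amp = (Te/Ti)/k


_EXP_K, _EXP_C_RATIO = _solve_expiration_shape()


@dataclass
class BreathModelParams:
    """Generative parameters for eupneic breathing plus events.

    Rates are breaths/min and events per 100 breaths; amplitudes are in
    arbitrary signal units.  ``sigh_amp_factor`` and ``apnea_ibi_factor``
    must be at least 2 so that programmed events satisfy the downstream
    event definitions (sigh amplitude >= 2x average breath, apnea IBI >=
    2x average IBI) by construction.
    """

    rate_mean: float = 150.0        # breaths/min
    rate_cv: float = 0.05
    amp_mean: float = 1.0           # signal units
    amp_cv: float = 0.05
    sigh_rate: float = 0.0          # per 100 breaths
    sigh_amp_factor: float = 2.5
    apnea_rate: float = 0.0         # per 100 breaths
    apnea_ibi_factor: float = 2.5
    cardiac_amp: float = 0.0        # signal units, superimposed on breath channel
    hr_mean: float = 450.0          # beats/min
    noise_sd: float = 0.0           # signal units

    def __post_init__(self) -> None:
        if not (10.0 < self.rate_mean < 900.0):
            raise ValueError("rate_mean must lie in (10, 900) breaths/min")
        for name in ("rate_cv", "amp_cv", "sigh_rate", "apnea_rate",
                     "cardiac_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.amp_mean <= 0:
            raise ValueError("amp_mean must be positive")
        if self.sigh_amp_factor < 2:
            raise ValueError("sigh_amp_factor must be >= 2 (event definition)")
        if self.apnea_ibi_factor < 2:
            raise ValueError("apnea_ibi_factor must be >= 2 (event definition)")
        if self.hr_mean <= 0:
            raise ValueError("hr_mean must be positive")


def adult_breath_defaults(**overrides) -> BreathModelParams:
    """Room-air adult mouse breathing: ~150 breaths/min, no cardiac bleed."""
    base = dict(rate_mean=150.0, rate_cv=0.08, amp_mean=1.0, amp_cv=0.10,
                sigh_rate=0.5, sigh_amp_factor=2.5, apnea_rate=0.5,
                apnea_ibi_factor=2.5, cardiac_amp=0.0, hr_mean=600.0,
                noise_sd=0.02)
    base.update(overrides)
    return BreathModelParams(**base)


def neonate_breath_defaults(**overrides) -> BreathModelParams:
    """P7-8 pup pneumotach baseline: ~120 breaths/min, visible cardiogenic
    oscillation at ~450 beats/min."""
    base = dict(rate_mean=120.0, rate_cv=0.08, amp_mean=1.0, amp_cv=0.10,
                sigh_rate=0.0, sigh_amp_factor=2.5, apnea_rate=0.0,
                apnea_ibi_factor=2.5, cardiac_amp=0.06, hr_mean=450.0,
                noise_sd=0.02)
    base.update(overrides)
    return BreathModelParams(**base)


@dataclass
class AdultProtocol:
    """Adult gas protocol: ordered (label, O2 fraction, CO2 fraction,
    duration s) periods plus chamber geometry.

    Defaults follow the standard adult session: five 20-min periods
    (room air / 5% CO2 hypercapnia / room air / 10% O2 hypoxia / room
    air), 198 mL/min flow, chamber water-jacketed at 30 °C.
    """

    epochs: list[tuple[str, float, float, float]] = field(default_factory=lambda: [
        ("room_air_1", ROOM_AIR_O2, ROOM_AIR_CO2, 1200.0),
        ("hypercapnia", 0.21, 0.05, 1200.0),
        ("room_air_2", ROOM_AIR_O2, ROOM_AIR_CO2, 1200.0),
        ("hypoxia", 0.10, ROOM_AIR_CO2, 1200.0),
        ("room_air_3", ROOM_AIR_O2, ROOM_AIR_CO2, 1200.0),
    ])
    flow_rate: float = 198.0        # mL/min
    chamber_volume: float = 450.0   # mL
    chamber_temp: float = 30.0      # °C

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol must have at least one epoch")
        for label, fo2, fco2, dur in self.epochs:
            if not (0.0 <= fo2 <= 1.0 and 0.0 <= fco2 <= 1.0):
                raise ValueError(f"gas fractions must lie in [0,1] ({label})")
            if fo2 + fco2 > 1.0:
                raise ValueError(f"O2+CO2 fraction exceeds 1 in epoch {label}")
            if dur <= 0:
                raise ValueError(f"epoch {label} duration must be positive")
        if self.flow_rate < 0 or self.chamber_volume < 0:
            raise ValueError("flow_rate and chamber_volume must be nonnegative")

    @property
    def duration(self) -> float:
        return float(sum(e[3] for e in self.epochs))


@dataclass
class AutoresusTrialParams:
    """One anoxic challenge of a neonatal session.

    ``gasp_intervals_true`` are the successive gaps (s): apnea onset ->
    first gasp, first -> second gasp, and so on.  ``recovery_hold`` is
    the time from the first gasp to the next anoxic switch (5 min by
    protocol).
    """

    induction_time_true: float = 30.0     # s of anoxia before apnea
    gasp_intervals_true: list[float] = field(default_factory=lambda: [12.0, 8.0])
    hr_recovery_tau: float = 20.0         # s
    vf_recovery_tau: float = 25.0         # s
    hr_floor: float = 100.0               # beats/min during apnea
    vf_floor: float = 20.0                # breaths/min at recovery onset
    recovers: bool = True
    recovery_hold: float = 300.0          # s between first gasp and next challenge

    def __post_init__(self) -> None:
        if self.induction_time_true <= 0:
            raise ValueError("induction_time_true must be positive")
        if any(g <= 0 for g in self.gasp_intervals_true):
            raise ValueError("gasp intervals must be strictly positive")
        if self.hr_recovery_tau <= 0 or self.vf_recovery_tau <= 0:
            raise ValueError("recovery time constants must be positive")


@dataclass
class CohortDesign:
    """Two-group (SPF control vs GF) by two-sex cohort with additive
    fixed effects and a per-animal random intercept on the outcome."""

    n_per_cell: int = 8
    group_effect: float = 0.0     # outcome units, added for GF
    sex_effect: float = 0.0       # outcome units, added for males
    animal_sd: float = 1.0        # random-intercept SD
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2 (model identifiability)")
        if self.animal_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be nonnegative")


@dataclass
class GroundTruth:
    """Construction-time truth for one synthetic recording."""

    breath_onsets: np.ndarray                 # s, every programmed breath onset
    event_log: pd.DataFrame                   # time_s, type, trial_index
    breath_table: pd.DataFrame | None = None  # onset_s, tt_s, ti_s, te_s, amp, is_sigh, is_apnea
    trial_metrics: pd.DataFrame | None = None # analytic per-trial autoresuscitation truth
    programmed_vo2: float = 0.0               # mL O2/min
    baseline: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# breathing trace
# ---------------------------------------------------------------------------

def _draw_cycles(params: BreathModelParams, duration: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Draw breath cycles (onset, tt, ti, te, amp, pause, flags) filling
    [0, duration); the programmed IBI of a breath is tt + pause."""
    mean_tt = 60.0 / params.rate_mean
    # generous upper bound on cycle count
    n_max = int(duration / mean_tt * (1.0 + 3.0 * params.rate_cv) + 20)
    tts = mean_tt * np.clip(rng.normal(1.0, params.rate_cv, n_max), 0.2, 3.0)
    amps = params.amp_mean * np.clip(rng.normal(1.0, params.amp_cv, n_max), 0.1, 3.0)

    # exact per-session event quotas based on the expected breath count
    n_expect = max(int(duration / mean_tt), 1)
    n_sigh = int(round(params.sigh_rate / 100.0 * n_expect))
    n_apnea = int(round(params.apnea_rate / 100.0 * n_expect))
    eligible = np.arange(1, max(n_expect - 1, 2))
    picks = rng.choice(eligible, size=min(n_sigh + n_apnea, len(eligible)),
                       replace=False)
    sigh_idx = set(picks[:n_sigh].tolist())
    apnea_idx = set(picks[n_sigh:].tolist())

    rows = []
    t = 0.0
    i = 0
    while i < n_max:
        tt = float(tts[i])
        amp = float(amps[i])
        is_sigh = i in sigh_idx
        is_apnea = i in apnea_idx
        if is_sigh:
            amp = params.amp_mean * params.sigh_amp_factor
        pause = (params.apnea_ibi_factor - 1.0) * tt if is_apnea else 0.0
        if t + tt + pause > duration + 1e-9:
            break
        rows.append((t, tt, TI_FRACTION * tt, (1 - TI_FRACTION) * tt,
                     amp, pause, is_sigh, is_apnea))
        t += tt + pause
        i += 1
    return pd.DataFrame(rows, columns=["onset_s", "tt_s", "ti_s", "te_s",
                                       "amp", "pause_s", "is_sigh", "is_apnea"])


def _render_cycles(cycles: pd.DataFrame, n_samples: int, sample_rate: float,
                   out: np.ndarray | None = None, t_offset: float = 0.0) -> np.ndarray:
    """Render breath cycles into a sample array (additive)."""
    if out is None:
        out = np.zeros(n_samples)
    for row in cycles.itertuples(index=False):
        onset = row.onset_s + t_offset
        ti, te, amp = row.ti_s, row.te_s, row.amp
        # lobe shape constants hold whenever ti/te matches the global
        # TI_FRACTION (always true for generated cycles)
        a_e = amp * _EXP_C_RATIO * (te / ti) * (TI_FRACTION / (1 - TI_FRACTION))
        i0 = int(math.ceil(onset * sample_rate - 1e-9))
        i1 = int(math.ceil((onset + ti) * sample_rate - 1e-9))
        i2 = int(math.ceil((onset + ti + te) * sample_rate - 1e-9))
        i0, i1, i2 = max(i0, 0), min(i1, n_samples), min(i2, n_samples)
        if i1 > i0:
            tr = np.arange(i0, i1) / sample_rate - onset
            out[i0:i1] += amp * np.sin(math.pi * tr / ti)
        if i2 > i1:
            tr = np.arange(i1, i2) / sample_rate - onset - ti
            u = np.clip(tr / te, 0.0, 1.0)
            out[i1:i2] += -a_e * np.sin(math.pi * u ** _EXP_K)
    return out


def generate_breathing_trace(params: BreathModelParams, duration: float,
                             sample_rate: float = 100.0, seed: int | None = 0,
                             rng: np.random.Generator | None = None,
                             animal: AnimalMeta | None = None,
                             ) -> tuple[TraceRecording, GroundTruth]:
    """Generate a single-channel breathing recording plus ground truth.

    The breath channel is the cycle train described in the module
    docstring, plus an additive cardiac sinusoid of amplitude
    ``cardiac_amp`` at ``hr_mean`` and white Gaussian noise of SD
    ``noise_sd``.  Identical ``(params, duration, sample_rate, seed)``
    give byte-identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 100.0:
        raise ValueError("sample_rate must be >= 100 Hz")
    if rng is None:
        rng = np.random.default_rng(seed)

    cycles = _draw_cycles(params, duration, rng)
    n = int(round(duration * sample_rate))
    sig = _render_cycles(cycles, n, sample_rate)
    t = np.arange(n) / sample_rate
    if params.cardiac_amp > 0:
        phase = rng.uniform(0, 2 * math.pi)
        sig = sig + params.cardiac_amp * np.sin(
            2 * math.pi * params.hr_mean / 60.0 * t + phase)
    if params.noise_sd > 0:
        sig = sig + rng.normal(0.0, params.noise_sd, n)

    events = []
    for row in cycles.itertuples(index=False):
        if row.is_sigh:
            events.append((row.onset_s, "sigh", 0))
        if row.is_apnea:
            events.append((row.onset_s + row.tt_s, "apnea", 0))
    gt = GroundTruth(
        breath_onsets=cycles["onset_s"].to_numpy(),
        event_log=pd.DataFrame(events, columns=["time_s", "type", "trial_index"]),
        breath_table=cycles,
    )
    rec = TraceRecording(channels={"breath": sig}, sample_rate=sample_rate,
                         animal=animal)
    return rec, gt


# ---------------------------------------------------------------------------
# gas channels
# ---------------------------------------------------------------------------

def generate_gas_channels(protocol: AdultProtocol, programmed_vo2: float,
                          sample_rate: float = 100.0,
                          ) -> tuple[dict[str, np.ndarray], list[tuple[float, str]]]:
    """Chamber O2/CO2/temperature channels for a gas protocol.

    Chamber fractions follow first-order washout toward each period's
    steady state with time constant ``tau = chamber_volume / flow_rate``.
    Oxygen's steady state is depressed below the inflow fraction by
    ``programmed_vo2 / flow_rate`` (animal O2 extraction under the
    flow-through mass balance); CO2 washes toward the inflow fraction.
    Returns the channel dict (O2/CO2 in percent) and the switch markers.
    ``chamber_volume = 0`` is the degenerate well-mixed limit in which
    the chamber tracks its steady state instantly.
    """
    if protocol.flow_rate <= 0:
        raise ValueError("flow_rate must be positive (washout undefined)")
    if programmed_vo2 < 0:
        raise ValueError("programmed_vo2 must be nonnegative")

    tau = 60.0 * protocol.chamber_volume / protocol.flow_rate  # s
    sink = programmed_vo2 / protocol.flow_rate                 # O2 fraction deficit

    n = int(round(protocol.duration * sample_rate))
    t = np.arange(n) / sample_rate
    o2 = np.empty(n)
    co2 = np.empty(n)

    markers: list[tuple[float, str]] = []
    t0 = 0.0
    # start the first period at its own steady state (post-acclimation)
    o2_prev = protocol.epochs[0][1] - sink
    co2_prev = protocol.epochs[0][2]
    for k, (label, fo2, fco2, dur) in enumerate(protocol.epochs):
        o2_ss = fo2 - sink
        co2_ss = fco2
        sel = (t >= t0 - 1e-12) & (t < t0 + dur - 1e-12) if k < len(protocol.epochs) - 1 \
            else (t >= t0 - 1e-12)
        tr = t[sel] - t0
        if tau > 0:
            decay = np.exp(-tr / tau)
        else:
            decay = np.zeros_like(tr)
        o2[sel] = o2_ss + (o2_prev - o2_ss) * decay
        co2[sel] = co2_ss + (co2_prev - co2_ss) * decay
        if k > 0:
            markers.append((t0, f"gas:{label}"))
        if tau > 0:
            o2_prev = o2_ss + (o2_prev - o2_ss) * math.exp(-dur / tau)
            co2_prev = co2_ss + (co2_prev - co2_ss) * math.exp(-dur / tau)
        else:
            o2_prev, co2_prev = o2_ss, co2_ss
        t0 += dur

    temp = np.full(n, protocol.chamber_temp)
    return ({"o2": 100.0 * o2, "co2": 100.0 * co2, "temp": temp}, markers)


# Ventilatory responses rendered in adult sessions: multiplicative
# (rate_factor, amp_factor) applied to the baseline breathing parameters
# during each challenge gas.  5% CO2 roughly doubles minute ventilation in
# mice (more depth than rate); 10% O2 gives a smaller, rate-led increase.
DEFAULT_GAS_RESPONSE: dict[str, tuple[float, float]] = {
    "hypercapnia": (1.35, 1.50),
    "hypoxia": (1.25, 1.10),
}


def generate_adult_session(params: BreathModelParams | None = None,
                           protocol: AdultProtocol | None = None,
                           programmed_vo2: float = 0.9,
                           gas_response: dict[str, tuple[float, float]] | None = None,
                           sample_rate: float = 100.0, seed: int = 0,
                           animal: AnimalMeta | None = None,
                           ) -> tuple[TraceRecording, GroundTruth]:
    """Full adult plethysmography session: breathing + gas channels.

    Breathing parameters are scaled per protocol period via
    ``gas_response`` (challenge label -> (rate factor, amplitude
    factor)); for simplicity the response is rendered as a step at the
    gas switch.  ``programmed_vo2`` is in mL O2/min.
    """
    if params is None:
        params = adult_breath_defaults()
    if protocol is None:
        protocol = AdultProtocol()
    if gas_response is None:
        gas_response = DEFAULT_GAS_RESPONSE

    rng = np.random.default_rng(seed)
    gas, markers = generate_gas_channels(protocol, programmed_vo2, sample_rate)
    n = gas["o2"].shape[0]
    sig = np.zeros(n)

    all_cycles = []
    t0 = 0.0
    for label, _, _, dur in protocol.epochs:
        key = label.rstrip("_0123456789").rstrip("_")
        rf, af = gas_response.get(label, gas_response.get(key, (1.0, 1.0)))
        p = replace(params, rate_mean=params.rate_mean * rf,
                    amp_mean=params.amp_mean * af)
        cycles = _draw_cycles(p, dur, rng)
        _render_cycles(cycles, n, sample_rate, out=sig, t_offset=t0)
        cycles = cycles.copy()
        cycles["onset_s"] += t0
        all_cycles.append(cycles)
        t0 += dur
    cycles = pd.concat(all_cycles, ignore_index=True)

    t = np.arange(n) / sample_rate
    if params.cardiac_amp > 0:
        sig += params.cardiac_amp * np.sin(
            2 * math.pi * params.hr_mean / 60.0 * t + rng.uniform(0, 2 * math.pi))
    if params.noise_sd > 0:
        sig += rng.normal(0.0, params.noise_sd, n)

    events = []
    for row in cycles.itertuples(index=False):
        if row.is_sigh:
            events.append((row.onset_s, "sigh", 0))
        if row.is_apnea:
            events.append((row.onset_s + row.tt_s, "apnea", 0))

    rec = TraceRecording(channels={"breath": sig, **gas}, sample_rate=sample_rate,
                         markers=markers, animal=animal)
    gt = GroundTruth(
        breath_onsets=cycles["onset_s"].to_numpy(),
        event_log=pd.DataFrame(events, columns=["time_s", "type", "trial_index"]),
        breath_table=cycles,
        programmed_vo2=programmed_vo2,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# neonatal autoresuscitation sessions
# ---------------------------------------------------------------------------

def analytic_recovery_latency(base: float, floor: float, tau: float,
                              fraction: float) -> float:
    """Closed-form latency for floor + (base-floor)(1 - e^{-t/tau}) to
    first reach fraction*base; NaN when the target is never reached."""
    target = fraction * base
    if target <= floor:
        return 0.0
    if target >= base:
        return float("nan")
    return -tau * math.log(1.0 - (target - floor) / (base - floor))


def generate_autoresus_session(trials: list[AutoresusTrialParams],
                               baseline: BreathModelParams | None = None,
                               sample_rate: float = 200.0, seed: int = 0,
                               baseline_duration: float = 180.0,
                               terminal_tail: float = 60.0,
                               animal: AnimalMeta | None = None,
                               ) -> tuple[TraceRecording, GroundTruth]:
    """Render a neonatal session of repeated anoxic challenges.

    Every trial renders: eupneic breathing during the induction window,
    cessation at the programmed induction time, a gasp train at the
    programmed intervals, and (for recovering trials) breathing resuming
    after the last gasp with instantaneous rate following
    ``vf_floor + (base - vf_floor)(1 - e^{-t/tau})`` measured from the
    first gasp.  Heart rate steps to ``hr_floor`` at apnea onset and
    recovers along its own exponential from the first gasp; the cardiac
    oscillation (on the breath channel and on a dedicated ``cardiac``
    channel) persists through apnea at the instantaneous simulated HR.
    The final trial must have ``recovers=False`` and no earlier trial
    may; ground truth stores the analytic recovery latencies.
    """
    if baseline is None:
        baseline = neonate_breath_defaults()
    if not trials:
        raise ValueError("at least one trial required")
    if trials[-1].recovers:
        raise ValueError("final trial must have recovers=False")
    if any(tr.recovers is False for tr in trials[:-1]):
        raise ValueError("only the final trial may fail to recover")
    if baseline_duration < 60.0:
        raise ValueError("baseline must be at least 60 s")

    rng = np.random.default_rng(seed)
    base_vf = baseline.rate_mean
    base_hr = baseline.hr_mean

    # --- assemble the event timeline analytically ------------------------
    segments = []       # (kind, t_start, payload) for rendering
    markers: list[tuple[float, str]] = []
    trial_rows = []
    onsets_all: list[float] = []
    event_rows = []

    # hr profile as piecewise segments: list of (t_start, kind, params)
    hr_segments: list[tuple[float, str, tuple]] = [(0.0, "const", (base_hr,))]

    def add_breathing(t0: float, dur: float) -> None:
        cyc = _draw_cycles(replace(baseline, sigh_rate=0.0, apnea_rate=0.0),
                           dur, rng)
        segments.append(("cycles", t0, cyc))
        onsets_all.extend((cyc["onset_s"] + t0).tolist())

    t = baseline_duration
    add_breathing(0.0, baseline_duration)

    for k, tr in enumerate(trials, start=1):
        t_switch = t
        markers.append((t_switch, f"anoxia:{k}"))
        # eupnea continues during induction; last rendered breath ends by
        # t_switch + induction_time_true
        add_breathing(t_switch, tr.induction_time_true)
        apnea_onset = t_switch + tr.induction_time_true
        hr_segments.append((apnea_onset, "const", (tr.hr_floor,)))

        gasp_times = apnea_onset + np.cumsum(tr.gasp_intervals_true)
        first_gasp = float(gasp_times[0])
        markers.append((first_gasp, f"recovery:{k}"))
        gasp_tt = 60.0 / base_vf
        gasp_cycles = pd.DataFrame({
            "onset_s": gasp_times - apnea_onset,
            "tt_s": gasp_tt, "ti_s": TI_FRACTION * gasp_tt,
            "te_s": (1 - TI_FRACTION) * gasp_tt,
            "amp": 1.5 * baseline.amp_mean,
            "pause_s": 0.0, "is_sigh": False, "is_apnea": False,
        })
        segments.append(("cycles", apnea_onset, gasp_cycles))
        onsets_all.extend(gasp_times.tolist())
        for g in gasp_times:
            event_rows.append((float(g), "gasp", k))

        lat_hr63 = analytic_recovery_latency(base_hr, tr.hr_floor,
                                             tr.hr_recovery_tau, 0.63)
        lat_hr50 = analytic_recovery_latency(base_hr, tr.hr_floor,
                                             tr.hr_recovery_tau, 0.50)
        lat_vf63 = analytic_recovery_latency(base_vf, tr.vf_floor,
                                             tr.vf_recovery_tau, 0.63)
        lat_vf50 = analytic_recovery_latency(base_vf, tr.vf_floor,
                                             tr.vf_recovery_tau, 0.50)

        if tr.recovers:
            hr_segments.append((first_gasp, "exp",
                                (tr.hr_floor, base_hr, tr.hr_recovery_tau)))
            # eupnea resumes after the last gasp, paced by the
            # instantaneous VF curve measured from the first gasp
            t_end = first_gasp + tr.recovery_hold
            onsets = []
            tb = float(gasp_times[-1])
            while True:
                vf = tr.vf_floor + (base_vf - tr.vf_floor) * (
                    1.0 - math.exp(-(tb - first_gasp) / tr.vf_recovery_tau))
                tb = tb + 60.0 / vf
                if tb >= t_end:
                    break
                onsets.append(tb)
            if onsets:
                tts = np.diff(onsets + [tb])
                cyc = pd.DataFrame({
                    "onset_s": np.asarray(onsets) - first_gasp,
                    "tt_s": tts, "ti_s": TI_FRACTION * tts,
                    "te_s": (1 - TI_FRACTION) * tts,
                    "amp": baseline.amp_mean *
                        np.clip(rng.normal(1.0, baseline.amp_cv, len(onsets)), 0.1, 3.0),
                    "pause_s": 0.0, "is_sigh": False, "is_apnea": False,
                })
                segments.append(("cycles", first_gasp, cyc))
                onsets_all.extend(onsets)
            t = t_end
            survived = True
        else:
            # terminal failure: no eupnea, HR decays away after the last gasp
            hr_segments.append((float(gasp_times[-1]), "decay",
                                (tr.hr_floor, 30.0)))
            t = float(gasp_times[-1]) + terminal_tail
            survived = False
            lat_hr63 = lat_hr50 = lat_vf63 = lat_vf50 = float("nan")

        trial_rows.append({
            "trial_index": k,
            "switch_s": t_switch,
            "induction_length_s": apnea_onset - t_switch,
            "apnea_onset_s": apnea_onset,
            "gasp_latency_s": tr.gasp_intervals_true[0],
            "inter_gasp_s": (tr.gasp_intervals_true[1]
                             if len(tr.gasp_intervals_true) > 1 else float("nan")),
            "first_gasp_s": first_gasp,
            "lat_hr63_s": lat_hr63, "lat_hr50_s": lat_hr50,
            "lat_vf63_s": lat_vf63, "lat_vf50_s": lat_vf50,
            "decoupling_s": lat_hr63 - lat_vf50,
            "survived": survived,
        })

    duration = t
    n = int(round(duration * sample_rate))
    ts = np.arange(n) / sample_rate
    sig = np.zeros(n)
    for kind, t0, payload in segments:
        _render_cycles(payload, n, sample_rate, out=sig, t_offset=t0)

    # instantaneous HR over the whole session from the piecewise profile
    hr_inst = np.empty(n)
    hr_segments.sort(key=lambda s: s[0])
    bounds = [s[0] for s in hr_segments] + [duration + 1.0]
    for (t0, kind, p), t1 in zip(hr_segments, bounds[1:]):
        sel = (ts >= t0 - 1e-12) & (ts < t1 - 1e-12)
        tr_ = ts[sel] - t0
        if kind == "const":
            hr_inst[sel] = p[0]
        elif kind == "exp":
            floor, base, tau = p
            hr_inst[sel] = floor + (base - floor) * (1.0 - np.exp(-tr_ / tau))
        else:  # decay
            start, tau = p
            hr_inst[sel] = start * np.exp(-tr_ / tau)

    phase = 2.0 * math.pi * np.cumsum(hr_inst / 60.0) / sample_rate
    cardiac = np.sin(phase)
    if baseline.cardiac_amp > 0:
        sig += baseline.cardiac_amp * cardiac
    if baseline.noise_sd > 0:
        sig += rng.normal(0.0, baseline.noise_sd, n)
    cardiac_chan = 0.5 * cardiac + rng.normal(0.0, 0.02, n)

    rec = TraceRecording(
        channels={"breath": sig, "cardiac": cardiac_chan},
        sample_rate=sample_rate, markers=markers, animal=animal)
    trial_df = pd.DataFrame(trial_rows)
    events = pd.DataFrame(event_rows, columns=["time_s", "type", "trial_index"])
    gt = GroundTruth(
        breath_onsets=np.asarray(sorted(onsets_all)),
        event_log=events,
        trial_metrics=trial_df,
        baseline={"vf": base_vf, "hr": base_hr, "amp": baseline.amp_mean},
    )
    return rec, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    """Stable per-animal substream: seed combined with a CRC32 of the ID."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(animal_id.encode())]))


def generate_cohort(design: CohortDesign, paradigm: str = "adult",
                    protocol: AdultProtocol | None = None,
                    sample_rate: float | None = None,
                    trace_duration: float = 120.0,
                    render_traces: bool = True,
                    ) -> tuple[list[tuple[TraceRecording | None, GroundTruth | None]],
                               pd.DataFrame]:
    """Generate a group x sex cohort with known per-animal parameters.

    Each animal's generative outcome parameter is ``grand mean +
    group_effect*1[GF] + sex_effect*1[M] + N(0, animal_sd)``; the
    paradigm decides which parameter carries the effect (adult: breath
    rate in breaths/min; neonate: apnea induction time in s).  The
    metadata table records id, group, sex, weight and the realized
    generative parameter (column ``true_param``).  With
    ``render_traces=False`` only the metadata table is produced.
    """
    if paradigm not in ("adult", "neonate"):
        raise ValueError("paradigm must be 'adult' or 'neonate'")
    if sample_rate is None:
        sample_rate = 100.0 if paradigm == "adult" else 200.0

    grand_mean = 150.0 if paradigm == "adult" else 30.0
    rows = []
    out = []
    for group in ("SPF", "GF"):
        for sex in ("F", "M"):
            for i in range(design.n_per_cell):
                aid = f"{group}_{sex}_{i:02d}"
                rng = _animal_rng(design.seed, aid)
                shift = (design.group_effect * (group == "GF")
                         + design.sex_effect * (sex == "M")
                         + rng.normal(0.0, design.animal_sd))
                true_param = grand_mean + shift
                weight = (rng.normal(25.0, 2.0) if paradigm == "adult"
                          else rng.normal(4.5, 0.7))
                weight = max(weight, 1.0)
                meta = AnimalMeta(id=aid, group=group, sex=sex,
                                  weight=float(weight),
                                  age=49.0 if paradigm == "adult" else 7.0)
                rows.append({"animal_id": aid, "group": group, "sex": sex,
                             "weight_g": float(weight),
                             "true_param": float(true_param)})
                if not render_traces:
                    out.append((None, None))
                    continue
                sub_seed = int(rng.integers(0, 2**31 - 1))
                if paradigm == "adult":
                    params = adult_breath_defaults(
                        rate_mean=float(np.clip(true_param, 20.0, 800.0)))
                    if protocol is None:
                        proto = AdultProtocol()
                    else:
                        proto = protocol
                    rec, gt = generate_adult_session(
                        params=params, protocol=proto, sample_rate=sample_rate,
                        seed=sub_seed, animal=meta)
                else:
                    trials = [
                        AutoresusTrialParams(
                            induction_time_true=float(max(true_param, 5.0)),
                            recovers=True, recovery_hold=trace_duration),
                        AutoresusTrialParams(
                            induction_time_true=float(max(true_param, 5.0)),
                            recovers=False),
                    ]
                    rec, gt = generate_autoresus_session(
                        trials, sample_rate=sample_rate, seed=sub_seed,
                        baseline_duration=max(60.0, trace_duration / 2),
                        animal=meta)
                out.append((rec, gt))
    return out, pd.DataFrame(rows)


def simulate_outcome_table(design: CohortDesign, grand_mean: float = 0.0,
                           n_obs: int = 5, outcome: str = "outcome",
                           seed: int | None = None) -> pd.DataFrame:
    """Repeated-measures outcome table drawn directly from the cohort's
    linear model (fixed group and sex effects, per-animal random
    intercept, residual noise) — the generative counterpart of the
    mixed-model statistics stage."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for group in ("SPF", "GF"):
        for sex in ("F", "M"):
            for i in range(design.n_per_cell):
                aid = f"{group}_{sex}_{i:02d}"
                b = rng.normal(0.0, design.animal_sd)
                mu = (grand_mean + design.group_effect * (group == "GF")
                      + design.sex_effect * (sex == "M") + b)
                for j in range(n_obs):
                    rows.append({"animal_id": aid, "group": group, "sex": sex,
                                 outcome: mu + rng.normal(0.0, design.residual_sd)})
    return pd.DataFrame(rows)
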