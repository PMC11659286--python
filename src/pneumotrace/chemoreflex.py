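"""Adult chemoreflex epoching, metabolic normalization, and contrasts.

An adult session has five gas periods (room air, hypercapnia, room air,
hypoxia, room air).  Analysis windows are derived from them:

==============  =====================================================
label           window
==============  =====================================================
room_air_1/2/3  last ``ss_window`` s of each room-air period
cap_reflex      first ``reflex_window`` s after the chamber reaches
                90% of the hypercapnic target ("initial reflex")
cap_ss          last ``ss_window`` s of the hypercapnic period
hyp_reflex/ss   likewise for hypoxia
==============  =====================================================

Oxygen consumption follows the flow-through mass balance
``VO2 = flow x (FiO2 - FeO2) / weight`` with FeO2 the mean chamber O2
fraction over the window.  Percent change contrasts reference each
challenge's steady state to the immediately preceding room-air window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TraceRecording, AnimalMeta
from .simulate import AdultProtocol
from .events import call_apneas, call_sighs, compute_event_rates

log = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "EpochingConfig",
    "assign_epochs",
    "compute_vo2",
    "summarize_condition",
    "summarize_session",
    "percent_change",
]

EPOCH_LABELS = ("room_air_1", "cap_reflex", "cap_ss", "room_air_2",
                "hyp_reflex", "hyp_ss", "room_air_3")

# summary variables eligible for percent-change contrasts
PERCENT_CHANGE_VARS = ("vf", "vt_ml", "ve", "ve_per_g", "vo2", "ve_over_vo2")


@dataclass
class Epoch:
    """Half-open analysis interval [start, end) of one gas condition."""

    label: str
    start: float
    end: float
    gas: tuple[float, float] = (0.2095, 0.0004)   # (O2, CO2) inflow fractions

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"epoch {self.label}: start must precede end")

    def contains(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.start) & (t < self.end)


@dataclass
class EpochingConfig:
    reflex_window: float = 120.0   # s of "initial reflex" after gas arrival
    ss_window: float = 300.0       # s of steady state at the period end
    arrival_fraction: float = 0.9  # challenge starts when gas is 90% of target
    min_breaths: int = 20          # calm breaths required to emit a summary
    event_factor: float = 2.0      # apnea/sigh threshold factor


def _detect_switches(rec: TraceRecording, protocol: AdultProtocol) -> list[float]:
    """Gas-switch times: markers when present, else the first halfway
    crossing of the chamber O2/CO2 toward each new target."""
    if rec.markers:
        gas_markers = [(t, label) for t, label in rec.markers
                       if label.startswith("gas:")]
        times = [t for t, _ in gas_markers]
        for (ta, la), (tb, lb) in zip(gas_markers, gas_markers[1:]):
            if tb <= ta:
                raise ValueError(f"marker {lb!r} at {tb} s out of order "
                                 f"(follows {la!r} at {ta} s)")
        if len(times) == len(protocol.epochs) - 1:
            return times
        log.warning("marker count does not match protocol; falling back to "
                    "gas-channel switch detection")
    t = rec.time()
    switches = []
    t_prev = 0.0
    for k in range(1, len(protocol.epochs)):
        prev = protocol.epochs[k - 1]
        new = protocol.epochs[k]
        # use whichever gas moves more
        d_o2, d_co2 = abs(new[1] - prev[1]), abs(new[2] - prev[2])
        chan, f_old, f_new = (("o2", prev[1], new[1]) if d_o2 >= d_co2
                              else ("co2", prev[2], new[2]))
        if chan not in rec.channels:
            raise KeyError(f"no markers and no {chan!r} channel to detect switches")
        y = rec.channels[chan] / 100.0
        half = 0.5 * (f_old + f_new)
        after = t >= t_prev + 1.0
        crossed = ((y - half) * np.sign(f_new - f_old) >= 0) & after
        idx = np.flatnonzero(crossed)
        if len(idx) == 0:
            raise ValueError(f"gas never crosses halfway to target in period {new[0]}")
        switches.append(float(t[idx[0]]))
        t_prev += prev[3]
    return switches


def _arrival_time(rec: TraceRecording, t_switch: float, t_end: float,
                  f_old: float, f_new: float, chan: str,
                  arrival_fraction: float) -> float:
    """First time in [t_switch, t_end) the chamber gas crosses
    ``arrival_fraction`` of the way from its pre-switch value to target."""
    t = rec.time()
    y = rec.channels[chan] / 100.0
    sel = (t >= t_switch) & (t < t_end)
    target = f_old + arrival_fraction * (f_new - f_old)
    crossed = (y[sel] - target) * np.sign(f_new - f_old) >= 0
    idx = np.flatnonzero(crossed)
    if len(idx) == 0:
        raise ValueError("chamber gas never reaches the target fraction")
    return float(t[sel][idx[0]])


def assign_epochs(rec: TraceRecording, protocol: AdultProtocol,
                  cfg: EpochingConfig | None = None) -> list[Epoch]:
    """Derive the seven analysis epochs of an adult session.

    Challenge periods whose gas never reaches ``arrival_fraction`` of the
    target are flagged unusable (their epochs are omitted with a log
    message rather than raising).
    """
    if cfg is None:
        cfg = EpochingConfig()
    if len(protocol.epochs) != 5:
        raise ValueError("adult protocol must have 5 gas periods")
    switches = _detect_switches(rec, protocol)
    bounds = [0.0] + list(switches) + [rec.duration]

    out: list[Epoch] = []
    labels = ["room_air_1", "cap", "room_air_2", "hyp", "room_air_3"]
    for k, (label, (plabel, fo2, fco2, dur)) in enumerate(zip(labels, protocol.epochs)):
        t0, t1 = bounds[k], bounds[k + 1]
        gas = (fo2, fco2)
        if label.startswith("room_air"):
            out.append(Epoch(label, max(t0, t1 - cfg.ss_window), t1, gas))
            continue
        prev = protocol.epochs[k - 1]
        chan = "o2" if abs(fo2 - prev[1]) >= abs(fco2 - prev[2]) else "co2"
        f_old = prev[1] if chan == "o2" else prev[2]
        f_new = fo2 if chan == "o2" else fco2
        try:
            t_arr = _arrival_time(rec, t0, t1, f_old, f_new, chan,
                                  cfg.arrival_fraction)
        except ValueError:
            log.warning("challenge %s unusable: gas never reached %d%% of target",
                        label, int(100 * cfg.arrival_fraction))
            continue
        ss_start = max(t0, t1 - cfg.ss_window)
        reflex_end = min(t_arr + cfg.reflex_window, t1)
        if reflex_end > ss_start:
            # epochs must not overlap (no sample analyzed twice)
            log.warning("challenge %s: reflex window truncated at the "
                        "steady-state boundary", label)
            reflex_end = ss_start
        if reflex_end > t_arr:
            out.append(Epoch(f"{label}_reflex", t_arr, reflex_end, gas))
        out.append(Epoch(f"{label}_ss", ss_start, t1, gas))
    return out


def compute_vo2(rec: TraceRecording, epoch: Epoch, flow: float, weight: float,
                fio2: float | None = None) -> float:
    """Mass-balance oxygen consumption over an epoch, mL O2/min/g.

    ``VO2 = flow x (FiO2 - FeO2) / weight`` with FeO2 the mean chamber O2
    fraction over the epoch (assumed at steady state) and FiO2 the inflow
    fraction (the epoch's nominal O2 unless given).  A negative value
    (FeO2 > FiO2) is returned as-is with a warning — it flags calibration
    drift and must not be silently clipped.
    """
    if "o2" not in rec.channels:
        raise KeyError("recording has no O2 channel")
    if weight <= 0 or flow <= 0:
        raise ValueError("flow and weight must be positive")
    if fio2 is None:
        fio2 = epoch.gas[0]
    t = rec.time()
    feo2 = float(np.mean(rec.channels["o2"][epoch.contains(t)])) / 100.0
    vo2 = flow * (fio2 - feo2) / weight
    if vo2 < 0:
        log.warning("negative VO2 (%.4g) in epoch %s: FeO2 exceeds FiO2 "
                    "(calibration drift?)", vo2, epoch.label)
    return vo2


def summarize_condition(breaths: pd.DataFrame, calls: pd.DataFrame,
                        epoch: Epoch, meta: AnimalMeta,
                        vo2: float | None = None,
                        min_breaths: int = 20) -> dict | None:
    """Per-animal x per-epoch outcome row, or None when the epoch fails
    the calm-breath quality bar (logged).

    Vf = 60 / mean TT (breaths/min) over calm breaths; VT = mean
    calibrated tidal volume; VE = Vf x VT; per-gram variants divide by
    body weight; VE/VO2 uses absolute VE and absolute VO2 (mL/min).
    """
    t = breaths["onset_s"].to_numpy()
    in_ep = breaths[(t >= epoch.start) & (t < epoch.end)]
    calm = in_ep[in_ep["calm"]]
    if len(calm) < min_breaths:
        log.info("epoch %s excluded: %d calm breaths < %d",
                 epoch.label, len(calm), min_breaths)
        return None
    vf = 60.0 / float(calm["tt_s"].mean())
    vt = float(calm["vt_ml"].mean()) if "vt_ml" in calm else float(calm["amp"].mean())
    ve = vf * vt
    rates = compute_event_rates(calls[calls["epoch_label"] == epoch.label]
                                if len(calls) else pd.DataFrame({"type": []}),
                                in_ep, epoch.label)
    row = {
        "animal_id": meta.id, "group": meta.group, "sex": meta.sex,
        "epoch_label": epoch.label,
        "vf": vf, "vt_ml": vt, "vt_ml_per_g": vt / meta.weight,
        "ve": ve, "ve_per_g": ve / meta.weight,
        "ti_s": float(calm["ti_s"].mean()),
        "te_s": float(calm["te_s"].mean()),
        "tt_s": float(calm["tt_s"].mean()),
        "apnea_per100": rates.apnea_rate, "sigh_per100": rates.sigh_rate,
        "n_breaths": len(in_ep), "n_calm": len(calm),
        "vo2": vo2 if vo2 is not None else np.nan,
        "ve_over_vo2": (ve / (vo2 * meta.weight)
                        if vo2 is not None and vo2 > 0 else np.nan),
    }
    return row


def summarize_session(rec: TraceRecording, breaths: pd.DataFrame,
                      protocol: AdultProtocol,
                      cfg: EpochingConfig | None = None) -> pd.DataFrame:
    """End-to-end condition summary for one adult session.

    Epochs are assigned, apneas/sighs called per epoch over its breaths,
    VO2 computed from the chamber O2 mass balance, and one row emitted
    per usable epoch.
    """
    if cfg is None:
        cfg = EpochingConfig()
    if rec.animal is None:
        raise ValueError("recording has no animal metadata")
    epochs = assign_epochs(rec, protocol, cfg)
    rows = []
    for ep in epochs:
        t = breaths["onset_s"].to_numpy()
        in_ep = breaths[(t >= ep.start) & (t < ep.end)]
        if len(in_ep) >= 2:
            calls = pd.concat([
                call_apneas(in_ep, cfg.event_factor, ep.label),
                call_sighs(in_ep, cfg.event_factor, ep.label),
            ], ignore_index=True)
        else:
            calls = pd.DataFrame({"type": [], "epoch_label": []})
        vo2 = (compute_vo2(rec, ep, protocol.flow_rate, rec.animal.weight)
               if "o2" in rec.channels else None)
        row = summarize_condition(in_ep, calls, ep, rec.animal, vo2,
                                  cfg.min_breaths)
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows)


# challenge steady state -> reference room-air epoch (the immediately
# preceding room-air period)
_PC_PAIRS = {"hypercapnia": ("cap_ss", "room_air_1"),
             "hypoxia": ("hyp_ss", "room_air_2")}


def percent_change(summaries: pd.DataFrame,
                   variables: tuple[str, ...] = PERCENT_CHANGE_VARS) -> pd.DataFrame:
    """Percent change of each variable from room air to challenge steady
    state, per animal: 100 x (ss - room_air) / room_air.

    Hypercapnia references the first room-air window; hypoxia references
    the room-air window immediately preceding it.  Animals missing either
    epoch contribute no row (logged).
    """
    rows = []
    for animal_id, sub in summaries.groupby("animal_id"):
        by_label = {r["epoch_label"]: r for _, r in sub.iterrows()}
        for challenge, (ss_label, ref_label) in _PC_PAIRS.items():
            if ss_label not in by_label or ref_label not in by_label:
                log.info("animal %s: missing %s or %s; no %% change for %s",
                         animal_id, ss_label, ref_label, challenge)
                continue
            ss, ref = by_label[ss_label], by_label[ref_label]
            for var in variables:
                ref_v = ref.get(var, np.nan)
                ss_v = ss.get(var, np.nan)
                if not np.isfinite(ref_v) or ref_v == 0 or not np.isfinite(ss_v):
                    continue
                rows.append({
                    "animal_id": animal_id, "group": ss["group"], "sex": ss["sex"],
                    "variable": var, "challenge": challenge,
                    "percent_change": 100.0 * (ss_v - ref_v) / ref_v,
                })
    return pd.DataFrame(rows)
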