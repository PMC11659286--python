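"""Apnea and sigh calling from the per-breath table.

Definitions (applied per gas epoch, inclusive thresholds):

* **sigh** — a breath whose amplitude is at least ``factor`` (default 2)
  times the mean amplitude of the epoch's calm breaths;
* **apnea** — a breath whose interbreath interval (onset-to-onset) is at
  least ``factor`` times the mean IBI of the epoch's calm breaths; the
  event is placed at the breath's offset (where the pause begins).

Rates are reported per 100 breaths (and square-root transformed as a
convenience column; the statistics stage applies its own transforms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["EventRates", "call_apneas", "call_sighs", "compute_event_rates"]

EVENT_COLUMNS = ["type", "time_s", "magnitude", "epoch_label"]


@dataclass
class EventRates:
    """Apnea/sigh rates over one epoch, as events per 100 breaths."""

    n_breaths: int
    n_apneas: int
    n_sighs: int
    epoch_label: str = ""

    @property
    def apnea_rate(self) -> float:
        return 100.0 * self.n_apneas / self.n_breaths if self.n_breaths else float("nan")

    @property
    def sigh_rate(self) -> float:
        return 100.0 * self.n_sighs / self.n_breaths if self.n_breaths else float("nan")


def _calm_reference(breaths: pd.DataFrame, column: str) -> float:
    """Mean of ``column`` over calm breaths, falling back to all breaths
    when no breath is calm (logged)."""
    vals = breaths.loc[breaths["calm"], column].dropna()
    if len(vals) == 0:
        log.warning("no calm breaths in epoch; reference uses all breaths")
        vals = breaths[column].dropna()
    return float(vals.mean())


def call_apneas(breaths: pd.DataFrame, factor: float = 2.0,
                epoch_label: str = "") -> pd.DataFrame:
    """Call apneas: breaths with IBI >= factor x mean calm IBI.

    The event time is the breath's offset (start of the pause); the
    magnitude is IBI / mean IBI.
    """
    if len(breaths) < 2:
        raise ValueError("need at least 2 breaths to call apneas")
    ref = _calm_reference(breaths, "ibi_s")
    sel = breaths["ibi_s"] >= factor * ref
    out = pd.DataFrame({
        "type": "apnea",
        "time_s": breaths.loc[sel, "offset_s"],
        "magnitude": breaths.loc[sel, "ibi_s"] / ref,
        "epoch_label": epoch_label,
    })
    return out.reset_index(drop=True)[EVENT_COLUMNS]


def call_sighs(breaths: pd.DataFrame, factor: float = 2.0,
               epoch_label: str = "") -> pd.DataFrame:
    """Call sighs: breaths with amplitude >= factor x mean calm amplitude.

    The event time is the breath onset; the magnitude is amp / mean amp.
    """
    if len(breaths) < 2:
        raise ValueError("need at least 2 breaths to call sighs")
    ref = _calm_reference(breaths, "amp")
    sel = breaths["amp"] >= factor * ref
    out = pd.DataFrame({
        "type": "sigh",
        "time_s": breaths.loc[sel, "onset_s"],
        "magnitude": breaths.loc[sel, "amp"] / ref,
        "epoch_label": epoch_label,
    })
    return out.reset_index(drop=True)[EVENT_COLUMNS]


def compute_event_rates(calls: pd.DataFrame, breaths: pd.DataFrame,
                        epoch_label: str = "") -> EventRates:
    """Event rates over one epoch as exact count ratios per 100 breaths."""
    if len(breaths) == 0:
        log.warning("epoch %s has zero breaths; rates undefined", epoch_label)
        return EventRates(0, 0, 0, epoch_label)
    n_a = int((calls["type"] == "apnea").sum()) if len(calls) else 0
    n_s = int((calls["type"] == "sigh").sum()) if len(calls) else 0
    return EventRates(n_breaths=len(breaths), n_apneas=n_a, n_sighs=n_s,
                      epoch_label=epoch_label)


def rates_table(rates: list[EventRates], animal_id: str = "") -> pd.DataFrame:
    """Tabulate per-epoch rates (TSV-ready), with sqrt-transformed
    convenience columns."""
    rows = []
    for r in rates:
        rows.append({
            "animal_id": animal_id,
            "epoch_label": r.epoch_label,
            "apnea_per100": r.apnea_rate,
            "sigh_per100": r.sigh_rate,
            "sqrt_apnea_per100": np.sqrt(r.apnea_rate) if np.isfinite(r.apnea_rate) else np.nan,
            "sqrt_sigh_per100": np.sqrt(r.sigh_rate) if np.isfinite(r.sigh_rate) else np.nan,
            "n_breaths": r.n_breaths,
        })
    return pd.DataFrame(rows)
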