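"""Trace containers and delimited-text I/O.

A recording is a set of equally sampled channels (breath pressure/flow in
arbitrary signal units, chamber O2 %, CO2 %, chamber temperature °C) plus
timed text markers (gas switches) and per-animal metadata.  On disk a
recording is a TSV of samples (first column ``time_s``), a sidecar YAML
metadata file holding the animal record, sample rate and markers, and —
for synthetic data — a ground-truth event table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnimalMeta",
    "TraceRecording",
    "read_trace",
    "write_trace",
]

GROUPS = ("SPF", "GF")
SEXES = ("F", "M")


@dataclass
class AnimalMeta:
    """Per-animal metadata attached to a recording.

    ``group`` is the microbiome status (SPF = specific-pathogen-free
    control, GF = germ-free); ``temp_pre``/``temp_post`` are the rectal
    temperatures (°C) taken before and after an adult plethysmography
    session and are used for body-temperature interpolation during tidal
    volume calibration.
    """

    id: str
    group: str = "SPF"
    sex: str = "F"
    weight: float = 25.0          # g
    temp_pre: float = 37.0        # °C
    temp_post: float = 37.0       # °C
    age: float | None = None      # days

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.weight > 0:
            raise ValueError("weight must be positive")


@dataclass
class TraceRecording:
    """Multichannel sampled recording.

    channels
        Mapping of channel name -> 1-D float array; all channels share
        ``sample_rate`` and length.  The breathing signal lives under the
        key ``"breath"`` by convention; gas channels under ``"o2"`` /
        ``"co2"`` (percent), temperature under ``"temp"`` (°C).
    markers
        List of ``(time_s, label)`` pairs, e.g. gas-switch annotations.
    """

    channels: dict[str, np.ndarray]
    sample_rate: float
    markers: list[tuple[float, str]] = field(default_factory=list)
    animal: AnimalMeta | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channels:
            raise ValueError("recording must have at least one channel")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"all channels must have equal length, got {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        dur = self.duration
        for t, label in self.markers:
            if not (0.0 <= t <= dur):
                raise ValueError(f"marker {label!r} at {t} s outside [0, {dur}] s")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds from recording start (0-based samples)."""
        return np.arange(self.n_samples) / self.sample_rate

    def slice(self, start: float, end: float) -> "TraceRecording":
        """Half-open time slice [start, end) as a new recording (markers dropped)."""
        i0 = max(0, int(np.ceil(start * self.sample_rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(end * self.sample_rate - 1e-9)))
        return TraceRecording(
            channels={k: v[i0:i1] for k, v in self.channels.items()},
            sample_rate=self.sample_rate,
            markers=[],
            animal=self.animal,
        )


_UNITS = {"breath": "au", "o2": "pct", "co2": "pct", "temp": "C"}


def _column_name(channel: str) -> str:
    return f"{channel}_{_UNITS.get(channel, 'au')}"


def write_trace(rec: TraceRecording, path: str | Path) -> Path:
    """Write a recording as ``<path>.tsv`` plus ``<path>.meta.yaml``.

    The TSV has one header line (channel names with units) and one row per
    sample; the first column is time in seconds.  Returns the TSV path.
    """
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    cols = {"time_s": rec.time()}
    for name, arr in rec.channels.items():
        cols[_column_name(name)] = arr
    pd.DataFrame(cols).to_csv(tsv, sep="\t", index=False, float_format="%.6g")

    meta: dict = {"sample_rate_hz": rec.sample_rate,
                  "markers": [{"time_s": float(t), "label": str(l)} for t, l in rec.markers]}
    if rec.animal is not None:
        meta["animal"] = asdict(rec.animal)
    with open(path.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return tsv


def read_trace(path: str | Path) -> TraceRecording:
    """Read a recording written by :func:`write_trace`."""
    path = Path(path)
    tsv = path if path.suffix == ".tsv" else path.with_suffix(".tsv")
    df = pd.read_csv(tsv, sep="\t")
    meta_path = tsv.with_suffix("").with_suffix(".meta.yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)

    channels: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        name = col.rsplit("_", 1)[0]
        channels[name] = df[col].to_numpy(dtype=float)

    animal = AnimalMeta(**meta["animal"]) if "animal" in meta else None
    markers = [(float(m["time_s"]), str(m["label"])) for m in meta.get("markers", [])]
    return TraceRecording(channels=channels, sample_rate=float(meta["sample_rate_hz"]),
                          markers=markers, animal=animal)
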