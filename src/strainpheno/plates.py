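"""Plate-reader run containers and the long-CSV dialect.

A kinetic run is a set of wells measured on one shared time grid in up to
three channels: OD600 (absorbance) and the two BCECF excitation channels
F440 (ex 440 nm / em 535 nm) and F490 (ex 490 nm / em 535 nm).  Data files
are long CSVs with columns ``well,time_h,channel,value``; the well layout
is a separate CSV mapping each well to its strain, condition, replicate
index, and BCECF / sterile-control flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CHANNELS = ("OD600", "F440", "F490")

LAYOUT_COLUMNS = [
    "well",
    "strain",
    "condition_type",
    "condition_value",
    "replicate",
    "bcecf",
    "sterile",
]


@dataclass(frozen=True)
class WellMeta:
    """Metadata for one well of a kinetic plate run.

    ``condition_type`` is ``"pH"`` (value in pH units) or ``"osmolality"``
    (value in mOsm/kg).  ``bcecf`` marks dye-loaded wells; ``sterile`` marks
    no-inoculum control wells used for contamination QC.
    """

    well: str
    strain: str
    condition_type: str
    condition_value: float
    replicate: int
    bcecf: bool = False
    sterile: bool = False

    def __post_init__(self) -> None:
        if self.condition_type not in ("pH", "osmolality"):
            raise ValueError(f"unknown condition type {self.condition_type!r}")
        if self.condition_type == "pH" and not 0.0 <= self.condition_value <= 14.0:
            raise ValueError(f"pH {self.condition_value} outside [0, 14]")
        if self.condition_type == "osmolality" and self.condition_value <= 0:
            raise ValueError("osmolality must be positive")


@dataclass
class PlateReaderRun:
    """Wells x timepoints x channels on one strictly increasing grid.

    ``channels`` maps a channel name to a DataFrame indexed by time (h) with
    one column per well id; missing readings are NaN gaps, never zeros.
    """

    times: np.ndarray
    wells: list[WellMeta]
    channels: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        ids = [w.well for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate well ids in layout")
        self._meta = {w.well: w for w in self.wells}

    def meta(self, well: str) -> WellMeta:
        return self._meta[well]

    @property
    def well_ids(self) -> list[str]:
        return [w.well for w in self.wells]

    def series(self, well: str, channel: str = "OD600") -> np.ndarray:
        """Readings for one well/channel on the shared grid (NaN for gaps)."""
        return self.channels[channel][well].to_numpy(dtype=float)

    def wells_where(self, **flags) -> list[WellMeta]:
        """Wells whose metadata attributes equal the given values."""
        out = []
        for w in self.wells:
            if all(getattr(w, k) == v for k, v in flags.items()):
                out.append(w)
        return out


def layout_frame(wells: Iterable[WellMeta]) -> pd.DataFrame:
    rows = [
        (w.well, w.strain, w.condition_type, w.condition_value, w.replicate,
         int(w.bcecf), int(w.sterile))
        for w in wells
    ]
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def write_layout_csv(wells: Iterable[WellMeta], path: str | Path) -> None:
    layout_frame(wells).to_csv(path, index=False)


def read_layout_csv(path: str | Path) -> list[WellMeta]:
    df = pd.read_csv(path, dtype={"well": str, "strain": str})
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    if df["well"].duplicated().any():
        dups = df.loc[df["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate well id(s) in layout: {dups}")
    return [
        WellMeta(
            well=r.well,
            strain=r.strain,
            condition_type=r.condition_type,
            condition_value=float(r.condition_value),
            replicate=int(r.replicate),
            bcecf=bool(r.bcecf),
            sterile=bool(r.sterile),
        )
        for r in df.itertuples(index=False)
    ]


def write_plate_csv(run: PlateReaderRun, path: str | Path) -> None:
    """Serialize a run to the long dialect (well, time_h, channel, value)."""
    parts = []
    for channel, frame in run.channels.items():
        long = frame.reset_index(names="time_h").melt(
            id_vars="time_h", var_name="well", value_name="value"
        )
        long["channel"] = channel
        parts.append(long.dropna(subset=["value"]))
    out = pd.concat(parts, ignore_index=True)
    out = out[["well", "time_h", "channel", "value"]].sort_values(
        ["well", "channel", "time_h"], kind="stable"
    )
    out.to_csv(path, index=False)


def parse_plate_run(data_path: str | Path, layout_path: str | Path) -> PlateReaderRun:
    """Read a long-CSV kinetic file against its layout.

    Every well present in the data must appear in the layout (hard error
    otherwise).  All channels are aligned onto the union time grid; readings
    absent for a (well, time, channel) combination become NaN gaps.
    """
    wells = read_layout_csv(layout_path)
    known = {w.well for w in wells}
    df = pd.read_csv(data_path, dtype={"well": str, "channel": str})
    required = {"well", "time_h", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"data file missing columns: {sorted(required - set(df.columns))}")
    unknown = set(df["well"]) - known
    if unknown:
        raise ValueError(f"data wells absent from layout: {sorted(unknown)}")
    bad = set(df["channel"]) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown channel(s): {sorted(bad)}")
    if df.duplicated(["well", "time_h", "channel"]).any():
        raise ValueError("duplicate (well, time, channel) readings")
    times = np.unique(df["time_h"].to_numpy(dtype=float))
    channels: dict[str, pd.DataFrame] = {}
    for channel, sub in df.groupby("channel"):
        wide = sub.pivot(index="time_h", columns="well", values="value")
        wide = wide.reindex(index=times)
        channels[channel] = wide
    present = {w for frame in channels.values() for w in frame.columns}
    if "OD600" not in channels or present - set(channels["OD600"].columns):
        raise ValueError("every data well must carry an OD600 channel")
    kept = [w for w in wells if w.well in present]
    return PlateReaderRun(times=times, wells=kept, channels=channels)
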