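"""Event-table data model and I/O for flow-cytometry samples.

An :class:`EventTable` wraps a per-event measurement matrix (one row per
event, one column per instrument channel) together with a *channel map*
assigning analysis roles — FSC, SSC, DNA, CK, KI67 — to channel names, plus
sample metadata.  A :class:`SamplePair` couples a stained table with its
isotype-matched control, the pairing every cutoff in this assay is derived
from.

No compensation or fluorescence transform is applied at I/O; gating operates
on linear channel values.  The CSV dialect (comma-separated, UTF-8, ``.``
decimal, header row of channel names, no index column) round-trips values
exactly; FCS 3.1 round-trips within float32 representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import read_fcs, write_fcs

__all__ = [
    "ROLES",
    "CORE_ROLES",
    "EventTable",
    "SamplePair",
    "read_events",
    "write_events",
]

#: All channel roles the pipeline understands.
ROLES = ("FSC", "SSC", "DNA", "CK", "KI67")
#: Roles every table must map.
CORE_ROLES = ("FSC", "SSC", "DNA")

STAIN_KINDS = ("antibody", "isotype_control")


class ChannelMappingError(KeyError):
    pass


@dataclass
class EventTable:
    """Per-event channel measurements with role mapping and metadata."""

    data: pd.DataFrame
    channel_map: dict
    sample_id: str = ""
    stain: str = "antibody"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stain not in STAIN_KINDS:
            raise ValueError(f"stain must be one of {STAIN_KINDS}, got {self.stain!r}")
        for role in CORE_ROLES:
            if role not in self.channel_map:
                raise ChannelMappingError(f"role {role} unmapped")
        for role, name in self.channel_map.items():
            if name not in self.data.columns:
                raise ChannelMappingError(
                    f"role {role} maps to channel {name!r} absent from the table"
                )
            values = self.data[name].to_numpy(dtype=float)
            bad = ~np.isfinite(values)
            if bad.any():
                raise ValueError(
                    f"channel {name!r} (role {role}): non-finite value at "
                    f"event {int(np.argmax(bad))}"
                )
            neg = values < 0
            if neg.any():
                raise ValueError(
                    f"channel {name!r} (role {role}): negative value at "
                    f"event {int(np.argmax(neg))}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channel(self, role: str) -> np.ndarray:
        """Values of the channel mapped to ``role`` as a float array."""
        if role not in self.channel_map:
            raise ChannelMappingError(f"role {role} unmapped")
        return self.data[self.channel_map[role]].to_numpy(dtype=float)

    def scatter(self) -> np.ndarray:
        """(n, 2) array of FSC/SSC values."""
        return np.column_stack([self.channel("FSC"), self.channel("SSC")])


@dataclass
class SamplePair:
    """A stained event table plus its isotype-matched control."""

    stained: EventTable
    control: EventTable
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.stained.stain != "antibody":
            raise ValueError("stained member must have stain kind 'antibody'")
        if self.control.stain != "isotype_control":
            raise ValueError("control member must have stain kind 'isotype_control'")
        if set(self.stained.channel_map) != set(self.control.channel_map):
            raise ValueError("stained and control members map different roles")


def read_events(path, channel_map: dict, fmt: str | None = None,
                sample_id: str = "", stain: str = "antibody") -> EventTable:
    """Read an event table from CSV or FCS.

    ``fmt`` is ``"csv"`` or ``"fcs"``; when omitted it is inferred from the
    file suffix.  Unknown extra channels are preserved but unused.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if fmt == "csv":
        # round_trip parser: bit-exact CSV round-trips are part of the contract
        data = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "fcs":
        data = read_fcs(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return EventTable(data=data, channel_map=dict(channel_map),
                      sample_id=sample_id or path.stem, stain=stain)


def write_events(table: EventTable, path, fmt: str | None = None) -> None:
    """Write an event table to CSV (exact) or FCS 3.1 (float32)."""
    path = Path(path)
    if fmt is None:
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if fmt == "csv":
        table.data.to_csv(path, index=False)
    elif fmt == "fcs":
        write_fcs(table.data, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
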