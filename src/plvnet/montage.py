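"""Electrode montage handling (10-20 extension layout).

A montage is the ordered list of scalp channel names plus their 3-D
positions in head coordinates (metres).  The package ships a 62-channel
10-20 extension layout matching a 63-channel amplifier referenced at the
right earlobe (62 effective scalp electrodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

_DEFAULT_MONTAGE_RESOURCE = "montage_62ch.csv"


@dataclass
class Montage:
    """Ordered channel names with scalp coordinates."""

    names: list[str]
    positions: np.ndarray  # (n_ch, 3), metres

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("montage channel names must be unique")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError(
                f"positions must be ({len(self.names)}, 3), got {self.positions.shape}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: list[str]) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(list(names), self.positions[idx])

    def to_csv(self, path: "str | Path") -> None:
        df = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        df.insert(0, "name", self.names)
        df.to_csv(path, index=False)


def load_montage(path: "str | Path") -> Montage:
    """Read a montage from a CSV with columns name, x, y, z."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage CSV needs columns {sorted(required)}")
    return Montage(df["name"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy())


def default_montage() -> Montage:
    """The packaged 62-channel 10-20 extension montage."""
    with resources.files("plvnet.data").joinpath(_DEFAULT_MONTAGE_RESOURCE).open() as f:
        df = pd.read_csv(f)
    return Montage(df["name"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy())
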