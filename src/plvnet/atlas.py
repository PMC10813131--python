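"""Ten-region scalp atlas for region-averaged network properties.

The scalp is split into 10 non-overlapping lateral sub-regions — left/right
frontal (LF, RF), central (LC, RC), temporal (LT, RT), parietal (LP, RP)
and occipital (LO, RO).  Hemisphere follows the 10-20 numbering convention
(odd suffix = left, even = right); midline electrodes (Z suffix) belong to
no lateral region.  Lobe follows the letter prefix: FP/AF/F frontal,
FC/C/CP central, FT/T/TP temporal, P parietal, PO/O occipital.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage

#: Region order used in all tabular outputs.
REGION_ORDER: tuple[str, ...] = (
    "LF", "RF", "LC", "RC", "LT", "RT", "LP", "RP", "LO", "RO",
)

# Prefix -> lobe letter; longest prefixes first so FC is not read as F.
_LOBE_BY_PREFIX = [
    ("FP", "F"), ("AF", "F"), ("FC", "C"), ("FT", "T"), ("CP", "C"),
    ("TP", "T"), ("PO", "O"), ("F", "F"), ("C", "C"), ("T", "T"),
    ("P", "P"), ("O", "O"),
]

_NAME_RE = re.compile(r"^([A-Za-z]+)(\d+|Z|z)$")


class AtlasError(ValueError):
    """Raised for invalid region definitions or montage mismatches."""


@dataclass
class RegionAtlas:
    """Mapping from region name to an ordered channel-name list."""

    regions: dict[str, list[str]]

    def __post_init__(self) -> None:
        unknown = set(self.regions) - set(REGION_ORDER)
        if unknown:
            raise AtlasError(f"unknown region names: {sorted(unknown)}")
        seen: set[str] = set()
        for region, chans in self.regions.items():
            dup = seen.intersection(chans)
            if dup:
                raise AtlasError(f"channels in more than one region: {sorted(dup)}")
            seen.update(chans)

    @property
    def channels(self) -> list[str]:
        return [c for r in REGION_ORDER for c in self.regions.get(r, [])]

    def validate_against(self, channel_names: list[str]) -> None:
        missing = [c for c in self.channels if c not in channel_names]
        if missing:
            raise AtlasError(
                f"atlas channels missing from montage: {missing}"
            )

    def to_csv(self, path: "str | Path") -> None:
        rows = [
            {"region": r, "channel": c}
            for r in REGION_ORDER
            for c in self.regions.get(r, [])
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_atlas(path: "str | Path") -> RegionAtlas:
    """Read an atlas from a CSV with columns region, channel."""
    df = pd.read_csv(path)
    if not {"region", "channel"}.issubset(df.columns):
        raise ValueError("atlas CSV needs columns region, channel")
    regions: dict[str, list[str]] = {}
    for region, sub in df.groupby("region", sort=False):
        regions[str(region)] = sub["channel"].astype(str).tolist()
    return RegionAtlas(regions)


def _classify(channel: str) -> "str | None":
    """Region code for one channel name, or None for midline/unknown."""
    m = _NAME_RE.match(channel)
    if m is None:
        return None
    prefix, suffix = m.group(1).upper(), m.group(2).upper()
    if suffix == "Z":
        return None  # midline electrodes are excluded from lateral regions
    lobe = next((lo for p, lo in _LOBE_BY_PREFIX if prefix == p), None)
    if lobe is None:
        return None
    hemi = "L" if int(suffix) % 2 == 1 else "R"
    return hemi + lobe


def default_atlas(montage: Montage) -> RegionAtlas:
    """Build the prefix/suffix rule-based 10-region atlas for a montage."""
    regions: dict[str, list[str]] = {r: [] for r in REGION_ORDER}
    for name in montage.names:
        region = _classify(name)
        if region is not None:
            regions[region].append(name)
    return RegionAtlas(regions)


def region_average(
    values: np.ndarray, channel_names: list[str], atlas: RegionAtlas
) -> pd.Series:
    """Average a per-channel metric within each atlas region.

    Parameters
    ----------
    values
        Per-channel metric aligned with ``channel_names``.
    channel_names
        Channel order of ``values``.
    atlas
        Region membership; every atlas channel must be present.

    Returns
    -------
    pandas.Series of 10 region means, indexed in canonical region order.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(channel_names),):
        raise ValueError("values must be one number per channel")
    atlas.validate_against(list(channel_names))
    idx = {c: i for i, c in enumerate(channel_names)}
    out = {}
    for region in REGION_ORDER:
        chans = atlas.regions.get(region, [])
        out[region] = float(np.mean([values[idx[c]] for c in chans])) if chans else np.nan
    return pd.Series(out, name="region_mean")
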