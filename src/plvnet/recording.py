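"""In-memory containers for continuous recordings and epoched data.

A :class:`Recording` is a continuous multichannel signal (channels x
samples, microvolts) with stage annotations.  An :class:`EpochSet` holds
fixed-length segments of one subject/stage, optionally band-filtered — the
unit on which phase-locking connectivity is computed.

Recordings round-trip through a portable container: an ``.npz`` array file
with a JSON sidecar carrying sampling rate, channel names and annotations.
EDF and BrainVision files are read through MNE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .bands import BandSpec


@dataclass
class Annotation:
    """A labelled time span [start_s, end_s) within a recording."""

    stage: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"annotation {self.stage!r}: end_s must exceed start_s"
            )


@dataclass
class Recording:
    """Continuous multichannel signal with stage annotations."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channels: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("one channel name per data row required")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.start_s < 0 or ann.end_s > dur + 1e-9:
                raise ValueError(
                    f"annotation {ann.stage!r} [{ann.start_s}, {ann.end_s}) "
                    f"outside recording extent 0..{dur:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def stages(self) -> list[str]:
        seen: list[str] = []
        for ann in self.annotations:
            if ann.stage not in seen:
                seen.append(ann.stage)
        return seen

    def spans(self, stage: str) -> list[Annotation]:
        return [a for a in self.annotations if a.stage == stage]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data))

    # -- portable container -------------------------------------------------

    def save(self, path: "str | Path") -> None:
        """Write ``<path>.npz`` plus a ``<path>.json`` sidecar."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix == ".npz" else path
        np.savez_compressed(base.with_suffix(".npz"), data=self.data)
        sidecar = {
            "fs": self.fs,
            "channels": self.channels,
            "subject_id": self.subject_id,
            "annotations": [
                {"stage": a.stage, "start_s": a.start_s, "end_s": a.end_s}
                for a in self.annotations
            ],
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: "str | Path") -> "Recording":
        base = Path(path)
        if base.suffix in {".npz", ".json"}:
            base = base.with_suffix("")
        with np.load(base.with_suffix(".npz")) as npz:
            data = npz["data"]
        meta = json.loads(base.with_suffix(".json").read_text())
        return cls(
            data=data,
            fs=float(meta["fs"]),
            channels=list(meta["channels"]),
            annotations=[Annotation(**a) for a in meta["annotations"]],
            subject_id=meta.get("subject_id", ""),
        )


@dataclass
class EpochSet:
    """Fixed-length segments of one subject/stage, optionally band-filtered."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    channels: list[str]
    stage: str
    subject_id: str = ""
    band: "BandSpec | None" = None  # None = broadband

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        if not np.issubdtype(self.epochs.dtype, np.floating):
            self.epochs = self.epochs.astype(float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x n_channels x n_samples")
        if self.epochs.shape[0] < 1:
            raise ValueError("EpochSet needs at least one epoch")
        if len(self.channels) != self.epochs.shape[1]:
            raise ValueError("one channel name per epoch row required")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def copy_with(self, epochs: np.ndarray, band: "BandSpec | None" = None) -> "EpochSet":
        return replace(
            self,
            epochs=np.asarray(epochs),
            band=band if band is not None else self.band,
        )


def read_raw(path: "str | Path") -> Recording:
    """Read a continuous recording from EDF, BrainVision or the container format.

    EDF (``.edf``) and BrainVision (``.vhdr``) go through MNE; annotations on
    the file are carried over as stage spans.  Any other path is treated as
    the package's npz+JSON container.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".edf", ".vhdr"}:
        import mne

        if suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        data_uv = raw.get_data() * 1e6  # MNE uses volts internally
        annotations = [
            Annotation(desc, float(onset), float(onset + dur))
            for desc, onset, dur in zip(
                raw.annotations.description,
                raw.annotations.onset,
                raw.annotations.duration,
            )
            if dur > 0
        ]
        return Recording(
            data=data_uv,
            fs=float(raw.info["sfreq"]),
            channels=list(raw.ch_names),
            annotations=annotations,
            subject_id=path.stem,
        )
    return Recording.load(path)
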