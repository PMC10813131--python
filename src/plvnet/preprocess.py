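"""Offline preprocessing: segmentation, filtering, re-referencing, ICA.

The canonical offline chain turns a continuous recording into 2-s epochs
per stage, band-passes 0.1-60 Hz, optionally removes high-kurtosis ICA
components, subtracts per-epoch baselines, applies the average reference,
and finally band-filters each epoch into the five canonical bands with a
zero-phase Chebyshev type-I cascade (low-pass at the upper edge, then
high-pass at the lower edge).  Zero net phase shift is required because
the epochs feed phase-locking estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BandSpec
from .recording import EpochSet, Recording

#: Chebyshev type-I design used for band separation.
CHEBY_ORDER = 4
CHEBY_RIPPLE_DB = 0.5


class EmptyStageError(ValueError):
    """A requested stage is absent or yields no full epoch."""


def segment(rec: Recording, stage: str, epoch_s: float = 2.0) -> EpochSet:
    """Cut non-overlapping consecutive epochs from every span of a stage.

    Each annotated span contributes ``floor(span / epoch_s)`` epochs; a
    trailing remainder shorter than ``epoch_s`` is dropped.  Epochs from
    multiple spans (e.g. a task stage across 16 trials) are concatenated.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    spans = rec.spans(stage)
    if not spans:
        raise EmptyStageError(f"stage {stage!r} not annotated in recording")
    n_per_epoch = int(round(epoch_s * rec.fs))
    pieces = []
    for ann in spans:
        start = int(round(ann.start_s * rec.fs))
        stop = min(int(round(ann.end_s * rec.fs)), rec.n_samples)
        n_epochs = (stop - start) // n_per_epoch
        for k in range(n_epochs):
            a = start + k * n_per_epoch
            pieces.append(rec.data[:, a : a + n_per_epoch])
    if not pieces:
        raise EmptyStageError(
            f"stage {stage!r}: no span is at least {epoch_s} s long"
        )
    return EpochSet(
        epochs=np.stack(pieces),
        fs=rec.fs,
        channels=list(rec.channels),
        stage=stage,
        subject_id=rec.subject_id,
        band=None,
    )


def _apply_filter(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, x, axis=-1)


def broadband_filter(
    obj: "Recording | EpochSet", low: float = 0.1, high: float = 60.0
) -> "Recording | EpochSet":
    """Zero-phase Butterworth band-pass (default 0.1-60 Hz)."""
    if not 0 < low < high < obj.fs / 2:
        raise ValueError(
            f"need 0 < low < high < Nyquist; got ({low}, {high}) at fs={obj.fs}"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=obj.fs, output="sos")
    if isinstance(obj, Recording):
        return obj.copy_with(_apply_filter(obj.data, sos))
    return obj.copy_with(_apply_filter(obj.epochs, sos))


def band_filter(epochs: EpochSet, band: BandSpec) -> EpochSet:
    """Chebyshev type-I low-pass then high-pass cascade, zero-phase.

    Order-4 sections with 0.5 dB passband ripple, each applied
    forward-backward so the net phase shift is zero; the output is tagged
    with the band.
    """
    nyq = epochs.fs / 2
    if not 0 < band.low_hz < band.high_hz < nyq:
        raise ValueError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) outside Nyquist {nyq} Hz"
        )
    sos_lp = sps.cheby1(
        CHEBY_ORDER, CHEBY_RIPPLE_DB, band.high_hz, btype="lowpass",
        fs=epochs.fs, output="sos",
    )
    sos_hp = sps.cheby1(
        CHEBY_ORDER, CHEBY_RIPPLE_DB, band.low_hz, btype="highpass",
        fs=epochs.fs, output="sos",
    )
    out = _apply_filter(_apply_filter(epochs.epochs, sos_lp), sos_hp)
    return epochs.copy_with(out, band=band)


def rereference_average(obj: "Recording | EpochSet") -> "Recording | EpochSet":
    """Subtract the across-channel mean at every sample (average reference)."""
    if isinstance(obj, Recording):
        if obj.n_channels < 2:
            raise ValueError("average reference needs at least 2 channels")
        return obj.copy_with(obj.data - obj.data.mean(axis=0, keepdims=True))
    if obj.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return obj.copy_with(obj.epochs - obj.epochs.mean(axis=1, keepdims=True))


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch/channel's own temporal mean.

    In a continuous task there is no pre-stimulus window, so the whole
    epoch serves as its own baseline.
    """
    return epochs.copy_with(
        epochs.epochs - epochs.epochs.mean(axis=-1, keepdims=True)
    )


@dataclass
class IcaReport:
    """Which ICA components were rejected and why."""

    n_components: int
    removed: list[int]
    kurtosis_z: np.ndarray


def remove_artifacts_ica(
    rec: Recording, kurtosis_z: float = 5.0, random_state: int = 0
) -> tuple[Recording, IcaReport]:
    """FastICA decomposition with kurtosis-based component rejection.

    Components whose excess-kurtosis z-score across components exceeds
    ``kurtosis_z`` (spiky, artifact-like sources) are zeroed before
    back-projection.  Intended for continuous data before segmentation;
    optional and off by default for synthetic cohorts.
    """
    from sklearn.decomposition import FastICA

    n_ch, n_samples = rec.data.shape
    if n_samples < 10 * n_ch:
        raise ValueError("ICA needs many more samples than channels")
    ica = FastICA(
        n_components=n_ch, whiten="unit-variance", random_state=random_state,
        max_iter=1000,
    )
    try:
        sources = ica.fit_transform(rec.data.T)  # (n_samples, n_comp)
    except Exception as exc:  # pragma: no cover - decomposition failure path
        raise RuntimeError(f"FastICA decomposition failed: {exc}") from exc
    from scipy.stats import kurtosis as _kurt

    k = _kurt(sources, axis=0, fisher=True)
    sd = k.std(ddof=1)
    z = (k - k.mean()) / sd if sd > 0 else np.zeros_like(k)
    removed = [int(i) for i in np.nonzero(z > kurtosis_z)[0]]
    cleaned_sources = sources.copy()
    if removed:
        cleaned_sources[:, removed] = 0.0
    cleaned = ica.inverse_transform(cleaned_sources).T
    report = IcaReport(n_components=sources.shape[1], removed=removed, kurtosis_z=z)
    return rec.copy_with(cleaned), report


def preprocess_stage(
    rec: Recording,
    stage: str,
    bands: "tuple[BandSpec, ...]",
    epoch_s: float = 2.0,
    low: float = 0.1,
    high: float = 60.0,
    ica: bool = False,
    ica_kurtosis_z: float = 5.0,
) -> dict[str, EpochSet]:
    """Run the canonical offline chain for one stage; returns band -> epochs.

    Order: (optional ICA on continuous data) -> segment -> broadband filter
    -> baseline correct -> average reference -> per-band Chebyshev filter.
    """
    if ica:
        rec, _ = remove_artifacts_ica(rec, kurtosis_z=ica_kurtosis_z)
    epochs = segment(rec, stage, epoch_s=epoch_s)
    epochs = broadband_filter(epochs, low=low, high=high)
    epochs = baseline_correct(epochs)
    epochs = rereference_average(epochs)
    return {band.name: band_filter(epochs, band) for band in bands}
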