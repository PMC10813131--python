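"""Phase-locking-value (PLV) connectivity matrices.

The PLV of two phase series is the magnitude of the time-averaged unit
phasor of their phase difference:

    PLV = | (1/N) sum_t exp(i (phi_i(t) - phi_j(t))) |

It equals 1 for perfectly locked (constant-lag) phases and tends to 0 as
1/sqrt(N) for independent phases.  Phases are taken from the analytic
signal of each band-filtered epoch; PLV is computed within each 2-s epoch
and averaged across epochs, yielding one symmetric channels x channels
matrix per subject, band and stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .recording import EpochSet


@dataclass
class ConnectivityMatrix:
    """Symmetric per-subject PLV adjacency with unit diagonal."""

    values: np.ndarray
    channels: list[str]
    band: str
    stage: str
    subject_id: str = ""
    n_epochs: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over the channel list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("connectivity matrix must have unit diagonal")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")

    def to_tsv(self, path: "str | Path") -> None:
        df = pd.DataFrame(self.values, index=self.channels, columns=self.channels)
        df.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(
        cls, path: "str | Path", band: str = "", stage: str = "", subject_id: str = ""
    ) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            channels=[str(c) for c in df.columns],
            band=band,
            stage=stage,
            subject_id=subject_id,
        )


def instantaneous_phase(epochs: EpochSet) -> np.ndarray:
    """Analytic-signal phase per channel and epoch, radians in (-pi, pi].

    Epochs are expected to be narrowband (band-filtered) so the analytic
    phase is interpretable as an instantaneous oscillation phase.
    """
    x = epochs.epochs
    if x.shape[-1] == 0:
        raise ValueError("zero-length epochs have no phase")
    return np.angle(hilbert(x, axis=-1))


def plv(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLV of two equal-length phase series."""
    phase_i = np.asarray(phase_i, dtype=float).ravel()
    phase_j = np.asarray(phase_j, dtype=float).ravel()
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series must have equal length")
    if phase_i.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.exp(1j * (phase_i - phase_j)).mean()))


def _plv_matrix_from_phasors(z: np.ndarray) -> np.ndarray:
    """Epoch-averaged pairwise PLV from unit phasors (n_epochs, n_ch, n_samples)."""
    n_epochs, n_ch, n_samples = z.shape
    acc = np.zeros((n_ch, n_ch))
    for e in range(n_epochs):
        g = z[e] @ z[e].conj().T / n_samples  # G[i, j] = mean_t exp(i(phi_i - phi_j))
        acc += np.abs(g)
    plv_mat = acc / n_epochs
    plv_mat = 0.5 * (plv_mat + plv_mat.T)  # enforce exact symmetry
    np.fill_diagonal(plv_mat, 1.0)
    return np.clip(plv_mat, 0.0, 1.0)


def plv_matrix_from_phases(phases: np.ndarray) -> np.ndarray:
    """Epoch-averaged pairwise PLV from a (n_epochs, n_ch, n_samples) phase tensor."""
    if phases.ndim != 3:
        raise ValueError("phases must be n_epochs x n_channels x n_samples")
    return _plv_matrix_from_phasors(np.exp(1j * phases))


def build_matrix(epochs: EpochSet) -> ConnectivityMatrix:
    """Per-subject PLV adjacency: per-epoch PLV averaged across epochs.

    The unit phasor of each sample is the analytic signal divided by its
    envelope, algebraically identical to ``exp(i * instantaneous_phase)``.
    """
    if epochs.n_epochs < 1:
        raise ValueError("EpochSet is empty")
    if epochs.epochs.shape[-1] < 2:
        raise ValueError("epochs too short for phase estimation")
    analytic = hilbert(epochs.epochs.astype(np.float32), axis=-1)
    env = np.abs(analytic)
    z = analytic / np.where(env > 0, env, 1.0)
    # accumulate in double precision so near-1 PLVs are exact to ~1e-9
    values = _plv_matrix_from_phasors(z.astype(np.complex128))
    band = epochs.band.name if epochs.band is not None else "broadband"
    return ConnectivityMatrix(
        values=values,
        channels=list(epochs.channels),
        band=band,
        stage=epochs.stage,
        subject_id=epochs.subject_id,
        n_epochs=epochs.n_epochs,
    )
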