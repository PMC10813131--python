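"""Small-world graph metrics of PLV networks.

Weighted metrics follow the standard weighted-network definitions: weights
are normalized by the maximum off-diagonal weight, the clustering
coefficient uses Onnela's geometric-mean triangle form, shortest-path
distances are reciprocal weights, the characteristic path length (CPL) is
the mean finite pairwise distance, global efficiency (Ge) is the mean
inverse distance over pairs, local efficiency (Le) is the global
efficiency of each node's neighborhood subgraph, and node degree (ND) is
the node strength.  A proportional-threshold mode keeps the strongest
fraction of edges, binarizes, and applies the binary formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .atlas import RegionAtlas, region_average  # noqa: F401  (re-exported)
from .connectivity import ConnectivityMatrix


@dataclass
class GraphMetrics:
    """Per-node and global small-world properties of one network."""

    cc: np.ndarray   # per-node clustering coefficient
    le: np.ndarray   # per-node local efficiency
    nd: np.ndarray   # per-node strength (degree for binary graphs)
    cpl: float       # characteristic path length
    ge: float        # global efficiency
    channels: list[str]
    band: str = ""
    stage: str = ""
    subject_id: str = ""
    mode: str = "weighted"
    connected: bool = True

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-node table (global values repeated per node)."""
        rows = []
        for metric, values in (("cc", self.cc), ("le", self.le), ("nd", self.nd)):
            for ch, v in zip(self.channels, values):
                rows.append(
                    {
                        "subject_id": self.subject_id, "band": self.band,
                        "stage": self.stage, "node": ch,
                        "metric": metric, "value": float(v),
                    }
                )
        for metric, v in (("cpl", self.cpl), ("ge", self.ge)):
            rows.append(
                {
                    "subject_id": self.subject_id, "band": self.band,
                    "stage": self.stage, "node": "GLOBAL",
                    "metric": metric, "value": float(v),
                }
            )
        return pd.DataFrame(rows)


def _validate_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if w.min() < -1e-12 or w.max() > 1 + 1e-9:
        raise ValueError("weights must lie in [0, 1]")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


def _onnela_clustering(w_hat: np.ndarray) -> np.ndarray:
    """Onnela geometric-mean triangle clustering on max-normalized weights."""
    k = (w_hat > 0).sum(axis=1)
    cbrt = np.cbrt(w_hat)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, triangles / denom, 0.0)
    return cc


def _distance_metrics(w_hat: np.ndarray) -> tuple[float, float, np.ndarray, bool]:
    """(CPL, Ge, pairwise-distance matrix, connected flag) from weights."""
    n = w_hat.shape[0]
    with np.errstate(divide="ignore"):
        dist_in = np.where(w_hat > 0, 1.0 / w_hat, np.inf)
    np.fill_diagonal(dist_in, 0.0)
    d = shortest_path(dist_in, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    connected = bool(finite.sum() == off.sum())
    cpl = float(d[finite].mean()) if finite.any() else np.inf
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    ge = float(inv[off].mean()) if n > 1 else 0.0
    return cpl, ge, d, connected


def _local_efficiency(w_hat: np.ndarray) -> np.ndarray:
    """Per-node Ge of the neighborhood subgraph (global weight scale kept)."""
    n = w_hat.shape[0]
    le = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(w_hat[i] > 0)[0]
        if nbrs.size < 2:
            continue
        sub = w_hat[np.ix_(nbrs, nbrs)]
        _, ge_sub, _, _ = _distance_metrics(sub)
        le[i] = ge_sub
    return le


def proportional_threshold(w: np.ndarray, density: float) -> np.ndarray:
    """Binary adjacency keeping the strongest ``density`` fraction of edges.

    Exactly ``round(density * n_pairs)`` upper-triangle edges are kept;
    ties at the cutoff are broken by channel-pair order.
    """
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    w = _validate_weights(w)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    flat = w[iu]
    m = max(1, int(round(density * flat.size)))
    keep = np.argsort(-flat, kind="stable")[:m]
    adj = np.zeros_like(w)
    adj[iu[0][keep], iu[1][keep]] = 1.0
    return adj + adj.T


def compute_metrics(
    matrix: "ConnectivityMatrix | np.ndarray",
    mode: str = "weighted",
    density: "float | None" = None,
) -> GraphMetrics:
    """Small-world properties of one connectivity matrix.

    ``mode='weighted'`` uses the weighted definitions on max-normalized
    weights; ``mode='threshold'`` first applies a proportional threshold at
    ``density`` and uses the binary formulas.  A disconnected network is
    flagged and its CPL averages finite distances only.
    """
    if isinstance(matrix, ConnectivityMatrix):
        w = matrix.values
        channels = list(matrix.channels)
        band, stage, subject_id = matrix.band, matrix.stage, matrix.subject_id
    else:
        w = np.asarray(matrix, dtype=float)
        channels = [f"n{i}" for i in range(w.shape[0])]
        band = stage = subject_id = ""
    w = _validate_weights(w)

    if mode == "threshold":
        if density is None:
            raise ValueError("threshold mode requires a density in (0, 1)")
        w_hat = proportional_threshold(w, density)
    elif mode == "weighted":
        wmax = w.max()
        w_hat = w / wmax if wmax > 0 else w
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cc = _onnela_clustering(w_hat)
    cpl, ge, _, connected = _distance_metrics(w_hat)
    le = _local_efficiency(w_hat)
    nd = w_hat.sum(axis=1)
    return GraphMetrics(
        cc=cc, le=le, nd=nd, cpl=cpl, ge=ge,
        channels=channels, band=band, stage=stage, subject_id=subject_id,
        mode=mode if mode == "weighted" else f"threshold({density})",
        connected=connected,
    )


def region_average_cc(metrics: GraphMetrics, atlas: RegionAtlas) -> pd.Series:
    """Region means of the per-node clustering coefficient."""
    return region_average(metrics.cc, metrics.channels, atlas)
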