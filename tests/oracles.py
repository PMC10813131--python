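"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit loops, Floyd-Warshall,
full enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# graph metrics


def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    d = dist.copy().astype(float)
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_metrics(w: np.ndarray) -> dict:
    """CC/Le/ND/CPL/Ge by explicit triangle and path enumeration.

    Expects a symmetric weight matrix with zero diagonal, already
    normalized the way the implementation normalizes (max off-diagonal
    weight = 1 for weighted graphs, 0/1 entries for binary graphs).
    """
    n = w.shape[0]
    # clustering: Onnela geometric-mean triangles
    cc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        cc[i] = total / (k * (k - 1))

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j]
    d = floyd_warshall(dist)

    finite_offdiag = [
        d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])
    ]
    cpl = float(np.mean(finite_offdiag)) if finite_offdiag else np.inf
    inv = [
        (1.0 / d[i, j]) if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    ge = float(np.mean(inv)) if inv else 0.0

    def subgraph_ge(nodes: list[int]) -> float:
        m = len(nodes)
        if m < 2:
            return 0.0
        sub = np.full((m, m), np.inf)
        np.fill_diagonal(sub, 0.0)
        for a, i in enumerate(nodes):
            for b, j in enumerate(nodes):
                if a != b and w[i, j] > 0:
                    sub[a, b] = 1.0 / w[i, j]
        ds = floyd_warshall(sub)
        vals = [
            (1.0 / ds[a, b]) if np.isfinite(ds[a, b]) and ds[a, b] > 0 else 0.0
            for a in range(m)
            for b in range(m)
            if a != b
        ]
        return float(np.mean(vals))

    le = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) >= 2:
            le[i] = subgraph_ge(nbrs)

    nd = w.sum(axis=1)
    return {"cc": cc, "le": le, "nd": nd, "cpl": cpl, "ge": ge}


# ---------------------------------------------------------------------------
# statistics


def bh_stepup(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration (mid-ranks, doubling rule)."""
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n].sum()
    total = math.comb(n + m, n)
    le = ge = 0
    for combo in itertools.combinations(range(n + m), n):
        w = sum(ranks[k] for k in combo)
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def spearman_via_ranks(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks."""
    from scipy.stats import rankdata

    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


# ---------------------------------------------------------------------------
# signal helpers


def fft_amplitude_at(x: np.ndarray, fs: float, freq: float) -> float:
    """Single-bin amplitude of a sinusoid component via the DFT."""
    n = x.size
    spectrum = np.fft.rfft(x * np.hanning(n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    k = int(np.argmin(np.abs(freqs - freq)))
    # Hann window coherent gain = 0.5
    return 2.0 * np.abs(spectrum[k]) / (n * 0.5)
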