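"""Nonparametric group contrasts, FDR control, and behavioral analysis.

Edgewise and nodewise DE-vs-HC contrasts use the Wilcoxon rank-sum test
with Benjamini-Hochberg FDR control within each band x stage family, and
report a *signed* significance: +1 where the DE median exceeds the HC
median on a surviving test, -1 for the reverse, 0 otherwise.  Behavioral
stage times are compared per stage without multiplicity correction
(flagged as such in the output).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

#: Task stages in chronological order: observation, large-scale movement,
#: fine operation, docking.
STAGE_NAMES = ("O", "LM", "FO", "D")

#: Canonical within-trial event sequence delimiting the four stages.
EVENT_SEQUENCE = ("start", "arm_move", "fine_adjust", "arm_move_again", "dock_complete")


class MalformedLogError(ValueError):
    """An event log is out of order or missing events."""


@dataclass
class BehaviorRecord:
    """Per-subject stage durations (seconds) and their total."""

    subject_id: str
    stage_times: dict[str, float]

    def __post_init__(self) -> None:
        missing = [s for s in STAGE_NAMES if s not in self.stage_times]
        if missing:
            raise ValueError(f"missing stage times: {missing}")
        for stage, t in self.stage_times.items():
            if not t > 0:
                raise ValueError(f"stage {stage} duration must be positive, got {t}")

    @property
    def total(self) -> float:
        return float(sum(self.stage_times[s] for s in STAGE_NAMES))

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update({s: self.stage_times[s] for s in STAGE_NAMES})
        row["total"] = self.total
        return row


@dataclass
class GroupContrast:
    """Result of an edgewise or nodewise DE-vs-HC contrast."""

    statistic: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    signed: np.ndarray  # entries in {+1, -1, 0}
    channels: list[str]
    band: str
    stage: str
    alpha: float
    kind: str  # "edgewise" | "nodewise"
    metadata: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        if self.kind == "edgewise":
            iu = np.triu_indices(len(self.channels), k=1)
            return int(np.count_nonzero(self.signed[iu]))
        return int(np.count_nonzero(self.signed))

    def edge_table(self) -> pd.DataFrame:
        """Long-format upper-triangle edge list (edgewise contrasts only)."""
        if self.kind != "edgewise":
            raise ValueError("edge_table is only defined for edgewise contrasts")
        iu = np.triu_indices(len(self.channels), k=1)
        return pd.DataFrame(
            {
                "ch_i": [self.channels[i] for i in iu[0]],
                "ch_j": [self.channels[j] for j in iu[1]],
                "stat": self.statistic[iu],
                "p": self.pvalues[iu],
                "q": self.qvalues[iu],
                "sign": self.signed[iu].astype(int),
            }
        )


# ---------------------------------------------------------------------------
# primitive tests


def rankdata_midranks(values: np.ndarray) -> np.ndarray:
    return spstats.rankdata(values, method="average")


def ranksum_test(
    x: np.ndarray, y: np.ndarray, mode: str = "normal_approx"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of ``x`` (mid-ranks for
    ties).  ``mode='exact'`` enumerates all C(n+m, n) group assignments of
    the observed ranks; ``mode='normal_approx'`` uses the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    ranks = rankdata_midranks(np.concatenate([x, y]))
    w_obs = float(ranks[:n].sum())
    if mode == "exact":
        if n + m > 25:
            raise ValueError("exact enumeration limited to combined n <= 25")
        total = math.comb(n + m, n)
        le = ge = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n + m), n):
            w = ranks[list(combo)].sum()
            if w <= w_obs + eps:
                le += 1
            if w >= w_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return w_obs, p
    if mode == "normal_approx":
        if np.ptp(np.concatenate([x, y])) == 0:
            return w_obs, 1.0  # all observations tied: no evidence either way
        res = spstats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return w_obs, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(qvals, reject)``; ``reject`` is True where q <= alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    reject, qvals, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return qvals, reject


def _vector_ranksum(
    de: np.ndarray, hc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise rank-sum tests: (W of DE, two-sided p, median difference)."""
    res = spstats.mannwhitneyu(
        de, hc, alternative="two-sided", method="asymptotic",
        use_continuity=True, axis=0,
    )
    n = de.shape[0]
    w = res.statistic + n * (n + 1) / 2.0
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate columns (all values tied) have zero variance: p is undefined
    # under the approximation but carries no evidence
    p = np.where(np.isnan(p), 1.0, p)
    med_diff = np.median(de, axis=0) - np.median(hc, axis=0)
    return np.asarray(w, dtype=float), p, med_diff


def edgewise_contrast(
    de: list[ConnectivityMatrix],
    hc: list[ConnectivityMatrix],
    alpha: float = 0.05,
) -> GroupContrast:
    """Rank-sum + BH-FDR contrast of every unordered channel pair.

    Tests the 1891 upper-triangle pairs of a 62-channel montage (one test
    per pair; the symmetric lower triangle is not double-counted) and
    corrects within this band x stage family.
    """
    if len(de) < 2 or len(hc) < 2:
        raise ValueError("need at least 2 subjects per group")
    ref = de[0]
    for m in itertools.chain(de, hc):
        if m.channels != ref.channels or m.band != ref.band or m.stage != ref.stage:
            raise ValueError("all matrices must share channels, band and stage")
    n_ch = len(ref.channels)
    iu = np.triu_indices(n_ch, k=1)
    de_vals = np.stack([m.values[iu] for m in de])
    hc_vals = np.stack([m.values[iu] for m in hc])
    w, p, med_diff = _vector_ranksum(de_vals, hc_vals)
    q, reject = fdr_bh(p, alpha)
    signed_flat = np.where(reject, np.sign(med_diff), 0.0)

    def to_matrix(flat: np.ndarray) -> np.ndarray:
        mat = np.zeros((n_ch, n_ch))
        mat[iu] = flat
        return mat + mat.T

    return GroupContrast(
        statistic=to_matrix(w),
        pvalues=to_matrix(p),
        qvalues=to_matrix(q),
        signed=to_matrix(signed_flat),
        channels=list(ref.channels),
        band=ref.band,
        stage=ref.stage,
        alpha=alpha,
        kind="edgewise",
        metadata={"n_tests": len(p), "n_de": len(de), "n_hc": len(hc)},
    )


def nodewise_contrast(
    de_values: np.ndarray,
    hc_values: np.ndarray,
    channels: list[str],
    band: str,
    stage: str,
    alpha: float = 0.05,
) -> GroupContrast:
    """Rank-sum + BH-FDR contrast of a per-node metric (e.g. clustering).

    ``de_values`` and ``hc_values`` are subjects x nodes arrays; FDR is
    applied across the nodes of one band x stage family.
    """
    de_values = np.atleast_2d(np.asarray(de_values, dtype=float))
    hc_values = np.atleast_2d(np.asarray(hc_values, dtype=float))
    if de_values.shape[1] != len(channels) or hc_values.shape[1] != len(channels):
        raise ValueError("values must be subjects x channels")
    if de_values.shape[0] < 2 or hc_values.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    w, p, med_diff = _vector_ranksum(de_values, hc_values)
    q, reject = fdr_bh(p, alpha)
    signed = np.where(reject, np.sign(med_diff), 0.0)
    return GroupContrast(
        statistic=w,
        pvalues=p,
        qvalues=q,
        signed=signed,
        channels=list(channels),
        band=band,
        stage=stage,
        alpha=alpha,
        kind="nodewise",
        metadata={"n_tests": len(p), "n_de": de_values.shape[0], "n_hc": hc_values.shape[0]},
    )


def spearman_region_cesd(
    region_cc: np.ndarray, cesd: np.ndarray, region_names: "list[str] | None" = None
) -> pd.DataFrame:
    """Spearman correlation of region-averaged clustering with CES-D scores.

    ``region_cc`` is subjects x regions; correlations use mid-ranks for
    ties and pool both groups (the symptom-severity gradient spans the
    whole cohort).
    """
    region_cc = np.asarray(region_cc, dtype=float)
    cesd = np.asarray(cesd, dtype=float)
    if region_cc.ndim != 2:
        raise ValueError("region_cc must be subjects x regions")
    if region_cc.shape[0] != cesd.shape[0]:
        raise ValueError("cesd must align with region_cc rows")
    if region_cc.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    names = region_names or [f"R{i}" for i in range(region_cc.shape[1])]
    rows = []
    for k, name in enumerate(names):
        rho, p = spstats.spearmanr(region_cc[:, k], cesd)
        rows.append({"region": name, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioral stage analysis


def stage_durations(trial_events: pd.DataFrame) -> dict[str, float]:
    """Stage durations of one trial from its five-event log.

    Expects exactly the canonical event sequence with strictly increasing
    timestamps; returns ``{"O": .., "LM": .., "FO": .., "D": ..}``.
    """
    df = trial_events
    trial = df["trial"].iloc[0] if "trial" in df.columns and len(df) else "?"
    events = df["event"].tolist()
    if events != list(EVENT_SEQUENCE):
        raise MalformedLogError(
            f"trial {trial}: expected events {EVENT_SEQUENCE}, got {events}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise MalformedLogError(f"trial {trial}: timestamps must strictly increase")
    return {stage: float(t[k + 1] - t[k]) for k, stage in enumerate(STAGE_NAMES)}


def behavior_from_events(events: pd.DataFrame) -> list[BehaviorRecord]:
    """Per-subject stage times: mean over each subject's trials."""
    records = []
    for subject_id, sub in events.groupby("subject_id", sort=False):
        per_trial = [
            stage_durations(trial_df.sort_values("time_s"))
            for _, trial_df in sub.groupby("trial", sort=True)
        ]
        if not per_trial:
            raise MalformedLogError(f"subject {subject_id}: no trials in log")
        means = {
            s: float(np.mean([d[s] for d in per_trial])) for s in STAGE_NAMES
        }
        records.append(BehaviorRecord(subject_id=str(subject_id), stage_times=means))
    return records


def behavior_table(records: list[BehaviorRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def group_stage_means(records: list[BehaviorRecord]) -> dict[str, float]:
    """Group-level stage means (mean over subjects), plus the total."""
    df = behavior_table(records)
    out = {s: float(df[s].mean()) for s in STAGE_NAMES}
    out["total"] = float(df["total"].mean())
    return out


def behavior_contrast(
    de: list[BehaviorRecord],
    hc: list[BehaviorRecord],
    alpha: float = 0.05,
    mode: str = "normal_approx",
) -> pd.DataFrame:
    """Rank-sum tests on the four stage times and the total.

    Reported per stage without multiplicity correction, mirroring the
    per-stage behavioral reporting convention; the ``corrected`` column
    makes this explicit.
    """
    if len(de) < 2 or len(hc) < 2:
        raise ValueError("need at least 2 subjects per group")
    de_df, hc_df = behavior_table(de), behavior_table(hc)
    rows = []
    for col in list(STAGE_NAMES) + ["total"]:
        w, p = ranksum_test(de_df[col].to_numpy(), hc_df[col].to_numpy(), mode=mode)
        rows.append(
            {
                "measure": col,
                "mean_DE": float(de_df[col].mean()),
                "sd_DE": float(de_df[col].std(ddof=1)),
                "mean_HC": float(hc_df[col].mean()),
                "sd_HC": float(hc_df[col].std(ddof=1)),
                "stat": w,
                "p": p,
                "significant": p < alpha,
                "corrected": False,
            }
        )
    return pd.DataFrame(rows)
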