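"""Config-driven orchestration of the full analysis.

A :class:`PipelineConfig` (usually read from YAML) describes the cohort,
preprocessing, connectivity and statistics settings.  :func:`run_pipeline`
executes simulate/ingest -> preprocess -> connectivity -> graph -> stats
and writes tabular outputs plus a provenance record (config hash, seed,
package version) into a run directory.  Re-running with the same config
reproduces all numeric outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import REGION_ORDER, RegionAtlas, default_atlas, load_atlas
from .bands import CANONICAL_BANDS, BandSpec, get_band
from .connectivity import ConnectivityMatrix, build_matrix
from .graph import GraphMetrics, compute_metrics, region_average
from .montage import Montage, default_montage, load_montage
from .preprocess import preprocess_stage
from .recording import Recording, read_raw
from .stats import (
    BehaviorRecord,
    behavior_contrast,
    behavior_from_events,
    behavior_table,
    edgewise_contrast,
    group_stage_means,
    nodewise_contrast,
    spearman_region_cesd,
)
from .synth import (
    COUPLING_BASELINE,
    COUPLING_STRONG,
    COUPLING_WEAK,
    SubjectSpec,
    default_coupling_plans,
    make_cohort,
    simulate_recording,
    simulate_trial_events,
    subject_plans,
)

NETWORK_STAGES_DEFAULT = ("RS", "LM", "FO")


@dataclass
class PipelineConfig:
    """Everything a run needs; validated before any computation."""

    seed: int = 0
    n_per_group: int = 15
    fs: float = 600.0
    epoch_s: float = 2.0
    durations: dict = field(
        default_factory=lambda: {"RS": 120.0, "LM": 120.0, "FO": 120.0}
    )
    bands: list = field(default_factory=lambda: [b.name for b in CANONICAL_BANDS])
    stages: list = field(default_factory=lambda: list(NETWORK_STAGES_DEFAULT))
    alpha: float = 0.05
    metric_mode: str = "weighted"        # "weighted" | "threshold"
    density: "float | None" = None       # for threshold mode
    ica: bool = False
    ica_kurtosis_z: float = 5.0
    exact_tests: bool = False
    noise_sigma: float = 2.0
    coupling_strong: "float | dict" = field(
        default_factory=lambda: dict(COUPLING_STRONG)
    )
    coupling_weak: "float | dict" = COUPLING_WEAK
    coupling_baseline: float = COUPLING_BASELINE
    coupling_jitter_sd: float = 0.05
    n_trials: int = 16
    montage_path: "str | None" = None
    atlas_path: "str | None" = None
    input_dir: "str | None" = None       # if set, ingest instead of simulate
    save_matrices: bool = False

    def band_specs(self) -> tuple[BandSpec, ...]:
        return tuple(
            get_band(b) if isinstance(b, str)
            else BandSpec(b["name"], float(b["low_hz"]), float(b["high_hz"]))
            for b in self.bands
        )

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fs <= 0 or self.epoch_s <= 0:
            raise ValueError("fs and epoch_s must be positive")
        for band in self.band_specs():
            if band.high_hz >= self.fs / 2:
                raise ValueError(
                    f"band {band.name} upper edge {band.high_hz} Hz at or above "
                    f"Nyquist {self.fs / 2} Hz"
                )
        if self.metric_mode == "threshold" and not (
            self.density and 0 < self.density < 1
        ):
            raise ValueError("threshold mode requires density in (0, 1)")
        if self.metric_mode not in {"weighted", "threshold"}:
            raise ValueError(f"unknown metric_mode {self.metric_mode!r}")
        for path in (self.montage_path, self.atlas_path, self.input_dir):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        unknown = set(self.stages) - set(self.durations)
        if self.input_dir is None and unknown:
            raise ValueError(f"stages without simulated durations: {sorted(unknown)}")

    def montage(self) -> Montage:
        return load_montage(self.montage_path) if self.montage_path else default_montage()

    def atlas(self, montage: Montage) -> RegionAtlas:
        atlas = load_atlas(self.atlas_path) if self.atlas_path else default_atlas(montage)
        atlas.validate_against(montage.names)
        return atlas

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: "str | Path") -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# helpers


def _provenance_line(cfg: PipelineConfig) -> str:
    return (
        f"# plvnet v{__version__} config={cfg.config_hash()} seed={cfg.seed}"
    )


def write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, sep: str = ",") -> None:
    """Write a CSV/TSV with a leading provenance comment line."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write(_provenance_line(cfg) + "\n")
        df.to_csv(f, sep=sep, index=False)


def read_table(path: "str | Path", sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def subject_recording(
    subject: SubjectSpec, cfg: PipelineConfig, montage: Montage
) -> Recording:
    """Simulate (or load, when ingesting) one subject's recording."""
    if cfg.input_dir is not None:
        return read_raw(Path(cfg.input_dir) / "recordings" / subject.subject_id)
    plans = subject_plans(
        subject,
        default_coupling_plans(
            subject.group,
            montage,
            c_strong=cfg.coupling_strong,
            c_weak=cfg.coupling_weak,
            baseline_c=cfg.coupling_baseline,
        ),
        coupling_jitter_sd=cfg.coupling_jitter_sd,
    )
    durations = {s: float(cfg.durations[s]) for s in cfg.stages}
    return simulate_recording(
        subject,
        plans,
        montage,
        fs=cfg.fs,
        durations=durations,
        noise_sigma=cfg.noise_sigma,
        bands=cfg.band_specs(),
    )


def subject_networks(
    rec: Recording, cfg: PipelineConfig
) -> dict[tuple[str, str], tuple[ConnectivityMatrix, GraphMetrics]]:
    """(stage, band) -> (PLV matrix, graph metrics) for one recording."""
    out = {}
    for stage in cfg.stages:
        per_band = preprocess_stage(
            rec, stage, cfg.band_specs(), epoch_s=cfg.epoch_s,
            ica=cfg.ica, ica_kurtosis_z=cfg.ica_kurtosis_z,
        )
        for band_name, epochs in per_band.items():
            matrix = build_matrix(epochs)
            metrics = compute_metrics(
                matrix, mode=cfg.metric_mode, density=cfg.density
            )
            out[(stage, band_name)] = (matrix, metrics)
    return out


def load_cohort(cfg: PipelineConfig) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Subject specs plus the event log, simulated or ingested."""
    if cfg.input_dir is not None:
        base = Path(cfg.input_dir)
        subjects_df = read_table(base / "subjects.csv")
        events = read_table(base / "events.csv")
        subjects = [
            SubjectSpec(
                subject_id=str(r.subject_id), group=str(r.group),
                cesd=int(r.cesd), bdi=int(r.bdi),
                seed=int(getattr(r, "seed", 0)),
            )
            for r in subjects_df.itertuples()
        ]
        return subjects, events
    subjects = make_cohort(cfg.n_per_group, seed=cfg.seed)
    all_events = []
    for sub in subjects:
        _, ev = simulate_trial_events(sub, n_trials=cfg.n_trials)
        all_events.extend(ev)
    return subjects, pd.DataFrame(all_events)


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(cfg: PipelineConfig, out_dir: "str | Path") -> Path:
    """Execute the whole analysis and write its outputs.

    Returns the run directory, which contains the subject table, event
    logs, per-band/stage signed difference networks and edge lists, the
    nodewise clustering contrast, behavioral summaries and tests, the
    10-region CES-D correlation table, per-subject graph metrics, and a
    provenance record.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = cfg.montage()
    atlas = cfg.atlas(montage)
    subjects, events = load_cohort(cfg)

    subjects_df = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "group": s.group, "cesd": s.cesd,
             "bdi": s.bdi, "seed": s.seed}
            for s in subjects
        ]
    )
    write_table(subjects_df, out / "subjects.csv", cfg)
    write_table(events, out / "events.csv", cfg)

    # --- EEG route: connectivity and graph metrics, one subject at a time
    matrices: dict[tuple[str, str], dict[str, ConnectivityMatrix]] = {}
    metrics: dict[tuple[str, str], dict[str, GraphMetrics]] = {}
    for sub in subjects:
        rec = subject_recording(sub, cfg, montage)
        nets = subject_networks(rec, cfg)
        for key, (mat, met) in nets.items():
            matrices.setdefault(key, {})[sub.subject_id] = mat
            metrics.setdefault(key, {})[sub.subject_id] = met
        del rec, nets

    if cfg.save_matrices:
        mat_dir = out / "connectivity"
        mat_dir.mkdir(exist_ok=True)
        for (stage, band), by_sub in matrices.items():
            for sid, mat in by_sub.items():
                mat.to_tsv(mat_dir / f"{sid}_{stage}_{band}.tsv")

    metrics_frames = [
        met.to_frame()
        for by_sub in metrics.values()
        for met in by_sub.values()
    ]
    write_table(pd.concat(metrics_frames, ignore_index=True), out / "metrics.csv", cfg)

    # --- group contrasts per band x stage
    de_ids = [s.subject_id for s in subjects if s.group == "DE"]
    hc_ids = [s.subject_id for s in subjects if s.group == "HC"]
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    corr_rows = []
    for (stage, band), by_sub in sorted(matrices.items()):
        de_mats = [by_sub[i] for i in de_ids]
        hc_mats = [by_sub[i] for i in hc_ids]
        contrast = edgewise_contrast(de_mats, hc_mats, alpha=cfg.alpha)
        signed_df = pd.DataFrame(
            contrast.signed.astype(int), index=contrast.channels,
            columns=contrast.channels,
        )
        path = stats_dir / f"edgewise_{stage}_{band}_signed.tsv"
        with open(path, "w") as f:
            f.write(_provenance_line(cfg) + "\n")
            signed_df.to_csv(f, sep="\t", index_label="channel")
        write_table(
            contrast.edge_table(), stats_dir / f"edgewise_{stage}_{band}_edges.csv", cfg
        )

        by_met = metrics[(stage, band)]
        de_cc = np.stack([by_met[i].cc for i in de_ids])
        hc_cc = np.stack([by_met[i].cc for i in hc_ids])
        node_contrast = nodewise_contrast(
            de_cc, hc_cc, contrast.channels, band, stage, alpha=cfg.alpha
        )
        write_table(
            pd.DataFrame(
                {
                    "node": node_contrast.channels,
                    "stat": node_contrast.statistic,
                    "p": node_contrast.pvalues,
                    "q": node_contrast.qvalues,
                    "sign": node_contrast.signed.astype(int),
                }
            ),
            stats_dir / f"nodewise_cc_{stage}_{band}.csv",
            cfg,
        )

        # region-averaged CC against CES-D, pooled over both groups
        all_ids = de_ids + hc_ids
        region_cc = np.stack(
            [
                region_average(by_met[i].cc, by_met[i].channels, atlas).to_numpy()
                for i in all_ids
            ]
        )
        cesd = np.array(
            [next(s.cesd for s in subjects if s.subject_id == i) for i in all_ids],
            dtype=float,
        )
        corr = spearman_region_cesd(region_cc, cesd, list(REGION_ORDER))
        for _, r in corr.iterrows():
            corr_rows.append(
                {
                    "stage": stage, "band": band, "region": r.region,
                    "rho": r.rho, "p": r.p, "significant": r.p < cfg.alpha,
                }
            )
    write_table(pd.DataFrame(corr_rows), out / "region_cesd_correlations.csv", cfg)

    # --- behavioral route
    records = behavior_from_events(events)
    by_id: dict[str, BehaviorRecord] = {r.subject_id: r for r in records}
    de_rec = [by_id[i] for i in de_ids if i in by_id]
    hc_rec = [by_id[i] for i in hc_ids if i in by_id]
    write_table(behavior_table(records), out / "behavior_subjects.csv", cfg)
    summary = pd.DataFrame(
        [
            {"group": "DE", **group_stage_means(de_rec)},
            {"group": "HC", **group_stage_means(hc_rec)},
        ]
    )
    write_table(summary, out / "behavior_summary.csv", cfg)
    mode = "exact" if cfg.exact_tests else "normal_approx"
    write_table(
        behavior_contrast(de_rec, hc_rec, alpha=cfg.alpha, mode=mode),
        out / "behavior_tests.csv",
        cfg,
    )

    provenance = {
        "package": "plvnet",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_subjects": len(subjects),
        "stages": list(cfg.stages),
        "bands": [b.name for b in cfg.band_specs()],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return out
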