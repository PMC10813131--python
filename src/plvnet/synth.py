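"""Synthetic cohort generator: EEG with planted phase coupling, behavior, scores.

The generator emulates the study conditions the analysis pipeline assumes:
62-channel recordings sampled at 600 Hz, a 2-minute eyes-closed resting
stage, a staged docking task, and two 15-subject groups — a depressive-
emotion (DE) group screened by CES-D > 16 with BDI-II <= 13, and healthy
controls (HC, CES-D < 16).

Each channel's narrowband component in a given band and stage is a cosine
of a mixed instantaneous phase

    phi_ch(t) = c * phi_driver(t) + (1 - c) * psi_ch(t)

where ``phi_driver`` is shared by coupled channels, ``psi_ch`` is an
independent band-limited random phase, and ``c`` in [0, 1] is the coupling
strength.  At c = 1 two coupled channels are identical (PLV = 1); at c = 0
they are independent; expected PLV increases monotonically with c (see
:func:`calibrate_coupling`).  Channel signals are sums of the five band
components plus white broadband noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft
from scipy import stats as spstats

from .bands import ALPHA, CANONICAL_BANDS, BandSpec, get_band
from .montage import Montage, default_montage
from .recording import Annotation, Recording
from .stats import STAGE_NAMES, BehaviorRecord

GROUPS = ("DE", "HC")

#: Group-level scale-score parameters: (cesd_mean, cesd_sd, bdi_mean, bdi_sd).
SCORE_PARAMS = {
    "DE": (24.8, 4.2, 10.9, 2.6),
    "HC": (14.6, 3.4, 8.2, 2.1),
}

#: Group-level stage-time parameters in seconds: stage -> (mean, sd),
#: for the observation (O), large-scale movement (LM), fine operation (FO)
#: and docking (D) stages.
BEHAVIOR_PARAMS = {
    "HC": {"O": (10.91, 2.6), "LM": (20.52, 3.2), "FO": (19.31, 1.9), "D": (24.22, 3.8)},
    "DE": {"O": (11.53, 3.0), "LM": (25.68, 2.9), "FO": (26.47, 2.2), "D": (25.75, 4.3)},
}

#: Default per-band oscillation amplitudes (microvolts), alpha-dominant as in
#: eyes-closed scalp EEG, with a roughly 1/f roll-off toward gamma.
DEFAULT_BAND_AMPLITUDES = {
    "delta": 6.0, "theta": 5.0, "alpha": 8.0, "beta": 3.0, "gamma": 2.0,
}

#: Coupling strengths used for planted group differences, chosen via
#: :func:`calibrate_coupling` so that the expected PLV gap between the
#: strong and weak settings is at least ~0.3 at 2-s epochs.  Wider bands
#: decorrelate faster, so beta/gamma need stronger coupling for the same
#: gap.
COUPLING_STRONG: dict[str, float] = {
    "delta": 0.95, "theta": 0.90, "alpha": 0.90, "beta": 0.90, "gamma": 0.90,
}
COUPLING_WEAK = 0.30
COUPLING_BASELINE = 0.10

#: Frontoparietal edge sets carrying the planted group differences.
RS_FRONTOPARIETAL_EDGES = [
    ("F3", "P3"), ("F4", "P4"), ("F5", "P5"), ("F6", "P6"), ("F1", "P1"),
    ("F2", "P2"), ("FC3", "CP3"), ("FC4", "CP4"), ("F3", "P4"), ("F4", "P3"),
]
LEFT_FRONTOPARIETAL_EDGES = [
    ("F3", "P3"), ("F5", "P5"), ("F7", "P7"), ("F1", "P1"), ("FC3", "CP3"),
    ("FC5", "CP5"), ("F3", "P5"), ("F5", "P3"), ("F3", "P1"), ("F1", "P3"),
]

#: Stages whose EEG is simulated and analysed for networks.
NETWORK_STAGES = ("RS", "LM", "FO")
DEFAULT_DURATIONS = {"RS": 120.0, "LM": 120.0, "FO": 120.0}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic subject: identity, group, scale scores, RNG seed."""

    subject_id: str
    group: str
    cesd: int
    bdi: int
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 0 <= self.cesd <= 60:
            raise ValueError(f"CES-D score out of range [0, 60]: {self.cesd}")
        if not 0 <= self.bdi <= 63:
            raise ValueError(f"BDI-II score out of range [0, 63]: {self.bdi}")
        if self.bdi > 13:
            raise ValueError("inclusion criteria require BDI-II <= 13 in both groups")
        if self.group == "DE" and not self.cesd > 16:
            raise ValueError("DE group requires CES-D > 16")
        if self.group == "HC" and not self.cesd < 16:
            raise ValueError("HC group requires CES-D < 16")


@dataclass(frozen=True)
class TrialSpec:
    """One docking trial: obstacle type and initial perspective angle."""

    trial: int
    obstacle: str
    perspective_deg: float


@dataclass
class CouplingPlan:
    """Planted pairwise coupling for one (band, stage) combination.

    ``edges`` lists (channel_i, channel_j, c) triples; all unlisted channels
    couple at ``baseline_c`` to a common background driver.
    """

    band: BandSpec
    stage: str
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_c: float = COUPLING_BASELINE

    def __post_init__(self) -> None:
        self.band = get_band(self.band)
        if not 0.0 <= self.baseline_c <= 1.0:
            raise ValueError("baseline_c must lie in [0, 1]")
        seen: set[frozenset[str]] = set()
        for i, j, c in self.edges:
            if i == j:
                raise ValueError(f"self-coupling edge {i!r}-{j!r} not allowed")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {i!r}-{j!r}")
            seen.add(key)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling strength {c} outside [0, 1] on {i}-{j}")

    def validate_against(self, montage: Montage) -> None:
        for i, j, _ in self.edges:
            for ch in (i, j):
                if ch not in montage.names:
                    raise ValueError(f"plan references channel {ch!r} not in montage")

    def with_jitter(self, rng: np.random.Generator, sd: float) -> "CouplingPlan":
        """Per-subject copy with coupling strengths jittered by N(0, sd)."""
        if sd == 0:
            return self
        edges = [
            (i, j, float(np.clip(c + rng.normal(0.0, sd), 0.0, 1.0)))
            for i, j, c in self.edges
        ]
        return replace(self, edges=edges)


# ---------------------------------------------------------------------------
# trial schedule


def make_trial_schedule(
    n_obstacle_types: int, n_perspectives: int, seed: int
) -> list[TrialSpec]:
    """Randomised full crossing of obstacle types and starting perspectives.

    The canonical design is 2 obstacle types (vertical bar, circular frame)
    x 8 perspectives at 30 degree steps from 30 to 240, i.e. 16 trials in
    random order.
    """
    if n_obstacle_types < 1 or n_perspectives < 1:
        raise ValueError("n_obstacle_types and n_perspectives must be >= 1")
    obstacle_names = ["vertical_bar", "circular_frame"] + [
        f"obstacle_{k}" for k in range(3, n_obstacle_types + 1)
    ]
    obstacles = obstacle_names[:n_obstacle_types]
    angles = [30.0 * (k + 1) for k in range(n_perspectives)]
    pairs = list(itertools.product(obstacles, angles))
    rng = np.random.default_rng(seed)
    rng.shuffle(pairs)
    return [
        TrialSpec(trial=t + 1, obstacle=ob, perspective_deg=ang)
        for t, (ob, ang) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# phase-mixing EEG model


def _deviation_phases(
    rng: np.random.Generator, n_series: int, n_samples: int, fs: float, band: BandSpec
) -> np.ndarray:
    """Integrated band-limited random frequency deviations (no carrier).

    Frequency-modulation synthesis: each row is the integral of a smooth
    zero-mean Gaussian frequency deviation (sd = bandwidth/6, modulation
    band-limited to bandwidth/3), so by Carson's rule an oscillation
    ``cos(carrier + deviation_phase)`` stays essentially within the band
    edges.  The carrier ramp and phase offsets are added by the caller.
    """
    bw = band.high_hz - band.low_hz
    f_mod = bw / 3.0
    sigma_f = bw / 6.0
    m = sfft.next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    in_band = (freqs > 0) & (freqs <= f_mod)
    n_bins = int(np.count_nonzero(in_band))
    spec = np.zeros((n_series, freqs.size), dtype=np.complex64)
    noise = rng.standard_normal((n_series, n_bins, 2), dtype=np.float32)
    spec[:, 1 : 1 + n_bins] = noise[..., 0] + 1j * noise[..., 1]
    dev = sfft.irfft(spec, n=m, axis=-1)[:, :n_samples]
    sd = dev.std(axis=-1, keepdims=True)
    dev *= np.where(sd > 0, sigma_f / sd, 0.0)
    phase = np.cumsum(dev.astype(np.float64), axis=-1)
    phase *= 2.0 * np.pi / fs
    return phase


def _carrier_ramp(n_samples: int, fs: float, band: BandSpec) -> np.ndarray:
    """Linear phase ramp of the band-centre carrier."""
    return 2.0 * np.pi * band.center_hz * (np.arange(n_samples) / fs)


def _band_limited_phases(
    rng: np.random.Generator, n_series: int, n_samples: int, fs: float, band: BandSpec
) -> np.ndarray:
    """Independent unwrapped random phases confined to a frequency band."""
    phase = _deviation_phases(rng, n_series, n_samples, fs, band)
    phase += _carrier_ramp(n_samples, fs, band)[None, :]
    phase += rng.uniform(0.0, 2.0 * np.pi, size=(n_series, 1))
    return phase


def _mix_deviations(
    c: np.ndarray, driver_dev: np.ndarray, private_dev: np.ndarray
) -> np.ndarray:
    """Couple private deviation phases to driver deviations, variance-preserving.

    A naive mixture ``c*driver + (1-c)*private`` shrinks the frequency-
    deviation variance by ``c**2 + (1-c)**2``, which narrows the effective
    bandwidth at intermediate ``c`` and inflates the chance-level PLV of a
    partially-coupled channel against *everything*.  Dividing by
    ``sqrt(c**2 + (1-c)**2)`` keeps the phase-diffusion rate identical for
    every channel, so coupling changes only phase alignment, not bandwidth.
    """
    norm = np.sqrt(c**2 + (1.0 - c) ** 2)
    return (c * driver_dev + (1.0 - c) * private_dev) / norm


def _connected_components(edges: list[tuple[str, str, float]]) -> list[set[str]]:
    adj: dict[str, set[str]] = {}
    for i, j, _ in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    components, seen = [], set()
    for start in adj:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        components.append(comp)
    return components


def _stage_band_signal(
    rng: np.random.Generator,
    plan: "CouplingPlan | None",
    band: BandSpec,
    channels: list[str],
    n_samples: int,
    fs: float,
) -> np.ndarray:
    """Unit-amplitude band component for all channels of one stage."""
    n_ch = len(channels)
    idx = {c: k for k, c in enumerate(channels)}
    # coupling strength and driver assignment per channel
    coupling = np.full(n_ch, plan.baseline_c if plan else 0.0)
    driver_of = np.zeros(n_ch, dtype=int)  # 0 = background driver
    n_drivers = 1
    if plan is not None and plan.edges:
        for comp in _connected_components(plan.edges):
            comp_id = n_drivers
            n_drivers += 1
            for ch in comp:
                driver_of[idx[ch]] = comp_id
        for i, j, c in plan.edges:
            # a channel on several edges follows its strongest coupling
            coupling[idx[i]] = max(coupling[idx[i]], c)
            coupling[idx[j]] = max(coupling[idx[j]], c)
    driver_dev = _deviation_phases(rng, n_drivers, n_samples, fs, band)
    private_dev = _deviation_phases(rng, n_ch, n_samples, fs, band)
    c = coupling[:, None]
    mixed = _mix_deviations(c, driver_dev[driver_of], private_dev)
    mixed += _carrier_ramp(n_samples, fs, band)[None, :]
    mixed += rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, 1))
    return np.cos(mixed).astype(np.float32)


def simulate_recording(
    subject: SubjectSpec,
    plans: list[CouplingPlan],
    montage: "Montage | None" = None,
    fs: float = 600.0,
    durations: "dict[str, float] | None" = None,
    band_amplitudes: "dict[str, float] | None" = None,
    noise_sigma: float = 2.0,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
) -> Recording:
    """Simulate one subject's continuous multichannel recording.

    Stages are laid out back to back in the order of ``durations`` and
    annotated accordingly.  Signals are reproducible from ``subject.seed``.
    """
    montage = montage if montage is not None else default_montage()
    durations = dict(durations) if durations else dict(DEFAULT_DURATIONS)
    amplitudes = dict(DEFAULT_BAND_AMPLITUDES)
    if band_amplitudes:
        amplitudes.update(band_amplitudes)
    if montage.n_channels < 2:
        raise ValueError("montage must have at least 2 channels")
    for band in bands:
        if fs < 2.0 * band.high_hz:
            raise ValueError(
                f"fs={fs} below Nyquist for band {band.name} (high edge {band.high_hz} Hz)"
            )
    plan_by_key: dict[tuple[str, str], CouplingPlan] = {}
    for plan in plans:
        plan.validate_against(montage)
        key = (plan.band.name, plan.stage)
        if key in plan_by_key:
            raise ValueError(f"multiple plans for band/stage {key}")
        plan_by_key[key] = plan

    rng = np.random.default_rng([int(subject.seed), 0])
    channels = list(montage.names)
    chunks, annotations, t0 = [], [], 0.0
    for stage, dur_s in durations.items():
        if dur_s <= 0:
            raise ValueError(f"stage {stage!r} duration must be positive")
        n_samples = int(round(dur_s * fs))
        x = np.zeros((montage.n_channels, n_samples), dtype=np.float32)
        for band in bands:
            plan = plan_by_key.get((band.name, stage))
            x += amplitudes.get(band.name, 1.0) * _stage_band_signal(
                rng, plan, band, channels, n_samples, fs
            )
        if noise_sigma > 0:
            x += noise_sigma * rng.standard_normal(x.shape, dtype=np.float32)
        chunks.append(x)
        annotations.append(Annotation(stage, t0, t0 + n_samples / fs))
        t0 += n_samples / fs
    return Recording(
        data=np.concatenate(chunks, axis=1),
        fs=fs,
        channels=channels,
        annotations=annotations,
        subject_id=subject.subject_id,
    )


def calibrate_coupling(
    c_grid: list[float],
    fs: float = 600.0,
    duration: float = 20.0,
    n_rep: int = 20,
    seed: int = 0,
    band: BandSpec = ALPHA,
    epoch_s: float = 2.0,
) -> dict[float, tuple[float, float]]:
    """Empirical PLV response curve of the phase-mixing model.

    For each coupling strength ``c`` the expected epoch-averaged PLV of a
    noiseless coupled pair is estimated over ``n_rep`` independent
    replicates.  Returns ``{c: (mean PLV, sd across replicates)}``; the mean
    is non-decreasing in ``c`` up to Monte-Carlo error.
    """
    if n_rep < 10:
        raise ValueError("n_rep must be >= 10 for a usable sd estimate")
    if not all(0.0 <= c <= 1.0 for c in c_grid):
        raise ValueError("coupling strengths must lie in [0, 1]")
    n_samples = int(round(duration * fs))
    n_per_epoch = int(round(epoch_s * fs))
    n_epochs = n_samples // n_per_epoch
    if n_epochs < 1:
        raise ValueError("duration shorter than one epoch")
    rng = np.random.default_rng(seed)
    out: dict[float, tuple[float, float]] = {}
    for c in c_grid:
        plvs = np.empty(n_rep)
        for r in range(n_rep):
            driver_dev = _deviation_phases(rng, 1, n_samples, fs, band)[0]
            psi_dev = _deviation_phases(rng, 2, n_samples, fs, band)
            phases = _mix_deviations(np.float64(c), driver_dev, psi_dev)
            dphi = (phases[0] - phases[1])[: n_epochs * n_per_epoch]
            dphi = dphi.reshape(n_epochs, n_per_epoch)
            plvs[r] = np.abs(np.exp(1j * dphi).mean(axis=1)).mean()
        out[float(c)] = (float(plvs.mean()), float(plvs.std(ddof=1)))
    return out


# ---------------------------------------------------------------------------
# behavior, scores, cohorts


def simulate_behavior(
    subject: SubjectSpec,
    group_params: "dict[str, dict[str, tuple[float, float]]] | None" = None,
) -> BehaviorRecord:
    """Draw one subject's four stage times from truncated-at-zero normals.

    With sd = 0 a stage time equals its mean exactly.  Reproducible from
    ``subject.seed``.
    """
    params = group_params if group_params is not None else BEHAVIOR_PARAMS
    stage_params = params[subject.group]
    rng = np.random.default_rng([int(subject.seed), 1])
    times: dict[str, float] = {}
    for stage in STAGE_NAMES:
        mean, sd = stage_params[stage]
        if mean <= 0:
            raise ValueError(f"stage {stage} mean must be positive")
        if sd < 0:
            raise ValueError(f"stage {stage} sd must be non-negative")
        if sd == 0:
            times[stage] = float(mean)
        else:
            a = (0.0 - mean) / sd  # truncate at zero
            times[stage] = float(
                spstats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)
            )
    return BehaviorRecord(subject_id=subject.subject_id, stage_times=times)


def simulate_scores(group: str, rng: np.random.Generator) -> tuple[int, int]:
    """Rounded truncated-normal CES-D/BDI-II scores satisfying group criteria."""
    cesd_mean, cesd_sd, bdi_mean, bdi_sd = SCORE_PARAMS[group]
    for _ in range(10_000):
        cesd = int(np.clip(round(rng.normal(cesd_mean, cesd_sd)), 0, 60))
        bdi = int(np.clip(round(rng.normal(bdi_mean, bdi_sd)), 0, 63))
        if bdi > 13:
            continue
        if group == "DE" and cesd > 16:
            return cesd, bdi
        if group == "HC" and cesd < 16:
            return cesd, bdi
    raise RuntimeError("score rejection sampling failed to converge")


def make_cohort(n_per_group: int = 15, seed: int = 0) -> list[SubjectSpec]:
    """Build DE and HC subject specs with scores and independent sub-seeds."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    score_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = []
    k = 0
    for group in ("DE", "HC"):
        for i in range(n_per_group):
            cesd, bdi = simulate_scores(group, score_rng)
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            subjects.append(
                SubjectSpec(
                    subject_id=f"{group}{i + 1:02d}",
                    group=group,
                    cesd=cesd,
                    bdi=bdi,
                    seed=sub_seed,
                )
            )
            k += 1
    return subjects


def _resolve_c(value: "float | dict[str, float]", band_name: str) -> float:
    if isinstance(value, dict):
        return float(value[band_name])
    return float(value)


def default_coupling_plans(
    group: str,
    montage: "Montage | None" = None,
    c_strong: "float | dict[str, float] | None" = None,
    c_weak: "float | dict[str, float]" = COUPLING_WEAK,
    baseline_c: float = COUPLING_BASELINE,
) -> list[CouplingPlan]:
    """Planted group-difference structure for a DE-vs-HC cohort.

    At rest (RS), frontoparietal theta/alpha coupling is strong in HC and
    weak in DE; during the movement stages (LM, FO), left-frontoparietal
    delta/beta/gamma coupling is strong in DE and weak in HC.  All other
    band/stage combinations carry only baseline coupling, identical across
    groups.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if c_strong is None:
        c_strong = COUPLING_STRONG
    plans = []
    for band_name in ("theta", "alpha"):
        c = _resolve_c(c_weak if group == "DE" else c_strong, band_name)
        plans.append(
            CouplingPlan(
                band=get_band(band_name),
                stage="RS",
                edges=[(i, j, c) for i, j in RS_FRONTOPARIETAL_EDGES],
                baseline_c=baseline_c,
            )
        )
    for stage in ("LM", "FO"):
        for band_name in ("delta", "beta", "gamma"):
            c = _resolve_c(c_strong if group == "DE" else c_weak, band_name)
            plans.append(
                CouplingPlan(
                    band=get_band(band_name),
                    stage=stage,
                    edges=[(i, j, c) for i, j in LEFT_FRONTOPARIETAL_EDGES],
                    baseline_c=baseline_c,
                )
            )
    if montage is not None:
        for plan in plans:
            plan.validate_against(montage)
    return plans


def subject_plans(
    subject: SubjectSpec,
    base_plans: list[CouplingPlan],
    coupling_jitter_sd: float = 0.05,
) -> list[CouplingPlan]:
    """Per-subject jittered copy of a group's coupling plans."""
    rng = np.random.default_rng([int(subject.seed), 3])
    return [p.with_jitter(rng, coupling_jitter_sd) for p in base_plans]


def simulate_trial_events(
    subject: SubjectSpec,
    n_trials: int = 16,
    within_subject_cv: float = 0.10,
    group_params: "dict[str, dict[str, tuple[float, float]]] | None" = None,
) -> "tuple[BehaviorRecord, list[dict]]":
    """Per-trial event logs consistent with the subject's mean stage times.

    Each trial draws its stage durations around the subject's own stage
    means (coefficient of variation ``within_subject_cv``) and converts them
    to cumulative event timestamps: start, whole-arm move, joint fine
    adjust, second whole-arm move, docking complete.
    """
    behavior = simulate_behavior(subject, group_params)
    rng = np.random.default_rng([int(subject.seed), 2])
    events = []
    for trial in range(1, n_trials + 1):
        t = 0.0
        rows = [{"subject_id": subject.subject_id, "trial": trial,
                 "event": "start", "time_s": 0.0}]
        for stage, name in zip(
            STAGE_NAMES, ("arm_move", "fine_adjust", "arm_move_again", "dock_complete")
        ):
            mean = behavior.stage_times[stage]
            sd = within_subject_cv * mean
            if sd > 0:
                a = (0.0 - mean) / sd
                dur = float(
                    spstats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)
                )
            else:
                dur = mean
            t += dur
            rows.append({"subject_id": subject.subject_id, "trial": trial,
                         "event": name, "time_s": round(t, 4)})
        events.extend(rows)
    return behavior, events
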