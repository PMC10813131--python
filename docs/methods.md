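# Methods

This note records the model, the numerical choices, and the scope of the
synthetic generator behind `plvnet`. It states what the package computes;
empirical claims are limited to properties the test suite actually
verifies.

## Study design being modeled

Two screened groups — a depressive-emotion group (DE, CES-D > 16 without a
clinical diagnosis, BDI-II ≤ 13) and healthy controls (HC, CES-D < 16,
BDI-II ≤ 13) — perform a simulated robotic-arm docking task while 62-channel
EEG is recorded at 600 Hz. Each session contains a resting state (RS) and
16 docking trials (2 obstacle types × 8 viewing perspectives at 30°
increments). Each trial decomposes into four behavioral stages delimited by
five logged events (`start`, `arm_move`, `fine_adjust`, `arm_move_again`,
`dock_complete`): observation (O), large-scale movement (LM), fine
operation (FO), and docking (D).

The analysis has two routes:

- **EEG route**: per stage and frequency band, a phase-locking-value (PLV)
  connectivity matrix per subject, graph metrics on that matrix, an
  edgewise DE-vs-HC contrast with FDR control, and a correlation of
  region-averaged clustering with CES-D scores.
- **Behavioral route**: per-stage completion times from the event logs,
  compared between groups.

## Phase-locking value

For two phase series φ_i, φ_j of length N,

    PLV = | (1/N) Σ_t exp(i (φ_i(t) − φ_j(t))) |.

Phases come from the analytic signal (Hilbert transform) of band-filtered
2-s epochs. PLV is computed within each epoch and averaged across epochs,
giving one symmetric 62×62 matrix with unit diagonal per subject × band ×
stage. For independent uniform phases E[PLV] ≈ √π/(2√N) (≈ 0.0256 at
N = 1200); this null expectation is verified by Monte Carlo in the tests.

Implementation notes: per-epoch PLV is a unit-phasor Gram matrix
(`z @ z.conj().T / N`). Phasors are accumulated in complex128 so that a
perfectly locked pair yields PLV = 1 to ~1e-9; signals are stored in
float32 upstream for memory and speed.

## Preprocessing

Per stage: (optional FastICA artifact removal on the continuous data, with
components rejected by excess-kurtosis z-score) → segmentation into
non-overlapping 2-s epochs (each annotated span contributes
⌊span/2 s⌋ epochs; spans concatenate across trials) → zero-phase
Butterworth band-pass 0.1–60 Hz (order 4, `sosfiltfilt`) → per-epoch
baseline (mean) subtraction → average reference → per-band zero-phase
Chebyshev type-I cascade (order 4, 0.5 dB ripple; low-pass at the upper
band edge, then high-pass at the lower edge). Zero-phase (forward–backward)
filtering is mandatory because any phase distortion would bias PLV.

Canonical bands: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–48 Hz.

## Graph metrics

Weighted-network definitions on weights normalized by the maximum
off-diagonal entry ŵ = w / max(w):

- clustering coefficient (CC): Onnela's geometric-mean triangle form,
  CC_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1));
- distances d_ij from shortest paths with edge lengths 1/ŵ (Dijkstra);
- characteristic path length (CPL): mean finite off-diagonal distance
  (disconnected networks are flagged);
- global efficiency (Ge): mean of 1/d_ij over off-diagonal pairs
  (0 for unreachable pairs);
- local efficiency (Le): Ge of each node's neighborhood subgraph, keeping
  the global weight scale;
- node strength (ND): row sum of ŵ.

A proportional-threshold mode keeps exactly `round(density · n_pairs)`
strongest upper-triangle edges (stable tie-break by pair order), binarizes,
and applies the same formulas. All metrics are cross-checked against an
independent Floyd–Warshall / explicit-loop oracle to < 1e-9.

A 10-region atlas averages per-node metrics: hemisphere by the 10-20
numbering convention (odd = left, even = right; midline Z electrodes
excluded), lobe by name prefix (FP/AF/F frontal; FC/C/CP central;
FT/T/TP temporal; P parietal; PO/O occipital).

## Statistics

- **Edgewise contrast**: two-sided Wilcoxon rank-sum test per upper-triangle
  channel pair (1891 tests for 62 channels), Benjamini–Hochberg FDR within
  one band × stage family, and a signed map: +1 where the DE median exceeds
  the HC median on a surviving test, −1 for the reverse, 0 otherwise.
  Default mode is the tie-corrected normal approximation with continuity
  correction; an exact full-enumeration mode is available for combined
  n ≤ 25. Columns with all observations tied carry no evidence and are
  assigned p = 1.
- **Nodewise contrast**: the same machinery on per-node clustering
  coefficients.
- **CES-D correlation**: Spearman rank correlation (mid-ranks) of
  region-averaged clustering with CES-D, pooling both groups.
- **Behavioral contrasts**: rank-sum tests on the four stage times and the
  total, reported per stage *without* multiplicity correction; the output
  carries an explicit `corrected=False` flag.

## Synthetic cohort generator

Real recordings for this design are not available, so the package ships a
generator with planted ground truth.

**Signals.** Each channel in each band is a unit-amplitude cosine of a
band-limited random phase, scaled by a per-band amplitude (µV) and summed
across bands, plus white Gaussian sensor noise (default σ = 2 µV).
Band-limited phases are synthesized directly in the frequency domain (FM
model): instantaneous frequency = band center + a smooth Gaussian deviation
(sd = bandwidth/6, modulation bandwidth = bandwidth/3), integrated to phase
with a uniform random offset. This is ~11× faster than filtering broadband
noise and extracting Hilbert phases, and yields narrowband signals whose
analytic phase matches the constructed phase.

**Planted coupling.** A coupling plan lists edges (i, j, c) per band and
stage. Channels touched by edges share a per-connected-component driver
phase: φ_ch = c·φ_driver + (1−c)·ψ_ch with private noise phase ψ_ch; a
channel on several edges takes its maximum incident c. Unlisted channels
mix a common background driver at a baseline c (default 0.1). Because
coupling is transitive through a shared driver, *all* pairs within a
connected component are coupled — the planted ground truth is the
component structure, not only the listed pairs.

**Calibration.** The map from c to realized PLV is band-dependent (faster
bands decorrelate faster through the 1−c noise term).
`calibrate_coupling()` measures mean ± sd PLV over Monte-Carlo replicates
per c value. The shipped defaults — strong coupling 0.95 (delta) / 0.90
(other bands), weak 0.30, baseline 0.10 — were frozen from this calibration
to give a noiseless group PLV difference of ≈ 0.4 per band; after
preprocessing with default sensor noise the realized difference is ≈ 0.3–0.45.

**Group structure (defaults).** At rest, HC couples strongly and DE weakly
on 10 bilateral frontoparietal theta and alpha edges (DE − HC negative).
During LM and FO, DE couples strongly and HC weakly on 10 left-lateralized
frontoparietal delta, beta, and gamma edges (DE − HC positive). Per-subject
coupling jitter (sd 0.05) individualizes subjects.

**Behavior.** Stage times are truncated-at-zero Gaussians with group
parameters (seconds, mean ± sd):

| stage | HC           | DE           |
|-------|--------------|--------------|
| O     | 10.91 ± 2.6  | 11.53 ± 3.0  |
| LM    | 20.52 ± 3.2  | 25.68 ± 2.9  |
| FO    | 19.31 ± 1.9  | 26.47 ± 2.2  |
| D     | 24.22 ± 3.8  | 25.75 ± 4.3  |
| total | 74.96        | 89.43        |

sd = 0 is legal and returns the mean exactly (used to verify bookkeeping);
negative sd is an error. Per-trial event logs are generated around each
subject's drawn stage times with 10% within-subject variability. Scale
scores are drawn by rejection sampling within each group's inclusion
window (DE CES-D 24.8 ± 4.2 truncated to > 16; HC 14.6 ± 3.4 truncated to
< 16; BDI-II ≤ 13 for both).

**Randomness.** A cohort seed spawns independent per-subject seeds via
`numpy.random.SeedSequence`; each subject seed feeds separate streams for
the recording, behavior, event logs and coupling jitter, all < 2³¹.

## Validation experiments

- **Planted-effect recovery**: 15-vs-15 cohort, 60 two-second epochs per
  subject and stage, full pipeline; the edgewise contrast must recover
  ≥ 80% of the 80 planted edges (10 edges × 8 band-stage families) with the
  correct sign, while edges between channels untouched by any plan stay
  below a 5% significant fraction.
- **Null FDR control**: 20 replicate cohorts with *identical* coupling in
  both groups (8-vs-8 subjects, alpha band, 30 s RS, the full 1891-test
  family); the mean significant-edge proportion must stay ≤ 0.05. The
  cohort scale here is a package choice sized to a 10-minute budget; the
  family size matches the real contrast.
- **Behavioral power**: 100 replicate cohorts; LM, FO and total contrasts
  must reject (p < 0.05) in ≥ 90% of replicates while O and D do not
  systematically reject.

## Limitations

- The generator is a phase-mixing model, not a biophysical EEG simulator:
  no 1/f spectrum, volume conduction, eye/muscle artifacts (unless added),
  or non-stationarity. ICA-based artifact rejection is therefore off by
  default for synthetic cohorts.
- PLV on scalp channels is susceptible to volume conduction in real data;
  the package computes PLV as defined and does not attempt leakage
  correction (e.g. imaginary coherence), which is out of scope.
- The behavioral contrasts are uncorrected by design and flagged as such.
- Exact rank-sum enumeration is limited to combined n ≤ 25; above that the
  normal approximation is used.
- EDF/BrainVision files can be read (via `mne`), but the portable
  NPZ + JSON container is the only writer shipped; no EDF export.
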