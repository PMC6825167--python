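"""Synthetic differential threat-conditioning EEG.

Emulates the two-day paradigm's trial structure and Day-2 recall EEG:
an occipitally focal 8–12 Hz oscillation rides on spatially mixed 1/f
background noise; after stimulus onset its amplitude is suppressed more
for threat cues (CS+) than safety cues (CS−) — event-related
desynchronization (ERD).  Absolute units are nominal µV; the analysis
endpoint is percent change from baseline, so only ratios matter.

Two generators are provided:

* :func:`simulate_subject` — full 64-channel epochs with alpha topography,
  volume-conduction-like noise mixing, per-channel DC offsets and a common
  reference drift (so CSD/baseline invariances are exercised).
* :func:`simulate_roi_subject` — a single virtual occipital-ROI channel
  with the same temporal statistics, for calibration studies (type-I
  error, FWER) where thousands of subjects are needed and the spatial
  stage is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochArray, epoch_times
from .montage import Montage

CS_TYPES = ("CS+E", "CS+N", "CS-E", "CS-N")
PHASES = ("habituation", "acquisition", "extinction", "recall")

#: trials per CS type in each phase of the two-day paradigm
PHASE_DESIGN: dict[str, dict[str, int]] = {
    "habituation": {cs: 5 for cs in CS_TYPES},
    "acquisition": {cs: 45 for cs in CS_TYPES},
    "extinction": {"CS+E": 40, "CS-E": 40},
    "recall": {cs: 60 for cs in CS_TYPES},
}

#: reinforced (US-paired) trials per CS type, acquisition only
N_REINFORCED_ACQ = 21


@dataclass(frozen=True)
class TrialRecord:
    phase: str
    cs_type: str
    reinforced: bool
    index: int


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial records for one phase of the paradigm."""

    phase: str
    records: tuple[TrialRecord, ...]

    def count(self, cs_type: str) -> int:
        return sum(1 for r in self.records if r.cs_type == cs_type)

    def n_reinforced(self, cs_type: str | None = None) -> int:
        return sum(
            1 for r in self.records
            if r.reinforced and (cs_type is None or r.cs_type == cs_type)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.phase, r.cs_type, int(r.reinforced), r.index) for r in self.records],
            columns=["phase", "cs_type", "reinforced", "index"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_schedule(phase: str, seed: int | None = None) -> TrialSchedule:
    """Seeded trial schedule for one paradigm phase.

    Trial order is a random interleaving of the CS types; during
    acquisition, 21 of each CS+ type's 45 trials are reinforced, at
    positions drawn uniformly at random within that CS's own sequence.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    rng = np.random.default_rng(seed)
    design = PHASE_DESIGN[phase]
    labels = [cs for cs, n in design.items() for _ in range(n)]
    order = rng.permutation(len(labels))
    ordered = [labels[i] for i in order]

    reinforced_slots: dict[str, set] = {cs: set() for cs in design}
    if phase == "acquisition":
        for cs in ("CS+E", "CS+N"):
            slots = rng.choice(design[cs], size=N_REINFORCED_ACQ, replace=False)
            reinforced_slots[cs] = set(int(s) for s in slots)

    seen = {cs: 0 for cs in design}
    records = []
    for i, cs in enumerate(ordered):
        records.append(
            TrialRecord(phase, cs, seen[cs] in reinforced_slots[cs], i)
        )
        seen[cs] += 1
    return TrialSchedule(phase, tuple(records))


@dataclass(frozen=True)
class SimParams:
    """Generator settings for one simulated subject/cohort.

    ``suppression_depth`` is the fraction of the baseline alpha amplitude
    removed post-onset per CS type (0 = no ERD, 1 = full suppression).
    Defaults encode the paradigm's study conditions: 500 Hz sampling,
    10 Hz alpha focus, ERD onset near 500 ms with a 200 ms ramp, and
    retained-trial counts in the study's observed 16–57 range.
    """

    n_subjects: int = 12
    srate: float = 500.0
    alpha_freq_hz: float = 10.0
    baseline_alpha_amp: float = 10.0
    amp_between_sd: float = 2.0
    erd_onset_ms: float = 500.0
    erd_ramp_ms: float = 200.0
    suppression_depth: dict[str, float] = field(
        default_factory=lambda: {"CS+E": 0.5, "CS+N": 0.5, "CS-E": 0.3, "CS-N": 0.3}
    )
    depth_jitter_sd: float = 0.05
    noise_1f_amp: float = 1.0
    trial_amp_jitter_sd: float = 0.2
    dc_offset_sd: float = 20.0
    drift_amp: float = 5.0
    topo_sd_rad: float = 0.6
    mix_sd_rad: float = 0.35
    trials_retained: tuple[int, int] = (16, 57)
    seed: int | None = None

    def __post_init__(self) -> None:
        for cs, d in self.suppression_depth.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"suppression_depth[{cs!r}]={d} outside [0, 1]")
        lo, hi = self.trials_retained
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid trials_retained range {self.trials_retained}")


def _pink_noise(rng: np.random.Generator, shape: tuple, srate: float) -> np.ndarray:
    """1/f-power noise along the last axis, unit variance, any leading shape."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC in the noise itself; offsets are added separately
    scale[1:] = freqs[1:] ** -0.5
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),)))
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _erd_envelope(times_ms: np.ndarray, depth: float, onset_ms: float,
                  ramp_ms: float) -> np.ndarray:
    """Multiplicative amplitude envelope: 1 before onset, 1−depth after ramp."""
    frac = np.clip((times_ms - onset_ms) / max(ramp_ms, 1e-9), 0.0, 1.0)
    return 1.0 - depth * frac


def _alpha_trials(rng, params: SimParams, labels: list[str],
                  times: np.ndarray) -> np.ndarray:
    """(n_trials, n_time) alpha oscillation with per-trial phase/amp jitter."""
    t_s = times / 1000.0
    out = np.empty((len(labels), len(times)))
    for i, cs in enumerate(labels):
        phase = rng.uniform(0, 2 * np.pi)
        amp = params.baseline_alpha_amp * np.exp(
            rng.normal(0.0, params.trial_amp_jitter_sd)
        )
        env = _erd_envelope(times, params.suppression_depth[cs],
                            params.erd_onset_ms, params.erd_ramp_ms)
        out[i] = amp * env * np.cos(2 * np.pi * params.alpha_freq_hz * t_s + phase)
    return out


def _retained_labels(rng, schedule: TrialSchedule, params: SimParams) -> list[str]:
    """Subsample each CS type's trials to a seeded retained count, keeping order."""
    lo, hi = params.trials_retained
    keep_idx: list[int] = []
    for cs in PHASE_DESIGN[schedule.phase]:
        cs_positions = [r.index for r in schedule.records if r.cs_type == cs]
        n_keep = min(int(rng.integers(lo, hi + 1)), len(cs_positions))
        chosen = rng.choice(len(cs_positions), size=n_keep, replace=False)
        keep_idx.extend(cs_positions[i] for i in sorted(chosen))
    keep_idx.sort()
    return [schedule.records[i].cs_type for i in keep_idx]


def simulate_subject(schedule: TrialSchedule, params: SimParams,
                     montage: Montage, seed: int | None = None) -> EpochArray:
    """Full multichannel epochs for one subject in the recall phase.

    Each trial is spatially mixed 1/f noise plus an alpha oscillation
    whose topography falls off as a Gaussian (on the sphere) around Oz
    and whose amplitude drops by ``suppression_depth[cs_type]`` from
    ``erd_onset_ms`` with a linear ramp.  A per-channel DC offset and a
    spatially constant slow drift are added so that the baseline and
    CSD reference invariances are non-trivially exercised.
    """
    if schedule.phase != "recall":
        raise ValueError("pipeline target is the recall phase; got "
                         f"{schedule.phase!r}")
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    times = epoch_times(params.srate)
    labels = _retained_labels(rng, schedule, params)
    n_trials, n_ch, n_t = len(labels), len(montage), len(times)

    topo = np.exp(-montage.angles_from("Oz") ** 2 / (2 * params.topo_sd_rad**2))
    ang = np.arccos(montage.pairwise_cos())
    mix = np.exp(-(ang**2) / (2 * params.mix_sd_rad**2))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)  # preserve noise variance

    alpha = _alpha_trials(rng, params, labels, times)  # (trials, time)
    noise = _pink_noise(rng, (n_trials, n_ch, n_t), params.srate)
    noise = params.noise_1f_amp * np.einsum("ij,tjn->tin", mix, noise)

    dc = rng.normal(0.0, params.dc_offset_sd, size=n_ch)
    drift_phase = rng.uniform(0, 2 * np.pi, size=n_trials)
    drift = params.drift_amp * np.sin(
        2 * np.pi * 0.3 * (times / 1000.0)[None, :] + drift_phase[:, None]
    )  # (trials, time), identical across channels

    data = (topo[None, :, None] * alpha[:, None, :]
            + noise + dc[None, :, None] + drift[:, None, :])
    return EpochArray(
        np.ascontiguousarray(data.transpose(1, 2, 0)), params.srate, times,
        montage.labels, tuple(labels), subject_id="S00",
    )


def simulate_roi_subject(params: SimParams, seed: int | None = None,
                         n_trials_per_cs: int | None = None) -> EpochArray:
    """Single virtual occipital-ROI channel for one recall-phase subject.

    Temporal statistics match :func:`simulate_subject` at the topography
    peak; spatial mixing, DC offsets and drift are omitted.  Intended for
    large calibration simulations.
    """
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    times = epoch_times(params.srate)
    if n_trials_per_cs is None:
        labels = []
        lo, hi = params.trials_retained
        for cs in CS_TYPES:
            labels.extend([cs] * int(rng.integers(lo, hi + 1)))
    else:
        labels = [cs for cs in CS_TYPES for _ in range(n_trials_per_cs)]
    alpha = _alpha_trials(rng, params, labels, times)
    noise = params.noise_1f_amp * _pink_noise(
        rng, (len(labels), len(times)), params.srate
    )
    data = (alpha + noise)[None, :, :].transpose(0, 2, 1)
    return EpochArray(
        np.ascontiguousarray(data), params.srate, times, ("ROI",),
        tuple(labels), subject_id="S00",
    )


def _subject_params(params: SimParams, rng) -> SimParams:
    """Per-subject draw of baseline amplitude and suppression-depth jitter."""
    amp = max(float(rng.normal(params.baseline_alpha_amp, params.amp_between_sd)),
              0.5)
    depths = {
        cs: float(np.clip(d + rng.normal(0.0, params.depth_jitter_sd), 0.0, 1.0))
        for cs, d in params.suppression_depth.items()
    }
    return replace(params, baseline_alpha_amp=amp, suppression_depth=depths)


def simulate_cohort(params: SimParams, montage: Montage,
                    seed: int | None = None) -> list[EpochArray]:
    """Independent recall-phase subjects with per-subject seeds.

    Subject ``i`` uses seed ``master + i`` (schedule seed included), so a
    cohort is reproducible piecewise as well as in full.
    """
    if params.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    master = seed if seed is not None else (params.seed or 0)
    cohort = []
    for i in range(params.n_subjects):
        sub_seed = master + i
        rng = np.random.default_rng(sub_seed)
        p_i = _subject_params(params, rng)
        schedule = generate_schedule("recall", seed=sub_seed)
        ep = simulate_subject(schedule, p_i, montage, seed=sub_seed + 10_000)
        ep.subject_id = f"S{i:03d}"
        cohort.append(ep)
    return cohort


def simulate_roi_cohort(params: SimParams, seed: int | None = None,
                        n_trials_per_cs: int | None = None) -> list[EpochArray]:
    """ROI-channel counterpart of :func:`simulate_cohort`."""
    if params.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    master = seed if seed is not None else (params.seed or 0)
    cohort = []
    for i in range(params.n_subjects):
        rng = np.random.default_rng(master + i)
        p_i = _subject_params(params, rng)
        ep = simulate_roi_subject(p_i, seed=master + i + 10_000,
                                  n_trials_per_cs=n_trials_per_cs)
        ep.subject_id = f"S{i:03d}"
        cohort.append(ep)
    return cohort
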