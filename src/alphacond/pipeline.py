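"""End-to-end orchestration: simulate/load → CSD → wavelet → infer → permute.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage;
all stochastic stages draw their own seed from one master seed by fixed
offsets, so a run is reproducible in full and per stage.  Outputs are
plain CSV/JSON/TXT files that embed the config hash and the seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csd as csd_mod
from . import inference, permutation, synthetic, timefreq
from .epochs import EpochArray, load_cohort
from .montage import ROI_CHANNELS, build_montage

log = logging.getLogger("alphacond")

SIM_SEED_OFFSET = 11
PERM_SEED_OFFSET = 13
BAYES_SEED_OFFSET = 17


class ConfigError(ValueError):
    """Invalid configuration or input paths (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the study parameters."""

    # data source: simulate unless input_dir is given
    input_dir: str | None = None
    n_subjects: int = 8
    n_channels: int = 64
    srate: float = 500.0
    trials_retained: tuple[int, int] = (16, 57)
    suppression_depth: dict = field(default_factory=lambda: dict(
        synthetic.SimParams().suppression_depth))
    depth_jitter_sd: float = 0.05
    baseline_alpha_amp: float = 10.0
    amp_between_sd: float = 2.0
    noise_1f_amp: float = 1.0
    erd_onset_ms: float = 500.0
    erd_ramp_ms: float = 200.0

    # CSD
    no_csd: bool = False
    spline_order: int = 4
    legendre_degree: int = 10
    lam: float = 1e-5

    # time-frequency
    taper_baseline_ms: tuple[float, float] = (-600.0, -500.0)
    power_baseline_ms: tuple[float, float] = (-400.0, -200.0)
    amplitude_baseline: bool = False
    band_hz: tuple[float, float] = timefreq.ALPHA_BAND_HZ
    roi: tuple[str, ...] = ROI_CHANNELS
    window_ms: tuple[float, float] = timefreq.ANALYSIS_WINDOW_MS

    # inference / permutation
    alpha: float = 0.05
    n_perm: int = 1000
    include_identity_perm: bool = False
    bayes: bool = True
    iterations: int = 10_000
    n_blocks: int = 4

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trials_retained", "taper_baseline_ms",
                     "power_baseline_ms", "band_hz", "window_ms"):
            setattr(self, name, tuple(getattr(self, name)))
        self.roi = tuple(self.roi)
        lo, hi = self.window_ms
        if not (-600.0 <= lo <= hi < 2000.0):
            raise ConfigError(f"analysis window {self.window_ms} outside epoch")
        for win in (self.taper_baseline_ms, self.power_baseline_ms):
            if not (-600.0 <= win[0] <= win[1] < 2000.0):
                raise ConfigError(f"baseline window {win} outside epoch")
        if self.n_perm < 1 or self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("invalid permutation settings")

    # -- seeds -----------------------------------------------------------
    @property
    def sim_seed(self) -> int:
        return self.seed + SIM_SEED_OFFSET

    @property
    def perm_seed(self) -> int:
        return self.seed + PERM_SEED_OFFSET

    @property
    def bayes_seed(self) -> int:
        return self.seed + BAYES_SEED_OFFSET

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml_str().encode()).hexdigest()[:16]

    def sim_params(self) -> synthetic.SimParams:
        return synthetic.SimParams(
            n_subjects=self.n_subjects, srate=self.srate,
            baseline_alpha_amp=self.baseline_alpha_amp,
            amp_between_sd=self.amp_between_sd,
            erd_onset_ms=self.erd_onset_ms, erd_ramp_ms=self.erd_ramp_ms,
            suppression_depth=dict(self.suppression_depth),
            depth_jitter_sd=self.depth_jitter_sd,
            noise_1f_amp=self.noise_1f_amp,
            trials_retained=self.trials_retained,
        )


@dataclass
class SubjectSummary:
    effect_rows: pd.DataFrame
    timecourses: dict[str, np.ndarray]
    #: cs_type -> (n_times, n_trials) band/ROI-averaged raw power per trial
    trial_alpha: dict[str, np.ndarray]
    times: np.ndarray
    subject_id: str = "S00"


def analyze_subject(epochs: EpochArray, config: PipelineConfig,
                    basis=None) -> SubjectSummary:
    """CSD (optional) → taper/baseline → alpha power → summaries.

    The wavelet stage runs on the ROI channels only, over the grid bins
    of the analysis band: every downstream quantity (effect table,
    contingency time courses, block trial power) is an ROI/band average.
    """
    if not config.no_csd:
        if basis is None:
            raise ValueError("CSD requested but no basis supplied")
        epochs = csd_mod.csd_transform(epochs, basis)
    else:
        # supplementary analysis path: average-referenced scalp data
        epochs = EpochArray(
            epochs.data - epochs.data.mean(axis=0, keepdims=True),
            epochs.srate, epochs.times, epochs.ch_names, epochs.trial_labels,
            epochs.subject_id,
        ) if epochs.n_channels > 1 else epochs

    epochs = timefreq.taper_and_baseline(epochs, config.taper_baseline_ms)
    roi = [ch for ch in config.roi if ch in epochs.ch_names]
    if not roi:
        roi = list(epochs.ch_names)  # single-virtual-channel inputs
    bank = timefreq.default_bank(config.srate).subset(config.band_hz)
    tf_trials = timefreq.morlet_power(epochs, bank, channels=roi)

    labels = np.array(epochs.trial_labels)
    tf_by_cond: dict[str, timefreq.TFPower] = {}
    trial_alpha: dict[str, np.ndarray] = {}
    for cond in dict.fromkeys(epochs.trial_labels):
        sel = labels == cond
        avg = tf_trials.power[:, :, :, sel].mean(axis=3)
        tf_raw = timefreq.TFPower(avg, tf_trials.freqs.copy(),
                                  tf_trials.times.copy(), tuple(roi),
                                  epochs.srate, edge_invalid=tf_trials.edge_invalid)
        tf_by_cond[cond] = timefreq.baseline_normalize(
            tf_raw, config.power_baseline_ms,
            amplitude_domain=config.amplitude_baseline)
        # band/ROI-averaged per-trial raw power, kept for the block analysis
        trial_alpha[cond] = tf_trials.power[:, :, :, sel].mean(axis=(0, 2))

    rows = timefreq.effect_table_rows(epochs.subject_id, tf_by_cond,
                                      config.band_hz, roi, config.window_ms)
    courses = timefreq.timecourse_summary(tf_by_cond, config.band_hz, roi)
    return SubjectSummary(rows, courses, trial_alpha, epochs.times.copy(),
                          epochs.subject_id)


def block_summaries(summary: SubjectSummary, config: PipelineConfig,
                    window_ms: tuple[float, float],
                    subject_id: str) -> pd.DataFrame:
    """Per-block alpha percent change for CS+ and CS− for one subject.

    Trials of each CS type are split sequentially into equal blocks
    (remainder to the earliest); each block's trial-averaged band/ROI
    power is rescaled to percent change against its own baseline and
    reduced to the mean over ``window_ms``.
    """
    times = summary.times

    def _idx(win):
        sel = np.where((times >= win[0] - 1e-9) & (times <= win[1] + 1e-9))[0]
        if sel.size == 0:
            raise ValueError(f"window {win} ms selects no samples")
        return sel

    bidx, widx = _idx(config.power_baseline_ms), _idx(window_ms)
    per_cs: dict[str, np.ndarray] = {}
    for cs, p in summary.trial_alpha.items():  # p: (n_times, n_trials)
        n_trials = p.shape[1]
        if n_trials < config.n_blocks:
            raise ValueError(
                f"subject {subject_id}: only {n_trials} trials for {cs}, "
                f"cannot form {config.n_blocks} blocks")
        vals = []
        for idx in inference.partition_blocks(n_trials, config.n_blocks):
            series = p[:, idx].mean(axis=1)
            base = series[bidx].mean()
            if base <= 0:
                raise ValueError(f"subject {subject_id}: zero baseline power")
            pct = 100.0 * (series / base - 1.0)
            vals.append(pct[widx].mean())
        per_cs[cs] = np.array(vals)
    rows = []
    for b in range(config.n_blocks):
        for cont, members in (("CS+", ("CS+E", "CS+N")), ("CS-", ("CS-E", "CS-N"))):
            have = [per_cs[m][b] for m in members if m in per_cs]
            rows.append((subject_id, b + 1, cont, float(np.mean(have))))
    return pd.DataFrame(rows, columns=["subject_id", "block", "contingency",
                                       "alpha_pct"])


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    Returns the in-memory results dict.  On stage failure all files
    created by this run are removed and the error is re-raised with the
    stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    meta = {"config_hash": config.digest(),
            "seed": config.seed, "sim_seed": config.sim_seed,
            "perm_seed": config.perm_seed, "bayes_seed": config.bayes_seed,
            "reference": "average-reference" if config.no_csd else "csd"}
    stage = "setup"
    try:
        # ---------------- data ----------------
        stage = "simulate/load"
        if config.input_dir is not None:
            cohort = load_cohort(config.input_dir)
            log.info("loaded %d subjects from %s", len(cohort), config.input_dir)
        else:
            montage = build_montage(config.n_channels)
            cohort = synthetic.simulate_cohort(config.sim_params(), montage,
                                               seed=config.sim_seed)
            log.info("simulated %d subjects (%d channels, %d samples)",
                     len(cohort), cohort[0].n_channels, cohort[0].n_times)

        basis = None
        if not config.no_csd:
            stage = "csd"
            mont = build_montage(cohort[0].n_channels)
            basis = csd_mod.csd_basis(mont, csd_mod.CsdParams(
                config.spline_order, config.legendre_degree, config.lam))
            log.info("CSD basis: m=%d N=%d lambda=%g", config.spline_order,
                     config.legendre_degree, config.lam)

        stage = "timefreq"
        summaries = [analyze_subject(ep, config, basis) for ep in cohort]
        table = timefreq.validate_effect_table(
            pd.concat([s.effect_rows for s in summaries], ignore_index=True))
        log.info("effect table: %d rows (%d subjects)", len(table),
                 table["subject_id"].nunique())

        # ---------------- inference ----------------
        stage = "anova"
        anova = inference.rm_anova_2x2(table)
        sem = inference.within_subject_sem(table)
        dist = (inference.distribution_check(table)
                if table["subject_id"].nunique() >= 8 else None)

        bayes = incl = None
        if config.bayes:
            stage = "bayes"
            bayes = inference.bayes_model_comparison(
                table, iterations=config.iterations, seed=config.bayes_seed)
            incl = inference.inclusion_bf(bayes)
            log.info("bayes: %s", {k: round(v, 2) for k, v in bayes.bf10.items()})

        # ---------------- permutation ----------------
        stage = "permutation"
        times = summaries[0].times
        diffs = np.stack([s.timecourses["CS+"] - s.timecourses["CS-"]
                          for s in summaries])
        perm = permutation.permutation_test(
            diffs, times, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.perm_seed, include_identity=config.include_identity_perm)
        log.info("permutation: t_crit = (%.2f, %.2f), %d window(s)",
                 perm.t_crit_low, perm.t_crit_high, len(perm.windows))

        # ---------------- blocks ----------------
        stage = "blocks"
        if perm.windows:
            block_window = max(perm.windows, key=lambda w: w[1] - w[0])
        else:
            block_window = config.window_ms
        blocked = pd.concat(
            [block_summaries(s, config, block_window, s.subject_id)
             for s in summaries], ignore_index=True)
        blocks = inference.block_anova(blocked)

        # ---------------- outputs ----------------
        stage = "write"
        def _w(path: Path):
            created.append(path)
            return path

        table.to_csv(_w(out / "effect_table.csv"), index=False,
                     float_format="%.10g")
        _json_dump({**meta, "anova": anova.to_dict(),
                    "within_subject_sem": sem.to_dict(orient="records"),
                    "distribution_check": (dist.to_dict(orient="records")
                                           if dist is not None else None)},
                   _w(out / "anova.json"))
        if bayes is not None:
            _json_dump({**meta, **bayes.to_dict(), "bf_incl": incl},
                       _w(out / "bayes.json"))
        pd.DataFrame({"time_ms": times, "t": perm.t_series,
                      "sig": perm.sig_mask.astype(int)}).to_csv(
            _w(out / "permutation.csv"), index=False, float_format="%.10g")
        _json_dump({**meta, "t_crit_low": perm.t_crit_low,
                    "t_crit_high": perm.t_crit_high, "n_perm": perm.n_perm,
                    "alpha": perm.alpha,
                    "windows_ms": [list(w) for w in perm.windows]},
                   _w(out / "permutation.json"))
        _json_dump({**meta, "window_ms": list(block_window),
                    "anova": blocks["anova"].to_dict(),
                    "per_block_t": blocks["per_block_t"]},
                   _w(out / "blocks.json"))
        with open(_w(out / "config_used.yaml"), "w") as fh:
            fh.write(config.to_yaml_str())

        report = render_report(meta, anova, bayes, incl, perm, blocks,
                               block_window)
        with open(_w(out / "report.txt"), "w") as fh:
            fh.write(report)

        return {"effect_table": table, "anova": anova, "bayes": bayes,
                "bf_incl": incl, "permutation": perm, "blocks": blocks,
                "meta": meta, "report": report}
    except Exception as err:
        for path in created:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def render_report(meta, anova, bayes, incl, perm, blocks, block_window) -> str:
    """Human-readable text report in the field's reporting style."""
    lines = [
        "alphacond analysis report",
        f"reference scheme: {meta['reference']}",
        f"config hash: {meta['config_hash']}  master seed: {meta['seed']}",
        "",
        "2x2 within-subject ANOVA (Contingency x Extinction):",
        anova.report(),
    ]
    if bayes is not None:
        lines += ["", "Bayesian model comparison (BF10 vs null):"]
        lines += [f"  {name}: BF10 = {inference.format_bf(v)}"
                  for name, v in bayes.bf10.items()]
        lines += ["Inclusion Bayes factors:"]
        lines += [f"  {name}: BF_Incl = {inference.format_bf(v)}"
                  for name, v in incl.items()]
    win_txt = (", ".join(f"{w[0]:.0f} to {w[1]:.0f} ms" for w in perm.windows)
               or "none")
    lines += [
        "",
        f"Permutation t-test ({perm.n_perm} permutations, alpha = {perm.alpha}):",
        f"  t_crit: CS+ < CS-: {perm.t_crit_low:.2f}; CS+ > CS-: "
        f"{perm.t_crit_high:.2f}",
        f"  significant window(s): {win_txt}",
        "",
        f"Block x Contingency ANOVA (window {block_window[0]:.0f}-"
        f"{block_window[1]:.0f} ms):",
        blocks["anova"].report(),
        "Per-block paired t-tests (uncorrected, two-sided):",
    ]
    lines += [f"  block {b}: t({r['df']}) = {r['t']:.2f}, p = {r['p']:.3f}"
              for b, r in blocks["per_block_t"].items()]
    return "\n".join(lines) + "\n"
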