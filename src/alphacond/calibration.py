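"""Calibration studies: empirical type-I error and family-wise error rate.

These helpers run many replicate cohorts through the analysis stack to
measure error rates under the null (identical suppression for CS+ and
CS−).  They use the single-virtual-channel generator, which shares the
temporal statistics of the full simulation but skips the spatial stage,
so hundreds of replicates fit in a desk-scale compute budget; the
time–frequency, summary and permutation code they exercise is exactly
the pipeline's.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import permutation, synthetic
from .pipeline import PipelineConfig, analyze_subject

#: depths used for null cohorts: ERD present but identical across CS types
NULL_DEPTHS = {cs: 0.3 for cs in synthetic.CS_TYPES}


def _roi_config() -> PipelineConfig:
    return PipelineConfig(no_csd=True, bayes=False)


def roi_cohort_summaries(n_subjects: int, seed: int,
                         depths: dict | None = None,
                         n_trials_per_cs: int = 8,
                         depth_jitter_sd: float = 0.05):
    """Analyzed single-channel cohort: per-subject summaries."""
    params = synthetic.SimParams(
        n_subjects=n_subjects,
        suppression_depth=dict(depths if depths is not None else NULL_DEPTHS),
        depth_jitter_sd=depth_jitter_sd,
    )
    cohort = synthetic.simulate_roi_cohort(params, seed=seed,
                                           n_trials_per_cs=n_trials_per_cs)
    cfg = _roi_config()
    with warnings.catch_warnings():
        # the default baseline window sits near the epoch edge by design;
        # the per-subject reminder is noise in replicate loops
        warnings.filterwarnings("ignore", message="baseline window touches",
                                category=RuntimeWarning)
        return [analyze_subject(ep, cfg) for ep in cohort]


def cohort_contingency_diffs(n_subjects: int, seed: int,
                             depths: dict | None = None,
                             n_trials_per_cs: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """(subjects, time) CS+ − CS− alpha time-series differences, and times."""
    summaries = roi_cohort_summaries(n_subjects, seed, depths, n_trials_per_cs)
    diffs = np.stack([s.timecourses["CS+"] - s.timecourses["CS-"]
                      for s in summaries])
    return diffs, summaries[0].times


def fwer_replicate(seed: int, n_subjects: int = 24, n_perm: int = 1000,
                   alpha: float = 0.05, n_trials_per_cs: int = 8) -> bool:
    """One null cohort through the full permutation stage.

    Returns True when any of the per-sample tests is declared
    significant (a family-wise false positive).
    """
    diffs, times = cohort_contingency_diffs(n_subjects, seed,
                                            n_trials_per_cs=n_trials_per_cs)
    res = permutation.permutation_test(diffs, times, n_perm=n_perm,
                                       alpha=alpha, seed=seed + 500_000)
    return bool(res.sig_mask.any())


def empirical_fwer(n_replicates: int = 400, seed: int = 0,
                   n_subjects: int = 24, n_perm: int = 1000,
                   alpha: float = 0.05) -> float:
    """Fraction of null replicates with any significant sample."""
    hits = sum(fwer_replicate(seed + rep, n_subjects, n_perm, alpha)
               for rep in range(n_replicates))
    return hits / n_replicates


def anova_type1_replicate(seed: int, n_subjects: int = 24,
                          alpha: float = 0.05,
                          n_trials_per_cs: int = 8) -> bool:
    """One null cohort through summaries + 2x2 ANOVA; True if the
    Contingency effect is (falsely) significant."""
    import pandas as pd

    from .inference import rm_anova_2x2

    summaries = roi_cohort_summaries(n_subjects, seed,
                                     n_trials_per_cs=n_trials_per_cs)
    table = pd.concat([s.effect_rows for s in summaries], ignore_index=True)
    res = rm_anova_2x2(table)
    return bool(res.effects["Contingency"].p < alpha)
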