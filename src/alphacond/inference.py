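"""Frequentist and Bayesian inference on subject x condition alpha summaries.

The core design is a fully within-subject 2x2: Contingency (CS+ vs CS−)
by Extinction (extinguished vs non-extinguished).  Each effect is tested
against its own effect-by-subject interaction (univariate repeated-
measures F), with partial eta squared SS_eff/(SS_eff+SS_err).  The block
stability analysis extends this to Block (4) x Contingency (2) with
Greenhouse–Geisser correction of Block-containing effects.

Bayes factors follow the mixed-model ANOVA construction: all factor
effects receive zero-centred normal priors with per-batch scale g·σ²,
g ~ InvGamma(1/2, r²/2) with r = 0.5 for fixed-effect batches and r = 1
for the subject batch; μ and σ² carry Jeffreys priors.  Conditional on
g the marginal likelihood is closed-form, and the g integral is done by
seeded Monte Carlo, so BF estimates carry a reported MC error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CELL_ORDER = [("CS+", "E"), ("CS+", "N"), ("CS-", "E"), ("CS-", "N")]
MODEL_TERMS = {
    "C": ("C",),
    "E": ("E",),
    "C+E": ("C", "E"),
    "C+E+CxE": ("C", "E", "CxE"),
}


@dataclass(frozen=True)
class EffectStats:
    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectStats]

    def report(self) -> str:
        lines = []
        for name, e in self.effects.items():
            line = (f"{name}: F({e.df1:g}, {e.df2:g}) = {e.F:.2f}, "
                    f"p = {e.p:.3f}, eta_p^2 = {e.eta_p2:.3f}")
            if e.gg_epsilon is not None:
                line += f" (GG eps = {e.gg_epsilon:.3f}, p_GG = {e.p_gg:.3f})"
            lines.append(line)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {name: vars(e) for name, e in self.effects.items()}


def _pivot_cells(table: pd.DataFrame) -> tuple[np.ndarray, list]:
    """(n_subjects, 4) cell matrix in CELL_ORDER; fails on missing cells."""
    piv = table.pivot_table(index="subject_id",
                            columns=["contingency", "extinction"],
                            values="alpha_pct", aggfunc="mean")
    missing = [s for s in piv.index
               if piv.loc[s].reindex(CELL_ORDER).isna().any()]
    if missing:
        raise ValueError(f"subjects with missing condition cells: {missing}")
    return piv.reindex(columns=CELL_ORDER).to_numpy(float), list(piv.index)


def gg_epsilon(M: np.ndarray) -> float:
    """Greenhouse–Geisser (Box) epsilon of an (n_subjects, k) measure set."""
    k = M.shape[1]
    if k <= 2:
        return 1.0
    S = np.cov(M, rowvar=False)
    # orthonormal contrast basis spanning the k-1 dim difference space
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    Sc = C.T @ S @ C
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.trace(Sc @ Sc)
    return float(min(num / den, 1.0)) if den > 0 else 1.0


def _two_way_rm(Y: np.ndarray, names=("A", "B", "AxB"),
                gg_for: tuple[str, ...] = ()) -> AnovaResult:
    """Univariate two-way repeated-measures ANOVA on (n, a, b) data.

    Balanced within design, so Type III and Type I sums of squares
    coincide.  GG epsilon is applied to the effects named in ``gg_for``
    (computed from the covariance of that effect's repeated measures).
    """
    n, a, b = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    g = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    mAB = Y.mean(axis=0)

    def entry(ss_eff, df_eff, ss_err, df_err, M_for_eps, name):
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        eps = p_gg = None
        if name in gg_for:
            eps = gg_epsilon(M_for_eps)
            p_gg = (float(stats.f.sf(F, df_eff * eps, df_err * eps))
                    if np.isfinite(F) else 0.0)
        return EffectStats(float(F), df_eff, df_err, p, float(eta), eps, p_gg)

    effects: dict[str, EffectStats] = {}
    ss_A = n * b * np.sum((mA - g) ** 2)
    ss_AS = b * np.sum((mSA - mS[:, None] - mA[None, :] + g) ** 2)
    effects[names[0]] = entry(ss_A, a - 1, ss_AS, (a - 1) * (n - 1), mSA, names[0])

    ss_B = n * a * np.sum((mB - g) ** 2)
    ss_BS = a * np.sum((mSB - mS[:, None] - mB[None, :] + g) ** 2)
    effects[names[1]] = entry(ss_B, b - 1, ss_BS, (b - 1) * (n - 1), mSB, names[1])

    ss_AB = n * np.sum((mAB - mA[:, None] - mB[None, :] + g) ** 2)
    resid = (Y - mSA[:, :, None] - mSB[:, None, :] - mAB[None, :, :]
             + mS[:, None, None] + mA[None, :, None] + mB[None, None, :] - g)
    ss_ABS = np.sum(resid**2)
    # interaction sphericity is assessed on the per-subject B-contrast across A
    M_int = (Y[:, :, 0] - Y[:, :, 1]) if b == 2 else mSA
    effects[names[2]] = entry(ss_AB, (a - 1) * (b - 1), ss_ABS,
                              (a - 1) * (b - 1) * (n - 1), M_int, names[2])
    return AnovaResult(effects)


def rm_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """2x2 within-subject ANOVA of the effect table.

    Effects: Contingency, Extinction, and their interaction, each with
    df (1, n−1); with two levels per factor sphericity holds trivially.
    """
    cells, _ = _pivot_cells(table)
    Y = cells.reshape(-1, 2, 2)  # (n, contingency, extinction)
    return _two_way_rm(Y, names=("Contingency", "Extinction",
                                 "Contingency x Extinction"))


# ---------------------------------------------------------------------------
# Bayesian model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesResult:
    """BF10 per fixed-effect model vs the subject-only null."""

    bf10: dict[str, float]
    mc_error: dict[str, float]
    iterations: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"bf10": self.bf10, "mc_error_log10": self.mc_error,
                "iterations": self.iterations, "seed": self.seed}


def _design_columns(n_subj: int) -> dict[str, np.ndarray]:
    """Centred design columns for the 4-cell within design (long order:
    subject-major, cells in CELL_ORDER)."""
    c = np.tile([0.5, 0.5, -0.5, -0.5], n_subj)
    e = np.tile([0.5, -0.5, 0.5, -0.5], n_subj)
    ce = 2.0 * c * e
    # subject batch in an orthonormal sum-to-zero contrast basis (full
    # column rank, so the conditional system stays well-posed for any g)
    Q = np.linalg.qr(np.eye(n_subj) - 1.0 / n_subj)[0][:, : n_subj - 1]
    S = np.repeat(Q, 4, axis=0)
    return {"C": c[:, None], "E": e[:, None], "CxE": ce[:, None], "subject": S}


def _log_marginal_mc(y, batches, scales, iterations, rng, chunk: int = 1024):
    """log mean_g p(y|g) via MC over g, plus an MC standard error (log10).

    Conditional on g (flat μ, Jeffreys σ², effects integrated out):
    ``log p(y|g) = −½(log|A| + log|G|) − ((n−1)/2)·log(ỹ'ỹ − Xỹ'A⁻¹Xỹ)``
    with ``A = X'X + G⁻¹`` (up to a model-independent constant).  The g
    draws are processed in batched linear-algebra chunks.
    """
    n = len(y)
    ytil = y - y.mean()
    X = np.hstack(batches)
    XtX = X.T @ X
    Xty = X.T @ ytil
    yty = ytil @ ytil
    sizes = np.array([b.shape[1] for b in batches])
    p = int(sizes.sum())
    logp = np.empty(iterations)
    done = 0
    diag = np.arange(p)
    while done < iterations:
        m = min(chunk, iterations - done)
        gs = np.stack([r**2 / rng.chisquare(1, size=m) for r in scales], axis=1)
        gvec = np.repeat(gs, sizes, axis=1)  # (m, p)
        A = np.broadcast_to(XtX, (m, p, p)).copy()
        A[:, diag, diag] += 1.0 / gvec
        sol = np.linalg.solve(A, np.broadcast_to(Xty, (m, p))[..., None])[..., 0]
        quad = yty - sol @ Xty
        _, logdetA = np.linalg.slogdet(A)
        logp[done:done + m] = (-0.5 * (logdetA + np.log(gvec).sum(axis=1))
                               - 0.5 * (n - 1) * np.log(quad))
        done += m
    mx = logp.max()
    w = np.exp(logp - mx)
    logmean = mx + np.log(w.mean())
    # delta-method SE of log10(mean w)
    se = w.std(ddof=1) / (w.mean() * np.sqrt(iterations)) / np.log(10)
    return logmean, se


def bayes_model_comparison(table: pd.DataFrame, iterations: int = 100_000,
                           seed: int | None = None,
                           fixed_scale: float = 0.5,
                           random_scale: float = 1.0) -> BayesResult:
    """BF10 of the four fixed-effect structures vs the subject-only null.

    Models: C, E, C+E, C+E+CxE — every model (including the null)
    contains the subject random-effect batch.
    """
    cells, _ = _pivot_cells(table)
    if not np.all(np.isfinite(cells)):
        raise ValueError("non-finite values in effect table")
    n_subj = cells.shape[0]
    y = cells.reshape(-1)  # subject-major, CELL_ORDER within subject
    resid = cells - cells.mean(axis=0)
    if np.allclose(resid, 0.0):
        raise ValueError("degenerate effect table: zero between-subject "
                         "variability within cells")
    cols = _design_columns(n_subj)
    rng = np.random.default_rng(seed)

    log_m: dict[str, float] = {}
    errs: dict[str, float] = {}
    for name, terms in [("null", ()), *MODEL_TERMS.items()]:
        batches = [cols[t] for t in terms] + [cols["subject"]]
        scales = [fixed_scale] * len(terms) + [random_scale]
        log_m[name], errs[name] = _log_marginal_mc(y, batches, scales,
                                                   iterations, rng)
    bf10 = {name: float(np.exp(log_m[name] - log_m["null"]))
            for name in MODEL_TERMS}
    mc = {name: float(np.hypot(errs[name], errs["null"])) for name in MODEL_TERMS}
    return BayesResult(bf10, mc, iterations, seed)


def inclusion_bf(result: BayesResult) -> dict[str, float]:
    """Matched-model inclusion Bayes factors from the four model BFs.

    With equal prior model probabilities, posterior model probabilities
    are proportional to BF10 (null = 1).  Main effects compare the
    models containing the effect but no higher-order interaction with
    the same models stripped of it; the interaction compares the full
    model with the additive model.
    """
    bf = dict(result.bf10)
    missing = [m for m in MODEL_TERMS if m not in bf]
    if missing:
        raise ValueError(f"missing models in BayesResult: {missing}")
    return {
        "Contingency": (bf["C"] + bf["C+E"]) / (1.0 + bf["E"]),
        "Extinction": (bf["E"] + bf["C+E"]) / (1.0 + bf["C"]),
        "Contingency x Extinction": bf["C+E+CxE"] / bf["C+E"],
    }


def format_bf(value: float) -> str:
    """Reciprocal reporting for BFs below 1 (e.g. ``1 / 8.1``)."""
    if value >= 1.0:
        return f"{value:.1f}"
    return f"1 / {1.0 / value:.1f}"


# ---------------------------------------------------------------------------
# Distribution checks and within-subject error bars
# ---------------------------------------------------------------------------

SKEW_THRESHOLD = 2.0
KURT_THRESHOLD = 7.0


def distribution_check(table: pd.DataFrame) -> pd.DataFrame:
    """Sample skewness and excess kurtosis per condition cell.

    Cells whose |skewness| <= 2 and |excess kurtosis| <= 7 are flagged as
    acceptably normal for ANOVA purposes.  Constant cells yield NaN
    moments and a False flag rather than an error.
    """
    cells, _ = _pivot_cells(table)
    if cells.shape[0] < 8:
        raise ValueError("distribution check needs at least 8 subjects")
    rows = []
    for j, (cont, ext) in enumerate(CELL_ORDER):
        x = cells[:, j]
        if np.ptp(x) == 0:
            sk = ku = np.nan
        else:
            sk = float(stats.skew(x, bias=True))
            ku = float(stats.kurtosis(x, bias=True))  # excess
        ok = bool(np.isfinite(sk) and np.isfinite(ku)
                  and abs(sk) <= SKEW_THRESHOLD and abs(ku) <= KURT_THRESHOLD)
        rows.append((cont, ext, sk, ku, ok))
    return pd.DataFrame(rows, columns=["contingency", "extinction",
                                       "skewness", "kurtosis", "acceptable"])


def within_subject_sem(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell SEM from subject-centred values with Morey correction.

    Each subject's cell values are centred on that subject's own mean
    (grand mean restored); deviations are inflated by sqrt(k/(k−1)) with
    k = 4 cells, and the SEM is the cell SD over subjects divided by
    sqrt(n).
    """
    cells, _ = _pivot_cells(table)
    n, k = cells.shape
    centred = cells - cells.mean(axis=1, keepdims=True) + cells.mean()
    grand_cell = centred.mean(axis=0)
    corrected = grand_cell + np.sqrt(k / (k - 1)) * (centred - grand_cell)
    sem = corrected.std(axis=0, ddof=1) / np.sqrt(n)
    rows = [(cont, ext, float(cells[:, j].mean()), float(sem[j]))
            for j, (cont, ext) in enumerate(CELL_ORDER)]
    return pd.DataFrame(rows, columns=["contingency", "extinction",
                                       "mean_alpha_pct", "sem"])


# ---------------------------------------------------------------------------
# Block stability
# ---------------------------------------------------------------------------

def partition_blocks(n_trials: int, n_blocks: int = 4) -> list[np.ndarray]:
    """Sequential split into near-equal blocks, remainder to the earliest."""
    if n_trials < n_blocks:
        raise ValueError(f"cannot split {n_trials} trials into {n_blocks} blocks")
    base, extra = divmod(n_trials, n_blocks)
    sizes = [base + (1 if i < extra else 0) for i in range(n_blocks)]
    bounds = np.cumsum([0] + sizes)
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_blocks)]


def block_anova(blocked: pd.DataFrame) -> dict:
    """Block (4) x Contingency (2) RM-ANOVA plus per-block paired t-tests.

    ``blocked`` needs columns subject_id, block (1..4), contingency,
    alpha_pct (E/N members already averaged within contingency level).
    Greenhouse–Geisser correction is applied to Block-containing
    effects; follow-up t-tests are two-sided and uncorrected.
    """
    required = {"subject_id", "block", "contingency", "alpha_pct"}
    if not required.issubset(blocked.columns):
        raise ValueError(f"blocked table missing columns "
                         f"{required - set(blocked.columns)}")
    piv = blocked.pivot_table(index="subject_id",
                              columns=["block", "contingency"],
                              values="alpha_pct", aggfunc="mean")
    blocks = sorted(blocked["block"].unique())
    conts = ["CS+", "CS-"]
    full_cols = [(b, c) for b in blocks for c in conts]
    missing = [s for s in piv.index
               if piv.loc[s].reindex(full_cols).isna().any()]
    if missing:
        raise ValueError(f"subjects with missing block cells: {missing}")
    Y = piv.reindex(columns=full_cols).to_numpy(float)
    Y = Y.reshape(-1, len(blocks), 2)  # (n, block, contingency)
    res = _two_way_rm(Y, names=("Block", "Contingency", "Block x Contingency"),
                      gg_for=("Block", "Block x Contingency"))
    ttests = {}
    for bi, b in enumerate(blocks):
        t, p = stats.ttest_rel(Y[:, bi, 0], Y[:, bi, 1])
        ttests[int(b)] = {"t": float(t), "df": Y.shape[0] - 1, "p": float(p)}
    return {"anova": res, "per_block_t": ttests}
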