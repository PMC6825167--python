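"""Repeated-measures ANOVA, Bayes factors, SEM, and block stability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alphacond import (bayes_model_comparison, block_anova,
                       distribution_check, inclusion_bf, rm_anova_2x2,
                       within_subject_sem)
from alphacond.inference import (BayesResult, format_bf, gg_epsilon,
                                 partition_blocks)

CELLS = [("CS+", "E"), ("CS+", "N"), ("CS-", "E"), ("CS-", "N")]


def make_table(values: np.ndarray) -> pd.DataFrame:
    """(n_subjects, 4) cell matrix -> long effect table."""
    rows = []
    for s, row in enumerate(values):
        for (c, e), v in zip(CELLS, row):
            rows.append((f"S{s:02d}", c, e, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "contingency",
                                       "extinction", "alpha_pct"])


def anova_oracle(values: np.ndarray) -> dict:
    """Longhand textbook sums-of-squares decomposition (explicit loops)."""
    n = values.shape[0]
    Y = values.reshape(n, 2, 2)
    grand = Y.mean()
    out = {}
    for name, lev in [("Contingency", 0), ("Extinction", 1)]:
        m = Y.mean(axis=(0, 2 - lev))  # (2,) factor means
        ss_eff = n * 2 * sum((m[i] - grand) ** 2 for i in range(2))
        ss_err = 0.0
        for s in range(n):
            for i in range(2):
                cell = Y[s, i, :].mean() if lev == 0 else Y[s, :, i].mean()
                ss_err += 2 * (cell - Y[s].mean() - m[i] + grand) ** 2
        out[name] = (ss_eff / 1) / (ss_err / (n - 1))
    # interaction
    mA, mB = Y.mean(axis=(0, 2)), Y.mean(axis=(0, 1))
    mAB = Y.mean(axis=0)
    ss_int = n * sum((mAB[i, j] - mA[i] - mB[j] + grand) ** 2
                     for i in range(2) for j in range(2))
    ss_err = 0.0
    for s in range(n):
        for i in range(2):
            for j in range(2):
                pred = (Y[s, i, :].mean() + Y[s, :, j].mean() + mAB[i, j]
                        - Y[s].mean() - mA[i] - mB[j] + grand)
                ss_err += (Y[s, i, j] - pred) ** 2
    out["Contingency x Extinction"] = ss_int / (ss_err / (n - 1))
    return out


# ---------------------------------------------------------------------------
# frequentist ANOVA
# ---------------------------------------------------------------------------

def test_identical_cells_give_zero_F():
    values = np.tile(np.array([[1.0, 1.0, 1.0, 1.0]]), (5, 1))
    values += np.arange(5)[:, None]  # subject offsets only
    res = rm_anova_2x2(make_table(values))
    for e in res.effects.values():
        assert e.F == 0.0


def test_anova_matches_longhand_ss_oracle_across_100_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(100):
        values = rng.standard_normal((5, 4)) * 10 + rng.standard_normal((5, 1)) * 5
        res = rm_anova_2x2(make_table(values))
        oracle = anova_oracle(values)
        for name, f_oracle in oracle.items():
            assert abs(res.effects[name].F - f_oracle) < 1e-8


def test_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    values = rng.standard_normal((12, 4))
    values[:, :2] -= 1.0
    table = make_table(values)
    mine = rm_anova_2x2(table)
    theirs = pg.rm_anova(table, dv="alpha_pct",
                         within=["contingency", "extinction"],
                         subject="subject_id", detailed=True)
    for name, src in [("Contingency", "contingency"),
                      ("Extinction", "extinction"),
                      ("Contingency x Extinction", "contingency * extinction")]:
        f_pg = float(theirs.loc[theirs["Source"] == src, "F"].iloc[0])
        assert mine.effects[name].F == pytest.approx(f_pg, rel=1e-9)


def test_partial_eta_squared_identity():
    rng = np.random.default_rng(1)
    res = rm_anova_2x2(make_table(rng.standard_normal((10, 4))))
    for e in res.effects.values():
        assert e.eta_p2 == pytest.approx(e.F / (e.F + e.df2), rel=1e-10)


def test_missing_cell_reported_with_subject():
    table = make_table(np.random.default_rng(0).standard_normal((4, 4)))
    table = table.drop(table.index[5])
    with pytest.raises(ValueError, match="S01"):
        rm_anova_2x2(table)


def test_anova_type1_error_within_binomial_ci():
    """Gaussian null tables: Contingency rejections near the nominal 5%."""
    rng = np.random.default_rng(9)
    n_rep, hits = 400, 0
    for _ in range(n_rep):
        values = rng.standard_normal((20, 4)) + rng.standard_normal((20, 1))
        res = rm_anova_2x2(make_table(values))
        hits += res.effects["Contingency"].p < 0.05
    rate = hits / n_rep
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
    assert 0.05 - half <= rate <= 0.05 + half


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def test_null_tables_rarely_reach_bf_three():
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        values = rng.standard_normal((24, 4)) + rng.standard_normal((24, 1))
        b = bayes_model_comparison(make_table(values), iterations=4000,
                                   seed=rep)
        hits += all(v < 3.0 for v in b.bf10.values())
    assert hits >= 90


def test_contingency_effect_makes_contingency_models_dominate():
    rng = np.random.default_rng(7)
    values = rng.standard_normal((24, 4)) + rng.standard_normal((24, 1))
    values[:, :2] -= 2.0  # CS+ cells suppressed
    b = bayes_model_comparison(make_table(values), iterations=10_000, seed=1)
    assert b.bf10["C"] > b.bf10["E"]
    assert b.bf10["C+E"] > b.bf10["E"]
    incl = inclusion_bf(b)
    assert incl["Contingency"] > 3.0


def test_bayes_determinism_and_mc_error():
    rng = np.random.default_rng(2)
    table = make_table(rng.standard_normal((10, 4)))
    a = bayes_model_comparison(table, iterations=2000, seed=42)
    b = bayes_model_comparison(table, iterations=2000, seed=42)
    assert a.bf10 == b.bf10
    assert all(err > 0 for err in a.mc_error.values())


def test_degenerate_table_rejected():
    values = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1))  # no subject variability
    with pytest.raises(ValueError, match="degenerate"):
        bayes_model_comparison(make_table(values), iterations=100, seed=0)


def test_inclusion_bf_arithmetic():
    flat = BayesResult({"C": 1.0, "E": 1.0, "C+E": 1.0, "C+E+CxE": 1.0},
                       {}, 0)
    assert all(v == pytest.approx(1.0) for v in inclusion_bf(flat).values())
    b = BayesResult({"C": 10.0, "E": 1.0, "C+E": 10.0, "C+E+CxE": 10.0}, {}, 0)
    incl = inclusion_bf(b)
    assert incl["Contingency"] == pytest.approx(10.0)  # (10+10)/(1+1)
    assert incl["Contingency x Extinction"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="missing"):
        inclusion_bf(BayesResult({"C": 1.0}, {}, 0))


def test_bf_reciprocal_reporting_convention():
    assert format_bf(26.0) == "26.0"
    assert format_bf(1 / 8.1) == "1 / 8.1"


# ---------------------------------------------------------------------------
# distribution check and within-subject SEM
# ---------------------------------------------------------------------------

def test_distribution_check_normal_and_exponential_cells():
    rng = np.random.default_rng(0)
    n = 100_000
    values = np.c_[rng.standard_normal((n, 1)),
                   rng.exponential(size=(n, 1)),
                   rng.standard_normal((n, 2))]
    chk = distribution_check(make_table(values))
    normal = chk.iloc[0]
    assert abs(normal["skewness"]) < 0.05 and abs(normal["kurtosis"]) < 0.05
    assert bool(normal["acceptable"])
    expo = chk.iloc[1]
    assert expo["skewness"] == pytest.approx(2.0, abs=0.1)


def test_distribution_check_constant_cell_flagged_not_crash():
    rng = np.random.default_rng(1)
    values = rng.standard_normal((10, 4))
    values[:, 2] = 5.0
    chk = distribution_check(make_table(values))
    row = chk.iloc[2]
    assert np.isnan(row["skewness"]) and not bool(row["acceptable"])


def test_within_subject_sem_zero_when_offsets_identical():
    base = np.array([1.0, -2.0, 0.5, 0.5])
    values = base[None, :] + np.arange(6)[:, None] * 3.0
    sem = within_subject_sem(make_table(values))
    assert np.allclose(sem["sem"], 0.0, atol=1e-12)


def test_within_subject_sem_matches_longhand():
    rng = np.random.default_rng(5)
    values = rng.standard_normal((3, 4))
    sem = within_subject_sem(make_table(values))
    centred = values - values.mean(axis=1, keepdims=True) + values.mean()
    k = 4
    expected = (np.sqrt(k / (k - 1)) * centred.std(axis=0, ddof=1)
                / np.sqrt(values.shape[0]))
    assert np.allclose(sem["sem"], expected, atol=1e-12)


def test_within_subject_sem_invariant_to_subject_constants():
    rng = np.random.default_rng(6)
    values = rng.standard_normal((8, 4))
    a = within_subject_sem(make_table(values))
    b = within_subject_sem(make_table(values + rng.standard_normal((8, 1)) * 50))
    assert np.allclose(a["sem"], b["sem"], atol=1e-10)


# ---------------------------------------------------------------------------
# block stability
# ---------------------------------------------------------------------------

def make_block_table(Y: np.ndarray) -> pd.DataFrame:
    rows = []
    for s in range(Y.shape[0]):
        for b in range(Y.shape[1]):
            for ci, c in enumerate(["CS+", "CS-"]):
                rows.append((f"S{s:02d}", b + 1, c, float(Y[s, b, ci])))
    return pd.DataFrame(rows, columns=["subject_id", "block", "contingency",
                                       "alpha_pct"])


def test_gg_epsilon_trivial_for_two_levels():
    rng = np.random.default_rng(0)
    assert gg_epsilon(rng.standard_normal((20, 2))) == 1.0


def test_gg_epsilon_near_one_under_compound_symmetry():
    rng = np.random.default_rng(1)
    n, k = 4000, 4
    subj = rng.standard_normal((n, 1)) * 2.0
    M = subj + rng.standard_normal((n, k))
    assert gg_epsilon(M) == pytest.approx(1.0, abs=0.02)


def test_partition_blocks_remainder_to_earliest():
    sizes = [len(b) for b in partition_blocks(23, 4)]
    assert sizes == [6, 6, 6, 5]
    assert max(sizes) - min(sizes) <= 1
    blocks = partition_blocks(8, 4)
    assert [list(b) for b in blocks] == [[0, 1], [2, 3], [4, 5], [6, 7]]
    with pytest.raises(ValueError, match="cannot split"):
        partition_blocks(3, 4)


def test_block_anova_structure_and_gg():
    rng = np.random.default_rng(2)
    Y = rng.standard_normal((15, 4, 2))
    Y[:, :, 0] -= 1.0  # stable contingency effect
    res = block_anova(make_block_table(Y))
    eff = res["anova"].effects
    assert eff["Contingency"].gg_epsilon is None  # two levels: no correction
    assert 0 < eff["Block"].gg_epsilon <= 1.0
    assert 0 < eff["Block x Contingency"].gg_epsilon <= 1.0
    assert eff["Contingency"].p < 0.01
    assert set(res["per_block_t"]) == {1, 2, 3, 4}
    for r in res["per_block_t"].values():
        assert r["df"] == 14
        t, p = r["t"], r["p"]
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 14), rel=1e-9)


def test_block_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    Y = rng.standard_normal((10, 4, 2))
    table = make_block_table(Y)
    mine = block_anova(table)["anova"].effects
    theirs = pg.rm_anova(table, dv="alpha_pct",
                         within=["block", "contingency"],
                         subject="subject_id", detailed=True)
    for name, src in [("Block", "block"), ("Contingency", "contingency"),
                      ("Block x Contingency", "block * contingency")]:
        f_pg = float(theirs.loc[theirs["Source"] == src, "F"].iloc[0])
        assert mine[name].F == pytest.approx(f_pg, rel=1e-9)


def test_block_anova_missing_cells_rejected():
    rng = np.random.default_rng(5)
    table = make_block_table(rng.standard_normal((5, 4, 2)))
    with pytest.raises(ValueError, match="S02"):
        block_anova(table.drop(table.index[17]))
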