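import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pharmacoscape as ps
from pharmacoscape.association import (
    ScanConfig,
    bh_fdr,
    cross_study_validate,
    downsample_experiment,
    effect_sizes,
    fit_association,
    run_scan,
)

from conftest import make_matrix


def make_responses(y, drug="D1", samples=None, max_conc=10.0):
    samples = samples or [f"S{i + 1}" for i in range(len(y))]
    ln = pd.DataFrame({drug: np.asarray(y, dtype=float)}, index=samples)
    return ps.DrugResponseTable(ln, None, pd.Series({drug: max_conc}))


# -- effect sizes -----------------------------------------------------------

def test_effect_sizes_identical_groups_are_zero():
    d, gp, gn = effect_sizes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (d, gp, gn) == (0.0, 0.0, 0.0)


def test_effect_sizes_hand_arithmetic():
    # means 2 vs 4, each sd 1, pooled sd 1
    d, gp, gn = effect_sizes([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
    assert d == pytest.approx(-2.0)
    assert gp == pytest.approx(2.0)
    assert gn == pytest.approx(2.0)


@pytest.mark.parametrize("shift,scale", [(5.0, 1.0), (0.0, 3.0), (-2.0, 0.5)])
def test_effect_sizes_affine_invariance(shift, scale):
    rng = np.random.default_rng(0)
    pos, neg = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
    base = effect_sizes(pos, neg)
    moved = effect_sizes(pos * scale + shift, neg * scale + shift)
    assert moved == pytest.approx(base)


def test_effect_sizes_zero_variance_group_is_nan():
    d, gp, gn = effect_sizes([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
    assert np.isnan(gp) and gn > 0


# -- BH FDR -----------------------------------------------------------------

def test_bh_fdr_step_up_hand_example():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_fdr_single_p():
    assert bh_fdr([0.2]) == pytest.approx([0.2])


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bh_fdr_is_monotone_in_p_ranking(p):
        q = bh_fdr(np.array(p))
        order = np.argsort(p, kind="stable")
        assert all(q[order[i]] <= q[order[i + 1]] + 1e-12
                   for i in range(len(p) - 1))
        assert np.all((q >= np.array(p) - 1e-12) & (q <= 1.0))
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_bh_fdr_matches_literal_step_up_reference():
    def reference(p):
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(n)
        running = np.inf
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            q[i] = min(running, 1.0)
        return q

    rng = np.random.default_rng(1)
    for _ in range(300):
        p = rng.random(rng.integers(1, 40))
        assert bh_fdr(p) == pytest.approx(reference(p), rel=1e-12)


# -- single-test ANOVA ------------------------------------------------------

def test_f_test_equals_two_sample_t_test_without_covariates():
    rng = np.random.default_rng(2)
    y = rng.normal(0, 1, 60)
    x = (rng.random(60) < 0.4).astype(float)
    p_ours = fit_association(y, x)
    p_t = stats.ttest_ind(y[x == 1], y[x == 0], equal_var=True).pvalue
    assert p_ours == pytest.approx(p_t, rel=1e-10)


def test_null_p_values_are_uniform():
    rng = np.random.default_rng(3)
    pvals = []
    for _ in range(1000):
        y = rng.normal(0, 1, 200)
        x = (rng.random(200) < 0.3).astype(float)
        cov = pd.DataFrame({"ct": rng.choice(["a", "b", "c"], 200)})
        pvals.append(fit_association(y, x, cov))
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_cfe_confounded_with_tissue_returns_nan():
    y = np.random.default_rng(4).normal(0, 1, 40)
    ct = np.array(["a"] * 20 + ["b"] * 20)
    x = (ct == "a").astype(float)  # identical to the tissue indicator
    assert np.isnan(fit_association(y, x, pd.DataFrame({"ct": ct})))


# -- scans ------------------------------------------------------------------

def test_single_test_scan_fdr_equals_p():
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, 30)
    x = np.zeros((30, 1))
    x[:10, 0] = 1.0
    m = make_matrix(x, cfe_ids=["A"])
    table = run_scan(make_responses(y, samples=m.sample_ids), m)
    assert len(table.results) == 1
    row = table.results.iloc[0]
    assert row.fdr == pytest.approx(row.p_value)


def test_planted_effect_is_flagged_significant_and_large():
    rng = np.random.default_rng(6)
    n = 300
    x = np.zeros((n, 5))
    x[:30, 0] = 1.0
    x[:, 1:] = (rng.random((n, 4)) < 0.2).astype(float)
    y = rng.normal(0, 1, n) - 2.0 * x[:, 0]
    m = make_matrix(x, cfe_ids=[f"F{j}" for j in range(5)])
    table = run_scan(make_responses(y, samples=m.sample_ids), m)
    row = table.results.set_index("cfe_id").loc["F0"]
    assert row.significant and row.large_effect
    assert row.direction == "sensitizing"
    assert row.n_pos == 30 and row.n_neg == 270


def test_scan_results_independent_of_input_ordering():
    rng = np.random.default_rng(7)
    n = 60
    x = (rng.random((n, 6)) < 0.3).astype(float)
    y = rng.normal(0, 1, n) - x[:, 2]
    m = make_matrix(x, cfe_ids=[f"F{j}" for j in range(6)])
    resp = make_responses(y, samples=m.sample_ids)
    base = run_scan(resp, m).results
    perm_rows = list(rng.permutation(m.sample_ids))
    perm_cols = list(rng.permutation(m.cfe_ids))
    m2 = ps.AlterationMatrix(m.values.loc[perm_rows, perm_cols],
                             m.annotations.loc[perm_rows])
    shuffled = run_scan(resp, m2).results
    pd.testing.assert_frame_equal(base, shuffled)


def test_scan_fast_and_generic_paths_agree():
    """Injecting a NaN forces a column down the per-test path; on the
    complete rows both paths must give identical statistics."""
    rng = np.random.default_rng(8)
    n = 80
    x = (rng.random((n, 3)) < 0.4).astype(float)
    y = rng.normal(0, 1, n) - x[:, 0]
    types = rng.choice(["a", "b"], n)
    m_full = make_matrix(x, cfe_ids=["F0", "F1", "F2"], cancer_types=types)
    resp = make_responses(y, samples=m_full.sample_ids)
    vals = m_full.values.copy()
    dropped = vals.index[5]
    vals.loc[dropped, "F0"] = np.nan
    m_nan = ps.AlterationMatrix(vals, m_full.annotations)
    res_nan = run_scan(resp, m_nan).results.set_index("cfe_id")
    # oracle: run the complete-case scan with that sample removed entirely
    m_sub = m_full.subset_samples([s for s in m_full.sample_ids if s != dropped])
    res_sub = run_scan(resp, m_sub).results.set_index("cfe_id")
    for col in ("p_value", "cohens_d", "glass_pos", "glass_neg", "n_pos"):
        assert res_nan.loc["F0", col] == pytest.approx(res_sub.loc["F0", col])


def test_group_size_gate_records_skip():
    y = np.random.default_rng(9).normal(0, 1, 20)
    x = np.zeros((20, 1))
    x[0, 0] = 1.0  # only one carrier
    m = make_matrix(x, cfe_ids=["A"])
    table = run_scan(make_responses(y, samples=m.sample_ids), m)
    assert len(table.results) == 0
    assert table.skipped[0][2] == "group size below minimum"


def test_cancer_specific_scan_requires_enough_lines():
    x = np.zeros((10, 1))
    m = make_matrix(x, cfe_ids=["A"])
    resp = make_responses(np.zeros(10), samples=m.sample_ids)
    with pytest.raises(ValueError, match="> 15"):
        run_scan(resp, m, "cancer_specific", "CT01")


# -- downsampling -----------------------------------------------------------

@pytest.fixture(scope="module")
def planted_scan():
    rng = np.random.default_rng(10)
    n = 240
    x = (rng.random((n, 10)) < 0.25).astype(float)
    y = rng.normal(0, 1, n) - 1.5 * x[:, 0] + 1.2 * x[:, 1]
    m = make_matrix(x, cfe_ids=[f"F{j}" for j in range(10)])
    return make_responses(y, samples=m.sample_ids), m


def test_downsample_size_validation(planted_scan):
    resp, m = planted_scan
    with pytest.raises(ValueError, match=">="):
        downsample_experiment(resp, m, sizes=[240], reps=1)


def test_downsample_deterministic_and_monotone(planted_scan):
    resp, m = planted_scan
    r1 = downsample_experiment(resp, m, sizes=[200, 100, 40], reps=20, seed=0)
    r2 = downsample_experiment(resp, m, sizes=[200, 100, 40], reps=20, seed=0)
    pd.testing.assert_frame_equal(r1, r2)
    means = r1.groupby("size")["sig_retention"].mean()
    # retention decreases (in expectation) as the cohort shrinks
    assert means[200] >= means[100] >= means[40]
    assert means[200] > 0.9


# -- cross-study validation -------------------------------------------------

def test_cross_study_self_comparison(planted_scan):
    resp, m = planted_scan
    table = run_scan(resp, m)
    r, v_sens, v_res, fet_p = cross_study_validate(table, table)
    assert r == pytest.approx(1.0)
    assert v_sens == 1.0 and v_res == 1.0


def test_cross_study_sign_flip_gives_negative_correlation(planted_scan):
    resp, m = planted_scan
    table = run_scan(resp, m)
    flipped_resp = make_responses(-resp.ln_ic50["D1"].to_numpy(),
                                  samples=list(resp.ln_ic50.index))
    flipped = run_scan(flipped_resp, m)
    r, v_sens, _, _ = cross_study_validate(table, flipped)
    assert r < -0.9
    assert v_sens == 0.0  # directions disagree everywhere


def test_cross_study_requires_overlap(planted_scan):
    resp, m = planted_scan
    table = run_scan(resp, m)
    empty = ps.AssociationTable(table.results.iloc[:2], "pan_cancer")
    with pytest.raises(ValueError, match="shared"):
        cross_study_validate(table, empty)
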