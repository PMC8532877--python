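"""FPKM, correlations, size factors, NB Wald test, BH, DE bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from capriseq.quant import (CountMatrix, bh_adjust, call_de, compute_fpkm,
                            correlation_matrix, nb_wald_test, set_overlap,
                            size_factors)
from capriseq.simdata import SimConfig, sim_counts


def _cm(counts, lengths=None, groups=None):
    counts = pd.DataFrame(counts)
    lengths = pd.Series(lengths if lengths is not None else 1000,
                        index=counts.index, dtype=float)
    if groups is None:
        half = counts.shape[1] // 2
        groups = pd.Series(["LD"] * half + ["BF"] * (counts.shape[1] - half),
                           index=counts.columns)
    return CountMatrix(counts, lengths, groups)


# -------------------------------------------------------------------- FPKM

def test_fpkm_formula():
    cm = _cm({"s1": [100, 0], "s2": [100, 1_999_900]},
             lengths=[2000, 1000])
    fpkm = compute_fpkm(cm)
    # count 100, length 2 kb, library 2e6 -> 100 / 2 / 2 = 25
    assert fpkm.loc[0, "s2"] == pytest.approx(25.0)
    assert fpkm.loc[1, "s1"] == 0.0


def test_fpkm_scale_invariance_per_sample():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                          columns=list("abcd"))
    cm1 = _cm(counts)
    cm2 = _cm(counts * 2)
    pd.testing.assert_frame_equal(compute_fpkm(cm1), compute_fpkm(cm2))


def test_fpkm_rejects_zero_library():
    with pytest.raises(ValueError):
        compute_fpkm(_cm({"s1": [0, 0], "s2": [1, 2]}))


def test_count_matrix_validation():
    with pytest.raises(ValueError):
        _cm({"s1": [-1, 2], "s2": [1, 2]})
    with pytest.raises(ValueError):
        _cm({"s1": [1, 2], "s2": [1, 2]}, lengths=[0, 100])


# ------------------------------------------------------------- correlation

def test_correlation_symmetric_unit_diagonal():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.random((100, 4)), columns=list("abcd"))
    expr["b2"] = expr["a"]
    r = correlation_matrix(expr)
    assert np.allclose(np.diag(r), 1.0)
    assert np.allclose(r, r.T)
    assert r.loc["a", "b2"] == pytest.approx(1.0)


def test_correlation_constant_column_flagged():
    expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.warns(RuntimeWarning):
        r = correlation_matrix(expr)
    assert np.isnan(r.loc["a", "b"])


def test_within_group_correlation_exceeds_between_group():
    cfg = SimConfig(seed=23, de_fraction=0.4, lfc_magnitude=4.0,
                    nb_dispersion=0.02, n_samples_per_group=4)
    counts, lengths, groups, _ = sim_counts(cfg, n_genes=3000)
    fpkm = compute_fpkm(CountMatrix(counts, lengths, groups))
    r = correlation_matrix(np.log1p(fpkm))
    ld = groups.index[groups == "LD"]
    bf = groups.index[groups == "BF"]
    within = min(r.loc[a, b] for g in (ld, bf)
                 for i, a in enumerate(g) for b in g[i + 1:])
    between = max(r.loc[a, b] for a in ld for b in bf)
    assert within > between


# ------------------------------------------------------------ size factors

def test_identical_columns_have_unit_factors():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
    assert np.allclose(size_factors(counts), 1.0)


def test_scaled_column_factor_doubles():
    rng = np.random.default_rng(2)
    base = rng.integers(1, 500, size=200)
    counts = pd.DataFrame({"a": base, "b": base * 2})
    f = size_factors(counts)
    assert f["b"] / f["a"] == pytest.approx(2.0)


def test_size_factors_recover_simulated_depths():
    cfg = SimConfig(seed=24, de_fraction=0.0, nb_dispersion=0.02,
                    n_samples_per_group=4, depth_range=(0.6, 1.6))
    sim = sim_counts(cfg, n_genes=4000)
    f = size_factors(sim.counts).to_numpy()
    # factors are defined up to a common scale; compare geometric-centered
    ratio = f / sim.depth.to_numpy()
    ratio /= np.exp(np.mean(np.log(ratio)))
    assert np.all(np.abs(ratio - 1.0) < 0.05)


def test_size_factor_fallback_warns():
    counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
    with pytest.warns(RuntimeWarning):
        f = size_factors(counts)
    assert np.allclose(f, 1.0)


# ---------------------------------------------------------------------- BH

def test_bh_matches_hand_computation():
    padj = bh_adjust([0.01, 0.02, 0.04, 0.05])
    assert np.allclose(padj, [0.04, 0.04, 0.05, 0.05])


def test_bh_degenerate_cases():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert bh_adjust([0.037]) == pytest.approx([0.037])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
def test_bh_equals_reference_step_up(pvals):
    from statsmodels.stats.multitest import multipletests
    ours = bh_adjust(pvals)
    ref = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, ref)
    assert np.all(ours >= np.asarray(pvals) - 1e-12)


# ------------------------------------------------------------------- DE

@pytest.fixture(scope="module")
def null_counts():
    cfg = SimConfig(seed=11, de_fraction=0.0, nb_dispersion=0.05,
                    n_samples_per_group=4)
    counts, lengths, groups, _ = sim_counts(cfg, n_genes=5000)
    return CountMatrix(counts, lengths, groups)


def test_nb_wald_type_one_error_controlled(null_counts):
    res = nb_wald_test(null_counts)
    p = res["p_value"].dropna()
    rate = (p < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_nb_wald_recall_and_fdr_on_strong_effects():
    cfg = SimConfig(seed=12, de_fraction=0.1, lfc_magnitude=3.0,
                    nb_dispersion=0.05, n_samples_per_group=4)
    counts, lengths, groups, truth = sim_counts(cfg, n_genes=2000)
    cm = CountMatrix(counts, lengths, groups)
    res = nb_wald_test(cm)
    called = call_de(res, compute_fpkm(cm))
    de = called["is_de"]
    recall = (de & truth["is_de"]).sum() / truth["is_de"].sum()
    fdr = (de & ~truth["is_de"]).sum() / max(int(de.sum()), 1)
    assert recall >= 0.8
    assert fdr <= 0.1


def test_swapping_groups_flips_every_fold_change(null_counts):
    res = nb_wald_test(null_counts)
    flipped_groups = null_counts.groups.map({"LD": "BF", "BF": "LD"})
    cm2 = CountMatrix(null_counts.counts, null_counts.lengths, flipped_groups)
    res2 = nb_wald_test(cm2)
    assert np.allclose(res["log2_fold_change"], -res2["log2_fold_change"])
    assert np.allclose(res["p_value"].dropna(), res2["p_value"].dropna())


def test_all_zero_group_is_skipped():
    counts = pd.DataFrame({"LD_1": [0, 5], "LD_2": [0, 6],
                           "BF_1": [4, 5], "BF_2": [6, 7]})
    cm = _cm(counts)
    res = nb_wald_test(cm, factors=pd.Series(1.0, index=counts.columns))
    assert bool(res["skipped"].iloc[0]) and np.isnan(res["p_value"].iloc[0])
    assert not res["skipped"].iloc[1]


def test_call_de_thresholds():
    res = pd.DataFrame({
        "log2_fold_change": [1.5, 0.5, -2.0, -2.0],
        "padj": [0.01, 0.001, 0.2, 0.01]})
    fpkm = pd.DataFrame({"s1": [5.0, 5.0, 5.0, 0.0], "s2": [5.0, 5.0, 5.0, 0.0]})
    out = call_de(res, fpkm)
    assert out["is_de"].tolist() == [True, False, False, False]
    assert out["direction"].tolist() == ["up", "", "", ""]


def test_up_down_partition_the_de_set():
    rng = np.random.default_rng(7)
    res = pd.DataFrame({
        "log2_fold_change": rng.normal(0, 2, 300),
        "padj": rng.random(300) * 0.1})
    fpkm = pd.DataFrame({"s": np.ones(300)})
    out = call_de(res, fpkm)
    n_up = (out["direction"] == "up").sum()
    n_down = (out["direction"] == "down").sum()
    assert n_up + n_down == out["is_de"].sum()


# ------------------------------------------------------------ set overlap

def test_set_overlap_two_sets():
    df = set_overlap({"A": {1, 2, 3}, "B": {2, 3, 4}}).set_index("set")
    assert df.loc["A&B", "size"] == 2
    assert df.loc["A", "exclusive"] == 1
    assert df.loc["B", "exclusive"] == 1
    assert df.loc["union", "size"] == 4


def test_set_overlap_disjoint_and_oracle():
    rng = np.random.default_rng(9)
    assert set_overlap({"A": {1}, "B": {2}}).set_index("set").loc["A&B", "size"] == 0
    for _ in range(50):
        a = set(rng.integers(0, 100, size=rng.integers(0, 50)).tolist())
        b = set(rng.integers(0, 100, size=rng.integers(0, 50)).tolist())
        df = set_overlap({"A": a, "B": b}).set_index("set")
        assert df.loc["union", "size"] == len(a | b)
        assert df.loc["A&B", "size"] == len(a & b)
        assert df.loc["A", "exclusive"] + df.loc["B", "exclusive"] \
            + df.loc["A&B", "size"] == len(a | b)
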