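import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panitg.cohort import TUMOR, OmicsCohort
from panitg.expression import (
    bh_fdr,
    coexpression_matrix,
    connectivity_matrix,
    differential_expression,
    enrichment_score,
    enrichment_test,
    jaccard_index,
    log2_fold_change,
)


# -- BH FDR ----------------------------------------------------------------

def brute_force_bh(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)


def test_bh_matches_brute_force_and_is_order_invariant():
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        q = bh_fdr(p)
        assert np.allclose(q, brute_force_bh(p), atol=1e-12)
        perm = rng.permutation(p.size)
        assert np.allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)
        assert (q >= p - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


# -- fold change and DE ------------------------------------------------------

def test_log2_fold_change_exact(tiny_cohort):
    expr = tiny_cohort.expression.copy()
    tumor = list(tiny_cohort.tumor_samples)
    normal = list(tiny_cohort.normal_samples)
    expr.loc["G1"] = [5.0] * 10
    assert log2_fold_change(expr, tumor, normal, "G1") == 0.0
    expr.loc["G1", tumor] = 6.0  # doubling on the linear scale
    assert log2_fold_change(expr, tumor, normal, "G1") == pytest.approx(1.0)
    # independent summation oracle on random values
    rng = np.random.default_rng(1)
    vals = rng.normal(size=10)
    expr.loc["G2"] = vals
    oracle = sum(vals[:5]) / 5 - sum(vals[5:]) / 5
    assert log2_fold_change(expr, tumor, normal, "G2") == pytest.approx(oracle)
    with pytest.raises(KeyError):
        log2_fold_change(expr, tumor, normal, "NOPE")
    with pytest.raises(ValueError):
        log2_fold_change(expr, [], normal, "G1")


def test_de_requires_both_conditions(tiny_cohort):
    """A big fold change with a non-significant p stays 'ns' at tiny n."""
    expr = tiny_cohort.expression.copy()
    tumor = list(tiny_cohort.tumor_samples)
    # big mean shift driven by one outlier: rank test stays non-significant
    expr.loc["G3", tumor] = expr.loc["G3", tiny_cohort.normal_samples].to_numpy()
    expr.loc["G3", tumor[0]] += 40.0
    cohort = OmicsCohort("TINY", expr, tiny_cohort.sample_type)
    de = differential_expression(cohort).set_index("gene")
    assert abs(de.loc["G3", "log2fc"]) >= 1.0
    assert de.loc["G3", "direction"] == "ns"


def test_de_insufficient_samples(tiny_cohort):
    st_small = tiny_cohort.sample_type.copy()
    st_small.iloc[5:8] = TUMOR  # leaves 2 normals
    cohort = OmicsCohort("TINY", tiny_cohort.expression, st_small)
    with pytest.raises(ValueError, match="insufficient"):
        differential_expression(cohort)


# -- enrichment score ---------------------------------------------------------

def exhaustive_es(ranked, gene_set, w=1.0):
    """Prefix-sum oracle: walk the list, track every partial sum."""
    hits = [g in set(gene_set) for g in ranked.index]
    stats_abs = [abs(v) ** w for v in ranked.to_numpy()]
    nh = sum(hits)
    nm = len(hits) - nh
    denom = sum(s for s, h in zip(stats_abs, hits) if h)
    if denom == 0:
        denom = nh
        stats_abs = [1.0] * len(hits)
    run = 0.0
    prefix = []
    for s, h in zip(stats_abs, hits):
        run += s / denom if h else -1.0 / nm
        prefix.append(run)
    mx, mn = max(prefix), min(prefix)
    # same tie convention as the implementation: positive deviation wins
    return mx if mx >= -mn - 1e-12 else mn


def test_es_extremes_and_symmetry():
    ranked = pd.Series(np.linspace(3, -3, 10), index=[f"g{i}" for i in range(10)])
    es_top, _ = enrichment_score(ranked, {"g0", "g1"})
    assert es_top > 0.7
    # reversing the ranking flips the sign for an end-concentrated set
    reverse = ranked.iloc[::-1]
    es_rev, _ = enrichment_score(reverse, {"g0", "g1"})
    assert es_rev < 0
    with pytest.raises(ValueError):
        enrichment_score(ranked, set(ranked.index))
    with pytest.raises(ValueError):
        enrichment_score(ranked, set())


def test_es_matches_exhaustive_oracle_small_universes():
    rng = np.random.default_rng(5)
    from itertools import combinations

    for n in range(4, 11):
        genes = [f"g{i}" for i in range(n)]
        stats_vec = np.sort(rng.normal(size=n))[::-1]
        ranked = pd.Series(stats_vec, index=genes)
        for size in (1, 2, 3):
            for combo in combinations(genes, size):
                es, _ = enrichment_score(ranked, combo)
                assert es == pytest.approx(exhaustive_es(ranked, combo),
                                           abs=1e-12)


def test_enrichment_test_detects_planted_signal(planted_cohort):
    cohort, _ = planted_cohort
    res = enrichment_test(cohort, ["ITGA11"], n_perm=99, seed=1)
    assert res.es > 0
    assert res.perm_p <= 0.05
    res2 = enrichment_test(cohort, ["ITGA11"], n_perm=99, seed=1)
    assert res2.perm_p == res.perm_p  # determinism
    with pytest.raises(ValueError):
        enrichment_test(cohort, ["ITGA11"], n_perm=5)


# -- jaccard / connectivity / co-expression -----------------------------------

def test_jaccard_examples():
    assert jaccard_index({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
    assert jaccard_index({"A"}, {"A"}) == 1.0
    assert jaccard_index({"A"}, {"B"}) == 0.0
    assert jaccard_index(set(), set()) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.sets(st.integers(0, 15), max_size=10),
    b=st.sets(st.integers(0, 15), max_size=10),
)
def test_jaccard_properties(a, b):
    j = jaccard_index(a, b)
    assert 0.0 <= j <= 1.0
    assert j == jaccard_index(b, a)
    if a == b and a:
        assert j == 1.0


def test_connectivity_matrix_structure_and_clustering():
    sets = {"X": {"g1", "g2", "g3"}, "Y": {"g1", "g2", "g3"}, "Z": {"g9"}}
    mat, order = connectivity_matrix(sets)
    assert np.allclose(np.diag(mat), 1.0)
    assert np.allclose(mat, mat.T)
    assert mat.loc["X", "Y"] == 1.0
    # the two identical cancers must be adjacent leaves
    assert abs(order.index("X") - order.index("Y")) == 1
    with pytest.raises(ValueError):
        connectivity_matrix({"X": {"g"}})


def test_coexpression_exact_values(tiny_cohort):
    expr = tiny_cohort.expression.copy()
    samples = list(expr.columns[:3])
    expr.loc["G1", samples] = [1.0, 2.0, 3.0]
    expr.loc["G2", samples] = [1.0, 2.0, 4.0]
    expr.loc["G3", samples] = [-1.0, -2.0, -3.0]
    cohort = OmicsCohort("TINY", expr, tiny_cohort.sample_type)
    corr = coexpression_matrix(cohort, samples=samples)
    assert corr.loc["G1", "G2"] == pytest.approx(9 / np.sqrt(84))
    assert corr.loc["G1", "G3"] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T)


def test_coexpression_zero_variance_gene_is_nan(tiny_cohort):
    expr = tiny_cohort.expression.copy()
    expr.loc["G1"] = 5.0
    cohort = OmicsCohort("TINY", expr, tiny_cohort.sample_type)
    with pytest.warns(UserWarning, match="zero-variance"):
        corr = coexpression_matrix(cohort, samples=list(expr.columns))
    assert corr.loc["G1"].isna().all()
    assert corr.loc["G2", "G3"] == pytest.approx(
        np.corrcoef(expr.loc["G2"], expr.loc["G3"])[0, 1]
    )
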