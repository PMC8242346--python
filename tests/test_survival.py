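import numpy as np
import pytest

from _oracles import cutpoint_scan_oracle, logrank_oracle
from conftest import weibull_ph_data
from panitg.survival import (
    SurvivalCall,
    apply_horizon,
    classify_prognosis,
    hazard_ratio,
    logrank_test,
    optimal_cutpoint_scan,
    prognostic_dysregulated,
    survival_screen,
)


# -- horizon censoring ---------------------------------------------------------

def test_apply_horizon_rules():
    times, events = apply_horizon([80.0, 40.0, 60.0], [1, 1, 1], 60.0)
    assert times.tolist() == [60.0, 40.0, 60.0]
    # event exactly at the horizon remains an event (closed interval)
    assert events.tolist() == [0, 1, 1]
    t2, e2 = apply_horizon([80.0, 40.0], [1, 0], None)
    assert t2.tolist() == [80.0, 40.0] and e2.tolist() == [1, 0]


# -- log-rank -----------------------------------------------------------------

def test_logrank_hand_tabulated_case():
    """Group A times [1,2] all events, group B [3,4] all events: the
    hypergeometric tables give O-E = -1 + stepwise expectations."""
    stat, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
    oracle_stat, oracle_p = logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1])
    assert stat == pytest.approx(oracle_stat, abs=1e-12)
    assert p == pytest.approx(oracle_p, abs=1e-12)
    # label swap leaves the statistic unchanged
    stat_sw, _ = logrank_test([3, 4], [1, 1], [1, 2], [1, 1])
    assert stat_sw == pytest.approx(stat, abs=1e-12)


def test_logrank_matches_oracle_random_small_datasets():
    rng = np.random.default_rng(11)
    for _ in range(100):
        na, nb = rng.integers(3, 16, size=2)
        # integer times force ties
        ta = rng.integers(1, 10, na).astype(float)
        tb = rng.integers(1, 10, nb).astype(float)
        ea = rng.integers(0, 2, na)
        eb = rng.integers(0, 2, nb)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        stat, p = logrank_test(ta, ea, tb, eb)
        o_stat, o_p = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(o_stat, abs=1e-8)
        assert p == pytest.approx(o_p, abs=1e-8)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(12)
    for _ in range(20):
        _, times, events = weibull_ph_data(rng, 40, [0.5])
        g = rng.integers(0, 2, 40).astype(bool)
        if events[g].sum() + events[~g].sum() == 0:
            continue
        stat, p = logrank_test(times[g], events[g], times[~g], events[~g])
        ll = ll_logrank(times[g], times[~g], events[g], events[~g])
        assert stat == pytest.approx(ll.test_statistic, rel=1e-9)
        assert p == pytest.approx(ll.p_value, rel=1e-9)


def test_logrank_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(13)
    ps = []
    for _ in range(200):
        _, times, events = weibull_ph_data(rng, 50, [0.0])
        g = np.zeros(50, dtype=bool)
        g[rng.permutation(50)[:25]] = True
        _, p = logrank_test(times[g], events[g], times[~g], events[~g])
        ps.append(p)
    ps = np.asarray(ps)
    assert abs((ps < 0.5).mean() - 0.5) < 0.12
    assert abs((ps < 0.1).mean() - 0.1) < 0.07


def test_logrank_errors():
    with pytest.raises(ValueError, match="non-empty"):
        logrank_test([], [], [1.0], [1])
    with pytest.raises(ValueError, match="no events"):
        logrank_test([1.0], [0], [2.0], [0])


# -- hazard ratio -------------------------------------------------------------

def test_hazard_ratio_null_and_inversion():
    rng = np.random.default_rng(14)
    _, times, events = weibull_ph_data(rng, 2000, [0.0])
    g = (rng.uniform(size=2000) < 0.5).astype(float)
    res = hazard_ratio(times, events, g)
    assert abs(res["log_hr"]) < 0.1
    res_inv = hazard_ratio(times, events, 1.0 - g)
    assert res_inv["hr"] == pytest.approx(1.0 / res["hr"], rel=1e-6)


def test_hazard_ratio_recovers_planted_effect():
    rng = np.random.default_rng(15)
    cover = 0
    for _ in range(40):
        n = 300
        g = (rng.uniform(size=n) < 0.5).astype(float)
        t = 60.0 * (-np.log(rng.uniform(size=n)) / np.exp(0.7 * g)) ** (1 / 1.2)
        events = np.ones(n, dtype=int)
        res = hazard_ratio(t, events, g)
        cover += res["ci_low"] <= np.exp(0.7) <= res["ci_high"]
    assert cover >= 33  # ~95% nominal coverage


def test_hazard_ratio_separation_sentinel():
    # all events in group 1, group 0 all censored late -> monotone likelihood
    times = np.array([1, 2, 3, 4, 100, 100, 100, 100], dtype=float)
    events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    group = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    with pytest.warns(UserWarning, match="separation"):
        res = hazard_ratio(times, events, group)
    assert not res["valid"]
    assert res["hr"] in (np.inf, 0.0)


# -- cutpoint scan ------------------------------------------------------------

def test_scan_perfect_anti_ordering_is_poor():
    """Highest expression dies first (all events) -> poor label."""
    n = 40
    values = np.arange(n, dtype=float)
    times = (n - values).astype(float)  # top expressor has shortest survival
    events = np.ones(n, dtype=int)
    call = optimal_cutpoint_scan(values, times, events, gene="G")
    assert call.label == "poor"
    assert call.hr > 1
    assert call.logrank_p < 0.001


def test_scan_matches_exhaustive_oracle():
    rng = np.random.default_rng(16)
    for _ in range(50):
        n = int(rng.integers(25, 60))
        x, times, events = weibull_ph_data(rng, n, [0.4])
        values = np.round(x[:, 0], 1)  # rounding forces tied expression
        if events.sum() == 0:
            events[0] = 1
        call = optimal_cutpoint_scan(values, times, events)
        oracle = cutpoint_scan_oracle(values, times, events)
        assert call.cut_value == pytest.approx(oracle[0])
        assert call.logrank_p == pytest.approx(oracle[1], abs=1e-10)


def test_scan_invariant_to_monotone_transform():
    rng = np.random.default_rng(17)
    x, times, events = weibull_ph_data(rng, 60, [0.6])
    values = x[:, 0]
    c1 = optimal_cutpoint_scan(values, times, events)
    c2 = optimal_cutpoint_scan(np.exp(values), times, events)
    # same induced partition
    assert np.array_equal(values <= c1.cut_value, np.exp(values) <= c2.cut_value)
    assert c1.logrank_p == pytest.approx(c2.logrank_p)


def test_scan_power_monotone_in_effect_size():
    hits = {}
    rng = np.random.default_rng(18)
    for effect in (0.0, 0.5, 1.0):
        k = 0
        for _ in range(20):
            x, times, events = weibull_ph_data(rng, 100, [effect])
            call = optimal_cutpoint_scan(x[:, 0], times, events,
                                         horizon_months=60.0)
            k += call.logrank_p < 0.05
        hits[effect] = k
    assert hits[0.0] <= hits[0.5] <= hits[1.0]
    assert hits[1.0] >= 18


def test_scan_degenerate_inputs():
    with pytest.raises(ValueError, match=">= 20"):
        optimal_cutpoint_scan([1.0] * 5, [1.0] * 5, [1] * 5)
    values = np.full(30, 2.0)
    times = np.arange(1, 31, dtype=float)
    events = np.ones(30, dtype=int)
    with pytest.warns(UserWarning, match="identical"):
        call = optimal_cutpoint_scan(values, times, events)
    assert call.label == "ns"


# -- classification and intersection ------------------------------------------

def _call(label, hr, p):
    return SurvivalCall("G", "X", "5yr", 1.0, 50.0, hr, p, label)


def test_classify_prognosis_rules():
    assert classify_prognosis({"5yr": _call("poor", 2.0, 0.01)}) == "poor"
    assert classify_prognosis({"5yr": _call("favorable", 0.5, 0.01)}) == "favorable"
    assert classify_prognosis({"5yr": _call("ns", 2.0, 0.2)}) == "ns"
    with pytest.warns(UserWarning, match="5-year"):
        assert classify_prognosis({"total": _call("poor", 2.0, 0.01)}) == "ns"


def test_prognostic_dysregulated_intersection(planted_cohort):
    cohort, truth = planted_cohort
    from panitg.expression import differential_expression

    de = differential_expression(cohort)
    sv = survival_screen(cohort, genes=["ITGA11", "ITGA8", "ITGA9", "GENE0001"])
    merged = prognostic_dysregulated(de, sv)
    # ITGA11 planted up + poor: must be recovered and concordant
    row = merged[merged.gene == "ITGA11"]
    assert len(row) == 1
    assert row.direction.iloc[0] == "up"
    assert row.final_label.iloc[0] == "poor"
    assert bool(row.concordant.iloc[0])
    # genes dysregulated but ns for survival are excluded
    assert set(merged.gene) <= {"ITGA11", "ITGA8", "ITGA9"}
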