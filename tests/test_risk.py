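import numpy as np
import pandas as pd
import pytest

from _oracles import auc_pair_counting
from conftest import weibull_ph_data
from panitg.risk import (
    CoxRiskModel,
    RankDeficiencyError,
    cox_log_partial_likelihood,
    fit_cox,
    five_year_outcome,
    risk_score,
    roc_auc,
    stratify_and_compare,
)


# -- fit_cox ------------------------------------------------------------------

def test_fit_cox_null_covariate_near_zero():
    rng = np.random.default_rng(21)
    x, times, events = weibull_ph_data(rng, 2000, [0.0])
    res = fit_cox(x, times, events)
    assert abs(res.coef[0]) < 0.1
    assert res.converged


def test_fit_cox_matches_lifelines_multivariate():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(22)
    x, times, events = weibull_ph_data(rng, 400, [0.7, -0.4])
    # integer times create ties exercising the Efron correction
    times = np.ceil(times)
    res = fit_cox(x, times, events, columns=["a", "b"])
    df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "t": times, "e": events})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    assert np.allclose(res.coef, cph.params_[["a", "b"]], atol=1e-6)
    assert np.allclose(res.se, cph.standard_errors_[["a", "b"]], atol=1e-6)


def test_fit_cox_optimality_spot_check():
    rng = np.random.default_rng(23)
    x, times, events = weibull_ph_data(rng, 150, [0.5, -0.3])
    res = fit_cox(x, times, events)
    ll_hat = cox_log_partial_likelihood(res.coef, x, times, events)
    for _ in range(100):
        beta = rng.normal(0, 1, 2)
        assert ll_hat >= cox_log_partial_likelihood(beta, x, times, events) - 1e-9


def test_fit_cox_rank_deficiency_names_columns():
    rng = np.random.default_rng(24)
    x, times, events = weibull_ph_data(rng, 100, [0.5])
    design = np.column_stack([x, 2.0 * x[:, 0]])
    with pytest.raises(RankDeficiencyError, match="g1|dup"):
        fit_cox(design, times, events, columns=["g1", "dup"])


def test_fit_cox_separation_capped_with_warning():
    # every death has the largest covariate in its risk set: the partial
    # likelihood is monotone in beta
    times = np.arange(1.0, 13.0)
    events = np.ones(12, dtype=int)
    x = -times[:, None]
    with pytest.warns(UserWarning, match="separation|capped"):
        res = fit_cox(x, times, events)
    assert res.separation
    assert abs(res.coef[0]) <= 20.0


def test_fit_cox_errors():
    with pytest.raises(ValueError, match="events"):
        fit_cox(np.ones((5, 1)) * np.arange(5)[:, None],
                np.arange(1.0, 6.0), np.zeros(5, dtype=int))


# -- risk scores ---------------------------------------------------------------

def test_risk_score_linearity_and_fixture():
    x = np.array([[1.0, 2.0, 0.5], [0.0, 1.0, 2.0], [3.0, 0.0, 1.0]])
    coef = np.array([0.5, -1.0, 2.0])
    scores = risk_score(coef, x)
    assert np.allclose(scores, [0.5 - 2.0 + 1.0, -1.0 + 4.0, 1.5 + 2.0])
    assert np.allclose(risk_score(np.zeros(3), x), 0.0)
    doubled = risk_score(coef * [2, 1, 1], x)
    assert np.allclose(doubled - scores, x[:, 0] * 0.5)
    with pytest.raises(ValueError, match="columns"):
        risk_score(coef, x[:, :2])


# -- stratification -------------------------------------------------------------

def test_stratify_null_scores_p_uniformish():
    rng = np.random.default_rng(25)
    ps = []
    for _ in range(40):
        _, times, events = weibull_ph_data(rng, 120, [0.0])
        scores = rng.normal(size=120)
        ps.append(stratify_and_compare(scores, times, events)["logrank_p"])
    ps = np.asarray(ps)
    assert (ps < 0.05).mean() < 0.2
    assert ps.mean() > 0.25


def test_stratify_planted_effect_dominance():
    rng = np.random.default_rng(26)
    x, times, events = weibull_ph_data(rng, 1000, [1.2], censor_frac=0.1)
    out = stratify_and_compare(x[:, 0], times, events)
    assert out["logrank_p"] < 1e-10
    km_h = out["km_high"].set_index("time").survival
    km_l = out["km_low"].set_index("time").survival
    # KM at time 0 is 1 for both groups
    assert km_h.iloc[0] == pytest.approx(1.0)
    assert km_l.iloc[0] == pytest.approx(1.0)
    # high-risk curve never above low-risk (checked on a common grid)
    grid = np.linspace(0, min(km_h.index.max(), km_l.index.max()), 30)
    sh = km_h.reindex(km_h.index.union(grid)).ffill().loc[grid]
    sl = km_l.reindex(km_l.index.union(grid)).ffill().loc[grid]
    assert (sh <= sl + 1e-9).all()


# -- AUC -------------------------------------------------------------------------

def test_auc_examples_and_oracle():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert roc_auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5
    assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75
    rng = np.random.default_rng(27)
    for _ in range(20):
        scores = rng.normal(size=30).round(1)
        outcome = rng.integers(0, 2, 30)
        if outcome.min() == outcome.max():
            outcome[0] = 1 - outcome[0]
        assert roc_auc(scores, outcome) == pytest.approx(
            auc_pair_counting(scores, outcome), abs=1e-12
        )
    with pytest.raises(ValueError, match="class"):
        roc_auc([1, 2], [1, 1])


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(28)
    scores = rng.normal(size=100)
    outcome = (scores + rng.normal(size=100) > 0).astype(int)
    a1 = roc_auc(scores, outcome)
    a2 = roc_auc(np.exp(3 * scores) + 7, outcome)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_five_year_outcome_definition():
    times = np.array([30.0, 70.0, 40.0, 60.0])
    events = np.array([1, 0, 0, 1])
    outcome, mask = five_year_outcome(times, events, 60.0)
    # death at 30 -> positive; followed to 70 -> negative;
    # censored at 40 -> excluded; death at 60 (boundary) -> positive
    assert mask.tolist() == [True, True, False, True]
    assert outcome.tolist() == [1, 0, 1]


# -- model/results surface --------------------------------------------------------

def test_cox_risk_model_end_to_end(planted_cohort):
    cohort, _ = planted_cohort
    results = CoxRiskModel.from_cohort(cohort, ["ITGA11", "ITGA9"]).fit()
    summ = results.summary()
    assert list(summ.index) == ["ITGA11", "ITGA9", "t_index", "n_index",
                                "m_index"]
    # planted effects recovered with the right signs
    assert summ.loc["ITGA11", "coef"] > 0.3
    assert summ.loc["ITGA9", "coef"] < -0.2
    scores = results.risk_scores()
    assert np.allclose(
        scores.to_numpy(),
        results.model.design.to_numpy() @ results.fit_result.coef,
    )
    strat = results.stratify()
    assert strat["logrank_p"] < 0.01
    assert 0.6 < results.auc() <= 1.0
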