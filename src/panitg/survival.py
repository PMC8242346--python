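"""Per-gene overall-survival screening via the minimum-p cutpoint scan.

For each gene and follow-up horizon (total, 10-year, 5-year), samples
are split into high- and low-expression groups at every admissible
cutpoint (the low group must hold between 10% and 90% of the samples),
the two-group log-rank p-value is computed at each split, and the
cutpoint minimizing p is selected. The hazard ratio (high vs low) at
the chosen split comes from a univariate Cox fit. A gene is labelled a
poor-survival gene when HR > 1 with p < 0.05 at the five-year horizon,
favorable when 0 < HR < 1 with p < 0.05; otherwise ns. No correction
is applied across the scanned cutpoints (the procedure's selection
inflation is characterized in the test suite rather than adjusted
away).

Times are in months throughout; an event falling exactly on the
horizon remains an event (closed-interval convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_MONTH = 365.25 / 12.0

__all__ = [
    "apply_horizon",
    "logrank_test",
    "hazard_ratio",
    "optimal_cutpoint_scan",
    "SurvivalCall",
    "classify_prognosis",
    "prognostic_dysregulated",
    "survival_screen",
    "km_curve",
]

HORIZONS = {"total": None, "10yr": 120.0, "5yr": 60.0}


def apply_horizon(times, events, horizon_months: float | None):
    """Administrative censoring at a follow-up horizon.

    Events after the horizon become censored observations at the
    horizon; an event exactly at the horizon stays an event. ``None``
    leaves the data unchanged (total follow-up).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon_months is None:
        return times.copy(), events.copy()
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    beyond = times > horizon_months
    return np.where(beyond, horizon_months, times), np.where(beyond, 0, events)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed-minus-expected event count
    in group A is accumulated with its hypergeometric variance; the
    statistic is (sum O-E)^2 / sum V, referred to chi-square with one
    degree of freedom. Returns ``(statistic, p)``.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    stat = _logrank_stat(ta, ea, tb, eb)
    return stat, float(stats.chi2.sf(stat, df=1))


def _logrank_stat(ta, ea, tb, eb) -> float:
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(bool)
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: ta.size] = True

    order = np.argsort(times, kind="mergesort")
    times, events, in_a = times[order], events[order], in_a[order]
    n = times.size

    # distinct event times and group boundaries
    uniq, start = np.unique(times, return_index=True)
    start = np.append(start, n)
    # counts at risk just before each distinct time
    at_risk_total = n - start[:-1]
    a_cum = np.concatenate([[0], np.cumsum(in_a)])
    at_risk_a = in_a.sum() - a_cum[start[:-1]]
    # events at each distinct time
    ev_cum = np.concatenate([[0], np.cumsum(events)])
    d_total = ev_cum[start[1:]] - ev_cum[start[:-1]]
    ev_a_cum = np.concatenate([[0], np.cumsum(events & in_a)])
    d_a = ev_a_cum[start[1:]] - ev_a_cum[start[:-1]]

    mask = d_total > 0
    n_i = at_risk_total[mask].astype(float)
    n_a = at_risk_a[mask].astype(float)
    d_i = d_total[mask].astype(float)
    d_ai = d_a[mask].astype(float)

    o_minus_e = d_ai - d_i * n_a / n_i
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_i * (n_a / n_i) * (1 - n_a / n_i) * (n_i - d_i) / (n_i - 1)
    var = np.where(n_i > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float(o_minus_e.sum() ** 2 / v)


def hazard_ratio(times, events, group) -> dict:
    """Univariate Cox hazard ratio for a binary group indicator
    (group 1 vs group 0), Efron tie handling, with a 95% Wald interval.

    Complete separation (all events confined to one group with a
    monotone likelihood) yields an inf/0 sentinel with ``valid=False``.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=float)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group must be a binary 0/1 indicator")
    if events.sum() == 0:
        raise ValueError("no events: hazard ratio undefined")
    ev1 = int(events[group == 1].sum())
    ev0 = int(events[group == 0].sum())
    if ev1 == 0 or ev0 == 0:
        # complete separation: the HR is not estimable
        warnings.warn(
            "no events in one group (complete separation); returning sentinel",
            stacklevel=2,
        )
        return {
            "hr": np.inf if ev1 > 0 else 0.0,
            "log_hr": np.nan,
            "se": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "valid": False,
        }
    df = pd.DataFrame({"time": times, "event": events, "group": group})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["group"])
        se = float(cph.standard_errors_["group"])
    except ConvergenceError:
        coef, se = np.nan, np.nan
    if not np.isfinite(coef) or abs(coef) > 15:
        # monotone likelihood with events in both groups: cap the estimate
        warnings.warn(
            "monotone likelihood in hazard-ratio fit; coefficient capped",
            stacklevel=2,
        )
        coef = 15.0 if (np.isnan(coef) and ev1 >= ev0) or coef > 0 else -15.0
        se = np.inf
    return {
        "hr": float(np.exp(coef)),
        "log_hr": coef,
        "se": se,
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "valid": True,
    }


@dataclass
class SurvivalCall:
    gene: str
    cancer_code: str
    horizon: str
    cut_value: float
    cut_percentile: float
    hr: float
    logrank_p: float
    label: str
    n_low: int = 0
    n_high: int = 0


def optimal_cutpoint_scan(
    values,
    times,
    events,
    horizon_months: float | None = None,
    lower_pct: float = 0.10,
    upper_pct: float = 0.90,
    gene: str = "",
    cancer_code: str = "",
    horizon_name: str = "total",
    alpha: float = 0.05,
) -> SurvivalCall:
    """Minimum-log-rank-p expression cutpoint scan for one gene.

    Candidate cutpoints are the distinct expression values whose
    induced low group (expression <= cut) holds between *lower_pct* and
    *upper_pct* of the samples. The cutpoint with the smallest log-rank
    p wins; ties are broken toward the cutpoint closest to the median
    expression. The HR (high vs low) at the winning split is a
    univariate Cox estimate and, together with p < *alpha*, sets the
    poor / favorable / ns label for this horizon.
    """
    values = np.asarray(values, dtype=float)
    times, events = apply_horizon(times, events, horizon_months)
    n = values.size
    if n < 20:
        raise ValueError(f"need >= 20 samples for the cutpoint scan (got {n})")

    order = np.argsort(values, kind="mergesort")
    v_sorted = values[order]
    distinct = np.unique(v_sorted)[:-1]  # cutting at the max leaves no high group
    if distinct.size == 0:
        warnings.warn(f"{gene}: all expression values identical; no cutpoint",
                      stacklevel=2)
        return SurvivalCall(gene, cancer_code, horizon_name, np.nan, np.nan,
                            np.nan, np.nan, "ns")
    n_low = np.searchsorted(v_sorted, distinct, side="right")
    admissible = (n_low >= lower_pct * n) & (n_low <= upper_pct * n)
    candidates = distinct[admissible]
    if candidates.size == 0 or events.sum() == 0:
        warnings.warn(
            f"{gene}: no admissible cutpoint or no events within the horizon",
            stacklevel=2,
        )
        return SurvivalCall(gene, cancer_code, horizon_name, np.nan, np.nan,
                            np.nan, np.nan, "ns")

    best_p, best_cut = np.inf, None
    median = float(np.median(values))
    for cut in candidates:
        low = values <= cut
        try:
            _, p = logrank_test(times[low], events[low], times[~low], events[~low])
        except ValueError:
            continue
        if p < best_p - 1e-15 or (
            abs(p - best_p) <= 1e-15
            and best_cut is not None
            and abs(cut - median) < abs(best_cut - median)
        ):
            best_p, best_cut = p, float(cut)
    if best_cut is None:
        return SurvivalCall(gene, cancer_code, horizon_name, np.nan, np.nan,
                            np.nan, np.nan, "ns")

    low = values <= best_cut
    hr_res = hazard_ratio(times, events, (~low).astype(float))
    hr = hr_res["hr"]
    if not hr_res["valid"]:
        label = "ns"
    elif best_p < alpha and hr > 1:
        label = "poor"
    elif best_p < alpha and 0 < hr < 1:
        label = "favorable"
    else:
        label = "ns"
    return SurvivalCall(
        gene=gene,
        cancer_code=cancer_code,
        horizon=horizon_name,
        cut_value=best_cut,
        cut_percentile=float(np.mean(values <= best_cut) * 100.0),
        hr=hr,
        logrank_p=float(best_p),
        label=label,
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
    )


def classify_prognosis(calls: dict) -> str:
    """Final per-gene prognosis label from the horizon-wise calls.

    The five-year call decides: HR > 1 with p < 0.05 is "poor",
    0 < HR < 1 with p < 0.05 is "favorable"; total/10-year calls are
    annotation only. A missing five-year call yields "ns" with a
    warning.
    """
    call = calls.get("5yr")
    if call is None:
        warnings.warn("no 5-year call available; labelling ns", stacklevel=2)
        return "ns"
    return call.label


def survival_screen(
    cohort,
    genes=None,
    horizons: dict | None = None,
    lower_pct: float = 0.10,
    upper_pct: float = 0.90,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the cutpoint scan for each gene at each horizon.

    Returns one row per gene per horizon plus a per-gene final label
    (the five-year rule) in the ``final_label`` column of the 5yr rows.
    Samples lacking survival data are dropped.
    """
    if cohort.clinical is None:
        raise ValueError(f"{cohort.cancer_code}: no clinical table")
    if horizons is None:
        horizons = HORIZONS
    if genes is None:
        genes = list(cohort.genes)
    clin = cohort.clinical.dropna(subset=["os_time", "os_event"])
    ids = [s for s in cohort.tumor_samples if s in clin.index]
    times = clin.loc[ids, "os_time"].to_numpy(dtype=float)
    events = clin.loc[ids, "os_event"].to_numpy(dtype=int)
    rows = []
    for gene in genes:
        values = cohort.expression.loc[gene, ids].to_numpy(dtype=float)
        calls = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, months in horizons.items():
                calls[name] = optimal_cutpoint_scan(
                    values, times, events, months,
                    lower_pct=lower_pct, upper_pct=upper_pct,
                    gene=gene, cancer_code=cohort.cancer_code,
                    horizon_name=name, alpha=alpha,
                )
        final = classify_prognosis(calls) if "5yr" in calls else "ns"
        for name, call in calls.items():
            rows.append(
                {
                    "gene": call.gene,
                    "cancer_code": call.cancer_code,
                    "horizon": name,
                    "cut_value": call.cut_value,
                    "cut_percentile": call.cut_percentile,
                    "hr": call.hr,
                    "logrank_p": call.logrank_p,
                    "label": call.label,
                    "final_label": final,
                }
            )
    return pd.DataFrame(rows)


def prognostic_dysregulated(
    de_calls: pd.DataFrame, survival_calls: pd.DataFrame
) -> pd.DataFrame:
    """Genes both dysregulated and prognostic in the same cancer.

    Intersects genes with DE direction != ns and five-year final label
    != ns; annotates each with (direction, label) and a concordance
    flag (up & poor, or down & favorable).
    """
    de = de_calls[de_calls.direction != "ns"][["cancer_code", "gene", "direction"]]
    sv = survival_calls[
        (survival_calls.horizon == "5yr") & (survival_calls.final_label != "ns")
    ][["cancer_code", "gene", "final_label", "hr", "logrank_p"]]
    merged = de.merge(sv, on=["cancer_code", "gene"], how="inner")
    merged["concordant"] = (
        ((merged.direction == "up") & (merged.final_label == "poor"))
        | ((merged.direction == "down") & (merged.final_label == "favorable"))
    )
    return merged.reset_index(drop=True)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates (time, survival)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
    )
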