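"""Multivariate Cox risk models over prognostic genes plus TNM indexes.

The partial likelihood is maximized by Newton-Raphson with Efron's tie
correction (convergence when the largest coefficient update falls below
1e-8, at most 100 iterations; step-halving on likelihood decreases).
Rank-deficient covariate matrices raise with the offending columns
named; a monotone likelihood (separation) caps the diverging
coefficients and warns. Gene expression is z-scored within the cancer
before fitting and TNM indexes enter as ordinal codes, so coefficients
are comparable across covariates.

The per-sample risk score is the linear predictor; the cohort is split
at the median score (percentile configurable) into high/low risk, the
groups are compared with Kaplan-Meier curves and a log-rank test, and
discrimination is summarized as the AUC for five-year death status
(events before the horizon are positives, samples followed past it
without an event are negatives, early-censored samples are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import OmicsCohort
from .survival import apply_horizon, km_curve, logrank_test

__all__ = [
    "fit_cox",
    "CoxFitResult",
    "cox_log_partial_likelihood",
    "risk_score",
    "stratify_and_compare",
    "roc_auc",
    "five_year_outcome",
    "CoxRiskModel",
    "CoxRiskResults",
]

_COEF_CAP = 20.0


class RankDeficiencyError(np.linalg.LinAlgError):
    """The covariate matrix is rank deficient (collinear columns)."""


def _efron_quantities(beta, x, times, events):
    """Log partial likelihood, gradient and Hessian under Efron ties.

    Rows must be sorted by time ascending. Suffix sums give the
    risk-set aggregates in O(n p^2).
    """
    n, p = x.shape
    eta = x @ beta
    theta = np.exp(eta)
    tx = theta[:, None] * x
    txx = tx[:, :, None] * x[:, None, :]
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum(tx[::-1], axis=0)[::-1]
    s2 = np.cumsum(txx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        idx = np.arange(i, j)[events[i:j].astype(bool)]
        d = idx.size
        if d:
            td0 = theta[idx].sum()
            td1 = tx[idx].sum(axis=0)
            td2 = txx[idx].sum(axis=0)
            loglik += eta[idx].sum()
            grad += x[idx].sum(axis=0)
            for ell in range(d):
                f = ell / d
                z0 = s0[i] - f * td0
                z1 = s1[i] - f * td1
                z2 = s2[i] - f * td2
                loglik -= np.log(z0)
                g = z1 / z0
                grad -= g
                hess -= z2 / z0 - np.outer(g, g)
        i = j
    return loglik, grad, hess


def cox_log_partial_likelihood(beta, covariates, times, events) -> float:
    """Efron-corrected log partial likelihood at a coefficient vector."""
    x = np.asarray(covariates, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="mergesort")
    ll, _, _ = _efron_quantities(
        np.asarray(beta, dtype=float), x[order], times[order], events[order]
    )
    return float(ll)


@dataclass
class CoxFitResult:
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation: bool
    columns: list = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])


def fit_cox(covariates, times, events, columns=None, tol: float = 1e-8,
            max_iter: int = 100) -> CoxFitResult:
    """Maximum-partial-likelihood Cox fit (Efron ties, Newton-Raphson).

    Raises on rank deficiency (naming the dependent columns) and when
    there is no event. A monotone likelihood is reported via the
    ``separation`` flag with the runaway coefficients capped.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = x.shape
    if columns is None:
        columns = [f"x{k}" for k in range(p)]
    if n <= p:
        raise ValueError(f"need more samples ({n}) than covariates ({p})")
    if events.sum() == 0:
        raise ValueError("no events: Cox model undefined")
    if not np.isfinite(x).all():
        raise ValueError("covariate matrix contains non-finite values")

    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < p:
        offenders = _dependent_columns(centered, columns)
        raise RankDeficiencyError(
            f"collinear covariates (rank {rank} < {p}): {offenders}"
        )

    order = np.argsort(times, kind="mergesort")
    xs, ts, es = x[order], times[order], events[order]

    beta = np.zeros(p)
    loglik, grad, hess = _efron_quantities(beta, xs, ts, es)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        step = 1.0
        while True:
            new_beta = beta + step * delta
            new_ll, new_grad, new_hess = _efron_quantities(new_beta, xs, ts, es)
            if new_ll >= loglik - 1e-12 or step < 1e-4:
                break
            step /= 2.0
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta).max() > _COEF_CAP:
            separation = True
            break
        if np.abs(step * delta).max() < tol:
            converged = True
            break
    if separation:
        warnings.warn(
            "monotone partial likelihood (separation); coefficients capped",
            stacklevel=2,
        )
        beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
        loglik, grad, hess = _efron_quantities(beta, xs, ts, es)
    if not converged and not separation:
        warnings.warn(f"Cox fit did not converge in {max_iter} iterations",
                      stacklevel=2)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxFitResult(
        coef=beta, se=se, pvalues=pvals, loglik=float(loglik), n_iter=it,
        converged=converged, separation=separation, columns=list(columns),
    )


def _dependent_columns(centered: np.ndarray, columns) -> list:
    _, r, piv = __import__("scipy").linalg.qr(centered, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(centered.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    return [columns[k] for k in sorted(piv[rank:])]


def risk_score(coef, covariates, columns=None) -> np.ndarray:
    """Linear predictor sum(coefficient x covariate) per sample."""
    x = np.asarray(covariates, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != coef.size:
        raise ValueError(
            f"covariate matrix has {x.shape[1]} columns but the model has "
            f"{coef.size} coefficients"
        )
    if not np.isfinite(x).all():
        raise ValueError("missing covariate values in score input")
    return x @ coef


def stratify_and_compare(
    scores, times, events, horizon_months: float | None = None,
    split_percentile: float = 50.0,
) -> dict:
    """Split at a score percentile (default median) into high/low risk
    and compare survival (KM coordinates plus log-rank p)."""
    scores = np.asarray(scores, dtype=float)
    times, events = apply_horizon(times, events, horizon_months)
    split = float(np.percentile(scores, split_percentile))
    high = scores > split
    n = scores.size
    if min(high.sum(), (~high).sum()) < 10:
        # heavy ties at the split value: move to the adjacent quantile
        warnings.warn("tied scores at the split; using quantile-adjacent split",
                      stacklevel=2)
        order = np.argsort(scores, kind="mergesort")
        half = n // 2
        high = np.zeros(n, dtype=bool)
        high[order[half:]] = True
        split = float(scores[order[half]])
    if min(high.sum(), (~high).sum()) < 10:
        raise ValueError("need >= 10 samples in each risk group")
    stat, p = logrank_test(times[high], events[high], times[~high], events[~high])
    return {
        "split_value": split,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "logrank_stat": stat,
        "logrank_p": p,
        "km_high": km_curve(times[high], events[high]),
        "km_low": km_curve(times[~high], events[~high]),
        "high_mask": high,
    }


def five_year_outcome(times, events, horizon_months: float = 60.0):
    """Binary five-year death status.

    Events at or before the horizon are positives; samples followed
    beyond the horizon without an event are negatives; samples censored
    before the horizon have indeterminable status and are excluded.
    Returns ``(outcome, mask)`` where *mask* selects the determinable
    samples.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    positive = (events == 1) & (times <= horizon_months)
    negative = times > horizon_months
    mask = positive | negative
    return positive[mask].astype(int), mask


def roc_auc(scores, outcome) -> float:
    """AUC by concordant-pair counting with half credit for ties
    (equivalently Mann-Whitney U / (n_pos x n_neg))."""
    outcome = np.asarray(outcome, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(outcome.tolist())) < 2:
        raise ValueError("AUC undefined: both outcome classes must be present")
    return float(roc_auc_score(outcome, scores))


# --------------------------------------------------------------------------
# Model / Results objects
# --------------------------------------------------------------------------

class CoxRiskModel:
    """Cox risk model over gene expression (z-scored) plus ordinal
    T/N/M staging indexes.

    Build with :meth:`from_cohort`, then :meth:`fit` to obtain a
    :class:`CoxRiskResults`. Samples with missing TNM codes are
    excluded from the design.
    """

    def __init__(self, design: pd.DataFrame, times: np.ndarray,
                 events: np.ndarray, cancer_code: str = ""):
        self.design = design
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        self.cancer_code = cancer_code

    @classmethod
    def from_cohort(cls, cohort: OmicsCohort, genes,
                    use_tnm: bool = True) -> "CoxRiskModel":
        if cohort.clinical is None:
            raise ValueError(f"{cohort.cancer_code}: no clinical table")
        genes = list(genes)
        if not genes:
            raise ValueError("need at least one gene covariate")
        clin = cohort.clinical.dropna(subset=["os_time", "os_event"])
        ids = [s for s in cohort.tumor_samples if s in clin.index]
        design = cohort.expression.loc[genes, ids].T.astype(float)
        # z-score within the cancer so gene coefficients are comparable
        design = (design - design.mean()) / design.std(ddof=0)
        if use_tnm:
            tnm = clin.loc[ids, ["t_index", "n_index", "m_index"]].astype(float)
            design = pd.concat([design, tnm], axis=1)
        design = design.dropna()
        ids = list(design.index)
        return cls(
            design=design,
            times=clin.loc[ids, "os_time"].to_numpy(dtype=float),
            events=clin.loc[ids, "os_event"].to_numpy(dtype=int),
            cancer_code=cohort.cancer_code,
        )

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "CoxRiskResults":
        res = fit_cox(
            self.design.to_numpy(dtype=float), self.times, self.events,
            columns=list(self.design.columns), tol=tol, max_iter=max_iter,
        )
        return CoxRiskResults(self, res)


class CoxRiskResults:
    """Fitted risk model: coefficients, risk scores, stratified KM
    comparison and five-year AUC."""

    def __init__(self, model: CoxRiskModel, fit_result: CoxFitResult):
        self.model = model
        self.fit_result = fit_result
        self.params = pd.Series(fit_result.coef, index=model.design.columns,
                                name="coef")
        self.bse = pd.Series(fit_result.se, index=model.design.columns, name="se")
        self.pvalues = pd.Series(fit_result.pvalues, index=model.design.columns,
                                 name="p")

    def risk_scores(self) -> pd.Series:
        scores = risk_score(
            self.fit_result.coef, self.model.design.to_numpy(dtype=float)
        )
        return pd.Series(scores, index=self.model.design.index, name="risk_score")

    def stratify(self, horizon_months: float | None = None,
                 split_percentile: float = 50.0) -> dict:
        return stratify_and_compare(
            self.risk_scores().to_numpy(), self.model.times, self.model.events,
            horizon_months=horizon_months, split_percentile=split_percentile,
        )

    def auc(self, horizon_months: float = 60.0) -> float:
        outcome, mask = five_year_outcome(
            self.model.times, self.model.events, horizon_months
        )
        return roc_auc(self.risk_scores().to_numpy()[mask], outcome)

    def summary(self) -> pd.DataFrame:
        ci = self.fit_result.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": np.exp(self.params),
                "se": self.bse,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CoxRiskResults {self.model.cancer_code}: "
            f"{len(self.params)} covariates, n={len(self.model.design)}, "
            f"converged={self.fit_result.converged}>"
        )
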