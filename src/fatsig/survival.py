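"""Survival layer: endpoints, KM curves, log-rank, Cox models, ROC/Youden.

Endpoints are overall survival (diagnosis to death) and recurrence-free
survival (diagnosis to recurrence), in months. Five-year comparisons apply
administrative censoring at a 60-month horizon first. Kaplan-Meier,
log-rank and Cox partial-likelihood machinery is delegated to lifelines
(Breslow tie handling by default); ROC/AUC to scikit-learn with a
DeLong-style variance for the AUC confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_curve

from fatsig.errors import DegenerateDataError, InvalidConfigError

log = logging.getLogger(__name__)

FIVE_YEARS = 60.0  # months


def truncate_horizon(df: pd.DataFrame, horizon: float = FIVE_YEARS,
                     time_col: str = "os_months",
                     event_col: str = "os_event") -> pd.DataFrame:
    """Administrative censoring: times beyond the horizon become censored
    observations at the horizon."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    out = df.copy()
    late = out[time_col] > horizon
    out.loc[late, event_col] = 0
    out.loc[late, time_col] = horizon
    return out


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct observed times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray | None = field(default=None, repr=False)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate; censored-at-event-time samples count as at risk."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise DegenerateDataError("no samples")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        (kmf.event_table.iloc[0][["observed", "censored"]] == 0).all() \
        else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    variance = kmf._cumulative_sq_.loc[times].to_numpy() if hasattr(
        kmf, "_cumulative_sq_") else None
    se = np.sqrt(variance) * surv if variance is not None else None
    return KMCurve(times=times,
                   at_risk=table["at_risk"].to_numpy(dtype=int),
                   events=table["observed"].to_numpy(dtype=int),
                   survival=surv,
                   greenwood_se=se)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Log-rank chi-square and p-value across >= 2 groups.

    Zero events returns (0, 1) with a warning, by convention.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise DegenerateDataError("log-rank test needs >= 2 groups")
    if event.sum() == 0:
        log.warning("log-rank: zero events; returning p=1 by convention")
        return 0.0, 1.0
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


def _prepare_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Complete-case design matrix; categoricals dummy-coded (drop first)."""
    sub = df[covariates].dropna()
    parts = []
    for col in covariates:
        s = sub[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s.astype("category"), prefix=col,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).to_frame(col))
    return pd.concat(parts, axis=1)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs."""

    table: pd.DataFrame       # index: covariate term; columns below
    log_likelihood: float
    n: int


_COX_COLUMNS = ["hazard_ratio", "ci_lower", "ci_upper", "p"]


def _fit_one_cox(df: pd.DataFrame, duration_col: str, event_col: str,
                 design: pd.DataFrame, ties: str) -> tuple[pd.DataFrame, float, int]:
    data = pd.concat([df[[duration_col, event_col]], design], axis=1).dropna()
    if int(data[event_col].sum()) < design.shape[1]:
        raise DegenerateDataError("fewer events than covariates")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col=duration_col, event_col=event_col,
                fit_options={"step_size": 0.5})
    summary = cph.summary
    out = pd.DataFrame({
        "hazard_ratio": summary["exp(coef)"],
        "ci_lower": summary["exp(coef) lower 95%"],
        "ci_upper": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })
    return out, float(cph.log_likelihood_), int(data.shape[0])


def cox_fit(df: pd.DataFrame, covariates: list[str],
            duration_col: str = "os_months", event_col: str = "os_event",
            multivariate: bool = True, ties: str = "breslow") -> CoxResult:
    """Cox proportional-hazards fit (Breslow ties), complete-case rows.

    ``multivariate=False`` fits each covariate in its own univariate model
    and stacks the per-term rows. Only Breslow tie handling is available;
    ``ties`` exists to make that contract explicit.
    """
    if ties != "breslow":
        raise InvalidConfigError(f"unsupported tie handling: {ties!r} "
                                 "(only 'breslow' is implemented)")
    if multivariate:
        design = _prepare_design(df, covariates)
        table, ll, n = _fit_one_cox(df, duration_col, event_col, design, ties)
        return CoxResult(table=table[_COX_COLUMNS], log_likelihood=ll, n=n)
    rows, lls, ns = [], [], []
    for cov in covariates:
        design = _prepare_design(df, [cov])
        table, ll, n = _fit_one_cox(df, duration_col, event_col, design, ties)
        rows.append(table)
        lls.append(ll)
        ns.append(n)
    return CoxResult(table=pd.concat(rows)[_COX_COLUMNS],
                     log_likelihood=float("nan"), n=max(ns))


def interaction_test(df: pd.DataFrame, factor_a: str, factor_b: str,
                     duration_col: str = "os_months",
                     event_col: str = "os_event") -> float:
    """Wald p-value of the a x b product term in a Cox model with main effects.

    Both factors must be two-level; every one of the four cells must be
    non-empty.
    """
    sub = df[[duration_col, event_col, factor_a, factor_b]].dropna()
    a_levels = sorted(sub[factor_a].unique())
    b_levels = sorted(sub[factor_b].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise DegenerateDataError("interaction test needs two-level factors")
    for la in a_levels:
        for lb in b_levels:
            if not ((sub[factor_a] == la) & (sub[factor_b] == lb)).any():
                raise DegenerateDataError(
                    f"empty cell: {factor_a}={la!r}, {factor_b}={lb!r}")
    a = (sub[factor_a] == a_levels[1]).astype(float)
    b = (sub[factor_b] == b_levels[1]).astype(float)
    design = pd.DataFrame({"a": a, "b": b, "a_x_b": a * b}, index=sub.index)
    table, _, _ = _fit_one_cox(sub, duration_col, event_col, design, "breslow")
    return float(table.loc["a_x_b", "p"])


# ---------------------------------------------------------------------------
# ROC / Youden

@dataclass
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    threshold: float
    sensitivity: float
    specificity: float


def _delong_auc_variance(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_scores)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n          # placements of positives
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m    # placements of negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc_youden(scores, truth) -> RocResult:
    """ROC with Youden-index threshold; AUC CI by DeLong variance.

    Ties in the Youden index are broken toward higher sensitivity. AUC equals
    the Mann-Whitney concordant-pair fraction.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise DegenerateDataError("ROC needs both classes present")
    auc, var = _delong_auc_variance(scores, truth)
    half = 1.959963984540054 * np.sqrt(var)
    fpr, tpr, thresholds = roc_curve(truth, scores)
    j = tpr - fpr
    best_j = j.max()
    candidates = np.where(j >= best_j - 1e-12)[0]
    best = candidates[np.argmax(tpr[candidates])]
    return RocResult(auc=auc,
                     ci_lower=max(0.0, auc - half),
                     ci_upper=min(1.0, auc + half),
                     threshold=float(thresholds[best]),
                     sensitivity=float(tpr[best]),
                     specificity=float(1.0 - fpr[best]))
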