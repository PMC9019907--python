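"""Bayesian compound covariate predictor (BCCP).

The compound covariate of sample i is c_i = sum_j t_j x_ij, where t_j is the
pooled-variance two-sample t-statistic (HR vs LR) of signature gene j on the
standardized training matrix. c is modeled as Gaussian within each class
with class-specific means and a common (pooled) standard deviation; the
posterior probability of HR follows from Bayes' rule with configurable class
priors (default 0.5/0.5). Expression is z-scored within each cohort before
training or prediction so that classifiers transfer across platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fatsig.errors import DegenerateDataError, SchemaError
from fatsig.io import MODEL_SCHEMA_VERSION

log = logging.getLogger(__name__)


@dataclass
class StandardizationParams:
    mean: pd.Series
    sd: pd.Series
    dropped_genes: list[str]


def standardize(expr: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Within-cohort per-gene z-scoring: (x - mean) / sd, sd with ddof=1.

    Constant genes are dropped with a logged warning. Idempotent up to
    floating-point tolerance.
    """
    if expr.shape[1] < 2:
        raise DegenerateDataError("need >= 2 samples to standardize")
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    keep = sd > 0.0
    dropped = list(expr.index[~keep])
    if dropped:
        log.warning("standardize: dropping %d constant gene(s)", len(dropped))
    std = expr.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return std, StandardizationParams(mean=mean[keep], sd=sd[keep],
                                      dropped_genes=dropped)


@dataclass
class BCCPModel:
    """t-statistic gene weights plus Gaussian parameters of the compound
    covariate."""

    gene_ids: list[str]
    weights: pd.Series        # gene_id -> t_j (HR minus LR)
    mu_lr: float
    mu_hr: float
    sigma: float              # pooled within-class SD of c
    prior_lr: float = 0.5
    prior_hr: float = 0.5
    decision_threshold: float = 0.5
    missing_genes: list[str] | None = None  # signature genes absent at fit time

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateDataError("compound covariate SD must be > 0")
        if not math.isclose(self.prior_lr + self.prior_hr, 1.0, abs_tol=1e-9):
            raise ValueError("priors must sum to 1")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("weights must be finite")

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "gene_ids": self.gene_ids,
            "weights": {g: float(w) for g, w in self.weights.items()},
            "mu_lr": self.mu_lr, "mu_hr": self.mu_hr, "sigma": self.sigma,
            "prior_lr": self.prior_lr, "prior_hr": self.prior_hr,
            "decision_threshold": self.decision_threshold,
            "missing_genes": self.missing_genes or [],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BCCPModel":
        required = ("schema_version", "gene_ids", "weights", "mu_lr", "mu_hr",
                    "sigma", "prior_lr", "prior_hr", "decision_threshold")
        for key in required:
            if key not in payload:
                raise SchemaError(f"model JSON missing key {key!r}")
        if payload["schema_version"] != MODEL_SCHEMA_VERSION:
            raise SchemaError(f"model schema version "
                              f"{payload['schema_version']} not supported")
        weights = pd.Series(payload["weights"], dtype=float)
        weights = weights.loc[payload["gene_ids"]]
        return cls(gene_ids=list(payload["gene_ids"]), weights=weights,
                   mu_lr=payload["mu_lr"], mu_hr=payload["mu_hr"],
                   sigma=payload["sigma"], prior_lr=payload["prior_lr"],
                   prior_hr=payload["prior_hr"],
                   decision_threshold=payload["decision_threshold"],
                   missing_genes=list(payload.get("missing_genes", [])))


def _resolve_priors(priors, labels01: np.ndarray) -> tuple[float, float]:
    if priors == "empirical":
        p_hr = float(labels01.mean())
        return 1.0 - p_hr, p_hr
    p_lr, p_hr = priors
    if not math.isclose(p_lr + p_hr, 1.0, abs_tol=1e-9):
        raise ValueError("priors must sum to 1")
    return float(p_lr), float(p_hr)


def _fit_parameters(x: np.ndarray, hr: np.ndarray
                    ) -> tuple[np.ndarray, float, float, float]:
    """Weights and compound-covariate Gaussian parameters.

    ``x`` is genes x samples (standardized), ``hr`` boolean per sample.
    Returns (t_weights, mu_lr, mu_hr, pooled_sd_of_c).
    """
    n_hr, n_lr = int(hr.sum()), int((~hr).sum())
    if n_hr < 2 or n_lr < 2:
        raise DegenerateDataError("both classes need >= 2 samples")
    x_hr, x_lr = x[:, hr], x[:, ~hr]
    dfree = n_hr + n_lr - 2
    pooled_var = ((x_hr.var(axis=1, ddof=1) * (n_hr - 1)
                   + x_lr.var(axis=1, ddof=1) * (n_lr - 1)) / dfree)
    se = np.sqrt(pooled_var * (1.0 / n_hr + 1.0 / n_lr))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x_hr.mean(axis=1) - x_lr.mean(axis=1)) / se
    t = np.where(np.isfinite(t), t, 0.0)  # zero-variance genes carry no weight
    c = t @ x
    c_hr, c_lr = c[hr], c[~hr]
    mu_hr, mu_lr = float(c_hr.mean()), float(c_lr.mean())
    pooled_c = ((c_hr.var(ddof=1) * (n_hr - 1) + c_lr.var(ddof=1) * (n_lr - 1))
                / dfree)
    sigma = float(np.sqrt(pooled_c))
    if sigma <= 0.0:
        raise DegenerateDataError("compound covariate has zero within-class "
                                  "variance")
    return t, mu_lr, mu_hr, sigma


def fit_bccp(train_expr_std: pd.DataFrame, labels: pd.Series,
             signature, priors=(0.5, 0.5),
             decision_threshold: float = 0.5) -> BCCPModel:
    """Fit the predictor on a standardized training matrix.

    ``labels`` maps sample IDs to "LR"/"HR"; ``signature`` is a
    SignatureGeneSet (or any object with ``gene_ids``). Signature genes
    absent from the matrix are dropped with a warning and recorded on the
    model.
    """
    sig_genes = list(signature.gene_ids)
    present = [g for g in sig_genes if g in train_expr_std.index]
    missing = [g for g in sig_genes if g not in train_expr_std.index]
    if not present:
        raise DegenerateDataError("no signature genes present in matrix")
    if missing:
        log.warning("fit_bccp: %d signature gene(s) absent from matrix",
                    len(missing))
    labels = labels.loc[train_expr_std.columns]
    hr = (labels == "HR").to_numpy()
    x = train_expr_std.loc[present].to_numpy()
    t, mu_lr, mu_hr, sigma = _fit_parameters(x, hr)
    p_lr, p_hr = _resolve_priors(priors, hr.astype(float))
    return BCCPModel(gene_ids=present,
                     weights=pd.Series(t, index=present, name="t_stat"),
                     mu_lr=mu_lr, mu_hr=mu_hr, sigma=sigma,
                     prior_lr=p_lr, prior_hr=p_hr,
                     decision_threshold=decision_threshold,
                     missing_genes=missing)


def _posterior_hr(c: np.ndarray, model: BCCPModel) -> np.ndarray:
    """Exact two-class Gaussian posterior, computed in log space."""
    log_lr = -0.5 * ((c - model.mu_lr) / model.sigma) ** 2
    log_hr = -0.5 * ((c - model.mu_hr) / model.sigma) ** 2
    if model.prior_hr == 0.0:
        return np.zeros_like(c)
    if model.prior_lr == 0.0:
        return np.ones_like(c)
    log_odds = (log_hr - log_lr
                + math.log(model.prior_hr) - math.log(model.prior_lr))
    return 1.0 / (1.0 + np.exp(-log_odds))


def predict_bccp(model: BCCPModel, expr_std: pd.DataFrame) -> pd.DataFrame:
    """Posterior HR probability and label per sample of a standardized cohort.

    The compound covariate uses model weights restricted to the genes shared
    with the cohort; a shared fraction below 50% logs a warning, zero shared
    genes is an error. posterior_lr + posterior_hr = 1 exactly.
    """
    shared = [g for g in model.gene_ids if g in expr_std.index]
    if not shared:
        raise DegenerateDataError("no model genes present in cohort matrix")
    if len(shared) < 0.5 * len(model.gene_ids):
        log.warning("predict_bccp: only %d/%d model genes shared with cohort",
                    len(shared), len(model.gene_ids))
    w = model.weights.loc[shared].to_numpy()
    c = w @ expr_std.loc[shared].to_numpy()
    post_hr = _posterior_hr(c, model)
    labels = np.where(post_hr > model.decision_threshold, "HR", "LR")
    return pd.DataFrame({
        "compound_covariate": c,
        "posterior_hr": post_hr,
        "posterior_lr": 1.0 - post_hr,
        "label": labels,
    }, index=pd.Index(expr_std.columns, name="sample_id"))


def loocv_error(train_expr_std: pd.DataFrame, labels: pd.Series,
                signature, priors=(0.5, 0.5),
                decision_threshold: float = 0.5) -> float:
    """Leave-one-out misclassification rate of the predictor.

    For every sample, weights and Gaussian parameters are refit on the other
    n-1 samples (the gene set stays fixed) and the held-out sample is
    predicted. Folds whose remainder lacks two samples of either class are
    skipped with a warning and removed from the denominator.
    """
    present = [g for g in signature.gene_ids if g in train_expr_std.index]
    if not present:
        raise DegenerateDataError("no signature genes present in matrix")
    labels = labels.loc[train_expr_std.columns]
    hr = (labels == "HR").to_numpy()
    n = len(labels)
    if n < 4:
        raise DegenerateDataError("LOOCV needs >= 4 samples")
    x = train_expr_std.loc[present].to_numpy()
    errors = skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        hr_rest = hr[mask]
        if hr_rest.sum() < 2 or (~hr_rest).sum() < 2:
            skipped += 1
            continue
        t, mu_lr, mu_hr, sigma = _fit_parameters(x[:, mask], hr_rest)
        p_lr, p_hr = _resolve_priors(priors, hr_rest.astype(float))
        fold = BCCPModel(gene_ids=present,
                         weights=pd.Series(t, index=present),
                         mu_lr=mu_lr, mu_hr=mu_hr, sigma=sigma,
                         prior_lr=p_lr, prior_hr=p_hr,
                         decision_threshold=decision_threshold)
        c_i = float(t @ x[:, i])
        pred_hr = _posterior_hr(np.array([c_i]), fold)[0] > decision_threshold
        if pred_hr != hr[i]:
            errors += 1
    if skipped:
        log.warning("loocv_error: skipped %d fold(s) with single-class "
                    "remainder", skipped)
    denom = n - skipped
    if denom == 0:
        raise DegenerateDataError("no usable LOOCV folds")
    return errors / denom
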