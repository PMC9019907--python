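"""Discovery and validation orchestration.

``discover``/``validate`` operate on in-memory cohorts and return result
objects; ``run_discovery``/``run_validation`` are their file-based wrappers,
writing TSV/JSON artifacts plus a run manifest with content digests so that
reruns with identical inputs are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from fatsig import io as fio
from fatsig.bccp import BCCPModel, fit_bccp, loocv_error, predict_bccp, standardize
from fatsig.errors import FatsigError
from fatsig.signature import SelectionThresholds, SignatureGeneSet, select_signature
from fatsig.stratify import RiskLabels, assign_risk_labels, cluster_samples, cut_two
from fatsig.survival import FIVE_YEARS, km_estimate, logrank_test, truncate_horizon

log = logging.getLogger(__name__)

MIN_SIGNATURE_GENES = 2


class NoSignalError(FatsigError):
    """The selection step found too few genes to build a signature."""


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    stage: str
    version: str
    seed: int | None
    config: dict
    inputs: dict[str, str]    # path -> sha256
    outputs: dict[str, str]   # path -> sha256
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _survival_report(clin: pd.DataFrame, labels: pd.Series,
                     horizon: float = FIVE_YEARS) -> pd.DataFrame:
    """Per-endpoint log-rank comparison of LR vs HR at the horizon."""
    rows = []
    for endpoint, (tcol, ecol) in {
        "os": ("os_months", "os_event"),
        "rfs": ("rfs_months", "rfs_event"),
    }.items():
        if tcol not in clin.columns or clin[tcol].isna().all():
            continue
        sub = clin[[tcol, ecol]].dropna()
        sub = truncate_horizon(sub, horizon, tcol, ecol)
        grp = labels.loc[sub.index]
        chi2, p = logrank_test(sub[tcol], sub[ecol], grp)
        rates = {}
        for lab in ("LR", "HR"):
            mask = grp == lab
            curve = km_estimate(sub.loc[mask, tcol], sub.loc[mask, ecol])
            rates[lab] = curve.survival_at(horizon)
        rows.append({"endpoint": endpoint, "chi2": chi2, "p": p,
                     "n": len(sub),
                     "surv_lr_at_horizon": rates["LR"],
                     "surv_hr_at_horizon": rates["HR"]})
    return pd.DataFrame(rows).set_index("endpoint")


@dataclass
class DiscoveryResult:
    signature: SignatureGeneSet
    risk_labels: RiskLabels
    model: BCCPModel
    loocv_misclassification: float
    survival_report: pd.DataFrame


def discover(expr: pd.DataFrame, clin: pd.DataFrame, mut: pd.Series,
             anchor: str,
             thresholds: SelectionThresholds = SelectionThresholds(),
             priors=(0.5, 0.5), horizon: float = FIVE_YEARS,
             ) -> DiscoveryResult:
    """Training-cohort run: derive -> stratify -> fit predictor -> survival."""
    expr, clin, mut, drops = fio.align_cohort(expr, clin, mut)
    if any(drops.values()):
        log.info("alignment dropped samples: %s", drops)
    log.info("discovery: selecting signature against anchor %s", anchor)
    signature = select_signature(expr, mut, anchor, thresholds)
    if len(signature) < MIN_SIGNATURE_GENES:
        raise NoSignalError(
            f"only {len(signature)} gene(s) passed the four criteria; "
            "no usable signature in this cohort")
    log.info("discovery: %d signature genes; clustering samples", len(signature))
    dendrogram = cluster_samples(expr.loc[signature.gene_ids])
    partition = cut_two(dendrogram)
    risk = assign_risk_labels(partition, mut, expr, anchor)
    expr_std, _ = standardize(expr)
    model = fit_bccp(expr_std, risk.labels, signature, priors=priors)
    loocv = loocv_error(expr_std, risk.labels, signature, priors=priors)
    report = _survival_report(clin, risk.labels, horizon)
    log.info("discovery: LOOCV misclassification %.3f", loocv)
    return DiscoveryResult(signature=signature, risk_labels=risk, model=model,
                           loocv_misclassification=loocv,
                           survival_report=report)


@dataclass
class CohortValidation:
    name: str
    labels: pd.Series
    posteriors: pd.DataFrame
    survival_report: pd.DataFrame
    subset_reports: dict[str, pd.DataFrame] = field(default_factory=dict)


def validate(model: BCCPModel, expr: pd.DataFrame, clin: pd.DataFrame,
             name: str = "validation", horizon: float = FIVE_YEARS,
             subsets: list[tuple[str, str]] | None = None) -> CohortValidation:
    """Validation-cohort run: standardize -> predict -> survival by label.

    ``subsets`` lists (column, value) filters, each producing an extra
    survival report restricted to the matching samples (e.g. ("hpv", "neg")).
    Empty subsets are skipped with a logged notice.
    """
    common = sorted(set(expr.columns) & set(clin.index))
    expr, clin = expr[common], clin.loc[common]
    expr_std, _ = standardize(expr)
    pred = predict_bccp(model, expr_std)
    labels = pred["label"].rename("label")
    report = _survival_report(clin, labels, horizon)
    subset_reports: dict[str, pd.DataFrame] = {}
    for col, value in subsets or []:
        if col not in clin.columns:
            raise FatsigError(f"subset column {col!r} missing from clinical "
                              "table")
        mask = clin[col] == value
        key = f"{col}={value}"
        if mask.sum() == 0 or labels[mask].nunique() < 2:
            log.info("subset %s skipped (too few samples or single class)", key)
            continue
        subset_reports[key] = _survival_report(clin[mask], labels[mask], horizon)
    return CohortValidation(name=name, labels=labels, posteriors=pred,
                            survival_report=report,
                            subset_reports=subset_reports)


# ---------------------------------------------------------------------------
# file-based wrappers

def run_discovery(expr_path: str | Path, clinical_path: str | Path,
                  mutation_path: str | Path, anchor: str, outdir: str | Path,
                  thresholds: SelectionThresholds = SelectionThresholds(),
                  priors=(0.5, 0.5), horizon: float = FIVE_YEARS,
                  seed: int | None = None) -> RunManifest:
    from fatsig import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = fio.read_expression(expr_path)
    clin = fio.read_clinical(clinical_path)
    mut = fio.read_mutations(mutation_path)
    result = discover(expr, clin, mut, anchor, thresholds, priors, horizon)

    outputs = {}
    sig_path = outdir / "signature.json"
    fio.write_signature(result.signature, sig_path)
    labels_path = outdir / "labels.tsv"
    fio.write_labels(result.risk_labels.labels, labels_path,
                     provenance=result.risk_labels.provenance)
    model_path = outdir / "model.json"
    fio.write_model(result.model, model_path)
    surv_path = outdir / "survival_training.tsv"
    result.survival_report.to_csv(surv_path, sep="\t")
    loocv_path = outdir / "loocv.json"
    loocv_path.write_text(json.dumps(
        {"loocv_misclassification": result.loocv_misclassification}) + "\n")
    for p in (sig_path, labels_path, model_path, surv_path, loocv_path):
        outputs[str(p)] = sha256_file(p)

    manifest = RunManifest(
        stage="discovery", version=__version__, seed=seed,
        config={"anchor": anchor, "horizon": horizon,
                "thresholds": dataclasses.asdict(thresholds),
                "priors": list(priors) if priors != "empirical" else priors},
        inputs={str(p): sha256_file(p)
                for p in (expr_path, clinical_path, mutation_path)},
        outputs=outputs)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def run_validation(model_path: str | Path, expr_path: str | Path,
                   clinical_path: str | Path, outdir: str | Path,
                   name: str = "validation", horizon: float = FIVE_YEARS,
                   subsets: list[tuple[str, str]] | None = None,
                   seed: int | None = None) -> RunManifest:
    from fatsig import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = fio.read_model(model_path)
    expr = fio.read_expression(expr_path)
    clin = fio.read_clinical(clinical_path)
    result = validate(model, expr, clin, name=name, horizon=horizon,
                      subsets=subsets)

    outputs = {}
    labels_path = outdir / f"labels_{name}.tsv"
    fio.write_labels(result.labels, labels_path, provenance="predicted")
    surv_path = outdir / f"survival_{name}.tsv"
    result.survival_report.to_csv(surv_path, sep="\t")
    outputs[str(labels_path)] = sha256_file(labels_path)
    outputs[str(surv_path)] = sha256_file(surv_path)
    for key, report in result.subset_reports.items():
        p = outdir / f"survival_{name}_{key.replace('=', '_')}.tsv"
        report.to_csv(p, sep="\t")
        outputs[str(p)] = sha256_file(p)

    manifest = RunManifest(
        stage="validation", version=__version__, seed=seed,
        config={"name": name, "horizon": horizon,
                "subsets": [list(s) for s in subsets or []]},
        inputs={str(p): sha256_file(p)
                for p in (model_path, expr_path, clinical_path)},
        outputs=outputs)
    manifest.to_json(outdir / f"manifest_{name}.json")
    return manifest
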