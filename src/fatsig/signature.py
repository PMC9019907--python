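"""Four-criterion signature selection.

A gene joins the signature when it is differentially expressed between
anchor-mutated and wild-type samples AND its expression correlates with
the anchor gene's expression:

1. fold change FC >= fc_min (default 1.5), with FC = 2**(difference of
   log2 group means) and the criterion applied direction-agnostically
   as max(FC, 1/FC) unless ``directional_fc`` is set;
2. pooled-variance Student t-test P < t_p_max (default 0.05);
3. |Pearson r with the anchor| > r_abs_min (default 0.2);
4. correlation P < r_p_max (default 0.05).

No multiple-testing correction is applied by default (raw p-values, as in
the discovery design this reproduces); Benjamini-Hochberg is available via
``fdr=True`` on :func:`select_signature`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from fatsig.errors import DegenerateDataError, SchemaError
from fatsig.io import SIGNATURE_SCHEMA_VERSION

log = logging.getLogger(__name__)

GENE_STAT_COLUMNS = ["fc", "log2fc", "t_stat", "t_p", "r", "r_p", "n_mut", "n_wt"]


@dataclass(frozen=True)
class SelectionThresholds:
    fc_min: float = 1.5
    t_p_max: float = 0.05
    r_abs_min: float = 0.2
    r_p_max: float = 0.05

    def __post_init__(self) -> None:
        if min(self.fc_min, self.t_p_max, self.r_abs_min + 1, self.r_p_max) <= 0:
            raise ValueError("thresholds must be positive (r_abs_min >= 0)")


@dataclass
class SignatureGeneSet:
    """Genes passing all four criteria, with their statistics."""

    anchor_gene: str
    genes: pd.DataFrame  # indexed by gene_id, columns GENE_STAT_COLUMNS
    thresholds: SelectionThresholds

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    def __len__(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        records = self.genes.reset_index().rename(
            columns={self.genes.index.name or "index": "gene_id"})
        return {
            "schema_version": SIGNATURE_SCHEMA_VERSION,
            "anchor_gene": self.anchor_gene,
            "thresholds": asdict(self.thresholds),
            "genes": records.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SignatureGeneSet":
        for key in ("schema_version", "anchor_gene", "thresholds", "genes"):
            if key not in payload:
                raise SchemaError(f"signature JSON missing key {key!r}")
        if payload["schema_version"] != SIGNATURE_SCHEMA_VERSION:
            raise SchemaError(
                f"signature schema version {payload['schema_version']} "
                f"not supported (expected {SIGNATURE_SCHEMA_VERSION})")
        genes = pd.DataFrame(payload["genes"],
                             columns=["gene_id"] + GENE_STAT_COLUMNS)
        genes = genes.set_index("gene_id")
        return cls(anchor_gene=payload["anchor_gene"], genes=genes,
                   thresholds=SelectionThresholds(**payload["thresholds"]))


def gene_group_stats(expr: pd.DataFrame, mut: pd.Series) -> pd.DataFrame:
    """Per-gene fold change and pooled-variance Student t between mutation groups.

    Returns a gene-indexed frame with fc, log2fc, t_stat, t_p, n_mut, n_wt and
    a boolean ``flagged`` column marking zero-pooled-variance genes (their t/p
    are NaN and they are excluded downstream).
    """
    mut = mut.loc[expr.columns]
    m = mut.to_numpy().astype(bool)
    n_mut, n_wt = int(m.sum()), int((~m).sum())
    if n_mut < 2 or n_wt < 2:
        raise DegenerateDataError(
            f"need >= 2 samples per mutation group (got {n_mut} mutated, "
            f"{n_wt} wild-type)")
    x = expr.to_numpy()
    x_mut, x_wt = x[:, m], x[:, ~m]
    mean_mut, mean_wt = x_mut.mean(axis=1), x_wt.mean(axis=1)
    log2fc = mean_mut - mean_wt
    df_t = n_mut + n_wt - 2
    pooled_var = ((x_mut.var(axis=1, ddof=1) * (n_mut - 1)
                   + x_wt.var(axis=1, ddof=1) * (n_wt - 1)) / df_t)
    flagged = pooled_var <= 0.0
    se = np.sqrt(pooled_var * (1.0 / n_mut + 1.0 / n_wt))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(flagged, np.nan, log2fc / se)
    t_p = 2.0 * stats.t.sf(np.abs(t_stat), df_t)
    if flagged.any():
        log.warning("%d gene(s) with zero pooled variance flagged and "
                    "excluded from selection", int(flagged.sum()))
    return pd.DataFrame({
        "fc": np.exp2(log2fc), "log2fc": log2fc,
        "t_stat": t_stat, "t_p": t_p,
        "n_mut": n_mut, "n_wt": n_wt, "flagged": flagged,
    }, index=expr.index)


def anchor_correlation(expr: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """Pearson correlation of every gene with the anchor gene across samples.

    p-values via the exact t transform t = r * sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom. Constant genes (or a constant anchor) are flagged with
    NaN correlation; the anchor's own row is reported as r=1 but is ineligible
    for selection.
    """
    if anchor not in expr.index:
        raise DegenerateDataError(f"anchor gene {anchor!r} not in matrix")
    n = expr.shape[1]
    if n < 3:
        raise DegenerateDataError("need >= 3 samples for correlation")
    x = expr.to_numpy()
    a = expr.loc[anchor].to_numpy()
    a_c = a - a.mean()
    a_ss = float(a_c @ a_c)
    if a_ss <= 0.0:
        raise DegenerateDataError("anchor expression is constant")
    x_c = x - x.mean(axis=1, keepdims=True)
    x_ss = (x_c ** 2).sum(axis=1)
    flagged = x_ss <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(flagged, np.nan, (x_c @ a_c) / np.sqrt(x_ss * a_ss))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    r_p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    r_p = np.where(np.isnan(r) | (np.abs(r) >= 1.0),
                   np.where(np.isnan(r), np.nan, 0.0), r_p)
    if flagged.any():
        log.warning("%d constant gene(s) flagged in correlation step",
                    int(flagged.sum()))
    return pd.DataFrame({"r": r, "r_p": r_p, "r_flagged": flagged},
                        index=expr.index)


def select_signature(expr: pd.DataFrame, mut: pd.Series, anchor: str,
                     thresholds: SelectionThresholds = SelectionThresholds(),
                     directional_fc: bool = False,
                     welch: bool = False,
                     fdr: bool = False) -> SignatureGeneSet:
    """Apply the four inclusion criteria; returns genes sorted by gene ID.

    ``directional_fc`` applies FC >= fc_min one-sidedly (up in mutated only);
    the default tests max(FC, 1/FC). ``welch`` swaps the pooled t for Welch's
    unequal-variance t. ``fdr`` applies Benjamini-Hochberg to both p-value
    families before thresholding.
    """
    group = gene_group_stats(expr, mut)
    if welch:
        m = mut.loc[expr.columns].to_numpy().astype(bool)
        t_stat, t_p = stats.ttest_ind(expr.to_numpy()[:, m],
                                      expr.to_numpy()[:, ~m],
                                      axis=1, equal_var=False)
        group["t_stat"], group["t_p"] = t_stat, t_p
    corr = anchor_correlation(expr, anchor)
    table = group.join(corr)
    t_p, r_p = table["t_p"], table["r_p"]
    if fdr:
        from statsmodels.stats.multitest import multipletests
        ok = table["t_p"].notna()
        t_p = table["t_p"].copy()
        t_p[ok] = multipletests(table["t_p"][ok], method="fdr_bh")[1]
        ok = table["r_p"].notna()
        r_p = table["r_p"].copy()
        r_p[ok] = multipletests(table["r_p"][ok], method="fdr_bh")[1]
    fc_eff = table["fc"] if directional_fc else np.maximum(table["fc"],
                                                           1.0 / table["fc"])
    keep = (
        (fc_eff >= thresholds.fc_min)
        & (t_p < thresholds.t_p_max)
        & (table["r"].abs() > thresholds.r_abs_min)
        & (r_p < thresholds.r_p_max)
        & ~table["flagged"] & ~table["r_flagged"]
        & (table.index != anchor)
    )
    genes = table.loc[keep, GENE_STAT_COLUMNS[:6]].copy()
    genes["n_mut"] = table.loc[keep, "n_mut"]
    genes["n_wt"] = table.loc[keep, "n_wt"]
    genes = genes.sort_index()
    return SignatureGeneSet(anchor_gene=anchor, genes=genes,
                            thresholds=thresholds)
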