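"""Readers/writers for the pipeline's tabular formats.

Canonical dialect: tab-separated UTF-8 text with '.' decimal. Expression
matrices are genes x samples with gene IDs in the first column and sample
IDs in the header. Readers validate structure and reject rather than
silently coerce; every writer's output loads back losslessly through its
paired reader.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from fatsig.errors import FormatError, SchemaError, ValidationError, DegenerateDataError

log = logging.getLogger(__name__)

SIGNATURE_SCHEMA_VERSION = 1
MODEL_SCHEMA_VERSION = 1

CLINICAL_REQUIRED = ["sample_id", "os_months", "os_event"]
CLINICAL_OPTIONAL = ["rfs_months", "rfs_event", "age_group", "sex", "smoking",
                     "alcohol", "t_class", "n_class", "stage", "hpv",
                     "radiotherapy"]

#: tokens that denote an explicitly missing value (never counted as junk)
_MISSING_TOKENS = {"", "na", "n/a", "nan", "unknown", "missing", "none", "."}

#: per-column category normalization: lower-cased input token -> canonical value
_ENUMS: dict[str, dict[str, str]] = {
    "age_group": {"<60": "<60", ">=60": ">=60", "≥60": ">=60",
                  "ge60": ">=60", "lt60": "<60"},
    "sex": {"male": "male", "m": "male", "female": "female", "f": "female"},
    "smoking": {"yes": "yes", "no": "no", "ever": "yes", "never": "no"},
    "alcohol": {"yes": "yes", "no": "no", "ever": "yes", "never": "no"},
    "t_class": {"t1-t2": "T1-T2", "t1–t2": "T1-T2", "t3-t4": "T3-T4",
                "t3–t4": "T3-T4"},
    "n_class": {"n0": "N0", "n1-3": "N1-3", "n1–3": "N1-3", "n1-n3": "N1-3"},
    "stage": {"i-ii": "I-II", "i–ii": "I-II", "iii-iv": "III-IV",
              "iii–iv": "III-IV"},
    "hpv": {"pos": "pos", "positive": "pos", "+": "pos",
            "neg": "neg", "negative": "neg", "-": "neg"},
    "radiotherapy": {"yes": "yes", "no": "no"},
}


# ---------------------------------------------------------------------------
# expression matrices

def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise FormatError(f"duplicate {what} ID {dup!r}")


def read_expression(path: str | Path, drop_missing_genes: bool = False) -> pd.DataFrame:
    """Load a genes x samples log2 expression matrix from TSV.

    Row/column order is preserved from the file. Non-numeric cells raise a
    parse error with coordinates; missing values raise unless
    ``drop_missing_genes`` drops the affected gene rows.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "gene")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}")
        values[:, j] = numeric.to_numpy()
    expr = pd.DataFrame(values, index=raw.index.rename("gene_id"),
                        columns=raw.columns)
    missing = expr.isna().any(axis=1)
    if missing.any():
        if not drop_missing_genes:
            raise FormatError(
                f"{int(missing.sum())} gene(s) with missing values "
                f"(first: {expr.index[missing][0]!r}); pass "
                f"drop_missing_genes=True to drop them")
        log.warning("dropping %d gene(s) with missing values", missing.sum())
        expr = expr.loc[~missing]
    if not np.isfinite(expr.to_numpy()).all():
        raise FormatError("expression matrix contains non-finite values")
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clinical tables

def _normalize_enum(series: pd.Series, mapping: dict[str, str]) -> tuple[pd.Series, int]:
    """Case-insensitive normalization; unknown tokens -> NaN, counted."""
    out, junk = [], 0
    for tok in series:
        if pd.isna(tok) or str(tok).strip().lower() in _MISSING_TOKENS:
            out.append(np.nan)
            continue
        key = str(tok).strip().lower()
        if key in mapping:
            out.append(mapping[key])
        else:
            out.append(np.nan)
            junk += 1
    return pd.Series(out, index=series.index, dtype=object), junk


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Load a clinical table; returns a sample-indexed DataFrame.

    Unknown category tokens become missing; their count is logged and stored
    in ``result.attrs["n_unknown_tokens"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"clinical table missing required column {col!r}")
    _check_unique(df["sample_id"], "sample")
    df = df.set_index(df["sample_id"].astype(str)).drop(columns=["sample_id"])
    df.index.name = "sample_id"

    n_junk = 0
    for col in ("os_months", "rfs_months"):
        if col in df.columns:
            times = pd.to_numeric(df[col], errors="coerce")
            bad = times.isna() & df[col].notna() & ~df[col].str.strip().str.lower().isin(_MISSING_TOKENS)
            if bad.any():
                raise FormatError(f"non-numeric {col} for sample "
                                  f"{df.index[bad.to_numpy().argmax()]!r}")
            if (times.dropna() < 0).any():
                raise ValidationError(f"negative {col} encountered")
            if col == "os_months" and times.isna().any():
                raise ValidationError("os_months is required for every sample")
            df[col] = times
    for col in ("os_event", "rfs_event"):
        if col in df.columns:
            ev = pd.to_numeric(df[col], errors="coerce")
            present = ev.notna()
            if col == "os_event" and not present.all():
                raise ValidationError("os_event is required for every sample")
            if not ev[present].isin([0, 1]).all():
                raise ValidationError(f"{col} must be 0/1")
            df[col] = ev
    for col, mapping in _ENUMS.items():
        if col in df.columns:
            df[col], junk = _normalize_enum(df[col], mapping)
            n_junk += junk
    if n_junk:
        log.warning("clinical table %s: %d unrecognized category token(s) "
                    "treated as missing", path, n_junk)
    df.attrs["n_unknown_tokens"] = n_junk
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# mutation status

def read_mutations(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "mutated"):
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")
    _check_unique(df["sample_id"], "sample")
    mut = pd.to_numeric(df["mutated"], errors="coerce")
    if mut.isna().any() or not mut.isin([0, 1]).all():
        raise ValidationError("mutated column must be binary 0/1")
    return pd.Series(mut.astype(int).to_numpy(),
                     index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
                     name="mutated")


def write_mutations(mut: pd.Series, path: str | Path) -> None:
    mut.rename("mutated").rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# risk labels

def write_labels(labels: pd.Series, path: str | Path,
                 provenance: str = "clustered") -> None:
    df = pd.DataFrame({"label": labels, "provenance": provenance})
    df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise FormatError(f"label table missing required column {col!r}")
    _check_unique(df["sample_id"], "sample")
    bad = ~df["label"].isin(["LR", "HR"])
    if bad.any():
        raise ValidationError(f"unknown risk label {df['label'][bad].iloc[0]!r}")
    return pd.Series(df["label"].to_numpy(),
                     index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
                     name="label")


# ---------------------------------------------------------------------------
# cohort alignment

def align_cohort(expr: pd.DataFrame, clin: pd.DataFrame, mut: pd.Series
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict[str, int]]:
    """Restrict all three tables to their common samples, in sorted ID order.

    Returns the aligned triple plus a report of how many samples each source
    lost. Raises if the intersection is empty.
    """
    common = sorted(set(expr.columns) & set(clin.index) & set(mut.index))
    if not common:
        raise DegenerateDataError("no samples shared by expression, clinical "
                                  "and mutation tables")
    drops = {
        "expression": expr.shape[1] - len(common),
        "clinical": clin.shape[0] - len(common),
        "mutation": mut.shape[0] - len(common),
    }
    return expr[common], clin.loc[common], mut.loc[common], drops


# ---------------------------------------------------------------------------
# signature JSON (see fatsig.signature for the in-memory type)

def write_signature(sig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sig.to_dict(), indent=2) + "\n")


def read_signature(path: str | Path):
    from fatsig.signature import SignatureGeneSet

    payload = json.loads(Path(path).read_text())
    return SignatureGeneSet.from_dict(payload)


def write_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path: str | Path):
    from fatsig.bccp import BCCPModel

    payload = json.loads(Path(path).read_text())
    return BCCPModel.from_dict(payload)
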