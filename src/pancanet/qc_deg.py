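"""Sample QC exclusion and per-dataset differential-expression calling.

A sample is excluded when it is flagged low-quality on at least half of the
QC metrics. DEGs are called per dataset with a two-gate rule: |log2FC| >= 1
(tumor mean minus normal mean on the log2 scale) and Benjamini-Hochberg
adjusted p < 0.05. Both gates must pass; the fold-change gate is independent
of the p-value gate.

The test engine is a per-gene Welch two-sample t-test (log2 intensities for
microarray, log2 CPM for counts). This is a deliberate simplification: the
contribution of this package is the threshold-and-consensus layer above the
test, not the test itself, and moderated-statistics engines (limma, DESeq2)
can be substituted upstream by supplying precomputed DEG tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    OVER,
    UNDER,
    DegTable,
    ExpressionStudy,
    InvalidParameterError,
    MalformedInputError,
)


def qc_exclude(flags: pd.DataFrame) -> list[str]:
    """Retain samples flagged low-quality on fewer than half of the metrics.

    ``flags`` is samples x metrics, boolean (True = low quality). A sample
    is excluded iff its flag count >= ceil(k/2) for k metrics — a tie at
    exactly half excludes ("at least half"). Retained order is input order.
    """
    if flags.shape[1] < 1:
        raise InvalidParameterError("at least one QC metric is required")
    if flags.isna().any().any():
        bad = flags.index[flags.isna().any(axis=1)].tolist()
        raise MalformedInputError(f"samples with missing QC flags: {bad}")
    cutoff = math.ceil(flags.shape[1] / 2)
    counts = flags.astype(bool).sum(axis=1)
    return list(flags.index[counts < cutoff])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_deg_table(
    log2_values: pd.DataFrame,
    tumor_cols: list[str],
    normal_cols: list[str],
    fc_threshold: float,
    alpha: float,
) -> pd.DataFrame:
    tumor = log2_values[tumor_cols].to_numpy(float)
    normal = log2_values[normal_cols].to_numpy(float)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    # Genes with zero variance in both groups carry no evidence: p = 1 so
    # they flow through BH harmlessly instead of propagating NaN.
    flat = (tumor.var(axis=1) == 0) & (normal.var(axis=1) == 0)
    p = np.where(flat | np.isnan(p), 1.0, p)
    p_adj = bh_adjust(p)
    significant = (np.abs(log2fc) >= fc_threshold) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "gene": log2_values.index,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(log2fc > 0, OVER, UNDER),
            "significant": significant,
        }
    ).reset_index(drop=True)


def _check_group_sizes(study: ExpressionStudy) -> tuple[list[str], list[str]]:
    tumor, normal = study.tumor_samples, study.normal_samples
    if len(tumor) < 3 or len(normal) < 3:
        raise InvalidParameterError(
            f"study {study.dataset_id}: at least three samples per group are "
            f"required (got {len(tumor)} tumor, {len(normal)} normal)"
        )
    return tumor, normal


def call_degs_microarray(
    study: ExpressionStudy, fc_threshold: float = 1.0, alpha: float = 0.05
) -> DegTable:
    """Welch t-test DEG calls on log2 intensities with the |log2FC| >= 1
    and BH-adjusted p < 0.05 gates."""
    tumor, normal = _check_group_sizes(study)
    records = _welch_deg_table(study.values, tumor, normal, fc_threshold, alpha)
    return DegTable(records, study.cancer_type, study.technology, study.dataset_id)


def call_degs_counts(
    study: ExpressionStudy,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> DegTable:
    """DEG calls on counts via log2 counts-per-million, then the same Welch
    machinery and gates as the microarray path.

    CPM is computed before adding the pseudocount, so a global library-size
    rescaling (e.g. doubling every count) leaves log2FC unchanged.
    """
    counts = study.values.to_numpy(float)
    if (counts < 0).any():
        raise MalformedInputError(f"study {study.dataset_id}: negative counts")
    if pseudocount <= 0:
        raise InvalidParameterError("pseudocount must be positive")
    tumor, normal = _check_group_sizes(study)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise MalformedInputError(
            f"study {study.dataset_id}: sample with zero library size"
        )
    cpm = counts / lib * 1e6
    log2cpm = pd.DataFrame(
        np.log2(cpm + pseudocount), index=study.values.index, columns=study.values.columns
    )
    records = _welch_deg_table(log2cpm, tumor, normal, fc_threshold, alpha)
    return DegTable(records, study.cancer_type, study.technology, study.dataset_id)


def call_degs(study: ExpressionStudy, **kwargs) -> DegTable:
    """Dispatch on the study's technology tag."""
    if study.technology == "rnaseq":
        return call_degs_counts(study, **kwargs)
    return call_degs_microarray(study, **kwargs)
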