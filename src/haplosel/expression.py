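"""Tissue-specificity (tau) and the gene subsets used for DFE runs.

tau = sum_i (1 - x_i / max(x)) / (N - 1) over N tissues: 0 for uniform
expression, 1 for single-tissue expression. Genes with tau >= 0.8 count as
tissue specific and are assigned to their arg-max tissue. Two further
subsets probe robustness of any selection signal: genes above the
within-set median tau (narrower breadth) and genes at or below the
within-set median expression level (lower expression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TAU_MIN_DEFAULT = 0.8


def tau(x) -> float:
    """Tissue-specificity index of one expression vector.

    Requires >= 2 tissues, non-negative values and a positive maximum
    (all-zero genes have undefined specificity and are excluded upstream).
    Scale-invariant: tau(c*x) = tau(x) for c > 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("expression vector must be 1-D with >= 2 tissues")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite and non-negative")
    m = x.max()
    if m <= 0:
        raise ValueError("all-zero expression vector: tau undefined")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def tau_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene tau, assigned (arg-max) tissue and expression level.

    ``matrix`` is genes x tissues (one mean normalized value per tissue;
    replicates are collapsed to means beforehand). The expression level of
    a gene is its value in the assigned tissue. All-zero genes are dropped.
    """
    rows = []
    for gene, vec in matrix.iterrows():
        x = vec.to_numpy(dtype=float)
        if x.max() <= 0:
            continue
        rows.append(
            {
                "gene": gene,
                "tau": tau(x),
                "tissue": matrix.columns[int(np.argmax(x))],
                "level": float(x.max()),
            }
        )
    return pd.DataFrame(rows)


def select_tissue_specific(
    table: pd.DataFrame, tau_min: float = TAU_MIN_DEFAULT
) -> dict[str, list[str]]:
    """Per-tissue tissue-specific gene sets plus the all-genes reference set.

    A gene is tissue specific when tau >= tau_min (inclusive); it joins the
    set of its arg-max tissue only, so per-tissue sets are disjoint. The
    ``all_genes`` set keeps every gene regardless of specificity.
    """
    sets: dict[str, list[str]] = {}
    spec = table[table["tau"] >= tau_min]
    for tissue, g in spec.groupby("tissue", sort=True):
        sets[str(tissue)] = sorted(g["gene"].tolist())
    sets["all_genes"] = sorted(table["gene"].tolist())
    return sets


def subset_high_tau(table: pd.DataFrame, genes: list[str]) -> list[str]:
    """Genes with tau strictly above the within-set median tau."""
    sub = table[table["gene"].isin(genes)]
    if len(sub) < 2:
        raise ValueError("need >= 2 genes to split at the median")
    med = sub["tau"].median()
    return sorted(sub.loc[sub["tau"] > med, "gene"].tolist())


def subset_low_expression(table: pd.DataFrame, genes: list[str]) -> list[str]:
    """Genes with expression level from the lowest value up to (and
    including) the within-set median level."""
    sub = table[table["gene"].isin(genes)]
    if len(sub) < 2:
        raise ValueError("need >= 2 genes to split at the median")
    med = sub["level"].median()
    return sorted(sub.loc[sub["level"] <= med, "gene"].tolist())


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")
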