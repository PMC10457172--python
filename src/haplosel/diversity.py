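"""Nucleotide diversity and folded-SFS summary statistics.

Per-gene pi uses the ratio-of-sums estimator over variant *and* invariant
sites (the pixy approach): summed pairwise differences divided by summed
comparable pairs, which is unbiased under missing data because sites with
fewer called alleles simply contribute fewer pairs, with no per-site
renormalization.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .sfs import FoldedSFS


def pi(sites: pd.DataFrame) -> float:
    """Ratio-of-sums nucleotide diversity for one gene/one degeneracy class.

    pi = sum_sites AC*(AN-AC) / sum_sites C(AN,2). Sites with AN < 2 offer
    no comparable pair and contribute nothing. Raises ValueError when no
    site has two called alleles (the gene is then excluded upstream).
    """
    an = sites["AN"].to_numpy(dtype=np.int64)
    ac = sites["AC"].to_numpy(dtype=np.int64)
    pairs = an * (an - 1) // 2
    denom = int(pairs.sum())
    if denom == 0:
        raise ValueError("no site with >= 2 called alleles: pi undefined")
    num = int((ac * (an - ac)).sum())
    return num / denom


def per_gene_diversity(sites: pd.DataFrame, min_total_sites: int = 50) -> pd.DataFrame:
    """Per-gene pi at 0-fold and 4-fold sites and their ratio.

    The ratio is reported only for genes passing the study's two filters:
    at least ``min_total_sites`` sites total (0-fold plus 4-fold, jointly)
    and both diversity estimates > 0.
    """
    rows = []
    for gene, g in sites.groupby("gene", sort=True):
        rec: dict = {"gene": gene}
        for klass, key in (("0-fold", "0"), ("4-fold", "4")):
            sub = g[g["degeneracy"] == klass]
            rec[f"n_sites_{key}"] = len(sub)
            try:
                rec[f"pi{key}"] = pi(sub) if len(sub) else np.nan
            except ValueError:
                rec[f"pi{key}"] = np.nan
        total = rec["n_sites_0"] + rec["n_sites_4"]
        ok = (
            total >= min_total_sites
            and np.isfinite(rec["pi0"]) and np.isfinite(rec["pi4"])
            and rec["pi0"] > 0 and rec["pi4"] > 0
        )
        rec["ratio"] = rec["pi0"] / rec["pi4"] if ok else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def pi_ratio_table(records: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-tissue mean pi0, pi4 and mean-of-ratios with standard errors.

    ``records`` comes from :func:`per_gene_diversity`; ``gene_sets`` maps a
    set label (tissue or all_genes) to its member genes. Means are
    arithmetic means across genes (mean of per-gene ratios, not a ratio of
    means); SE = sample SD / sqrt(N genes).
    """
    rows = []
    for label, genes in gene_sets.items():
        sub = records[records["gene"].isin(genes)]
        rec = {"gene_set": label, "n_genes": len(sub)}
        for col in ("pi0", "pi4", "ratio"):
            vals = sub[col].dropna().to_numpy()
            rec[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{col}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
            rec[f"{col}_n"] = len(vals)
        rows.append(rec)
    return pd.DataFrame(rows)


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float((1.0 / i**power).sum())


def watterson_theta(fsfs: FoldedSFS) -> float:
    """Watterson's theta per site: S / (a1 * L), L = total sites in the fSFS."""
    L = fsfs.total_sites
    if L == 0:
        raise ValueError("empty spectrum")
    return fsfs.segregating / (_harmonic(fsfs.n) * L)


def pi_from_sfs(fsfs: FoldedSFS) -> float:
    """Average pairwise diversity per site from a folded spectrum."""
    n = fsfs.n
    i = np.arange(1, n // 2 + 1)
    weights = i * (n - i) / (n * (n - 1) / 2.0)
    L = fsfs.total_sites
    if L == 0:
        raise ValueError("empty spectrum")
    return float((fsfs.bins[1:] * weights).sum()) / L


class TajimaResult(NamedTuple):
    d: float
    defined: bool


def tajimas_d(fsfs: FoldedSFS) -> TajimaResult:
    """Tajima's D from a folded spectrum (standard variance normalization).

    With zero segregating sites D is undefined; it is reported as 0.0 with
    ``defined=False`` so that summary tables can still print a value the way
    the per-tissue reports do.
    """
    n = fsfs.n
    S = fsfs.segregating
    if S == 0:
        return TajimaResult(0.0, False)
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    i = np.arange(1, n // 2 + 1)
    pi_total = float((fsfs.bins[1:] * (i * (n - i) / (n * (n - 1) / 2.0))).sum())
    var = e1 * S + e2 * S * (S - 1)
    return TajimaResult((pi_total - S / a1) / np.sqrt(var), True)
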