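"""Collapsed-paralog detection and genotype/site filtering.

Haploid tissue cannot be heterozygous, so any heterozygote produced by a
diploid-mode call of the same reads flags reads from two collapsed paralog
copies mapping to one locus. Sites with two or more heterozygous calls are
flagged, a 150-bp window around each is masked, and the haploid-mode call
is then filtered: masked regions, indels, complex variants and >2-allele
sites removed; genotypes failing GQ/DP set missing; sites above the
missingness ceiling dropped; AN/AC recomputed from the surviving genotypes
(the vcffixup step).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .callset import CallSet, MISSING

WINDOW_BP_DEFAULT = 150
GQ_MIN_DEFAULT = 20
DP_MIN_DEFAULT = 10
MAX_MISSING_DEFAULT = 0.20


def detect_paralog_sites(diploid: CallSet, min_het: int = 2) -> list[tuple[str, int]]:
    """Positions where >= min_het samples are heterozygous in diploid mode.

    A heterozygote is a genotype with two distinct *called* alleles,
    whatever the alleles; genotypes with any missing allele never count.
    """
    if diploid.ploidy != 2:
        raise ValueError("paralog detection requires a diploid-mode call set")
    a, b = diploid.gt[:, :, 0], diploid.gt[:, :, 1]
    het = (a != b) & (a != MISSING) & (b != MISSING)
    flagged = het.sum(axis=1) >= min_het
    return [
        (str(c), int(p))
        for c, p in zip(diploid.contig[flagged], diploid.pos[flagged])
    ]


def build_mask(
    flagged: list[tuple[str, int]], window_bp: int = WINDOW_BP_DEFAULT
) -> pd.DataFrame:
    """Merged mask intervals (BED convention: 0-based, half-open).

    Each flagged site gets a window of ±window_bp//2 around it (a site at
    1-based position 1000 with the default 150-bp setting yields
    [924, 1075)); overlapping or adjacent windows are merged and the source
    site positions carried along.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    half = window_bp // 2
    cols = ["contig", "start", "end", "sources"]
    if not flagged:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(flagged, columns=["contig", "pos"]).sort_values(["contig", "pos"])
    rows = []
    for contig, g in df.groupby("contig", sort=True):
        cur_start = cur_end = None
        cur_sources: list[int] = []
        for p in g["pos"]:
            start, end = max(p - 1 - half, 0), p - 1 + half + 1
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    rows.append((contig, cur_start, cur_end, ",".join(map(str, cur_sources))))
                cur_start, cur_end, cur_sources = start, end, [p]
            else:
                cur_end = max(cur_end, end)
                cur_sources.append(p)
        rows.append((contig, cur_start, cur_end, ",".join(map(str, cur_sources))))
    return pd.DataFrame(rows, columns=cols)


def write_mask_bed(mask: pd.DataFrame, path) -> None:
    mask.to_csv(path, sep="\t", header=False, index=False)


def _in_mask(cs: CallSet, mask: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(cs.n_sites, dtype=bool)
    if mask is None or len(mask) == 0:
        return hit
    for contig, g in mask.groupby("contig"):
        on_ctg = cs.contig == contig
        if not on_ctg.any():
            continue
        p0 = cs.pos[on_ctg] - 1  # 0-based
        sub = np.zeros(p0.shape, dtype=bool)
        for start, end in zip(g["start"], g["end"]):
            sub |= (p0 >= start) & (p0 < end)
        hit[np.flatnonzero(on_ctg)[sub]] = True
    return hit


def filter_callset(
    haploid: CallSet,
    mask: pd.DataFrame | None = None,
    gq_min: int = GQ_MIN_DEFAULT,
    dp_min: int = DP_MIN_DEFAULT,
    max_missing: float = MAX_MISSING_DEFAULT,
) -> CallSet:
    """The QC chain on a haploid-mode call, returning the surviving call set.

    Order: mask removal -> variant-type filters (biallelic SNPs or invariant
    single-base records only) -> genotype-level GQ/DP masking (strict >) ->
    site-level missingness (> max_missing dropped). Genotypes already
    missing keep their GQ/DP untouched.
    """
    if haploid.ploidy != 1:
        raise ValueError("site filtering expects the haploid-mode call set")
    keep = ~_in_mask(haploid, mask)
    for i in np.flatnonzero(keep):
        ref, alts = haploid.ref[i], haploid.alt[i]
        if ref is None or len(ref) != 1:
            keep[i] = False            # indel or complex representation
        elif len(alts) > 1:
            keep[i] = False            # more than two alleles
        elif any(len(a) != 1 for a in alts):
            keep[i] = False            # indel/complex alt
    cs = haploid.take(np.flatnonzero(keep))
    gt = cs.gt.copy()
    bad = ~((cs.gq > gq_min) & (cs.dp > dp_min))
    gt[bad] = MISSING
    called = (gt[:, :, 0] != MISSING).sum(axis=1)
    missing_frac = 1.0 - called / cs.n_samples
    ok = missing_frac <= max_missing + 1e-12
    out = cs.take(np.flatnonzero(ok))
    out.gt = gt[ok]
    return out


def site_table(
    cs: CallSet, site_to_gene: dict[str, str] | None = None
) -> pd.DataFrame:
    """SiteTable with AN/AC recomputed from the (possibly masked) genotypes.

    ``site_to_gene`` maps contig -> gene id (the synthetic reference puts
    one gene per contig); by default the contig name is used. The
    degeneracy column is left unset for the annotation stage to fill.
    """
    alleles = cs.gt[:, :, 0]
    an = (alleles != MISSING).sum(axis=1)
    ac = (alleles == 1).sum(axis=1)
    genes = [
        (site_to_gene or {}).get(str(c), str(c)) for c in cs.contig
    ]
    df = pd.DataFrame(
        {
            "contig": cs.contig.astype(str),
            "pos": cs.pos,
            "gene": genes,
            "AN": an.astype(np.int64),
            "AC": ac.astype(np.int64),
        }
    )
    if np.any(df["AC"] > df["AN"]):
        raise AssertionError("AC exceeds AN after recomputation")
    return df


def apply_filters(
    haploid: CallSet,
    mask: pd.DataFrame | None = None,
    gq_min: int = GQ_MIN_DEFAULT,
    dp_min: int = DP_MIN_DEFAULT,
    max_missing: float = MAX_MISSING_DEFAULT,
    site_to_gene: dict[str, str] | None = None,
    return_callset: bool = False,
):
    """Filter the haploid call and emit the SiteTable (AN/AC fixed up)."""
    filtered = filter_callset(haploid, mask, gq_min, dp_min, max_missing)
    table = site_table(filtered, site_to_gene)
    if return_callset:
        return table, filtered
    return table
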