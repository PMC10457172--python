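"""Folded site frequency spectra: construction, downsampling, replicates.

A folded SFS (fSFS) counts sites by minor-allele count 0..n//2 at a fixed
downsampled size n. Because per-genotype filtering leaves unequal numbers of
called alleles (AN) across sites, sites are projected to a common n by
hypergeometric draws without replacement; sites with AN < n are dropped.
Replicated draws (200 by default) propagate the downsampling noise into the
downstream DFE fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import child_rng


@dataclass
class FoldedSFS:
    """Counts over minor-allele bins 0..n//2 at downsampled size n.

    Bin 0 holds invariant sites: originally monomorphic sites, sites
    monomorphic for the alternate allele (AN=AC, folded to zero), and sites
    that lose their minor allele in the downsample.
    """

    n: int
    bins: np.ndarray
    klass: str | None = None
    gene_set: str | None = None
    replicate: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if len(self.bins) != self.n // 2 + 1:
            raise ValueError(
                f"expected {self.n // 2 + 1} bins for n={self.n}, got {len(self.bins)}"
            )
        if np.any(self.bins < 0):
            raise ValueError("negative bin count")

    @property
    def total_sites(self) -> int:
        return int(self.bins.sum())

    @property
    def segregating(self) -> int:
        return int(self.bins[1:].sum())

    def to_two_line(self) -> str:
        """DFE-alpha-style text block: line 1 sample size, line 2 bins 0..n
        (folded counts in the lower half, zeros above)."""
        full = np.zeros(self.n + 1, dtype=np.int64)
        full[: len(self.bins)] = self.bins
        return f"{self.n}\n" + " ".join(map(str, full)) + "\n"

    @classmethod
    def from_two_line(cls, text: str, **meta) -> "FoldedSFS":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0])
        full = np.array(lines[1].split(), dtype=np.int64)
        if len(full) != n + 1:
            raise ValueError(f"expected {n + 1} entries, got {len(full)}")
        half = n // 2
        if np.any(full[half + 1:] != 0):
            raise ValueError("folded spectrum has mass above n//2")
        return cls(n=n, bins=full[: half + 1], **meta)


def fix_reference_mismatch(sites: pd.DataFrame) -> pd.DataFrame:
    """Set AC to zero wherever AN = AC.

    Sites monomorphic among the samples but carrying a non-reference allele
    (reference individual from another population/species) are not
    polymorphisms; they are folded into the invariant class.
    """
    out = sites.copy()
    out.loc[out["AC"] == out["AN"], "AC"] = 0
    return out


def downsample_site(an: int, ac: int, n: int, rng: np.random.Generator) -> int | None:
    """Minor-allele count of a hypergeometric subsample of n alleles.

    Returns None (drop) when fewer than n alleles were called at the site.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if ac > an or ac < 0:
        raise ValueError(f"AC={ac} outside [0, AN={an}]")
    if an < n:
        return None
    if ac == 0:
        return 0
    k = int(rng.hypergeometric(ac, an - ac, n))
    return min(k, n - k)


def build_sfs(
    sites: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
    klass: str | None = None,
    gene_set: str | None = None,
    replicate: int | None = None,
    seed: int | None = None,
) -> FoldedSFS:
    """One folded SFS: every retained site independently downsampled to n."""
    half = n // 2
    bins = np.zeros(half + 1, dtype=np.int64)
    an = sites["AN"].to_numpy()
    ac = sites["AC"].to_numpy()
    keep = an >= n
    an, ac = an[keep], ac[keep]
    exact = an == n
    for k in np.minimum(ac[exact], n - ac[exact]):
        bins[k] += 1
    for a_n, a_c in zip(an[~exact], ac[~exact]):
        if a_c == 0:
            bins[0] += 1
        else:
            k = int(rng.hypergeometric(a_c, a_n - a_c, n))
            bins[min(k, n - k)] += 1
    return FoldedSFS(n=n, bins=bins, klass=klass, gene_set=gene_set,
                     replicate=replicate, seed=seed)


def build_replicates(
    sites: pd.DataFrame,
    n_list: tuple[int, ...] = (16, 17, 18, 19, 20),
    reps: int = 200,
    seed: int = 0,
    gene_set: str | None = None,
    apply_an_ac_fix: bool = True,
) -> list[FoldedSFS]:
    """Replicate folded SFSs per degeneracy class and downsampling size.

    The site table must carry AN, AC and (if present) a ``degeneracy``
    column; each (class, n, replicate) triple gets its own child stream of
    the master seed, so any single spectrum is reproducible in isolation.
    """
    if apply_an_ac_fix:
        sites = fix_reference_mismatch(sites)
    if "degeneracy" in sites.columns:
        groups = [(k, g) for k, g in sites.groupby("degeneracy", sort=True)]
    else:
        groups = [("all", sites)]
    out: list[FoldedSFS] = []
    for ci, (klass, group) in enumerate(groups):
        for n in n_list:
            for rep in range(reps):
                rng = child_rng(seed, 71, ci, n, rep)
                out.append(
                    build_sfs(group, n, rng, klass=str(klass), gene_set=gene_set,
                              replicate=rep, seed=seed)
                )
    return out


def sfs_long_table(spectra: list[FoldedSFS]) -> pd.DataFrame:
    """Long-format table (gene_set, class, n, replicate, bin, count)."""
    rows = []
    for s in spectra:
        for b, c in enumerate(s.bins):
            rows.append((s.gene_set, s.klass, s.n, s.replicate, b, int(c)))
    return pd.DataFrame(rows, columns=["gene_set", "class", "n", "replicate", "bin", "count"])
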