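"""In-memory call sets and VCF v4.2 round-tripping via pysam.

A CallSet holds one variant call of the whole cohort at a fixed ploidy:
haploid-mode (one allele per genotype) or diploid-mode (two). Invariant
sites are first-class records with no ALT allele. Genotypes, GQ and DP are
dense numpy arrays; -1 marks missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

MISSING = -1


@dataclass
class CallSet:
    contig: np.ndarray            # per-site contig name
    pos: np.ndarray               # per-site position, 1-based
    ref: list                     # per-site reference allele string
    alt: list                     # per-site list of alternate alleles (possibly empty)
    gt: np.ndarray                # (n_sites, n_samples, ploidy) allele indices, -1 missing
    gq: np.ndarray                # (n_sites, n_samples)
    dp: np.ndarray                # (n_sites, n_samples)
    samples: list
    ploidy: int
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.gt.shape[2] != self.ploidy:
            raise ValueError("genotype array ploidy mismatch")
        # positions strictly increasing within each contig
        for ctg in np.unique(self.contig):
            p = self.pos[self.contig == ctg]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {ctg}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_variant(self) -> np.ndarray:
        return np.array([len(a) > 0 for a in self.alt])

    def take(self, idx) -> "CallSet":
        idx = np.asarray(idx)
        return CallSet(
            contig=self.contig[idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            gt=self.gt[idx],
            gq=self.gq[idx],
            dp=self.dp[idx],
            samples=list(self.samples),
            ploidy=self.ploidy,
            contig_lengths=dict(self.contig_lengths),
        )


def write_vcf(cs: CallSet, path: str) -> None:
    """Plain-text VCF v4.2; invariant records carry '.' in the ALT column
    (pysam's record constructor cannot emit ALT-less records)."""
    lengths = dict(cs.contig_lengths)
    with open(str(path), "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for ctg in dict.fromkeys(cs.contig.tolist()):
            length = lengths.get(ctg) or int(cs.pos[cs.contig == ctg].max()) + 1000
            out.write(f"##contig=<ID={ctg},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, cs.samples)) + "\n"
        )
        for i in range(cs.n_sites):
            alt = ",".join(cs.alt[i]) if cs.alt[i] else "."
            fields = [
                str(cs.contig[i]), str(int(cs.pos[i])), ".", cs.ref[i], alt,
                ".", "PASS", ".", "GT:GQ:DP",
            ]
            for j in range(cs.n_samples):
                gt = "/".join(
                    "." if a == MISSING else str(int(a)) for a in cs.gt[i, j]
                )
                gq = "." if cs.gq[i, j] == MISSING else str(int(cs.gq[i, j]))
                dp = "." if cs.dp[i, j] == MISSING else str(int(cs.dp[i, j]))
                fields.append(f"{gt}:{gq}:{dp}")
            out.write("\t".join(fields) + "\n")


def read_vcf(path: str, ploidy: int | None = None) -> CallSet:
    """Read a VCF into a CallSet; ploidy is inferred from the first genotype
    unless given. Invariant records (no ALT) are kept."""
    contigs, pos, ref, alt = [], [], [], []
    gts, gqs, dps = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        contig_lengths = {
            name: ctg.length for name, ctg in vf.header.contigs.items()
        }
        for rec in vf:
            contigs.append(rec.contig)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alts = [a for a in (rec.alts or ()) if a not in (None, ".", "<NON_REF>")]
            alt.append(alts)
            row_gt, row_gq, row_dp = [], [], []
            for s in samples:
                call = rec.samples[s]
                g = call.get("GT") or (None,)
                if ploidy is None:
                    ploidy = len(g)
                g = tuple(MISSING if a is None else int(a) for a in g)
                if len(g) < ploidy:
                    g = g + (MISSING,) * (ploidy - len(g))
                row_gt.append(g[:ploidy])
                gq = call.get("GQ")
                dp = call.get("DP")
                row_gq.append(MISSING if gq is None else int(gq))
                row_dp.append(MISSING if dp is None else int(dp))
            gts.append(row_gt)
            gqs.append(row_gq)
            dps.append(row_dp)
    if ploidy is None:
        ploidy = 1
    return CallSet(
        contig=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref,
        alt=alt,
        gt=np.array(gts, dtype=np.int16).reshape(len(pos), len(samples), ploidy),
        gq=np.array(gqs, dtype=np.int32),
        dp=np.array(dps, dtype=np.int32),
        samples=samples,
        ploidy=int(ploidy),
        contig_lengths=contig_lengths,
    )
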