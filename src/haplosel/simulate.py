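"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: a reference with gene models,
a haploid cohort called at both ploidy levels (with collapsed-paralog
artifacts in the diploid-mode call), a tissue expression matrix with known
per-gene tau, and folded SFS pairs drawn by Poisson sampling around the
Wright-Fisher expectation under a known gamma DFE and two-epoch demography.

All generators are pure functions of (config, truth, seed): child random
streams are derived from the master seed by fixed offsets, so one seed
pins the whole study byte-for-byte.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .callset import CallSet, MISSING
from .config import GroundTruth, N_REF, SimulationConfig, child_rng
from .degeneracy import GeneModel
from .wright_fisher import expected_folded_sfs
from .sfs import FoldedSFS

_BASES = np.array(["A", "C", "G", "T"])
_STOPS = ("TAA", "TAG", "TGA")

# fixed child-stream offsets, one per generator
_STREAM_REFERENCE = 3
_STREAM_TRUTH = 5
_STREAM_COHORT = 11
_STREAM_PARALOG = 13
_STREAM_EXPRESSION = 17
_STREAM_FSFS = 19


class Reference:
    """Synthetic reference: one contig per gene, CDS flanked by noncoding
    sequence, mixed strands."""

    def __init__(self, sequences: dict[str, str], models: list[GeneModel]):
        self.sequences = sequences
        self.models = models

    @property
    def site_to_gene(self) -> dict[str, str]:
        return {m.contig: m.gene for m in self.models}

    def gene_names(self) -> list[str]:
        return [m.gene for m in self.models]

    def cds_sequence(self, gene: str) -> str:
        model = next(m for m in self.models if m.gene == gene)
        seq = "".join(
            self.sequences[model.contig][s - 1:e] for s, e in model.segments
        )
        if model.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in self.models:
                start = min(s for s, _ in m.segments)
                end = max(e for _, e in m.segments)
                fh.write(
                    f"{m.contig}\thaplosel\tgene\t{start}\t{end}\t.\t{m.strand}\t.\tID={m.gene}\n"
                )
                for s, e in m.segments:
                    fh.write(
                        f"{m.contig}\thaplosel\tCDS\t{s}\t{e}\t.\t{m.strand}\t{m.phase}\tParent={m.gene}\n"
                    )


def gene_names(config: SimulationConfig) -> list[str]:
    return [f"g{i:04d}" for i in range(1, config.n_genes + 1)]


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop codon; length in bp."""
    n_codons = length // 3
    if n_codons < 2:
        raise ValueError("gene_length must allow at least start + stop codons")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def make_reference(config: SimulationConfig) -> Reference:
    """One contig per gene; CDS starts with ATG, has no internal stop, and
    sits on the plus or minus strand with the configured strand mix
    (matched exactly when n_genes * fraction is integral)."""
    rng = child_rng(config.seed, _STREAM_REFERENCE)
    names = gene_names(config)
    n_minus = int(round(config.n_genes * config.minus_strand_fraction))
    strands = np.array(["+"] * config.n_genes, dtype=object)
    strands[rng.permutation(config.n_genes)[:n_minus]] = "-"
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    for gi, gene in enumerate(names):
        contig = f"ctg{gi + 1:04d}"
        cds = _random_cds(config.gene_length, rng)
        genomic_cds = cds if strands[gi] == "+" else str(Seq(cds).reverse_complement())
        left = "".join(rng.choice(_BASES, size=config.flank_length))
        right = "".join(rng.choice(_BASES, size=config.flank_length))
        sequences[contig] = left + genomic_cds + right
        start = config.flank_length + 1
        end = config.flank_length + config.gene_length
        models.append(
            GeneModel(gene=gene, contig=contig, strand=str(strands[gi]),
                      segments=[(start, end)], phase=0)
        )
    return Reference(sequences, models)


def default_truth(
    config: SimulationConfig,
    true_beta: float = 0.5,
    true_Es: float = 0.1,
    true_N2_ratio: float = 1.0,
    true_t2: float = 0.0,
) -> GroundTruth:
    """Draw per-gene tau and tissue assignments for the configured cohort.

    A ``tissue_specific_fraction`` of genes gets tau uniform in [0.8, 1]
    (tissue specific), the rest uniform in [0.05, 0.8); assigned tissues
    cycle so every tissue receives specific genes.
    """
    rng = child_rng(config.seed, _STREAM_TRUTH)
    names = gene_names(config)
    tissues = config.tissues
    n_spec = int(round(config.n_genes * config.tissue_specific_fraction))
    order = rng.permutation(config.n_genes)
    tau, tissue = {}, {}
    for rank, gi in enumerate(order):
        g = names[gi]
        if rank < n_spec:
            tau[g] = float(rng.uniform(0.8, 1.0))
        else:
            tau[g] = float(rng.uniform(0.05, 0.8))
        tissue[g] = tissues[rank % len(tissues)]
    return GroundTruth(
        true_beta=true_beta, true_Es=true_Es,
        true_N2_ratio=true_N2_ratio, true_t2=true_t2,
        tau=tau, tissue=tissue,
    )


def _derived_count_weights(n: int) -> np.ndarray:
    j = np.arange(1, n)
    w = 1.0 / j
    return w / w.sum()


def simulate_cohort(
    reference: Reference, config: SimulationConfig, truth: GroundTruth
) -> tuple[CallSet, CallSet]:
    """Haploid-mode and diploid-mode call sets over the same samples.

    Variant sites appear at density ~ theta_pop * a1(n) with sample allele
    counts drawn from the neutral equilibrium (P(j) ~ 1/j); per-genotype GQ
    is a shifted Poisson and DP a negative binomial around the configured
    means; genotypes go missing independently at ``missing_rate``. Genes in
    ``truth.paralog_genes`` (drawn here if unset) carry collapsed-duplicate
    sites where all callable samples are heterozygous in diploid mode.
    """
    n = config.n_samples
    a1 = float((1.0 / np.arange(1, n)).sum())
    p_var = config.theta_pop * a1
    if p_var > 1:
        raise ValueError("requested SNP density exceeds one per site")
    rng = child_rng(config.seed, _STREAM_COHORT)
    prng = child_rng(config.seed, _STREAM_PARALOG)
    names = reference.gene_names()
    if not truth.paralog_genes and config.paralog_fraction > 0:
        k = int(np.ceil(config.n_genes * config.paralog_fraction))
        truth.paralog_genes = sorted(
            np.array(names, dtype=object)[prng.permutation(len(names))[:k]].tolist()
        )
    paralogs = set(truth.paralog_genes)
    truth.paralog_sites = []
    jw = _derived_count_weights(n)
    nb_r = config.depth_dispersion
    nb_p = nb_r / (nb_r + config.depth_mean)

    contigs, positions, refs, alts = [], [], [], []
    gt_h, gt_d, gqs, dps = [], [], [], []
    first_model = reference.models[0]
    for model in reference.models:
        seq = reference.sequences[model.contig]
        L = len(seq)
        variant = rng.random(L) < p_var
        divergent = np.zeros(L, dtype=bool)
        if model.gene in paralogs:
            divergent = prng.random(L) < config.paralog_divergence
            if not divergent.any():
                divergent[prng.integers(L)] = True
        missing = rng.random((L, n)) < config.missing_rate
        # collapsed paralogs still produce reads: keep >=2 callable samples
        missing[divergent, :2] = False
        gq = 1 + rng.poisson(config.gq_mean - 1, size=(L, n))
        dp = rng.negative_binomial(nb_r, nb_p, size=(L, n))
        hap = np.zeros((L, n), dtype=np.int16)
        for p0 in np.flatnonzero(variant):
            j = rng.choice(np.arange(1, n), p=jw)
            hap[p0, rng.permutation(n)[:j]] = 1
        # haploid caller picks one collapsed copy quasi-randomly per sample
        for p0 in np.flatnonzero(divergent & ~variant):
            hap[p0] = rng.integers(0, 2, size=n)
        # spiked filter-test variants (totals, placed on the first contig)
        spiked = (
            _spike_positions(config, rng, variant | divergent, L)
            if model is first_model
            else {}
        )
        for p0 in range(L):
            is_var = variant[p0] or divergent[p0]
            ref_base = seq[p0]
            if p0 in spiked:
                kind = spiked[p0]
                if kind == "indel":
                    contigs.append(model.contig)
                    positions.append(p0 + 1)
                    refs.append(ref_base + seq[(p0 + 1) % L])
                    alts.append([ref_base])
                    g = rng.integers(0, 2, size=n)
                    _append_site(gt_h, gt_d, gqs, dps, g, missing[p0], gq[p0], dp[p0], het=False)
                    continue
                if kind == "multiallelic":
                    others = [b for b in _BASES if b != ref_base]
                    contigs.append(model.contig)
                    positions.append(p0 + 1)
                    refs.append(ref_base)
                    alts.append(list(rng.choice(others, size=2, replace=False)))
                    g = rng.integers(0, 3, size=n)
                    _append_site(gt_h, gt_d, gqs, dps, g, missing[p0], gq[p0], dp[p0], het=False)
                    continue
            contigs.append(model.contig)
            positions.append(p0 + 1)
            refs.append(ref_base)
            if is_var:
                alt_base = str(rng.choice([b for b in _BASES if b != ref_base]))
                alts.append([alt_base])
            else:
                alts.append([])
            if divergent[p0]:
                truth.paralog_sites.append((model.contig, p0 + 1))
            _append_site(
                gt_h, gt_d, gqs, dps, hap[p0], missing[p0], gq[p0], dp[p0],
                het=bool(divergent[p0]),
            )
    n_sites = len(positions)
    common = dict(
        contig=np.array(contigs, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=refs,
        alt=alts,
        samples=[f"mg{i + 1:02d}" for i in range(n)],
        contig_lengths={c: len(s) for c, s in reference.sequences.items()},
    )
    gq_arr = np.array(gqs, dtype=np.int32)
    dp_arr = np.array(dps, dtype=np.int32)
    hap_cs = CallSet(
        gt=np.array(gt_h, dtype=np.int16).reshape(n_sites, n, 1),
        gq=gq_arr, dp=dp_arr, ploidy=1, **common,
    )
    dip_cs = CallSet(
        gt=np.array(gt_d, dtype=np.int16).reshape(n_sites, n, 2),
        gq=gq_arr.copy(), dp=dp_arr.copy(), ploidy=2, **common,
    )
    return hap_cs, dip_cs


def _spike_positions(config, rng, occupied, L) -> dict[int, str]:
    spiked: dict[int, str] = {}
    free = np.flatnonzero(~occupied)
    want = config.spike_indels + config.spike_multiallelic
    if want == 0 or len(free) == 0:
        return spiked
    chosen = rng.choice(free, size=min(want, len(free)), replace=False)
    for i, p0 in enumerate(chosen):
        spiked[int(p0)] = "indel" if i < config.spike_indels else "multiallelic"
    return spiked


def _append_site(gt_h, gt_d, gqs, dps, hap_alleles, missing, gq_row, dp_row, het):
    h = np.where(missing, MISSING, hap_alleles).astype(np.int16)
    gt_h.append(h[:, None])
    if het:
        d = np.stack([np.zeros_like(h), np.ones_like(h)], axis=1)
        d[missing] = MISSING
    else:
        d = np.stack([h, h], axis=1)
    gt_d.append(d)
    gq_masked = np.where(missing, 0, gq_row)
    dp_masked = np.where(missing, 0, dp_row)
    gqs.append(gq_masked)
    dps.append(dp_masked)


def simulate_expression(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Genes x tissues matrix whose per-gene tau equals the truth exactly.

    Construction: the assigned tissue carries the gene's expression level
    (log-normal across genes, TMM-like units) and every other tissue
    carries level*(1 - tau), which makes the tau index of the emitted
    vector equal the target by construction.
    """
    rng = child_rng(config.seed, _STREAM_EXPRESSION)
    tissues = list(config.tissues)
    rows = []
    for gene in sorted(truth.tau):
        t = truth.tau[gene]
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"target tau {t} outside [0, 1] for gene {gene}")
        level = float(rng.lognormal(mean=np.log(50.0), sigma=1.0))
        vec = np.full(len(tissues), level * (1.0 - t))
        vec[tissues.index(truth.tissue[gene])] = level
        rows.append(vec)
    return pd.DataFrame(rows, index=sorted(truth.tau), columns=tissues)


def simulate_fsfs_pair(
    truth: GroundTruth,
    L0: int,
    L4: int,
    n: int,
    seed: int,
    theta: float = 0.005,
    nes_grid_size: int = 64,
) -> tuple[FoldedSFS, FoldedSFS]:
    """Poisson-sampled folded SFS pair (0-fold, 4-fold) under the truth.

    The 4-fold spectrum is neutral under the two-epoch demography; the
    0-fold spectrum mixes the Wright-Fisher expectation over a gamma
    distribution of deleterious effects (shape ``true_beta``, mean scaled
    effect ``N_REF * true_Es``). The per-site mutation influx is set so
    the neutral class has Watterson theta ~ ``theta`` per site. Bin 0
    holds the invariant remainder of the L sites.
    """
    from .dfe import nes_grid, gamma_weights  # local import: avoid cycle

    if L0 <= 0 or L4 <= 0:
        raise ValueError("L0 and L4 must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAM_FSFS])
    )
    a1 = float((1.0 / np.arange(1, n)).sum())
    e4 = expected_folded_sfs(n, 0.0, truth.true_N2_ratio, truth.true_t2)[1:]
    u_site = theta * a1 / e4.sum()
    if truth.true_Es > 0:
        grid = nes_grid(nes_grid_size)
        w = gamma_weights(truth.true_beta, N_REF * truth.true_Es, grid)
        e0 = np.zeros_like(e4)
        for wc, nes in zip(w, grid):
            if wc <= 0:
                continue
            e0 += wc * expected_folded_sfs(
                n, -nes / N_REF, truth.true_N2_ratio, truth.true_t2
            )[1:]
    else:
        e0 = e4
    out = []
    for klass, L, e in (("0-fold", L0, e0), ("4-fold", L4, e4)):
        lam = u_site * L * e
        if not np.all(np.isfinite(lam)):
            raise ValueError("non-finite expected spectrum")
        seg = rng.poisson(lam)
        if seg.sum() > L:
            raise ValueError("expected segregating sites exceed class size")
        bins = np.concatenate([[L - seg.sum()], seg])
        out.append(FoldedSFS(n=n, bins=bins, klass=klass, seed=seed))
    return out[0], out[1]


def write_truth_tsv(truth: GroundTruth, path) -> None:
    df = truth.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    with open(path, "a") as fh:
        fh.write(
            f"# true_beta={truth.true_beta} true_Es={truth.true_Es} "
            f"true_N2_ratio={truth.true_N2_ratio} true_t2={truth.true_t2}\n"
        )
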