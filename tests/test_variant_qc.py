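"""Paralog detection, window masking and the genotype/site filter chain."""

import numpy as np
import pandas as pd
import pytest

from haplosel import simulate, variant_qc
from haplosel.callset import CallSet, MISSING, read_vcf, write_vcf
from haplosel.config import SimulationConfig


def diploid_from_gt(gt_pairs, contig="c1"):
    """Build a tiny diploid call set from a list of per-site genotype lists."""
    n_sites = len(gt_pairs)
    n_samples = len(gt_pairs[0])
    gt = np.array(gt_pairs, dtype=np.int16).reshape(n_sites, n_samples, 2)
    return CallSet(
        contig=np.array([contig] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64) * 10,
        ref=["A"] * n_sites,
        alt=[["G"]] * n_sites,
        gt=gt,
        gq=np.full((n_sites, n_samples), 60, dtype=np.int32),
        dp=np.full((n_sites, n_samples), 30, dtype=np.int32),
        samples=[f"s{i}" for i in range(n_samples)],
        ploidy=2,
    )


class TestDetect:
    def test_two_hets_flagged_one_not(self):
        hom = (0, 0)
        het = (0, 1)
        sites = [
            [hom] * 3 + [het] + [hom] * 3 + [het] + [hom] * 2,   # hets in samples 3 and 7
            [het] + [hom] * 9,                                   # single het
            [hom] * 10,
        ]
        flagged = variant_qc.detect_paralog_sites(diploid_from_gt(sites))
        assert flagged == [("c1", 10)]

    def test_all_homozygous_empty(self):
        flagged = variant_qc.detect_paralog_sites(diploid_from_gt([[(1, 1)] * 4]))
        assert flagged == []

    def test_missing_allele_never_counts(self):
        sites = [[(0, MISSING), (MISSING, MISSING), (0, 1), (0, 0)]]
        assert variant_qc.detect_paralog_sites(diploid_from_gt(sites)) == []

    def test_requires_diploid(self, small_cohort):
        _, _, hap, _ = small_cohort
        with pytest.raises(ValueError):
            variant_qc.detect_paralog_sites(hap)

    def test_recovers_injected_paralogs_exactly(self, small_cohort):
        ref, truth, hap, dip = small_cohort
        a, b = dip.gt[:, :, 0], dip.gt[:, :, 1]
        het = ((a != b) & (a != MISSING) & (b != MISSING)).sum(axis=1)
        expected = {
            (str(c), int(p)) for c, p in zip(dip.contig[het >= 2], dip.pos[het >= 2])
        }
        assert set(variant_qc.detect_paralog_sites(dip)) == expected
        assert expected <= set(map(tuple, truth.paralog_sites)) or expected == set(
            map(tuple, truth.paralog_sites)
        )

    def test_paralog_free_simulation_flags_nothing(self):
        c = SimulationConfig(n_genes=6, gene_length=300, flank_length=30,
                             seed=21, paralog_fraction=0.0)
        truth = simulate.default_truth(c)
        _, dip = simulate.simulate_cohort(simulate.make_reference(c), c, truth)
        assert variant_qc.detect_paralog_sites(dip) == []


class TestMask:
    def test_window_geometry(self):
        mask = variant_qc.build_mask([("c1", 1000)], window_bp=150)
        assert mask.iloc[0][["start", "end"]].tolist() == [924, 1075]

    def test_nearby_windows_merge(self):
        mask = variant_qc.build_mask([("c1", 1000), ("c1", 1010)], window_bp=150)
        assert len(mask) == 1
        assert mask.iloc[0][["start", "end"]].tolist() == [924, 1085]
        assert mask.iloc[0]["sources"] == "1000,1010"

    def test_empty_input(self):
        assert len(variant_qc.build_mask([])) == 0

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            variant_qc.build_mask([("c1", 5)], window_bp=0)


def toy_haploid():
    """20 samples; crafted boundary sites for the filter semantics."""
    n = 20
    sites = []

    def site(pos, ref, alt, alleles, gq=60, dp=30):
        gqv = np.full(n, gq) if np.isscalar(gq) else np.asarray(gq)
        dpv = np.full(n, dp) if np.isscalar(dp) else np.asarray(dp)
        sites.append((pos, ref, alt, np.asarray(alleles), gqv, dpv))

    ones = [1] * 5 + [0] * 15
    site(100, "A", ["G"], ones)                          # clean biallelic SNP
    site(200, "AT", ["A"], ones)                         # indel: dropped
    site(300, "A", ["C", "T"], [2] * 3 + [1] * 3 + [0] * 14)  # triallelic: dropped
    site(400, "A", ["G"], ones, gq=[20] * 1 + [60] * 19)  # GQ=20 boundary genotype
    site(500, "A", ["G"], ones, dp=[10] * 1 + [30] * 19)  # DP=10 boundary genotype
    site(600, "A", ["G"], [0] * 5 + [1] * 2 + [0] * 13, gq=[15] * 5 + [60] * 15)  # 25% missing: dropped
    site(700, "A", ["G"], [0] * 4 + [1] * 2 + [0] * 14, gq=[15] * 4 + [60] * 16)  # 20% missing: kept
    site(800, "A", [], [0] * n)                          # invariant record
    site(900, "A", ["G"], [MISSING] * 2 + [1] * 6 + [0] * 12)  # called-missing genotypes

    pos = np.array([s[0] for s in sites], dtype=np.int64)
    return CallSet(
        contig=np.array(["c1"] * len(sites), dtype=object),
        pos=pos,
        ref=[s[1] for s in sites],
        alt=[s[2] for s in sites],
        gt=np.stack([s[3] for s in sites]).astype(np.int16)[:, :, None],
        gq=np.stack([s[4] for s in sites]).astype(np.int32),
        dp=np.stack([s[5] for s in sites]).astype(np.int32),
        samples=[f"s{i:02d}" for i in range(n)],
        ploidy=1,
    )


class TestFilters:
    def test_toy_vcf_semantics(self, tmp_path):
        """Spiked indel/triallelic/boundary/missing sites give the exact
        expected surviving table, with AN/AC recomputed."""
        path = tmp_path / "toy.vcf"
        write_vcf(toy_haploid(), path)
        hap = read_vcf(path, ploidy=1)
        table = variant_qc.apply_filters(hap, mask=None)
        expected = pd.DataFrame(
            {
                "pos": [100, 400, 500, 700, 800, 900],
                "AN": [20, 19, 19, 16, 20, 18],
                "AC": [5, 4, 4, 2, 0, 6],
            }
        )
        got = table[["pos", "AN", "AC"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)

    def test_site_at_exact_missing_threshold_kept(self):
        table = variant_qc.apply_filters(toy_haploid(), mask=None)
        assert 700 in table["pos"].values      # exactly 20% missing
        assert 600 not in table["pos"].values  # 25% missing

    def test_mask_removes_windowed_sites(self):
        mask = variant_qc.build_mask([("c1", 100)], window_bp=150)
        table = variant_qc.apply_filters(toy_haploid(), mask)
        assert 100 not in table["pos"].values
        assert 400 in table["pos"].values

    def test_an_ac_match_bruteforce(self, small_cohort):
        ref, _, hap, dip = small_cohort
        mask = variant_qc.build_mask(variant_qc.detect_paralog_sites(dip))
        table, cs = variant_qc.apply_filters(hap, mask, return_callset=True)
        for i in range(cs.n_sites):
            alleles = [a for a in cs.gt[i, :, 0] if a != MISSING]
            assert table["AN"].iloc[i] == len(alleles)
            assert table["AC"].iloc[i] == sum(1 for a in alleles if a == 1)

    def test_idempotent(self, small_cohort):
        _, _, hap, dip = small_cohort
        mask = variant_qc.build_mask(variant_qc.detect_paralog_sites(dip))
        once, cs = variant_qc.apply_filters(hap, mask, return_callset=True)
        twice = variant_qc.apply_filters(cs, mask)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )
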