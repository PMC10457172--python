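"""Degeneracy classes against a brute-force substitution translator."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from haplosel import degeneracy
from haplosel.degeneracy import GeneModel


def brute_force_classes(cds: str) -> list[str]:
    """Independent oracle: translate all 9 substitutions per codon."""
    out = []
    for ci in range(0, len(cds), 3):
        codon = cds[ci:ci + 3]
        aa = str(Seq(codon).translate())
        for off in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[off]:
                    continue
                alt = codon[:off] + b + codon[off + 1:]
                if str(Seq(alt).translate()) == aa:
                    syn += 1
            out.append({0: "0-fold", 1: "2-fold", 2: "3-fold", 3: "4-fold"}[syn])
    return out


def random_cds(rng, n_codons=30) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


class TestCodonClass:
    def test_glycine_third_position_fourfold(self):
        assert degeneracy.codon_position_class("GGG", 2) == "4-fold"

    def test_atg_all_zerofold(self):
        assert all(degeneracy.codon_position_class("ATG", i) == "0-fold" for i in range(3))

    def test_twofold_and_threefold(self):
        assert degeneracy.codon_position_class("TTT", 2) == "2-fold"  # Phe
        assert degeneracy.codon_position_class("ATT", 2) == "3-fold"  # Ile


class TestAnnotate:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_bruteforce_on_random_cds(self, rng, strand):
        for _ in range(50):
            cds = random_cds(rng)
            genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
            ref = {"c": "AAAA" + genomic + "TTTT"}
            model = GeneModel("g", "c", strand, [(5, 4 + len(cds))])
            out = degeneracy.annotate_degeneracy(ref, [model])
            expected = brute_force_classes(cds)
            got = out.sort_values("pos")
            if strand == "-":
                got = got.iloc[::-1]
            assert got["degeneracy"].tolist() == expected

    def test_minus_strand_equals_flipped_plus(self, rng):
        cds = random_cds(rng)
        plus_ref = {"c": cds}
        minus_ref = {"c": str(Seq(cds).reverse_complement())}
        L = len(cds)
        plus = degeneracy.annotate_degeneracy(plus_ref, [GeneModel("g", "c", "+", [(1, L)])])
        minus = degeneracy.annotate_degeneracy(minus_ref, [GeneModel("g", "c", "-", [(1, L)])])
        flipped = minus.assign(pos=L + 1 - minus["pos"]).sort_values("pos")
        assert flipped["degeneracy"].tolist() == plus.sort_values("pos")["degeneracy"].tolist()

    def test_class_counts_cover_cds(self, rng):
        cds = random_cds(rng, n_codons=40)
        out = degeneracy.annotate_degeneracy(
            {"c": cds}, [GeneModel("g", "c", "+", [(1, len(cds))])]
        )
        assert len(out) == len(cds)

    def test_skips_internal_stop_and_bad_length(self):
        ref = {"c": "ATGTAATTTTAA" + "ATGAAAA"}
        models = [
            GeneModel("stop", "c", "+", [(1, 12)]),     # internal TAA
            GeneModel("len", "c", "+", [(13, 19)]),     # 7 bp
        ]
        with pytest.warns(UserWarning):
            out = degeneracy.annotate_degeneracy(ref, models)
        assert len(out) == 0

    def test_conflicting_overlap_dropped(self):
        # overlapping frames, both stop-free: conflicting positions vanish
        seq = "ATG" + "CCA" * 4 + "TAA"
        models = [
            GeneModel("a", "c", "+", [(1, 18)]),
            GeneModel("b", "c", "+", [(5, 16)]),   # shifted reading frame
        ]
        out = degeneracy.annotate_degeneracy({"c": seq}, models)
        claimed = out.groupby("pos").size()
        assert (claimed <= 1).all()
        # position 6: 4-fold in gene a (CCA wobble), 0-fold in gene b -> dropped
        assert 6 not in out["pos"].values
        # position 17: only gene a claims it -> kept
        assert 17 in out["pos"].values

    def test_phase_honoured(self):
        cds = "ATGAAATTTTAA"
        ref = {"c": "GG" + cds}
        # segment includes 2 leading bases; phase=2 skips them
        model = GeneModel("g", "c", "+", [(1, 2 + len(cds))], phase=2)
        out = degeneracy.annotate_degeneracy(ref, [model])
        got = out.sort_values("pos")["degeneracy"].tolist()
        assert got == brute_force_classes(cds)


class TestRestrict:
    def make_map(self):
        return pd.DataFrame(
            {
                "contig": ["c"] * 4,
                "pos": [1, 2, 3, 4],
                "gene": ["g"] * 4,
                "degeneracy": ["0-fold", "2-fold", "4-fold", "3-fold"],
            }
        )

    def test_keeps_only_requested_classes(self):
        sites = pd.DataFrame({"contig": ["c"] * 4, "pos": [1, 2, 3, 4],
                              "AN": [20] * 4, "AC": [1] * 4})
        out = degeneracy.restrict_sites(sites, self.make_map())
        assert out["pos"].tolist() == [1, 3]
        assert out["degeneracy"].tolist() == ["0-fold", "4-fold"]

    def test_empty_intersection(self):
        sites = pd.DataFrame({"contig": ["c"], "pos": [99], "AN": [20], "AC": [0]})
        assert len(degeneracy.restrict_sites(sites, self.make_map())) == 0

    def test_count_equals_bruteforce_join(self, rng):
        degmap = pd.DataFrame(
            {
                "contig": "c",
                "pos": np.arange(1, 201),
                "gene": "g",
                "degeneracy": rng.choice(
                    ["0-fold", "2-fold", "3-fold", "4-fold"], size=200
                ),
            }
        )
        pos = rng.choice(np.arange(1, 301), size=120, replace=False)
        sites = pd.DataFrame({"contig": "c", "pos": np.sort(pos),
                              "AN": 20, "AC": 0})
        out = degeneracy.restrict_sites(sites, degmap)
        wanted = {
            p for p, k in zip(degmap["pos"], degmap["degeneracy"])
            if k in ("0-fold", "4-fold")
        }
        assert len(out) == len(set(sites["pos"]) & wanted)


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 100.0), ("ATAT", 0.0), ("ATGC", 50.0)]
    )
    def test_examples(self, seq, expected):
        assert degeneracy.gc_content(seq) == pytest.approx(expected)

    def test_ambiguity_excluded_from_denominator(self):
        assert degeneracy.gc_content("GCNN") == pytest.approx(100.0)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            degeneracy.gc_content("NNNN")
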