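"""Codon degeneracy annotation (0-fold/4-fold) and GC content.

A coding position is 4-fold degenerate when every possible nucleotide
substitution leaves the encoded amino acid unchanged, 0-fold when none
does; 2-fold/3-fold cover the intermediate cases. Degeneracy is evaluated
per position by explicit substitution-and-translate under the standard
genetic code (stop treated as its own identity), which handles serine-type
edge cases uniformly instead of relying on codon-family tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from Bio.Data import CodonTable

_BASES = ("A", "C", "G", "T")
_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon: str) -> str | None:
    codon = codon.upper()
    if any(b not in _BASES for b in codon):
        return None
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


def codon_position_class(codon: str, offset: int) -> str | None:
    """Degeneracy class of one position (offset 0..2) of one codon."""
    ref_aa = _aa(codon)
    if ref_aa is None:
        return None
    syn = 0
    for b in _BASES:
        if b == codon[offset].upper():
            continue
        alt = codon[:offset] + b + codon[offset + 1:]
        if _aa(alt) == ref_aa:
            syn += 1
    return {0: "0-fold", 1: "2-fold", 2: "3-fold", 3: "4-fold"}[syn]


@dataclass
class GeneModel:
    gene: str
    contig: str
    strand: str
    # CDS segments as (start, end), 1-based inclusive, ascending
    segments: list[tuple[int, int]]
    phase: int = 0


def read_gff3_cds(path) -> list[GeneModel]:
    """Collect CDS segments per gene from a GFF3 (1-based inclusive).

    Segments are grouped by the Parent attribute (falling back to ID),
    which for the models this package writes is the gene id.
    """
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ) if len(f) > 8 else {}
            parent = attrs.get("Parent", attrs.get("ID", f[0]))
            g = groups.setdefault(parent, {
                "contig": f[0], "strand": f[6], "segments": [], "phases": []
            })
            g["segments"].append((int(f[3]), int(f[4])))
            g["phases"].append(0 if f[7] == "." else int(f[7]))
    models = []
    for gene, g in groups.items():
        order = sorted(range(len(g["segments"])), key=lambda i: g["segments"][i][0])
        segs = [g["segments"][i] for i in order]
        # phase of the segment translated first (leftmost on +, rightmost on -)
        phase = g["phases"][order[0]] if g["strand"] == "+" else g["phases"][order[-1]]
        models.append(GeneModel(gene=gene, contig=g["contig"], strand=g["strand"],
                                segments=segs, phase=phase))
    return models


def _cds_positions_and_seq(model: GeneModel, contig_seq: str) -> tuple[list[int], str]:
    """Genomic positions (1-based) in translation order and the CDS sequence."""
    positions: list[int] = []
    for start, end in model.segments:
        positions.extend(range(start, end + 1))
    seq = "".join(contig_seq[p - 1] for p in positions).upper()
    if model.strand == "-":
        positions = positions[::-1]
        seq = str(Seq(seq).reverse_complement())
    if model.phase:
        positions = positions[model.phase:]
        seq = seq[model.phase:]
    return positions, seq


def annotate_degeneracy(reference: dict[str, str], models: list[GeneModel]) -> pd.DataFrame:
    """Per-position degeneracy classes for every annotated CDS.

    Genes whose CDS length is not a multiple of 3 or that contain an
    internal stop codon are skipped with a warning. Positions covered by
    overlapping CDS with conflicting classes are dropped.
    """
    assigned: dict[tuple[str, int], tuple[str, str]] = {}
    conflicts: set[tuple[str, int]] = set()
    for model in models:
        contig_seq = reference[model.contig]
        positions, seq = _cds_positions_and_seq(model, contig_seq)
        if len(seq) % 3 != 0:
            warnings.warn(f"gene {model.gene}: CDS length not divisible by 3, skipped")
            continue
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if any(_aa(c) == "*" for c in codons[:-1]):
            warnings.warn(f"gene {model.gene}: internal stop codon, skipped")
            continue
        for ci, codon in enumerate(codons):
            for off in range(3):
                klass = codon_position_class(codon, off)
                if klass is None:
                    continue
                key = (model.contig, positions[3 * ci + off])
                prev = assigned.get(key)
                if prev is not None and prev[1] != klass:
                    conflicts.add(key)
                else:
                    assigned[key] = (model.gene, klass)
    rows = [
        {"contig": c, "pos": p, "gene": g, "degeneracy": k}
        for (c, p), (g, k) in assigned.items()
        if (c, p) not in conflicts
    ]
    return (
        pd.DataFrame(rows, columns=["contig", "pos", "gene", "degeneracy"])
        .sort_values(["contig", "pos"])
        .reset_index(drop=True)
    )


def restrict_sites(
    sites: pd.DataFrame,
    degeneracy_map: pd.DataFrame,
    classes: tuple[str, ...] = ("0-fold", "4-fold"),
) -> pd.DataFrame:
    """Keep only sites whose position carries one of the requested classes,
    attaching the class (and the map's gene id) to each site."""
    keep = degeneracy_map[degeneracy_map["degeneracy"].isin(classes)]
    merged = sites.drop(columns=[c for c in ("degeneracy", "gene") if c in sites.columns]).merge(
        keep[["contig", "pos", "gene", "degeneracy"]], on=["contig", "pos"], how="inner"
    )
    return merged.sort_values(["contig", "pos"]).reset_index(drop=True)


def gc_content(sequences) -> float:
    """Percent G+C over unambiguous bases of a set of sequences.

    Ambiguity codes are excluded from the denominator; an input with no
    A/C/G/T at all is rejected.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("no unambiguous bases in input")
    return 100.0 * gc / total


def degeneracy_bed(degeneracy_map: pd.DataFrame, classes=("0-fold", "4-fold")) -> pd.DataFrame:
    """BED-style (0-based half-open) table of classified positions."""
    sub = degeneracy_map[degeneracy_map["degeneracy"].isin(classes)]
    return pd.DataFrame(
        {
            "contig": sub["contig"],
            "start": sub["pos"] - 1,
            "end": sub["pos"],
            "name": sub["degeneracy"],
        }
    )
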