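"""Simulation configuration and ground-truth containers.

The synthetic cohort emulates the sampling design of the study system: 20
megagametophytes (haploid seed tissue) from unrelated trees of a single
panmictic conifer population, genotyped in parallel at ploidy 1 and ploidy 2,
plus a 5-tissue expression matrix and folded site frequency spectra drawn
under a known gamma distribution of fitness effects (DFE) and a two-epoch
demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import yaml

#: Reference ancestral (diploid) population size of the Wright-Fisher engine.
#: Scaled selection is expressed as Nes = N_REF * |s|.
N_REF = 100

DEFAULT_TISSUES = ("megagametophyte", "bud", "embryo", "needle", "phloem")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    ``theta_pop`` mirrors the population-model prior conventionally given
    to the variant caller (0.005 per site). ``missing_rate`` is the
    per-genotype missing probability and should stay within the 20%
    missing-data ceiling for the cohort to be usable at n=16 downsampling.
    """

    n_samples: int = 20
    n_genes: int = 40
    n_tissues: int = 5
    gene_length: int = 900          # CDS length in bp, multiple of 3
    flank_length: int = 60          # noncoding flank on each side of the CDS
    theta_pop: float = 0.005
    paralog_fraction: float = 0.1
    paralog_divergence: float = 0.01
    missing_rate: float = 0.1
    depth_mean: float = 30.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    gq_mean: float = 60.0
    minus_strand_fraction: float = 0.5
    tissue_specific_fraction: float = 0.6
    spike_indels: int = 0
    spike_multiallelic: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must be in [0, 1]")
        if self.theta_pop <= 0:
            raise ValueError("theta_pop must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")

    @property
    def tissues(self) -> tuple[str, ...]:
        names = list(DEFAULT_TISSUES)
        while len(names) < self.n_tissues:
            names.append(f"tissue{len(names) + 1}")
        return tuple(names[: self.n_tissues])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class GroundTruth:
    """Known truth the generators embed, against which recovery is judged.

    ``true_Es`` is the mean deleterious effect in per-copy units of the
    Wright-Fisher engine; the corresponding scaled mean is
    ``N_REF * true_Es`` (e.g. Es=0.5 -> mean Nes=50). ``true_t2`` counts
    generations at the engine's reference size.
    """

    true_beta: float = 0.5
    true_Es: float = 0.1
    true_N2_ratio: float = 1.0
    true_t2: float = 0.0
    tau: dict[str, float] = field(default_factory=dict)
    tissue: dict[str, str] = field(default_factory=dict)
    paralog_genes: list[str] = field(default_factory=list)
    paralog_sites: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.true_beta <= 0:
            raise ValueError("true_beta must be > 0")
        if self.true_Es < 0:
            raise ValueError("true_Es must be >= 0")
        if self.true_N2_ratio <= 0:
            raise ValueError("true_N2_ratio must be > 0")
        if self.true_t2 < 0:
            raise ValueError("true_t2 must be >= 0")

    @property
    def mean_nes(self) -> float:
        return N_REF * self.true_Es

    def to_frame(self):
        import pandas as pd

        genes = sorted(self.tau)
        return pd.DataFrame(
            {
                "gene": genes,
                "true_tau": [self.tau[g] for g in genes],
                "true_tissue": [self.tissue.get(g, "") for g in genes],
                "is_paralog": [g in set(self.paralog_genes) for g in genes],
            }
        )


def child_seed(master: int, *stream: int) -> np.random.SeedSequence:
    """Derive a reproducible child seed stream by fixed offsets.

    Every generator in the package draws from a stream obtained this way, so
    a single master seed pins the whole synthetic study.
    """
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *map(int, stream)])


def child_rng(master: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *stream))


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "N_REF",
    "DEFAULT_TISSUES",
    "child_seed",
    "child_rng",
    "replace",
]
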