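"""End-to-end orchestration on synthetic (or user-provided) inputs.

Stage order matches the analysis chain: simulate -> qc -> annotate ->
expression -> diversity -> sfs -> dfe -> compare. Every stage writes its
tables into the output directory; a JSON manifest records configuration
hash, seeds, stage status and row counts. The whole run is a pure function
of (config, seed): repeated runs emit byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    compare,
    degeneracy,
    dfe,
    diversity,
    expression,
    sfs,
    simulate,
    variant_qc,
)
from .callset import write_vcf
from .config import GroundTruth, SimulationConfig

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    truth: GroundTruth | None = None
    window_bp: int = variant_qc.WINDOW_BP_DEFAULT
    gq_min: int = variant_qc.GQ_MIN_DEFAULT
    dp_min: int = variant_qc.DP_MIN_DEFAULT
    max_missing: float = variant_qc.MAX_MISSING_DEFAULT
    tau_min: float = expression.TAU_MIN_DEFAULT
    min_total_sites: int = 50
    n_list: tuple[int, ...] = (16,)
    primary_n: int = 16
    reps: int = 200
    mutation_scale: str = "tied"
    min_segregating: int = 5
    subset_analyses: bool = True
    fit_options: dfe.FitOptions = field(default_factory=dfe.FitOptions)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "sim": self.sim.to_dict(),
                "truth": None if self.truth is None else {
                    "true_beta": self.truth.true_beta,
                    "true_Es": self.truth.true_Es,
                    "true_N2_ratio": self.truth.true_N2_ratio,
                    "true_t2": self.truth.true_t2,
                },
                "qc": [self.window_bp, self.gq_min, self.dp_min, self.max_missing],
                "tau_min": self.tau_min,
                "sfs": [list(self.n_list), self.primary_n, self.reps],
                "mutation_scale": self.mutation_scale,
                "subset_analyses": self.subset_analyses,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    A stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages remain on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "stages": [],
    }
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            info = fn() or {}
        except Exception as exc:  # noqa: BLE001 - halt with stage name
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            _write_manifest(manifest, out)
            raise PipelineError(name, exc) from exc
        manifest["stages"].append(
            {"name": name, "status": "completed",
             "seconds": round(time.perf_counter() - t0, 3), **info}
        )

    def do_simulate():
        truth = config.truth or simulate.default_truth(config.sim)
        ref = simulate.make_reference(config.sim)
        hap, dip = simulate.simulate_cohort(ref, config.sim, truth)
        expr = simulate.simulate_expression(config.sim, truth)
        ref.write_fasta(out / "reference.fasta")
        ref.write_gff3(out / "genes.gff3")
        write_vcf(hap, out / "haploid.vcf")
        write_vcf(dip, out / "diploid.vcf")
        expression.write_expression_tsv(expr, out / "expression.tsv")
        simulate.write_truth_tsv(truth, out / "truth.tsv")
        state.update(truth=truth, ref=ref, hap=hap, dip=dip, expr=expr)
        return {"n_sites": hap.n_sites, "n_paralog_genes": len(truth.paralog_genes)}

    def do_qc():
        flagged = variant_qc.detect_paralog_sites(state["dip"])
        mask = variant_qc.build_mask(flagged, config.window_bp)
        variant_qc.write_mask_bed(mask, out / "paralog_mask.bed")
        sites = variant_qc.apply_filters(
            state["hap"], mask, config.gq_min, config.dp_min,
            config.max_missing, state["ref"].site_to_gene,
        )
        _write(sites, out / "sites_qc.tsv")
        state.update(sites=sites, mask=mask)
        return {"n_flagged": len(flagged), "n_sites_pass": len(sites)}

    def do_annotate():
        degmap = degeneracy.annotate_degeneracy(
            state["ref"].sequences, state["ref"].models
        )
        sites = degeneracy.restrict_sites(state["sites"], degmap)
        _write(sites, out / "sites_degeneracy.tsv")
        state.update(degmap=degmap, sites04=sites)
        return {"n_sites_04": len(sites)}

    def do_expression():
        table = expression.tau_table(state["expr"])
        sets = expression.select_tissue_specific(table, config.tau_min)
        if config.subset_analyses:
            # robustness subsets per tissue: narrower breadth (tau strictly
            # above the set median) and lower expression (at or below the
            # set median level)
            for label in [k for k in sets if k != "all_genes"]:
                genes = sets[label]
                if len(genes) < 2:
                    continue
                sets[f"{label}:high_tau"] = expression.subset_high_tau(table, genes)
                sets[f"{label}:low_expr"] = expression.subset_low_expression(table, genes)
        sets = {k: v for k, v in sets.items() if v}
        _write(table, out / "tau.tsv")
        rows = [
            {"gene_set": label, "gene": g} for label, gs in sets.items() for g in gs
        ]
        _write(pd.DataFrame(rows), out / "gene_sets.tsv")
        state.update(tau=table, sets=sets)
        return {"n_sets": len(sets)}

    def do_diversity():
        records = diversity.per_gene_diversity(state["sites04"], config.min_total_sites)
        summary = diversity.pi_ratio_table(records, state["sets"])
        # per-set theta_W, Tajima's D at the primary downsampling, and GC
        extra = []
        for label, genes in state["sets"].items():
            sub = state["sites04"][state["sites04"]["gene"].isin(genes)]
            rec = {"gene_set": label}
            for klass, key in (("0-fold", "0"), ("4-fold", "4")):
                ssub = sub[sub["degeneracy"] == klass]
                rng = simulate.child_rng(config.sim.seed, 23)
                f = sfs.build_sfs(
                    sfs.fix_reference_mismatch(ssub), config.primary_n, rng
                )
                if f.total_sites:
                    d = diversity.tajimas_d(f)
                    rec[f"theta_w_{key}"] = diversity.watterson_theta(f)
                    rec[f"tajimas_d_{key}"] = d.d
                    rec[f"d_defined_{key}"] = d.defined
                else:
                    rec[f"theta_w_{key}"] = np.nan
                    rec[f"tajimas_d_{key}"] = np.nan
                    rec[f"d_defined_{key}"] = False
            rec["gc_pct"] = degeneracy.gc_content(
                [state["ref"].cds_sequence(g) for g in genes]
            ) if genes else np.nan
            extra.append(rec)
        summary = summary.merge(pd.DataFrame(extra), on="gene_set")
        _write(records, out / "diversity_per_gene.tsv")
        _write(summary, out / "diversity_summary.tsv")
        state.update(diversity=summary)
        return {"n_genes_with_pi": int(records["ratio"].notna().sum())}

    def do_sfs():
        spectra: dict[str, list] = {}
        for si, (label, genes) in enumerate(sorted(state["sets"].items())):
            sub = state["sites04"][state["sites04"]["gene"].isin(genes)]
            spectra[label] = sfs.build_replicates(
                sub, config.n_list, config.reps,
                seed=config.sim.seed + 1000 + si, gene_set=label,
            )
        long = sfs.sfs_long_table([s for ss in spectra.values() for s in ss])
        _write(long, out / "fsfs.tsv")
        # two-line spectra (replicate 0, primary n) per set and class
        two_line_dir = out / "fsfs_two_line"
        two_line_dir.mkdir(exist_ok=True)
        for label, spec_list in spectra.items():
            for s in spec_list:
                if s.replicate == 0 and s.n == config.primary_n:
                    name = f"{label}_{s.klass}_n{s.n}.sfs"
                    (two_line_dir / name).write_text(s.to_two_line())
        state.update(spectra=spectra)
        return {"n_spectra": sum(len(v) for v in spectra.values())}

    def do_dfe():
        all_fits = []
        skipped = []
        for label, spec_list in sorted(state["spectra"].items()):
            pairs = []
            for rep in range(config.reps):
                f0 = [s for s in spec_list
                      if s.klass == "0-fold" and s.n == config.primary_n
                      and s.replicate == rep]
                f4 = [s for s in spec_list
                      if s.klass == "4-fold" and s.n == config.primary_n
                      and s.replicate == rep]
                if f0 and f4:
                    pairs.append((f0[0], f4[0]))
            if not pairs or pairs[0][1].segregating < config.min_segregating:
                skipped.append(label)
                continue
            all_fits.append(
                dfe.run_replicates(pairs, config.fit_options,
                                   config.mutation_scale, gene_set=label)
            )
        fits = pd.concat(all_fits, ignore_index=True) if all_fits else pd.DataFrame()
        summary = dfe.summarize_replicates(fits) if len(fits) else pd.DataFrame()
        _write(fits, out / "dfe_fits.tsv")
        _write(summary, out / "dfe_summary.tsv")
        state.update(fits=fits)
        return {"n_sets_fit": len(all_fits), "skipped": skipped}

    def do_compare():
        fits = state["fits"]
        samples = {}
        if len(fits):
            ok = fits[fits["converged"] == True]  # noqa: E712
            for label, g in ok.groupby("gene_set"):
                if len(g) >= 10:
                    samples[label] = g["beta"].to_numpy()
        if len(samples) >= 2:
            mat = compare.overlap_matrix(samples)
            mat.to_csv(out / "beta_overlap.tsv", sep="\t", float_format=FLOAT_FMT)
        else:
            pd.DataFrame().to_csv(out / "beta_overlap.tsv", sep="\t")
        return {"n_sets_compared": len(samples)}

    stage("simulate", do_simulate)
    stage("qc", do_qc)
    stage("annotate", do_annotate)
    stage("expression", do_expression)
    stage("diversity", do_diversity)
    stage("sfs", do_sfs)
    stage("dfe", do_dfe)
    stage("compare", do_compare)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
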