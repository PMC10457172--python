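# Methods

## Study design the synthetic data emulates

The pipeline is built for cohorts of haploid tissue sampled from a single
panmictic population — the reference case being 20 megagametophytes (one
per unrelated mother tree) of an outcrossing conifer — genotyped by a
double variant call of the same reads at ploidy 1 and ploidy 2, with
invariant sites reported. Gene expression over five tissues (one haploid,
four diploid) assigns genes to tissues via the τ specificity index. The
contrast of interest is the distribution of fitness effects (DFE) of new
0-fold mutations between haploid- and diploid-tissue-specific gene sets.

The synthetic generator reproduces the statistical structure this chain
consumes, not the underlying biology of reads or mapping:

- **Reference/gene models.** One contig per gene; CDS begins ATG, ends with
  a stop, contains no internal stop; strands mixed (default 50 %); 60-bp
  noncoding flanks. Gene length default 900 bp.
- **Cohort.** Variant sites placed per position with probability
  θ·a₁(n) (θ default 0.005 per site, the population-model prior
  conventionally given to the variant caller; a₁ the Watterson constant), sample
  allele counts from the neutral equilibrium law P(j) ∝ 1/j. Per-genotype
  depth is negative binomial (mean 30, size 10), genotype quality a shifted
  Poisson (mean 60); genotypes go missing independently (default 10 %,
  ceiling 20 %). These per-genotype distributions are conventions — the
  kind of exome-capture summaries a cohort of this design typically shows —
  not estimates from any particular data set.
- **Collapsed paralogs.** A configurable fraction of genes carries a
  collapsed duplicate: at divergent positions (per-site probability 1 %,
  at least one per paralog gene) every callable sample is heterozygous
  under diploid-mode calling, while haploid-mode calls pick one copy at
  random. At least two samples are kept callable at such sites, so the
  ≥ 2-heterozygote detection rule is exercised deterministically.
- **Expression.** The assigned tissue carries the gene's level (log-normal
  across genes); all other tissues carry level·(1 − τ). The emitted
  vector's τ equals the target exactly; levels span the TMM-like range.
- **Folded SFS pairs.** Poisson draws around the Wright–Fisher expected
  spectrum (below) under the true demography; the 0-fold class integrates
  the expectation over the true gamma DFE. The per-site mutation influx is
  calibrated so the neutral class has Watterson θ equal to the configured
  θ.

What the generator does **not** emulate: read-level error, mapping bias,
linked selection, population structure, indel/complex variants beyond the
small spiked sets used to exercise the filters, and selection acting on the
cohort's 0-fold genotypes (cohort genotypes are neutral; selection enters
through the folded-SFS pairs that feed the DFE stage). Passing tests
therefore demonstrate correctness of the inference chain under its own
model assumptions, not robustness to real-data artifacts.

## Wright–Fisher expected-SFS engine

Expected folded spectra are computed on a discrete Wright–Fisher grid: N₁ =
100 diploids (2N = 200 chromosomes), deterministic additive selection
(fitnesses 1, 1 + s/2, 1 + s; s ≤ 0, clamped at −1), binomial resampling,
and new mutations injected at count 1 at a rate proportional to the current
population size. The standing density of segregating mutations solves
v = Av + e₁ at ancestral equilibrium; a size change to N₂ = ratio·N₁
projects v binomially onto the new grid and iterates t₂ generations with
continued (size-scaled) influx. Sampling n alleles is binomial; spectra are
folded with the middle bin shared at even n. Bin 0 carries the
sampled-invariant mass of population-segregating sites; the truly invariant
remainder of an L-site class is L minus the influx-scaled segregating sum.

Scaled parameters are preserved under the N₁ = 100 rescaling (Nes = N₁·|s|;
t₂ in reference-size generations). Because the discrete-grid spectrum
differs from the diffusion limit by O(1/N), every expectation is evaluated
at N₁ and 2N₁ (with s halved and t₂ doubled) and Richardson-extrapolated;
this reduces the neutral folded-shape error at n = 16 from ≈ 2 % to
≈ 1e-4, and to ≲ 1e-3 under strong selection. Transition matrices are
sparsified (binomial rows are narrow bands) and all expectations memoized;
demography parameters are snapped to a lattice (ΔN₂ = 0.05·N₁, Δt₂ = 5) so
optimizer sweeps and replicate fits reuse cached spectra.

## DFE inference

**Neutral step.** The 4-fold folded spectrum fixes the nuisance demography
and the mutation scale. Each of the T sites segregates at folded class i
with probability u·eᵢ(N₂, t₂); the likelihood is multinomial over the bins
including bin 0 (equivalently independent Poissons with the total pinned),
and u has the closed-form MLE u* = S/(T·Σe). The search is a coarse
(N₂, t₂) grid followed by Nelder–Mead from the best cell, with t₂
initialized at 50 generations. Because the *neutral folded shape is
invariant to population size at equilibrium*, (N₂, t₂) form a weakly
identified ridge; the two-epoch parameters are adopted only when they beat
the ancestral-equilibrium null by a likelihood-ratio margin of χ²₂ at the
5 % level (2Δll > 5.99). Without this gate, equilibrium data drive fits to
the search boundary on sampling noise and corrupt the selected-class
expectations. Search box: N₂/N₁ ∈ [0.2, 4], t₂ ∈ [0, 250].

**Selected step.** With demography fixed, the 0-fold spectrum is fit by a
gamma(β, mean E(s)) mixture over 64 log-spaced Nes classes spanning
10⁻⁴..10⁴; gamma mass below the grid is assigned to the lowest
(effectively neutral) class and mass above it to the highest (effectively
lethal — no segregating contribution), the point mass handling the tail.
The selected-class per-site mutation influx is **tied** to the neutral
estimate u*, so the overall deficit of segregating 0-fold sites — the
diversity reduction — is part of the selection signal. (A per-class free
scale is available via `mutation_scale="free"`, but it reduces the fit to
spectrum shape alone and leaves a β–E(s) ridge that biases β by tens of
percent; the tied default matches the classic neutral-sites-estimate-the-
mutation-rate treatment.) Optimization is Nelder–Mead on (log β, log E(s))
from the conventional initial values (β = 0.5, s = −0.1) with five
jittered restarts from a fixed seed; fits are deterministic.

**Class proportions.** The fitted gamma is summarized by its mass in
Nes ∈ {0–1, 1–10, 10–100, > 100}, using the most recent epoch's size
(N₁·N₂-ratio) as the Ne scale — a convention; the most recent size is the
one shaping current frequencies. Proportions are gamma CDF differences
(exact).

**Replicates.** Each downsampling replicate is refit end to end
(demography and DFE), which propagates downsampling noise into the β
sample used for the overlap comparison; non-converged replicates are
flagged and excluded from summaries with counts reported.

Known limitation: at weak selection (mean Nes ≈ 5) and moderate
information (10⁵ sites per class, n = 16), β and E(s) trade off along a
likelihood ridge. The MLE is consistent (bias vanishes by 10⁶ sites and is
unchanged when the true demography and mutation rate are supplied), but
single-replicate β estimates scatter several-fold and the 20-replicate
median can sit 10–30 % from truth. Comparisons between gene sets (the
β-overlap statistic) are unaffected by the common bias; absolute β values
at weak selection should be read with this spread in mind.

## QC conventions

- Heterozygote: diploid genotype with two distinct called alleles; any
  missing allele disqualifies. Detection threshold: ≥ 2 heterozygous
  samples.
- Mask windows: ±75 bp inclusive around each flagged site (151 positions),
  exported as 0-based half-open BED; overlapping windows merged.
- Filters, in order: mask removal → variant-type (biallelic SNPs or
  single-base invariant records only; indels, complex alleles, > 2-allele
  sites dropped) → genotype masking with strict thresholds (kept only if
  GQ > 20 *and* DP > 10) → site missingness (> 20 % dropped; exactly 20 %
  kept) → AN/AC recomputation from surviving genotypes.
- The AN=AC → AC=0 reset turns sites monomorphic for a non-reference
  allele into invariant sites before spectrum construction (the reference
  individual is not from the study population).

## Diversity and SFS statistics

π is the ratio-of-sums estimator over variant and invariant sites:
Σ AC·(AN−AC) / Σ C(AN,2); sites with AN < 2 contribute nothing and no
per-site renormalization is applied (missing-data-aware, as in pixy).
Per-gene π₀/π₄ ratios require ≥ 50 total sites (0-fold plus 4-fold,
jointly) and both π > 0; tissue summaries are means of per-gene ratios
with SE = SD/√N. θ_W and Tajima's D (standard variance normalization) are
computed from the n = 16 downsampled folded spectrum; with S = 0, D is
reported as 0 with an explicit `defined=False` flag so summary tables can
still print a value. Downsampling is per-site independent hypergeometric
without replacement; sites with AN < n are dropped; fold ties (k = n−k) go
to the shared middle bin.

## β-overlap

Kernel density estimates use Gaussian kernels with a single Silverman
bandwidth computed on the pooled sample (keeping the statistic symmetric),
a 512-point grid spanning pooled min−3h..max+3h, renormalization to unit
integral on the grid, and overlap = 100·∫min(f_A, f_B) by trapezoid.
Zero-variance samples fall back to a point-mass convention (100 if the
samples coincide, else 0, with a warning). The bandwidth/grid are
documented conventions; the statistic is validated against the closed-form
overlap of two unit normals (2Φ(−1) ≈ 31.7 % at distance 2).

## Numerical and design choices

- Median-based gene subsets: "high-τ" keeps genes strictly above the
  within-set median τ; "low-expression" keeps genes at or below the
  within-set median of the assigned-tissue expression level (expression
  "level" = value in the arg-max tissue; a convention, since replicate
  collapse and level definition admit alternatives).
- Degeneracy is evaluated per position by substitution-and-translate under
  the standard code (stop is its own identity), so 2-/3-fold serine-type
  edge cases need no special casing; positions claimed by overlapping CDS
  with conflicting classes are dropped; genes with internal stops or
  non-multiple-of-3 CDS are skipped with a warning.
- Problem sizes in the test-suite simulations (gene counts of tens,
  replicate counts of 12–200, 10⁵-site spectra) are chosen to exercise
  every code path at desk scale while keeping the suite fast; the
  pipeline accepts arbitrary sizes.
- Seeds: one master seed; every generator and every replicate derives a
  child stream by fixed offsets, so any single artifact is reproducible in
  isolation and full runs are byte-identical.
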