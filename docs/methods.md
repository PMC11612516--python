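# Methods

`poolscan` re-implements, as a tested library, a Pool-Seq genome-scan
workflow for detecting domestication signatures: pooled read counts from
farmed and natural-origin (wild) populations are turned into a biallelic SNP
table, scanned with two complementary differentiation statistics, and the
resulting outlier SNPs are annotated with nearby genes and CpG islands and
tested for enrichment in a functional-interaction network. This note
documents the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Pool representation and the depth filter

Pooled sequencing samples reads, not individuals. At one position, `d` reads
from a pool of `n` diploid individuals hit individuals with replacement; the
expected number of distinct individuals represented is the occupancy formula
`n (1 − (1 − 1/n)^d)`. `depth_sim` estimates the full distribution by
Monte-Carlo (default 10⁶ resampling events) and reads the "lower 95%
confidence limit" as the 2.5% empirical quantile (lower bound of the central
95% interval). A one-sided 5% quantile option is provided because the
sidedness convention is ambiguous; for the reference case (pool 25,
depth 25) both give 13 individuals, i.e. a depth of 25 represents at least
half the pool with high confidence — the rationale for the default
`min_depth = 25` filter. Reads are assumed uniform over individuals (equal
DNA contribution); "represented" counts individuals, not haplotypes.
`min_depth_for_representation` inverts the simulation by doubling +
bisection over depth, with one deterministic sub-seed per candidate depth so
the search agrees exactly with a linear scan.

## SNP calling

Technical replicates are merged by summing per-base counts. A site is kept
only when **every** population reaches the minimum depth after merging — the
downstream group contrasts need all pools typed, so an any-population rule
would only defer the loss. The minor-allele screen removes alleles whose
dataset-wide frequency is strictly below 1% (a 1.0% allele survives); it is
a guard against sequencing error and mismapping, and it is applied globally
(pooled over populations) by default because it screens the dataset, not the
pool. A per-population variant (`per_population=True`: allele retained when
it reaches the threshold in at least one pool) is available. A site is
emitted only when exactly two alleles survive; the reference base is kept as
the reference allele when it survives, otherwise the highest-count allele
takes its place, with ties broken in base order A<C<G<T for determinism.
Per-population depth in the SNP table is `ref_count + alt_count`: reads on
removed error alleles do not count toward a SNP's depth.

## Genome scan

Two statistic tracks per SNP, mirroring a two-program consensus design:

* **FST / Fisher track.** Per farmed×wild population pair,
  `FST = (hT − hS)/hT` with `hT = 2 p̄ (1 − p̄)` at the pair mean frequency
  and `hS` the mean within-population heterozygosity (0 when `hT = 0`);
  the per-SNP statistic is the average over all pairs. Significance comes
  from a two-sided Fisher exact test on the 2×2 table of (ref, alt) read
  counts summed within each group, using the point-probability rule (sum of
  all table probabilities ≤ the observed). The classical heterozygosity
  estimator is used without pool-size bias correction; the estimator choice
  is isolated behind `pairwise_fst`.
* **XtX track.** Frequencies are standardised per site,
  `z_j = (p_j − π)/√(π(1−π))` with `π` the across-population mean, and the
  scaled covariance Ω of populations is estimated by the method of moments,
  `Ω = Z Zᵀ/L` over polymorphic sites plus a ridge `10⁻⁶·trace` for
  invertibility. `XtX = zᵀ Ω⁻¹ z` whitens shared demography (drift scale and
  finite-pool noise enter Ω) before measuring differentiation; p-values come
  from the upper tail of χ² with J (number of pools) degrees of freedom.
  This is a deterministic surrogate for the hierarchical-Bayesian treatment
  of the same statistic: it preserves the definition (deviation standardised
  by the populations' scaled covariance) at desk scale, without MCMC.
  Because `π` is the sample mean, the per-site z-scores sum to zero and the
  raw quadratic form has null mean J−1; `xtx_stat` rescales by `J/(J−1)`
  (the same lost-degree-of-freedom first-moment correction as Bessel's) so
  the statistic is genuinely calibrated against χ²_J. The raw form is
  exposed as `xtx_from_z`.

Each track is Benjamini–Hochberg adjusted genome-wide, separately —
mirroring two independently run programs. The consensus classes are:
**highly suggestive** when both adjusted values are below 10⁻⁵, and
**suggestive** when one is below 10⁻⁵ and the other below 10⁻³. The
classifier is monotone: lowering either adjusted p never demotes a SNP.
Population structure is summarised by PCA of the column-centred frequency
matrix (SVD; at most J−1 components).

The two tracks fail differently, deliberately. On summed read counts,
Fisher's exact test assumes binomial sampling from a common group frequency;
genetic drift between pools and the finite pool size (depth comparable to
2N) overdisperse the counts, so the Fisher track alone is liberal. The XtX
track absorbs exactly that overdispersion into Ω and pays a J-degree-of-
freedom penalty, so it is very conservative. The consensus inherits the
conservativeness — on the synthetic planted-selection fixture (below), the
Fisher track recovers ~98% of planted loci at q < 10⁻⁵ while the consensus
class recovers only a minority, because XtX adjusted p-values rarely cross
10⁻³ at realistic pool sizes and depths. This asymmetry is a property of
the method, not a defect of the implementation, and is measured by the
test suite.

## Candidate annotation

Every suggestive or highly suggestive SNP is mapped to features whose
intervals intersect the closed window `[pos − 100 kbp, pos + 100 kbp]`
(GFF3 conventions: 1-based, inclusive ends; the window is clipped at
coordinate 1 and anchored on the SNP point position). Candidates are the
de-duplicated union over SNPs, with per-SNP provenance retained. Orthology
to a better-annotated reference genome is treated as data: a two-column
gene→ortholog table is applied to candidate and background gene ids before
term enrichment. Term enrichment over a supplied gene→term table is a
one-sided hypergeometric test per term, BH-adjusted across terms; terms with
no annotated background gene are skipped, and no ontology-graph propagation
is performed (the table is taken as given).

## Network enrichment

The interactome is an undirected gene–gene graph with a coupling probability
per edge. Edges below probability 0.90 are removed (boundary inclusive, so a
0.90 edge survives); the graph is then restricted to edges with at least one
candidate endpoint, non-candidate endpoints becoming intermediate partners.
The degree sweep retains, at threshold k, only partners connected to at
least k **distinct candidate** genes — the sweep's purpose is to concentrate
the network around the candidate set; a total-degree reading is available
via `mode="total"`. At each k the surviving gene set is scored with a
one-sided Fisher exact test (network membership × candidacy) against the
genome-wide gene universe, which defaults to the genes of the supplied
annotation. The permutation null redraws same-size gene sets uniformly from
that universe (default 1000 permutations) and repeats the whole sweep.

The reported network is the largest connected component at the smallest k
whose observed p falls below the permutation 5th percentile while the null
median has become non-significant (the null curves have collapsed); when no
k qualifies, the k with the smallest observed p is used. Ties between
equal-size components go to the one containing the lexicographically
smallest gene id. Topology indices follow the Cytoscape conventions: degree
is the neighbour count; radiality of node v in a component of n nodes and
diameter D is `Σ_u (D + 1 − d(v,u))/(n − 1)`; singleton components get
radiality 0.

## Synthetic data generator

The generator emulates the study design the pipeline targets, and its
defaults are those conditions: 12 farmed and 8 wild pools of 11–25 diploid
individuals (sizes spread evenly over that range), mean read depth 60 split
over two technical replicates (Poisson per replicate), 24 linkage groups.
Drift uses the Balding–Nichols Beta parameterisation: population frequency
`~ Beta(p₀(1−c)/c, (1−p₀)(1−c)/c)` with `c` playing the role of FST to the
common ancestor. Defaults `c = 0.10` (farmed; consistent with effective
sizes of a few tens over a handful of domesticated generations) and
`c = 0.02` (wild; large natural effective sizes). Ancestral frequencies are
uniform on [0.05, 0.95] (an agnostic choice for a common-SNP panel; the
Beta shape is configurable). At a planted minority of loci the farmed-group
mean is displaced by `δ` (default 0.45), clamped to [0.01, 0.99], with the
shift direction randomised per locus — the direction of domestication
alleles is not assumed. Read counts are two-stage: 2N allele copies drawn
binomially per pool, then reads drawn binomially from the realised copy
frequency — this reproduces the finite-pool variance that motivates the
depth simulation, and is the reason Fisher-on-pools is overdispersed.
Not modelled (out of scope): linkage disequilibrium along chromosomes,
sequencing error, overdispersed (negative-binomial) depth, read-level
(FASTQ) output. Passing tests therefore validate the statistical machinery
under drift + finite-pool + finite-depth noise, not robustness to error
alleles or LD structure in real data.

The annotation generator places non-overlapping genes (one per equal slot of
each linkage group, 2–15 kbp) and freely placed CpG islands (0.3–2 kbp,
may overlap genes). The interactome generator plants a clique whose edges
carry probabilities ≥ 0.95 (surviving the 0.90 filter) inside an
Erdős–Rényi background whose probabilities are < 0.90 (removed by the
filter), and records the full gene universe on the graph.

## Validation fixtures and problem sizes

The suite runs at desk scale, with fixed seeds throughout:

* **Calibration fixture** (20 pools, 5·10⁴ sites): drift 0.001 and pool
  size 1000 ≫ depth, the limit in which the generative model converges to
  the binomial sampling null that Fisher's exact test and the χ² XtX
  calibration assume. There the mean XtX matches J to well under 5% and no
  SNP reaches fisher_q < 10⁻³. Calibration is deliberately checked in the
  regime the tests assume; under the realistic study design the Fisher
  track is overdispersed by construction (see above), which is measured by
  the planted fixture instead.
* **Planted-selection fixture** (20 pools of 11–25, depth 60, 4·10³ sites,
  60 selected loci, δ = 0.6): measures Fisher-track power (≥80% at
  q < 10⁻⁵), the consensus false-positive rate on null loci (≤1%), and the
  conservativeness of the consensus class.
* **Planted-module fixture** (300-gene universe, 20 candidates + 3
  partners): the network stage recovers the module (Jaccard ≥ 0.8 on
  candidate genes) and its enrichment p beats all 200 permutation minima,
  while the null curves sit at non-significance for large k.
* **End-to-end dataset** (1200 sites, 4 linkage groups, module planted on
  genes neighbouring the selected loci): exercises the full pipeline,
  including byte-identical reruns under a fixed seed. Because the consensus
  class is so conservative, the end-to-end configuration relaxes the class
  thresholds (10⁻² / 5·10⁻²) so the annotation and network stages receive a
  non-empty candidate set; the paper-scale thresholds remain the library
  defaults.

## Numerical and degenerate-input choices

* BH adjustment is delegated to `statsmodels` (`fdr_bh`); a literal step-up
  implementation serves as the test oracle.
* Fisher exact tests and hypergeometric tails come from `scipy.stats`; an
  exhaustive hypergeometric enumeration is the test oracle.
* Ω for identical populations is the zero matrix (the ridge is proportional
  to the trace); `xtx_from_z` raises a descriptive error on singular Ω.
* Sites monomorphic across all populations contribute z = 0 (XtX 0, p 1)
  and are skipped in Ω estimation.
* Empty Fisher margins give p = 1 with a warning; zero-variance PCA returns
  all-zero fractions with a warning; unknown linkage groups in window
  queries return empty results with a warning.
* Every output table carries header comments with the tool version, a
  configuration hash (excluding the output directory, so reruns into
  different directories compare byte-identical) and the seed.

## Known limitations

* The XtX surrogate shares the statistic's definition with the
  hierarchical-Bayesian original but not its shrinkage or its POD
  calibration; its χ²_J p-values are approximate and markedly conservative
  after BH at realistic pool sizes.
* The FST estimator carries finite-depth and finite-pool upward bias; no
  unbiased pool-size correction is applied.
* The permutation null redraws gene sets ignoring gene length and degree
  biases; with a planted-clique interactome this is exact, with real
  interactomes it is the usual optimistic null.
* The generator draws sites independently; nothing is claimed about
  windowed statistics or LD-aware scans.
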