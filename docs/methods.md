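# Methods

This note documents the models, conventions and design choices behind
viromescope: what each stage computes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Read processing

Reads pass through a fixed order — quality trim, exact-sequence
de-duplication, host removal, viral mapping — and the read count surviving
the first three stages is the sample's *decontaminated read number*, the
normalization denominator for all abundances.

**Trimming.** Bases are removed from both read ends while their Phred
quality is below `phred_min` (default 10); reads shorter than `min_length`
(default 30 bp) are dropped. This is a deliberately minimal end-trimmer:
the synthetic data carry flat qualities, and real data are expected to
arrive pre-trimmed or via SAM.

**De-duplication** removes exact sequence copies, keeping the first
occurrence. It runs before alignment, so coincidentally identical fragments
(common for short reads from small genomes) are also collapsed — the same
behavior as exact-match de-duplication on real libraries.

**The built-in mapper** indexes every k-mer (default k = 21) of every
reference sequence and queries a strided subset of each read's k-mers on
both strands; every candidate diagonal is scored by ungapped comparison of
the full read against the reference, and hits with percent identity ≥ the
threshold (default 95, inclusive) are kept. Each read's best hit — highest
identity, ties broken by lowest (genome_id, start) — is flagged, and only
best hits contribute to coverage. The mapper handles substitutions only;
data with indels should be aligned externally and imported as SAM, where
percent identity is computed as 100·(aligned_length − NM)/aligned_length
over M/=/X/I/D columns. Internally all coordinates are 0-based half-open;
SAM's 1-based coordinates are converted on input.

With substitution rate e and seed stride k, a read of length L misses all
seeds with probability ≈ (1−(1−e)ᵏ)^(L/k); at e = 0.005, k = 21, L = 150
this is ≈ 10⁻⁸, so seeding loss is negligible at the simulated error rate.

## Presence and abundance

A population is **present** when positions with depth ≥ 1 (from qualifying
best hits) form at least one consecutive run ≥ `min_run_bp` (default
200 bp, inclusive). Fragmented coverage of the same total extent does not
qualify — scattered spurious hits on a long genome should not count as
detection.

**Abundance** is the median depth over *all* genome positions, zeros
included (the even-length median is the mean of the two central order
statistics), scaled per million decontaminated reads. Including zeros
penalizes fragmentary coverage and is the stricter of the two plausible
conventions; `covered_only=True` exposes the alternative (median over
covered positions only). The presence gate is applied first: an absent
population has abundance 0 regardless of its median. The per-million scale
is arbitrary and cancels under row normalization to relative abundances.

Host-taxon aggregation sums feature columns within host genus or phylum
(eukaryotic viruses form their own class) and conserves row totals exactly.

## Ecology and statistics

* Shannon's H uses natural logarithms, so Pielou's J = H/ln S lies in
  [0, 1]; J is defined as 0 for S ≤ 1.
* Bray–Curtis requires non-negative input; a pair of all-zero profiles gets
  distance 0 with a warning. For metabolite intensity data (negative after
  autoscaling) profiles are min-shifted per feature before Bray–Curtis;
  Euclidean distance on autoscaled data is used for Mantel regressions.
* PCoA: Gower double-centering B = −½ J D∘D J, symmetric eigendecomposition,
  axes kept for eigenvalues above a relative tolerance (10⁻¹²·|λ|max) and
  scaled by √λ. Negative eigenvalues (non-Euclidean distances) are reported
  but contribute no axes. Axis signs are fixed so each axis's
  largest-magnitude loading is positive, making outputs deterministic.
* Factor fits use r² = 1 − SS_within/SS_total on the first two ordination
  axes by default (`n_axes` exposed); vector fits regress the variable on
  those axes and report r² plus the unit coefficient direction. Null
  distributions permute labels (or the variable) across samples.
* The Mantel statistic is the Spearman correlation of upper-triangle
  entries; permutations shuffle rows and columns of the second matrix
  simultaneously; the p-value is one-sided for r ≥ r_obs.
* Every permutation p uses the add-one estimator (1+#extreme)/(1+n_perm),
  bounded below by 1/(n_perm+1) and never zero. Default permutation counts:
  9999 for ordination fits and Mantel tests, 1000 for differential
  abundance. Bonferroni (min(1, m·p)) is applied within each declared test
  family.
* Mann-Whitney U uses exact enumeration when the pooled sample size is ≤12
  with no ties, otherwise the tie-corrected normal approximation with
  continuity correction (scipy). Exhaustive enumeration at n = 6+6 shows
  the two branches differ by at most 0.0155 in p.
* The 2×2 chi-squared test applies **no** Yates continuity correction by
  default: the plain Pearson statistic reproduces standard cohort-table
  p-values (e.g. 13/7 vs 8/2 → χ² = 0.714, p = 0.3980; 19/1 vs 5/5 →
  χ² = 8.438, p = 0.0037); a corrected variant is available by flag.
* The differential-abundance test follows the classic two-part scheme for
  sparse microbiome data: features with ≥ `sparse_min_nonzero` (default 4)
  nonzero samples get a Welch t statistic with a two-sided group-label
  permutation p (all features share each permutation); sparser features
  fall back to Fisher's exact test on group × detected counts; all-zero
  features are reported as NA. Whether relative abundances or counts are
  supplied is the caller's choice; relative is the default throughout the
  pipeline.
* UPGMA is implemented directly so tie-breaking is deterministic (smallest
  distance first, ties by lexicographically smallest pair of cluster
  labels, a cluster labelled by its smallest leaf id); heights are the
  standard average-linkage heights, written as an ultrametric Newick tree.
  The linkage choice for heatmap dendrograms is ours; nothing downstream
  depends on it.

## Association network

Relative abundances are CLR-transformed — z = ln(x+pc) − mean(ln(x+pc)) per
sample — with pseudocount 1 on count-like data or half the smallest nonzero
value otherwise, which makes the transform invariant to global rescaling.
Each feature is then regressed on all others by lasso (standardized
predictors, coordinate descent, tolerance 10⁻⁶); an edge joins i and j when
either (OR, default) or both (AND) directed neighborhoods contain the
other. Edge sets are monotone non-increasing in the penalty λ.

λ is either supplied or selected from a fixed grid of 10 log-spaced values
from λ_max = max|xᵢᵀxⱼ|/n (the smallest penalty giving an empty graph) down
two decades. The automatic pick is the end of the **longest plateau** of
the edge-count curve within the sparse regime (edge count ≤ 2p, i.e.
average degree ≤ 4), ties resolved toward larger penalties: a stable edge
set across a stretch of penalties indicates real structure, while for
structure-free data the longest plateau is the initial empty stretch, so
the selected graph stays (near-)empty. Stability-based subsampling
selection (StARS-like) is deliberately out of scope; the plateau heuristic
is its cheap deterministic cousin. Clusters are connected components;
singletons are labelled −1 ("noise").

## Synthetic-data generator

The generator defines the study conditions every statistical claim in the
test suite is made under:

* **Reference database**: i.i.d. uniform-base genomes of 1–3 kb (default
  200 genomes), host phyla drawn with proportions Proteobacteria 0.37,
  Firmicutes 0.36, Actinobacteria 0.23, Bacteriodetes 0.03, Fusobacteria
  0.01, a genus uniform within the phylum; 2% of genomes are eukaryotic
  viruses with no bacterial host.
* **Communities**: two groups of 20 and 10 samples. Per sample, a Poisson
  richness around the group target (base 40; deflated ×0.6 in the
  low-diversity "smoker" group) selects taxa weighted by a shared
  heavy-tailed occupancy vector (log-normal, σ = 1), so some populations
  recur across samples. Abundances on the support are log-normal: σ = 1
  baseline, multiplied by the dominance factor 2.5 in the low-diversity
  group so its communities are also markedly less even — the two knobs
  together plant the lower-richness *and* lower-evenness condition the
  package's group comparisons are required to detect (α = 0.01, power
  ≥ 0.8 at 20+10). Planted fold changes (defaults: 10× Lactobacillus and
  Gardnerella phages toward nonsmokers, 2× Prevotella phages toward
  smokers) multiply planted taxa that land in a sample's support before
  renormalization; because compositions are closed, the realized group
  mean ratio of a *large* planted genus is suppressed below its nominal
  fold change (≈4.5 realized for a nominal 10× on a genus holding ~9% of
  mass) — an intrinsic property of relative data, not a bug.
* **Reads**: origins drawn ∝ abundance × genome length; uniform start,
  random strand, i.i.d. substitutions (default 0.5%); a host-contamination
  fraction (default 30%) drawn from a single random 100 kb host sequence;
  a duplicate fraction (default 5%) of reads are exact copies of earlier
  reads. The true contamination regime of acellular BAL (viral signal
  ~0.03% of reads) would need millions of reads per sample to leave a
  usable viral signal; 30% contamination at 50k reads/sample reproduces
  the same pipeline behavior (dominant host fraction, decontamination
  denominator ≪ raw reads) at desk scale.
* **Omics**: metabolites and cytokines are Gaussian log-intensities
  (feature means N(5,1), unit SD) with a planted mean shift toward the
  smoker-like group — 2.5 SD for metabolites, chosen so that most features
  survive a Bonferroni-corrected Mann-Whitney comparison at 20+10 (the
  asymptotic U p-value has a floor of ~10⁻⁵ at these group sizes, so a
  2 SD shift leaves only ~70% detectable); 1 SD for cytokines. A dropout
  parameter zeroes entries to exercise the ≥50%-presence reporting filter.
  The bacteriome matrix is an independent log-normal composition with **no**
  group effect, providing the negative control (group fits on it must
  reject at ≈α).

What the generator does **not** emulate: real error profiles and indels,
paired-end structure, strain microdiversity, genome-composition biases,
database incompleteness, or correlated taxon occurrence. Passing tests
therefore demonstrate that the pipeline's rules and statistics behave as
specified under a controlled community model — not that any biological
conclusion transfers to real BAL data.

## Numerical and procedural choices

* Determinism: every random operation takes an explicit integer seed;
  per-sample streams are spawned from a SeedSequence, so outputs are
  byte-identical across runs and platforms for a fixed seed.
* Degenerate inputs: all-zero abundance rows yield S = H = J = 0 with a
  warning and are preserved (not dropped) by relative normalization;
  constant features are dropped by autoscaling with a warning; all-zero
  distance pairs get Bray–Curtis 0.
* The pipeline configuration is YAML with explicit field-by-field
  validation (unknown keys rejected, thresholds range-checked) rather than
  a JSON-schema engine; the guarantees are the same and the error messages
  are friendlier.
* Outlier handling is an explicit sample-exclusion list
  (`exclude_samples`); no automatic multivariate outlier detection is
  performed.
* Problem sizes used by the test suite and the acceptance script — 30
  samples × 200 genomes × 50k reads for recovery, 200 replicates × 499
  permutations for calibration, 50 seeds for power — were chosen as the
  smallest sizes at which the binomial error bands around the tested rates
  are meaningfully tight.

## Known limitations

* The built-in mapper is for substitution-only data; it does not replace a
  production aligner and real data should enter via SAM.
* Whether the consecutive-coverage rule should use union coverage (our
  reading) or a single spanning read pair is ambiguous for real paired-end
  data; with single-end reads the two coincide per read.
* The Metastats reimplementation covers the two-part test with permutation
  p-values; it omits the original's per-feature variance moderation for
  very small groups.
* Network selection at n = 30 samples has limited power; the plateau
  heuristic is conservative by construction and will return empty graphs
  on weak structure.
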