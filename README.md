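# viromescope

Quantitative analysis of low-biomass shotgun viromes, built for two-group
comparisons such as smoker vs nonsmoker bronchoalveolar-lavage (BAL)
studies. The package covers the full path from reads to biology:

1. **Read processing** — quality trimming, exact-sequence de-duplication,
   host-genome decontamination at ≥95% alignment identity, and alignment to
   a viral reference database (a built-in exact-seed/ungapped-extension
   mapper for synthetic data; external aligners via SAM import, with
   percent identity from the NM tag).
2. **Quantification** — a viral population is *present* in a sample when
   qualifying reads (≥95% identity) cover a consecutive stretch of its
   genome ≥200 bp; present populations are quantified as the **median read
   depth over all genome positions per million decontaminated reads**, then
   row-normalized to relative abundances and optionally summed by bacterial
   host genus or phylum.
3. **Ecology & statistics** — richness *S*, Shannon's *H* (nats), Pielou's
   *J* = *H*/ln *S*; Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ);
   PCoA by Gower double-centering; envfit-style permutation fitting of
   factors (r² = 1 − SS_within/SS_total) and vectors onto the ordination;
   Spearman Mantel tests between distance matrices; UPGMA dendrograms;
   Mann-Whitney U, 2×2 chi-squared and Bonferroni correction; a
   Metastats-style two-part differential-abundance test (permutation Welch
   t for common features, Fisher's exact on detection for sparse ones).
4. **Association networks** — centered log-ratio transform followed by
   Meinshausen–Bühlmann neighborhood selection (per-feature lasso
   regressions, OR/AND symmetrization) to look for co-occurrence clusters
   ("pneumotypes").
5. **Synthetic data** — a generator that emulates the structure of a
   30-subject BAL virome study (20 vs 10 samples, a few hundred candidate
   viral populations, host-read contamination, planted fold-change and
   diversity effects, companion metabolite/cytokine/bacteriome matrices),
   so every stage is testable without external data.

All permutation p-values use the add-one estimator
p = (1 + #extreme) / (1 + n_perm).

## Worked example

```python
from viromescope import synthetic, quant, ecology, stats
from viromescope.reads import KmerIndex, process_sample

ref = synthetic.generate_reference_db(100, rng_seed=0)
host = synthetic.generate_host_genome(rng_seed=1)
design = synthetic.design_communities(ref, group_sizes=(10, 5), base_richness=25, rng_seed=2)
reads, truth = synthetic.simulate_reads(
    ref, design, host, synthetic.SimulationConfig(reads_per_sample=20_000, rng_seed=3)
)

viral_index, host_index = KmerIndex(ref.sequences()), KmerIndex({"host": host})
per_sample = {}
for sid in design.sample_ids:
    hits, acct = process_sample(reads[sid], host_index, viral_index)
    abund, calls = quant.quantify_sample(hits, ref.lengths(), acct["decontaminated"], sample_id=sid)
    per_sample[sid] = abund
matrix = quant.build_abundance_matrix(per_sample)
print(f"{matrix.shape[1]} viral populations detected across {matrix.shape[0]} samples")

alpha = ecology.alpha_diversity_table(matrix)
g = design.groups
res = stats.mann_whitney(
    alpha.loc[g[g == "smoker"].index, "richness"],
    alpha.loc[g[g == "nonsmoker"].index, "richness"],
)
print(f"richness: smoker median {res.group_summary['median_x']:.0f}, "
      f"nonsmoker median {res.group_summary['median_y']:.0f}, p = {res.p_raw:.4f}")

ordn = ecology.pcoa(ecology.bray_curtis(matrix))
fit = ecology.factor_fit(ordn, g.to_numpy(), n_perm=999, rng_seed=4)
print(f"smoking status vs virome ordination: r^2 = {fit.effect:.2f}, p = {fit.p_raw:.3f}")
```

prints

```
81 viral populations detected across 15 samples
richness: smoker median 10, nonsmoker median 27, p = 0.0029
smoking status vs virome ordination: r^2 = 0.11, p = 0.169
```

The smoker-like group's planted richness deficit is already detectable at
this toy scale (10+5 samples, 20k reads); the ordination-level composition
shift needs the default study scale (20+10 samples, 50k reads/sample),
where the factor fit typically lands at r² ≈ 0.23 with p ≈ 3·10⁻⁴ while the
no-effect bacterial matrix stays non-significant.

The same pipeline is available from the shell:

```bash
viromescope run-all --outdir my_run --seed 2
viromescope simulate --outdir sim --seed 0 --n-genomes 100
viromescope diffabund --matrix sim/bacteriome.tsv --metadata meta.tsv --out diff.tsv
```

`run-all` writes plain-text artifacts (FASTA/TSV/JSON/Newick) plus a
`run_report.json` summarizing read accounting, diversity tests, ordination
fits, differential abundance and the association network.

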