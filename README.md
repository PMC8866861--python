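# stressdecomp

Decomposition of a two-arm dose-series transcriptome (NaCl vs iso-osmolar
sorbitol, shared untreated control) into **salt-specific** and **osmotic**
gene lists, with DAG-aware term enrichment and the downstream
group-comparison statistics, plus a synthetic-data module that plants
known truth so the whole pipeline is testable offline.

## Pipeline

1. **preprocess** — per-sample quantile normalization (ties get the mean of
   the reference values they span), per-gene z-score (ddof=1, constant
   rows → 0), signed log scaling `x ↦ sign(x)·ln(1+|x|)`. Stage tags make
   misordered pipelines fail loudly. Fold changes are computed on the raw
   matrix as `log2(mean(condition)/mean(control))`, with the per-arm
   greatest-magnitude entry ("max |log2FC|") reported.
2. **differential** — Mann-Whitney U of the control replicates vs *all*
   pooled samples of one arm (3 vs 12 in the default design). Exact
   tie-aware permutation enumeration up to a pooled size of 20, then
   tie-corrected normal approximation. Benjamini–Hochberg step-up
   adjustment; significance at adjusted p < 0.01 (raw-p mode behind a
   flag). Salt-specific = NaCl list minus sorbitol list; osmotic = their
   intersection; up/down split by the NaCl-arm direction; a two-fold
   filter produces the enrichment input subsets.
3. **enrichment** — self-contained OBO parsing, true-path propagation over
   `is_a`/`part_of`, exact integer hypergeometric upper tails, and elim
   decorrelation (children before parents by longest-path depth; genes of
   significantly enriched descendants removed before testing ancestors).
   Reporting keeps terms with more than `min_genes` study hits.
4. **groupstats** — one-way ANOVA with unprotected Fisher LSD pairwise
   tests and a compact letter display, pooled t-tests with Bonferroni
   correction, per-sample Na:K ratios, metabolite fold summaries.
5. **synthetic** — expression/ontology/phenotype/metabolite generators
   with exact planted truth; bit-identical under a fixed seed.

## CLI

```sh
stressdecomp run-all --out out/ --seed 1            # simulate + full pipeline
stressdecomp simulate --out sim/ --genes 500 --seed 1
stressdecomp preprocess --expression sim/expression.tsv --design sim/design.csv --out norm.tsv
stressdecomp diff --expression sim/expression.tsv --design sim/design.csv --arm NaCl --out diff.tsv
stressdecomp decompose --expression sim/expression.tsv --design sim/design.csv --out dec/
stressdecomp enrich --ontology sim/ontology.obo --annotations sim/annotations.tsv \
    --genes dec/salt_specific_up.go_input.txt --out enrich.tsv
stressdecomp stats --phenotype sim/phenotype.csv --metabolites sim/metabolites.csv --out stats/
```

Exit codes: 0 success, 2 invalid configuration, 3 data validation error.
`--config cfg.yml` accepts a YAML mapping of the `RunConfig` fields
(`alpha`, `fold_threshold`, `elim_cutoff`, `min_genes`, `exact_limit`,
`seed`, ...); unknown keys are rejected. All randomness derives from the
single seed, so reruns are byte-identical.

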