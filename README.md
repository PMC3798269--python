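# tilepc

Analysis pipeline for two-colour ChIP tiling-array (ChIP-chip) experiments,
built around the question of whether Polycomb (Pc) binds the promoters of
defined gene sets — e.g. spermatogenesis genes in *Drosophila* testes —
and how that binding changes between genotypes or purified cell
populations.

The package takes raw two-channel probe intensities from a dense tiling
design (NimbleGen-style, ~50–100 bp probe spacing) through to gene-set
statistics:

1. **Normalization** — each sample is median-scaled to 500, all ChIP and
   input channels are quantile-normalized together, per-replicate
   log2(ChIP/input) ratios are formed, smoothed with a 500 bp sliding
   window requiring ≥ 4 oligos, and replicates are averaged.
2. **Scoring** — each gene's Pc enrichment is the mean smoothed oligo
   score in a 1 kb window centred on the TSS (−500..+500 bp); binding
   intervals are maximal probe runs with log2 enrichment > 1.0, scored in
   a 1 kb window on the interval midpoint; accumulated (metagene) profiles
   average strand-oriented probe offsets in 50 bp bins, with random-gene
   backgrounds (10 samplings of 942 genes by default).
3. **Gene-set statistics** — boxplot summaries (median, quartiles,
   1.5×IQR whiskers), linear fold enrichment 2^median, Welch t-tests
   between sets, between-condition median ratios 2^(med_A − med_B),
   top-k ranking by per-gene ratio, and Pearson correlations.
4. **Chromatin domains** — genes are assigned to five-state chromatin
   domains (BLACK/BLUE/RED/YELLOW/GREEN) by TSS containment or majority
   coverage, and a gene set's per-state fold enrichment over a gene
   universe is computed as a ratio of fractions.

Because raw array data are bulky and external, the package ships a
**synthetic tiling-array generator** (`tilepc.simulate`) producing probe
layouts, gene models, two-channel intensities with replicates and dye
swaps, and planted log2-enrichment domains at target-gene TSSs — with the
ground truth serialized next to the data — so every stage is testable
end-to-end by parameter recovery.

## Worked example

```python
import tilepc as tp

cfg = tp.SimConfig(seed=42)                     # 2 chroms x 9 Mb, 2000 genes,
genes, probes, matrix, truth = tp.simulate_dataset(cfg)  # 200 targets at 1.5 log2
tracks = tp.normalize_experiment(matrix)        # median scale, quantile, smooth
table = tp.score_gene_table(tracks, genes)      # 1 kb TSS windows

target = truth.target_set("targets")
background = truth.nontarget_set("background")
s = tp.summarize_set(table, target, "wildtype", reference=background)
print(f"target set: n={s.n} median log2 = {s.median:.2f} "
      f"({s.median_fold:.2f}-fold), p {s.p_display}")

peaks = tp.call_intervals(tracks["wildtype"], threshold=1.0)
recovery = tp.domain_recovery(peaks, truth.domains())
print(f"called {len(peaks)} intervals; "
      f"{100 * (recovery['jaccard'] > 0.5).mean():.0f}% of planted domains "
      f"recovered (mean Jaccard {recovery['jaccard'].mean():.2f})")
```

prints

```
target set: n=200 median log2 = 1.46 (2.76-fold), p < 2.2e-16
called 200 intervals; 100% of planted domains recovered (mean Jaccard 0.85)
```

The planted amplitude is 1.5 log2 units; the pipeline recovers a target-set
median of 1.46 (the small shrinkage is the expected cost of quantile-
normalizing ChIP and input together, see `docs/methods.md`), separates
targets from background at machine-precision significance, and recalls
every planted domain with good positional overlap.

The same stages are available from the shell via `tilepc simulate |
normalize | tss-score | peaks | metagene | compare-sets | domains`
(`tilepc --help`).

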