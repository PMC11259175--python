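# ohnoscope

Analysis toolkit for genomes shaped by a recent **whole-genome duplication
(WGD)** — written for the situation of a facultative microalgal symbiont
whose haploid genome duplicated wholesale, leaving thousands of
WGD-derived duplicate gene pairs (*ohnologs*) whose fates can be read from
gene order, sequence divergence, expression, and splicing.

It is aimed at comparative genomicists and transcriptomicists who want a
self-contained, testable pipeline for:

- **Collinear gene blocks** — dynamic-programming chaining of all-vs-all
  homology hits over gene-rank coordinates; a block is ≥ 5 genes conserved in
  order and orientation, the classical evidence for segmental duplication or
  WGD. Every gene is classified as singleton, dispersed (> 20 intervening
  genes to its nearest homolog), proximal (< 20), tandem (adjacent), or
  WGD/segmental (block anchor).
- **Ka/Ks and the WGD peak** — the Nei–Gojobori (1986) counting method with
  Jukes–Cantor correction,
  `Ks = -3/4 · ln(1 - 4/3 · ps)`, node-averaged over homologous clusters,
  and a 1-D Gaussian mixture over the Ks distribution with AIC model
  selection (k ≤ 4): a recent WGD appears as a narrow low-Ks component.
- **Ohnolog expression divergence** — a negative-binomial GLM per gene over
  the 2×2 design lifestyle × temperature
  (free-living/symbiotic × 28/34 °C), Wald tests on the four contrasts
  L-28, L-34, T-Fr, T-Sy (DE when BH-FDR < 0.01 and |log₂FC| > 1), and the
  five-group classification of pair behaviour: (1) neither copy DE,
  (2) one copy, (3) both in the same contrast and direction, (4) both but
  in disjoint contrasts, (5) both in the same contrast, opposite directions.
- **Expression specificity** — the τ index
  `τ = Σᵢ (1 − xᵢ/x_max) / (N − 1)` over the four condition means on the
  log₂(FPKM+1) scale (Yanai et al.), with Kruskal–Wallis/Wilcoxon tests
  across duplication categories and chi-square + standardized-residual
  post-hoc tests for categorical preference.
- **Splicing** — exon counting bins with a quasi-binomial test of relative
  usage (gene-level BH), and splice-junction conservation by 300-bp flank
  alignment (a junction is conserved only when *both* flanks match at
  E ≤ 10⁻⁵), scored per pair with Kendall τ-b and an exact binomial test.
- **Pathway retention** — enzymes uniquely retained as ohnologs vs
  singletons per pathway, one-sided Fisher tests against the genome
  background, requiring ≥ 5 uniquely retained enzymes and significance in
  both isolates.

A **synthetic-data generator** plants all of the above (ohnolog pairs with a
low-Ks peak, tandem/proximal/dispersed duplicates, five-group DE behaviour,
condition-specific genes, exon-usage shifts, junction conservation) with
known ground truth, so the whole pipeline is testable without external data.

## Worked example

```python
from ohnoscope import RunConfig, run_pipeline

cfg = RunConfig(seed=5, outdir="ohnoscope_out",
                genome={"n_ancestral_genes": 150, "n_scaffolds": 3})
report = run_pipeline(cfg)
```

With this seed the simulated genome has 293 genes after duplication and
loss; the report (also written to `ohnoscope_out/report.json`) contains:

```
block_stats         {"n_blocks": 3, "n_genes_in_blocks": 268, "pct_genes_in_blocks": 91.47}
duplication_census  {"wgd_segmental": 268, "singleton": 16, "tandem": 5, "proximal": 3, "dispersed": 1}
ks.median_ks        0.309        (planted WGD peak: Ks = 0.30)
ks.gmm              k=4 components; dominant component mean 0.307, weight 0.94
group_census        {1: 43 (32.09%), 2: 43 (32.09%), 3: 14 (10.45%), 4: 20 (14.93%), 5: 14 (10.45%)}
tau_census          {"n_eligible": 293, "n_high_tau": 2}
splicing            {"n_deu_bins": 76, "n_deu_genes": 37, "n_junction_pairs": 132,
                     "mean_conserved_fraction": 0.723}   (planted: 0.70)
```

Reading it: three collinear blocks capture 91.47 % of genes (every surviving
WGD pair sits in a block); the mixture's dominant component recovers the
planted Ks peak at 0.31; the five-group census of the 134 expressed pairs
tracks the planted group fractions; and the mean fraction of junctions
conserved within a pair (0.723) recovers the planted conservation
probability 0.70.

The same stages are available from the shell:

```bash
ohnoscope simulate --outdir sim --seed 3        # write GFF/FASTA/hits/counts/truth
ohnoscope synteny sim/genes.gff3 sim/hits.tsv   # blocks + summary JSON
ohnoscope de sim/counts.tsv sim/samples.tsv --contrast L-28 --out de.tsv
ohnoscope run --seed 5 --outdir out             # full pipeline + report.json
```

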