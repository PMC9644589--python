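# iskit — integration-site analysis for retroviral and lentiviral vector products

`iskit` maps vector integration sites (IS) from LTR-junction sequencing
libraries of the kind used to profile gene-modified cell products (CAR
T-cells transduced with lentiviral or γ-retroviral vectors). Such libraries
are built from adaptor-ligated chimeric hDNA–vDNA fragments: each read pair
carries the terminal LTR bases, the flanking host genomic DNA, and a linker
adaptor at the sheared fragment end. The package covers the full desk-scale
analysis:

- **simjunction** — a junction-library simulator with planted ground truth
  (fragments 100–2,000 bp, PCR duplicates, per-base sequencing error, and
  vector-class-specific feature-insertion propensities), used both as the
  test bed and as a first-class data generator;
- **junctionproc** — anchored LTR-tail and linker trimming with per-read
  reject reasons;
- **iscall** — a built-in seed-and-extend aligner (31-mer exact seeds,
  gapless Hamming extension, unique-best rule), SAM/BAM ingestion for
  external aligners, and single-linkage site calling (±5 bp) with read
  counts and PCR-deduplicated fragment counts (distinct shear ends);
- **refmodel / annotate** — strand-aware feature annotation with mutually
  exclusive classes `promoter > utr > exon > intron > intergenic`
  (promoter = 2 kb upstream + 500 bp downstream of the TSS), read-weighted
  feature-coverage percentages, chromosome distributions, TSS-relative
  profiles, and gene × sample hotspot matrices;
- **cohortstats / exprlink** — outcome-group summaries, per-gene
  differential integration (presence/absence Fisher exact + Benjamini–
  Hochberg, pseudocounted log2 enrichment), Pearson covariate scans, PCA,
  and intersection of IS annotations with differential-expression and
  alternative-splicing tables.

The feature-coverage statistic follows the read-weighted definition
`percent(class) = 100 × reads mapped on class / reads mapped on genome`,
and the per-gene differential test between outcome groups A and B is

    p_g  = Fisher exact (two-sided) on [[n_with_A, n_A − n_with_A],
                                        [n_with_B, n_B − n_with_B]]
    enr_g = log2[ ((n_with_A + 0.5)/(n_A + 1)) / ((n_with_B + 0.5)/(n_B + 1)) ]

with BH q-values over the tested genes.

## Worked example

Simulate a γ-retroviral-preset library and run it end to end:

```python
from iskit.simjunction import SimConfig, simulate_sample
from iskit.pipeline import run_simulated_sample, match_sites_to_truth
from iskit.annotate import annotate_sites, feature_coverage

cfg = SimConfig(seed=1, vector_preset="retro")   # 2,000 sites, 3 x 300 kb genome
sim = simulate_sample(cfg)                       # ~110,000 read pairs
res = run_simulated_sample(sim)
print(match_sites_to_truth(res.sites, sim.truth))
cov = feature_coverage(annotate_sites(res.sites, sim.index), weight_mode="reads")
print({k: round(v, 2) for k, v in cov.percentages.items()})
```

prints

```
{'n_truth': 2000, 'n_called': 1971, 'recall': 1.0, 'precision': 1.0}
{'promoter': 13.87, 'utr': 6.6, 'exon': 22.07, 'intron': 22.86, 'intergenic': 34.6}
```

Every planted site is recovered within ±5 bp (nearby planted sites merge,
hence 1,971 called loci), and the read-weighted coverage recovers the
planted γ-retroviral propensities (promoter 14%, utr 7%, exon 21%,
intron 23%, intergenic 35%) to within multinomial noise.

The `analysis/` directory holds numbered drivers that run the same steps
as a narrative cohort analysis (4 lentiviral + 4 γ-retroviral simulated
products over a shared reference): `01_simulate_cohort.py` through
`05_expression_overlap.py`, writing tables under `results/cohort/` and bulky
intermediates under `scratch/`.

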