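# Methods

## The measurement being modelled

Integrating vectors (lentiviral and γ-retroviral) join their proviral DNA to
host genomic DNA at a single base per insertion. Junction libraries expose
that base by amplifying chimeric fragments that run LTR → host flank →
linker adaptor; sequencing the pair from both ends yields R1 anchored at the
vector–host junction and R2 anchored at the sheared fragment end. `iskit`
reconstructs, per product, the set of integration loci, their genomic
feature context, and cohort-level contrasts between vector classes and
clinical outcome groups.

## Coordinates and feature classes

All internal coordinates are 1-based inclusive (GTF convention); BED exports
are 0-based half-open. An integration site is reported at the junction base:
the first host base adjacent to the LTR, with the strand giving the provirus
orientation relative to the reference.

Each genomic position gets exactly one feature class with precedence
`promoter > utr > exon > intron > intergenic`. The promoter window is
`[tss − 2000, tss + 499]` in strand-oriented coordinates (2 kb upstream plus
500 bp downstream of the TSS), so its downstream arm overlaps the 5'UTR and
first exon; the precedence rule resolves that overlap in favour of the
regulatory class, and the same rule is applied identically by the classifier
and by the simulator's planting pools, so planted classes and recovered
classes are comparable by construction. UTR is reported as a single class
(5' and 3' combined) with the sub-labels kept internally. When two genes
could claim a position with the same class, the gene with the smaller
|distance to TSS| wins, then lexicographic gene id. Classification is by
position only; the vector's orientation relative to the gene is not used.
Distances to TSS are strand-oriented with negative = upstream.

One isoform per gene is assumed; overlapping-transcript selection is out of
scope.

## Simulator

`simjunction` generates the study conditions rather than emulating any
particular instrument:

- **Reference**: 3 chromosomes × 300 kb of uniform random sequence, 60
  non-overlapping genes of 3–8 exons with terminal UTR segments; gene counts
  per chromosome follow density weights (default 0.5/0.25/0.25), giving one
  gene-dense chromosome as the desk-scale analogue of the observation that
  integration concentrates in gene-dense chromosomes.
- **Planting**: site classes are multinomial draws from the vector preset —
  lentiviral {intron .33, exon .13, promoter .04, utr .04, intergenic .46},
  γ-retroviral {intron .23, exon .21, promoter .14, utr .07, intergenic
  .35} — then a uniform position within that class's genome-wide pool,
  strand uniform.
- **Fragments**: per site Poisson(50) fragments (a fixed-count mode exists
  for arithmetic checks), lengths uniform in [100, 2000] bp truncated at
  chromosome ends. Fragmentation is modelled as uniform shearing with the
  kit's observed size range rather than literal restriction digestion; the
  reported chemistry ("random shearing" with a six-cutter) is internally
  contradictory, and the uniform model is the simpler faithful reading.
- **Reads**: R1 = 34-nt LTR tail + flank (+ linker if the fragment is short),
  R2 = reverse complement from the shear end, both 150 nt, flat Q40
  qualities. Substitution errors at 0.5%/base; no indels and no quality-score
  error model. 10% of fragments are emitted twice as exact PCR duplicates
  (same junction and shear end, independent sequencing errors). Read names
  are bare serials that encode nothing about the truth; the emitted pair
  list is shuffled.
- **Determinism**: every stage derives its generator from `SimConfig.seed`;
  identical configs are byte-identical, including FASTA/GTF/FASTQ output.

The LTR tail and linker default to synthetic sequences (no licensed vector
sequence is embedded) and are configurable. Reads-per-site, duplicate rate
and the trimming thresholds below are free parameters of the design — no
per-sample distribution is published for them — and the defaults above are
the package's declared study conditions.

What the simulator does **not** reproduce about real data: non-uniform
shear-site preferences, GC/accessibility-driven integration bias within a
class, index hopping between multiplexed samples, indel errors, and
quality-degraded read tails. Passing recovery tests therefore demonstrates
the pipeline's correctness under the stated error model, not robustness to
every artefact of production sequencing.

## Trimming

LTR detection is an anchored Hamming comparison of the read start against
the tail (min aligned length 15, ≤2 mismatches) — junction chemistry
guarantees the tail at position 1, so no local alignment is needed. The
genomic portion is truncated at the first linker occurrence, tolerating one
mismatch per 10 nt of overlap and trimming exact partial matches down to a
single base at the read end so no linker residue survives. Reads are
rejected (as data, with a reason) for missing LTR, genomic portion < 20 nt,
or mean genomic base quality < Q20. Demultiplexing is upstream (one FASTQ
pair per sample).

## Alignment and site calling

The built-in aligner indexes every 31-mer of the reference and evaluates
candidate gapless placements of the query (both orientations) by exact byte
comparison, accepting the unique best placement with identity ≥ 0.95 over
≥ 25 nt. Ties across loci are treated as multimapped and discarded — IS
coordinates must be unambiguous, so random placement is deliberately not
offered. Seeds are taken at non-overlapping offsets plus a tail seed, so any
read with fewer than three well-spread errors still seeds its true locus.
With ≤2% substitutions and desk-scale genomes this recovers the exhaustive
sliding-window optimum; the test suite checks exactly that equivalence.
External aligners are supported by ingesting primary SAM/BAM records
(leading soft-clips ≤ 3 nt tolerated as residual tail; secondary and
supplementary records dropped and counted).

The junction base is the alignment end nearest the LTR (start for forward
placements, end for reverse). The shear end comes from the linker-trimmed
mate; when the mate cannot be placed the far end of the R1 alignment is the
fallback. Junctions are clustered per (chromosome, strand) by single linkage
with gap ≤ 5 bp — an allowance for trimming/error jitter; no clustering rule
is published — and each cluster is reported at its modal junction position
(ties → smallest), with `n_reads` = cluster size and `n_fragments` =
distinct (junction, shear end) pairs, the LM-PCR deduplication convention.
Output is invariant to read order. Two planted sites closer than the
tolerance merge by construction; exact-recovery checks therefore condition
on separations > 5 bp.

## Per-sample statistics

- **Feature coverage**: percentage of weight per class, summing to 100.
  Reads mode (default) weights each site by its read count, matching the
  reads-on-feature / reads-on-genome definition; sites mode weights sites
  equally. Denominators contain accepted, uniquely aligned reads only.
- **TSS profile**: each site contributes its read weight at its
  strand-oriented distance to the *nearest* TSS (no double counting across
  genes), over ±3 kb in 50 bp bins, normalized to sum 1 within the window
  (the normalization is a package choice; all-zero windows are flagged
  empty).
- **Hotspot matrices**: gene × sample counts of distinct integration events
  in one region class (promoter/utr/exon). Events, not reads, are counted —
  read counts are PCR-skewed — though read weights remain exportable. Genes
  are ordered by (samples hit, total events) descending then gene id, with
  optional per-row z-scaling ((x − mean)/sd, zero-sd rows → 0) matching the
  usual heatmap normalization; rendering itself is out of scope.

## Cohort statistics

The per-gene differential-integration test between outcome groups is a
two-sided Fisher exact test on presence/absence (≥1 event vs none) with BH
control across tested genes; genes with no event anywhere are excluded. At
cohort sizes near n = 28 a 2×2 exact test is robust where count models would
inherit PCR skew; count-based alternatives are out of scope. The log2
enrichment uses 0.5/1 pseudocounts to keep volcano abscissae finite.
Pearson correlations (two-tailed t, n−2 df) are computed within vector-class
strata per feature class, reported as not-computable below 3 samples.
Group comparisons of per-sample counts use the pooled-variance t-test
(Welch optional). PCA column-centers the samples × genes matrix (the
z-scored event matrix transposed) and decomposes by SVD; variance
percentages sum to 100.

Because Fisher's exact test is discrete and conservative, permuted-label
calibration is checked one-sided: the p-value distribution must show no
excess of small values relative to uniform.

## Expression and splicing intersection

Differential-expression and alternative-splicing results are consumed as
tables (limma-style and rMATS-style columns accepted, 0-based rMATS exon
coordinates converted to 1-based); recomputing them is out of scope. DEG
filtering keeps |log2FC| ≥ 1 — fold change ≥ 2 in either direction — with
adjusted p strictly < 0.05. A DEG counts as integration-affected if any
sample has ≥1 site of the requested classes in that gene (unique genes, not
gene–sample pairs). AS events pass at FDR < 0.05 and |ΔPSI| ≥ 0.2 and are
flagged when the alternative interval contains ≥1 site (closed-interval
containment).

## Problem sizes and numerical choices

The standard simulated condition is 2,000 sites per library over a 3 × 300 kb
genome with Poisson-50 read pairs per site (~110,000 pairs); recovery there
is recall = precision = 1.0 at ±5 bp and coverage percentages land within
multinomial noise (±2 points) of the planted presets. The cohort drivers use
8 × 300 sites to keep the narrative analysis light. Oracle-equivalence tests
run the classifier against a linear-scan oracle on 10⁴ random positions, the
aligner against the sliding-window optimum on 10³ fragments, the Fisher
p-value against direct hypergeometric enumeration over all small-margin
tables, and the clusterer against graph connected components on 500 random
inputs. Percentages in reports are rounded to one decimal; all randomness
flows from explicit seeds.

## Known limitations

Single isoform per gene; no chimera/translocation or vector-internal
rearrangement detection; no clonality indices (Shannon, UC50); no GO or
pathway enrichment; no survival or multivariable outcome modelling; the
built-in aligner is gapless and sized for simulated references, not a
production short-read mapper.
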