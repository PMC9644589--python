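"""Annotate called sites against the gene models and summarize per-sample
integration patterns: feature-coverage percentages, chromosome distribution,
gene density, TSS-relative profiles, and promoter/utr/exon hotspot matrices.

The headline comparison is lentiviral vs γ-retroviral mean coverage per
feature class — the expected picture is promoter/utr/exon-shifted
γ-retroviral products and intron/intergenic-heavy lentiviral products.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, SCRATCH, base_config, sample_plan

from iskit.annotate import (
    annotate_sites,
    annotated_frame,
    chrom_distribution,
    feature_coverage,
    gene_density,
    hotspot_tally,
    tss_profile,
)
from iskit.iscall import IntegrationSite
from iskit.refmodel import Genome, build_feature_index, load_gene_models


def load_sites(sample_id):
    df = pd.read_csv(RESULTS / "sites" / f"{sample_id}_sites.tsv", sep="\t")
    return [
        IntegrationSite(r.sample_id, r.chrom, r.pos, r.strand, r.n_reads, r.n_fragments, r.site_id)
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    genome = Genome.from_fasta(SCRATCH / "reference.fa")
    models = load_gene_models(SCRATCH / "genes.gtf")
    cfg = base_config()
    index = build_feature_index(models, cfg.annotation, chromosomes=genome.lengths)

    annotated, coverage_rows, chrom_rows = {}, [], []
    for sample_id, vector_class, _cfg in sample_plan():
        ann = annotate_sites(load_sites(sample_id), index)
        annotated[sample_id] = ann
        annotated_frame(ann).to_csv(RESULTS / "sites" / f"{sample_id}_annotated.tsv", sep="\t", index=False)
        cov = feature_coverage(ann, weight_mode="reads")
        for cls, pct in cov.percentages.items():
            coverage_rows.append((sample_id, vector_class, cls, round(pct, 2)))
        for chrom, pct in chrom_distribution(ann).items():
            chrom_rows.append((sample_id, vector_class, chrom, round(pct, 2)))
        prof = tss_profile(ann, index)
        prof.frame().to_csv(RESULTS / f"tss_profile_{sample_id}.tsv", sep="\t", index=False)

    coverage = pd.DataFrame(coverage_rows, columns=["sample_id", "vector_class", "feature_class", "percent"])
    coverage.to_csv(RESULTS / "feature_coverage.tsv", sep="\t", index=False)
    mean_cov = coverage.pivot_table(index="feature_class", columns="vector_class", values="percent")
    print("mean read-weighted coverage (%) by vector class:")
    print(mean_cov.round(1).to_string())

    pd.DataFrame(chrom_rows, columns=["sample_id", "vector_class", "chrom", "percent"]).to_csv(
        RESULTS / "chrom_distribution.tsv", sep="\t", index=False
    )
    dens = gene_density(models, genome)
    pd.Series(dens, name="genes_per_mb").rename_axis("chrom").to_csv(RESULTS / "gene_density.tsv", sep="\t")
    print("\ngenes per Mb:", {k: round(v, 1) for k, v in dens.items()})

    for region in ("promoter", "utr", "exon"):
        mat = hotspot_tally(annotated, region, top_k=50, zscore=False)
        mat.to_csv(RESULTS / f"hotspot_{region}.tsv", sep="\t")
        matz = hotspot_tally(annotated, region, top_k=50, zscore=True)
        matz.to_csv(RESULTS / f"hotspot_{region}_zscore.tsv", sep="\t")
    print(f"\nhotspot matrices and coverage tables -> {RESULTS}")


if __name__ == "__main__":
    main()
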