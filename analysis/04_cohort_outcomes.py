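"""Cross-sample statistics: outcome-group summaries on the packaged
28-product outcomes table, differential gene integration between vector
classes in the simulated cohort, PCA of the normalized gene-integration
matrix, and covariate correlations with feature coverage.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, SCRATCH, base_config, sample_plan

from iskit.annotate import annotate_sites, presence_matrix, hotspot_tally
from iskit.cohortstats import (
    covariate_scan,
    diffint_frame,
    differential_integration,
    group_summary,
    load_example_outcomes,
    pca_samples,
)
from iskit.refmodel import Genome, build_feature_index, load_gene_models

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from importlib import import_module

load_sites = import_module("03_feature_annotation").load_sites


def main() -> None:
    # outcome-group composition of the packaged example cohort
    outcomes = load_example_outcomes()
    for field in ("response", "crs", "hlh"):
        summary = group_summary(outcomes, field)
        summary.to_csv(RESULTS / f"outcome_summary_{field}.tsv", sep="\t", index=False)
        print(f"{field}:")
        print(summary.to_string(index=False), "\n")

    genome = Genome.from_fasta(SCRATCH / "reference.fa")
    models = load_gene_models(SCRATCH / "genes.gtf")
    index = build_feature_index(models, base_config().annotation, chromosomes=genome.lengths)
    plan = sample_plan()
    annotated = {sid: annotate_sites(load_sites(sid), index) for sid, _, _ in plan}
    lenti = [sid for sid, vc, _ in plan if vc == "lentiviral"]
    retro = [sid for sid, vc, _ in plan if vc == "retroviral"]

    presence = presence_matrix(annotated, region_classes=("promoter", "utr", "exon"))
    results = differential_integration(presence, retro, lenti)
    volcano = diffint_frame(results).sort_values("p_value")
    volcano.to_csv(RESULTS / "differential_integration_retro_vs_lenti.tsv", sep="\t", index=False)
    n_sig = (volcano["q_value"] < 0.05).sum()
    print(f"differential integration (retro vs lenti): {len(volcano)} genes tested, {n_sig} at q<0.05")
    print(volcano.head(5).to_string(index=False), "\n")

    counts = hotspot_tally(annotated, "promoter", zscore=True)
    pca = pca_samples(counts.T)
    scores = pca.scores_frame()
    scores["pct_var_pc1"] = pca.pct_variance[0]
    scores.to_csv(RESULTS / "pca_scores.tsv", sep="\t")
    print(f"PCA: PC1 {pca.pct_variance[0]:.1f}% / PC2 {pca.pct_variance[1]:.1f}% of variance")

    coverage = pd.read_csv(RESULTS / "feature_coverage.tsv", sep="\t")
    meta = pd.read_csv(RESULTS / "sample_sheet.tsv", sep="\t")
    tables = []
    for covariate in ("cd4_pct", "cd8_pct", "vcn", "transduction_eff_pct"):
        tables.append(covariate_scan(coverage, meta, covariate))
    scan = pd.concat(tables, ignore_index=True)
    scan.to_csv(RESULTS / "covariate_correlations.tsv", sep="\t", index=False)
    computable = scan.dropna(subset=["r"])
    print(f"covariate scan: {len(scan)} cells, {len(computable)} computable (n >= 3 per stratum)")


if __name__ == "__main__":
    main()
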