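"""Simulate the junction-library cohort: shared reference, 4 lentiviral and
4 γ-retroviral products with planted integration sites and full ground truth.

Writes the reference (FASTA/GTF), per-sample paired FASTQ and truth tables
under scratch/cohort/, and the sample sheet with plausible product
covariates under results/cohort/.
"""

import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import BASE_SEED, RESULTS, SCRATCH, base_config, sample_plan

from iskit.refmodel import build_feature_index, write_gtf
from iskit.simjunction import plant_sites, simulate_reads, simulate_reference, write_fastq_pair, write_truth


def main(seed: int = BASE_SEED) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = base_config(seed)
    genome, models = simulate_reference(cfg)
    genome.to_fasta(SCRATCH / "reference.fa")
    write_gtf(models, SCRATCH / "genes.gtf")
    index = build_feature_index(models, cfg.annotation, chromosomes=genome.lengths)

    meta_rng = np.random.default_rng(seed + 77)
    rows = []
    for sample_id, vector_class, sample_cfg in sample_plan(seed):
        truth = plant_sites(sample_cfg, genome, index)
        pairs, truth, _frags = simulate_reads(genome, truth, sample_cfg)
        write_fastq_pair(pairs, SCRATCH / f"{sample_id}_R1.fastq", SCRATCH / f"{sample_id}_R2.fastq")
        write_truth(truth, SCRATCH / f"{sample_id}_truth.tsv", SCRATCH / f"{sample_id}_truth.bed")
        cd4 = float(np.round(meta_rng.uniform(25, 75), 1))
        rows.append(
            {
                "sample_id": sample_id,
                "vector_class": vector_class,
                "car_target": "CD22" if vector_class == "lentiviral" else "BCMA",
                "disease": "B-ALL" if vector_class == "lentiviral" else "MM",
                "gender": "F" if meta_rng.random() < 0.5 else "M",
                "cd4_pct": cd4,
                "cd8_pct": float(np.round(np.clip(95 - cd4 + meta_rng.normal(0, 3), 5, 75), 1)),
                "transduction_eff_pct": float(np.round(meta_rng.uniform(25, 85), 1)),
                "vcn": float(np.round(meta_rng.uniform(0.5, 4.5), 2)),
                "n_planted_sites": len(truth),
                "n_read_pairs": len(pairs),
            }
        )
        print(f"{sample_id} ({vector_class}): {len(truth)} sites, {len(pairs)} read pairs")
    sheet = pd.DataFrame(rows)
    sheet.to_csv(RESULTS / "sample_sheet.tsv", sep="\t", index=False)
    print(f"\nreference: {sum(genome.lengths.values()):,} bp, {len(models)} genes")
    print(f"sample sheet -> {RESULTS / 'sample_sheet.tsv'}")


if __name__ == "__main__":
    main()
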