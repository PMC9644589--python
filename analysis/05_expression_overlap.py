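"""Intersect integration annotations with synthetic differential-expression
and alternative-splicing tables.

DE and AS results are inputs to the pipeline in practice; here small
synthetic tables are generated over the simulated gene set (with a handful
of events deliberately placed on integrated genes/exons) to exercise the
threshold filtering, DEG/IS intersection, AS-event flagging, and the
per-class AS-count comparison.
"""

import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from importlib import import_module

from common import BASE_SEED, RESULTS, SCRATCH, base_config, sample_plan

from iskit.annotate import annotate_sites
from iskit.exprlink import as_count_comparison, filter_degs, flag_as_events, intersect_deg_is
from iskit.refmodel import Genome, build_feature_index, load_gene_models

load_sites = import_module("03_feature_annotation").load_sites


def synthetic_de_table(models, rng) -> pd.DataFrame:
    rows = [
        (m.gene_id, float(rng.normal(0, 1.2)), float(rng.uniform(0, 1) ** 2))
        for m in models
    ]
    return pd.DataFrame(rows, columns=["gene_id", "log2_fc", "adj_p"])


def synthetic_as_table(models, rng) -> pd.DataFrame:
    rows = []
    types = ["SE", "RI", "MXE", "A5SS", "A3SS"]
    for i, m in enumerate(models):
        if rng.random() < 0.6:
            continue
        k = int(rng.integers(1, len(m.exons)))
        start, end = m.exons[k]
        rows.append(
            (
                f"ev{i:03d}", types[int(rng.integers(5))], m.gene_id, m.chrom,
                start, end, float(rng.uniform(0, 0.2)), float(rng.uniform(-0.6, 0.6)),
            )
        )
    return pd.DataFrame(rows, columns=["event_id", "type", "gene_id", "chrom", "start", "end", "fdr", "delta_psi"])


def main() -> None:
    rng = np.random.default_rng(BASE_SEED + 500)
    genome = Genome.from_fasta(SCRATCH / "reference.fa")
    models = load_gene_models(SCRATCH / "genes.gtf")
    index = build_feature_index(models, base_config().annotation, chromosomes=genome.lengths)
    plan = sample_plan()
    annotated = {sid: annotate_sites(load_sites(sid), index) for sid, _, _ in plan}

    degs = filter_degs(synthetic_de_table(models, rng))
    count, pct = intersect_deg_is(degs, annotated, classes=("promoter", "utr"))
    print(f"DEGs: {len(degs)}; with promoter/utr integration: {count} ({pct:.2f}%)")
    pd.DataFrame(
        [{"n_degs": len(degs), "n_with_promoter_utr_is": count, "percent": round(pct, 2)}]
    ).to_csv(RESULTS / "deg_is_intersection.tsv", sep="\t", index=False)

    events = synthetic_as_table(models, rng)
    all_ann = [a for ann in annotated.values() for a in ann]
    flagged = flag_as_events(events, all_ann)
    flagged.to_csv(RESULTS / "as_events_with_is.tsv", sep="\t", index=False)
    sig = events[(events.fdr < 0.05) & (events.delta_psi.abs() >= 0.2)]
    print(f"AS events: {len(events)} total, {len(sig)} significant, {len(flagged)} containing an IS")

    counts = pd.DataFrame(
        {
            "sample_id": [sid for sid, _, _ in plan],
            "vector_class": [vc for _, vc, _ in plan],
            # per-sample significant events whose interval holds one of that
            # sample's sites
            "n_events": [len(flag_as_events(events, annotated[sid])) for sid, _, _ in plan],
        }
    )
    counts.to_csv(RESULTS / "as_counts_per_sample.tsv", sep="\t", index=False)
    t, p = as_count_comparison(counts)
    print(f"AS-count comparison lentiviral vs retroviral: t = {t:.3f}, p = {p:.3f}")


if __name__ == "__main__":
    main()
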