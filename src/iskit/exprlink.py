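"""Intersection of integration-site annotations with externally computed
differential-expression and alternative-splicing results.

Expression and splicing analyses themselves are inputs (tables from
limma-style DE and rMATS-style AS pipelines); this module contributes the
threshold filtering and the gene/interval intersection logic linking those
results to integration sites.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedIS
from .cohortstats import ttest_two_sample

AS_EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")

DE_COLUMNS = ["gene_id", "log2_fc", "adj_p"]
AS_COLUMNS = ["event_id", "type", "gene_id", "chrom", "start", "end", "fdr", "delta_psi"]


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if ((df["adj_p"] < 0) | (df["adj_p"] > 1)).any():
        raise ValueError("adj_p outside [0, 1]")
    return df


def read_as_events(path) -> pd.DataFrame:
    """Read an alternative-splicing events table.

    Accepts either the native schema (``AS_COLUMNS``, 1-based inclusive
    ``start``/``end`` of the alternative interval) or rMATS-style columns
    (GeneID, chr, exonStart_0base, exonEnd, FDR, IncLevelDifference), which
    are converted to 1-based.
    """
    df = pd.read_csv(path, sep="\t")
    if "exonStart_0base" in df.columns:
        df = pd.DataFrame(
            {
                "event_id": df.get("ID", pd.RangeIndex(len(df))).astype(str),
                "type": df.get("type", "SE"),
                "gene_id": df["GeneID"],
                "chrom": df["chr"],
                "start": df["exonStart_0base"].astype(int) + 1,
                "end": df["exonEnd"].astype(int),
                "fdr": df["FDR"].astype(float),
                "delta_psi": df["IncLevelDifference"].astype(float),
            }
        )
    missing = set(AS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"AS table missing columns: {sorted(missing)}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("fdr outside [0, 1]")
    if (df["delta_psi"].abs() > 1).any():
        raise ValueError("|delta_psi| must be <= 1")
    bad = df[~df["type"].isin(AS_EVENT_TYPES)]
    if len(bad):
        raise ValueError(f"unknown AS event types: {sorted(bad['type'].unique())}")
    return df


def filter_degs(records: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 0.05) -> pd.DataFrame:
    """Significant DE genes: |fold change| ≥ fc_threshold (i.e. |log2FC| ≥
    log2(fc_threshold), both directions) and adjusted p strictly < p_threshold.
    Idempotent; output is a row subset of the input."""
    lfc_min = np.log2(fc_threshold)
    keep = (records["log2_fc"].abs() >= lfc_min) & (records["adj_p"] < p_threshold)
    return records[keep].copy()


def intersect_deg_is(
    degs: pd.DataFrame,
    annotated_per_sample: dict[str, Sequence[AnnotatedIS]],
    classes: Sequence[str] = ("promoter", "utr"),
) -> tuple[int, float]:
    """Count DEGs with an integration site in the given feature classes.

    A DEG counts once (unique genes across the cohort) if any sample has ≥1
    site annotated to that gene with a class in ``classes``. Returns
    ``(count, percent of DEGs)``.
    """
    hit_genes = {
        a.gene_id
        for annotated in annotated_per_sample.values()
        for a in annotated
        if a.gene_id is not None and a.feature_class in classes
    }
    deg_genes = set(degs["gene_id"])
    count = len(deg_genes & hit_genes)
    percent = 100.0 * count / len(deg_genes) if deg_genes else 0.0
    return count, percent


def flag_as_events(
    events: pd.DataFrame,
    annotated_sites: Sequence[AnnotatedIS],
    fdr_max: float = 0.05,
    dpsi_min: float = 0.2,
) -> pd.DataFrame:
    """Significant AS events whose alternative interval contains ≥1 site.

    Threshold filter (fdr < fdr_max and |ΔPSI| ≥ dpsi_min) followed by
    closed-interval containment of the integration position.
    """
    sig = events[(events["fdr"] < fdr_max) & (events["delta_psi"].abs() >= dpsi_min)]
    if sig.empty or not annotated_sites:
        return sig.iloc[0:0].copy()
    by_chrom: dict[str, np.ndarray] = {}
    for a in annotated_sites:
        by_chrom.setdefault(a.chrom, [])
        by_chrom[a.chrom].append(a.pos)
    by_chrom = {c: np.asarray(sorted(v)) for c, v in by_chrom.items()}
    flags = []
    for ev in sig.itertuples(index=False):
        pool = by_chrom.get(ev.chrom)
        if pool is None:
            flags.append(False)
            continue
        lo = np.searchsorted(pool, ev.start, side="left")
        hi = np.searchsorted(pool, ev.end, side="right")
        flags.append(hi > lo)
    return sig[np.asarray(flags, dtype=bool)].copy()


def as_count_comparison(
    counts: pd.DataFrame, group_field: str = "vector_class"
) -> tuple[float, float]:
    """t-test of per-sample significant-AS-event counts between vector classes.

    ``counts`` needs columns ``n_events`` and ``group_field`` with exactly
    two levels. Delegates to :func:`cohortstats.ttest_two_sample`.
    """
    levels = sorted(counts[group_field].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a = counts.loc[counts[group_field] == levels[0], "n_events"]
    b = counts.loc[counts[group_field] == levels[1], "n_events"]
    return ttest_two_sample(a, b)
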