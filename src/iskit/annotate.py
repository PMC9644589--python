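"""Per-sample integration-site statistics: feature classification,
read-weighted feature coverage, chromosome distribution, TSS-relative
profiles, and gene-region hotspot matrices.

Coverage percentages follow the read-weighted definition (reads mapped on a
feature / reads mapped on the genome × 100); a sites mode weighting each
distinct site equally is also available. Hotspot matrices count distinct
integration events per gene region, not reads, since read counts are
PCR-skewed; both weightings can be exported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .iscall import IntegrationSite
from .refmodel import FEATURE_CLASSES, AnnotationParams, FeatureIndex, GeneModel, Genome


@dataclass
class AnnotatedIS:
    site: IntegrationSite
    feature_class: str
    gene_id: Optional[str]
    dist_to_tss: Optional[int]

    # convenience pass-throughs
    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos

    @property
    def n_reads(self) -> int:
        return self.site.n_reads


def annotate_sites(sites: Sequence[IntegrationSite], index: FeatureIndex) -> list[AnnotatedIS]:
    """Classify each site's junction position against the feature index."""
    unknown = [s.site_id or f"{s.chrom}:{s.pos}" for s in sites
               if index.known_chroms is not None and s.chrom not in index.known_chroms]
    if unknown:
        raise KeyError(f"sites on chromosomes unknown to the index: {unknown[:5]}")
    out = []
    for s in sites:
        cls, gene_id, dist = index.classify(s.chrom, s.pos)
        out.append(AnnotatedIS(s, cls, gene_id, dist))
    return out


def annotated_frame(annotated: Sequence[AnnotatedIS]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.site.sample_id, a.site.site_id, a.chrom, a.pos, a.site.strand,
                a.site.n_reads, a.site.n_fragments, a.feature_class, a.gene_id, a.dist_to_tss,
            )
            for a in annotated
        ],
        columns=[
            "sample_id", "site_id", "chrom", "pos", "strand",
            "n_reads", "n_fragments", "feature_class", "gene_id", "dist_to_tss",
        ],
    )


@dataclass
class FeatureCoverage:
    sample_id: str
    percentages: dict[str, float]
    weight_mode: str  # reads | sites

    def as_series(self) -> pd.Series:
        return pd.Series(self.percentages, name=self.sample_id)


def feature_coverage(annotated: Sequence[AnnotatedIS], weight_mode: str = "reads", sample_id: str | None = None) -> FeatureCoverage:
    """Percentage of weight per feature class (sums to 100).

    reads mode weights each site by its read count (the reads-on-feature /
    reads-on-genome definition); sites mode weights each site equally.
    """
    if not annotated:
        raise ValueError("feature_coverage requires at least one annotated site")
    if weight_mode not in ("reads", "sites"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    weights = {c: 0.0 for c in FEATURE_CLASSES}
    for a in annotated:
        weights[a.feature_class] += a.n_reads if weight_mode == "reads" else 1
    total = sum(weights.values())
    pct = {c: 100.0 * w / total for c, w in weights.items()}
    sid = sample_id if sample_id is not None else annotated[0].site.sample_id
    return FeatureCoverage(sid, pct, weight_mode)


def chrom_distribution(annotated: Sequence[AnnotatedIS], weight_mode: str = "sites") -> dict[str, float]:
    """Percentage of sites (or reads) per chromosome; sums to 100."""
    if not annotated:
        raise ValueError("empty annotation")
    weights: dict[str, float] = {}
    for a in annotated:
        w = a.n_reads if weight_mode == "reads" else 1
        weights[a.chrom] = weights.get(a.chrom, 0.0) + w
    total = sum(weights.values())
    return {c: 100.0 * w / total for c, w in sorted(weights.items())}


def gene_density(models: Sequence[GeneModel], genome: Genome) -> dict[str, float]:
    """Genes per megabase per chromosome (0 for gene-less chromosomes)."""
    counts: dict[str, int] = {c: 0 for c in genome.lengths}
    for m in models:
        counts[m.chrom] = counts.get(m.chrom, 0) + 1
    return {c: counts[c] / (genome.lengths[c] / 1e6) for c in counts}


@dataclass
class TssProfile:
    edges: np.ndarray  # bin edges over [-window, +window]
    signal: np.ndarray  # normalized to sum 1 (all-zero if empty)
    n_in_window: int

    @property
    def empty(self) -> bool:
        return self.n_in_window == 0

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.edges[:-1], "bin_end": self.edges[1:], "signal": self.signal})


def tss_profile(
    annotated: Sequence[AnnotatedIS],
    index: FeatureIndex,
    params: AnnotationParams | None = None,
    weight_mode: str = "reads",
) -> TssProfile:
    """Read-weighted distribution of strand-oriented distance to the nearest TSS.

    Each site contributes at its distance to the *nearest* TSS (no double
    counting across genes); only sites within ±tss_window of some TSS enter.
    The signal is normalized to sum 1 over the window; with no reads in the
    window an all-zero profile flagged empty is returned.
    """
    params = params or index.params
    if (2 * params.tss_window) % params.tss_bin != 0:
        raise ValueError("tss_bin must divide 2 * tss_window")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {m.chrom for m in index.models}:
        ms = sorted((m for m in index.models if m.chrom == chrom), key=lambda m: m.tss)
        by_chrom[chrom] = (
            np.array([m.tss for m in ms]),
            np.array([1 if m.strand == "+" else -1 for m in ms]),
        )
    dists, weights = [], []
    for a in annotated:
        entry = by_chrom.get(a.chrom)
        if entry is None:
            continue
        tss_arr, strand_arr = entry
        j = int(np.searchsorted(tss_arr, a.pos))
        best = None
        for idx in (j - 1, j):
            if 0 <= idx < len(tss_arr):
                d = abs(a.pos - int(tss_arr[idx]))
                if best is None or d < best[0]:
                    best = (d, idx)
        if best is None or best[0] > params.tss_window:
            continue
        idx = best[1]
        signed = (a.pos - int(tss_arr[idx])) * int(strand_arr[idx])
        dists.append(signed)
        weights.append(a.n_reads if weight_mode == "reads" else 1)
    edges = np.arange(-params.tss_window, params.tss_window + params.tss_bin, params.tss_bin)
    if not dists:
        return TssProfile(edges, np.zeros(len(edges) - 1), 0)
    hist, _ = np.histogram(dists, bins=edges, weights=np.asarray(weights, dtype=float))
    return TssProfile(edges, hist / hist.sum(), len(dists))


# ---------------------------------------------------------------------------
# hotspot matrices

def hotspot_tally(
    annotated_per_sample: dict[str, Sequence[AnnotatedIS]],
    region_class: str,
    top_k: Optional[int] = None,
    zscore: bool = False,
) -> pd.DataFrame:
    """Gene × sample matrix of integration-event counts in one region class.

    A cell counts the distinct sites of that sample classified to that gene
    with ``feature_class == region_class``. Genes are ordered by (number of
    samples with ≥1 event, total events) descending, then gene_id. With
    ``zscore`` each row is scaled to (x − mean) / sd; zero-sd rows become 0.
    """
    if region_class not in ("promoter", "utr", "exon", "intron"):
        raise ValueError(f"unknown region_class {region_class!r}")
    if not annotated_per_sample:
        raise ValueError("need at least one sample")
    samples = list(annotated_per_sample)
    counts: dict[str, dict[str, int]] = {}
    for sid in samples:
        for a in annotated_per_sample[sid]:
            if a.feature_class == region_class and a.gene_id is not None:
                counts.setdefault(a.gene_id, {}).setdefault(sid, 0)
                counts[a.gene_id][sid] += 1
    mat = pd.DataFrame(
        [[counts.get(g, {}).get(s, 0) for s in samples] for g in counts],
        index=list(counts), columns=samples, dtype=float,
    )
    if mat.empty:
        return pd.DataFrame(columns=samples)
    order = sorted(
        mat.index,
        key=lambda g: (-(mat.loc[g] > 0).sum(), -mat.loc[g].sum(), g),
    )
    mat = mat.loc[order]
    if top_k is not None:
        mat = mat.iloc[:top_k]
    if zscore:
        mean = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=0)
        mat = mat.sub(mean, axis=0)
        nz = sd > 0
        mat.loc[nz] = mat.loc[nz].div(sd[nz], axis=0)
        mat.loc[~nz] = 0.0
    return mat


def presence_matrix(annotated_per_sample: dict[str, Sequence[AnnotatedIS]], region_classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene × sample boolean matrix: sample has ≥1 event at the gene.

    ``region_classes`` restricts to given feature classes (default: any
    genic class).
    """
    samples = list(annotated_per_sample)
    genes: dict[str, set[str]] = {}
    for sid in samples:
        for a in annotated_per_sample[sid]:
            if a.gene_id is None:
                continue
            if region_classes is not None and a.feature_class not in region_classes:
                continue
            genes.setdefault(a.gene_id, set()).add(sid)
    return pd.DataFrame(
        [[s in genes[g] for s in samples] for g in sorted(genes)],
        index=sorted(genes), columns=samples, dtype=bool,
    )
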