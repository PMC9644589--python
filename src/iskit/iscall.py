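"""Alignment of genomic junction fragments and integration-site calling.

The built-in aligner is a gapless seed-and-extend mapper (31-mer exact
seeds, Hamming extension, unique-best rule) sized for the simulated desk-
scale genomes this package analyses; externally produced SAM/BAM is accepted
through :func:`ingest_alignments` so a production aligner can be swapped in.

A called integration site is a single-linkage cluster of junction positions
(same chromosome and provirus strand, gap ≤ ``tol``), reported at the modal
junction base with read counts and PCR-deduplicated fragment counts
(distinct shear ends).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .refmodel import Genome
from .simjunction import revcomp


@dataclass
class Alignment:
    read_id: str
    chrom: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    strand: str  # orientation of the query on the reference
    identity: float
    unique: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("alignment start > end")


@dataclass
class IntegrationSite:
    sample_id: str
    chrom: str
    pos: int  # junction base: first host base adjacent to the LTR
    strand: str  # provirus orientation relative to the reference
    n_reads: int
    n_fragments: int
    site_id: str = ""


class GenomeAligner:
    """Exact k-mer seed + gapless Hamming extension aligner over a Genome.

    Returns the unique best full-length placement with identity ≥
    ``min_identity``; reads whose best identity is tied across loci are
    treated as multimapped and rejected (IS coordinates must be unambiguous).
    """

    def __init__(self, genome: Genome, k: int = 31):
        self.genome = genome
        self.k = k
        self.index: dict[bytes, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            b = seq.encode("ascii")
            for i in range(len(b) - k + 1):
                self.index.setdefault(b[i : i + k], []).append((chrom, i))

    def align(self, seq: str, read_id: str = "", min_len: int = 25, min_identity: float = 0.95) -> Optional[Alignment]:
        n = len(seq)
        if n < min_len:
            return None
        k = self.k
        candidates: dict[tuple[str, int, str], None] = {}
        queries = {"+": seq, "-": revcomp(seq)}
        for strand, q in queries.items():
            b = q.encode("ascii")
            offsets = list(range(0, n - k + 1, k))
            if offsets and offsets[-1] != n - k:
                offsets.append(n - k)  # tail seed catches errors in every block
            for off in offsets:
                for chrom, p in self.index.get(b[off : off + k], ()):
                    start0 = p - off
                    if start0 < 0 or start0 + n > self.genome.lengths[chrom]:
                        continue
                    candidates[(chrom, start0, strand)] = None
        if not candidates:
            return None
        best: list[tuple[str, int, str]] = []
        best_ident = -1.0
        for chrom, start0, strand in candidates:
            ref = self.genome.as_array(chrom)[start0 : start0 + n]
            qarr = np.frombuffer(queries[strand].encode("ascii"), dtype=np.uint8)
            ident = float((ref == qarr).mean())
            if ident > best_ident + 1e-12:
                best_ident, best = ident, [(chrom, start0, strand)]
            elif abs(ident - best_ident) <= 1e-12:
                best.append((chrom, start0, strand))
        if best_ident < min_identity:
            return None
        loci = {(c, s) for c, s, _ in best}
        if len(loci) > 1:
            return None  # multimapped
        chrom, start0, strand = best[0]
        return Alignment(read_id, chrom, start0 + 1, start0 + n, strand, best_ident, unique=True)


def align_genomic(
    seq: str, genome: Genome, min_len: int = 25, min_identity: float = 0.95, aligner: GenomeAligner | None = None
) -> Optional[Alignment]:
    """One-shot convenience wrapper; build a :class:`GenomeAligner` for bulk use."""
    if aligner is None:
        aligner = GenomeAligner(genome)
    return aligner.align(seq, min_len=min_len, min_identity=min_identity)


def junction_position(aln: Alignment) -> tuple[int, str]:
    """Junction base and provirus strand from a junction-fragment alignment.

    The genomic fragment is read away from the LTR, so the junction base is
    the alignment end nearest the LTR: the start for a forward placement, the
    end for a reverse one.
    """
    return (aln.start, "+") if aln.strand == "+" else (aln.end, "-")


def ingest_alignments(sam_path: str | Path, max_leading_clip: int = 3) -> tuple[list[Alignment], dict[str, int]]:
    """Read primary mapped records from SAM/BAM.

    Leading soft-clips up to ``max_leading_clip`` nt (residual LTR bases) are
    tolerated; secondary/supplementary/unmapped records are excluded and
    counted. Identity is derived from the NM tag when present.
    """
    import pysam

    out: list[Alignment] = []
    excluded: Counter[str] = Counter()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                excluded["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                excluded["secondary_or_supplementary"] += 1
                continue
            cig = rec.cigartuples or []
            lead = cig[0][1] if cig and cig[0][0] == 4 else 0
            if rec.is_reverse:
                lead = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            if lead > max_leading_clip:
                excluded["excess_soft_clip"] += 1
                continue
            aln_len = rec.reference_length or 0
            if aln_len == 0:
                excluded["zero_length"] += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start + 1,
                    end=rec.reference_start + aln_len,
                    strand="-" if rec.is_reverse else "+",
                    identity=max(0.0, 1.0 - nm / aln_len),
                    unique=True,
                )
            )
    return out, dict(excluded)


# ---------------------------------------------------------------------------
# clustering

def call_sites(
    junctions: Iterable[tuple[str, int, str, Optional[int], str]],
    tol: int = 5,
    sample_id: str = "",
) -> list[IntegrationSite]:
    """Cluster junction records into integration sites.

    ``junctions`` holds ``(chrom, pos, strand, shear_end, read_id)``. Records
    are grouped per (chrom, strand) and single-linkage clustered with gap ≤
    ``tol``; each cluster is reported at its modal junction position
    (ties → smallest). ``n_fragments`` counts distinct (junction, shear_end)
    pairs; a missing shear end falls back to the read_id (no collapsing).
    Output is invariant to input order.
    """
    groups: dict[tuple[str, str], list[tuple[int, object]]] = defaultdict(list)
    for chrom, pos, strand, shear_end, read_id in junctions:
        frag_key = shear_end if shear_end is not None else f"read:{read_id}"
        groups[(chrom, strand)].append((pos, frag_key))
    sites: list[IntegrationSite] = []
    for (chrom, strand), recs in sorted(groups.items()):
        recs.sort(key=lambda t: (t[0], str(t[1])))
        cluster: list[tuple[int, object]] = []
        for rec in recs:
            if cluster and rec[0] - cluster[-1][0] > tol:
                sites.append(_summarize_cluster(cluster, chrom, strand, sample_id))
                cluster = []
            cluster.append(rec)
        if cluster:
            sites.append(_summarize_cluster(cluster, chrom, strand, sample_id))
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    for i, s in enumerate(sites, start=1):
        s.site_id = f"{sample_id or 'IS'}_{i:05d}"
    return sites


def _summarize_cluster(cluster: list[tuple[int, object]], chrom: str, strand: str, sample_id: str) -> IntegrationSite:
    positions = [p for p, _ in cluster]
    counts = Counter(positions)
    top = max(counts.values())
    pos = min(p for p, c in counts.items() if c == top)
    n_fragments = len({(p, f) for p, f in cluster})
    return IntegrationSite(sample_id, chrom, pos, strand, n_reads=len(cluster), n_fragments=n_fragments)


def sites_to_frame(sites: Sequence[IntegrationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.site_id, s.chrom, s.pos, s.strand, s.n_reads, s.n_fragments)
            for s in sites
        ],
        columns=["sample_id", "site_id", "chrom", "pos", "strand", "n_reads", "n_fragments"],
    )


def write_sites_bed(sites: Sequence[IntegrationSite], path: str | Path) -> None:
    """BED6: 0-based half-open single-base interval, score = n_fragments."""
    with open(path, "w") as out:
        for s in sites:
            out.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.site_id}\t{s.n_fragments}\t{s.strand}\n")
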