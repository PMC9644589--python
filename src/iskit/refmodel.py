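"""Reference data model: genome sequences, gene models, and the strand-aware
feature interval index used to classify integration sites.

Coordinates are 1-based inclusive throughout (GTF convention); BED output
converts to 0-based half-open at the boundary.

Feature classes are mutually exclusive with precedence
``promoter > utr > exon > intron > intergenic``. The promoter window is
2 kb upstream plus 500 bp downstream of the TSS by default, so its downstream
arm overlaps the 5'UTR/first exon; the precedence rule resolves that overlap
in favour of the regulatory class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from intervaltree import IntervalTree

FEATURE_CLASSES = ("promoter", "utr", "exon", "intron", "intergenic")

# precedence rank, lower wins
_CLASS_RANK = {"promoter": 0, "utr": 1, "exon": 2, "intron": 3}

_DNA_OK = set("ACGTN")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


class GeneModelError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass
class Genome:
    """In-memory reference genome: chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _DNA_OK
            if bad:
                raise ValueError(f"chromosome {name}: non-DNA characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence, 1-based inclusive coordinates, clipped to the chromosome."""
        seq = self.sequences[chrom]
        return seq[max(start, 1) - 1 : min(end, len(seq))]

    def as_array(self, chrom: str) -> np.ndarray:
        """Chromosome as a uint8 byte array (cached) for fast Hamming slices."""
        cache = getattr(self, "_arr_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_arr_cache", cache)
        if chrom not in cache:
            cache[chrom] = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)
        return cache[chrom]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pysam

        seqs: dict[str, str] = {}
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                seqs[rec.name] = rec.sequence.upper()
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as out:
            for name, seq in self.sequences.items():
                out.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")


@dataclass
class GeneModel:
    """Single-isoform gene structure.

    ``tss`` coincides with ``span[0]`` on the + strand and ``span[1]`` on −.
    UTR intervals must be contained in the exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]

    def validate(self) -> None:
        gid = self.gene_id
        if self.strand not in "+-":
            raise GeneModelError(f"{gid}: strand must be + or -")
        s, e = self.span
        if s > e:
            raise GeneModelError(f"{gid}: span start > end")
        prev_end = 0
        for a, b in self.exons:
            if a > b:
                raise GeneModelError(f"{gid}: exon end < exon start ({a}-{b})")
            if a < s or b > e:
                raise GeneModelError(f"{gid}: exon {a}-{b} outside gene span {s}-{e}")
            if a <= prev_end:
                raise GeneModelError(f"{gid}: exons overlap or are unsorted at {a}-{b}")
            prev_end = b
        exon_cover = _interval_union(self.exons)
        for label, utrs in (("utr5", self.utr5), ("utr3", self.utr3)):
            for a, b in utrs:
                if a > b:
                    raise GeneModelError(f"{gid}: {label} end < start ({a}-{b})")
                if not _contained_in(a, b, exon_cover):
                    raise GeneModelError(f"{gid}: {label} {a}-{b} not within exon union")

    @property
    def utr(self) -> list[tuple[int, int]]:
        """All UTR intervals (5' and 3' combined, as reported)."""
        return sorted(self.utr5 + self.utr3)

    def introns(self) -> list[tuple[int, int]]:
        return subtract_intervals([self.span], _interval_union(self.exons))

    def dist_to_tss(self, pos: int) -> int:
        """Strand-oriented distance; negative values are upstream of the TSS."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass
class AnnotationParams:
    """Windows controlling promoter definition and TSS-relative profiling.

    promoter_up/promoter_down: bp upstream/downstream of the TSS in the
    promoter window (defaults 2000/500). tss_window/tss_bin: half-width and
    bin size of the TSS-relative profile.
    """

    promoter_up: int = 2000
    promoter_down: int = 500
    tss_window: int = 3000
    tss_bin: int = 50

    def __post_init__(self) -> None:
        if min(self.promoter_up, self.promoter_down, self.tss_window, self.tss_bin) <= 0:
            raise ValueError("annotation window parameters must be positive")


def promoter_interval(model: GeneModel, params: AnnotationParams) -> tuple[int, int]:
    """Promoter window around the TSS, strand-aware, clipped at position 1."""
    if model.strand == "+":
        lo = model.tss - params.promoter_up
        hi = model.tss + params.promoter_down - 1
    else:
        lo = model.tss - params.promoter_down + 1
        hi = model.tss + params.promoter_up
    return max(lo, 1), hi


# ---------------------------------------------------------------------------
# interval helpers (1-based inclusive tuples)

def _interval_union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def subtract_intervals(
    base: Iterable[tuple[int, int]], minus: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference base \\ minus over 1-based inclusive intervals."""
    minus = _interval_union(minus)
    out: list[tuple[int, int]] = []
    for a, b in _interval_union(base):
        cur = a
        for ma, mb in minus:
            if mb < cur or ma > b:
                continue
            if ma > cur:
                out.append((cur, ma - 1))
            cur = max(cur, mb + 1)
            if cur > b:
                break
        if cur <= b:
            out.append((cur, b))
    return out


def _contained_in(a: int, b: int, union: list[tuple[int, int]]) -> bool:
    return any(ua <= a and b <= ub for ua, ub in union)


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

# feature keys accepted for UTR records
_UTR_FEATURES = {
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
    "5UTR": "utr5",
    "3UTR": "utr3",
}


def load_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Read single-isoform gene models from a GTF file.

    Expects ``gene``, ``exon`` and optionally UTR records, one isoform per
    gene_id. Raises :class:`GtfParseError` naming the line number on a
    malformed line and :class:`GeneModelError` naming the gene on an
    invariant violation.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}")
            m = dict(_ATTR_RE.findall(attrs))
            gid = m.get("gene_id")
            if gid is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            rec = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "span": None, "exons": [], "utr5": [], "utr3": []}
            )
            if gid not in order:
                order.append(gid)
            if feature == "gene":
                rec["span"] = (start, end)
                rec["chrom"], rec["strand"] = chrom, strand
            elif feature == "exon":
                rec["exons"].append((start, end))
            elif feature in _UTR_FEATURES:
                rec[_UTR_FEATURES[feature]].append((start, end))
            # other feature kinds (CDS, transcript, ...) are ignored
    models = []
    for gid in order:
        rec = genes[gid]
        span = rec["span"]
        exons = sorted(rec["exons"])
        if span is None:
            if not exons:
                raise GeneModelError(f"{gid}: no gene or exon records")
            span = (exons[0][0], exons[-1][1])
        model = GeneModel(
            gene_id=gid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            span=span,
            exons=exons,
            utr5=sorted(rec["utr5"]),
            utr3=sorted(rec["utr3"]),
        )
        model.validate()
        models.append(model)
    return models


def write_gtf(models: list[GeneModel], path: str | Path, source: str = "iskit") -> None:
    with open(path, "w") as out:
        for m in models:
            def row(feature: str, a: int, b: int) -> str:
                return (
                    f"{m.chrom}\t{source}\t{feature}\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f'gene_id "{m.gene_id}";\n'
                )

            out.write(row("gene", *m.span))
            for a, b in m.exons:
                out.write(row("exon", a, b))
            for a, b in m.utr5:
                out.write(row("five_prime_utr", a, b))
            for a, b in m.utr3:
                out.write(row("three_prime_utr", a, b))


# ---------------------------------------------------------------------------
# feature index

@dataclass
class FeatureIndex:
    """Strand-aware interval index over all genes' feature intervals.

    ``classify`` returns one mutually exclusive class per position by the
    precedence rule; gene attribution ties are broken by smallest
    ``|dist_to_tss|`` then lexicographic gene_id.
    """

    models: list[GeneModel]
    params: AnnotationParams
    known_chroms: Optional[set[str]] = None
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _by_id: dict[str, GeneModel] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for m in self.models:
            m.validate()
            if m.gene_id in self._by_id:
                raise GeneModelError(f"duplicate gene_id {m.gene_id}")
            self._by_id[m.gene_id] = m
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            pa, pb = promoter_interval(m, self.params)
            self._add(tree, pa, pb, "promoter", m)
            utr_union = _interval_union(m.utr)
            for a, b in utr_union:
                self._add(tree, a, b, "utr", m)
            for a, b in subtract_intervals(m.exons, utr_union):
                self._add(tree, a, b, "exon", m)
            for a, b in m.introns():
                self._add(tree, a, b, "intron", m)
        self.chromosomes = set(self._trees)

    @staticmethod
    def _add(tree: IntervalTree, a: int, b: int, cls: str, m: GeneModel) -> None:
        # intervaltree is half-open; store [a, b] as [a, b+1)
        tree.addi(a, b + 1, (cls, m))

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def classify(self, chrom: str, pos: int) -> tuple[str, Optional[str], Optional[int]]:
        """Classify a 1-based position.

        Returns ``(feature_class, gene_id, dist_to_tss)``; intergenic
        positions return ``("intergenic", None, None)``. Unknown chromosomes
        are an error only if the index has never seen them; chromosomes with
        no genes are legal and entirely intergenic.
        """
        if self.known_chroms is not None and chrom not in self.known_chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic", None, None
        hits = tree[pos]
        if not hits:
            return "intergenic", None, None
        best = min(
            hits,
            key=lambda iv: (
                _CLASS_RANK[iv.data[0]],
                abs(iv.data[1].dist_to_tss(pos)),
                iv.data[1].gene_id,
            ),
        )
        cls, model = best.data
        return cls, model.gene_id, model.dist_to_tss(pos)

    def feature_intervals(self, gene_id: str, feature_class: str) -> list[tuple[int, int]]:
        """Precedence-resolved intervals of one class for one gene.

        These are the gene's own intervals of that class minus any
        higher-precedence interval of *any* gene overlapping them, so that a
        position is counted for a gene/class pair iff ``classify`` could
        assign that class there.
        """
        m = self._by_id[gene_id]
        if feature_class == "promoter":
            base = [promoter_interval(m, self.params)]
        elif feature_class == "utr":
            base = _interval_union(m.utr)
        elif feature_class == "exon":
            base = subtract_intervals(m.exons, _interval_union(m.utr))
        elif feature_class == "intron":
            base = m.introns()
        else:
            raise ValueError(f"unknown feature class {feature_class!r}")
        rank = _CLASS_RANK[feature_class]
        higher: list[tuple[int, int]] = []
        tree = self._trees[m.chrom]
        for a, b in base:
            for iv in tree.overlap(a, b + 1):
                if _CLASS_RANK[iv.data[0]] < rank:
                    higher.append((iv.begin, iv.end - 1))
        return subtract_intervals(base, higher)


def build_feature_index(
    models: list[GeneModel],
    params: AnnotationParams | None = None,
    chromosomes: Iterable[str] | None = None,
) -> FeatureIndex:
    """Build the annotation index; see :class:`FeatureIndex`.

    ``chromosomes`` fixes the chromosome namespace (typically the genome's);
    when given, classifying a position on any other chromosome is an error,
    and listed chromosomes without genes are entirely intergenic.
    """
    genic = {m.chrom for m in models}
    known = set(chromosomes) | genic if chromosomes is not None else None
    return FeatureIndex(models=models, params=params or AnnotationParams(), known_chroms=known)


def classify_position(index: FeatureIndex, chrom: str, pos: int):
    return index.classify(chrom, pos)


def write_feature_bed(index: FeatureIndex, path: str | Path) -> None:
    """Export precedence-resolved feature intervals as BED6 (0-based half-open)."""
    rows = []
    for m in index.models:
        for cls in ("promoter", "utr", "exon", "intron"):
            for a, b in index.feature_intervals(m.gene_id, cls):
                rows.append((m.chrom, a - 1, b, f"{m.gene_id}:{cls}", 0, m.strand))
    rows.sort()
    with open(path, "w") as out:
        for r in rows:
            out.write("\t".join(map(str, r)) + "\n")
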