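"""Synthetic junction-library generator with planted ground truth.

Emulates an adaptor-ligated hDNA–vDNA fragment library: each planted provirus
contributes chimeric fragments of the form

    LTR tail | genomic flank (from the junction base, away from the provirus) | linker

sheared to lengths uniform in [frag_min, frag_max] bp (the size range such
kits yield), sequenced as read pairs: R1 starts at the LTR end, R2 at the
linker (shear) end. Per-base substitution errors and exact PCR re-emissions
(duplicates share junction and shear end) are added on top. Feature-class
propensities of the planted sites are configurable; the ``lenti`` and
``retro`` presets encode the insertion-preference profiles reported for
lentiviral and γ-retroviral vectors (lentiviral: intron/intergenic-heavy;
γ-retroviral: promoter/exon-shifted).

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .refmodel import (
    AnnotationParams,
    FeatureIndex,
    GeneModel,
    Genome,
    build_feature_index,
    promoter_interval,
)

# feature-insertion propensities by vector class (fractions of sites)
PRESETS: dict[str, dict[str, float]] = {
    "lenti": {"intron": 0.33, "exon": 0.13, "promoter": 0.04, "utr": 0.04, "intergenic": 0.46},
    "retro": {"intron": 0.23, "exon": 0.21, "promoter": 0.14, "utr": 0.07, "intergenic": 0.35},
}

# synthetic 34-mer standing in for the terminal LTR bases next to the junction
DEFAULT_LTR_TAIL = "AGTCCTGCGTCGGAGAACTCCTAGTATTAAGCCA"
# synthetic linker adaptor ligated at the shear end
DEFAULT_LINKER = "GACCAGCTTACGGTACTTCGAGATCT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator. See module docstring."""

    seed: int = 0
    n_chrom: int = 3
    chrom_len: int = 300_000
    n_genes: int = 60
    gene_density_weights: tuple[float, ...] = (0.5, 0.25, 0.25)
    vector_preset: str = "retro"
    feature_proportions: Optional[dict[str, float]] = None
    n_sites: int = 2000
    reads_per_site: float = 50.0
    fixed_reads_per_site: bool = False  # replace the Poisson by its mean exactly
    error_rate: float = 0.005
    dup_rate: float = 0.1
    frag_min: int = 100
    frag_max: int = 2000
    ltr_tail: str = DEFAULT_LTR_TAIL
    linker: str = DEFAULT_LINKER
    read_len: int = 150
    annotation: AnnotationParams = field(default_factory=AnnotationParams)

    def __post_init__(self) -> None:
        if self.feature_proportions is None:
            if self.vector_preset not in PRESETS:
                raise ValueError(
                    f"vector_preset {self.vector_preset!r} unknown and no feature_proportions given"
                )
            self.feature_proportions = dict(PRESETS[self.vector_preset])
        total = sum(self.feature_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"feature_proportions sum to {total}, expected 1")
        if not 0 < self.frag_min < self.frag_max:
            raise ValueError("need 0 < frag_min < frag_max")
        if len(self.gene_density_weights) != self.n_chrom:
            raise ValueError("gene_density_weights length must equal n_chrom")
        if not 0 <= self.error_rate < 1 or not 0 <= self.dup_rate < 1:
            raise ValueError("error_rate and dup_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# reference simulation

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def simulate_reference(config: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Simulate a genome and non-overlapping single-isoform gene models.

    Gene counts per chromosome follow ``gene_density_weights``, so with the
    default weights the first chromosome is gene-dense relative to the others
    (the genome-wide analogue of a chr19-like chromosome). Each gene has 3–8
    exons with terminal 5'/3' UTR segments.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    sequences = {name: _random_dna(rng, config.chrom_len) for name in chrom_names}
    genome = Genome(sequences)

    weights = np.asarray(config.gene_density_weights, dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(config.n_genes, weights)

    models: list[GeneModel] = []
    gene_serial = 0
    for chrom, n_genes in zip(chrom_names, counts):
        if n_genes == 0:
            continue
        structures = [_draw_gene_structure(rng) for _ in range(n_genes)]
        total = sum(s["length"] for s in structures)
        free = config.chrom_len - total
        if free < n_genes + 1:
            raise ValueError(
                "genome too small to place requested genes; increase chrom_len or reduce n_genes"
            )
        # spread the leftover length over the n_genes + 1 intergenic gaps
        gaps = rng.multinomial(free - (n_genes + 1), np.full(n_genes + 1, 1 / (n_genes + 1))) + 1
        cur = 1
        for structure, gap in zip(structures, gaps[:-1]):
            cur += int(gap)
            gene_serial += 1
            models.append(_materialize_gene(f"G{gene_serial:04d}", chrom, cur, structure, rng))
            cur += structure["length"]
    models.sort(key=lambda m: (m.chrom, m.span[0]))
    return genome, models


def _draw_gene_structure(rng: np.random.Generator) -> dict:
    n_exons = int(rng.integers(3, 9))
    exon_lens = rng.integers(80, 401, size=n_exons)
    intron_lens = rng.integers(200, 2001, size=n_exons - 1)
    return {
        "n_exons": n_exons,
        "exon_lens": exon_lens,
        "intron_lens": intron_lens,
        "length": int(exon_lens.sum() + intron_lens.sum()),
    }


def _materialize_gene(gene_id: str, chrom: str, start: int, structure: dict, rng: np.random.Generator) -> GeneModel:
    exons: list[tuple[int, int]] = []
    cur = start
    for i in range(structure["n_exons"]):
        a = cur
        b = a + int(structure["exon_lens"][i]) - 1
        exons.append((a, b))
        cur = b + 1
        if i < structure["n_exons"] - 1:
            cur += int(structure["intron_lens"][i])
    span = (start, exons[-1][1])
    strand = "+" if rng.random() < 0.5 else "-"
    first, last = exons[0], exons[-1]
    len_first = int(rng.integers(30, min(151, first[1] - first[0] + 1)))
    len_last = int(rng.integers(30, min(151, last[1] - last[0] + 1)))
    if strand == "+":
        utr5 = [(first[0], first[0] + len_first - 1)]
        utr3 = [(last[1] - len_last + 1, last[1])]
    else:
        utr5 = [(last[1] - len_last + 1, last[1])]
        utr3 = [(first[0], first[0] + len_first - 1)]
    m = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, span=span, exons=exons, utr5=utr5, utr3=utr3)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# site planting

_CLASS_CODE = {"intergenic": 0, "intron": 1, "exon": 2, "utr": 3, "promoter": 4}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}


def class_label_arrays(genome: Genome, models: list[GeneModel], params: AnnotationParams) -> dict[str, np.ndarray]:
    """Per-chromosome position→class arrays under the precedence rule.

    Index ``i`` (0-based) holds the class of 1-based position ``i+1``. Built
    by painting intron, then exon, then UTR per gene, then all promoter
    windows, which reproduces promoter > utr > exon > intron > intergenic.
    """
    labels = {c: np.zeros(n, dtype=np.uint8) for c, n in genome.lengths.items()}
    for m in models:
        arr = labels[m.chrom]
        s, e = m.span
        arr[s - 1 : e] = _CLASS_CODE["intron"]
        for a, b in m.exons:
            arr[a - 1 : b] = _CLASS_CODE["exon"]
        for a, b in m.utr:
            arr[a - 1 : b] = _CLASS_CODE["utr"]
    for m in models:
        arr = labels[m.chrom]
        a, b = promoter_interval(m, params)
        arr[a - 1 : min(b, len(arr))] = _CLASS_CODE["promoter"]
    return labels


def plant_sites(config: SimConfig, genome: Genome, index: FeatureIndex) -> pd.DataFrame:
    """Plant integration sites with class propensities ``feature_proportions``.

    Each site's class is a multinomial draw; its position is then uniform over
    all genomic positions of that class, strand uniform. Returns the truth
    table (site_id, chrom, pos, strand, planted_feature_class, gene_id,
    n_fragments_emitted); fragment counts are filled by ``simulate_reads``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    labels = class_label_arrays(genome, index.models, index.params)
    chroms = list(labels)
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls, code in _CLASS_CODE.items():
        pos_per_chrom = [np.flatnonzero(labels[c] == code) + 1 for c in chroms]
        chrom_idx = np.concatenate(
            [np.full(len(p), i, dtype=np.int32) for i, p in enumerate(pos_per_chrom)]
        ) if pos_per_chrom else np.array([], dtype=np.int32)
        pools[cls] = (chrom_idx, np.concatenate(pos_per_chrom) if pos_per_chrom else np.array([], dtype=int))

    classes = list(config.feature_proportions)
    probs = np.array([config.feature_proportions[c] for c in classes])
    counts = rng.multinomial(config.n_sites, probs)
    rows = []
    serial = 0
    for cls, n in zip(classes, counts):
        if n == 0:
            continue
        chrom_idx, positions = pools[cls]
        if len(positions) == 0:
            raise ValueError(f"no genomic positions available for class {cls!r}")
        pick = rng.integers(0, len(positions), size=n)
        for j in pick:
            serial += 1
            chrom = chroms[chrom_idx[j]]
            pos = int(positions[j])
            strand = "+" if rng.random() < 0.5 else "-"
            _, gene_id, _ = index.classify(chrom, pos)
            rows.append((f"site{serial:05d}", chrom, pos, strand, cls, gene_id, 0))
    truth = pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "strand", "planted_feature_class", "gene_id", "n_fragments_emitted"]
    )
    return truth.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# read simulation

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_reads(
    genome: Genome, truth: pd.DataFrame, config: SimConfig
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, pd.DataFrame]:
    """Emit read pairs for every planted site.

    Returns ``(pairs, truth, fragments)``: ``pairs`` is a shuffled list of
    ``(read_name, r1_seq, r2_seq)``; the truth table's
    ``n_fragments_emitted`` column counts distinct shear ends per site;
    ``fragments`` records every emitted fragment (site_id, chrom, pos,
    strand, shear_end, frag_len, n_copies). Fragment counts per site are
    Poisson(``reads_per_site``) (or exactly ``reads_per_site`` in fixed
    mode); a ``dup_rate`` fraction of fragments is emitted twice (PCR
    duplicates). Read names carry a bare serial and encode nothing about the
    truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pairs: list[tuple[str, str, str]] = []
    frag_rows = []
    n_frag_distinct = np.zeros(len(truth), dtype=int)
    serial = 0
    for i, site in enumerate(truth.itertuples(index=False)):
        if config.fixed_reads_per_site:
            n_frags = int(round(config.reads_per_site))
        else:
            n_frags = int(rng.poisson(config.reads_per_site))
        chrom_len = genome.lengths[site.chrom]
        shear_ends = set()
        for _ in range(n_frags):
            frag_len = int(rng.integers(config.frag_min, config.frag_max + 1))
            if site.strand == "+":
                end = min(site.pos + frag_len - 1, chrom_len)
                flank = genome.fetch(site.chrom, site.pos, end)
                shear = end
            else:
                start = max(site.pos - frag_len + 1, 1)
                flank = revcomp(genome.fetch(site.chrom, start, site.pos))
                shear = start
            shear_ends.add(shear)
            molecule = config.ltr_tail + flank + config.linker
            r1 = molecule[: config.read_len]
            r2 = revcomp(molecule)[: config.read_len]
            n_copies = 2 if rng.random() < config.dup_rate else 1
            frag_rows.append((site.site_id, site.chrom, site.pos, site.strand, shear, len(flank), n_copies))
            for _copy in range(n_copies):
                serial += 1
                pairs.append(
                    (
                        f"frag{serial:07d}",
                        _add_errors(r1, rng, config.error_rate),
                        _add_errors(r2, rng, config.error_rate),
                    )
                )
        n_frag_distinct[i] = len(shear_ends)
    truth = truth.copy()
    truth["n_fragments_emitted"] = n_frag_distinct
    fragments = pd.DataFrame(
        frag_rows, columns=["site_id", "chrom", "pos", "strand", "shear_end", "frag_len", "n_copies"]
    )
    order = rng.permutation(len(pairs))
    pairs = [pairs[k] for k in order]
    return pairs, truth, fragments


def write_fastq_pair(pairs: list[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")


# ---------------------------------------------------------------------------
# one-call sample simulation

@dataclass
class SimulatedSample:
    sample_id: str
    config: SimConfig
    genome: Genome
    models: list[GeneModel]
    index: FeatureIndex
    truth: pd.DataFrame
    pairs: list[tuple[str, str, str]]
    fragments: pd.DataFrame


def simulate_sample(
    config: SimConfig,
    sample_id: str = "S01",
    genome: Genome | None = None,
    models: list[GeneModel] | None = None,
) -> SimulatedSample:
    """Simulate one junction library end to end (reference optionally shared)."""
    if genome is None or models is None:
        genome, models = simulate_reference(config)
    index = build_feature_index(models, config.annotation, chromosomes=genome.lengths)
    truth = plant_sites(config, genome, index)
    pairs, truth, fragments = simulate_reads(genome, truth, config)
    return SimulatedSample(sample_id, config, genome, models, index, truth, pairs, fragments)


def write_truth(truth: pd.DataFrame, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    truth.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as out:
            for r in truth.itertuples(index=False):
                out.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.site_id}\t{r.n_fragments_emitted}\t{r.strand}\n")


def cohort_configs(
    base: SimConfig, n_lenti: int, n_retro: int
) -> list[tuple[str, str, SimConfig]]:
    """Per-sample configs for a mixed cohort sharing one reference seed.

    Returns (sample_id, vector_class, config) with per-sample site seeds
    derived from the base seed; the reference itself is simulated once from
    ``base`` and shared.
    """
    out = []
    for i in range(n_lenti + n_retro):
        preset = "lenti" if i < n_lenti else "retro"
        sid = f"{'L' if preset == 'lenti' else 'R'}{(i if preset == 'lenti' else i - n_lenti) + 1:02d}"
        cfg = replace(base, vector_preset=preset, feature_proportions=None, seed=base.seed + 101 + i)
        out.append((sid, "lentiviral" if preset == "lenti" else "retroviral", cfg))
    return out
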