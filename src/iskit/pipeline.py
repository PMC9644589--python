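"""End-to-end junction-library processing: raw read pairs → called sites.

This is the driver layer the analysis scripts and acceptance checks use; the
individual steps live in :mod:`junctionproc` and :mod:`iscall`.

Shear-end localization: R2 starts at the sheared fragment end with the
reverse-complemented linker in front; the linker is trimmed off and a prefix
of the remaining genomic sequence is aligned, placing the shear base so PCR
duplicates (same junction *and* shear end) collapse in fragment counts. When
the mate cannot be placed, the far end of the R1 alignment is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .iscall import GenomeAligner, IntegrationSite, call_sites, junction_position
from .junctionproc import match_ltr, trim_pairs
from .refmodel import Genome
from .simjunction import SimConfig, SimulatedSample, revcomp


@dataclass
class PipelineResult:
    sample_id: str
    sites: list[IntegrationSite]
    trim_report: pd.DataFrame
    n_aligned: int
    n_unaligned: int

    @property
    def sites_frame(self) -> pd.DataFrame:
        from .iscall import sites_to_frame

        return sites_to_frame(self.sites)


def _mate_shear_end(
    mate_seq: Optional[str],
    aligner: GenomeAligner,
    linker: str,
    chrom: str,
    max_len: int = 80,
    min_identity: float = 0.9,
) -> Optional[int]:
    """Locate the shear base from the untrimmed mate, or None."""
    if not mate_seq:
        return None
    rc_linker = revcomp(linker)
    m = match_ltr(mate_seq, rc_linker, min_match=min(15, len(rc_linker)), max_mismatch=max(2, len(rc_linker) // 10))
    if m is None:
        return None
    genomic = mate_seq[m.end_offset : m.end_offset + max_len]
    aln = aligner.align(genomic, min_identity=min_identity)
    if aln is None or aln.chrom != chrom:
        return None
    pos, _ = junction_position(aln)  # end nearest the linker = shear base
    return pos


def run_sample(
    pairs: list[tuple[str, str, str]],
    genome: Genome,
    config: SimConfig,
    sample_id: str = "S01",
    aligner: GenomeAligner | None = None,
    tol: int = 5,
) -> PipelineResult:
    """Process in-memory read pairs ``(name, r1_seq, r2_seq)`` into sites."""
    if aligner is None:
        aligner = GenomeAligner(genome)
    quals = "I"
    raw = ((name, r1, quals * len(r1), r2, quals * len(r2)) for name, r1, r2 in pairs)
    accepted, report = trim_pairs(raw, config.ltr_tail, config.linker, sample_id=sample_id)
    junctions = []
    n_unaligned = 0
    for jr in accepted:
        aln = aligner.align(jr.genomic_seq, read_id=jr.read_id)
        if aln is None:
            n_unaligned += 1
            continue
        pos, strand = junction_position(aln)
        shear = _mate_shear_end(jr.mate_seq, aligner, config.linker, aln.chrom)
        if shear is None:
            shear = aln.end if aln.strand == "+" else aln.start  # R1 far end fallback
        junctions.append((aln.chrom, pos, strand, shear, jr.read_id))
    sites = call_sites(junctions, tol=tol, sample_id=sample_id)
    return PipelineResult(sample_id, sites, report, n_aligned=len(junctions), n_unaligned=n_unaligned)


def run_simulated_sample(sim: SimulatedSample, aligner: GenomeAligner | None = None, tol: int = 5) -> PipelineResult:
    return run_sample(sim.pairs, sim.genome, sim.config, sample_id=sim.sample_id, aligner=aligner, tol=tol)


def match_sites_to_truth(
    sites: list[IntegrationSite], truth: pd.DataFrame, tol: int = 5
) -> dict[str, float]:
    """Recall/precision of called sites against the planted truth at ± ``tol`` bp.

    Recall: fraction of truth sites with a called site within ``tol`` on the
    same chromosome and strand. Precision: fraction of called sites within
    ``tol`` of some truth site.
    """
    called_by_key: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        called_by_key.setdefault((s.chrom, s.strand), []).append(s.pos)
    truth_by_key: dict[tuple[str, str], list[int]] = {}
    for r in truth.itertuples(index=False):
        truth_by_key.setdefault((r.chrom, r.strand), []).append(r.pos)

    def near(pos: int, pool: list[int]) -> bool:
        return any(abs(pos - p) <= tol for p in pool)

    n_truth = len(truth)
    n_called = len(sites)
    hits_truth = sum(
        near(p, called_by_key.get(k, [])) for k, pool in truth_by_key.items() for p in pool
    )
    hits_called = sum(
        near(s.pos, truth_by_key.get((s.chrom, s.strand), [])) for s in sites
    )
    return {
        "n_truth": n_truth,
        "n_called": n_called,
        "recall": hits_truth / n_truth if n_truth else float("nan"),
        "precision": hits_called / n_called if n_called else float("nan"),
    }
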