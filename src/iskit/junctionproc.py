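"""Junction-read trimming: strip the LTR tail and linker adaptor from raw
read pairs, leaving the genomic portion used for integration-site mapping.

The library chemistry anchors the LTR tail at the start of R1, so LTR
detection is an anchored Hamming comparison rather than a local alignment.
Reads failing LTR detection, minimum genomic length, or mean base quality
are rejected with a reason; rejections are data, not errors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd


@dataclass
class LTRMatch:
    matched_len: int
    mismatches: int
    end_offset: int  # 0-based position in the read where genomic sequence begins


@dataclass
class JunctionRead:
    read_id: str
    genomic_seq: str
    mate_seq: Optional[str]
    sample_id: str
    ltr: Optional[LTRMatch]
    reject_reason: Optional[str] = None  # no_ltr | too_short | low_quality

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_ltr(read_seq: str, ltr_tail: str, min_match: int = 15, max_mismatch: int = 2) -> Optional[LTRMatch]:
    """Anchored comparison of the read start against the LTR tail.

    The aligned length is ``min(len(read), len(ltr_tail))``; returns None if
    that is below ``min_match`` or the Hamming distance exceeds
    ``max_mismatch``.
    """
    if len(ltr_tail) < min_match:
        raise ValueError("ltr_tail shorter than min_match")
    n = min(len(read_seq), len(ltr_tail))
    if n < min_match:
        return None
    mm = _hamming(read_seq[:n], ltr_tail[:n])
    if mm > max_mismatch:
        return None
    return LTRMatch(matched_len=n, mismatches=mm, end_offset=n)


def find_linker(seq: str, linker: str, min_overlap: int = 1) -> Optional[int]:
    """First start position of the linker in ``seq`` (0-based), or None.

    Tolerates one mismatch per 10 nt of overlap; partial linker occurrences
    truncated by the read end are matched down to ``min_overlap`` nt
    (mismatch-free below 10 nt), so no linker residue survives trimming.
    """
    if not linker or len(seq) < min_overlap:
        return None
    hit = seq.find(linker)  # exact fast path
    full_positions = len(seq) - len(linker) + 1
    if full_positions > 0:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        lk = np.frombuffer(linker.encode("ascii"), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(linker))
        mm = (windows != lk).sum(axis=1)
        approx = np.flatnonzero(mm <= len(linker) // 10)
        if len(approx):
            hit = int(approx[0]) if hit < 0 else min(hit, int(approx[0]))
    if hit >= 0:
        return hit
    # partial occurrence truncated by the read end
    for i in range(max(full_positions, 0), len(seq) - min_overlap + 1):
        ov = len(seq) - i
        if _hamming(seq[i:], linker[:ov]) <= ov // 10:
            return i
    return None


def _mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.mean(np.frombuffer(qual.encode("ascii"), dtype=np.uint8))) - 33.0


def trim_junction(
    pair: tuple[str, str, str, Optional[str], Optional[str]],
    ltr_tail: str,
    linker: str,
    min_genomic_len: int = 20,
    min_match: int = 15,
    max_mismatch: int = 2,
    min_mean_q: float = 20.0,
    sample_id: str = "",
) -> JunctionRead:
    """Trim one read pair ``(read_id, r1_seq, r1_qual, r2_seq, r2_qual)``.

    On LTR match the genomic portion is everything beyond the tail, truncated
    at the first linker occurrence. The mate is retained untrimmed for
    shear-end localization downstream.
    """
    read_id, r1_seq, r1_qual, r2_seq, _r2_qual = pair
    ltr = match_ltr(r1_seq, ltr_tail, min_match=min_match, max_mismatch=max_mismatch)
    if ltr is None:
        return JunctionRead(read_id, "", r2_seq, sample_id, None, "no_ltr")
    genomic = r1_seq[ltr.end_offset :]
    gqual = r1_qual[ltr.end_offset :] if r1_qual else ""
    cut = find_linker(genomic, linker)
    if cut is not None:
        genomic, gqual = genomic[:cut], gqual[:cut]
    if len(genomic) < min_genomic_len:
        return JunctionRead(read_id, genomic, r2_seq, sample_id, ltr, "too_short")
    if gqual and _mean_quality(gqual) < min_mean_q:
        return JunctionRead(read_id, genomic, r2_seq, sample_id, ltr, "low_quality")
    return JunctionRead(read_id, genomic, r2_seq, sample_id, ltr, None)


def iter_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (read_id, r1_seq, r1_qual, r2_seq, r2_qual) from paired FASTQ."""
    import pysam

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            name = rec1.name.removesuffix("/1")
            yield name, rec1.sequence, rec1.quality or "", rec2.sequence, rec2.quality or ""


def trim_pairs(
    pairs: Iterable[tuple[str, str, str, Optional[str], Optional[str]]],
    ltr_tail: str,
    linker: str,
    sample_id: str = "",
    **kwargs,
) -> tuple[list[JunctionRead], pd.DataFrame]:
    """Trim a stream of pairs; returns accepted reads and a report of counts
    by outcome (accepted / no_ltr / too_short / low_quality)."""
    accepted: list[JunctionRead] = []
    tally: Counter[str] = Counter()
    for pair in pairs:
        jr = trim_junction(pair, ltr_tail, linker, sample_id=sample_id, **kwargs)
        tally[jr.reject_reason or "accepted"] += 1
        if jr.accepted:
            accepted.append(jr)
    report = pd.DataFrame(
        [(sample_id, k, tally.get(k, 0)) for k in ("accepted", "no_ltr", "too_short", "low_quality")],
        columns=["sample_id", "outcome", "n_reads"],
    )
    return accepted, report
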