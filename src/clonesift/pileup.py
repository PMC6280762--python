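"""Build the pileup matrix from pre-aligned read records.

Read-level rules applied in order: primer trimming, a mismatch cap counted
after trimming, and mate-overlap resolution keeping the higher-quality base
so a pair never contributes twice at one position.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    ALLELES,
    Amplicon,
    AmpliconPanel,
    InputError,
    PileupMatrix,
    SampleSheet,
)

logger = logging.getLogger(__name__)

MAX_MISMATCHES = 10


@dataclass(frozen=True)
class ReadRecord:
    """One aligned mate: bases with qualities over amplicon coordinates."""

    sample_id: str
    amplicon_id: str
    pair_id: str
    mate: str  # R1 | R2
    start: int  # genomic position of the first base
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise InputError(f"read {self.pair_id}/{self.mate}: bases/quals length mismatch")
        if any(not 0 <= q <= 60 for q in self.quals):
            raise InputError(f"read {self.pair_id}/{self.mate}: quality outside [0, 60]")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)

    def is_empty(self) -> bool:
        return len(self.bases) == 0


def trim_primers(read: ReadRecord, amplicon: Amplicon) -> ReadRecord:
    """Drop bases overlapping either primer-binding interval.

    A read entirely inside a primer trims to an empty record (the caller
    drops and logs it).
    """
    if read.start < amplicon.start or read.end > amplicon.end:
        raise InputError(
            f"read {read.pair_id}/{read.mate} maps outside amplicon "
            f"{amplicon.amplicon_id}"
        )
    lo = max(read.start, amplicon.callable_start)
    hi = min(read.end, amplicon.callable_end)
    if hi <= lo:
        return replace(read, start=amplicon.callable_start, bases="", quals=())
    i, j = lo - read.start, hi - read.start
    return replace(read, start=lo, bases=read.bases[i:j], quals=read.quals[i:j])


def count_mismatches(read: ReadRecord, amplicon: Amplicon) -> int:
    return sum(
        1
        for i, b in enumerate(read.bases)
        if b != amplicon.ref_base(read.start + i)
    )


def filter_read(
    read: ReadRecord, amplicon: Amplicon, max_mismatches: int = MAX_MISMATCHES
) -> bool:
    """Keep unless the read carries more than ``max_mismatches`` nonreference
    bases (counted on the trimmed span)."""
    return count_mismatches(read, amplicon) <= max_mismatches


def resolve_overlap(
    mate1: Optional[ReadRecord], mate2: Optional[ReadRecord]
) -> list[tuple[int, str, int]]:
    """Per-position (pos, base, qual) contributions of a read pair.

    Where the mates overlap, only the higher-quality base counts; on a
    quality tie R1 wins (deterministic, and R1 is typically the early-cycle,
    higher-quality mate).
    """
    out: dict[int, tuple[str, int, int]] = {}  # pos -> (base, qual, rank)
    for rank, read in enumerate(m for m in (mate1, mate2) if m is not None):
        is_r1 = read.mate == "R1"
        for i, b in enumerate(read.bases):
            pos = read.start + i
            q = read.quals[i]
            prev = out.get(pos)
            if prev is None:
                out[pos] = (b, q, 0 if is_r1 else 1)
            else:
                pb, pq, prank = prev
                if q > pq or (q == pq and is_r1 and prank == 1):
                    out[pos] = (b, q, 0 if is_r1 else 1)
    return [(pos, b, q) for pos, (b, q, _) in sorted(out.items())]


def build_pileup(
    reads: Iterable[ReadRecord],
    panel: AmpliconPanel,
    sheet: Optional[SampleSheet] = None,
    max_mismatches: int = MAX_MISMATCHES,
) -> PileupMatrix:
    """Trim, filter, overlap-resolve and tally reads into a pileup.

    Positions are restricted to callable intervals; depth at a position never
    exceeds the number of read pairs covering it.
    """
    pairs: dict[tuple[str, str, str], dict[str, ReadRecord]] = {}
    n_reads = 0
    for read in reads:
        n_reads += 1
        if read.amplicon_id not in panel:
            raise InputError(
                f"read {read.pair_id}/{read.mate}: unknown amplicon_id "
                f"{read.amplicon_id!r}"
            )
        key = (read.sample_id, read.amplicon_id, read.pair_id)
        pairs.setdefault(key, {})[read.mate] = read

    dropped_primer = 0
    dropped_mismatch = 0
    # counts[(sample, amp)][pos] -> [4 allele counts, qual_sum, n]
    counts: dict[tuple[str, str], dict[int, list]] = {}
    for (sample_id, amplicon_id, _pair), mates in pairs.items():
        amp = panel[amplicon_id]
        kept: dict[str, ReadRecord] = {}
        for mate_name, read in mates.items():
            trimmed = trim_primers(read, amp)
            if trimmed.is_empty():
                dropped_primer += 1
                continue
            if not filter_read(trimmed, amp, max_mismatches):
                dropped_mismatch += 1
                continue
            kept[mate_name] = trimmed
        if not kept:
            continue
        tally = counts.setdefault((sample_id, amplicon_id), {})
        for pos, base, qual in resolve_overlap(kept.get("R1"), kept.get("R2")):
            if base not in ALLELES:
                continue
            cell = tally.setdefault(pos, [0, 0, 0, 0, 0.0, 0])
            cell[ALLELES.index(base)] += 1
            cell[4] += qual
            cell[5] += 1

    if dropped_primer or dropped_mismatch:
        logger.info(
            "build_pileup: dropped %d primer-confined and %d high-mismatch "
            "reads of %d total",
            dropped_primer, dropped_mismatch, n_reads,
        )

    rows = []
    for (sample_id, amplicon_id), tally in sorted(counts.items()):
        amp = panel[amplicon_id]
        for pos in sorted(tally):
            a, c, g, t, qsum, nq = tally[pos]
            rows.append(
                {
                    "sample_id": sample_id,
                    "amplicon_id": amplicon_id,
                    "chrom": amp.chrom,
                    "pos": pos,
                    "ref": amp.ref_base(pos),
                    "A": a, "C": c, "G": g, "T": t,
                    "mean_bq": round(qsum / nq, 2) if nq else 0.0,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "amplicon_id", "chrom", "pos", "ref",
                 "A", "C", "G", "T", "mean_bq"],
    )
    return PileupMatrix(df)


def reads_from_df(df: pd.DataFrame) -> list[ReadRecord]:
    """Materialize ReadRecords from the reads TSV schema."""
    required = ["sample_id", "amplicon_id", "pair_id", "mate", "start", "bases", "quals"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"reads frame missing columns {missing}")
    out = []
    for r in df.itertuples(index=False):
        bases = "" if pd.isna(r.bases) else str(r.bases)
        quals_raw = "" if pd.isna(r.quals) else str(r.quals)
        quals = tuple(int(q) for q in quals_raw.split(",") if q != "")
        out.append(
            ReadRecord(
                sample_id=str(r.sample_id),
                amplicon_id=str(r.amplicon_id),
                pair_id=str(r.pair_id),
                mate=str(r.mate),
                start=int(r.start),
                bases=bases,
                quals=quals,
            )
        )
    return out
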