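"""FASTQ summary statistics and read filtering.

Reproduces the standard WGBS quality ledger: total reads/bases, Q20/Q30
base counts, GC and N content, and the retained high-quality fraction
after dropping reads that are N-rich (more than ``max_n_frac`` of bases)
or low quality (mean Phred at or below ``min_mean_phred``).  Adapter
trimming is left to dedicated external trimmers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import percent


@dataclass
class ReadStats:
    n_reads: int = 0
    n_bases: int = 0
    q20_bases: int = 0
    q30_bases: int = 0
    gc_bases: int = 0
    n_bases_N: int = 0
    n_reads_kept: int = 0
    n_bases_kept: int = 0

    def __post_init__(self):
        if not (self.q30_bases <= self.q20_bases <= self.n_bases):
            raise ValueError("quality base counts out of order")
        if self.gc_bases + self.n_bases_N > self.n_bases:
            raise ValueError("GC + N exceeds total bases")
        if self.n_reads_kept > self.n_reads:
            raise ValueError("kept more reads than seen")

    # percentages on demand, 2 decimals, N bases in every denominator
    @property
    def q20_percent(self) -> float:
        return percent(self.q20_bases, self.n_bases)

    @property
    def q30_percent(self) -> float:
        return percent(self.q30_bases, self.n_bases)

    @property
    def gc_percent(self) -> float:
        return percent(self.gc_bases, self.n_bases)

    @property
    def n_percent(self) -> float:
        return percent(self.n_bases_N, self.n_bases)


def _iter_fastq(path: str | Path, phred_offset: int):
    if phred_offset not in (33, 64):
        raise ValueError("phred_offset must be 33 or 64")
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: sequence/quality length mismatch in @{title}")
            phred = np.frombuffer(qual.encode(), dtype=np.uint8).astype(
                np.int32) - phred_offset
            if len(phred) and (phred.min() < 0 or phred.max() > 93):
                raise ValueError(
                    f"{path}: quality out of range for offset {phred_offset} "
                    f"in @{title}")
            yield title, seq, qual, phred


def _tally(stats: ReadStats, seq: str, phred: np.ndarray) -> None:
    up = seq.upper()
    stats.n_reads += 1
    stats.n_bases += len(up)
    stats.q20_bases += int((phred >= 20).sum())
    stats.q30_bases += int((phred >= 30).sum())
    stats.gc_bases += up.count("G") + up.count("C")
    stats.n_bases_N += up.count("N")


def summarize_fastq(path: str | Path, phred_offset: int = 33) -> ReadStats:
    """Count reads, bases, Q20/Q30 bases, GC and N bases of a FASTQ file."""
    stats = ReadStats()
    for _, seq, _, phred in _iter_fastq(path, phred_offset):
        _tally(stats, seq, phred)
    return stats


def filter_reads(path_in: str | Path, path_out: str | Path,
                 max_n_frac: float = 0.10, min_mean_phred: float = 20,
                 phred_offset: int = 33) -> ReadStats:
    """Drop N-rich and low-quality reads, writing survivors unchanged.

    A read is discarded iff its N fraction exceeds ``max_n_frac`` or its
    mean Phred score is at or below ``min_mean_phred`` (the removal
    boundary is inclusive).  Returned stats describe the input file plus
    the kept totals, so retention percentages can be derived directly.
    """
    stats = ReadStats()
    with open(path_out, "w") as out:
        for title, seq, qual, phred in _iter_fastq(path_in, phred_offset):
            _tally(stats, seq, phred)
            n_frac = seq.upper().count("N") / len(seq) if seq else 0.0
            mean_q = float(phred.mean()) if len(phred) else 0.0
            if n_frac > max_n_frac or mean_q <= min_mean_phred:
                continue
            stats.n_reads_kept += 1
            stats.n_bases_kept += len(seq)
            out.write(f"@{title}\n{seq}\n+\n{qual}\n")
    return stats


def retention_percent(kept: int, total: int) -> float:
    """Retained share as a percentage, rounded half-up to 2 decimals."""
    if total == 0:
        raise ZeroDivisionError("retention with zero total is undefined")
    if not 0 <= kept <= total:
        raise ValueError("kept must lie in [0, total]")
    return percent(kept, total)
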