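"""Random-access genome sequence store.

Thin wrapper presenting one interface over either an in-memory dict of
chromosome strings (as the simulator produces) or an indexed FASTA file
opened with pyfaidx.  All coordinates are 1-based closed, matching the
cytosine reports and GFF3.
"""

from __future__ import annotations

from pathlib import Path

from pyfaidx import Fasta


class GenomeStore:
    def __init__(self, source: "str | Path | dict[str, str] | GenomeStore"):
        if isinstance(source, GenomeStore):
            self._seqs = source._seqs
            self._fasta = source._fasta
        elif isinstance(source, dict):
            self._seqs = {c: s.upper() for c, s in source.items()}
            self._fasta = None
        else:
            self._seqs = None
            self._fasta = Fasta(str(source), sequence_always_upper=True,
                                rebuild=False)

    @property
    def chroms(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.length(c) for c in self.chroms}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based closed interval [start, end], clamped to
        the contig; positions outside the contig are simply absent from the
        returned string."""
        start = max(1, start)
        end = min(self.length(chrom), end)
        if end < start:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1:end]
        return str(self._fasta[chrom][start - 1:end]).upper()

    def base(self, chrom: str, pos: int) -> str:
        seq = self.fetch(chrom, pos, pos)
        return seq if seq else "N"
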