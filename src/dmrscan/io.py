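"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 1-based closed internally; BED emission is the only
0-based half-open surface.  The cytosine report is a 6-column
tab-separated table (chrom, pos, strand, meth_count, unmeth_count,
context); a shim maps the 7-column Bismark CX report onto it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gffutils
import numpy as np
import pandas as pd

from .calls import ValidationError, contexts_for_positions
from .genome import GenomeStore

COMPONENT_KINDS = ("promoter", "five_prime_utr", "exon", "intron",
                   "three_prime_utr")

_REPORT_COLS = ["chrom", "pos", "strand", "meth_count", "unmeth_count",
                "context"]


class ParseError(ValueError):
    pass


class CytosineRecord(NamedTuple):
    """One strand-resolved cytosine with its methylation evidence."""
    chrom: str
    pos: int
    strand: str
    context: str
    meth_count: int
    unmeth_count: int

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


# ---------------------------------------------------------------------------
# cytosine reports

def read_cytosine_report(path: str | Path,
                         genome: GenomeStore | None = None,
                         recompute_context: bool = False) -> pd.DataFrame:
    """Read a 6-column cytosine report into a sorted table.

    With a genome and ``recompute_context`` the context column is
    overwritten from sequence; with a genome and ``recompute_context``
    False the two sources are cross-checked and any disagreement raises.
    """
    df = _read_report_columns(path, _REPORT_COLS)
    return _finish_report(df, genome, recompute_context, path)


def read_bismark_cx(path: str | Path,
                    genome: GenomeStore | None = None,
                    recompute_context: bool = False) -> pd.DataFrame:
    """Shim for Bismark's 7-column CX report (extra trailing trinucleotide
    column, context in column 6 as in our layout)."""
    cols = _REPORT_COLS + ["trinucleotide"]
    df = _read_report_columns(path, cols).drop(columns="trinucleotide")
    return _finish_report(df, genome, recompute_context, path)


def _read_report_columns(path, cols) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", names=cols, comment="#",
                         dtype={"chrom": str, "strand": str, "context": str},
                         header=None)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=cols)
    for col in ("pos", "meth_count", "unmeth_count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: malformed {col} at data line {line}")
        df[col] = numeric.astype(np.int64)
    if (df[["meth_count", "unmeth_count"]] < 0).any().any():
        raise ValidationError(f"{path}: negative read counts")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: strand must be + or -")
    return df


def _finish_report(df, genome, recompute_context, path) -> pd.DataFrame:
    if genome is not None and len(df):
        for chrom, sub in df.groupby("chrom", sort=False):
            ctx = contexts_for_positions(genome, chrom,
                                         sub["pos"].to_numpy(),
                                         sub["strand"].to_numpy())
            if recompute_context:
                df.loc[sub.index, "context"] = ctx
            else:
                bad = sub["context"].to_numpy() != ctx
                if bad.any():
                    i = sub.index[np.flatnonzero(bad)[0]]
                    raise ValidationError(
                        f"{path}: context mismatch at {chrom}:"
                        f"{df.at[i, 'pos']} (file {df.at[i, 'context']}, "
                        f"sequence {ctx[np.flatnonzero(bad)[0]]})")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate positions")
    return df.reset_index(drop=True)


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    df[_REPORT_COLS].to_csv(path, sep="\t", header=False, index=False)


def records_from_frame(df: pd.DataFrame) -> list[CytosineRecord]:
    return [CytosineRecord(*row) for row in
            df[_REPORT_COLS].itertuples(index=False, name=None)]


# ---------------------------------------------------------------------------
# methylome set

@dataclass
class MethylomeSet:
    """Aligned per-cytosine tables across samples with group labels."""
    samples: list[str]
    group_of: dict[str, str]
    tables: dict[str, pd.DataFrame]
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self):
        groups = set(self.group_of.values())
        for g in groups:
            if not any(self.group_of[s] == g for s in self.samples):
                raise ValidationError(f"group {g!r} has no samples")
        for s in self.samples:
            if s not in self.tables:
                raise ValidationError(f"no table for sample {s!r}")

    @property
    def groups(self) -> list[str]:
        seen = []
        for s in self.samples:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def pooled(self, group: str) -> pd.DataFrame:
        """Sum read counts across the replicates of one group, outer-joined
        on (chrom, pos, strand)."""
        frames = [self.tables[s] for s in self.samples_in(group)]
        cat = pd.concat(frames, ignore_index=True)
        agg = (cat.groupby(["chrom", "pos", "strand"], sort=True)
               .agg(meth_count=("meth_count", "sum"),
                    unmeth_count=("unmeth_count", "sum"),
                    context=("context", "first"))
               .reset_index())
        return agg

    @classmethod
    def from_files(cls, paths: dict[str, str | Path],
                   group_of: dict[str, str],
                   genome: GenomeStore | None = None,
                   recompute_context: bool = False) -> "MethylomeSet":
        tables = {s: read_cytosine_report(p, genome, recompute_context)
                  for s, p in paths.items()}
        sizes = genome.chrom_sizes() if genome is not None else None
        return cls(samples=list(paths), group_of=dict(group_of),
                   tables=tables, chrom_sizes=sizes)


# ---------------------------------------------------------------------------
# gene models

@dataclass(frozen=True)
class Component:
    kind: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneModel:
    """A gene with its ordered functional components in genome coordinates.

    The promoter spans ``promoter_bp`` bases immediately 5' of the TSS on
    the gene's strand (truncated at contig boundaries); introns are the
    gaps between consecutive exons of the representative transcript.
    """
    gene_id: str
    chrom: str
    strand: str
    tss: int
    components: tuple[Component, ...]

    @property
    def start(self) -> int:
        return min(c.start for c in self.components)

    @property
    def end(self) -> int:
        return max(c.end for c in self.components)

    def of_kind(self, kind: str) -> list[Component]:
        return [c for c in self.components if c.kind == kind]


def _promoter(strand: str, tss: int, promoter_bp: int,
              contig_len: int | None) -> Component | None:
    if strand == "+":
        start, end = tss - promoter_bp, tss - 1
    else:
        start, end = tss + 1, tss + promoter_bp
    start = max(1, start)
    if contig_len is not None:
        end = min(contig_len, end)
    if end < start:
        return None
    return Component("promoter", start, end)


def build_gene_model(gene_id: str, chrom: str, strand: str,
                     exons: Iterable[tuple[int, int]],
                     utr5: Iterable[tuple[int, int]] = (),
                     utr3: Iterable[tuple[int, int]] = (),
                     promoter_bp: int = 2000,
                     contig_len: int | None = None) -> GeneModel:
    """Assemble a GeneModel from exon (and optional UTR) intervals."""
    exons = sorted((int(a), int(b)) for a, b in exons)
    if not exons:
        raise ValidationError(f"gene {gene_id} has no exons")
    tss = exons[0][0] if strand == "+" else exons[-1][1]
    comps: list[Component] = []
    prom = _promoter(strand, tss, promoter_bp, contig_len)
    if prom is not None:
        comps.append(prom)
    comps += [Component("exon", a, b) for a, b in exons]
    for (a0, b0), (a1, b1) in zip(exons, exons[1:]):
        if a1 > b0 + 1:
            comps.append(Component("intron", b0 + 1, a1 - 1))
    comps += [Component("five_prime_utr", int(a), int(b)) for a, b in utr5]
    comps += [Component("three_prime_utr", int(a), int(b)) for a, b in utr3]
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                     components=tuple(comps))


_UTR5_TYPES = {"five_prime_utr", "5utr", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "3utr", "three_prime_UTR"}


def read_gene_models(path: str | Path, promoter_bp: int = 2000,
                     contig_sizes: dict[str, int] | None = None,
                     ) -> list[GeneModel]:
    """Parse gene models from GFF3/GTF.

    One representative transcript per gene — the longest by genomic span —
    defines the exon/intron/UTR structure.  Genes without exons are
    skipped with a warning; exons outside the gene's bounds raise.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="warning",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        transcripts = [t for t in db.children(gene, level=1)
                       if t.featuretype in ("mRNA", "transcript")]
        if transcripts:
            rep = max(transcripts, key=lambda t: (t.end - t.start, t.id))
            parent = rep
        else:
            parent = gene
        exons = [(e.start, e.end) for e in db.children(parent, featuretype="exon")]
        if not exons:
            warnings.warn(f"gene {gid} has no exons; skipped")
            continue
        if min(a for a, _ in exons) < gene.start or \
                max(b for _, b in exons) > gene.end:
            raise ValidationError(f"gene {gid}: exon outside gene bounds")
        utr5 = [(u.start, u.end) for u in db.children(parent)
                if u.featuretype in _UTR5_TYPES]
        utr3 = [(u.start, u.end) for u in db.children(parent)
                if u.featuretype in _UTR3_TYPES]
        clen = contig_sizes.get(gene.seqid) if contig_sizes else None
        models.append(build_gene_model(
            gid, gene.seqid, gene.strand, exons, utr5, utr3,
            promoter_bp=promoter_bp, contig_len=clen))
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


# ---------------------------------------------------------------------------
# DMR output

_DMR_TSV_COLS = ["id", "chrom", "start", "end", "direction",
                 "dominant_context", "n_windows", "n_sites",
                 "level_treatment", "level_control", "q_min"]


def write_dmr_bed(dmrs, path: str | Path) -> Path:
    """Write DMRs as BED6 plus a companion TSV with full statistics.

    BED is 0-based half-open; score = min(1000, round(-10*log10(q_min))).
    Returns the companion TSV path (``<path>`` with a .tsv suffix).
    """
    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    with open(path, "w") as bed:
        for d in dmrs:
            if d.q_min > 0:
                score = min(1000, round(-10.0 * math.log10(d.q_min)))
            else:
                score = 1000
            bed.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.id}"
                      f"\t{score}\t.\n")
    rows = [{c: getattr(d, c) for c in _DMR_TSV_COLS} for d in dmrs]
    pd.DataFrame(rows, columns=_DMR_TSV_COLS).to_csv(
        tsv_path, sep="\t", index=False)
    return tsv_path


def read_dmr_table(path: str | Path) -> pd.DataFrame:
    """Read back the companion DMR TSV."""
    return pd.read_csv(path, sep="\t",
                       dtype={"id": str, "chrom": str, "direction": str,
                              "dominant_context": str})


# ---------------------------------------------------------------------------
# DEG table and GMT term maps

def read_deg_table(path: str | Path) -> pd.DataFrame:
    """TSV of differentially expressed genes: gene_id, log2fc[, p]."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "log2fc" not in df.columns:
        raise ParseError(f"{path}: DEG table needs gene_id and log2fc "
                         "columns")
    return df


def write_deg_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: term, description, then member genes, tab-separated."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: GMT line {lineno} has fewer "
                                 "than 3 fields")
            terms[parts[0]] = set(parts[2:])
    return terms


def write_gmt(terms: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, "na", *sorted(genes)]) + "\n")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
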