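"""Cytosine-context classification, bisulfite conversion-rate estimation,
methylated-site calling and genome-wide context summaries.

Contexts follow the standard plant/insect three-way scheme: a cytosine is
CG, CHG or CHH according to the two bases downstream of it on its own
strand, where H is A, C or T.  Site calling tests each cytosine's
methylated read count against the bisulfite conversion *failure* rate
estimated from an unmethylated spike-in genome: under complete
non-methylation the count is Binomial(coverage, failure_rate), so a
one-sided binomial tail below ``site_call_alpha`` calls the site
methylated.  No multiple-testing correction is applied at the site level;
only windows are tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent
from .genome import GenomeStore

CONTEXTS = ("CG", "CHG", "CHH")


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# context classification

def classify_context(genome: GenomeStore, chrom: str, pos: int,
                     strand: str) -> str:
    """Context (CG/CHG/CHH/unknown) of the cytosine at a 1-based position.

    On the minus strand the walk runs 5'->3' of that strand, i.e. toward
    smaller forward coordinates, reading complements.  Returns ``unknown``
    when fewer than two strand-downstream bases exist or a needed base
    is N.  Raises :class:`ValidationError` if the position is not a
    cytosine on the requested strand.
    """
    out = contexts_for_positions(genome, chrom, np.array([pos]),
                                 np.array([strand]))
    return out[0]


def contexts_for_positions(genome: GenomeStore, chrom: str,
                           pos: np.ndarray, strand: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_context` over one chromosome."""
    seq = genome.fetch(chrom, 1, genome.length(chrom))
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    pos = np.asarray(pos, dtype=np.int64)
    fwd = np.asarray(strand) == "+"
    if np.any((pos < 1) | (pos > n)):
        raise ValidationError(f"position outside contig {chrom}")

    base = arr[pos - 1]
    bad = np.where(fwd, base != b"C", base != b"G")
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValidationError(
            f"no cytosine at {chrom}:{pos[i]}({np.asarray(strand)[i]}): "
            f"reference base is {base[i].decode()}")

    # strand-wise downstream bases; reverse strand reads complements, so a
    # minus-strand G is a plus-strand C at the smaller coordinate
    idx1 = np.where(fwd, pos, pos - 2)      # 0-based index of next base
    idx2 = np.where(fwd, pos + 1, pos - 3)
    in1 = (idx1 >= 0) & (idx1 < n)
    in2 = (idx2 >= 0) & (idx2 < n)
    b1 = np.where(in1, arr[np.clip(idx1, 0, n - 1)], b"N")
    b2 = np.where(in2, arr[np.clip(idx2, 0, n - 1)], b"N")
    g1 = np.where(fwd, b1 == b"G", b1 == b"C")
    g2 = np.where(fwd, b2 == b"G", b2 == b"C")
    n1 = b1 == b"N"
    n2 = b2 == b"N"

    out = np.full(len(pos), "unknown", dtype=object)
    usable = in1 & in2
    out[usable & g1] = "CG"
    out[usable & ~g1 & ~n1 & g2] = "CHG"
    out[usable & ~g1 & ~n1 & ~g2 & ~n2] = "CHH"
    return out.astype(str)


def genome_context_totals(genome: GenomeStore) -> dict[str, int]:
    """Number of genomic cytosine positions (both strands) per context."""
    totals = {c: 0 for c in CONTEXTS}
    for chrom in genome.chroms:
        seq = genome.fetch(chrom, 1, genome.length(chrom))
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for strand, target in (("+", b"C"), ("-", b"G")):
            pos = np.flatnonzero(arr == target) + 1
            if len(pos) == 0:
                continue
            ctx = contexts_for_positions(
                genome, chrom, pos, np.full(len(pos), strand))
            for c in CONTEXTS:
                totals[c] += int(np.sum(ctx == c))
    return totals


# ---------------------------------------------------------------------------
# conversion rate

@dataclass(frozen=True)
class ConversionEstimate:
    """Bisulfite conversion efficiency from an unmethylated spike-in.

    Every cytosine read at a reference C position of the (fully
    unmethylated) spike-in genome is a conversion failure, so the failure
    rate is simply the pooled fraction of unconverted observations.
    """
    n_cytosines_observed: int
    n_unconverted: int

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.n_unconverted / self.n_cytosines_observed

    @property
    def failure_rate(self) -> float:
        return self.n_unconverted / self.n_cytosines_observed


def estimate_conversion(spikein: pd.DataFrame) -> ConversionEstimate:
    """Pool all spike-in read observations into one conversion estimate."""
    n_unconv = int(spikein["meth_count"].sum())
    n_obs = n_unconv + int(spikein["unmeth_count"].sum())
    if n_obs == 0:
        raise ValidationError("spike-in has zero read observations; "
                              "conversion rate undefined")
    return ConversionEstimate(n_cytosines_observed=n_obs,
                              n_unconverted=n_unconv)


# ---------------------------------------------------------------------------
# site calling

def call_methylated_sites(tables: "dict[str, pd.DataFrame]",
                          failure_rate: float,
                          min_site_coverage: int = 4,
                          site_call_alpha: float = 0.05,
                          ) -> dict[str, pd.DataFrame]:
    """Per-sample methylated-site calls.

    A site is called iff coverage >= ``min_site_coverage`` and the
    one-sided binomial tail P(X >= meth | n=coverage, p=failure_rate)
    falls below ``site_call_alpha``.  Accepts either a mapping of sample
    id -> cytosine table or a :class:`~dmrscan.io.MethylomeSet`.
    """
    if hasattr(tables, "tables"):
        tables = tables.tables
    if not 0 <= failure_rate < 1:
        raise ValidationError(f"failure_rate {failure_rate} outside [0, 1)")
    called = {}
    for sample, df in tables.items():
        cov = (df["meth_count"] + df["unmeth_count"]).to_numpy()
        meth = df["meth_count"].to_numpy()
        with np.errstate(divide="ignore"):
            tail = stats.binom.sf(meth - 1, np.maximum(cov, 1), failure_rate)
        keep = (cov >= min_site_coverage) & (tail < site_call_alpha)
        sub = df.loc[keep, ["chrom", "pos", "strand", "context",
                            "meth_count", "unmeth_count"]].copy()
        sub.reset_index(drop=True, inplace=True)
        called[sample] = sub
    return called


def group_called_sites(called: dict[str, pd.DataFrame],
                       group_of: dict[str, str],
                       group: str,
                       rule: str = "majority") -> pd.DataFrame:
    """Combine per-replicate calls into one group-level called-site set.

    ``rule``: "majority" (default; called in more than half the
    replicates), "union" or "intersection".  Majority voting keeps sites
    with replicate dropout while suppressing the sporadic false calls an
    uncorrected per-site binomial test produces.
    """
    samples = [s for s, g in group_of.items() if g == group]
    if not samples:
        raise ValidationError(f"no samples in group {group!r}")
    frames = [called[s][["chrom", "pos", "strand", "context"]]
              for s in samples]
    allcalls = pd.concat(frames, ignore_index=True)
    counts = (allcalls.groupby(["chrom", "pos", "strand", "context"])
              .size().rename("n_reps").reset_index())
    if rule == "union":
        need = 1
    elif rule == "intersection":
        need = len(samples)
    elif rule == "majority":
        need = len(samples) // 2 + 1
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out = counts[counts["n_reps"] >= need].drop(columns="n_reps")
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# context summaries

@dataclass(frozen=True)
class ContextSummary:
    """Methylated-site counts per context and their share of the
    three-context total, as printed in genome-wide methylation tables."""
    counts: dict[str, int]
    percents: dict[str, float] = field(default=None)

    def __post_init__(self):
        total = sum(self.counts.get(c, 0) for c in CONTEXTS)
        if self.percents is None:
            pct = ({c: percent(self.counts.get(c, 0), total)
                    for c in CONTEXTS} if total else None)
            object.__setattr__(self, "percents", pct)

    @property
    def total(self) -> int:
        return sum(self.counts.get(c, 0) for c in CONTEXTS)


def summarize_contexts(sites: "pd.DataFrame | dict[str, int]") -> ContextSummary:
    """Tally called methylated sites by context.

    Accepts either a called-site table with a ``context`` column or a
    ready-made mapping context -> count (e.g. printed table values).
    """
    if isinstance(sites, dict):
        counts = {c: int(sites.get(c, 0)) for c in CONTEXTS}
    else:
        vc = sites["context"].value_counts()
        counts = {c: int(vc.get(c, 0)) for c in CONTEXTS}
    return ContextSummary(counts=counts)


def compare_group_totals(summary_a: ContextSummary,
                         summary_b: ContextSummary,
                         genome_totals: dict[str, int]) -> pd.DataFrame:
    """Two-sided Fisher's exact test per context on called-vs-uncalled
    site counts, with the genome-wide cytosine totals as margins.

    Returns a frame with one row per context: counts, the p-value and the
    direction (sign of the a-minus-b difference in called fraction).
    """
    rows = []
    for c in CONTEXTS:
        total = genome_totals.get(c, 0)
        ka, kb = summary_a.counts.get(c, 0), summary_b.counts.get(c, 0)
        if total <= 0 or ka > total or kb > total:
            raise ValidationError(f"bad genome total for context {c}")
        table = [[ka, total - ka], [kb, total - kb]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"context": c, "called_a": ka, "called_b": kb,
                     "genome_total": total, "p": float(p),
                     "direction": "a>b" if ka > kb else
                                  ("a<b" if ka < kb else "equal")})
    return pd.DataFrame(rows)
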