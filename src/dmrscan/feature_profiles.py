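"""Where methylation falls in gene anatomy.

Two views: (1) assignment of called methylated sites to gene components
(promoter, 5'UTR, exon, intron, 3'UTR, or intergenic), with a site
counting toward every kind it hits across overlapping genes; and (2) a
compressed-coordinate meta-profile in which every component instance is
rescaled to a fixed number of bins, read 5'->3' of its gene, and the
coverage-weighted methylation level (sum meth / sum total) is pooled per
bin across instances and replicates of a group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import percent
from .io import COMPONENT_KINDS, GeneModel

KIND_ORDER = COMPONENT_KINDS          # promoter .. three_prime_utr
ASSIGN_KINDS = KIND_ORDER + ("intergenic",)


@dataclass(frozen=True)
class FeatureAssignment:
    chrom: str
    pos: int
    strand: str
    kinds: frozenset[str]


def _component_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for comp in g.components:
            # interval tree is half-open; components are 1-based closed
            tree.addi(comp.start, comp.end + 1, (g.gene_id, comp.kind))
    return trees


def assign_sites(sites: pd.DataFrame, genes: list[GeneModel],
                 ) -> tuple[list[FeatureAssignment], pd.DataFrame]:
    """Label each site with the component kinds it falls in.

    Returns the per-site assignments plus a summary frame with one row
    per kind: site count, percent of all site-kind assignments (sums to
    100) and percent of sites.
    """
    trees = _component_trees(genes)
    assignments: list[FeatureAssignment] = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        for pos, strand in zip(sub["pos"].to_numpy(),
                               sub["strand"].to_numpy()):
            kinds = (frozenset(kind for _, _, (_, kind) in tree[pos])
                     if tree is not None else frozenset())
            if not kinds:
                kinds = frozenset({"intergenic"})
            assignments.append(FeatureAssignment(chrom, int(pos),
                                                 str(strand), kinds))
    counts = {k: 0 for k in ASSIGN_KINDS}
    for a in assignments:
        for k in a.kinds:
            counts[k] += 1
    total_assign = sum(counts.values())
    n_sites = len(assignments)
    rows = []
    for k in ASSIGN_KINDS:
        rows.append({
            "kind": k,
            "n_sites": counts[k],
            "percent_of_assignments":
                percent(counts[k], total_assign) if total_assign else 0.0,
            "percent_of_sites":
                percent(counts[k], n_sites) if n_sites else 0.0,
        })
    return assignments, pd.DataFrame(rows)


@dataclass(frozen=True)
class MetaProfile:
    kind_order: tuple[str, ...]
    n_bins: int
    levels: np.ndarray          # (kind, bin); NaN where no coverage
    n_cytosines: np.ndarray     # (kind, bin) int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, kind in enumerate(self.kind_order):
            for b in range(self.n_bins):
                rows.append({"kind": kind, "bin": b,
                             "level": self.levels[i, b],
                             "n_cytosines": int(self.n_cytosines[i, b])})
        return pd.DataFrame(rows)


class EmptyProfileError(ValueError):
    pass


def meta_profile(methylome, group: str, genes: list[GeneModel],
                 n_bins: int = 20) -> MetaProfile:
    """Compressed-coordinate methylation meta-profile for one group.

    Each component instance is split into ``n_bins`` equal-length bins
    oriented 5'->3' of the gene; a bin's level is sum(meth)/sum(total)
    over all cytosines of that bin pooled across instances and the
    group's replicates.  Bins never touched by a covered cytosine carry
    NaN.
    """
    pooled = methylome.pooled(group) if hasattr(methylome, "pooled") \
        else methylome
    pooled = pooled[(pooled["meth_count"] + pooled["unmeth_count"]) > 0]
    if pooled.empty:
        raise EmptyProfileError(f"group {group!r} has no covered cytosines")
    by_chrom = {c: sub.sort_values("pos") for c, sub in
                pooled.groupby("chrom", sort=False)}
    kidx = {k: i for i, k in enumerate(KIND_ORDER)}
    meth = np.zeros((len(KIND_ORDER), n_bins))
    tot = np.zeros((len(KIND_ORDER), n_bins))
    ncyt = np.zeros((len(KIND_ORDER), n_bins), dtype=np.int64)
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        m = sub["meth_count"].to_numpy()
        u = sub["unmeth_count"].to_numpy()
        for comp in g.components:
            lo = np.searchsorted(pos, comp.start, "left")
            hi = np.searchsorted(pos, comp.end, "right")
            if hi <= lo:
                continue
            p = pos[lo:hi]
            length = comp.end - comp.start + 1
            offset = (p - comp.start) if g.strand == "+" else (comp.end - p)
            bins = np.minimum((offset * n_bins) // length, n_bins - 1)
            ki = kidx[comp.kind]
            np.add.at(meth[ki], bins, m[lo:hi])
            np.add.at(tot[ki], bins, m[lo:hi] + u[lo:hi])
            np.add.at(ncyt[ki], bins, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
    return MetaProfile(kind_order=KIND_ORDER, n_bins=n_bins,
                       levels=levels, n_cytosines=ncyt)
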