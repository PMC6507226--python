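"""DMR-to-gene annotation, term enrichment and the DMG x DEG overlap.

A DMR is assigned to every gene whose span or functional component
(promoter, 5'UTR, exon, intron, 3'UTR) it overlaps by at least one base;
the union of linked genes is the differentially methylated gene (DMG)
set.  Term enrichment is a hypergeometric upper-tail test against the
whole annotated gene set as background with BH correction across terms.
The DMG x DEG association is judged against a resampling null: random
gene sets of DMG size are drawn from the annotated universe and their
overlap with the DEG list recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._util import percent
from .calls import ValidationError
from .dmr import DMR, adjust_fdr
from .io import GeneModel


# ---------------------------------------------------------------------------
# DMR -> gene links

def link_dmrs_to_genes(dmrs: list[DMR], genes: list[GeneModel],
                       ) -> tuple[pd.DataFrame, set[str], dict]:
    """Interval-overlap join of DMRs onto gene models.

    Returns (link table with one row per DMR-gene pair and the component
    kinds overlapped, the DMG set, and per-direction gene counts with
    genes linked to both directions flagged ambiguous).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        tree.addi(g.start, g.end + 1, g)
    rows = []
    for d in dmrs:
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(d.start, d.end + 1),
                         key=lambda iv: iv.data.gene_id):
            g: GeneModel = iv.data
            kinds = frozenset(
                c.kind for c in g.components
                if c.start <= d.end and c.end >= d.start)
            rows.append({"dmr_id": d.id, "gene_id": g.gene_id,
                         "direction": d.direction, "kinds": kinds})
    links = pd.DataFrame(rows, columns=["dmr_id", "gene_id", "direction",
                                        "kinds"])
    dmg = set(links["gene_id"]) if len(links) else set()
    hyper = set(links.loc[links["direction"] == "hyper", "gene_id"]) \
        if len(links) else set()
    hypo = set(links.loc[links["direction"] == "hypo", "gene_id"]) \
        if len(links) else set()
    counts = {"hyper": len(hyper), "hypo": len(hypo),
              "ambiguous": sorted(hyper & hypo)}
    return links, dmg, counts


# ---------------------------------------------------------------------------
# term enrichment

def enrich_terms(dmg: set[str], background: set[str],
                 term_map: dict[str, set[str]],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene set per term.

    p = P(X >= k) with X ~ Hypergeom(N=len(background), K=term size,
    n=len(dmg)); BH across terms.  Terms with no background genes are
    skipped.
    """
    if not dmg <= background:
        raise ValidationError("DMG set must be a subset of the background")
    N, n = len(background), len(dmg)
    rows = []
    for term, members in term_map.items():
        K = len(members & background)
        if K == 0:
            continue
        k = len(members & dmg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "p_raw": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_raw"])
    if len(df):
        df["q"] = adjust_fdr(df["p_raw"].to_numpy())
        df["enriched"] = df["q"] < alpha
        df = df.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# DMG x DEG overlap

@dataclass(frozen=True)
class OverlapTest:
    """Observed DMG x DEG intersection with its resampling null."""
    n_deg: int
    n_dmg: int
    observed_overlap: int
    null_overlaps: tuple[int, ...]
    #: percentages truncate at 2 decimals by default (floor); switchable
    #: to conventional half-up rounding.
    rounding: str = "truncate"

    @property
    def pct_of_deg(self) -> float:
        return percent(self.observed_overlap, self.n_deg,
                       mode=self.rounding)

    @property
    def pct_of_dmg(self) -> float:
        return percent(self.observed_overlap, self.n_dmg,
                       mode=self.rounding)

    @property
    def empirical_p(self) -> float:
        n_ge = sum(1 for x in self.null_overlaps
                   if x >= self.observed_overlap)
        return (1 + n_ge) / (1 + len(self.null_overlaps))


def overlap_with_degs(dmg: set[str], deg_table: pd.DataFrame,
                      genes: "list[GeneModel] | set[str]",
                      n_permutations: int = 25,
                      rng_seed: int = 0,
                      rounding: str = "truncate") -> OverlapTest:
    """Observed |DMG intersect DEG| against random same-size gene draws.

    Each permutation draws ``len(dmg)`` genes uniformly without
    replacement from the annotated universe and records the overlap with
    the DEG list.
    """
    universe = sorted({g.gene_id for g in genes}
                      if genes and isinstance(next(iter(genes)), GeneModel)
                      else set(genes))
    deg = set(deg_table["gene_id"])
    if len(dmg) > len(universe):
        raise ValidationError("DMG set larger than gene universe")
    observed = len(dmg & deg)
    rng = np.random.default_rng(rng_seed)
    universe_arr = np.array(universe, dtype=object)
    deg_mask = np.isin(universe_arr, list(deg))
    nulls = []
    for _ in range(n_permutations):
        pick = rng.choice(len(universe_arr), size=len(dmg), replace=False)
        nulls.append(int(deg_mask[pick].sum()))
    return OverlapTest(n_deg=len(deg), n_dmg=len(dmg),
                       observed_overlap=observed,
                       null_overlaps=tuple(nulls), rounding=rounding)


def overlap_with_random_intervals(dmrs: list[DMR],
                                  genes: list[GeneModel],
                                  chrom_sizes: dict[str, int],
                                  deg_table: pd.DataFrame,
                                  n_permutations: int = 25,
                                  rng_seed: int = 0) -> list[int]:
    """Interval-placement control: drop DMR-sized intervals uniformly on
    the genome, re-run gene linking and record the DEG overlap each time."""
    deg = set(deg_table["gene_id"])
    rng = np.random.default_rng(rng_seed)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    nulls = []
    for _ in range(n_permutations):
        fake = []
        for i, d in enumerate(dmrs, 1):
            length = d.end - d.start + 1
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(1, max(2, chrom_sizes[chrom]
                                            - length + 2)))
            fake.append(DMR(id=f"R{i}", chrom=chrom, start=start,
                            end=start + length - 1, direction=d.direction,
                            dominant_context=d.dominant_context,
                            n_windows=d.n_windows, n_sites=d.n_sites,
                            level_treatment=d.level_treatment,
                            level_control=d.level_control, q_min=d.q_min))
        _, fake_dmg, _ = link_dmrs_to_genes(fake, genes)
        nulls.append(len(fake_dmg & deg))
    return nulls


# ---------------------------------------------------------------------------
# methylation/expression concordance

def correlate_methylation_expression(links: pd.DataFrame,
                                     deg_table: pd.DataFrame,
                                     ) -> pd.DataFrame:
    """Label each linked gene by methylation/expression concordance.

    negative-correlated: methylation change and expression change have
    opposite signs (hypo DMR with an upregulated gene, or hyper with a
    downregulated one); positive-correlated: same sign; unmatched: gene
    absent from the DEG table.
    """
    lfc = dict(zip(deg_table["gene_id"], deg_table["log2fc"]))
    rows = []
    for gene_id, sub in links.groupby("gene_id", sort=True):
        directions = set(sub["direction"])
        meth_sign = (0 if len(directions) == 2 else
                     (1 if "hyper" in directions else -1))
        if gene_id not in lfc:
            label = "unmatched"
        elif meth_sign == 0:
            label = "ambiguous"
        else:
            expr_sign = 1 if lfc[gene_id] > 0 else \
                (-1 if lfc[gene_id] < 0 else 0)
            if expr_sign == 0:
                label = "unmatched"
            else:
                label = ("negative-correlated" if meth_sign != expr_sign
                         else "positive-correlated")
        rows.append({"gene_id": gene_id,
                     "meth_direction": "/".join(sorted(directions)),
                     "log2fc": lfc.get(gene_id, np.nan),
                     "label": label})
    return pd.DataFrame(rows)
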