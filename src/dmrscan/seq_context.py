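"""Flanking-sequence preference profiles around methylated cytosines.

For each called site the window of ``length`` bases centred on the
cytosine is read 5'->3' on the methylated strand (reverse-complemented
for minus-strand sites), and per-position base frequencies are
accumulated.  The centre column is therefore always C.  Sites too close
to a contig edge for a full window are skipped and counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import revcomp
from .genome import GenomeStore

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class KmerProfile:
    context: str
    length: int
    probs: np.ndarray           # (length, 4) rows sum to 1
    n_sites: int
    n_skipped_edge: int = 0

    @property
    def center(self) -> int:
        return self.length // 2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(BASES))
        df.insert(0, "offset", np.arange(self.length) - self.center)
        return df


class EmptyProfileError(ValueError):
    pass


def kmer_profile(sites: pd.DataFrame, genome: GenomeStore,
                 length: int = 9, context: str = "all") -> KmerProfile:
    """Per-position base probabilities in the strand-oriented window of
    ``length`` bases centred on each methylated cytosine.

    ``sites`` needs chrom/pos/strand columns (e.g. a group called-site
    table); pass ``context`` for labelling only — filter beforehand.
    """
    if length % 2 == 0:
        raise ValueError("length must be odd")
    half = length // 2
    counts = np.zeros((length, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    n_used = n_edge = 0
    for chrom, sub in sites.groupby("chrom", sort=False):
        clen = genome.length(chrom)
        for pos, strand in zip(sub["pos"].to_numpy(),
                               sub["strand"].to_numpy()):
            if pos - half < 1 or pos + half > clen:
                n_edge += 1
                continue
            window = genome.fetch(chrom, pos - half, pos + half)
            if strand == "-":
                window = revcomp(window)
            if "N" in window:
                n_edge += 1
                continue
            for i, b in enumerate(window):
                counts[i, base_idx[b]] += 1
            n_used += 1
    if n_used == 0:
        raise EmptyProfileError("no usable sites for k-mer profile")
    probs = counts / counts.sum(axis=1, keepdims=True)
    return KmerProfile(context=context, length=length, probs=probs,
                       n_sites=n_used, n_skipped_edge=n_edge)


@dataclass(frozen=True)
class FlankString:
    upstream: str               # 3 bases 5' of the cytosine, 5'->3'
    downstream: str             # 3 bases 3' of the cytosine, 5'->3'
    probability: float          # product of per-position probabilities


def top_flank_strings(profile: KmerProfile, k: int = 5,
                      flank: int = 3) -> list[FlankString]:
    """The ``k`` most probable flanking base runs adjacent to the centre.

    Probability of a run is the product of the per-position marginal
    probabilities over the ``flank`` positions upstream and downstream of
    the centre.  Ties break lexicographically (upstream, then
    downstream), so a uniform profile returns runs in alphabetical order.
    """
    c = profile.center
    if c < flank or profile.length - 1 - c < flank:
        raise ValueError("profile too short for requested flank")
    up_cols = range(c - flank, c)
    down_cols = range(c + 1, c + 1 + flank)
    combos = []
    for up in itertools.product(range(4), repeat=flank):
        p_up = float(np.prod([profile.probs[col, b]
                              for col, b in zip(up_cols, up)]))
        for down in itertools.product(range(4), repeat=flank):
            p = p_up * float(np.prod([profile.probs[col, b]
                                      for col, b in zip(down_cols, down)]))
            combos.append(FlankString(
                upstream="".join(BASES[b] for b in up),
                downstream="".join(BASES[b] for b in down),
                probability=p))
    combos.sort(key=lambda f: (-f.probability, f.upstream, f.downstream))
    return combos[:k]


def merge_profiles(a: KmerProfile, b: KmerProfile) -> KmerProfile:
    """n-weighted average of two profiles over the same window length."""
    if a.length != b.length:
        raise ValueError("profiles have different lengths")
    n = a.n_sites + b.n_sites
    probs = (a.probs * a.n_sites + b.probs * b.n_sites) / n
    ctx = a.context if a.context == b.context else "mixed"
    return KmerProfile(context=ctx, length=a.length, probs=probs, n_sites=n,
                       n_skipped_edge=a.n_skipped_edge + b.n_skipped_edge)
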