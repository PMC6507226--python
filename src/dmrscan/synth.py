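"""Synthetic WGBS study generator with planted ground truth.

Emulates a two-group (treatment vs control), three-replicates-per-group
bisulfite study of a compact insect-like genome: an i.i.d. uniform ACGT
sequence, intron-heavy gene models, a sparse methylome in which roughly
0.1% of cytosines are methylated with the CHH context dominating the
called set, imperfect bisulfite conversion, beta-binomial replicate
overdispersion, and optional planted differentially methylated regions
whose level shift and direction are recorded as ground truth.  A fully
unmethylated spike-in contig is generated with the same conversion
failure so the conversion-rate estimator can be exercised end to end.

Every random draw flows from one seed; the same design therefore yields
a byte-identical bundle on disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import contexts_for_positions
from .dmr import DMR
from .genome import GenomeStore
from .io import (GeneModel, MethylomeSet, build_gene_model, write_deg_table,
                 write_fasta, write_gmt)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    start: int
    end: int
    direction: str              # hyper / hypo (treatment vs control)
    delta_level: float


@dataclass(frozen=True)
class SimulationDesign:
    genome_length_bp: int = 300_000
    n_chromosomes: int = 2
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    #: per-context probability that a cytosine is a methylated site.
    #: Near-equal rates reproduce the observed called-set mix (CHH most
    #: abundant at ~55%, then CG, then CHG) because the context background
    #: frequencies on random sequence are 25% / 18.75% / 56.25%.
    baseline_meth: dict = field(default_factory=lambda: {
        "CG": 0.0012, "CHG": 0.0011, "CHH": 0.0010})
    #: latent methylation level of a baseline methylated site
    methylated_level: float = 0.75
    #: regional level of a planted DMR in its low group
    dmr_base_level: float = 0.1
    planted_dmrs: tuple[PlantedDMR, ...] | None = None
    n_planted_dmrs: int = 0
    planted_dmr_length_bp: int = 1500
    planted_delta: float = 0.2
    coverage_mean: float = 30.0
    #: beta-binomial overdispersion rho; 0 gives pure binomial sampling
    replicate_dispersion: float = 0.05
    conversion_failure: float = 0.005
    n_replicates_per_group: int = 3
    spikein_length_bp: int = 48_502
    n_deg: int = 8
    planted_overlap_genes: int = 3
    n_terms: int = 5
    promoter_bp: int = 2000
    rng_seed: int = 0

    def __post_init__(self):
        for ctx, rate in self.baseline_meth.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"baseline rate for {ctx} outside [0,1]")
        for name in ("methylated_level", "dmr_base_level", "planted_delta",
                     "conversion_failure", "replicate_dispersion"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0,1]")
        if self.dmr_base_level + self.planted_delta > 1:
            raise ValueError("planted base + delta exceeds level 1")


@dataclass
class SimulatedBundle:
    design: SimulationDesign
    genome: dict[str, str]
    genes: list[GeneModel]
    methylome: MethylomeSet
    spikein: pd.DataFrame
    deg: pd.DataFrame
    terms: dict[str, set[str]]
    truth: dict
    paths: dict[str, Path] | None = None


# ---------------------------------------------------------------------------

def _random_genome(rng, design) -> dict[str, str]:
    per = design.genome_length_bp // design.n_chromosomes
    return {f"chr{i + 1}": "".join(_BASES[rng.integers(0, 4, per)])
            for i in range(design.n_chromosomes)}


def _place_genes(rng, design, genome) -> list[GeneModel]:
    """Intron-heavy gene models laid left to right across chromosomes."""
    genes: list[GeneModel] = []
    chroms = list(genome)
    ci = 0
    cursor = design.promoter_bp + 1000
    for gi in range(design.n_genes):
        k = int(rng.integers(design.exons_per_gene[0],
                             design.exons_per_gene[1] + 1))
        exon_lens = rng.integers(100, 201, size=k)
        intron_lens = rng.integers(800, 2001, size=max(0, k - 1))
        span = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(1500, 4001))
        while ci < len(chroms) and \
                cursor + span + design.promoter_bp > len(genome[chroms[ci]]):
            ci += 1
            cursor = design.promoter_bp + 1000
        if ci >= len(chroms):
            break
        start = cursor
        exons = []
        p = start
        for j in range(k):
            exons.append((p, p + int(exon_lens[j]) - 1))
            p = exons[-1][1] + 1
            if j < k - 1:
                p += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        first, last = exons[0], exons[-1]
        if strand == "+":
            utr5 = [(first[0], first[0] + min(99, first[1] - first[0]))]
            utr3 = [(max(last[0], last[1] - 119), last[1])]
        else:
            utr5 = [(max(last[0], last[1] - 99), last[1])]
            utr3 = [(first[0], first[0] + min(119, first[1] - first[0]))]
        genes.append(build_gene_model(
            f"gene{gi + 1:03d}", chroms[ci], strand, exons,
            utr5=utr5, utr3=utr3, promoter_bp=design.promoter_bp,
            contig_len=len(genome[chroms[ci]])))
        cursor = exons[-1][1] + gap + design.promoter_bp
    return genes


def plant_dmrs(rng, design, genes: list[GeneModel]) -> tuple[PlantedDMR, ...]:
    """Drop planted DMR intervals inside distinct gene bodies, alternating
    hyper/hypo, so every planted region implies a true DMG."""
    if design.n_planted_dmrs > len(genes):
        raise ValueError("more planted DMRs than genes")
    pick = rng.choice(len(genes), size=design.n_planted_dmrs, replace=False)
    planted = []
    for j, gi in enumerate(sorted(pick)):
        g = genes[gi]
        body = [c for c in g.components if c.kind != "promoter"]
        lo = min(c.start for c in body)
        hi = max(c.end for c in body)
        length = min(design.planted_dmr_length_bp, hi - lo + 1)
        start = lo if hi - lo + 1 <= length else \
            int(rng.integers(lo, hi - length + 2))
        planted.append(PlantedDMR(
            chrom=g.chrom, start=start, end=start + length - 1,
            direction="hyper" if j % 2 == 0 else "hypo",
            delta_level=design.planted_delta))
    return tuple(planted)


def _cytosine_sites(genome: dict[str, str]) -> pd.DataFrame:
    store = GenomeStore(genome)
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for strand, target in (("+", b"C"), ("-", b"G")):
            pos = np.flatnonzero(arr == target) + 1
            if len(pos) == 0:
                continue
            ctx = contexts_for_positions(store, chrom, pos,
                                         np.full(len(pos), strand))
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                        "strand": strand, "context": ctx}))
    sites = pd.concat(frames, ignore_index=True)
    sites = sites[sites["context"] != "unknown"]
    return (sites.sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True))


def _replicate_counts(rng, level: np.ndarray, cov: np.ndarray,
                      failure: float, rho: float) -> np.ndarray:
    """Methylated read counts for one replicate.

    Biological replicate noise perturbs the latent methylation level of
    methylated positions with a beta of mean ``level`` and dispersion
    ``rho``; bisulfite conversion failure then acts per read, so the
    observed count is Binomial(cov, level' + (1-level')*failure).
    Unmethylated positions (level 0) carry pure conversion noise.
    """
    level = np.clip(level, 0.0, 1.0)
    if rho > 0:
        varying = (level > 0) & (level < 1)
        a = level * (1 - rho) / rho
        b = (1 - level) * (1 - rho) / rho
        level = np.where(varying,
                         rng.beta(np.maximum(a, 1e-12),
                                  np.maximum(b, 1e-12)),
                         level)
    p = level + (1 - level) * failure
    return rng.binomial(cov, p)


def simulate(design: SimulationDesign,
             outdir: str | Path | None = None) -> SimulatedBundle:
    """Generate the full input bundle; optionally write it to ``outdir``."""
    rng = np.random.default_rng(design.rng_seed)
    genome = _random_genome(rng, design)
    genes = _place_genes(rng, design, genome)
    if design.planted_dmrs is not None:
        planted = tuple(design.planted_dmrs)
    elif design.n_planted_dmrs > 0:
        planted = plant_dmrs(rng, design, genes)
    else:
        planted = ()

    sites = _cytosine_sites(genome)
    n = len(sites)
    ctx = sites["context"].to_numpy()
    rate = np.zeros(n)
    for c, r in design.baseline_meth.items():
        rate[ctx == c] = r
    is_meth = rng.random(n) < rate
    base = np.where(is_meth, design.methylated_level, 0.0)
    level_t = base.copy()
    level_c = base.copy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for d in planted:
        mask = (chrom_arr == d.chrom) & (pos_arr >= d.start) & \
            (pos_arr <= d.end)
        lo_level = design.dmr_base_level
        hi_level = design.dmr_base_level + d.delta_level
        if d.direction == "hyper":
            level_t[mask], level_c[mask] = hi_level, lo_level
        else:
            level_t[mask], level_c[mask] = lo_level, hi_level

    f = design.conversion_failure
    samples, group_of, tables = [], {}, {}
    for group, level in (("control", level_c), ("treatment", level_t)):
        for r in range(1, design.n_replicates_per_group + 1):
            name = f"{group}_{r}"
            cov = rng.poisson(design.coverage_mean, n)
            meth = _replicate_counts(rng, level, cov, f,
                                     design.replicate_dispersion)
            df = sites.copy()
            df["meth_count"] = meth.astype(np.int64)
            df["unmeth_count"] = (cov - meth).astype(np.int64)
            tables[name] = df[["chrom", "pos", "strand", "meth_count",
                               "unmeth_count", "context"]]
            samples.append(name)
            group_of[name] = group
    methylome = MethylomeSet(
        samples=samples, group_of=group_of, tables=tables,
        chrom_sizes={c: len(s) for c, s in genome.items()})

    # unmethylated spike-in contig with the same conversion failure
    spike_seq = "".join(_BASES[rng.integers(0, 4, design.spikein_length_bp)])
    spike_store = GenomeStore({"spikein": spike_seq})
    spike_sites = _cytosine_sites({"spikein": spike_seq})
    scov = rng.poisson(design.coverage_mean, len(spike_sites))
    smeth = rng.binomial(scov, f)
    spikein = spike_sites.copy()
    spikein["meth_count"] = smeth.astype(np.int64)
    spikein["unmeth_count"] = (scov - smeth).astype(np.int64)
    spikein = spikein[["chrom", "pos", "strand", "meth_count",
                      "unmeth_count", "context"]]

    # DEG table: planted overlap genes get expression changes whose sign
    # opposes the methylation change (the predominant real pattern)
    dmr_genes = _genes_over_planted(planted, genes)
    n_overlap = min(design.planted_overlap_genes, len(dmr_genes))
    overlap_pick = [g for g, _ in dmr_genes[:n_overlap]]
    others = [g.gene_id for g in genes
              if g.gene_id not in {x for x, _ in dmr_genes}]
    extra = list(rng.choice(
        others, size=min(max(0, design.n_deg - n_overlap), len(others)),
        replace=False))
    rows = []
    direction_of = dict(dmr_genes)
    for gid in overlap_pick:
        sign = 1.0 if direction_of[gid] == "hypo" else -1.0
        rows.append({"gene_id": gid,
                     "log2fc": float(np.round(sign * rng.uniform(1, 3), 3)),
                     "p": float(np.round(rng.uniform(1e-6, 0.01), 6))})
    for gid in extra:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rows.append({"gene_id": gid,
                     "log2fc": float(np.round(sign * rng.uniform(1, 3), 3)),
                     "p": float(np.round(rng.uniform(1e-6, 0.01), 6))})
    deg = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p"])

    # GMT: term 1 concentrates the DMR genes, the rest are random slices
    gene_ids = [g.gene_id for g in genes]
    terms: dict[str, set[str]] = {}
    if gene_ids:
        t1 = set(x for x, _ in dmr_genes)
        pad = [g for g in gene_ids if g not in t1]
        t1 |= set(rng.choice(pad, size=min(2, len(pad)), replace=False)) \
            if pad else set()
        terms["TERM0001"] = t1 if t1 else set(gene_ids[:2])
        for t in range(2, design.n_terms + 1):
            size = int(rng.integers(3, max(4, len(gene_ids) // 2 + 1)))
            terms[f"TERM{t:04d}"] = set(rng.choice(
                gene_ids, size=min(size, len(gene_ids)), replace=False))

    truth = {
        "seed": design.rng_seed,
        "conversion_failure": f,
        "baseline_meth": dict(design.baseline_meth),
        "planted_dmrs": [dataclasses.asdict(d) for d in planted],
        "dmr_genes": [g for g, _ in dmr_genes],
        "deg_genes": sorted(deg["gene_id"]),
        "planted_overlap_genes": sorted(overlap_pick),
        "n_methylated_sites": int(is_meth.sum()),
        "n_cytosines": int(n),
    }

    bundle = SimulatedBundle(design=design, genome=genome, genes=genes,
                             methylome=methylome, spikein=spikein, deg=deg,
                             terms=terms, truth=truth)
    if outdir is not None:
        bundle.paths = _write_bundle(bundle, Path(outdir))
    return bundle


def _genes_over_planted(planted, genes) -> list[tuple[str, str]]:
    """(gene_id, direction) for genes whose span overlaps a planted DMR."""
    out = []
    for g in genes:
        for d in planted:
            if d.chrom == g.chrom and d.start <= g.end and d.end >= g.start:
                out.append((g.gene_id, d.direction))
                break
    return out


# ---------------------------------------------------------------------------
# on-disk bundle

def _write_gff3(genes: list[GeneModel], path: Path) -> None:
    type_of = {"five_prime_utr": "five_prime_UTR",
               "three_prime_utr": "three_prime_UTR", "exon": "exon"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            body = [c for c in g.components if c.kind != "promoter"]
            start = min(c.start for c in body)
            end = max(c.end for c in body)
            fh.write(f"{g.chrom}\tsim\tgene\t{start}\t{end}\t.\t{g.strand}"
                     f"\t.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{g.strand}"
                     f"\t.\tID={tid};Parent={g.gene_id}\n")
            i = 0
            for c in sorted(body, key=lambda c: (c.start, c.kind)):
                if c.kind == "intron":
                    continue
                i += 1
                fh.write(f"{g.chrom}\tsim\t{type_of[c.kind]}\t{c.start}\t"
                         f"{c.end}\t.\t{g.strand}\t.\t"
                         f"ID={tid}.{type_of[c.kind]}{i};Parent={tid}\n")


def _write_bundle(bundle: SimulatedBundle, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(bundle.genome, paths["genome"])
    paths["annotation"] = outdir / "genes.gff3"
    _write_gff3(bundle.genes, paths["annotation"])
    for sample in bundle.methylome.samples:
        p = outdir / f"{sample}.cytosine.tsv"
        bundle.methylome.tables[sample].to_csv(p, sep="\t", header=False,
                                               index=False)
        paths[sample] = p
    paths["spikein"] = outdir / "spikein.cytosine.tsv"
    bundle.spikein.to_csv(paths["spikein"], sep="\t", header=False,
                          index=False)
    paths["deg"] = outdir / "deg.tsv"
    write_deg_table(bundle.deg, paths["deg"])
    paths["terms"] = outdir / "terms.gmt"
    write_gmt(bundle.terms, paths["terms"])
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# evaluation against ground truth

@dataclass(frozen=True)
class TruthComparison:
    sensitivity: float | None
    precision: float | None
    n_planted: int
    n_detected: int
    matches: tuple[tuple[str, int], ...]   # (detected id, planted index)


def truth_compare(detected: list[DMR], truth: dict,
                  min_reciprocal_overlap: float = 0.5) -> TruthComparison:
    """Match detected DMRs to planted ones by reciprocal overlap.

    A pair matches when the intersection covers at least the threshold
    fraction of BOTH intervals.  Sensitivity = matched planted / planted;
    precision = matched detected / detected (None when nothing was
    detected or planted, reported as NA downstream).
    """
    planted = truth["planted_dmrs"] if isinstance(truth, dict) else truth
    matches = []
    matched_planted: set[int] = set()
    matched_detected: set[str] = set()
    for d in detected:
        dlen = d.end - d.start + 1
        for i, p in enumerate(planted):
            if p["chrom"] != d.chrom:
                continue
            inter = min(d.end, p["end"]) - max(d.start, p["start"]) + 1
            plen = p["end"] - p["start"] + 1
            if inter > 0 and inter / dlen >= min_reciprocal_overlap \
                    and inter / plen >= min_reciprocal_overlap:
                matches.append((d.id, i))
                matched_planted.add(i)
                matched_detected.add(d.id)
    sens = len(matched_planted) / len(planted) if planted else None
    prec = len(matched_detected) / len(detected) if detected else None
    return TruthComparison(sensitivity=sens, precision=prec,
                           n_planted=len(planted), n_detected=len(detected),
                           matches=tuple(matches))
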