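"""Sliding-window DMR detection.

The genome is tiled with fixed-size windows advanced at a fixed step
(defaults 1000 bp / 100 bp).  Read counts are pooled over replicates
within each group and over the cytosine sites of the window that are
covered in both groups; windows with at most ``min_c_sites`` such sites
are dropped before testing.  Each retained window's pooled 2x2 table
(methylated vs unmethylated reads, treatment vs control) gets a
two-sided Fisher's exact p-value; Benjamini-Hochberg q-values are
computed over all tested windows.  Candidate windows must additionally
pass the level-ratio (> min_fold_change), absolute-difference
(> min_abs_diff) and raw-p (< alpha_raw) gates; candidates with
q < alpha_fdr are merged in a single pass (overlapping or bookended
runs) into DMRs whose statistics are recomputed from raw counts over
the merged span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import CONTEXTS, ValidationError
from .config import RunConfig

WINDOW_COLS = ["chrom", "start", "end", "n_sites",
               "meth_t", "unmeth_t", "meth_c", "unmeth_c",
               "level_treatment", "level_control",
               "fold_change", "abs_diff", "p_raw", "q", "clamped"]


@dataclass(frozen=True)
class DMR:
    id: str
    chrom: str
    start: int
    end: int
    direction: str              # hyper / hypo, treatment vs control
    dominant_context: str
    n_windows: int
    n_sites: int
    level_treatment: float
    level_control: float
    q_min: float


# ---------------------------------------------------------------------------
# per-window exact test

def test_window(table) -> float:
    """Two-sided Fisher's exact p for a pooled 2x2 window table
    [[meth_t, unmeth_t], [meth_c, unmeth_c]].

    A zero row or column margin makes the table uninformative and returns
    p = 1.0 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValidationError("negative count in contingency table")
    if a + b + c + d == 0:
        raise ValidationError("empty contingency table")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# window scan

def _fold_change(la: float, lb: float) -> float:
    hi, lo = max(la, lb), min(la, lb)
    if lo == 0:
        return np.inf if hi > 0 else 1.0
    return hi / lo


def _union_arrays(methylome, config: RunConfig):
    """Outer-join the two groups' pooled tables per chromosome."""
    groups = methylome.groups
    if len(groups) != 2:
        raise ValidationError("DMR scan needs exactly two groups")
    treat = "treatment" if "treatment" in groups else groups[0]
    ctrl = "control" if "control" in groups else \
        [g for g in groups if g != treat][0]
    pt = methylome.pooled(treat)
    pc = methylome.pooled(ctrl)
    merged = pt.merge(pc, on=["chrom", "pos", "strand"], how="outer",
                      suffixes=("_t", "_c"))
    for col in ("meth_count_t", "unmeth_count_t",
                "meth_count_c", "unmeth_count_c"):
        merged[col] = merged[col].fillna(0).astype(np.int64)
    merged["context"] = merged["context_t"].fillna(merged["context_c"])
    if config.scan_context != "joint":
        merged = merged[merged["context"] == config.scan_context]
    merged = merged.sort_values(["chrom", "pos", "strand"])
    out = {}
    for chrom, sub in merged.groupby("chrom", sort=True):
        out[chrom] = {
            "pos": sub["pos"].to_numpy(),
            "mt": sub["meth_count_t"].to_numpy(),
            "ut": sub["unmeth_count_t"].to_numpy(),
            "mc": sub["meth_count_c"].to_numpy(),
            "uc": sub["unmeth_count_c"].to_numpy(),
            "context": sub["context"].to_numpy(),
        }
    return out


def window_starts(chrom_len: int, window: int, step: int) -> np.ndarray:
    """1-based start positions tiling a chromosome; only full windows,
    except a single clamped window on contigs shorter than one window."""
    if chrom_len < window:
        return np.array([1], dtype=np.int64)
    last = chrom_len - window + 1
    return np.arange(1, last + 1, step, dtype=np.int64)


def scan_windows(methylome, config: RunConfig | None = None,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Tile, gate and test sliding windows; returns one row per tested
    window with q-values already BH-adjusted across all tested windows."""
    config = config or RunConfig()
    arrays = _union_arrays(methylome, config)
    sizes = chrom_sizes or methylome.chrom_sizes or {
        c: int(a["pos"].max()) for c, a in arrays.items()}
    rows = []
    for chrom in sorted(arrays):
        a = arrays[chrom]
        clen = sizes.get(chrom, int(a["pos"].max()))
        covered = ((a["mt"] + a["ut"] > 0) & (a["mc"] + a["uc"] > 0))
        cmt = np.concatenate([[0], np.cumsum(np.where(covered, a["mt"], 0))])
        cut = np.concatenate([[0], np.cumsum(np.where(covered, a["ut"], 0))])
        cmc = np.concatenate([[0], np.cumsum(np.where(covered, a["mc"], 0))])
        cuc = np.concatenate([[0], np.cumsum(np.where(covered, a["uc"], 0))])
        csites = np.concatenate([[0], np.cumsum(covered.astype(np.int64))])
        starts = window_starts(clen, config.window_size_bp, config.step_bp)
        clamped = clen < config.window_size_bp
        ends = np.minimum(starts + config.window_size_bp - 1, clen)
        lo = np.searchsorted(a["pos"], starts, "left")
        hi = np.searchsorted(a["pos"], ends, "right")
        n_sites = csites[hi] - csites[lo]
        keep = n_sites > config.min_c_sites
        for s, e, i, j, ns in zip(starts[keep], ends[keep],
                                  lo[keep], hi[keep], n_sites[keep]):
            mt, ut = int(cmt[j] - cmt[i]), int(cut[j] - cut[i])
            mc, uc = int(cmc[j] - cmc[i]), int(cuc[j] - cuc[i])
            lt = mt / (mt + ut)
            lc = mc / (mc + uc)
            rows.append({
                "chrom": chrom, "start": int(s), "end": int(e),
                "n_sites": int(ns), "meth_t": mt, "unmeth_t": ut,
                "meth_c": mc, "unmeth_c": uc,
                "level_treatment": lt, "level_control": lc,
                "fold_change": _fold_change(lt, lc),
                "abs_diff": abs(lt - lc),
                "p_raw": test_window([[mt, ut], [mc, uc]]),
                "clamped": bool(clamped),
            })
    windows = pd.DataFrame(rows, columns=[c for c in WINDOW_COLS if c != "q"])
    windows["q"] = adjust_fdr(windows["p_raw"].to_numpy()) \
        if len(windows) else np.array([])
    return windows[WINDOW_COLS]


def threshold_windows(windows: pd.DataFrame,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """Apply the ratio / absolute-difference / raw-p gates."""
    config = config or RunConfig()
    keep = ((windows["fold_change"] > config.min_fold_change)
            & (windows["abs_diff"] > config.min_abs_diff)
            & (windows["p_raw"] < config.alpha_raw))
    return windows[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# merging

def merge_dmrs(candidates: pd.DataFrame, methylome,
               config: RunConfig | None = None) -> list[DMR]:
    """One-pass merge of significant candidate windows into DMRs.

    Windows on the same chromosome that overlap or are bookended
    (next start = current end + 1) join one DMR; merged-span levels,
    direction and dominant context are recomputed from raw counts.
    """
    config = config or RunConfig()
    cand = candidates[candidates["q"] < config.alpha_fdr]
    cand = cand.sort_values(["chrom", "start"])
    arrays = _union_arrays(methylome, config)
    dmrs: list[DMR] = []
    runs: list[tuple[str, int, int, list]] = []
    for row in cand.itertuples(index=False):
        if runs and runs[-1][0] == row.chrom and row.start <= runs[-1][2] + 1:
            chrom, s, e, members = runs[-1]
            runs[-1] = (chrom, s, max(e, row.end), members + [row])
        else:
            runs.append((row.chrom, row.start, row.end, [row]))
    for i, (chrom, s, e, members) in enumerate(runs, 1):
        a = arrays[chrom]
        lo = np.searchsorted(a["pos"], s, "left")
        hi = np.searchsorted(a["pos"], e, "right")
        covered = ((a["mt"][lo:hi] + a["ut"][lo:hi] > 0)
                   & (a["mc"][lo:hi] + a["uc"][lo:hi] > 0))
        mt = int(a["mt"][lo:hi][covered].sum())
        ut = int(a["ut"][lo:hi][covered].sum())
        mc = int(a["mc"][lo:hi][covered].sum())
        uc = int(a["uc"][lo:hi][covered].sum())
        lt = mt / (mt + ut) if mt + ut else 0.0
        lc = mc / (mc + uc) if mc + uc else 0.0
        ctx = a["context"][lo:hi][covered]
        ctx_counts = {c: int(np.sum(ctx == c)) for c in CONTEXTS}
        dominant = max(CONTEXTS, key=lambda c: (ctx_counts[c],
                                                -CONTEXTS.index(c)))
        dmrs.append(DMR(
            id=f"DMR{i:04d}", chrom=chrom, start=int(s), end=int(e),
            direction="hyper" if lt > lc else "hypo",
            dominant_context=dominant, n_windows=len(members),
            n_sites=int(covered.sum()),
            level_treatment=lt, level_control=lc,
            q_min=float(min(m.q for m in members))))
    return dmrs


def detect_dmrs(methylome, config: RunConfig | None = None,
                chrom_sizes: dict[str, int] | None = None,
                ) -> tuple[pd.DataFrame, list[DMR]]:
    """Full scan -> gate -> FDR -> merge pipeline."""
    config = config or RunConfig()
    windows = scan_windows(methylome, config, chrom_sizes)
    candidates = threshold_windows(windows, config)
    dmrs = merge_dmrs(candidates, methylome, config)
    return windows, dmrs


# ---------------------------------------------------------------------------
# summaries

def qq_coordinates(p_values) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot; expected quantile for
    rank i of n is -log10((i - 0.5) / n)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    i = np.arange(1, n + 1)
    return pd.DataFrame({
        "expected": -np.log10((i - 0.5) / n),
        "observed": -np.log10(np.maximum(p, 1e-300)),
    }).iloc[::-1].reset_index(drop=True)


def dmr_summaries(dmrs: list[DMR], windows: pd.DataFrame | None = None,
                  links: pd.DataFrame | None = None) -> dict:
    """Tabulations used in the result figures: per-chromosome,
    per-direction, per-context (and per-component when gene links are
    given) DMR counts, level quartiles per group, and QQ data from the
    window-level p-values."""
    out: dict = {
        "n_dmrs": len(dmrs),
        "per_chromosome": {},
        "per_direction": {"hyper": 0, "hypo": 0},
        "per_context": {c: 0 for c in CONTEXTS},
    }
    for d in dmrs:
        out["per_chromosome"][d.chrom] = \
            out["per_chromosome"].get(d.chrom, 0) + 1
        out["per_direction"][d.direction] += 1
        out["per_context"][d.dominant_context] += 1
    if dmrs:
        lt = [d.level_treatment for d in dmrs]
        lc = [d.level_control for d in dmrs]
        # type-7 (linear interpolation) quartiles
        out["level_quartiles"] = {
            "treatment": [float(q) for q in np.percentile(lt, [25, 50, 75])],
            "control": [float(q) for q in np.percentile(lc, [25, 50, 75])],
        }
    if links is not None and len(links):
        per_comp: dict[str, int] = {}
        for kinds in links["kinds"]:
            for k in kinds:
                per_comp[k] = per_comp.get(k, 0) + 1
        out["per_component"] = per_comp
    if windows is not None and len(windows):
        out["qq"] = qq_coordinates(windows["p_raw"].to_numpy())
    return out
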