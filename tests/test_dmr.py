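import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dmrscan as ds
from dmrscan.calls import ValidationError
from dmrscan.config import RunConfig
from dmrscan.dmr import (DMR, adjust_fdr, dmr_summaries, merge_dmrs,
                         qq_coordinates, scan_windows,
                         threshold_windows, window_starts)
from dmrscan.dmr import test_window as fisher_window_p
from dmrscan.synth import PlantedDMR, SimulationDesign, simulate, \
    truth_compare
from conftest import make_methylome, site_frame
from oracles import bh_oracle, fisher_two_sided_enum, window_tiling_enum


# ---------------------------------------------------------------------------
# tiling

def test_window_tiling_enumeration():
    assert list(window_starts(1500, 1000, 100)) == [1, 101, 201, 301,
                                                    401, 501]
    assert list(window_starts(1500, 1000, 100)) == \
        window_tiling_enum(1500, 1000, 100)
    # contig shorter than one window -> single clamped window
    assert list(window_starts(600, 1000, 100)) == [1]


def test_site_count_gate_is_strict():
    def methylome(n_sites):
        pos = list(range(10, 10 + 10 * n_sites, 10))
        t = site_frame("c", pos, meth=[2] * n_sites, unmeth=[8] * n_sites)
        c = site_frame("c", pos, meth=[3] * n_sites, unmeth=[7] * n_sites)
        return make_methylome({"t1": t, "c1": c}, chrom_sizes={"c": 1000})

    assert len(scan_windows(methylome(10))) == 0     # exactly 10 -> dropped
    assert len(scan_windows(methylome(11))) == 1     # >10 -> tested


def test_all_zero_coverage_yields_no_windows():
    t = site_frame("c", [100, 200], meth=[0, 0], unmeth=[0, 0])
    c = site_frame("c", [100, 200], meth=[0, 0], unmeth=[0, 0])
    m = make_methylome({"t1": t, "c1": c}, chrom_sizes={"c": 1000})
    assert len(scan_windows(m)) == 0


# ---------------------------------------------------------------------------
# Fisher's exact test

def test_fisher_examples():
    assert fisher_window_p([[3, 0], [0, 3]]) == pytest.approx(0.1)
    assert fisher_window_p([[5, 5], [5, 5]]) == 1.0
    assert fisher_window_p([[0, 0], [3, 7]]) == 1.0      # zero margin
    with pytest.raises(ValidationError):
        fisher_window_p([[0, 0], [0, 0]])
    with pytest.raises(ValidationError):
        fisher_window_p([[-1, 2], [3, 4]])


@given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
       st.integers(0, 12))
def test_fisher_matches_enumeration_oracle(a, b, c, d):
    if a + b + c + d == 0:
        return
    assert fisher_window_p([[a, b], [c, d]]) == \
        pytest.approx(fisher_two_sided_enum(a, b, c, d), abs=1e-12)


# ---------------------------------------------------------------------------
# BH correction

def test_bh_step_up_by_hand():
    np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(adjust_fdr([0.05]), [0.05])
    assert len(adjust_fdr([])) == 0
    with pytest.raises(ValidationError):
        adjust_fdr([0.5, 1.5])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
def test_bh_matches_direct_minimisation(p):
    q = adjust_fdr(p)
    np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
    assert np.all(q >= np.asarray(p) - 1e-12)       # q >= p under BH
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-12)      # order-preserving


# ---------------------------------------------------------------------------
# gates

def _window_row(lt, lc, p=0.01):
    fc = max(lt, lc) / min(lt, lc) if min(lt, lc) > 0 else \
        (np.inf if max(lt, lc) > 0 else 1.0)
    return {"chrom": "c", "start": 1, "end": 1000, "n_sites": 20,
            "meth_t": 1, "unmeth_t": 1, "meth_c": 1, "unmeth_c": 1,
            "level_treatment": lt, "level_control": lc,
            "fold_change": fc, "abs_diff": abs(lt - lc), "p_raw": p,
            "q": p, "clamped": False}


def test_threshold_gates():
    wins = pd.DataFrame([
        _window_row(0.4, 0.1),           # FC 4, diff 0.3 -> passes
        _window_row(0.15, 0.10),         # FC 1.5 -> fails
        _window_row(0.22, 0.10, p=0.04),  # FC 2.2, diff 0.12 -> passes
        _window_row(0.3, 0.1, p=0.2),    # p gate fails
        _window_row(0.02, 0.0),          # FC inf but diff 0.02 -> fails
    ])
    kept = threshold_windows(wins)
    assert list(kept["level_treatment"]) == [0.4, 0.22]


# ---------------------------------------------------------------------------
# merging

def _uniform_methylome():
    pos = list(range(50, 1301, 25))
    n = len(pos)
    t = site_frame("c", pos, meth=[8] * n, unmeth=[2] * n)
    c = site_frame("c", pos, meth=[1] * n, unmeth=[9] * n)
    return make_methylome({"t1": t, "c1": c}, chrom_sizes={"c": 1300})


def test_merge_overlapping_and_bookended():
    m = _uniform_methylome()
    cand = pd.DataFrame([
        dict(_window_row(0.8, 0.1), chrom="c", start=101, end=1100, q=0.01),
        dict(_window_row(0.8, 0.1), chrom="c", start=201, end=1200, q=0.02),
    ])
    dmrs = merge_dmrs(cand, m)
    assert len(dmrs) == 1
    assert (dmrs[0].start, dmrs[0].end) == (101, 1200)
    assert dmrs[0].direction == "hyper"
    assert dmrs[0].q_min == 0.01
    assert dmrs[0].n_windows == 2
    # merged-span levels recomputed from raw counts
    assert dmrs[0].level_treatment == pytest.approx(0.8)
    assert dmrs[0].level_control == pytest.approx(0.1)


def test_disjoint_candidates_stay_separate():
    m = _uniform_methylome()
    cand = pd.DataFrame([
        dict(_window_row(0.8, 0.1), chrom="c", start=101, end=400, q=0.01),
        dict(_window_row(0.8, 0.1), chrom="c", start=402, end=700, q=0.01),
        dict(_window_row(0.8, 0.1), chrom="c", start=701, end=1000, q=0.01),
    ])
    dmrs = merge_dmrs(cand, m)
    # gap of 1 bp between 400 and 402 separates; 700/701 are bookended
    assert [(d.start, d.end) for d in dmrs] == [(101, 400), (402, 1000)]


def test_planted_region_recovered_as_single_dmr():
    planted = (PlantedDMR("chr1", 20_001, 21_500, "hypo", 0.2),)
    design = SimulationDesign(genome_length_bp=50_000, n_chromosomes=1,
                              n_genes=4, planted_dmrs=planted,
                              coverage_mean=20.0, rng_seed=13)
    b = simulate(design)
    _, dmrs = ds.detect_dmrs(b.methylome)
    assert len(dmrs) == 1
    d = dmrs[0]
    assert d.direction == "hypo"
    covered = (min(d.end, 21_500) - max(d.start, 20_001) + 1) / 1500
    assert covered >= 0.9
    tc = truth_compare(dmrs, b.truth)
    assert tc.sensitivity == 1.0 and tc.precision == 1.0


def test_fold_change_gate_monotonicity(bundle, detected):
    windows, _ = detected
    counts = []
    for fc in (2.0, 3.0, 4.0, 6.0):
        cfg = RunConfig(min_fold_change=fc)
        cand = threshold_windows(windows, cfg)
        counts.append(len(merge_dmrs(cand, bundle.methylome, cfg)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# summaries

def _fake_dmrs(n_hyper, n_hypo):
    out = []
    levels = [0.1, 0.2, 0.3, 0.4]
    for i in range(n_hyper + n_hypo):
        lv = levels[i % 4]
        out.append(DMR(id=f"D{i}", chrom="c", start=1 + 2000 * i,
                       end=1000 + 2000 * i,
                       direction="hyper" if i < n_hyper else "hypo",
                       dominant_context="CHH", n_windows=1, n_sites=20,
                       level_treatment=lv, level_control=lv / 2,
                       q_min=0.01))
    return out


def test_direction_counts_and_quartiles():
    summ = dmr_summaries(_fake_dmrs(30, 41))
    assert summ["per_direction"] == {"hyper": 30, "hypo": 41}
    # linear-interpolation quartiles of [0.1, 0.2, 0.3, 0.4]
    dmrs = [d for d in _fake_dmrs(4, 0)]
    q = dmr_summaries(dmrs)["level_quartiles"]["treatment"]
    assert q == pytest.approx([0.175, 0.25, 0.325])


def test_qq_uniform_pvalues_on_diagonal():
    rng = np.random.default_rng(2)
    qq = qq_coordinates(rng.random(5000))
    close = np.abs(qq["observed"] - qq["expected"]) < 0.25
    assert close.mean() > 0.95
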