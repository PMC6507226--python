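import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dmrscan as ds
from dmrscan._util import revcomp
from dmrscan.calls import (CONTEXTS, ValidationError, call_methylated_sites,
                           classify_context, compare_group_totals,
                           estimate_conversion, genome_context_totals,
                           summarize_contexts)
from conftest import site_frame


# ---------------------------------------------------------------------------
# context classification

@pytest.mark.parametrize("seq,pos,expected", [
    ("ACGTA", 2, "CG"),
    ("ACAGT", 2, "CHG"),
    ("ACTTA", 2, "CHH"),
    ("ACGN", 2, "CG"),      # second downstream base not needed for CG
    ("ACN", 2, "unknown"),  # needed base is N
    ("AAAC", 4, "unknown"),  # fewer than 2 downstream bases
])
def test_forward_contexts(seq, pos, expected):
    g = ds.GenomeStore({"c": seq})
    assert classify_context(g, "c", pos, "+") == expected


def test_reverse_strand_cg():
    # G at forward pos 4 of TACGT is a minus-strand C whose next minus-
    # strand base (forward pos 3, complemented) is G -> CG
    g = ds.GenomeStore({"c": "TACGT"})
    assert classify_context(g, "c", 4, "-") == "CG"


def test_not_a_cytosine_raises(toy_genome):
    with pytest.raises(ValidationError, match="no cytosine"):
        classify_context(toy_genome, "chrA", 1, "+")   # A
    with pytest.raises(ValidationError):
        classify_context(toy_genome, "chrA", 2, "-")   # C, but not on -


def test_reverse_contexts_match_forward_on_revcomp():
    """Brute-force complement oracle: classifying (pos, -) on a sequence
    must equal classifying the mirrored position on the reverse
    complement read forward."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    g = ds.GenomeStore({"c": seq})
    g_rc = ds.GenomeStore({"c": revcomp(seq)})
    L = len(seq)
    for pos in range(1, L + 1):
        if seq[pos - 1] != "G":
            continue
        mirrored = L - pos + 1
        assert classify_context(g, "c", pos, "-") == \
            classify_context(g_rc, "c", mirrored, "+")


def test_genome_context_totals_small():
    # ACGCAGCTT: forward Cs at 2 (CG), 4 (CHG: C-A-G), 7 (CHH: C-T-T);
    # reverse Gs at 3 (next - base = complement of pos2 C = G -> CG),
    # 6 (complement walk A,C -> ...), edge cases excluded as unknown
    g = ds.GenomeStore({"c": "ACGCAGCTT"})
    totals = genome_context_totals(g)
    assert totals["CG"] >= 2 and sum(totals.values()) >= 4


# ---------------------------------------------------------------------------
# conversion rate

def test_estimate_conversion_arithmetic():
    df = site_frame("sp", [1, 2], meth=[5, 0], unmeth=[500, 495])
    est = estimate_conversion(df)
    assert est.n_cytosines_observed == 1000
    assert est.conversion_rate == pytest.approx(0.995)
    zero = site_frame("sp", [1], meth=[0], unmeth=[100])
    assert estimate_conversion(zero).conversion_rate == 1.0
    with pytest.raises(ValidationError):
        estimate_conversion(site_frame("sp", [1], meth=[0], unmeth=[0]))


def test_conversion_recovered_from_simulation(bundle):
    est = estimate_conversion(bundle.spikein)
    f = bundle.truth["conversion_failure"]
    sd = np.sqrt(f * (1 - f) / est.n_cytosines_observed)
    assert abs(est.failure_rate - f) < 3 * sd


# ---------------------------------------------------------------------------
# site calling

def test_site_calling_rule():
    tables = {"s": site_frame("c", [10, 20, 30],
                              meth=[5, 0, 3], unmeth=[5, 10, 0])}
    # pos 30 has coverage 3 < 4 -> never called; pos 20 meth=0 -> not
    called = call_methylated_sites(tables, failure_rate=0.005,
                                   min_site_coverage=4,
                                   site_call_alpha=0.05)["s"]
    assert list(called["pos"]) == [10]
    with pytest.raises(ValidationError):
        call_methylated_sites(tables, failure_rate=1.0)


@given(st.integers(0, 20), st.integers(0, 20))
def test_site_calling_monotone_in_meth_count(m1, m2):
    """At fixed coverage, calling is monotone in the methylated count."""
    cov = 20
    tables = {"s": site_frame("c", [10, 20], meth=[min(m1, m2), max(m1, m2)],
                              unmeth=[cov - min(m1, m2), cov - max(m1, m2)])}
    called = call_methylated_sites(tables, 0.01)["s"]
    if 10 in set(called["pos"]):
        assert 20 in set(called["pos"])


def test_raising_failure_rate_never_adds_calls(bundle):
    t = {"s": bundle.methylome.tables["treatment_1"]}
    lo = set(call_methylated_sites(t, 0.005)["s"]["pos"])
    hi = set(call_methylated_sites(t, 0.02)["s"]["pos"])
    assert hi <= lo


# ---------------------------------------------------------------------------
# context summaries

def test_summarize_contexts_reproduces_published_percentages():
    control = summarize_contexts({"CG": 15854, "CHG": 12243, "CHH": 37246})
    assert control.percents == {"CG": 24.26, "CHG": 18.74, "CHH": 57.00}
    treated = summarize_contexts({"CG": 12397, "CHG": 9880, "CHH": 30678})
    assert treated.percents == {"CG": 23.41, "CHG": 18.66, "CHH": 57.93}
    sym = summarize_contexts({"CG": 1, "CHG": 1, "CHH": 1})
    assert sym.percents == {"CG": 33.33, "CHG": 33.33, "CHH": 33.33}


@given(st.lists(st.integers(0, 10**6), min_size=3, max_size=3))
def test_percents_sum_to_100_within_rounding(counts):
    s = summarize_contexts(dict(zip(CONTEXTS, counts)))
    if s.total:
        assert abs(sum(s.percents.values()) - 100) <= 0.02


def test_summary_from_called_frame(called_sites):
    s = summarize_contexts(called_sites["control"])
    assert s.total == len(called_sites["control"])
    assert set(s.counts) == set(CONTEXTS)


# ---------------------------------------------------------------------------
# group comparison

def test_compare_group_totals():
    a = summarize_contexts({"CG": 3, "CHG": 3, "CHH": 3})
    b = summarize_contexts({"CG": 0, "CHG": 3, "CHH": 3})
    totals = {c: 3 for c in CONTEXTS}
    res = compare_group_totals(a, b, totals).set_index("context")
    # identical counts -> p = 1; [[3,0],[0,3]] -> p = 2/20
    assert res.loc["CHG", "p"] == 1.0
    assert res.loc["CG", "p"] == pytest.approx(0.1)
    assert res.loc["CG", "direction"] == "a>b"


def test_compare_group_totals_at_published_magnitudes():
    a = summarize_contexts({"CG": 15854, "CHG": 12243, "CHH": 37246})
    b = summarize_contexts({"CG": 12397, "CHG": 9880, "CHH": 30678})
    totals = {c: 5_000_000 for c in CONTEXTS}
    res = compare_group_totals(a, b, totals)
    assert (res["p"] < 0.05).all()
    assert (res["direction"] == "a>b").all()
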