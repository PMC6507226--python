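import numpy as np
import pandas as pd
import pytest

from dmrscan.annotate import (OverlapTest, correlate_methylation_expression,
                              enrich_terms, link_dmrs_to_genes,
                              overlap_with_degs,
                              overlap_with_random_intervals)
from dmrscan.calls import ValidationError
from dmrscan.dmr import DMR
from dmrscan.io import build_gene_model
from oracles import hypergeom_upper_enum


def _dmr(start, end, direction="hypo", chrom="c", id_=None):
    return DMR(id=id_ or f"D{start}", chrom=chrom, start=start, end=end,
               direction=direction, dominant_context="CHH", n_windows=1,
               n_sites=15, level_treatment=0.1, level_control=0.3,
               q_min=0.01)


@pytest.fixture()
def gene_set():
    a = build_gene_model("A", "c", "+", [(5000, 5200), (5400, 5600)])
    b = build_gene_model("B", "c", "+", [(20_000, 20_500)])
    return [a, b]


def test_link_promoter_containment(gene_set):
    links, dmg, counts = link_dmrs_to_genes([_dmr(3500, 3700)], gene_set)
    assert dmg == {"A"}
    assert links.iloc[0]["kinds"] == {"promoter"}
    assert counts == {"hyper": 0, "hypo": 1, "ambiguous": []}


def test_link_spanning_exon_intron_junction(gene_set):
    links, _, _ = link_dmrs_to_genes([_dmr(5150, 5250)], gene_set)
    assert links.iloc[0]["kinds"] == {"exon", "intron"}


def test_many_dmrs_fewer_genes(gene_set):
    dmrs = [_dmr(3500, 3700, "hypo"), _dmr(5100, 5300, "hypo"),
            _dmr(20_100, 20_200, "hyper"), _dmr(20_300, 20_400, "hyper")]
    links, dmg, counts = link_dmrs_to_genes(dmrs, gene_set)
    assert len(dmrs) == 4 and dmg == {"A", "B"}   # many-to-one structure
    assert counts["hyper"] == 1 and counts["hypo"] == 1


def test_gene_hit_in_both_directions_is_ambiguous(gene_set):
    dmrs = [_dmr(5100, 5200, "hypo"), _dmr(5400, 5500, "hyper")]
    _, _, counts = link_dmrs_to_genes(dmrs, gene_set)
    assert counts["ambiguous"] == ["A"]


def test_links_invariant_under_joint_coordinate_shift(gene_set):
    dmrs = [_dmr(3500, 3700), _dmr(5150, 5250)]
    links, _, _ = link_dmrs_to_genes(dmrs, gene_set)
    shift = 10_000
    shifted_genes = [build_gene_model(
        g.gene_id, g.chrom, g.strand,
        [(c.start + shift, c.end + shift) for c in g.of_kind("exon")])
        for g in gene_set]
    shifted_dmrs = [_dmr(d.start + shift, d.end + shift, d.direction)
                    for d in dmrs]
    shifted_links, _, _ = link_dmrs_to_genes(shifted_dmrs, shifted_genes)
    assert list(links["kinds"]) == list(shifted_links["kinds"])
    assert list(links["gene_id"]) == list(shifted_links["gene_id"])


# ---------------------------------------------------------------------------
# enrichment

def _genes(n, prefix="g"):
    return {f"{prefix}{i}" for i in range(n)}


def test_enrichment_exact_example():
    background = {f"g{i}" for i in range(20)}
    term = {f"g{i}" for i in range(5)}              # K = 5
    dmg = {"g0", "g1", "g2", "g10"}                 # n = 4, k = 3
    row = enrich_terms(dmg, background, {"T": term}).iloc[0]
    assert row["p_raw"] == pytest.approx(155 / 4845)
    assert (row["k"], row["K"], row["n"], row["N"]) == (3, 5, 4, 20)


def test_enrichment_identity_cases():
    background = _genes(10)
    dmg = {"g0", "g1"}
    # k = 0 -> P(X >= 0) = 1
    row = enrich_terms(dmg, background, {"T": {"g8", "g9"}}).iloc[0]
    assert row["p_raw"] == 1.0
    # DMG = background -> k = K for every term -> p = 1
    rows = enrich_terms(background, background,
                        {"T1": {"g1", "g2"}, "T2": {"g3"}})
    assert (rows["p_raw"] == 1.0).all()
    # empty terms are skipped
    assert len(enrich_terms(dmg, background, {"T": {"zz"}})) == 0
    with pytest.raises(ValidationError):
        enrich_terms({"not_there"}, background, {"T": {"g1"}})


def test_enrichment_matches_enumeration_oracle():
    rng = np.random.default_rng(4)
    for _ in range(40):
        N = int(rng.integers(2, 26))
        background = _genes(N)
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        term = set(rng.choice(sorted(background), size=K, replace=False))
        dmg = set(rng.choice(sorted(background), size=n, replace=False))
        row = enrich_terms(dmg, background, {"T": term}).iloc[0]
        expect = hypergeom_upper_enum(len(term & dmg), N, K, n)
        assert row["p_raw"] == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# DMG x DEG overlap

def test_overlap_identity_and_truncation():
    deg = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                        "log2fc": 1.0})
    universe = _genes(50)
    dmg = set(deg["gene_id"])
    res = overlap_with_degs(dmg, deg, universe, n_permutations=10,
                            rng_seed=0)
    assert res.observed_overlap == 10 and res.pct_of_deg == 100.0

    published = OverlapTest(n_deg=1971, n_dmg=63, observed_overlap=37,
                            null_overlaps=(0,) * 25)
    assert published.pct_of_deg == 1.87          # 37/1971 truncates
    assert published.empirical_p == pytest.approx(1 / 26)


def test_null_overlap_mean_matches_hypergeometric_expectation():
    universe = _genes(1000)
    deg_ids = sorted(universe)[:100]
    deg = pd.DataFrame({"gene_id": deg_ids, "log2fc": 1.0})
    dmg = set(sorted(universe)[-50:])
    res = overlap_with_degs(dmg, deg, universe, n_permutations=2000,
                            rng_seed=1)
    assert np.mean(res.null_overlaps) == pytest.approx(5.0, abs=0.3)
    assert len(res.null_overlaps) == 2000


def test_overlap_validation():
    deg = pd.DataFrame({"gene_id": ["g1"], "log2fc": 1.0})
    with pytest.raises(ValidationError):
        overlap_with_degs({"a", "b", "c"}, deg, {"g1", "g2"},
                          n_permutations=2)


def test_empirical_p_well_calibrated_under_null():
    """With DMG itself a uniform random draw, the permutation p-value is
    near-uniform: its mean over seeds should be ~0.5."""
    universe = sorted(_genes(200))
    deg = pd.DataFrame({"gene_id": universe[:40], "log2fc": 1.0})
    rng = np.random.default_rng(8)
    ps = []
    for seed in range(30):
        dmg = set(rng.choice(universe, size=30, replace=False))
        res = overlap_with_degs(dmg, deg, set(universe),
                                n_permutations=200, rng_seed=seed)
        ps.append(res.empirical_p)
    assert 0.35 < np.mean(ps) < 0.65


def test_interval_placement_null(gene_set):
    deg = pd.DataFrame({"gene_id": ["A", "B"], "log2fc": [1.0, -2.0]})
    nulls = overlap_with_random_intervals(
        [_dmr(3500, 3700)], gene_set, {"c": 30_000}, deg,
        n_permutations=50, rng_seed=0)
    assert len(nulls) == 50 and all(0 <= x <= 2 for x in nulls)


# ---------------------------------------------------------------------------
# methylation / expression concordance

def test_concordance_labels():
    links = pd.DataFrame({
        "dmr_id": ["d1", "d2", "d3", "d4"],
        "gene_id": ["up_hypo", "up_hyper", "no_deg", "down_hypo"],
        "direction": ["hypo", "hyper", "hypo", "hypo"],
        "kinds": [frozenset({"exon"})] * 4,
    })
    deg = pd.DataFrame({"gene_id": ["up_hypo", "up_hyper", "down_hypo"],
                        "log2fc": [2.0, 1.5, -1.0]})
    res = correlate_methylation_expression(links, deg).set_index("gene_id")
    assert res.loc["up_hypo", "label"] == "negative-correlated"
    assert res.loc["up_hyper", "label"] == "positive-correlated"
    assert res.loc["down_hypo", "label"] == "positive-correlated"
    assert res.loc["no_deg", "label"] == "unmatched"
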