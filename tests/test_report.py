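"""Consensus calling, enrichment, group comparison, correlation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from codonsel.annotations import ExpressionRecord, IntervalAnnotation
from codonsel.errors import UsageError
from codonsel.rates import SiteScores
from codonsel.report import (
    ConsensusCall,
    consensus_calls,
    group_dn_minus_ds_compare,
    idr_enrichment,
    rate_expression_correlation,
    selected_calls,
)
from codonsel.sitemodels import BEBScores


def make_inputs(beb, fubar, fel_p, fel_dir, site_map=None):
    n = len(beb)
    scores = SiteScores(
        n_sites=n,
        fubar_post_positive=np.asarray(fubar, float),
        fel_p=np.asarray(fel_p, float),
        fel_direction=list(fel_dir),
    )
    bs = BEBScores(
        post_positive=np.asarray(beb, float), post_mean_omega=np.ones(n)
    )
    sm = np.asarray(site_map) if site_map is not None else np.arange(1, n + 1)
    return bs, scores, sm


class TestConsensus:
    def test_two_methods_select(self):
        bs, sc, sm = make_inputs([0.95], [0.85], [0.05], ["positive"])
        calls = consensus_calls(bs, sc, sm)
        assert calls[0].selected and calls[0].methods == {"BEB", "FEL"}

    def test_single_method_not_selected(self):
        bs, sc, sm = make_inputs([0.99], [0.5], [0.5], ["none"])
        calls = consensus_calls(bs, sc, sm)
        assert len(calls) == 1 and not calls[0].selected

    def test_negative_fel_direction_excluded(self):
        bs, sc, sm = make_inputs([0.91], [0.92], [0.05], ["negative"])
        calls = consensus_calls(bs, sc, sm)
        assert calls[0].selected and calls[0].methods == {"BEB", "FUBAR"}

    def test_unmapped_site_reported_in_alignment_coords(self):
        bs, sc, sm = make_inputs([0.95, 0.95], [0.95, 0.95], [1, 1], ["none"] * 2,
                                 site_map=[-1, 1])
        calls = consensus_calls(bs, sc, sm)
        unmapped = [c for c in calls if c.site_ref is None]
        assert len(unmapped) == 1 and unmapped[0].site_aln == 1

    def test_invalid_cutoff_rejected(self):
        bs, sc, sm = make_inputs([0.5], [0.5], [0.5], ["none"])
        with pytest.raises(UsageError):
            consensus_calls(bs, sc, sm, cutoffs={"beb": 1.5})

    def test_loosening_cutoffs_never_removes_calls(self):
        rng = np.random.default_rng(5)
        n = 40
        bs, sc, sm = make_inputs(
            rng.random(n), rng.random(n), rng.random(n),
            rng.choice(["positive", "negative", "none"], n),
        )
        tight = {"beb": 0.95, "fubar": 0.95, "fel_p": 0.05}
        loose = {"beb": 0.85, "fubar": 0.80, "fel_p": 0.2}
        sel_tight = {c.site_ref for c in selected_calls(consensus_calls(bs, sc, sm, cutoffs=tight))}
        sel_loose = {c.site_ref for c in selected_calls(consensus_calls(bs, sc, sm, cutoffs=loose))}
        assert sel_tight <= sel_loose

    def test_idr_and_motif_annotation(self):
        bs, sc, sm = make_inputs([0.95], [0.95], [1.0], ["none"])
        ivs = [
            IntervalAnnotation("g", "IDR", 1, 40),
            IntervalAnnotation("g", "MOTIF", 1, 3, label="PKC"),
        ]
        calls = consensus_calls(bs, sc, sm, intervals=ivs)
        assert calls[0].in_idr and calls[0].in_motif == "PKC"


def sel(site_refs):
    return [
        ConsensusCall(gene="g", site_ref=r, methods=frozenset({"BEB", "FEL"}), selected=True)
        for r in site_refs
    ]


class TestEnrichment:
    IDR = [IntervalAnnotation("g", "IDR", 1, 50)]

    def test_closed_form_all_inside(self):
        # n=10, k=10, p0=0.5 -> p = 0.5^10
        res = idr_enrichment(sel(range(1, 11)), self.IDR, 100)
        assert res.idr_fraction == pytest.approx(0.5)
        assert res.p_value == pytest.approx(0.5**10)

    def test_k_zero_gives_one(self):
        res = idr_enrichment(sel([60, 70, 80]), self.IDR, 100)
        assert res.k_in_idr == 0 and res.p_value == 1.0

    def test_matches_pmf_tail_summation(self):
        # n=6, k=4, p0=0.3 against explicit pmf summation
        ivs = [IntervalAnnotation("g", "IDR", 1, 30)]
        res = idr_enrichment(sel([1, 2, 3, 4, 50, 60]), ivs, 100)
        exact = sum(
            sps.binom.pmf(i, 6, 0.3) for i in range(4, 7)
        )
        assert res.p_value == pytest.approx(exact, rel=1e-10)

    def test_no_selected_sites_degenerate(self):
        res = idr_enrichment([], self.IDR, 100)
        assert res.degenerate and res.p_value == 1.0 and res.n_sites == 0

    def test_monotone_in_k_and_p0(self):
        p_small_k = idr_enrichment(sel([1, 2, 60, 70, 80]), self.IDR, 100).p_value
        p_large_k = idr_enrichment(sel([1, 2, 3, 4, 80]), self.IDR, 100).p_value
        assert p_large_k < p_small_k
        wide = [IntervalAnnotation("g", "IDR", 1, 80)]
        p_wide = idr_enrichment(sel([1, 2, 3, 4, 90]), wide, 100).p_value
        assert p_wide > p_large_k

    def test_overlapping_intervals_merged(self):
        ivs = [
            IntervalAnnotation("g", "IDR", 1, 50),
            IntervalAnnotation("g", "IDR", 20, 60),
        ]
        res = idr_enrichment(sel([10]), ivs, 120)
        assert res.idr_fraction == pytest.approx(0.5)


class TestGroupCompare:
    def test_identical_groups(self):
        x = np.arange(10.0)
        res = group_dn_minus_ds_compare({"a": x, "b": x.copy()})
        assert res.p_value > 0.9
        assert res.pairwise_p[("a", "b")] > 0.9

    def test_hand_ranked_h_statistic(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            "b": np.array([6.0, 7.0, 8.0, 9.0, 10.0]),
            "c": np.array([11.0, 12.0, 13.0, 14.0, 15.0]),
        }
        # no ties: H = 12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)
        n_tot = 15
        mean_ranks = [3.0, 8.0, 13.0]
        h_hand = 12.0 / (n_tot * 16) * sum(5 * r * r for r in mean_ranks) - 3 * 16
        res = group_dn_minus_ds_compare(groups)
        assert res.h_stat == pytest.approx(h_hand, rel=1e-10)

    def test_shifted_groups_detected(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            groups = {
                "a": rng.normal(0, 1, 100),
                "b": rng.normal(1, 1, 100),
            }
            res = group_dn_minus_ds_compare(groups)
            assert res.p_value < 1e-3
            assert res.pairwise_p[("a", "b")] < 0.01

    def test_preconditions(self):
        with pytest.raises(UsageError):
            group_dn_minus_ds_compare({"a": np.arange(10.0)})
        with pytest.raises(UsageError):
            group_dn_minus_ds_compare({"a": np.arange(10.0), "b": np.arange(3.0)})


def tau_b_oracle(x, y):
    """Brute-force Kendall tau-b over all C(n,2) pairs, with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


def correlate(x, y):
    genes = [f"g{i}" for i in range(len(x))]
    rates = dict(zip(genes, map(float, x)))
    expr = [ExpressionRecord(g, "leptotene_F", float(v)) for g, v in zip(genes, y)]
    return rate_expression_correlation(rates, expr, "leptotene_F")


class TestCorrelation:
    def test_perfect_concordance(self):
        res = correlate([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.tau == pytest.approx(1.0)
        assert res.rho == pytest.approx(1.0)

    def test_perfect_discordance(self):
        res = correlate([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.tau == pytest.approx(-1.0)

    def test_pair_enumeration_example(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        res = correlate(x, y)
        assert res.tau == pytest.approx(tau_b_oracle(x, y))

    def test_too_few_pairs(self):
        with pytest.raises(UsageError):
            correlate([1, 2, 3], [1, 2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=4, max_size=8),
        st.data(),
    )
    def test_tau_matches_oracle_up_to_length_8(self, x, data):
        y = data.draw(st.lists(st.integers(-5, 5), min_size=len(x), max_size=len(x)))
        # gene rates must be joinable: x values are per-gene, keep unique genes
        if len(set(zip(x, y))) < 4:
            return
        oracle = tau_b_oracle(x, y)
        if not np.isfinite(oracle):
            return  # fully tied margin: tau undefined
        res = correlate(x, y)
        assert res.tau == pytest.approx(oracle, abs=1e-10)
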