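"""The statistical core: hypergeometric tail, corrections, the test itself."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bh_step_up, tail_by_enumeration
from conftest import make_annotations, make_ontology
from oranet import (
    DomainError,
    OverRepresentationAnalysis,
    QueryInput,
    ValidationError,
    adjust_bh,
    adjust_bonferroni,
    build_term_index,
    enrich,
    hypergeom_upper_tail,
    hypergeom_upper_tail_exact,
)


class TestHypergeomUpperTail:
    def test_x_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 5, 20) == 1.0

    def test_fully_annotated_background_is_one(self):
        assert hypergeom_upper_tail(3, 3, 8, 8) == pytest.approx(1.0, abs=1e-12)

    # expected values computed with the subset-enumeration oracle, which also
    # pins them to the closed-form rational sums 1126/15504 and 6/252
    @pytest.mark.parametrize(
        "x,k,m,N,expected",
        [
            (3, 5, 5, 20, Fraction(1126, 15504)),
            (4, 5, 4, 10, Fraction(6, 252)),
        ],
    )
    def test_worked_values_all_three_routes(self, x, k, m, N, expected):
        assert tail_by_enumeration(x, k, m, N) == expected
        assert hypergeom_upper_tail_exact(x, k, m, N) == expected
        assert hypergeom_upper_tail(x, k, m, N) == pytest.approx(float(expected), abs=1e-12)

    def test_matches_enumeration_on_small_grid(self):
        for N in range(1, 9):
            for k in range(1, min(5, N) + 1):
                for m in range(N + 1):
                    for x in range(min(m, k) + 1):
                        exact = tail_by_enumeration(x, k, m, N)
                        assert hypergeom_upper_tail(x, k, m, N) == pytest.approx(
                            float(exact), abs=1e-12
                        )

    def test_matches_scipy_sf_at_scale(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(3)
        for _ in range(200):
            N = int(rng.integers(10, 100_000))
            k = int(rng.integers(1, min(N, 500) + 1))
            m = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(m, k) + 1))
            ours = hypergeom_upper_tail(x, k, m, N)
            ref = hypergeom.sf(x - 1, N, m, k)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_monotone_nonincreasing_in_x(self):
        ps = [hypergeom_upper_tail(x, 10, 30, 100) for x in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_pmf_normalization(self):
        # tail differences are the pmf; they must sum to one
        N, m, k = 60, 25, 12
        tails = [hypergeom_upper_tail(x, k, m, N) for x in range(min(m, k) + 1)] + [0.0]
        pmf = [a - b for a, b in zip(tails, tails[1:])]
        assert all(v >= -1e-15 for v in pmf)
        assert math.fsum(pmf) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "x,k,m,N,fragment",
        [
            (6, 5, 10, 20, "min(m, k)"),
            (1, 5, 25, 20, "m <= N"),
            (1, 25, 5, 20, "k <= N"),
            (-1, 5, 5, 20, "min(m, k)"),
        ],
    )
    def test_domain_errors_name_violated_inequality(self, x, k, m, N, fragment):
        with pytest.raises(DomainError, match=__import__("re").escape(fragment)):
            hypergeom_upper_tail(x, k, m, N)

    def test_exact_and_log_paths_agree_at_moderate_n(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(10, 1000))
            k = int(rng.integers(1, min(N, 80) + 1))
            m = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(m, k) + 1))
            assert hypergeom_upper_tail(x, k, m, N) == pytest.approx(
                float(hypergeom_upper_tail_exact(x, k, m, N)), rel=1e-11, abs=1e-300
            )


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.5]) == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_single_test_is_identity(self):
        assert adjust_bh([0.3]) == [0.3]

    def test_empty_input(self):
        assert adjust_bh([]) == []

    def test_matches_independent_step_up_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 40))).tolist()
            ours = adjust_bh(p)
            assert ours == pytest.approx(bh_step_up(p), abs=1e-12)
            ref = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(ref.tolist(), abs=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0, allow_nan=False), min_size=1, max_size=30))
    def test_properties_never_below_input_and_monotone(self, p):
        q = adjust_bh(p)
        assert all(qi >= pi - 1e-15 and qi <= 1.0 for pi, qi in zip(p, q))
        order = sorted(range(len(p)), key=lambda i: p[i])
        resorted = [q[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(resorted, resorted[1:]))


class TestAdjustBonferroni:
    def test_product_and_cap(self):
        assert adjust_bonferroni([0.01, 0.2], M_effective=19) == [0.19, 1.0]

    def test_m_effective_one_is_identity(self):
        assert adjust_bonferroni([0.3], M_effective=1) == [0.3]

    def test_invalid_multiplier(self):
        with pytest.raises(DomainError):
            adjust_bonferroni([0.1], M_effective=0)


def _simple_index(n_bg=20, term_genes=None):
    onto = make_ontology({t: [] for t in (term_genes or {"GO:T": []})})
    pairs = [(g, t) for t, genes in term_genes.items() for g in genes]
    ann = make_annotations(pairs)
    return build_term_index(ann, onto, "BP", background_ids=[f"g{i}" for i in range(n_bg)])


class TestEnrich:
    def test_saturated_query_nothing_significant(self):
        idx = _simple_index(20, {"GO:T": [f"g{i}" for i in range(5)],
                                 "GO:U": [f"g{i}" for i in range(3, 9)]})
        report = enrich(QueryInput(query_ids=[f"g{i}" for i in range(20)]), idx)
        assert all(r.p_value == pytest.approx(1.0) for r in report.results)
        assert not report.significant_results
        assert all(r.counts.x == r.counts.m for r in report.results)

    def test_planted_term_ranks_first_and_passes_bh(self, planted_report):
        report, fx, _ = planted_report
        truth = fx.truth[0]
        top = report.results[0]
        assert top.term_id == truth.term_id
        assert top.counts.x == truth.x and top.counts.m == truth.m
        assert (top.counts.k, top.counts.N) == (truth.k, truth.N)
        assert top.significant and top.p_adjusted < 1e-10

    def test_significance_flag_matches_threshold(self, planted_report):
        report, _, _ = planted_report
        n_sig = sum(1 for r in report.results if r.p_adjusted <= report.alpha)
        assert len(report.significant_results) == n_sig

    def test_unmatched_ids_reported_and_excluded_from_k(self):
        idx = _simple_index(10, {"GO:T": ["g0", "g1", "g2"]})
        report = enrich(QueryInput(query_ids=["g0", "g1", "nope"]), idx)
        assert report.k == 2
        assert report.unmatched_query_ids == {"nope"}

    def test_no_query_in_background_raises(self):
        idx = _simple_index(10, {"GO:T": ["g0"]})
        with pytest.raises(ValidationError, match="background"):
            enrich(QueryInput(query_ids=["absent"]), idx)

    def test_query_order_invariance(self):
        idx = _simple_index(20, {"GO:T": [f"g{i}" for i in range(6)],
                                 "GO:U": [f"g{i}" for i in range(4, 12)]})
        ids = [f"g{i}" for i in range(0, 10)]
        r1 = enrich(QueryInput(query_ids=ids), idx)
        r2 = enrich(QueryInput(query_ids=list(reversed(ids))), idx)
        assert [(r.term_id, r.p_value) for r in r1.results] == [
            (r.term_id, r.p_value) for r in r2.results
        ]

    def test_sorted_by_p_then_term_id(self, planted_report):
        report, _, _ = planted_report
        keys = [(r.p_value, r.term_id) for r in report.results]
        assert keys == sorted(keys)

    def test_bonferroni_uses_represented_terms_only(self):
        idx = _simple_index(20, {"GO:T": [f"g{i}" for i in range(4)],
                                 "GO:U": [f"g{i}" for i in range(10, 14)]})
        # query hits GO:T only, so M_effective is 1 and p_adjusted == p_value
        report = enrich(QueryInput(query_ids=["g0", "g1"]), idx, correction="bonferroni")
        assert len(report) == 1
        assert report.results[0].p_adjusted == pytest.approx(report.results[0].p_value)

    def test_adjusted_never_below_raw(self, planted_report):
        report, _, _ = planted_report
        assert all(r.p_adjusted >= r.p_value - 1e-15 for r in report.results)

    def test_report_frame_and_summary(self, planted_report):
        report, _, _ = planted_report
        df = report.to_frame()
        assert list(df.columns[:7]) == ["term_id", "name", "namespace", "x", "k", "m", "N"]
        assert (df["N"] == report.N).all()
        text = report.summary()
        assert "background N" in text and str(report.N) in text


class TestModelFrontEnd:
    def test_fit_equals_functional_path(self, planted_report):
        report, fx, model = planted_report
        direct = enrich(model.query, model.index, alpha=0.05, correction="fdr_bh")
        assert [(r.term_id, r.p_value) for r in direct.results] == [
            (r.term_id, r.p_value) for r in report.results
        ]

    def test_kegg_route_matches_go_route_counts(self, planted_fixture):
        spec, fx = planted_fixture
        model = OverRepresentationAnalysis.from_files(
            fx.query_path,
            kegg_map_path=fx.kegg_map_path,
            kegg_names_path=fx.kegg_names_path,
        )
        report = model.fit(alpha=0.1)
        # pathway syn00001 mirrors the planted GO term gene-for-gene
        top = report.results[0]
        assert top.term_id == "syn00001"
        assert top.counts.x == fx.truth[0].x and top.counts.m == fx.truth[0].m


class TestNullCalibration:
    def test_rejection_rate_matches_exact_discrete_level(self, null_simulation):
        """Under the null, each term's empirical rejection rate at nominal
        p <= 0.05 must match the exact achievable level of its discrete
        test (the largest attainable tail probability <= 0.05)."""
        sim = null_simulation
        reps = sim["reps"]
        se = np.sqrt(sim["alpha_star"] * (1 - sim["alpha_star"]) / reps)
        z = np.abs(sim["term_rates"] - sim["alpha_star"]) / np.maximum(se, 1e-9)
        assert (z < 4.5).all()
        # and in aggregate, using the replicate-level spread
        agg_se = sim["per_replicate_fraction"].std(ddof=1) / np.sqrt(reps)
        assert abs(sim["pooled_fraction"] - sim["alpha_star"].mean()) < 4 * agg_se

    def test_discrete_test_is_conservative(self, null_simulation):
        assert null_simulation["pooled_fraction"] <= 0.05 + 1e-9
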