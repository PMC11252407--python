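"""Screen hit-calling: Φ computation, binning, the exact conditional test,
BH, and the end-to-end pipeline."""

import itertools
from math import comb, prod

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmoscreen.screen import (
    N_BINS,
    GeneContingency,
    bh_fdr,
    bin_phi,
    call_hits,
    compute_phi,
    fisher_gene_p,
    gene_contingency,
    normalize_abundance,
    run_screen_pipeline,
)


# -- independent oracles ----------------------------------------------------

def compositions(n, k):
    """All k-part non-negative integer compositions of n (recursive)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in compositions(n - first, k - 1):
            yield (first,) + rest


def oracle_fisher_p(gene, background):
    """Exact-integer brute force over the multivariate hypergeometric."""
    n, N = sum(gene), sum(background)
    denom = comb(N, n)

    def pmf(x):
        if any(xj > bj for xj, bj in zip(x, background)):
            return 0.0
        return prod(comb(bj, xj) for xj, bj in zip(x, background)) / denom

    obs = pmf(tuple(gene))
    total = sum(
        p for x in compositions(n, len(background))
        if (p := pmf(x)) > 0 and p <= obs * (1 + 1e-12)
    )
    return min(1.0, total)


def oracle_bh(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# -- normalization and Φ ----------------------------------------------------

class TestNormalizeAndPhi:
    def test_column_proportions(self):
        counts = pd.DataFrame({"s": [10, 30, 60]}, index=["a", "b", "c"])
        np.testing.assert_allclose(normalize_abundance(counts)["s"], [0.1, 0.3, 0.6])

    def test_columns_sum_to_one_and_row_order_invariance(self, small_screen):
        _, counts, _, _ = small_screen
        rel = normalize_abundance(counts)
        np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)
        perm = counts.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(
            normalize_abundance(perm).sort_index(), rel.sort_index()
        )

    def test_empty_column_rejected(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            normalize_abundance(counts)

    def test_phi_hand_example(self):
        counts = pd.DataFrame(
            {"ctl": [100, 900], "trt": [25, 975]}, index=["a", "b"]
        )
        ann = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "allele_index": [0, 0]}, index=["a", "b"]
        )
        phen = compute_phi(counts, ann, "ctl", "trt")
        assert phen.loc["a", "phi"] == pytest.approx((25 / 1000) / (100 / 1000))

    def test_read_minimum_on_control(self):
        counts = pd.DataFrame({"ctl": [40, 960], "trt": [100, 900]}, index=["a", "b"])
        ann = pd.DataFrame({"gene_id": ["g", "g"], "allele_index": [0, 1]},
                           index=["a", "b"])
        phen = compute_phi(counts, ann, "ctl", "trt", min_reads=50)
        assert not phen.loc["a", "qualified"]
        assert np.isnan(phen.loc["a", "phi"])

    def test_treatment_dropout_gives_phi_zero(self):
        counts = pd.DataFrame({"ctl": [200, 800], "trt": [0, 1000]}, index=["a", "b"])
        ann = pd.DataFrame({"gene_id": ["g", "g"], "allele_index": [0, 1]},
                           index=["a", "b"])
        phen = compute_phi(counts, ann, "ctl", "trt")
        assert phen.loc["a", "qualified"] and phen.loc["a", "phi"] == 0.0

    def test_missing_sample_rejected(self):
        counts = pd.DataFrame({"ctl": [1]}, index=["a"])
        ann = pd.DataFrame({"gene_id": ["g"], "allele_index": [0]}, index=["a"])
        with pytest.raises(KeyError):
            compute_phi(counts, ann, "ctl", "nope")


class TestBinPhi:
    @pytest.mark.parametrize(
        "phi,expected",
        [(1.0, 4), (0.0625, 1), (20.0, 7), (0.0, 0), (0.124999, 1),
         (0.125, 2), (2.0, 5), (15.999, 7), (16.0, 7)],
    )
    def test_edges(self, phi, expected):
        assert bin_phi(phi) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_phi(-0.1)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_monotone_total_step_function(self, phis):
        idx = bin_phi(np.sort(np.asarray(phis)))
        assert np.all(np.diff(idx) >= 0)
        assert set(np.atleast_1d(idx)) <= set(range(N_BINS))


class TestGeneContingency:
    def test_hand_binned_gene_vector(self):
        phen = pd.DataFrame(
            {
                "gene_id": ["g", "g", "g", "h"],
                "phi": [0.03, 0.05, 1.0, 1.0],
                "qualified": [True] * 4,
            }
        )
        tab = gene_contingency(phen, "g")
        np.testing.assert_array_equal(tab.gene_counts, [2, 0, 0, 0, 1, 0, 0, 0])
        assert tab.background_counts.sum() == 4

    def test_neutral_pool_background_concentrates_in_unity_bin(self, small_screen):
        _, counts, ann, truth = small_screen
        phen = compute_phi(counts, ann, "control_r1", "treatment_r1")
        neutral_gene = truth.gene_s.index[truth.gene_s == 0][0]
        tab = gene_contingency(phen, neutral_gene)
        assert tab.background_counts.argmax() == 4

    def test_single_gene_screen_background_equals_gene(self):
        phen = pd.DataFrame(
            {"gene_id": ["g"] * 3, "phi": [0.3, 0.4, 1.0], "qualified": [True] * 3}
        )
        tab = gene_contingency(phen, "g")
        np.testing.assert_array_equal(tab.gene_counts, tab.background_counts)

    def test_gene_without_qualified_alleles_rejected(self):
        phen = pd.DataFrame({"gene_id": ["g"], "phi": [np.nan], "qualified": [False]})
        with pytest.raises(ValueError):
            gene_contingency(phen, "g")


class TestFisherGeneP:
    def test_single_allele_symmetric_background_gives_p_one(self):
        tab = GeneContingency("g", np.array([1, 0, 0, 0, 0, 0, 0, 0]),
                              np.array([50, 50, 0, 0, 0, 0, 0, 0]))
        assert fisher_gene_p(tab) == pytest.approx(1.0)

    def test_two_bin_case_matches_closed_form_hypergeometric(self):
        from scipy.stats import hypergeom

        gene = np.array([2, 0, 0, 0, 0, 0, 0, 0])
        bg = np.array([10, 90, 0, 0, 0, 0, 0, 0])
        p = fisher_gene_p(GeneContingency("g", gene, bg))
        rv = hypergeom(100, 10, 2)
        pmf = rv.pmf(np.arange(3))
        expected = pmf[pmf <= pmf[2] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expected, rel=1e-10)

    def test_exact_path_matches_integer_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 5))
            bg = rng.integers(0, 12, size=N_BINS)
            bg[rng.integers(0, N_BINS)] += n  # ensure feasibility
            gene = rng.multivariate_hypergeometric(bg, n)
            tab = GeneContingency("g", gene, bg)
            assert fisher_gene_p(tab) == pytest.approx(
                oracle_fisher_p(tuple(gene), tuple(bg)), abs=1e-12
            )

    def test_monte_carlo_agrees_with_exact(self, rng):
        bg = np.array([5, 10, 8, 12, 60, 9, 4, 2])
        gene = np.array([2, 0, 0, 1, 2, 0, 0, 0])
        tab = GeneContingency("g", gene, bg)
        p_exact = fisher_gene_p(tab)
        p_mc, method = fisher_gene_p(tab, exact_cap=0, n_mc=200_000, seed=1,
                                     with_method=True)
        assert method == "monte-carlo"
        se = np.sqrt(p_exact * (1 - p_exact) / 200_000)
        assert abs(p_mc - p_exact) < 3 * se + 1e-5

    def test_validity_of_conditional_test(self):
        """Σ P(outcome)·1[p(outcome) ≤ α] ≤ α over all outcomes at fixed
        margins — exhaustively for small tables."""
        cases = [
            (2, (4, 6, 0, 0, 0, 0, 0, 0)),
            (3, (3, 5, 7, 0, 0, 0, 0, 0)),
            (4, (2, 9, 4, 0, 0, 0, 0, 0)),
        ]
        for n, bg in cases:
            occupied = [j for j, b in enumerate(bg) if b]
            outcomes = [
                x for x in compositions(n, len(occupied))
                if all(xj <= bg[occupied[j]] for j, xj in enumerate(x))
            ]
            denom = comb(sum(bg), n)

            def pmf(x):
                return prod(comb(bg[occupied[j]], xj) for j, xj in enumerate(x)) / denom

            for alpha in (0.01, 0.05, 0.3):
                mass = 0.0
                for x in outcomes:
                    full = np.zeros(N_BINS, dtype=int)
                    full[occupied] = x
                    p = fisher_gene_p(GeneContingency("g", full, np.array(bg)))
                    if p <= alpha:
                        mass += pmf(x)
                assert mass <= alpha + 1e-12

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_gene_p(GeneContingency("g", np.zeros(8, int), np.zeros(8, int)))


class TestBH:
    def test_printed_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1, 1, 1]), [1, 1, 1])

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 100))
            p = rng.uniform(0, 1, size=m)
            np.testing.assert_allclose(bh_fdr(p), oracle_bh(p), atol=1e-12)

    def test_sorted_q_non_decreasing(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCallHits:
    def test_two_allele_gene_never_a_hit(self):
        stats = pd.DataFrame(
            {"gene_id": ["a", "b"], "p": [1e-9, 0.5], "n_alleles": [2, 3]}
        )
        out = call_hits(stats)
        assert not out.loc[out.gene_id == "a", "hit"].iloc[0]
        assert np.isnan(out.loc[out.gene_id == "a", "q"].iloc[0])

    def test_fdr_boundary_is_strict(self):
        # single eligible gene: q == p
        for p, expect in [(0.29, True), (0.31, False)]:
            out = call_hits(
                pd.DataFrame({"gene_id": ["a"], "p": [p], "n_alleles": [3]})
            )
            assert bool(out.hit.iloc[0]) is expect

    def test_empty_input(self):
        out = call_hits(pd.DataFrame(columns=["gene_id", "p", "n_alleles"]))
        assert out.empty and "q" in out.columns and "hit" in out.columns


class TestPipeline:
    def test_recovers_planted_hits(self, small_screen):
        _, counts, ann, truth = small_screen
        res = run_screen_pipeline(
            counts, ann, {"scr": {"control": "control_r1", "treatment": "treatment_r1"}}
        )["scr"]
        called = set(res.loc[res.hit, "gene_id"])
        planted = set(truth.hit_genes)
        assert len(called & planted) / len(planted) >= 0.9

    def test_invariant_to_row_and_column_order(self, small_screen):
        _, counts, ann, _ = small_screen
        design = {"scr": {"control": "control_r1", "treatment": "treatment_r1"}}
        base = run_screen_pipeline(counts, ann, design)["scr"]
        shuffled = counts.sample(frac=1.0, random_state=1)[counts.columns[::-1]]
        again = run_screen_pipeline(shuffled, ann, design)["scr"]
        pd.testing.assert_frame_equal(base, again)

    def test_malformed_design_rejected(self, small_screen):
        _, counts, ann, _ = small_screen
        with pytest.raises(ValueError):
            run_screen_pipeline(counts, ann, {"scr": {"control": "control_r1"}})
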