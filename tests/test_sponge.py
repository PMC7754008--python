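"""Sponge-pair statistics against enumeration, closed-form and sort oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from spongenet.io_formats import TargetMap
from spongenet.sponge import (
    SpongeThresholds,
    assemble_network,
    bh_adjust,
    call_sponge_pairs,
    correlation_test,
    fisher_combine,
    pair_passes,
    rank_mediators,
    shared_mirna_test,
)


def hypergeom_tail_enum(N, K, n, k):
    """P(X >= k) by exhaustive summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


class TestSharedMirnaTest:
    def test_full_overlap_worked_value(self):
        universe = {f"m{i}" for i in range(10)}
        s = set(list(universe)[:5])
        k, p = shared_mirna_test(s, s, universe)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-9)  # 1/252

    def test_disjoint_sets(self):
        universe = {f"m{i}" for i in range(8)}
        k, p = shared_mirna_test({"m0", "m1"}, {"m5", "m6"}, universe)
        assert k == 0 and p == 1.0

    def test_set_equal_to_universe(self):
        universe = {f"m{i}" for i in range(6)}
        k, p = shared_mirna_test(universe, {"m0", "m3"}, universe)
        assert k == 2 and p == pytest.approx(1.0)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            shared_mirna_test(set(), set(), set())

    def test_matches_enumeration_small_universes(self):
        """Exhaustive check over every configuration up to |universe| = 8
        (the acceptance suite extends this to 12)."""
        for N in range(1, 9):
            universe = {f"m{i}" for i in range(N)}
            ids = sorted(universe)
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        s1 = set(ids[:K])
                        s2 = set(ids[:k]) | set(ids[K:K + n - k])
                        if len(s2) != n:
                            continue
                        kk, p = shared_mirna_test(s1, s2, universe)
                        assert kk == k
                        assert abs(p - hypergeom_tail_enum(N, K, n, k)) < 1e-12


class TestCorrelationTest:
    def test_exact_linear_pair(self):
        r, p = correlation_test(np.arange(5.0), 2 * np.arange(5.0) + 1)
        assert r == pytest.approx(1.0)

    def test_matches_permutation_oracle(self, rng):
        n = 7
        perms = list(itertools.permutations(range(n)))
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            r_obs, p = correlation_test(x, y)
            r_perm = [abs(np.corrcoef(x, y[list(pp)])[0, 1]) for pp in perms]
            p_perm = np.mean(np.array(r_perm) >= abs(r_obs) - 1e-12)
            assert abs(p - p_perm) < 0.1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation_test(np.ones(5), np.arange(5.0))


class TestFisherCombine:
    def test_both_unity(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)

    def test_worked_value(self):
        # X = -4 ln 0.05 = 11.98293; chi2_4 tail = exp(-X/2)(1 + X/2)
        assert fisher_combine(0.05, 0.05) == pytest.approx(0.017479, abs=5e-6)

    def test_closed_form_grid(self):
        for p1 in np.logspace(-6, 0, 10):
            for p2 in np.logspace(-6, 0, 10):
                x = -2 * (np.log(p1) + np.log(p2))
                expected = np.exp(-x / 2) * (1 + x / 2)
                assert fisher_combine(p1, p2) == pytest.approx(expected, abs=1e-10)

    def test_combination_beats_larger_p_when_both_small(self):
        # p_combined < p1 whenever p2 <= p1 <= 0.05
        for p1 in np.linspace(0.001, 0.05, 8):
            for p2 in np.linspace(0.0005, p1, 8):
                assert fisher_combine(p1, p2) < p1

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = fisher_combine(0.0, 0.5)
        assert 0 < p < 1e-100


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_worked_vector(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 200))
    def test_matches_statsmodels(self, seed, n):
        p = np.random.default_rng(seed).uniform(1e-12, 1.0, size=n)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0.0001, 1, size=300)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPairFilter:
    @pytest.mark.parametrize("fdr,k,r,expected", [
        (0.049, 10, 0.26, True),    # all three just inside
        (0.05, 10, 0.26, True),     # FDR boundary inclusive
        (1e-6, 9, 0.9, False),      # shared-miRNA floor k >= 10
        (0.049, 10, 0.25, False),   # r boundary strict
        (0.0500001, 10, 0.9, False),
        (0.01, 25, -0.5, False),
    ])
    def test_printed_boundaries(self, fdr, k, r, expected):
        assert pair_passes(fdr, k, r) is expected


def _pair_inputs(k_shared=10, n_extra=2, r_sign=1.0):
    """Hand-built inputs: one lncRNA, one gene, a controllable shared set."""
    mirnas = [f"m{i:02d}" for i in range(k_shared + n_extra)]
    edges = [(m, "L1", "lncrna") for m in mirnas[:k_shared]]
    edges += [(m, "G1", "mrna") for m in mirnas[:k_shared]]
    edges += [(mirnas[k_shared + i], "L1", "lncrna") for i in range(n_extra // 2)]
    targets = TargetMap(edges)
    samples = [f"s{i}" for i in range(8)]
    base = np.array([1.0, 2.0, 1.5, 3.0, 5.0, 6.0, 5.5, 7.0])
    expr = pd.DataFrame(
        {s: None for s in samples}, index=["L1", "G1"], dtype=float)
    expr.loc["L1"] = base
    expr.loc["G1"] = r_sign * base + np.array([0.1, -0.1, 0.05, 0, -0.05, 0.1, 0, -0.1])
    de = lambda ids: pd.DataFrame({"p_value": [0.01] * len(ids)}, index=ids)
    return de(["L1"]), de(["G1"]), de(mirnas), expr, targets


class TestCallSpongePairs:
    def test_planted_pair_passes(self):
        de_lnc, de_mrna, de_mirna, expr, targets = _pair_inputs(k_shared=10)
        pairs = call_sponge_pairs(de_lnc, de_mrna, de_mirna, expr, targets)
        row = pairs.iloc[0]
        assert row["k"] == 10
        assert row["corr_r"] > 0.25
        assert bool(row["passes"])

    def test_nine_shared_fails_floor(self):
        de_lnc, de_mrna, de_mirna, expr, targets = _pair_inputs(k_shared=9)
        pairs = call_sponge_pairs(de_lnc, de_mrna, de_mirna, expr, targets)
        assert pairs.iloc[0]["k"] == 9
        assert not bool(pairs.iloc[0]["passes"])

    def test_negative_correlation_fails(self):
        de_lnc, de_mrna, de_mirna, expr, targets = _pair_inputs(r_sign=-1.0)
        pairs = call_sponge_pairs(de_lnc, de_mrna, de_mirna, expr, targets)
        assert pairs.iloc[0]["corr_r"] < 0
        assert not bool(pairs.iloc[0]["passes"])

    def test_non_de_features_not_enumerated(self):
        de_lnc, de_mrna, de_mirna, expr, targets = _pair_inputs()
        de_lnc.loc["L1", "p_value"] = 0.5  # filtered at p < 0.05
        pairs = call_sponge_pairs(de_lnc, de_mrna, de_mirna, expr, targets)
        assert pairs.empty

    def test_passes_column_consistent_with_filter(self):
        de_lnc, de_mrna, de_mirna, expr, targets = _pair_inputs()
        pairs = call_sponge_pairs(de_lnc, de_mrna, de_mirna, expr, targets)
        for _, row in pairs.iterrows():
            assert bool(row["passes"]) == pair_passes(row["fdr"], row["k"],
                                                      row["corr_r"])

    def test_seed_family_collapse(self):
        """Mapping every shared miRNA into one family collapses the count."""
        de_lnc, de_mrna, de_mirna, expr, targets = _pair_inputs(k_shared=10)
        fam = {f"m{i:02d}": "famA" for i in range(10)}
        pairs = call_sponge_pairs(de_lnc, de_mrna, de_mirna, expr, targets,
                                  seed_families=fam)
        assert pairs.iloc[0]["k"] == 1
        assert not bool(pairs.iloc[0]["passes"])


class TestRankMediators:
    def _mediator_setup(self, rng, n_mir=6):
        mirnas = [f"m{i}" for i in range(n_mir)]
        samples = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(size=(n_mir + 2, 8)),
                            index=["L1", "G1"] + mirnas, columns=samples)
        de_mirna = pd.DataFrame(
            {"p_value": rng.uniform(0.001, 0.04, size=n_mir)}, index=mirnas)
        pair = pd.Series({"lncrna_id": "L1", "gene_id": "G1",
                          "shared_mirnas": ",".join(mirnas)})
        return pair, de_mirna, expr

    def test_fewer_than_k_top_all_returned(self, rng):
        pair, de_mirna, expr = self._mediator_setup(rng)
        med = rank_mediators(pair, de_mirna, expr, k_top=20)
        assert len(med) == 6

    def test_order_matches_sort_oracle(self, rng):
        pair, de_mirna, expr = self._mediator_setup(rng, n_mir=10)
        med = rank_mediators(pair, de_mirna, expr, k_top=5)
        expected = de_mirna["p_value"].sort_values(kind="mergesort").index[:5]
        assert med["mirna_id"].tolist() == list(expected)

    def test_ties_break_lexicographically(self, rng):
        pair, de_mirna, expr = self._mediator_setup(rng)
        de_mirna["p_value"] = 0.01
        med = rank_mediators(pair, de_mirna, expr)
        assert med["mirna_id"].tolist() == sorted(med["mirna_id"])

    def test_correlation_rank_key(self, rng):
        pair, de_mirna, expr = self._mediator_setup(rng)
        med = rank_mediators(pair, de_mirna, expr, rank_key="corr_r")
        strength = med[["r_lnc", "r_gene"]].abs().mean(axis=1)
        assert (strength.diff().dropna() <= 1e-12).all()


class TestAssembleNetwork:
    def test_counts_conserved(self, rng):
        pairs = pd.DataFrame([{
            "lncrna_id": "L1", "gene_id": "G1", "passes": True,
            "shared_mirnas": "", "k": 20, "fdr": 0.01, "corr_r": 0.9,
        }])
        med = pd.DataFrame({"mirna_id": [f"m{i:02d}" for i in range(20)],
                            "de_p": 0.01, "r_lnc": -0.4, "r_gene": -0.3})
        net = assemble_network(pairs, {("L1", "G1"): med})
        assert len(net.triplets) == 20
        assert len(net.sif_edges()) == 40

    def test_no_passing_pairs_empty(self):
        pairs = pd.DataFrame([{"lncrna_id": "L1", "gene_id": "G1",
                               "passes": False}])
        net = assemble_network(pairs, {})
        assert net.triplets == []

    def test_shared_mediator_keyed_per_pair(self):
        pairs = pd.DataFrame([
            {"lncrna_id": "L1", "gene_id": "G1", "passes": True},
            {"lncrna_id": "L2", "gene_id": "G1", "passes": True},
        ])
        med = pd.DataFrame({"mirna_id": ["m1"], "de_p": [0.01],
                            "r_lnc": [0.0], "r_gene": [0.0]})
        net = assemble_network(pairs, {("L1", "G1"): med, ("L2", "G1"): med})
        assert len(net.triplets) == 2
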