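"""RNA differential expression, coupling statistics, partitions and trends."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from agemark.integrate import (
    aggregate_peak_logfc,
    correlate_changes,
    geneset_overlap_test,
    length_trend,
    overlap_partition,
    rna_differential,
    tmm_factors,
)


def nb_counts(rng, mu, disp, shape):
    return rng.negative_binomial(1 / disp, 1 / (1 + disp * np.asarray(mu)[:, None]), shape)


class TestRnaDifferential:
    def test_duplicated_libraries_give_no_calls(self, rng):
        base = rng.poisson(rng.lognormal(6, 1, 300))
        counts = pd.DataFrame(
            {f"l{i}": base for i in range(4)}, index=[f"g{i}" for i in range(300)]
        )
        res = rna_differential(counts, ["D2", "D2", "D12", "D12"])
        assert len(res.changed) == 0

    def test_recovers_injected_effects(self, rng):
        # default-design recovery: 2 reps, dispersion 0.02, |log2FC| = 1
        n, disp = 500, 0.02
        base = rng.lognormal(0, 1, n) * 2000
        eff = np.zeros(n)
        eff[:60] = 1.0
        eff[60:120] = -1.0
        d2 = nb_counts(rng, base, disp, (n, 2))
        d12 = nb_counts(rng, base * 2.0 ** eff, disp, (n, 2))
        counts = pd.DataFrame(
            np.hstack([d2, d12]),
            index=[f"g{i}" for i in range(n)],
            columns=["D2_1", "D2_2", "D12_1", "D12_2"],
        )
        res = rna_differential(counts, ["D2", "D2", "D12", "D12"])
        called = res.changed
        true = {f"g{i}" for i in range(120)}
        recall = len(set(called) & true) / 120
        fdr = len(set(called) - true) / max(1, len(called))
        assert recall >= 0.8
        assert fdr <= 0.1
        # directions agree
        up = set(res.classed("up"))
        assert up <= {f"g{i}" for i in range(60)} | (set(called) - true)

    def test_depth_rescale_changes_no_calls(self, rng):
        n, disp = 300, 0.02
        base = rng.lognormal(0, 1, n) * 1000
        eff = np.zeros(n)
        eff[:40] = 1.0
        d2 = nb_counts(rng, base, disp, (n, 2))
        d12 = nb_counts(rng, base * 2.0 ** eff, disp, (n, 2))
        counts = pd.DataFrame(np.hstack([d2, d12]), index=[f"g{i}" for i in range(n)])
        scaled = counts.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 3).astype(int)
        r1 = rna_differential(counts, ["D2", "D2", "D12", "D12"])
        r2 = rna_differential(scaled, ["D2", "D2", "D12", "D12"])
        agree = (r1.table["class"] == r2.table["class"]).mean()
        assert agree >= 0.97

    def test_non_integer_counts_rejected(self):
        counts = pd.DataFrame(np.full((5, 4), 1.5))
        with pytest.raises(ValueError):
            rna_differential(counts, ["a", "a", "b", "b"])

    def test_tmm_factors_absorb_depth(self, rng):
        base = rng.poisson(rng.lognormal(6, 1, 400), (4, 400)).T
        counts = pd.DataFrame(base)
        scaled = counts.copy()
        scaled[0] = counts[0] * 5
        f = tmm_factors(scaled)
        # effective library sizes should match: factor ~ 1 despite 5x depth
        assert np.allclose(f, 1.0, atol=0.1)


class TestCorrelateChanges:
    def test_monotone_pairs_give_rho_one(self):
        k4 = pd.Series([0.1, 0.5, 1.2, 2.0], index=list("abcd"))
        rna = pd.Series([1, 2, 3, 4.0], index=list("abcd"))
        res = correlate_changes(k4, rna)
        assert res.rho == pytest.approx(1.0)
        assert res.n == 4

    def test_antimonotone_pairs_give_minus_one(self):
        k4 = pd.Series([0.1, 0.5, 1.2], index=list("abc"))
        rna = pd.Series([3, 2, 1.0], index=list("abc"))
        assert correlate_changes(k4, rna).rho == pytest.approx(-1.0)

    def test_exact_small_n_p_value(self):
        # perfectly monotone n=5: P(|rho| = 1) = 2/5! under permutation
        k4 = pd.Series(np.arange(5.0), index=list("abcde"))
        rna = pd.Series(np.arange(5.0) ** 2, index=list("abcde"))
        res = correlate_changes(k4, rna)
        assert res.p == pytest.approx(2 / 120)

    def test_small_intersection_is_error(self):
        k4 = pd.Series([1.0], index=["a"])
        rna = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            correlate_changes(k4, rna)

    def test_rho_invariant_under_monotone_transform(self, rng):
        idx = [f"g{i}" for i in range(30)]
        k4 = pd.Series(rng.normal(size=30), index=idx)
        rna = pd.Series(rng.normal(size=30), index=idx)
        r1 = correlate_changes(k4, rna).rho
        r2 = correlate_changes(k4.apply(np.exp), rna * 7 + 2).rho
        assert r1 == pytest.approx(r2)

    def test_multi_peak_aggregation_weighted_mean(self):
        from agemark.genes import GeneAssignment

        table = pd.DataFrame(
            {"peak_id": ["p1", "p2", "p3"], "gene_id": ["g1", "g1", "g2"],
             "relation": ["overlap"] * 3, "distance": [0, 0, 0]}
        )
        lfc = pd.Series({"p1": 1.0, "p2": 3.0, "p3": -1.0})
        w = pd.Series({"p1": 1.0, "p2": 3.0, "p3": 2.0})
        agg = aggregate_peak_logfc(GeneAssignment(table), lfc, weights=w)
        assert agg["g1"] == pytest.approx((1 * 1 + 3 * 3) / 4)
        assert agg["g2"] == pytest.approx(-1.0)


class TestOverlapPartition:
    def test_disjoint_sets_empty_intersections(self):
        universe = {f"g{i}" for i in range(9)}
        res = overlap_partition(
            {"g0", "g1"}, {"g2": "up"}, {"g3": "down"}, universe
        )
        assert res.cell(True, True, True) == 0
        assert res.cell(True, True, False) == 0
        assert res.discordant == 0

    def test_identical_directions_no_discordance(self):
        universe = {"a", "b", "c"}
        k4 = {"a": "up", "b": "down"}
        rna = {"a": "up", "b": "down"}
        res = overlap_partition(set(), k4, rna, universe)
        assert res.concordant_up == 1 and res.concordant_down == 1
        assert res.discordant == 0

    def test_ten_gene_fixture_matches_enumeration(self):
        universe = {f"g{i}" for i in range(10)}
        marked = {"g0", "g1", "g2", "g3", "g4"}
        k4 = {"g0": "up", "g1": "down", "g5": "up"}
        rna = {"g0": "up", "g1": "up", "g6": "down"}
        res = overlap_partition(marked, k4, rna, universe)
        # hand enumeration of the 8 cells
        assert res.cell(True, True, True) == 2      # g0, g1
        assert res.cell(True, True, False) == 0
        assert res.cell(True, False, False) == 3    # g2 g3 g4
        assert res.cell(False, True, False) == 1    # g5
        assert res.cell(False, False, True) == 1    # g6
        assert res.cell(False, False, False) == 3   # g7 g8 g9
        assert sum(res.cells.values()) == 10
        assert res.concordant_up == 1 and res.discordant == 1

    def test_gene_outside_universe_is_error(self):
        with pytest.raises(ValueError):
            overlap_partition({"x"}, {}, {}, {"a"})


class TestLengthTrend:
    def test_all_flagged_is_degenerate(self):
        lengths = pd.Series([300, 900, 2500, 7000.0], index=list("abcd"))
        changed = pd.Series(True, index=list("abcd"))
        res = length_trend(lengths, changed)
        assert np.isnan(res.rho)
        assert "degenerate" in res.note
        assert (res.table["fraction_changed"] == 1.0).all()

    def test_single_bin_not_applicable(self):
        lengths = pd.Series([500, 510, 520.0], index=list("abc"))
        changed = pd.Series([True, False, True], index=list("abc"))
        res = length_trend(lengths, changed, bin_edges=np.array([100.0, 100_000.0]))
        assert np.isnan(res.rho)

    def test_positive_trend_detected(self, rng):
        # longer domains carry a higher change probability
        n = 400
        lengths = pd.Series(np.exp(rng.uniform(np.log(250), np.log(9000), n)))
        prob = np.interp(np.log(lengths), [np.log(250), np.log(9000)], [0.1, 0.8])
        changed = pd.Series(rng.random(n) < prob)
        res = length_trend(lengths, changed, seed=1)
        assert res.rho > 0
        assert res.p < 0.05


class TestGenesetOverlap:
    def test_target_subset_of_flagged_maximal_odds(self):
        universe = [f"g{i}" for i in range(20)]
        flag = pd.Series([i < 8 for i in range(20)], index=universe)
        odds, p = geneset_overlap_test(flag, [f"g{i}" for i in range(4)], universe)
        assert np.isinf(odds)
        assert p < 0.05

    def test_known_table_matches_hypergeometric_oracle(self):
        # table [[8, 32], [546, 6000]]
        universe = [f"g{i}" for i in range(8 + 32 + 546 + 6000)]
        target = universe[: 8 + 32]
        flagged = set(universe[:8]) | set(universe[40 : 40 + 546])
        flag = pd.Series([g in flagged for g in universe], index=universe)
        _, p = geneset_overlap_test(flag, target, universe)
        n = 6586
        K, N = 40, 554
        probs = hypergeom.pmf(np.arange(0, K + 1), n, K, N)
        p_exp = probs[probs <= hypergeom.pmf(8, n, K, N) * (1 + 1e-9)].sum()
        assert p == pytest.approx(p_exp, rel=1e-9)

    def test_empty_target_is_error(self):
        flag = pd.Series([True, False], index=["a", "b"])
        with pytest.raises(ValueError):
            geneset_overlap_test(flag, [], ["a", "b"])

    def test_null_flag_p_roughly_uniform(self, rng):
        universe = [f"g{i}" for i in range(200)]
        target = list(rng.choice(universe, 40, replace=False))
        ps = []
        for _ in range(200):
            flag = pd.Series(rng.random(200) < 0.3, index=universe)
            ps.append(geneset_overlap_test(flag, target, universe)[1])
        # discrete conservative p: check no excess of small values
        assert np.mean(np.asarray(ps) < 0.05) <= 0.08
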