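"""NB-GLM differential binding: counting, testing, filtering, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agemark.differential import (
    classify_dynamic,
    count_in_peaks,
    nb_glm_test,
    peak_bin_counts,
    timepoint_contrast,
)
from agemark.peaks import Peak, PeakSet
from conftest import make_track


def _peak(s, e, chrom="chr1"):
    return Peak(chrom, s, e, s, 1.0, 2.0, "narrow")


class TestCounting:
    def test_exact_bin_sum(self):
        track = make_track([3, 4, 5, 7])
        ps = PeakSet([_peak(0, 75)])
        assert peak_bin_counts(ps, track)[0] == 12

    def test_partial_bin_pro_rated(self):
        track = make_track([10, 0])
        ps = PeakSet([_peak(0, 12)])  # covers 12/25 of the first bin
        assert peak_bin_counts(ps, track)[0] == pytest.approx(10 * 12 / 25)

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.poisson(5, 40))
        cuts = [0, 130, 400, 612, 1000]
        ps = PeakSet([_peak(a, b) for a, b in zip(cuts[:-1], cuts[1:])])
        total = peak_bin_counts(ps, track).sum()
        assert total == pytest.approx(track.data["chr1"].sum())

    def test_out_of_bounds_peak_raises(self):
        track = make_track([1] * 4)
        with pytest.raises(ValueError):
            peak_bin_counts(PeakSet([_peak(0, 200)]), track)


class TestNbGlm:
    def test_identical_groups_null_result(self):
        y = pd.DataFrame(np.tile([[10, 20, 30, 10, 20, 30]], (5, 1)))
        res = nb_glm_test(y, ["a", "a", "a", "b", "b", "b"], pd.Series(np.full(6, 1e4)))
        np.testing.assert_allclose(res["logFC"], 0.0, atol=1e-8)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-8)

    def test_matches_poisson_lrt_at_zero_dispersion(self):
        # dispersion -> 0 limit: exact two-sample Poisson likelihood-ratio oracle
        def poisson_lrt_p(y1, y2):
            lam1, lam2 = np.mean(y1), np.mean(y2)
            lam0 = np.mean(np.concatenate([y1, y2]))

            def ll(y, lam):
                return np.sum(stats.poisson.logpmf(y, lam)) if lam > 0 else (
                    0.0 if np.sum(y) == 0 else -np.inf
                )

            lr = 2 * (ll(y1, lam1) + ll(y2, lam2) - ll(np.concatenate([y1, y2]), lam0))
            return stats.chi2.sf(max(lr, 0), 1)

        rng = np.random.default_rng(8)
        rows = [rng.poisson(rng.uniform(50, 500), 6) for _ in range(20)]
        y = pd.DataFrame(np.array(rows))
        res = nb_glm_test(
            y, ["a", "a", "a", "b", "b", "b"], pd.Series(np.full(6, 1.0)),
            dispersion=0.0,
        )
        for i, row in enumerate(rows):
            expected = poisson_lrt_p(row[:3], row[3:])
            assert abs(res["p"].iloc[i] - expected) <= 0.02

    def test_recovers_fourfold_spike(self):
        rng = np.random.default_rng(4)
        n = 300
        mu = rng.lognormal(6, 0.5, n)
        disp = 0.1
        y1 = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu[:, None]), (n, 3))
        y2 = rng.negative_binomial(1 / disp, 1 / (1 + disp * 4 * mu[:, None]), (n, 3))
        y = pd.DataFrame(np.hstack([y1, y2]))
        res = nb_glm_test(y, list("aaabbb"), pd.Series(np.full(6, 1.0)))
        assert np.median(res["logFC"]) == pytest.approx(2.0, abs=0.25)

    def test_single_replicate_group_raises(self):
        y = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError):
            nb_glm_test(y, ["a", "a", "b"], pd.Series(np.ones(3)))


def _levels(index, d2, d12):
    cols = pd.MultiIndex.from_tuples(
        [("D2", r) for r in (1, 2, 3)] + [("D12", r) for r in (1, 2, 3)],
        names=["timepoint", "replicate"],
    )
    vals = np.array([list(a) + list(b) for a, b in zip(d2, d12)])
    return pd.DataFrame(vals, index=index, columns=cols)


class TestClassify:
    def _diff(self, index, logfc, p):
        return pd.DataFrame({"logFC": logfc, "p": p}, index=index)

    def test_small_fold_fails_30pct_rule(self):
        idx = ["pk1"]
        diff = self._diff(idx, [np.log2(1.25)], [0.001])
        levels = _levels(idx, [[1.5, 1.5, 1.5]], [[1.5, 1.5, 1.5]])
        res = classify_dynamic(diff, levels)
        assert res.table.loc["pk1", "class"] == "stable"

    def test_low_ratio_in_every_timepoint_fails(self):
        idx = ["pk1"]
        diff = self._diff(idx, [np.log2(1.4)], [0.001])
        levels = _levels(idx, [[1.2, 1.3, 0.9]], [[1.4, 0.9, 1.2]])
        res = classify_dynamic(diff, levels)
        assert res.table.loc["pk1", "class"] == "stable"

    def test_ratio_ok_in_one_timepoint_passes(self):
        idx = ["pk1"]
        diff = self._diff(idx, [np.log2(1.4)], [0.001])
        levels = _levels(idx, [[1.2, 1.3, 1.1]], [[0.9, 0.8, 1.0]])
        res = classify_dynamic(diff, levels)
        assert res.table.loc["pk1", "class"] == "increased"

    def test_monotone_in_min_fc(self):
        rng = np.random.default_rng(2)
        n = 50
        idx = [f"pk{i}" for i in range(n)]
        diff = self._diff(idx, rng.normal(0, 1, n), rng.uniform(0, 0.2, n))
        levels = _levels(idx, rng.uniform(0.8, 2, (n, 3)), rng.uniform(0.8, 2, (n, 3)))
        loose = classify_dynamic(diff, levels, min_fc=1.2).table["class"]
        strict = classify_dynamic(diff, levels, min_fc=1.8).table["class"]
        newly_dynamic = (loose == "stable") & (strict != "stable")
        assert not newly_dynamic.any()

    def test_invariant_to_global_depth_rescale(self):
        # classes depend on logFC/p/ratios, all of which are depth-invariant;
        # verify end-to-end through nb_glm_test with scaled counts+libs
        rng = np.random.default_rng(5)
        n = 40
        y = pd.DataFrame(rng.poisson(200, (n, 6)), index=[f"p{i}" for i in range(n)])
        libs = pd.Series(np.full(6, 1e5))
        groups = list("aaabbb")
        lv = _levels(y.index, rng.uniform(1.1, 2, (n, 3)), rng.uniform(1.1, 2, (n, 3)))
        r1 = classify_dynamic(nb_glm_test(y, groups, libs), lv)
        r2 = classify_dynamic(nb_glm_test(y * 3, groups, libs * 3), lv)
        assert (r1.table["class"] == r2.table["class"]).all()


class TestTimepointContrast:
    def test_exchangeable_null_gives_uniform_p(self, small_experiment):
        # H3 occupancy is truth-blind: a D2-vs-D12 contrast on the control
        # libraries is an exchangeable null and p-values should be uniform
        from agemark.peaks import PeakCallParams, call_peaks
        from agemark.pipeline import pooled_track

        exp = small_experiment
        mark = pooled_track(exp, "H3K4me3", "D2")
        ctrl = pooled_track(exp, "H3", "D2")
        ps = call_peaks(mark, ctrl, PeakCallParams(), "narrow")
        assert len(ps) > 30
        tracks = {
            ("H3", tp, r): exp.tracks[("H3", tp, r)]
            for tp in ("D2", "D12") for r in (1, 2, 3)
        }
        counts = count_in_peaks(ps, tracks)
        meta = counts.meta
        libs = meta.index[meta["timepoint"] == "D2"].append(
            meta.index[meta["timepoint"] == "D12"]
        )
        res = nb_glm_test(
            counts.counts[libs], list("aaabbb"), counts.library_sizes[libs]
        )
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_adult_onset_recall_on_small_sim(self, small_config, small_experiment):
        from agemark.differential import normalized_peak_levels
        from agemark.peaks import PeakCallParams, call_peaks, merge_peaksets
        from agemark.pipeline import pooled_track
        from agemark.genes import assign_peaks

        exp = small_experiment
        merged = None
        for tp in ("D2", "D12"):
            ps = call_peaks(
                pooled_track(exp, "H3K4me3", tp), pooled_track(exp, "H3", tp),
                PeakCallParams(), "narrow",
            )
            merged = ps if merged is None else merge_peaksets(merged, ps)
        counts = count_in_peaks(merged, exp.tracks)
        levels = normalized_peak_levels(counts)
        res = timepoint_contrast(counts, levels, ("L3", "D2"))
        assignment = assign_peaks(merged, exp.annotation)
        truth = exp.truth.table
        adult = set(truth.index[truth["onset"] == "adult"])
        t = assignment.table.copy()
        t["class"] = t["peak_id"].map(res.table["class"])
        gained = set(t.loc[t["class"] == "D2>L3", "gene_id"])
        covered = adult & set(t["gene_id"])
        assert len(covered) >= 5
        assert sum(1 for g in covered if g in gained) / len(covered) >= 0.8

        # larval-onset stable genes are predominantly non-significant
        larval_stable = set(
            truth.index[(truth["onset"] == "larval") & (truth["trend"] == "stable")]
        ) & set(t["gene_id"])
        ns_genes = {
            g for g in larval_stable
            if (t.loc[t["gene_id"] == g, "class"] == "ns").all()
        }
        assert len(ns_genes) / len(larval_stable) >= 0.9
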