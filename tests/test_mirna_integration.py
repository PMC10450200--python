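import numpy as np
import pandas as pd
import pytest
from scipy import stats

from patpipe._utils import rng_for
from patpipe.mirna_integration import (
    ShiftTestResult,
    correlation_network,
    filter_target_pairs,
    negative_correlation_screen,
    nested_model_anova,
    stratified_shift_test,
    target_shift_test,
)


def _pairs(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "context_score"])


class TestFilterTargetPairs:
    def test_strong_score_kept(self):
        out = filter_target_pairs(_pairs([("m1", "g1", -0.5)]))
        assert len(out) == 1

    def test_weak_score_dropped(self):
        out = filter_target_pairs(_pairs([("m1", "g1", -0.1)]))
        assert out.empty

    def test_boundary_score_kept(self):
        out = filter_target_pairs(_pairs([("m1", "g1", -0.2)]))
        assert len(out) == 1  # only scores > -0.2 are excluded

    def test_excluded_mirna_dropped_entirely(self):
        out = filter_target_pairs(
            _pairs([("m1", "g1", -0.5), ("m1", "g2", -0.9), ("m2", "g1", -0.5)]),
            exclusion_list={"m1"},
        )
        assert set(out["mirna_id"]) == {"m2"}


class TestTargetShiftTest:
    def _metrics(self, n=400, seed=0):
        rng = rng_for(seed, "metrics")
        return pd.DataFrame(
            {"rfp_lfc": rng.normal(0, 1, n)},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_random_targets_null(self):
        metrics = self._metrics(seed=1)
        rng = rng_for(1, "targets")
        targets = rng.choice(metrics.index, 50, replace=False)
        pairs = _pairs([("m1", g, -0.5) for g in targets])
        res = target_shift_test(pairs, metrics, metric="rfp_lfc")
        assert res.loc[0, "p_adjusted"] > 0.05

    def test_shifted_targets_detected_with_direction(self):
        metrics = self._metrics(seed=2)
        targets = list(metrics.index[:300])
        metrics.loc[targets, "rfp_lfc"] -= 0.5
        pairs = _pairs([("m1", g, -0.5) for g in targets])
        res = target_shift_test(pairs, metrics, metric="rfp_lfc")
        assert res.loc[0, "p_adjusted"] < 0.01
        assert res.loc[0, "direction"] == -1
        assert res.loc[0, "n_targets"] == 300
        assert res.loc[0, "n_background"] == 100

    def test_toy_d_matches_brute_force(self):
        vals = pd.DataFrame(
            {"m": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0, 4.0, 5.0, 6.0, 10.0]},
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
        )
        pairs = _pairs([("m1", f"g{i}", -0.5) for i in range(5)])
        res = target_shift_test(pairs, vals, metric="m")
        t = vals["m"].iloc[:5].to_numpy()
        b = vals["m"].iloc[5:].to_numpy()
        grid = np.concatenate([t, b])
        d_brute = max(abs((t <= x).mean() - (b <= x).mean()) for x in grid)
        assert res.loc[0, "D"] == pytest.approx(d_brute)

    def test_too_few_targets_skipped(self):
        metrics = self._metrics()
        pairs = _pairs([("m1", "g0", -0.5), ("m1", "g1", -0.5)])
        assert target_shift_test(pairs, metrics, metric="rfp_lfc").empty

    def test_bonferroni_across_mirnas(self):
        metrics = self._metrics(seed=3)
        rows = []
        rng = rng_for(3, "multi")
        for m in range(4):
            for g in rng.choice(metrics.index, 30, replace=False):
                rows.append((f"m{m}", g, -0.5))
        res = target_shift_test(_pairs(rows), metrics, metric="rfp_lfc")
        assert len(res) == 4
        assert np.allclose(res["p_adjusted"], np.minimum(res["p_raw"] * 4, 1.0))

    def test_background_is_set_membership_not_order(self):
        metrics = self._metrics(seed=4)
        pairs = _pairs([("m1", g, -0.5) for g in metrics.index[:50]])
        res1 = target_shift_test(pairs, metrics, metric="rfp_lfc")
        res2 = target_shift_test(pairs, metrics.sample(frac=1, random_state=0), metric="rfp_lfc")
        assert res1.loc[0, "D"] == res2.loc[0, "D"]


class TestShiftTestResultInvariants:
    def test_d_bounds_enforced(self):
        with pytest.raises(ValueError):
            ShiftTestResult("x", "m", 10, 10, D=1.5, p_raw=0.1, p_adjusted=0.1, direction=1)


class TestStratifiedShiftTest:
    def test_bins_partition_counts(self):
        counts = pd.Series(
            [0, 1, 2, 3, 4, 5, 6, 9, 0, 1],
            index=[f"g{i}" for i in range(10)],
        )
        bins = [(0, 0), (1, 2), (3, 5), (6, np.inf)]
        seen = []
        for lo, hi in bins:
            seen += list(counts[(counts >= lo) & (counts <= hi)].index)
        assert sorted(seen) == sorted(counts.index)

    def test_dose_effect_monotone_medians(self):
        rng = rng_for(5, "dose")
        n = 800
        peaks = rng.integers(0, 10, n)
        metric = 0.15 * peaks + rng.normal(0, 0.3, n)
        strata = pd.Series(peaks, index=[f"g{i}" for i in range(n)])
        metrics = pd.DataFrame(
            {"mrna_lfc": metric}, index=pd.Index(strata.index, name="gene_id")
        )
        res, trend = stratified_shift_test(strata, metrics, metric="mrna_lfc")
        assert trend == pytest.approx(1.0)
        assert res["p_adjusted"].iloc[-1] < 0.01

    def test_empty_stratum_skipped(self):
        strata = pd.Series([0, 0, 0], index=["g0", "g1", "g2"])
        metrics = pd.DataFrame(
            {"m": [0.1, 0.2, 0.3]}, index=pd.Index(["g0", "g1", "g2"], name="gene_id")
        )
        res, _ = stratified_shift_test(strata, metrics, metric="m")
        assert set(res["set_label"]) <= {"0"}


class TestNegativeCorrelationScreen:
    def _exprs(self, n_samples=8, seed=0):
        rng = rng_for(seed, "corr")
        samples = [f"s{i}" for i in range(n_samples)]
        mirna = pd.DataFrame(
            rng.normal(5, 1, (3, n_samples)),
            index=["m1", "m2", "m3"],
            columns=samples,
        )
        genes = pd.DataFrame(
            rng.normal(40, 5, (3, n_samples)),
            index=["g1", "g2", "g3"],
            columns=samples,
        )
        return mirna, genes

    def test_perfect_anticorrelation(self):
        mirna, genes = self._exprs()
        genes.loc["g1"] = -mirna.loc["m1"].to_numpy()
        pairs = _pairs([("m1", "g1", -0.5)])
        res = negative_correlation_screen(mirna, genes, pairs)
        assert res.loc[0, "pearson_r"] == pytest.approx(-1.0)
        assert res.loc[0, "p_value"] < 1e-6

    def test_null_pairs_rarely_pass_fdr(self):
        rng = rng_for(7, "null-corr")
        samples = [f"s{i}" for i in range(6)]
        mirna = pd.DataFrame(
            rng.normal(0, 1, (40, 6)), index=[f"m{i}" for i in range(40)], columns=samples
        )
        genes = pd.DataFrame(
            rng.normal(0, 1, (25, 6)), index=[f"g{i}" for i in range(25)], columns=samples
        )
        pairs = _pairs([(m, g, -0.5) for m in mirna.index for g in genes.index])
        res = negative_correlation_screen(mirna, genes, pairs)
        assert len(res) == 1000
        assert abs((res["p_value"] < 0.05).mean() - 0.05) < 0.03
        assert res["significant"].mean() <= 0.005  # essentially none pass FDR

    def test_toy_r_matches_hand_covariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        mirna = pd.DataFrame([x], index=["m1"], columns=[f"s{i}" for i in range(5)])
        genes = pd.DataFrame([y], index=["g1"], columns=[f"s{i}" for i in range(5)])
        res = negative_correlation_screen(mirna, genes, _pairs([("m1", "g1", -0.5)]))
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.loc[0, "pearson_r"] == pytest.approx(r_hand)

    def test_zero_variance_series_skipped(self):
        mirna, genes = self._exprs()
        mirna.loc["m1"] = 3.0
        res = negative_correlation_screen(mirna, genes, _pairs([("m1", "g1", -0.5)]))
        assert res.empty

    def test_too_few_shared_samples_raises(self):
        mirna, genes = self._exprs(n_samples=3)
        with pytest.raises(ValueError):
            negative_correlation_screen(mirna, genes, _pairs([("m1", "g1", -0.5)]))

    def test_network_export(self):
        mirna, genes = self._exprs()
        genes.loc["g1"] = -mirna.loc["m1"].to_numpy()
        res = negative_correlation_screen(mirna, genes, _pairs([("m1", "g1", -0.5)]))
        nodes, edges = correlation_network(res)
        assert set(nodes["kind"]) == {"mirna", "gene"}
        assert len(edges) == 1


class TestNestedModelAnova:
    def test_toy_matches_hand_rss_arithmetic(self):
        rng = rng_for(11, "anova")
        n = 12
        base = rng.normal(0, 1, n)
        added = rng.normal(0, 1, n)
        y = 0.5 * base + 0.8 * added + rng.normal(0, 0.3, n)
        F, p = nested_model_anova(y, base, added)
        X0 = np.column_stack([np.ones(n), base])
        X1 = np.column_stack([np.ones(n), base, added])
        rss0 = np.sum((y - X0 @ np.linalg.pinv(X0) @ y) ** 2)
        rss1 = np.sum((y - X1 @ np.linalg.pinv(X1) @ y) ** 2)
        F_hand = (rss0 - rss1) / (rss1 / (n - 3))
        assert F == pytest.approx(F_hand)
        assert p == pytest.approx(stats.f.sf(F_hand, 1, n - 3))

    def test_noise_covariate_null_uniform(self):
        rng = rng_for(12, "anova-null")
        ps = []
        for _ in range(200):
            base = rng.normal(0, 1, 30)
            y = 0.5 * base + rng.normal(0, 1, 30)
            noise = rng.normal(0, 1, 30)
            ps.append(nested_model_anova(y, base, noise)[1])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_generating_covariate_significant(self):
        rng = rng_for(13, "anova-sig")
        base = rng.normal(0, 1, 200)
        added = rng.normal(0, 1, 200)
        y = 0.5 * base + 0.6 * added + rng.normal(0, 0.5, 200)
        _, p = nested_model_anova(y, base, added)
        assert p < 1e-6

    def test_collinear_covariates_flagged(self):
        base = np.arange(20.0)
        F, p = nested_model_anova(base * 0.5, base, 2 * base)
        assert np.isnan(F) and np.isnan(p)

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError):
            nested_model_anova(np.ones(5), np.ones(5), np.ones(5))
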