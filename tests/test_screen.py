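"""Feature matching, ANOVA + BH statistics, binder calling, and PCA QC."""

import numpy as np
import pytest

from ligandfish.feature_io import Feature, FeatureRun
from ligandfish.screen import (
    MatchedFeature,
    anova_pvalues,
    bh_adjust,
    call_binders,
    match_runs,
    oneway_anova_p,
    pca_qc,
)


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        j_values = [(m / (j + 1)) * p[order[j]] for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(j_values))
    return q


def make_run(condition, replicate, rows, polarity="negative"):
    feats = [
        Feature(id=f"{condition[0]}{replicate}_{i}", mz=mz, rt=rt, area=area, polarity=polarity)
        for i, (mz, rt, area) in enumerate(rows)
    ]
    return FeatureRun("s", condition, replicate, polarity, feats)


class TestMatchRuns:
    def test_identical_duplicated_run_matches_one_to_one(self):
        rows = [(191.0561, 8.08, 100.0), (300.0, 10.0, 50.0), (577.1563, 27.3, 20.0)]
        runs = [make_run("control", 1, rows), make_run("enzyme", 1, rows)]
        matched = match_runs(runs)
        assert len(matched) == 3
        for m in matched:
            areas = list(m.areas.values())
            assert len(areas) == 2 and areas[0] == areas[1]

    def test_close_features_matched(self):
        runs = [
            make_run("control", 1, [(191.0561, 8.08, 100.0)]),
            make_run("enzyme", 1, [(191.0563, 8.10, 60.0)]),
        ]
        matched = match_runs(runs)
        assert len(matched) == 1
        assert set(matched[0].areas) == {("control", 1), ("enzyme", 1)}

    def test_distant_masses_not_matched(self):
        runs = [
            make_run("control", 1, [(400.0, 8.0, 100.0)]),
            make_run("enzyme", 1, [(400.0 * (1 + 25e-6), 8.0, 100.0)]),
        ]
        assert len(match_runs(runs, tol_ppm=10)) == 2

    def test_distant_rt_not_matched(self):
        runs = [
            make_run("control", 1, [(400.0, 8.0, 100.0)]),
            make_run("enzyme", 1, [(400.0, 8.5, 100.0)]),
        ]
        assert len(match_runs(runs, tol_rt=0.3)) == 2

    def test_mixed_polarity_rejected(self):
        runs = [
            make_run("control", 1, [(400.0, 8.0, 1.0)]),
            make_run("enzyme", 1, [(400.0, 8.0, 1.0)], polarity="positive"),
        ]
        with pytest.raises(ValueError, match="polarity"):
            match_runs(runs)

    def test_condition_swap_flips_log2fc_only(self):
        rng = np.random.default_rng(7)
        rows_c = [(m, r, a) for m, r, a in zip(rng.uniform(100, 900, 20), rng.uniform(1, 30, 20), rng.uniform(10, 1e4, 20))]
        rows_e = [(m * (1 + 1e-6), r + 0.01, a * 0.5) for m, r, a in rows_c]
        forward = [
            make_run("control", 1, rows_c), make_run("control", 2, rows_c),
            make_run("enzyme", 1, rows_e), make_run("enzyme", 2, rows_e),
        ]
        swapped = [
            make_run("enzyme", 1, rows_c), make_run("enzyme", 2, rows_c),
            make_run("control", 1, rows_e), make_run("control", 2, rows_e),
        ]
        fwd = sorted(call_binders(match_runs(forward)), key=lambda c: c.matched.consensus_mz)
        swp = sorted(call_binders(match_runs(swapped)), key=lambda c: c.matched.consensus_mz)
        for a, b in zip(fwd, swp):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-9)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestAnova:
    def test_identical_groups_p_one(self):
        assert oneway_anova_p(np.array([3.0, 3.0, 3.0]), np.array([3.0, 3.0, 3.0])) == 1.0

    def test_f_statistic_matches_brute_force_and_scipy(self):
        from scipy.stats import f_oneway

        a = np.array([4.1, 5.0, 3.9])
        b = np.array([7.2, 8.1, 7.7])
        ours = oneway_anova_p(a, b)
        # brute-force sums of squares
        grand = np.concatenate([a, b]).mean()
        ss_b = 3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
        ss_w = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_stat = (ss_b / 1) / (ss_w / 4)
        from scipy.stats import f as f_dist

        assert ours == pytest.approx(float(f_dist.sf(f_stat, 1, 4)), rel=1e-12)
        assert ours == pytest.approx(f_oneway(a, b).pvalue, rel=1e-9)

    def test_large_separation_small_p(self):
        a = np.array([0.0, 0.1, -0.1])
        b = a + 10 * a.std(ddof=1)
        assert oneway_anova_p(a, b) < 1e-3

    def test_underpowered_feature_flagged_not_dropped(self):
        matched = [
            MatchedFeature(200.0, 5.0, "negative",
                           {("control", 1): 10.0, ("control", 2): 12.0,
                            ("enzyme", 1): 5.0, ("enzyme", 2): 6.0}),
            MatchedFeature(300.0, 6.0, "negative", {("control", 1): 10.0}),
        ]
        p, flags = anova_pvalues(matched)
        assert p.shape == (2,)
        assert not flags[0] and flags[1]
        assert p[1] == 1.0


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]).tolist() == [0.123]

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2] * 3)

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.array_equal(bh_adjust(p), bh_oracle(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallBinders:
    def _matched(self, control, enzyme, mz=200.0):
        areas = {("control", i + 1): a for i, a in enumerate(control)}
        areas.update({("enzyme", i + 1): a for i, a in enumerate(enzyme)})
        return MatchedFeature(mz, 5.0, "negative", areas)

    def test_strong_decrease_called_binder(self):
        m = self._matched([100.0, 100.0, 100.0], [10.0, 10.1, 9.9])
        null = self._matched([50.0, 50.5, 49.5], [50.2, 49.8, 50.1], mz=300.0)
        calls = call_binders([m, null])
        by_mz = {c.matched.consensus_mz: c for c in calls}
        binder = by_mz[200.0]
        assert binder.decision == "binder"
        assert binder.log2fc == pytest.approx(np.log2(10.0 / 100.0), abs=0.01)
        assert by_mz[300.0].decision == "unchanged"

    def test_identical_areas_unchanged(self):
        m = self._matched([100.0, 101.0, 99.0], [100.0, 101.0, 99.0])
        (call,) = call_binders([m])
        assert call.decision == "unchanged"
        assert call.log2fc == pytest.approx(0.0, abs=1e-9)

    def test_increase_called_increased(self):
        m = self._matched([10.0, 10.1, 9.9], [100.0, 100.0, 100.0])
        null = self._matched([50.0, 50.5, 49.5], [50.2, 49.8, 50.1], mz=300.0)
        calls = call_binders([m, null])
        assert {c.matched.consensus_mz: c.decision for c in calls}[200.0] == "increased"

    def test_sorted_by_q_then_effect(self):
        calls = call_binders(
            [
                self._matched([100.0, 99.0, 101.0], [10.0, 10.5, 9.5], mz=200.0),
                self._matched([100.0, 99.0, 101.0], [98.0, 102.0, 100.0], mz=300.0),
            ]
        )
        assert calls[0].q_value <= calls[1].q_value

    def test_zero_noise_spike_in_exact_recovery(self):
        from ligandfish.synth import default_scenario, evaluate_calls, simulate_screen

        scenario = default_scenario(seed=5, cv=0.0, mz_sd_ppm=0.0, rt_jitter_sd=0.0)
        runs, truth = simulate_screen(scenario)
        calls = call_binders(match_runs(runs))
        metrics = evaluate_calls(calls, truth)
        assert metrics["recall"] == 1.0
        assert metrics["fdr"] == 0.0


class TestPcaQc:
    def _matched_from_matrix(self, X, conditions):
        matched = []
        for j in range(X.shape[1]):
            areas = {}
            rep_counter = {}
            for i, condition in enumerate(conditions):
                rep_counter[condition] = rep_counter.get(condition, 0) + 1
                areas[(condition, rep_counter[condition])] = float(X[i, j])
            matched.append(MatchedFeature(100.0 + j, 5.0, "negative", areas))
        return matched

    def test_zero_variance_matrix_zero_scores(self):
        X = np.full((4, 10), 100.0)
        result = pca_qc(self._matched_from_matrix(X, ["control", "control", "enzyme", "enzyme"]))
        assert np.allclose(result.scores.to_numpy(), 0.0)

    def test_explained_variance_sums_below_one(self, rng):
        X = rng.uniform(10, 1000, size=(6, 30))
        result = pca_qc(self._matched_from_matrix(X, ["control"] * 3 + ["enzyme"] * 3))
        assert result.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_strong_condition_effect_separates(self):
        from ligandfish.synth import benchmark_scenario, simulate_screen

        scenario = benchmark_scenario(seed=3, n_null=50, n_binders=50, decrease=0.9)
        runs, _ = simulate_screen(scenario)
        result = pca_qc(match_runs(runs))
        assert result.condition_silhouette > 0.5

    def test_fewer_runs_than_components_raises(self):
        X = np.ones((3, 5))
        matched = self._matched_from_matrix(X, ["control", "control", "enzyme"])
        with pytest.raises(ValueError):
            pca_qc(matched, n_components=4)
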