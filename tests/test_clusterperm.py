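"""Pointwise statistics, cluster formation, and the permutation null.

The exhaustive-enumeration mode is checked against an independent brute-force
reimplementation (scipy paired t per time point, hand-rolled run scanning)
over all (c!)^n relabelings of a small instance.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

import latemp
from latemp.clusterperm import ConditionMeans, PointwiseStats
from latemp.errors import ConfigurationError, ValidationError
from latemp.preprocess import TrialSample


def _sample(participant, valence, values, emotion=None, trial_id=0):
    emotion = emotion or ("joy" if valence == "positive" else "fear")
    return TrialSample(participant, "exp1", "tympanic", emotion, valence,
                       trial_id, np.asarray(values, float))


class TestConditionMeans:
    def test_replicates_average_to_cell_value(self):
        samples = [
            _sample("P01", "negative", [1.0, 2.0], trial_id=0),
            _sample("P01", "negative", [3.0, 4.0], trial_id=1),
            _sample("P01", "positive", [5.0, 6.0], trial_id=2),
            _sample("P02", "negative", [0.0, 0.0], trial_id=3),
            _sample("P02", "positive", [1.0, 1.0], trial_id=4),
        ]
        m = latemp.condition_means(samples, "valence")
        assert m.conditions == ["negative", "positive"]
        np.testing.assert_array_equal(m.data[0, 0], [2.0, 3.0])  # mean of replicates
        np.testing.assert_array_equal(m.data[0, 1], [5.0, 6.0])

    def test_default_design_shapes(self, tympanic_samples):
        corrected = [latemp.baseline_correct(s) for s in tympanic_samples]
        assert latemp.condition_means(corrected, "valence").data.shape == (10, 2, 120)
        m = latemp.condition_means(corrected, "emotion")
        assert m.data.shape == (10, 4, 120)
        assert m.conditions == ["fear", "sadness", "joy", "love"]

    def test_missing_condition_is_an_error(self):
        samples = [
            _sample("P01", "negative", [1.0]),
            _sample("P01", "positive", [1.0], trial_id=1),
            _sample("P02", "negative", [1.0], trial_id=2),
        ]
        with pytest.raises(ValidationError, match="P02"):
            latemp.condition_means(samples, "valence")


class TestPairedT:
    def test_threshold_matches_published_critical_value(self):
        m = ConditionMeans(np.random.default_rng(0).normal(size=(10, 2, 5)),
                           [f"P{i}" for i in range(10)], ["negative", "positive"])
        ps = latemp.paired_t_series(m)
        assert ps.df == (9,)
        assert round(ps.threshold, 2) == 2.26
        # cross-check the pointwise values against scipy's paired t-test
        for k in range(5):
            expected = sstats.ttest_rel(m.data[:, 1, k], m.data[:, 0, k]).statistic
            assert ps.values[k] == pytest.approx(expected)

    def test_identical_conditions_give_zero(self):
        data = np.tile(np.random.default_rng(1).normal(size=(4, 1, 6)), (1, 2, 1))
        m = ConditionMeans(data, list("abcd"), ["negative", "positive"])
        with pytest.warns(UserWarning, match="zero-variance"):
            ps = latemp.paired_t_series(m)
        np.testing.assert_array_equal(ps.values, np.zeros(6))

    def test_constant_nonzero_difference_is_degenerate(self):
        data = np.zeros((4, 2, 3))
        data[:, 1, :] = 1.0  # d = [1,1,1,1]: sd = 0, statistic set to 0
        m = ConditionMeans(data, list("abcd"), ["negative", "positive"])
        with pytest.warns(UserWarning, match="zero-variance"):
            ps = latemp.paired_t_series(m)
        np.testing.assert_array_equal(ps.values, np.zeros(3))


class TestRmAnovaF:
    def test_threshold_matches_published_critical_value(self):
        m = ConditionMeans(np.random.default_rng(0).normal(size=(10, 4, 5)),
                           [f"P{i}" for i in range(10)], list("wxyz"))
        ps = latemp.rm_anova_F_series(m)
        assert ps.df == (3, 27)
        assert round(ps.threshold, 2) == 2.96

    def test_identical_conditions_give_zero(self):
        data = np.tile(np.random.default_rng(2).normal(size=(5, 1, 4)), (1, 3, 1))
        m = ConditionMeans(data, list("abcde"), list("xyz"))
        with pytest.warns(UserWarning, match="zero residual"):
            ps = latemp.rm_anova_F_series(m)
        np.testing.assert_allclose(ps.values, np.zeros(4), atol=1e-20)

    def test_two_conditions_reduce_to_squared_t(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(8, 2, 10))
        m = ConditionMeans(data, [f"P{i}" for i in range(8)],
                           ["negative", "positive"])
        t = latemp.paired_t_series(m).values
        F = latemp.rm_anova_F_series(m).values
        np.testing.assert_allclose(F, t**2, rtol=1e-10)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        data = rng.normal(size=(6, 4, 3))
        m = ConditionMeans(data, [f"P{i}" for i in range(6)], list("wxyz"))
        ours = latemp.rm_anova_F_series(m).values
        for k in range(3):
            df = pd.DataFrame(
                {
                    "y": data[:, :, k].ravel(),
                    "subject": np.repeat(np.arange(6), 4),
                    "cond": np.tile(np.arange(4), 6),
                }
            )
            aov = pingouin.rm_anova(data=df, dv="y", within="cond", subject="subject")
            assert ours[k] == pytest.approx(float(aov["F"].iloc[0]), rel=1e-8)

    def test_too_small_designs_rejected(self):
        with pytest.raises(ValidationError):
            latemp.rm_anova_F_series(
                ConditionMeans(np.zeros((1, 4, 3)), ["a"], list("wxyz"))
            )


class TestFormClusters:
    def _stats(self, values, threshold=2.26, kind="paired_t"):
        return PointwiseStats(kind, np.asarray(values, float), (9,), threshold)

    def test_no_suprathreshold_points(self):
        assert latemp.form_clusters(self._stats([0.0, 1.0, -2.0])) == []

    def test_single_run_mass(self):
        values = np.zeros(10)
        values[5:8] = 3.0
        (cl,) = latemp.form_clusters(self._stats(values))
        assert (cl.start_s, cl.end_s, cl.sign) == (5, 7, "+")
        assert cl.mass == pytest.approx(9.0)

    def test_sign_change_breaks_adjacency(self):
        clusters = latemp.form_clusters(self._stats([3.0, -3.0, 3.0]))
        assert [(c.start_s, c.end_s, c.sign) for c in clusters] == [
            (0, 0, "+"), (1, 1, "-"), (2, 2, "+"),
        ]
        assert [c.mass for c in clusters] == pytest.approx([3.0, -3.0, 3.0])

    def test_f_statistic_has_single_tail(self):
        values = np.array([4.0, 0.0, 4.0, 4.0])
        clusters = latemp.form_clusters(self._stats(values, 2.96, "rm_anova_F"))
        assert [(c.start_s, c.end_s) for c in clusters] == [(0, 0), (2, 3)]
        assert all(c.sign == "n/a" for c in clusters)

    def test_mass_is_sum_of_pointwise_statistics(self):
        rng = np.random.default_rng(5)
        values = rng.normal(scale=3, size=200)
        for cl in latemp.form_clusters(self._stats(values)):
            np.testing.assert_allclose(
                cl.mass, values[cl.start_s : cl.end_s + 1].sum(), rtol=1e-12
            )


def brute_force_valence_test(data: np.ndarray, threshold: float):
    """Independent oracle: exhaustive cluster test for c = 2.

    Enumerates every within-participant relabeling (sign pattern on the paired
    differences), computes scipy's paired t per time point, scans runs with a
    plain loop, and returns (observed clusters, null max-masses, p-values).
    """

    def t_series(d):
        out = np.zeros(d.shape[1])
        for k in range(d.shape[1]):
            if d[:, k].std(ddof=1) == 0:
                continue
            out[k] = sstats.ttest_1samp(d[:, k], 0.0).statistic
        return out

    def clusters_of(values):
        found, run = [], []
        for k, v in enumerate(values):
            lab = 1 if v > threshold else (-1 if v < -threshold else 0)
            if run and (lab == 0 or lab != run[0][1]):
                found.append(sum(x for _, _, x in run))
                run = []
            if lab != 0:
                run.append((k, lab, v))
        if run:
            found.append(sum(x for _, _, x in run))
        return found

    d = data[:, 1, :] - data[:, 0, :]
    n = d.shape[0]
    observed = clusters_of(t_series(d))
    null = []
    for signs in itertools.product([1, -1], repeat=n):
        masses = clusters_of(t_series(np.array(signs)[:, None] * d))
        null.append(max((abs(m) for m in masses), default=0.0))
    null = np.array(null)
    pvals = [float((null >= abs(m)).sum()) / null.size for m in observed]
    return observed, null, pvals


class TestPermutationNull:
    def test_exhaustive_space_size_two_conditions(self):
        rng = np.random.default_rng(6)
        m = ConditionMeans(rng.normal(size=(3, 2, 4)), list("abc"),
                           ["negative", "positive"])
        null = latemp.permutation_null(m, "paired_t", exhaustive=True)
        assert null.n_permutations == 8  # (2!)^3

    def test_zero_signal_zero_noise_gives_all_zero_null(self):
        m = ConditionMeans(np.zeros((4, 2, 6)), list("abcd"),
                           ["negative", "positive"])
        null = latemp.permutation_null(m, "paired_t", n_permutations=50, seed=1)
        np.testing.assert_array_equal(null.max_stats, np.zeros(50))

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(4, 2, 10))
        data[:, 1, 3:6] += 1.5  # plant a short excursion
        m = ConditionMeans(data, list("abcd"), ["negative", "positive"])
        ps = latemp.paired_t_series(m)
        clusters = latemp.form_clusters(ps)
        null = latemp.permutation_null(m, "paired_t", exhaustive=True)
        clusters = latemp.cluster_p_values(clusters, null)

        exp_masses, exp_null, exp_p = brute_force_valence_test(data, ps.threshold)
        assert null.n_permutations == 16
        np.testing.assert_allclose(np.sort(null.max_stats), np.sort(exp_null),
                                   rtol=1e-10)
        assert [c.mass for c in clusters] == pytest.approx(exp_masses)
        assert [c.p_value for c in clusters] == pytest.approx(exp_p)

    def test_exhaustive_cap_enforced(self):
        rng = np.random.default_rng(8)
        m = ConditionMeans(rng.normal(size=(10, 4, 3)),
                           [f"P{i}" for i in range(10)], list("wxyz"))
        with pytest.raises(ConfigurationError, match="cap"):
            latemp.permutation_null(m, "rm_anova_F", exhaustive=True)

    def test_null_reproducible_under_seed(self):
        rng = np.random.default_rng(9)
        m = ConditionMeans(rng.normal(size=(6, 4, 12)),
                           [f"P{i}" for i in range(6)], list("wxyz"))
        a = latemp.permutation_null(m, "rm_anova_F", 40, seed=3)
        b = latemp.permutation_null(m, "rm_anova_F", 40, seed=3)
        c = latemp.permutation_null(m, "rm_anova_F", 40, seed=4)
        np.testing.assert_array_equal(a.max_stats, b.max_stats)
        assert not np.array_equal(a.max_stats, c.max_stats)

    def test_fast_and_generic_paths_agree_for_two_conditions(self):
        """The sign-flip vectorization must reproduce the per-permutation loop."""
        rng = np.random.default_rng(10)
        data = rng.normal(size=(5, 2, 15))
        m = ConditionMeans(data, list("abcde"), ["negative", "positive"])
        fast = latemp.permutation_null(m, "paired_t", exhaustive=True)
        # generic route: per-pattern gather + squared-t == F for c = 2
        mF = latemp.permutation_null(m, "rm_anova_F", exhaustive=True)
        thr_t = latemp.paired_t_series(m).threshold
        thr_F = latemp.rm_anova_F_series(m).threshold
        assert thr_F == pytest.approx(thr_t**2)
        # identical supra-threshold sets => same cluster spans; masses are t vs
        # t^2 so compare detection counts only
        assert (fast.max_stats > 0).sum() == (mF.max_stats > 0).sum()


class TestClusterPValues:
    def test_counting_rule(self):
        null = latemp.NullDistribution(np.array([1.0, 2.0, 3.0, 4.0]), 4, None)
        (cl,) = latemp.cluster_p_values(
            [latemp.Cluster(0, 1, -2.5, "-")], null
        )
        assert cl.p_value == pytest.approx(0.5)
        assert cl.p_value_corrected == pytest.approx(3 / 5)

    def test_mass_larger_than_every_null_entry(self):
        null = latemp.NullDistribution(np.array([1.0, 2.0]), 2, None)
        (cl,) = latemp.cluster_p_values([latemp.Cluster(0, 0, 9.0, "+")], null)
        assert cl.p_value == 0.0
        assert cl.p_value_corrected == pytest.approx(1 / 3)

    def test_zero_mass_has_p_one(self):
        null = latemp.NullDistribution(np.array([0.0, 1.0, 2.0]), 3, None)
        (cl,) = latemp.cluster_p_values([latemp.Cluster(0, 0, 0.0, "+")], null)
        assert cl.p_value == 1.0


class TestClusterTest:
    def test_injected_effect_found_in_window(self, tympanic_samples):
        res = latemp.cluster_test(tympanic_samples, "valence", 1000, seed=2)
        sig = res.significant_clusters
        assert sig, "expected a significant valence cluster"
        assert any(c.start_s <= 84 and c.end_s >= 70 for c in sig)
        # the negative-valence shift makes positive-minus-negative positive
        assert all(c.sign == "+" for c in sig)

    def test_wrist_channels_show_no_effect(self, wrist_samples):
        res = latemp.cluster_test(wrist_samples, "valence", 1000, seed=2)
        assert res.significant_clusters == []

    def test_single_participant_rejected(self):
        samples = [
            _sample("P01", "negative", np.zeros(10)),
            _sample("P01", "positive", np.zeros(10), trial_id=1),
        ]
        with pytest.raises(ValidationError, match="participants"):
            latemp.cluster_test(samples, "valence", 10, seed=0)

    def test_exchangeability_under_fixed_relabeling(self):
        """Swapping each participant's condition labels flips the observed
        cluster signs but leaves the exhaustive null, and hence every p-value,
        unchanged."""
        rng = np.random.default_rng(11)
        base = rng.normal(size=(5, 2, 12))
        base[:, 1, 4:7] += 1.0
        samples, swapped = [], []
        for i in range(5):
            p = f"P{i:02d}"
            samples += [
                _sample(p, "negative", base[i, 0], trial_id=2 * i),
                _sample(p, "positive", base[i, 1], trial_id=2 * i + 1),
            ]
            swapped += [
                _sample(p, "negative", base[i, 1], trial_id=2 * i),
                _sample(p, "positive", base[i, 0], trial_id=2 * i + 1),
            ]
        res_a = latemp.cluster_test(samples, "valence", seed=0, exhaustive=True)
        res_b = latemp.cluster_test(swapped, "valence", seed=0, exhaustive=True)
        np.testing.assert_allclose(np.sort(res_a.null.max_stats),
                                   np.sort(res_b.null.max_stats), rtol=1e-10)
        assert [c.p_value for c in res_a.clusters] == [
            c.p_value for c in res_b.clusters
        ]
        assert [c.mass for c in res_a.clusters] == pytest.approx(
            [-c.mass for c in res_b.clusters]
        )

    def test_result_serializable(self, tympanic_samples):
        import json

        res = latemp.cluster_test(tympanic_samples[:40], "valence", 50, seed=0)
        blob = json.dumps(res.to_dict())
        assert json.loads(blob)["n_permutations"] == 50


def test_detection_rate_monotone_in_effect_magnitude():
    """Power increases with the planted effect size (checked at 3 magnitudes)."""
    rates = []
    for magnitude in (0.0, -0.1, -0.3):
        hits = 0
        for seed in range(6):
            eff = latemp.EffectSpec(effect_magnitude=magnitude, noise_sd=0.08)
            design = latemp.StudyDesign(n_participants=6, experiments=("exp1",))
            recs, trials, _ = latemp.generate_experiment(design, eff, seed=100 + seed)
            samples = [
                s
                for s in latemp.preprocess_dataset(recs, trials)
                if s.site == "tympanic"
            ]
            res = latemp.cluster_test(samples, "valence", 200, seed=seed)
            hits += bool(res.significant_clusters)
        rates.append(hits / 6)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]
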