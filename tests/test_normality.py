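"""KDE model of normality, bandwidth rule, novelty scores and trajectories."""

import numpy as np
import pandas as pd
import pytest

import vitaldrift as vd
from vitaldrift.normality import NormalityModel, NoveltyThreshold
from vitaldrift.sammon import NormalizationParams

UNIT_PARAMS = NormalizationParams(mu=np.zeros(5), sigma=np.ones(5))


def direct_kde(X, sigma, q):
    """Naive direct-summation oracle for the KDE likelihood."""
    X = np.atleast_2d(X)
    N, D = X.shape
    s = sum(np.exp(-np.sum((q - xi) ** 2) / (2 * sigma**2)) for xi in X)
    return s / (N * (2 * np.pi) ** (D / 2) * sigma**D)


class TestBandwidth:
    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            vd.estimate_bandwidth(np.ones((5, 5)))

    def test_two_points_reduces_k_and_gives_their_distance(self):
        X = np.zeros((2, 5))
        X[1, 0] = 3.0
        with pytest.warns(UserWarning, match="reduced"):
            bw = vd.estimate_bandwidth(X, k=10)
        assert bw.k == 1
        assert bw.sigma == pytest.approx(3.0)

    def test_line_configuration_matches_exhaustive_oracle(self):
        """12 unit-spaced points on a line embedded in 5-D, k = 10."""
        X = np.zeros((12, 5))
        X[:, 0] = np.arange(12.0)
        bw = vd.estimate_bandwidth(X, k=10)
        deltas = []
        for i in range(12):
            d = np.sort([abs(i - j) for j in range(12) if j != i])[:10]
            deltas.append(np.mean(d))
        assert bw.sigma == pytest.approx(np.mean(deltas), rel=1e-12)
        np.testing.assert_allclose(bw.deltas, deltas, rtol=1e-12)

    def test_random_points_match_brute_force(self, rng):
        X = rng.normal(size=(40, 5))
        bw = vd.estimate_bandwidth(X, k=10)
        for i in rng.integers(0, 40, size=5):
            dists = np.sort(np.linalg.norm(X - X[i], axis=1))[1:11]
            assert bw.deltas[i] == pytest.approx(dists.mean(), rel=1e-12)

    def test_scaling_property_exact(self, rng):
        X = rng.normal(size=(30, 5))
        s1 = vd.estimate_bandwidth(X, k=10).sigma
        s3 = vd.estimate_bandwidth(3.0 * X, k=10).sigma
        assert s3 == pytest.approx(3.0 * s1, rel=1e-12)


class TestLikelihood:
    def test_single_centre_closed_form(self):
        model = NormalityModel(np.zeros((1, 5)), sigma=1.0)
        val = vd.likelihood(model, np.zeros(5))
        assert val == pytest.approx((2 * np.pi) ** -2.5, rel=1e-12)
        assert val == pytest.approx(0.01011, abs=1e-5)

    def test_far_query_tends_to_zero(self):
        model = NormalityModel(np.zeros((1, 5)), sigma=1.0)
        assert vd.likelihood(model, np.full(5, 50.0)) < 1e-100

    def test_matches_direct_summation(self, rng):
        X = rng.normal(size=(4, 5))
        model = NormalityModel(X, sigma=0.7)
        q = rng.normal(size=5)
        assert vd.likelihood(model, q) == pytest.approx(direct_kde(X, 0.7, q), rel=1e-12)

    def test_monte_carlo_integral_d2(self, rng):
        """In a 2-D reduction, the KDE integrates to ~1 over a bounding box."""
        X = rng.normal(size=(10, 2))
        model = NormalityModel(X, sigma=0.5)
        lo, hi = X.min() - 6, X.max() + 6
        n = 200_000
        pts = rng.uniform(lo, hi, size=(n, 2))
        vals = vd.likelihood(model, pts)
        vol = (hi - lo) ** 2
        est = vol * vals.mean()
        se = vol * vals.std(ddof=1) / np.sqrt(n)
        assert abs(est - 1.0) < 3 * se


class TestNoveltyScore:
    def test_analytic_single_centre(self):
        model = NormalityModel(np.zeros((1, 5)), sigma=1.0)
        z = vd.novelty_score(model, np.zeros(5))
        assert z == pytest.approx(2.5 * np.log(2 * np.pi), rel=1e-12)
        assert z == pytest.approx(4.594, abs=1e-3)

    def test_agrees_with_direct_sum_at_moderate_distance(self, rng):
        X = rng.normal(size=(50, 5))
        model = NormalityModel(X, sigma=1.0)
        q = rng.normal(size=5) + 2.0
        assert vd.novelty_score(model, q) == pytest.approx(
            -np.log(direct_kde(X, 1.0, q)), abs=1e-10)

    def test_finite_where_direct_sum_underflows(self, rng):
        X = rng.normal(size=(20, 5))
        model = NormalityModel(X, sigma=0.3)
        q = np.full(5, 100.0)
        assert direct_kde(X, 0.3, q) == 0.0  # naive evaluation underflows
        z = vd.novelty_score(model, q)
        assert np.isfinite(z) and z > 1000

    def test_translation_consistency(self, rng):
        X = rng.normal(size=(30, 5))
        q = rng.normal(size=5)
        shift = rng.normal(size=5) * 10
        a = vd.novelty_score(NormalityModel(X, sigma=0.8), q)
        b = vd.novelty_score(NormalityModel(X + shift, sigma=0.8), q + shift)
        assert a == pytest.approx(b, abs=1e-10)

    def test_decreasing_in_likelihood(self, rng):
        X = rng.normal(size=(30, 5))
        model = NormalityModel(X, sigma=1.0)
        near, far = X.mean(axis=0), X.mean(axis=0) + 5
        assert vd.likelihood(model, near) > vd.likelihood(model, far)
        assert vd.novelty_score(model, near) < vd.novelty_score(model, far)


class TestTrainingSet:
    def test_counts_last_day_observations(self):
        obs = [vd.VitalSignObservation("P", t, 80 + t, 16, 97, 120, 36.5)
               for t in (0.0, 12.0, 25.0, 30.0)]
        cohort = vd.Cohort([vd.PatientRecord("P", obs, outcome="normal")])
        X = vd.training_set(cohort, UNIT_PARAMS)
        assert X.shape == (2, 5)          # two observations on day 2

    def test_matches_tagged_filter_oracle(self, small_cohort):
        normal, _ = vd.split_by_outcome(vd.preprocess(small_cohort))
        X = vd.training_set(normal, UNIT_PARAMS)
        expected = [o.values() for p in normal
                    for o in p.observations
                    if vd.day_index(o.time) == p.last_day]
        np.testing.assert_allclose(X, np.array(expected), rtol=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            vd.training_set(vd.Cohort([]), UNIT_PARAMS)

    def test_study_scale_training_count(self, default_model):
        """Discharge-day pooling at study scale lands near the ~1,100-vector regime."""
        _, model, _ = default_model
        assert 700 <= model.n_training <= 1500


def _const_score_patient(pid, z_target_obs):
    obs = [vd.VitalSignObservation(pid, float(t), *vals)
           for t, vals in z_target_obs]
    return vd.PatientRecord(pid, obs, outcome="normal")


class TestDailyNovelty:
    def test_single_observation_days(self, rng):
        X = rng.normal(size=(20, 5))
        model = NormalityModel(X, sigma=1.0)
        obs = [vd.VitalSignObservation("P", 24.0 * d, *rng.normal(size=5))
               for d in range(3)]
        p = vd.PatientRecord("P", obs, outcome="normal")
        f = vd.daily_novelty(model, p, UNIT_PARAMS)
        for _, row in f.iterrows():
            o = p.observations_on_day(int(row["day"]))[0]
            assert row["z_mean"] == pytest.approx(
                vd.novelty_score(model, o.values()), rel=1e-12)

    def test_matches_groupby_oracle(self, rng, default_model):
        params, model, _ = default_model
        patient = vd.generate_cohort(vd.SyntheticParams(n_normal=1, n_abnormal=0,
                                                        seed=77)).patients[0]
        f = vd.daily_novelty(model, patient, params)
        Z = vd.novelty_score(model, vd.normalize(patient.matrix(), params))
        oracle = (pd.DataFrame({"day": [vd.day_index(o.time) for o in patient.observations],
                                "z": Z}).groupby("day")["z"].mean())
        for _, row in f.iterrows():
            assert row["z_mean"] == pytest.approx(oracle[row["day"]], rel=1e-12)

    def test_abnormal_scored_only_to_event(self, default_model):
        params, model, _ = default_model
        p = vd.generate_cohort(vd.SyntheticParams(n_normal=0, n_abnormal=1,
                                                  seed=5)).patients[0]
        f = vd.daily_novelty(model, p, params)
        assert f["day"].max() <= vd.day_index(p.event_time)


class TestThreshold:
    def test_constant_scores_give_k_equal_mu(self):
        thr = NoveltyThreshold(mu_z=2.0, sd_z=0.0)
        assert thr.k_threshold == 2.0

    def test_hand_computed_example(self):
        # z in {0, 1, 2}: mean 1, sample SD 1 -> k = 1 + 3*1 = 4
        z = np.array([0.0, 1.0, 2.0])
        thr = NoveltyThreshold(mu_z=float(z.mean()), sd_z=float(z.std(ddof=1)))
        assert thr.k_threshold == pytest.approx(4.0)

    def test_zero_multiplier_gives_mu(self, default_model):
        params, model, _ = default_model
        normal = vd.Cohort([vd.generate_cohort(
            vd.SyntheticParams(n_normal=3, n_abnormal=0, seed=8)).patients[0]])
        thr = vd.compute_threshold(model, normal, params, multiplier=0.0)
        assert thr.k_threshold == pytest.approx(thr.mu_z)


class TestGroupTrajectory:
    def test_single_patient_group(self, default_model):
        params, model, _ = default_model
        p = vd.generate_cohort(vd.SyntheticParams(n_normal=1, n_abnormal=0,
                                                  seed=31)).patients[0]
        traj = vd.group_trajectory(vd.Cohort([p]), model, params)
        daily = vd.daily_novelty(model, p, params).set_index("day")["z_mean"]
        for _, row in traj.summary.iterrows():
            assert row["z_mean"] == pytest.approx(daily[row["day"]], rel=1e-12)
            assert row["z_se"] == 0.0

    def test_two_constant_patients_average(self, monkeypatch, default_model):
        params, model, _ = default_model
        cohort = vd.generate_cohort(vd.SyntheticParams(n_normal=2, n_abnormal=0, seed=9))

        def fake_daily(model_, patient, params_):
            z = 1.0 if patient.patient_id == "N001" else 3.0
            return pd.DataFrame({"day": [1, 2, 3, 4], "z_mean": z, "n_obs": 1})

        monkeypatch.setattr(vd.normality, "daily_novelty", fake_daily)
        traj = vd.normality.group_trajectory(cohort, model, params)
        assert (traj.summary["z_mean"] == 2.0).all()
        # SE of {1, 3}: sd = sqrt(2), over sqrt(2) patients -> 1
        np.testing.assert_allclose(traj.summary["z_se"], 1.0, rtol=1e-12)

    def test_normal_group_recovers_then_flattens(self, default_split, default_model):
        """Mean novelty falls over days 1-4, then is approximately constant."""
        normal, _ = default_split
        params, model, _ = default_model
        traj = vd.group_trajectory(normal, model, params)
        s = traj.summary.set_index("day")["z_mean"]
        early = np.polyfit([1, 2, 3, 4], s.loc[[1, 2, 3, 4]], 1)[0]
        late_days = [d for d in s.index if d > 4]
        late = np.polyfit(late_days, s.loc[late_days], 1)[0]
        assert early < 0
        assert abs(late) < 0.25 * abs(early)
        assert traj.truncation_day == 12   # 75th percentile of stays at study scale
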