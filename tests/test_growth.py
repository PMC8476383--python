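"""Saturating-exponential growth model: fitting, prediction, scoring."""

import numpy as np
import pytest

from myelinmap.growth import (
    FitError,
    GrowthParams,
    NormativeReference,
    RegionObservation,
    compare_strata,
    correct_age,
    deviation_z,
    fit_growth,
    fit_growth_arrays,
    params_from_anchors,
    predict_r1,
    read_observations,
    reference_table,
    round_half_away,
    write_observations,
)

SPLENIUM_LIKE = GrowthParams(r1_inf=1.22, amplitude=-0.78, tau=12.9)


def make_obs(age, r1, sd=0.03, region="splenium", side="midline", sex="unknown", sid="S1"):
    return RegionObservation(
        subject_id=sid, age=age, region=region, side=side, r1_mean=r1, r1_sd=sd, sex=sex
    )


class TestPredict:
    def test_birth_value_is_r1_inf_plus_amplitude(self):
        assert predict_r1(SPLENIUM_LIKE, 0.0) == pytest.approx(1.22 - 0.78)

    def test_monotone_increasing_and_saturating(self):
        ages = np.linspace(0, 200, 500)
        values = predict_r1(SPLENIUM_LIKE, ages)
        assert np.all(np.diff(values) > 0)
        assert abs(predict_r1(SPLENIUM_LIKE, 50 * 12.9) - 1.22) < 1e-9

    @pytest.mark.parametrize(
        "tau, anchors, age, expected",
        [
            (13.6, ((0, 0.37), (12, 0.84)), 24, 1.03),  # genu
            (12.9, ((0, 0.44), (24, 1.09)), 12, 0.91),  # splenium
        ],
    )
    def test_published_reference_values(self, tau, anchors, age, expected):
        params = params_from_anchors(tau, *anchors)
        assert round_half_away(predict_r1(params, age), 2) == expected


class TestParamsFromAnchors:
    def test_recovers_generating_curve(self):
        anchors = [(3.0, predict_r1(SPLENIUM_LIKE, 3.0)), (40.0, predict_r1(SPLENIUM_LIKE, 40.0))]
        params = params_from_anchors(12.9, anchors[0], anchors[1])
        assert params.r1_inf == pytest.approx(1.22, abs=1e-12)
        assert params.amplitude == pytest.approx(-0.78, abs=1e-12)
        # identity on its anchors
        for age, r1 in anchors:
            assert predict_r1(params, age) == pytest.approx(r1, abs=1e-12)

    def test_coincident_ages_rejected(self):
        with pytest.raises(ValueError):
            params_from_anchors(12.9, (5.0, 0.8), (5.0, 0.9))


class TestFitGrowth:
    def test_noise_free_recovery(self):
        ages = np.array([3.0, 6, 12, 24, 48, 72])
        r1 = predict_r1(SPLENIUM_LIKE, ages)
        fit = fit_growth_arrays(ages, r1, np.full(ages.size, 0.03))
        assert fit.r1_inf == pytest.approx(1.22, abs=1e-6)
        assert fit.amplitude == pytest.approx(-0.78, abs=1e-6)
        assert fit.tau == pytest.approx(12.9, abs=1e-5)

    def test_uniform_weight_scaling_leaves_estimates_invariant(self, rng):
        ages = rng.uniform(3, 72, 40)
        r1 = predict_r1(SPLENIUM_LIKE, ages) + rng.normal(0, 0.03, 40)
        fit1 = fit_growth_arrays(ages, r1, np.full(40, 0.03))
        fit2 = fit_growth_arrays(ages, r1, np.full(40, 0.06))
        assert fit2.r1_inf == pytest.approx(fit1.r1_inf, rel=1e-7)
        assert fit2.tau == pytest.approx(fit1.tau, rel=1e-7)
        np.testing.assert_allclose(fit2.covariance, 4.0 * fit1.covariance, rtol=1e-5)

    def test_objective_at_optimum_not_worse_than_truth(self, rng):
        ages = rng.uniform(3, 72, 60)
        sigma = np.full(60, 0.03)
        r1 = predict_r1(SPLENIUM_LIKE, ages) + rng.normal(0, 0.03, 60)
        fit = fit_growth_arrays(ages, r1, sigma)

        def objective(p):
            return float((((r1 - predict_r1(p, ages)) / sigma) ** 2).sum())

        assert objective(fit) <= objective(SPLENIUM_LIKE) + 1e-9

    def test_monte_carlo_self_consistency(self, rng):
        # recovered tau is unbiased within 5% and its spread matches the
        # quoted (linearized) uncertainty
        taus, reported = [], []
        for _ in range(200):
            ages = rng.uniform(3, 72, 94)
            r1 = predict_r1(SPLENIUM_LIKE, ages) + rng.normal(0, 0.03, 94)
            fit = fit_growth_arrays(ages, r1, np.full(94, 0.03))
            taus.append(fit.tau)
            reported.append(fit.tau_uncertainty)
        taus = np.array(taus)
        assert abs(taus.mean() - 12.9) / 12.9 < 0.05
        assert np.mean(reported) == pytest.approx(taus.std(), rel=0.25)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_growth_arrays([1, 2, 3], [0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            fit_growth_arrays([1, 2, 3, 4], [0.5, 0.6, 0.7, 0.8])  # span < 12 mo

    def test_zero_sigma_falls_back_unweighted(self):
        ages = np.array([3.0, 6, 12, 24, 48, 72])
        r1 = predict_r1(SPLENIUM_LIKE, ages)
        obs = [make_obs(a, v, sd=0.0) for a, v in zip(ages, r1)]
        obs[0] = make_obs(3.0, r1[0], sd=0.02)
        with pytest.warns(UserWarning, match="unweighted"):
            fit = fit_growth(obs)
        assert fit.tau == pytest.approx(12.9, abs=1e-4)

    def test_mixed_regions_rejected(self):
        obs = [make_obs(3, 0.5), make_obs(40, 1.1, region="genu")]
        with pytest.raises(ValueError, match="mix regions"):
            fit_growth(obs)


class TestDeviation:
    def test_on_curve_scores_zero(self):
        obs = make_obs(20.0, predict_r1(SPLENIUM_LIKE, 20.0), sd=0.05)
        score = deviation_z(obs, SPLENIUM_LIKE)
        assert score.z == pytest.approx(0.0, abs=1e-12)
        assert not score.flagged

    def test_low_r1_patient_flagged(self):
        # internal-capsule curve anchored at published birth/12-month
        # values; a 42.5-month-old with R1 = 0.99 +- 0.05 sits ~2.9 SD low
        params = params_from_anchors(16.5, (0.0, 0.76), (12.0, 0.97))
        obs = make_obs(42.5, 0.99, sd=0.05, region="plic", side="right")
        score = deviation_z(obs, params)
        assert score.z == pytest.approx(-2.9, abs=0.05)
        assert score.flagged

    def test_zero_uncertainty_without_covariance_errors(self):
        obs = make_obs(20.0, 1.0, sd=0.0)
        with pytest.raises(ValueError, match="undefined"):
            deviation_z(obs, SPLENIUM_LIKE)

    def test_model_covariance_widens_the_score(self, rng):
        ages = rng.uniform(3, 72, 60)
        r1 = predict_r1(SPLENIUM_LIKE, ages) + rng.normal(0, 0.03, 60)
        fit = fit_growth_arrays(ages, r1, np.full(60, 0.03))
        obs = make_obs(30.0, predict_r1(fit, 30.0) - 0.1, sd=0.03)
        with_cov = deviation_z(obs, fit)
        bare = GrowthParams(fit.r1_inf, fit.amplitude, fit.tau)
        without_cov = deviation_z(obs, bare)
        assert abs(with_cov.z) < abs(without_cov.z)


class TestReferenceTable:
    def test_cells_round_half_away(self):
        reference = NormativeReference(
            params={"splenium": params_from_anchors(12.9, (0, 0.44), (24, 1.09))}
        )
        table = reference_table(reference, ages=[0, 12, 24])
        assert list(table.loc["splenium"]) == [0.44, 0.91, 1.09]

    def test_empty_reference_gives_empty_table(self):
        table = reference_table(NormativeReference(params={}))
        assert table.empty

    def test_precision_only_affects_rounding(self):
        params = {"genu": params_from_anchors(13.6, (0, 0.37), (12, 0.84))}
        ref = NormativeReference(params=params)
        fine = reference_table(ref, ages=[24], precision=6)
        coarse = reference_table(ref, ages=[24], precision=2)
        assert round_half_away(float(fine.iloc[0, 0]), 2) == float(coarse.iloc[0, 0])

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13


class TestStrata:
    @staticmethod
    def simulate(tau, n, rng, sex, noise=0.02):
        params = GrowthParams(1.1, -0.6, tau)
        ages = rng.uniform(3, 72, n)
        return [
            make_obs(a, predict_r1(params, a) + rng.normal(0, noise), sd=noise,
                     sex=sex, sid=f"{sex}{i}")
            for i, a in enumerate(ages)
        ]

    def test_identical_strata_overlap(self, rng):
        male = self.simulate(15.0, 40, np.random.default_rng(7), "male")
        female = [
            RegionObservation(
                subject_id=f"f{i}", age=o.age, region=o.region, side=o.side,
                r1_mean=o.r1_mean, r1_sd=o.r1_sd, sex="female",
            )
            for i, o in enumerate(male)
        ]
        report = compare_strata(male + female)["splenium"]
        assert report.tau_overlap is True
        assert report.male.tau == pytest.approx(report.female.tau, rel=1e-6)

    def test_distinct_time_constants_separate(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            obs = self.simulate(13.0, 40, rng, "male") + self.simulate(20.0, 40, rng, "female")
            report = compare_strata(obs)["splenium"]
            hits += report.tau_overlap is False
        assert hits >= 90

    def test_single_sex_marks_other_absent(self, rng):
        report = compare_strata(self.simulate(15.0, 40, rng, "male"))["splenium"]
        assert report.female is None
        assert report.tau_overlap is None


class TestIngest:
    def test_prematurity_correction(self):
        assert correct_age(10.0, None) == 10.0
        # born at 32 weeks: 8 weeks early ~ 1.84 months
        assert correct_age(10.0, 32.0) == pytest.approx(10.0 - 8 / (365.25 / 12 / 7))
        assert correct_age(0.5, 28.0) == 0.0  # clipped at zero

    def test_csv_round_trip_and_correction(self, tmp_path):
        obs = [make_obs(10.0, 0.9, sd=0.02, sid="A"), make_obs(30.0, 1.1, sd=0.03, sid="B")]
        path = tmp_path / "obs.csv"
        write_observations(obs, path)
        back = read_observations(path)
        assert [o.age for o in back] == [10.0, 30.0]
        assert [o.r1_mean for o in back] == [0.9, 1.1]
        # gestational_weeks column triggers correction at ingest
        text = path.read_text().splitlines()
        text[0] += ",gestational_weeks"
        text[1] += ",32"
        text[2] += ",40"
        path.write_text("\n".join(text))
        corrected = read_observations(path)
        assert corrected[0].age < 10.0
        assert corrected[1].age == 30.0
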