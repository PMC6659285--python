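import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streetpa.aggregation import Neighbourhood
from streetpa.config import (
    INDICATORS,
    INTENSITIES,
    SimulationTruth,
    WorldConfig,
    default_truth,
    null_truth,
)
from streetpa.errors import ConfigError, DimensionError
from streetpa.synthetic_data import (
    SceneFeatureVector,
    generate_scene_features,
    generate_survey,
    generate_world,
    latent_perception,
    latent_scores_frame,
    points_along_segment,
    rater_oracle,
    sample_scene_matrix,
)


class TestGenerateWorld:
    def test_deterministic(self, small_world):
        p1, n1 = generate_world(small_world)
        p2, n2 = generate_world(small_world)
        assert [(p.x, p.y) for p in p1] == [(p.x, p.y) for p in p2]
        assert [(nb.x, nb.y) for nb in n1] == [(nb.x, nb.y) for nb in n2]

    def test_single_neighbourhood_has_point_in_buffer(self):
        cfg = WorldConfig(n_neighbourhoods=1, seed=1)
        points, nbhds = generate_world(cfg)
        nb = nbhds[0]
        d = [np.hypot(p.x - nb.x, p.y - nb.y) for p in points]
        assert min(d) <= cfg.buffer_radius_m

    def test_segment_point_count(self):
        assert len(points_along_segment(1000.0, 100.0)) == 11

    def test_stranding_config_rejected(self):
        with pytest.raises(ConfigError):
            WorldConfig(point_spacing_m=2500.0, buffer_radius_m=1000.0)

    def test_heading_validation(self):
        with pytest.raises(ConfigError):
            WorldConfig(headings=(0.0, 0.0))
        with pytest.raises(ConfigError):
            WorldConfig(headings=(0.0, 360.0))


class TestSceneFeatures:
    def test_simplex_and_cardinality(self, small_world, small_truth):
        points, _ = generate_world(small_world)
        scenes = generate_scene_features(points[:10], small_world, small_truth, seed=1)
        assert len(scenes) == 10 * len(small_world.headings)
        feats = scenes[[c for c in scenes.columns if c.startswith("class_")]].to_numpy()
        assert np.allclose(feats.sum(axis=1), 1.0, atol=1e-9)
        assert feats.min() >= 0

    def test_deterministic(self, small_world, small_truth):
        points, _ = generate_world(small_world)
        s1 = generate_scene_features(points[:5], small_world, small_truth, seed=9)
        s2 = generate_scene_features(points[:5], small_world, small_truth, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_symmetric_dirichlet_moment(self):
        # K=4 symmetric concentration: each component mean 1/4
        world = WorldConfig(n_neighbourhoods=1, n_object_classes=4, seed=0)
        truth = default_truth(world, seed=0)
        truth = truth.replace(
            nbhd_compositions=np.full((1, 4), 0.25), scene_concentration=8.0
        )
        X, _ = sample_scene_matrix(10_000, truth, np.random.default_rng(5))
        assert np.allclose(X.mean(axis=0), 0.25, atol=0.01)

    def test_between_neighbourhood_contrast(self, small_world, small_truth):
        # latent point scores must genuinely differ across neighbourhoods
        points, _ = generate_world(small_world)
        scenes = generate_scene_features(points, small_world, small_truth, seed=2)
        latent = latent_scores_frame(scenes, small_truth)
        nbhd_of_point = {p.point_id: p.nearest_nbhd for p in points}
        groups = latent["point_id"].map(nbhd_of_point)
        for ind in INDICATORS:
            samples = [latent.loc[groups == j, ind] for j in sorted(groups.unique())]
            f, p = stats.f_oneway(*samples)
            assert p < 1e-6, f"no neighbourhood contrast for {ind}"


class TestLatentPerception:
    def _truth(self, weights, intercept, K=2):
        w = {ind: np.zeros(K) for ind in INDICATORS}
        w["safe"] = np.asarray(weights, dtype=float)
        ic = {ind: 5.0 for ind in INDICATORS}
        ic["safe"] = intercept
        return SimulationTruth(
            indicator_weights=w, indicator_intercepts=ic, rater_sd=0.0,
            beta={"const": 0.0}, sigma2_u=0.0, sigma2_e=1.0,
        )

    def test_zero_weights_gives_intercept(self):
        truth = self._truth([0.0, 0.0], 5.0)
        assert latent_perception(np.array([0.4, 0.6]), truth, "safe") == 5.0

    def test_clipping_at_scale_top(self):
        truth = self._truth([1.0, 1.0], 20.0)
        assert latent_perception(np.array([0.5, 0.5]), truth, "safe") == 10.0

    def test_dot_product(self):
        truth = self._truth([10.0, 0.0], 0.0)
        assert latent_perception(np.array([0.3, 0.7]), truth, "safe") == pytest.approx(3.0)

    def test_dimension_mismatch(self):
        truth = self._truth([1.0, 1.0], 0.0)
        with pytest.raises(DimensionError):
            latent_perception(np.array([0.2, 0.3, 0.5]), truth, "safe")

    def test_scene_feature_vector_validation(self):
        with pytest.raises(DimensionError):
            SceneFeatureVector("i", "p", 0.0, np.array([0.5, 0.6]))


class TestRaterOracle:
    def test_zero_noise_exact(self, rng):
        assert rater_oracle(6.3, 0.0, rng) == 6.3

    def test_clipped_at_top(self):
        rng = np.random.default_rng(0)
        assert all(rater_oracle(10.0, 3.0, rng) <= 10.0 for _ in range(200))

    def test_noise_sd_recovered(self):
        rng = np.random.default_rng(3)
        draws = np.array([rater_oracle(5.0, 0.5, rng) for _ in range(10_000)])
        assert draws.std() == pytest.approx(0.5, abs=0.02)


def _scored_neighbourhoods(n, scores=None):
    nbhds = []
    for j in range(n):
        nb = Neighbourhood(nbhd_id=j, x=0.0, y=0.0)
        nb.true_scores = scores or {ind: 5.0 for ind in INDICATORS}
        nbhds.append(nb)
    return nbhds


class TestGenerateSurvey:
    def test_intercept_only_degenerate(self, small_world):
        truth = null_truth(small_world, icc=0.0, intercept=4.0, seed=1)
        truth = truth.replace(sigma2_e=1e-12)
        survey = generate_survey(_scored_neighbourhoods(4), small_world, truth, seed=1)
        assert np.allclose(survey["total_pa_latent"], 4.0, atol=1e-5)

    def test_product_identity_within_rounding(self, small_world, small_truth):
        survey = generate_survey(
            _scored_neighbourhoods(6), small_world, small_truth, seed=5
        )
        recon = sum(
            survey[f"{i}_days"] * survey[f"{i}_min_per_day"] for i in INTENSITIES
        )
        latent_minutes = np.expm1(survey["total_pa_latent"])
        days_total = sum(survey[f"{i}_days"] for i in INTENSITIES)
        tol = 0.5 * days_total + 3.0  # rounding rule: +-day/2 per intensity, <1-min drops
        assert (np.abs(recon - latent_minutes) <= tol + 1e-9).all()

    def test_minutes_zero_when_days_zero(self, small_world, small_truth):
        survey = generate_survey(
            _scored_neighbourhoods(6), small_world, small_truth, seed=8
        )
        for i in INTENSITIES:
            zero_days = survey[f"{i}_days"] == 0
            assert (survey.loc[zero_days, f"{i}_min_per_day"] == 0).all()
            assert survey[f"{i}_days"].between(0, 7).all()

    def test_total_respondents_poisson_bounds(self, small_truth):
        world = WorldConfig(n_neighbourhoods=35, respondents_per_nbhd_mean=23, seed=4)
        survey = generate_survey(_scored_neighbourhoods(35), world, small_truth, seed=4)
        expect = 35 * 23
        assert abs(len(survey) - expect) < 4 * np.sqrt(expect)

    def test_covariate_margins(self, small_truth):
        world = WorldConfig(n_neighbourhoods=35, respondents_per_nbhd_mean=60, seed=6)
        survey = generate_survey(_scored_neighbourhoods(35), world, small_truth, seed=6)
        assert survey["age"].min() >= 18
        assert (survey["gender"] == "female").mean() == pytest.approx(0.507, abs=0.04)
        assert survey["age"].mean() == pytest.approx(42.5, abs=1.5)
        assert (survey["marital"] == "married").mean() == pytest.approx(0.822, abs=0.04)

    def test_requires_true_scores(self, small_world, small_truth):
        with pytest.raises(ConfigError):
            generate_survey(
                [Neighbourhood(nbhd_id=0, x=0, y=0)], small_world, small_truth, seed=1
            )

    def test_deterministic(self, small_world, small_truth):
        s1 = generate_survey(_scored_neighbourhoods(4), small_world, small_truth, seed=3)
        s2 = generate_survey(_scored_neighbourhoods(4), small_world, small_truth, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_variance_components_method_of_moments(self):
        # pooled one-way moments over 200 replicated surveys recover (s2u, s2e)
        world = WorldConfig(n_neighbourhoods=35, respondents_per_nbhd_mean=23, seed=2)
        truth = null_truth(world, icc=0.137, seed=2)
        nbhds = _scored_neighbourhoods(35)
        s2u_hat, s2e_hat = [], []
        for rep in range(200):
            survey = generate_survey(nbhds, world, truth, seed=1000 + rep)
            y = survey["total_pa_latent"].to_numpy()
            g = survey["nbhd_id"].to_numpy()
            means = pd.Series(y).groupby(g).mean()
            sizes = pd.Series(y).groupby(g).size()
            resid = y - means[g].to_numpy()
            msw = (resid**2).sum() / (len(y) - len(means))
            msb = (sizes * (means - y.mean()) ** 2).sum() / (len(means) - 1)
            m0 = (len(y) - (sizes**2).sum() / len(y)) / (len(means) - 1)
            s2e_hat.append(msw)
            s2u_hat.append(max(0.0, (msb - msw) / m0))
        assert np.mean(s2e_hat) == pytest.approx(truth.sigma2_e, abs=0.01)
        assert np.mean(s2u_hat) == pytest.approx(truth.sigma2_u, abs=0.008)


class TestTruthSerialisation:
    def test_round_trip(self, small_world, tmp_path):
        truth = default_truth(small_world, seed=11)
        truth.save(tmp_path / "truth.json")
        back = SimulationTruth.load(tmp_path / "truth.json")
        assert back.beta == truth.beta
        for ind in INDICATORS:
            assert np.allclose(back.indicator_weights[ind], truth.indicator_weights[ind])
        assert np.allclose(back.nbhd_compositions, truth.nbhd_compositions)

    def test_invalid_variances_rejected(self, small_world):
        truth = default_truth(small_world, seed=1)
        with pytest.raises(ConfigError):
            truth.replace(sigma2_e=0.0)
        with pytest.raises(ConfigError):
            truth.replace(sigma2_u=-0.1)
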