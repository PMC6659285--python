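"""Synthetic world generator: streets, scenes, raters, neighbourhoods, survey.

Everything downstream (scoring, aggregation, multilevel modelling) is tested
by recovering the parameters this module generates from.  All stages are
deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    Neighbourhood,
    SamplingPoint,
    attach_point_coords,
    build_exposure_table,
    point_scores_table,
)
from .config import (
    EDUCATION_LEVELS,
    GENDER_LEVELS,
    INCOME_LEVELS,
    INDICATORS,
    INTENSITIES,
    MARITAL_LEVELS,
    SCORE_MAX,
    SCORE_MIN,
    SimulationTruth,
    WorldConfig,
    invert_transform,
)
from .errors import ConfigError, DimensionError

# Dirichlet split of total PA minutes into light/moderate/vigorous shares.
INTENSITY_SHARE_ALPHA = (5.0, 2.2, 2.6)
# Intensities contributing less than this many minutes are recorded as zero days.
MIN_INTENSITY_MINUTES = 1.0


@dataclass
class SceneFeatureVector:
    """Composition of one image over the object classes (a simplex vector)."""

    image_id: str
    point_id: str
    heading: float
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise DimensionError("scene proportions must sum to 1")
        if (self.proportions < 0).any() or (self.proportions > 1).any():
            raise DimensionError("scene proportions must lie in [0, 1]")


def points_along_segment(length_m: float, spacing_m: float) -> np.ndarray:
    """Offsets of sampling points along one street segment (both ends kept)."""
    if spacing_m <= 0:
        raise ConfigError("spacing must be > 0")
    n = int(math.floor(length_m / spacing_m)) + 1
    return np.arange(n) * spacing_m


def generate_world(config: WorldConfig) -> tuple[list[SamplingPoint], list[Neighbourhood]]:
    """Lay out a rectangular street grid with sampling points and centroids.

    Neighbourhood centroids sit on a jittered grid spaced
    ``config.nbhd_spacing_m`` apart; streets run horizontally and vertically
    every ``config.street_spacing_m`` with points every
    ``config.point_spacing_m`` along them.  Raises :class:`ConfigError` for
    configs that could strand a centroid outside every buffer.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neighbourhoods
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    width = ncols * config.nbhd_spacing_m
    height = nrows * config.nbhd_spacing_m

    jit = config.centroid_jitter_m
    neighbourhoods: list[Neighbourhood] = []
    for idx in range(n):
        i, j = idx % ncols, idx // ncols
        cx = (i + 0.5) * config.nbhd_spacing_m + rng.uniform(-jit, jit)
        cy = (j + 0.5) * config.nbhd_spacing_m + rng.uniform(-jit, jit)
        neighbourhoods.append(Neighbourhood(nbhd_id=idx, x=float(cx), y=float(cy)))

    eps = 1e-9
    line_pos = np.arange(0.0, max(width, height) + eps, config.street_spacing_m)
    along_x = points_along_segment(width, config.point_spacing_m)
    along_y = points_along_segment(height, config.point_spacing_m)

    seen: set[tuple[float, float]] = set()
    coords: list[tuple[float, float]] = []
    for y in line_pos[line_pos <= height + eps]:  # horizontal streets
        for x in along_x:
            key = (round(float(x), 6), round(float(y), 6))
            if key not in seen:
                seen.add(key)
                coords.append(key)
    for x in line_pos[line_pos <= width + eps]:  # vertical streets
        for y in along_y:
            key = (round(float(x), 6), round(float(y), 6))
            if key not in seen:
                seen.add(key)
                coords.append(key)

    cxy = np.array([[nb.x, nb.y] for nb in neighbourhoods])
    points: list[SamplingPoint] = []
    for k, (x, y) in enumerate(sorted(coords)):
        d = np.hypot(cxy[:, 0] - x, cxy[:, 1] - y)
        points.append(
            SamplingPoint(point_id=f"pt{k:05d}", x=x, y=y, nearest_nbhd=int(d.argmin()))
        )

    xy = np.array([[p.x, p.y] for p in points])
    for nb in neighbourhoods:
        d = np.hypot(xy[:, 0] - nb.x, xy[:, 1] - nb.y)
        if not (d <= config.buffer_radius_m).any():
            raise ConfigError(
                f"neighbourhood {nb.nbhd_id} has no sampling point within "
                f"{config.buffer_radius_m} m"
            )
    return points, neighbourhoods


def generate_scene_features(
    points: Sequence[SamplingPoint],
    config: WorldConfig,
    truth: SimulationTruth,
    seed: int,
) -> pd.DataFrame:
    """One composition vector per (point, heading).

    Each scene is a Dirichlet draw whose concentration is centred on the mean
    composition of the point's neighbourhood, so neighbourhood-average
    compositions (and hence latent perceptions) genuinely differ.
    """
    if len(points) == 0:
        raise ConfigError("points must be non-empty")
    if truth.nbhd_compositions is None:
        raise ConfigError("truth lacks nbhd_compositions")
    rng = np.random.default_rng(seed)
    K = config.n_object_classes
    comp = np.asarray(truth.nbhd_compositions, dtype=float)
    if comp.shape[1] != K:
        raise DimensionError("truth compositions incompatible with n_object_classes")

    records = []
    feats = []
    for p in points:
        alpha = truth.scene_concentration * comp[p.nearest_nbhd] + 1e-3
        for h in config.headings:
            x = rng.dirichlet(alpha)
            records.append((f"{p.point_id}_h{int(h):03d}", p.point_id, float(h)))
            feats.append(x)
    df = pd.DataFrame(records, columns=["image_id", "point_id", "heading"])
    feat_cols = [f"class_{k}" for k in range(K)]
    df[feat_cols] = np.asarray(feats)
    return df


def feature_matrix(scenes: pd.DataFrame) -> np.ndarray:
    cols = [c for c in scenes.columns if c.startswith("class_")]
    return scenes[cols].to_numpy(dtype=float)


def sample_scene_matrix(
    n: int, truth: SimulationTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` standalone scene compositions (for scoring experiments)."""
    comp = np.asarray(truth.nbhd_compositions, dtype=float)
    idx = rng.integers(0, comp.shape[0], size=n)
    X = np.vstack(
        [rng.dirichlet(truth.scene_concentration * comp[j] + 1e-3) for j in idx]
    )
    return X, idx


def latent_perception(features, truth: SimulationTruth, indicator: str) -> float:
    """True (noise-free) perception score of one scene: clipped affine map."""
    x = features.proportions if isinstance(features, SceneFeatureVector) else np.asarray(features, float)
    w = truth.indicator_weights[indicator]
    if x.shape[-1] != w.shape[0]:
        raise DimensionError(
            f"feature length {x.shape[-1]} != weight length {w.shape[0]} for {indicator!r}"
        )
    raw = truth.indicator_intercepts[indicator] + x @ w
    return float(np.clip(raw, SCORE_MIN, SCORE_MAX))


def latent_scores_matrix(X: np.ndarray, truth: SimulationTruth, indicator: str) -> np.ndarray:
    w = truth.indicator_weights[indicator]
    if X.shape[1] != w.shape[0]:
        raise DimensionError("feature/weight length mismatch")
    return np.clip(truth.indicator_intercepts[indicator] + X @ w, SCORE_MIN, SCORE_MAX)


def latent_scores_frame(scenes: pd.DataFrame, truth: SimulationTruth) -> pd.DataFrame:
    """Per-image latent scores for all six indicators."""
    X = feature_matrix(scenes)
    out = scenes[["image_id", "point_id", "heading"]].copy()
    for ind in INDICATORS:
        out[ind] = latent_scores_matrix(X, truth, ind)
    return out


def rater_oracle(latent_score: float, rater_sd: float, rng: np.random.Generator) -> float:
    """A volunteer's observed rating: latent + Gaussian noise, clipped to scale."""
    return float(np.clip(latent_score + rng.normal(0.0, rater_sd), SCORE_MIN, SCORE_MAX))


def make_oracle(
    truth: SimulationTruth, indicator: str, rng: np.random.Generator
) -> Callable[[np.ndarray], float]:
    """Callable rating oracle for one indicator (used by the calibration loop)."""

    def oracle(proportions: np.ndarray) -> float:
        return rater_oracle(latent_perception(proportions, truth, indicator), truth.rater_sd, rng)

    return oracle


def true_neighbourhood_scores(
    scenes: pd.DataFrame,
    points: Sequence[SamplingPoint],
    neighbourhoods: Sequence[Neighbourhood],
    truth: SimulationTruth,
    radius_m: float,
) -> pd.DataFrame:
    """Noise-free neighbourhood scores via the same aggregation path as estimates.

    Fills ``Neighbourhood.true_scores`` in place and returns the table.
    """
    latent = latent_scores_frame(scenes, truth)
    long = latent.melt(
        id_vars=["image_id", "point_id", "heading"],
        value_vars=list(INDICATORS),
        var_name="indicator",
        value_name="score",
    )
    pts = attach_point_coords(point_scores_table(long), list(points))
    table = build_exposure_table(pts, list(neighbourhoods), radius_m)
    for nb in neighbourhoods:
        row = table.loc[table["nbhd_id"] == nb.nbhd_id].iloc[0]
        nb.true_scores = {ind: float(row[ind]) for ind in INDICATORS}
    return table


# -- survey ------------------------------------------------------------

def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Independent covariate draws approximating the target survey margins."""
    age = np.clip(rng.normal(42.5, 13.8, n), 18.0, 93.0).round(1)
    stay = np.clip(rng.normal(13.6, 11.3, n), 1.0, 60.0).round(1)
    return pd.DataFrame(
        {
            "gender": rng.choice(GENDER_LEVELS, size=n, p=(0.507, 0.493)),
            "age": age,
            "marital": rng.choice(MARITAL_LEVELS, size=n, p=(0.178, 0.822)),
            "education": rng.choice(EDUCATION_LEVELS, size=n, p=(0.028, 0.513, 0.459)),
            "income_band": rng.choice(INCOME_LEVELS, size=n, p=(0.080, 0.710, 0.152, 0.058)),
            "household_size": np.clip(np.round(rng.normal(3.3, 0.9, n)), 1, 8).astype(int),
            "length_of_stay": stay,
            "functional_restriction": rng.random(n) < 0.041,
        }
    )


def _fixed_part(cov: pd.DataFrame, scores: dict[str, float], beta: dict[str, float]) -> np.ndarray:
    eta = np.full(len(cov), beta["const"], dtype=float)
    eta += beta["gender:male"] * (cov["gender"] == "male").to_numpy()
    eta += beta["age"] * cov["age"].to_numpy()
    eta += beta["marital:married"] * (cov["marital"] == "married").to_numpy()
    eta += beta["education:high_school"] * (cov["education"] == "high_school").to_numpy()
    eta += beta["education:college_or_above"] * (cov["education"] == "college_or_above").to_numpy()
    eta += beta["income_band:10_20k"] * (cov["income_band"] == "10_20k").to_numpy()
    eta += beta["income_band:20_40k"] * (cov["income_band"] == "20_40k").to_numpy()
    eta += beta["income_band:ge_40k"] * (cov["income_band"] == "ge_40k").to_numpy()
    eta += beta["household_size"] * cov["household_size"].to_numpy()
    eta += beta["length_of_stay"] * cov["length_of_stay"].to_numpy()
    eta += beta["functional_restricted"] * cov["functional_restriction"].to_numpy()
    for ind in INDICATORS:
        eta += beta[ind] * scores[ind]
    return eta


def _factor_minutes(
    total: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Split total minutes into (days, minutes/day) per intensity.

    Rounding rule: intensities below ``MIN_INTENSITY_MINUTES`` are dropped;
    otherwise days ~ 1 + min(Poisson(2.5), 6) and minutes/day is the rounded
    share, floored at 1.  The per-intensity product identity
    ``minutes = days * minutes_per_day`` holds exactly by construction.
    """
    n = total.shape[0]
    shares = rng.dirichlet(INTENSITY_SHARE_ALPHA, size=n)
    out: dict[str, np.ndarray] = {}
    for i, intensity in enumerate(INTENSITIES):
        minutes = shares[:, i] * total
        days = np.where(
            minutes < MIN_INTENSITY_MINUTES, 0, 1 + np.minimum(rng.poisson(2.5, n), 6)
        ).astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            mpd = np.where(days > 0, np.maximum(np.round(minutes / np.maximum(days, 1)), 1), 0)
        out[f"{intensity}_days"] = days
        out[f"{intensity}_min_per_day"] = mpd.astype(int)
    return out


def generate_survey(
    neighbourhoods: Sequence[Neighbourhood],
    config: WorldConfig,
    truth: SimulationTruth,
    seed: int,
) -> pd.DataFrame:
    """Respondent table with covariates, IPAQ items and the latent outcome.

    Every neighbourhood must already carry its six TRUE perception scores
    (``Neighbourhood.true_scores``).  The transformed total-PA outcome follows
    the two-level linear model of ``truth``; IPAQ (days, minutes/day) items
    are factored from total minutes so that the product identity holds.
    ``total_pa_latent`` preserves the continuous transformed outcome.
    """
    rng = np.random.default_rng(seed)
    for nb in neighbourhoods:
        if not nb.true_scores:
            raise ConfigError(f"neighbourhood {nb.nbhd_id} lacks true perception scores")

    frames = []
    for nb in neighbourhoods:
        n_j = max(1, int(rng.poisson(config.respondents_per_nbhd_mean)))
        cov = _draw_covariates(n_j, rng)
        eta = _fixed_part(cov, nb.true_scores, truth.beta)
        u_j = rng.normal(0.0, math.sqrt(truth.sigma2_u))
        e = rng.normal(0.0, math.sqrt(truth.sigma2_e), n_j)
        y = eta + u_j + e
        total_minutes = invert_transform(y, truth.outcome_transform)
        cov.insert(0, "nbhd_id", nb.nbhd_id)
        cov["total_pa_latent"] = y
        for col, vals in _factor_minutes(total_minutes, rng).items():
            cov[col] = vals
        frames.append(cov)
    survey = pd.concat(frames, ignore_index=True)
    survey.insert(0, "person_id", [f"r{i:05d}" for i in range(len(survey))])
    return survey


# -- writers (plain-text interchange formats) --------------------------

def write_points_geojson(points: Sequence[SamplingPoint], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "metadata": {"crs": "local planar metres"},
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": {"point_id": p.point_id, "nearest_nbhd": p.nearest_nbhd},
            }
            for p in points
        ],
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def write_neighbourhoods_geojson(
    neighbourhoods: Sequence[Neighbourhood], path: str | Path
) -> None:
    fc = {
        "type": "FeatureCollection",
        "metadata": {"crs": "local planar metres"},
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [nb.x, nb.y]},
                "properties": {"nbhd_id": nb.nbhd_id},
            }
            for nb in neighbourhoods
        ],
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def neighbourhoods_frame(neighbourhoods: Sequence[Neighbourhood]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nbhd_id": [nb.nbhd_id for nb in neighbourhoods],
            "x": [nb.x for nb in neighbourhoods],
            "y": [nb.y for nb in neighbourhoods],
        }
    )
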