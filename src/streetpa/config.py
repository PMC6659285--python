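"""Configuration containers, ground-truth parameters and their (de)serialisation.

Every knob of the synthetic pipeline lives here: the world geometry, the
scoring-loop settings, and the generating parameters (``SimulationTruth``)
that downstream stages are tested against by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ConfigError

#: The six scene-perception indicators, in canonical order.
INDICATORS = ("wealthy", "safe", "lively", "depressing", "boring", "beautiful")

#: Physical-activity intensity levels.
INTENSITIES = ("light", "moderate", "vigorous")

GENDER_LEVELS = ("female", "male")
MARITAL_LEVELS = ("single_divorced_widowed", "married")
EDUCATION_LEVELS = ("primary_or_below", "high_school", "college_or_above")
INCOME_LEVELS = ("le_10k", "10_20k", "20_40k", "ge_40k")

#: Score scale bounds used everywhere a rating appears.
SCORE_MIN, SCORE_MAX = 0.0, 10.0


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and size of the synthetic study area."""

    n_neighbourhoods: int = 35
    respondents_per_nbhd_mean: float = 23.0
    point_spacing_m: float = 100.0
    n_object_classes: int = 12
    headings: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    buffer_radius_m: float = 1000.0
    street_spacing_m: float = 600.0
    nbhd_spacing_m: float = 1200.0
    centroid_jitter_m: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbourhoods < 1:
            raise ConfigError("n_neighbourhoods must be >= 1")
        if self.respondents_per_nbhd_mean < 1:
            raise ConfigError("respondents_per_nbhd_mean must be >= 1")
        if self.n_object_classes < 1:
            raise ConfigError("n_object_classes must be >= 1")
        if self.point_spacing_m <= 0 or self.street_spacing_m <= 0:
            raise ConfigError("spacings must be > 0")
        if self.buffer_radius_m <= 0:
            raise ConfigError("buffer_radius_m must be > 0")
        if len(set(self.headings)) != len(self.headings):
            raise ConfigError("headings must be distinct")
        if any(h < 0 or h >= 360 for h in self.headings):
            raise ConfigError("headings must lie in [0, 360)")
        if self.point_spacing_m > 2 * self.buffer_radius_m:
            raise ConfigError(
                "point_spacing_m exceeds twice the buffer radius; "
                "neighbourhood centroids could be stranded without points"
            )


@dataclass(frozen=True)
class ScoringConfig:
    """Settings of the iterative human-machine calibration loop."""

    initial_batch: int = 300
    rmse_window: int = 100
    rmse_threshold: float = 0.5
    retrain_every: int = 25
    max_calibration_images: int = 2000
    regressor_params: dict[str, Any] = field(
        default_factory=lambda: {"n_estimators": 100, "min_samples_leaf": 2, "n_jobs": 1}
    )
    holdout_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rmse_window < 1:
            raise ConfigError("rmse_window must be >= 1")
        if self.rmse_threshold <= 0:
            raise ConfigError("rmse_threshold must be > 0")
        if self.retrain_every < 1:
            raise ConfigError("retrain_every must be >= 1")
        if self.initial_batch < 2:
            raise ConfigError("initial_batch must be >= 2")


@dataclass
class SimulationTruth:
    """All generating parameters of one synthetic world.

    ``indicator_weights[ind]`` (length ``n_object_classes``) and
    ``indicator_intercepts[ind]`` define the latent perception score of a
    scene as ``clip(intercept + weights . proportions, 0, 10)``.
    ``beta`` holds the fixed effects of the two-level outcome model on the
    transformed scale; ``sigma2_u``/``sigma2_e`` its variance components.
    """

    indicator_weights: dict[str, np.ndarray]
    indicator_intercepts: dict[str, float]
    rater_sd: float
    beta: dict[str, float]
    sigma2_u: float
    sigma2_e: float
    outcome_transform: str = "log1p"
    nbhd_compositions: np.ndarray | None = None  # (n_neighbourhoods, K) mean compositions
    scene_concentration: float = 60.0

    def __post_init__(self) -> None:
        if self.sigma2_u < 0:
            raise ConfigError("sigma2_u must be >= 0")
        if self.sigma2_e <= 0:
            raise ConfigError("sigma2_e must be > 0")
        if self.rater_sd < 0:
            raise ConfigError("rater_sd must be >= 0")
        if self.outcome_transform not in ("identity", "log1p"):
            raise ConfigError("outcome_transform must be 'identity' or 'log1p'")
        for ind, w in self.indicator_weights.items():
            self.indicator_weights[ind] = np.asarray(w, dtype=float)

    def replace(self, **kwargs: Any) -> "SimulationTruth":
        return dataclasses.replace(self, **kwargs)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "indicator_weights": {k: v.tolist() for k, v in self.indicator_weights.items()},
            "indicator_intercepts": dict(self.indicator_intercepts),
            "rater_sd": self.rater_sd,
            "beta": dict(self.beta),
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
            "outcome_transform": self.outcome_transform,
            "nbhd_compositions": None
            if self.nbhd_compositions is None
            else np.asarray(self.nbhd_compositions).tolist(),
            "scene_concentration": self.scene_concentration,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationTruth":
        d = dict(d)
        if d.get("nbhd_compositions") is not None:
            d["nbhd_compositions"] = np.asarray(d["nbhd_compositions"], dtype=float)
        d["indicator_weights"] = {
            k: np.asarray(v, dtype=float) for k, v in d["indicator_weights"].items()
        }
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Baseline neighbourhood-mean score targets used when synthesising indicator
# weight vectors: negative indicators sit above mid-scale, "beautiful" below.
BASELINE_SCORE_MEANS = {
    "wealthy": 4.9,
    "safe": 4.7,
    "lively": 4.8,
    "depressing": 6.3,
    "boring": 5.7,
    "beautiful": 3.9,
}

#: Default fixed effects of the outcome model (transformed scale).  The sign
#: pattern of the six perception effects is the design target of the
#: parameter-recovery experiments: zero for "wealthy", positive for
#: safe/lively/beautiful, negative for depressing/boring.
DEFAULT_BETA = {
    "const": 4.5,
    "gender:male": 0.10,
    "age": 0.004,
    "marital:married": -0.02,
    "education:high_school": -0.05,
    "education:college_or_above": -0.02,
    "income_band:10_20k": 0.10,
    "income_band:20_40k": 0.16,
    "income_band:ge_40k": 0.02,
    "household_size": -0.03,
    "length_of_stay": 0.001,
    "functional_restricted": -0.06,
    "wealthy": 0.0,
    "safe": 0.50,
    "lively": 0.45,
    "depressing": -0.45,
    "boring": -0.40,
    "beautiful": 0.40,
}


def default_truth(world: WorldConfig, seed: int | None = None) -> SimulationTruth:
    """Draw a complete :class:`SimulationTruth` for ``world``.

    Each indicator's latent score is driven by four randomly chosen object
    classes; intercepts are set so that the score at the average composition
    matches ``BASELINE_SCORE_MEANS``.  Neighbourhood mean compositions are
    Dirichlet draws, giving real between-neighbourhood perception contrast.
    """
    rng = np.random.default_rng(world.seed if seed is None else seed)
    K = world.n_object_classes
    comp_alpha = 5.0
    nbhd_comp = rng.dirichlet(np.full(K, comp_alpha), size=world.n_neighbourhoods)
    mean_comp = np.full(K, 1.0 / K)

    # Disjoint driver classes per indicator (when K allows): indicators stay
    # only mildly collinear (through the simplex constraint), so each keeps
    # real partial between-neighbourhood contrast.
    perm = rng.permutation(K)
    if K >= len(INDICATORS):
        chunks = np.array_split(perm, len(INDICATORS))
    else:
        chunks = [rng.choice(K, size=1) for _ in INDICATORS]

    weights: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    target_contrast = 1.0  # sd of nbhd-mean latent scores, same for every indicator
    for ind, active in zip(INDICATORS, chunks):
        w = np.zeros(K)
        w[np.asarray(active)] = rng.normal(0.0, 20.0, size=len(active))
        spread = float((nbhd_comp @ w).std())
        if spread > 1e-9:
            w *= target_contrast / spread
        weights[ind] = w
        intercepts[ind] = float(BASELINE_SCORE_MEANS[ind] - w @ mean_comp)

    return SimulationTruth(
        indicator_weights=weights,
        indicator_intercepts=intercepts,
        rater_sd=0.25,
        beta=dict(DEFAULT_BETA),
        sigma2_u=0.022,
        sigma2_e=0.141,
        outcome_transform="log1p",
        nbhd_compositions=nbhd_comp,
        scene_concentration=60.0,
    )


def null_truth(world: WorldConfig, icc: float = 0.137, sigma2_e: float = 0.141,
               intercept: float = 5.0, seed: int | None = None) -> SimulationTruth:
    """Truth with no fixed effects except the intercept and a target ICC.

    Used by the ICC-recovery experiment: ``sigma2_u`` is set so that
    ``sigma2_u / (sigma2_u + sigma2_e)`` equals ``icc`` exactly.
    """
    if not 0 <= icc < 1:
        raise ConfigError("icc must lie in [0, 1)")
    truth = default_truth(world, seed=seed)
    beta = {k: 0.0 for k in truth.beta}
    beta["const"] = intercept
    sigma2_u = icc / (1.0 - icc) * sigma2_e
    return truth.replace(beta=beta, sigma2_u=sigma2_u, sigma2_e=sigma2_e)


# -- outcome transforms ------------------------------------------------

def apply_transform(minutes: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(minutes, dtype=float)
    if name == "identity":
        return x
    if name == "log1p":
        return np.log1p(x)
    raise ConfigError(f"unknown outcome transform {name!r}")


def invert_transform(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if name == "identity":
        return np.maximum(y, 0.0)
    if name == "log1p":
        return np.maximum(np.expm1(y), 0.0)
    raise ConfigError(f"unknown outcome transform {name!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of everything one end-to-end run needs."""

    world: WorldConfig = field(default_factory=WorldConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    outcome_transform: str = "log1p"
    radii_m: tuple[float, float] = (1000.0, 1500.0)
    standardise_scores: bool = False
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            world=dataclasses.replace(self.world, seed=seed),
            scoring=dataclasses.replace(self.scoring, seed=seed),
        )

    def to_dict(self) -> dict[str, Any]:
        d = {
            "world": dataclasses.asdict(self.world),
            "scoring": dataclasses.asdict(self.scoring),
            "outcome_transform": self.outcome_transform,
            "radii_m": list(self.radii_m),
            "standardise_scores": self.standardise_scores,
            "seed": self.seed,
        }
        d["world"]["headings"] = list(self.world.headings)
        return d


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (all keys optional)."""
    raw: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    world_kw = dict(raw.get("world", {}))
    if "headings" in world_kw:
        world_kw["headings"] = tuple(float(h) for h in world_kw["headings"])
    scoring_kw = dict(raw.get("scoring", {}))
    cfg = PipelineConfig(
        world=WorldConfig(**world_kw),
        scoring=ScoringConfig(**scoring_kw),
        outcome_transform=raw.get("outcome_transform", "log1p"),
        radii_m=tuple(raw.get("radii_m", (1000.0, 1500.0))),
        standardise_scores=bool(raw.get("standardise_scores", False)),
        seed=int(raw.get("seed", 0)),
    )
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
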