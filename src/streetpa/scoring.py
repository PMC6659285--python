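"""Human-machine adversarial scoring loop.

A random-forest regressor per indicator recommends a score for each new
scene; a rating oracle (simulated volunteer) corrects it; the corrected pair
joins the training set and the model is periodically refit.  Calibration
stops when the rolling RMSE between recommendations and corrections over the
last ``rmse_window`` images falls below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .config import SCORE_MAX, SCORE_MIN, INDICATORS, ScoringConfig
from .errors import CalibrationError, DimensionError, TrainingError
from .synthetic_data import SceneFeatureVector, feature_matrix


def _as_features(scene) -> np.ndarray:
    if isinstance(scene, SceneFeatureVector):
        return scene.proportions
    return np.asarray(scene, dtype=float)


@dataclass
class ScoringModelState:
    """Fitted regressor plus its full calibration audit trail."""

    indicator: str
    config: ScoringConfig
    regressor: RandomForestRegressor | None = None
    X_train: list = field(default_factory=list)
    y_train: list = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)
    converged: bool = False
    images_consumed: int = 0

    @property
    def rolling_rmse(self) -> float | None:
        """RMSE over the last ``rmse_window`` trace entries (None if too short)."""
        w = self.config.rmse_window
        if len(self.trace) < w:
            return None
        recent = self.trace[-w:]
        sq = [(t["recommended"] - t["corrected"]) ** 2 for t in recent]
        return float(np.sqrt(np.mean(sq)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.regressor is None:
            raise TrainingError("model not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.X_train[0]):
            raise DimensionError(
                f"feature length {X.shape[1]} != training length {len(self.X_train[0])}"
            )
        return np.clip(self.regressor.predict(X), SCORE_MIN, SCORE_MAX)


def _refit(state: ScoringModelState) -> None:
    params = dict(state.config.regressor_params)
    params.setdefault("n_jobs", 1)
    reg = RandomForestRegressor(random_state=state.config.seed, **params)
    reg.fit(np.asarray(state.X_train, dtype=float), np.asarray(state.y_train, dtype=float))
    state.regressor = reg


def fit_initial_model(
    rated: Sequence[tuple], indicator: str, config: ScoringConfig
) -> ScoringModelState:
    """Fit the first regressor from a batch of (scene, rating) pairs."""
    X = [_as_features(f) for f, _ in rated]
    y = [float(s) for _, s in rated]
    if len(X) < 2 or len(np.unique(np.asarray(X), axis=0)) < 2:
        raise TrainingError("need at least 2 distinct rated scenes to fit")
    state = ScoringModelState(indicator=indicator, config=config, X_train=X, y_train=y)
    _refit(state)
    return state


def calibration_step(
    state: ScoringModelState, scene, oracle: Callable[[np.ndarray], float]
) -> ScoringModelState:
    """One adversarial round: recommend, get corrected, learn, update RMSE."""
    x = _as_features(scene)
    recommended = float(state.predict(x)[0])
    corrected = float(oracle(x))
    state.X_train.append(x)
    state.y_train.append(corrected)
    state.images_consumed += 1
    if state.images_consumed % state.config.retrain_every == 0:
        _refit(state)
    state.trace.append(
        {
            "recommended": recommended,
            "corrected": corrected,
            "rolling_rmse": np.nan,
        }
    )
    rmse = state.rolling_rmse
    state.trace[-1]["rolling_rmse"] = np.nan if rmse is None else rmse
    return state


def run_adversarial_calibration(
    state: ScoringModelState,
    scene_stream: Iterable,
    oracle: Callable[[np.ndarray], float],
    config: ScoringConfig | None = None,
) -> ScoringModelState:
    """Consume scenes until the rolling-RMSE rule fires or the budget runs out.

    Raises :class:`CalibrationError` when the stream ends before one full
    RMSE window has been seen.
    """
    cfg = config or state.config
    it: Iterator = iter(scene_stream)
    while state.images_consumed < cfg.max_calibration_images:
        try:
            scene = next(it)
        except StopIteration:
            if state.images_consumed < cfg.rmse_window:
                raise CalibrationError(
                    f"calibration stream exhausted after {state.images_consumed} "
                    f"scenes; need at least rmse_window={cfg.rmse_window}"
                )
            break
        calibration_step(state, scene, oracle)
        rmse = state.rolling_rmse
        if rmse is not None and rmse < cfg.rmse_threshold:
            state.converged = True
            break
    else:
        if state.images_consumed < cfg.rmse_window:
            raise CalibrationError(
                "calibration budget exhausted before one full RMSE window"
            )
    # make sure the last corrections are part of the final model
    if state.images_consumed % cfg.retrain_every != 0:
        _refit(state)
    return state


def score_images(state: ScoringModelState, scenes: pd.DataFrame) -> pd.DataFrame:
    """Score every scene row with the fitted model (long format output)."""
    if not state.converged:
        warnings.warn(
            f"scoring with a non-converged model for {state.indicator!r}", stacklevel=2
        )
    X = feature_matrix(scenes)
    preds = state.predict(X)
    out = scenes[["image_id", "point_id", "heading"]].copy()
    out["indicator"] = state.indicator
    out["score"] = preds
    return out


@dataclass
class HoldoutResult:
    indicator: str
    r: float | None
    p: float | None
    n: int
    status: str  # "ok" or a defined error status


def validate_holdout(
    state: ScoringModelState,
    scenes,
    oracle: Callable[[np.ndarray], float],
    holdout_n: int | None = None,
) -> HoldoutResult:
    """Pearson correlation between model scores and fresh oracle ratings.

    Zero variance in either vector yields a defined error status rather than
    NaN propagation.
    """
    if isinstance(scenes, pd.DataFrame):
        X = feature_matrix(scenes)
    else:
        X = np.vstack([_as_features(s) for s in scenes])
    if holdout_n is not None:
        X = X[:holdout_n]
    preds = state.predict(X)
    ratings = np.array([oracle(x) for x in X])
    n = len(X)
    if np.std(preds) == 0 or np.std(ratings) == 0:
        return HoldoutResult(state.indicator, None, None, n, "degenerate: zero variance")
    r, p = stats.pearsonr(preds, ratings)
    return HoldoutResult(state.indicator, float(r), float(p), n, "ok")


def trace_frame(states: dict[str, ScoringModelState]) -> pd.DataFrame:
    """Combined calibration traces of several indicators (for audit output)."""
    frames = []
    for ind, st in states.items():
        df = pd.DataFrame(st.trace)
        df.insert(0, "step", np.arange(1, len(df) + 1))
        df.insert(0, "indicator", ind)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["indicator", "step", "recommended", "corrected", "rolling_rmse"])
    return pd.concat(frames, ignore_index=True)
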