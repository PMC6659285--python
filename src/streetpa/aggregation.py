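"""Spatial aggregation: image scores -> point scores -> neighbourhood exposure.

Points carry the mean of their (up to four) heading scores; neighbourhoods
carry the mean of all point scores within a circular buffer around their
centroid.  All distances are planar Euclidean on projected-metre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import INDICATORS
from .errors import AggregationError


@dataclass
class SamplingPoint:
    point_id: str
    x: float
    y: float
    nearest_nbhd: int | None = None
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class Neighbourhood:
    nbhd_id: int
    x: float
    y: float
    scores: dict[str, float] = field(default_factory=dict)
    true_scores: dict[str, float] = field(default_factory=dict)
    n_points_in_buffer: int | None = None
    buffer_radius_m: float | None = None


def point_score(heading_scores, n_expected: int = 4) -> tuple[float, bool]:
    """Mean of the available heading scores; flags when fewer than expected.

    Returns ``(mean, complete)`` where ``complete`` is False when some
    headings are missing (NaN entries are treated as missing).
    """
    vals = np.asarray(list(heading_scores), dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise AggregationError("point has no heading scores")
    return float(vals.mean()), bool(vals.size >= n_expected)


def point_scores_table(image_scores: pd.DataFrame, n_expected: int = 4) -> pd.DataFrame:
    """Collapse per-image scores to per-point scores.

    ``image_scores`` must have columns ``point_id``, ``indicator``, ``score``
    (one row per image x indicator).  Output is wide: one row per point with
    one column per indicator plus ``n_headings`` and ``complete``.
    """
    required = {"point_id", "indicator", "score"}
    missing = required - set(image_scores.columns)
    if missing:
        raise AggregationError(f"image_scores missing columns: {sorted(missing)}")
    wide = (
        image_scores.pivot_table(
            index="point_id", columns="indicator", values="score", aggfunc="mean"
        )
        .rename_axis(columns=None)
        .reset_index()
    )
    counts = (
        image_scores.groupby("point_id")["score"]
        .count()
        .rename("n_image_scores")
        .reset_index()
    )
    n_ind = image_scores["indicator"].nunique()
    counts["n_headings"] = counts["n_image_scores"] // n_ind
    wide = wide.merge(counts[["point_id", "n_headings"]], on="point_id")
    wide["complete"] = wide["n_headings"] >= n_expected
    return wide


def neighbourhood_score(
    points: pd.DataFrame,
    centroid: tuple[float, float],
    radius_m: float,
    indicator: str,
    nbhd_id=None,
) -> tuple[float, int]:
    """Mean ``indicator`` score of all points within ``radius_m`` of ``centroid``.

    The buffer boundary is inclusive.  Raises :class:`AggregationError`
    naming the neighbourhood when the buffer is empty.
    """
    dx = points["x"].to_numpy() - centroid[0]
    dy = points["y"].to_numpy() - centroid[1]
    inside = np.hypot(dx, dy) <= radius_m
    if not inside.any():
        raise AggregationError(
            f"no sampling points within {radius_m} m of neighbourhood {nbhd_id!r}"
        )
    vals = points.loc[inside, indicator].to_numpy(dtype=float)
    return float(vals.mean()), int(inside.sum())


def build_exposure_table(
    point_scores: pd.DataFrame,
    neighbourhoods: list[Neighbourhood] | pd.DataFrame,
    radius_m: float,
    indicators=INDICATORS,
) -> pd.DataFrame:
    """Per-neighbourhood mean scores over all points inside the buffer.

    ``point_scores`` needs columns ``x``, ``y`` and one column per indicator.
    Returns one row per neighbourhood: ``nbhd_id``, the indicator columns,
    ``n_points`` and ``radius_m``.
    """
    if isinstance(neighbourhoods, pd.DataFrame):
        nbhd_iter = [
            Neighbourhood(nbhd_id=row["nbhd_id"], x=row["x"], y=row["y"])
            for _, row in neighbourhoods.iterrows()
        ]
    else:
        nbhd_iter = list(neighbourhoods)
    for ind in indicators:
        if ind not in point_scores.columns:
            raise AggregationError(f"point scores lack indicator column {ind!r}")
    rows = []
    for nb in nbhd_iter:
        rec: dict = {"nbhd_id": nb.nbhd_id}
        n_used = None
        for ind in indicators:
            score, n_used = neighbourhood_score(
                point_scores, (nb.x, nb.y), radius_m, ind, nbhd_id=nb.nbhd_id
            )
            rec[ind] = score
        rec["n_points"] = n_used
        rec["radius_m"] = radius_m
        rows.append(rec)
    return pd.DataFrame(rows)


def attach_point_coords(point_scores: pd.DataFrame, points: list[SamplingPoint]) -> pd.DataFrame:
    coords = pd.DataFrame(
        {"point_id": [p.point_id for p in points], "x": [p.x for p in points], "y": [p.y for p in points]}
    )
    return point_scores.merge(coords, on="point_id", how="left")
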