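"""The quality predictor: weighted combination of peak-normalized Gaussian densities.

Each present feature i contributes a Gaussian density in the candidate
quality X, centred at its adjusted score Adjust_pre_i = pre_i - M_i and
with width SD_i, divided by its own peak so its maximum is exactly 1.
The combined score P_combine(X) = sum_i W_i * density_i(X) is evaluated
on a fixed grid over [0, 1]; the maximizing X is the predicted GDT-TS.

A weighted sum (not a product) is used: the published combination
normalizes each density into [0, 1] and carries a negative weight, which
a product could not accommodate.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, FEATURE_ORDER, N_FEATURES, QprobConfig
from .errors import FeatureErrorStats
from .normalize import FeatureVector

logger = logging.getLogger(__name__)


def _weights_array(weights) -> np.ndarray:
    """Coerce a WeightSet / dict / sequence into the canonical 11-array."""
    if hasattr(weights, "as_array"):
        w = weights.as_array()
    elif isinstance(weights, dict):
        w = np.array([weights[f] for f in FEATURE_ORDER], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} weights, got shape {w.shape}")
    return w


def quality_grid(config: QprobConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The candidate-quality grid {0, step, ..., 1}."""
    n = int(round(1.0 / config.grid_step))
    return np.linspace(0.0, 1.0, n + 1)


def normalized_density(x, center: float, sd: float):
    """Gaussian density divided by its peak: exp(-(x-center)^2 / (2 sd^2)).

    Maximum over x is exactly 1, attained at x = center.
    """
    if sd <= 0:
        raise ValueError("sd must be positive (floor it upstream)")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - center) ** 2) / (2.0 * sd ** 2))
    return float(out) if out.ndim == 0 else out


def scoring_context(fv: FeatureVector, stats: FeatureErrorStats, weights,
                    config: QprobConfig = DEFAULT_CONFIG):
    """Adjusted centers, SDs and renormalized weights for the present features.

    Returns (centers, sds, weights) arrays over the usable features.  When
    features are missing, the remaining weights are scaled so they sum to
    the full-set weight total, keeping the combined magnitude comparable.
    """
    w_full = _weights_array(weights)
    values = fv.as_array()
    m = stats.mean_array()
    sd = stats.sd_array()
    usable = ~np.isnan(values) & ~np.isnan(m) & ~np.isnan(sd)
    if not usable.any():
        raise ValueError(f"{fv.model_id}: no usable features (stats/weights coverage)")
    centers = values[usable] - m[usable]
    if config.clip_adjusted:
        centers = np.clip(centers, 0.0, 1.0)
    w = w_full[usable].astype(float)
    if not np.any(w != 0.0):
        raise ValueError("all weights zero over present features")
    present_sum = w.sum()
    full_sum = w_full.sum()
    if usable.sum() < N_FEATURES and present_sum != 0.0 and full_sum != 0.0:
        w = w * (full_sum / present_sum)
    return centers, sd[usable], w


def combined_probability(x, centers, sds, weights):
    """P_combine(x) = sum_i W_i * normalized_density(x; center_i, sd_i)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    dens = np.exp(-((x[None, :] - np.asarray(centers)[:, None]) ** 2)
                  / (2.0 * np.asarray(sds)[:, None] ** 2))
    out = np.asarray(weights) @ dens
    return out if out.size > 1 else float(out[0])


def predict_quality(fv: FeatureVector, stats: FeatureErrorStats, weights,
                    config: QprobConfig = DEFAULT_CONFIG) -> float:
    """Predicted global quality: the grid argmax of the combined density.

    Ties break toward the smallest X; the result is a grid point, i.e.
    already rounded to the grid step (3 decimals by default).
    """
    centers, sds, w = scoring_context(fv, stats, weights, config)
    grid = quality_grid(config)
    p = combined_probability(grid, centers, sds, w)
    return float(grid[int(np.argmax(p))])   # np.argmax returns first (smallest X) tie


def score_pool(vectors: Iterable[FeatureVector], stats: FeatureErrorStats, weights,
               config: QprobConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Score a pool of models; ranked table (model_id, score), descending.

    Per-model failures are logged and the model omitted; ties in score
    order lexicographically by model_id.
    """
    rows = []
    for fv in vectors:
        try:
            rows.append((fv.model_id, predict_quality(fv, stats, weights, config)))
        except (ValueError, KeyError) as exc:
            logger.warning("model %s could not be scored: %s", fv.model_id, exc)
    if not rows:
        raise ValueError("no model in the pool could be scored")
    df = pd.DataFrame(rows, columns=["model_id", "score"])
    df = df.sort_values(["score", "model_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df


def write_casp_qa(scores: pd.DataFrame, target_id: str, path,
                  method: str = "qprob") -> None:
    """Emit a CASP QA (QMODE 1) global-score block."""
    lines = ["PFRMAT QA", f"TARGET {target_id}", f"AUTHOR {method}",
             "METHOD probability-density feature combination", "MODEL 1", "QMODE 1"]
    for _, row in scores.iterrows():
        lines.append(f"{row.model_id} {row.score:.3f}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
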