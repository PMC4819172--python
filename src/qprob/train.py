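"""Coordinate-descent weight estimation minimizing per-target GDT-TS loss.

The trainer searches the 11 combination weights over the grid
[-0.8, 0.8] in steps of 0.01.  Starting from a random grid initialization
it sweeps the features in canonical order; for each feature it scans all
161 grid values with the other weights fixed and accepts the
loss-minimizing value when it strictly lowers the current minimum
per-target average loss (Min-Loss).  Sweeps repeat until one full sweep
changes nothing.  There is no latent-variable expectation step; the
procedure is plain coordinate descent on a finite grid.

Loss evaluations exploit that, per model, the combined density is linear
in the weights: each model's per-feature density matrix over the quality
grid is precomputed once, and a coordinate scan reuses the fixed-feature
part of the combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .config import DEFAULT_CONFIG, DEFAULT_WEIGHTS, FEATURE_ORDER, N_FEATURES, QprobConfig
from .errors import FeatureErrorStats
from .normalize import FeatureVector
from .scoring import quality_grid

logger = logging.getLogger(__name__)


@dataclass
class WeightSet:
    """The 11 combination weights plus the training Min-Loss."""

    weights: dict[str, float]
    min_loss: float | None = None
    sweeps: int = 0

    def __post_init__(self):
        missing = set(FEATURE_ORDER) - set(self.weights)
        extra = set(self.weights) - set(FEATURE_ORDER)
        if missing or extra:
            raise ValueError(f"weight set must cover exactly the 11 features "
                             f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for name, w in self.weights.items():
            if not (-0.8 - 1e-9 <= w <= 0.8 + 1e-9):
                raise ValueError(f"weight {name}={w} outside [-0.8, 0.8]")
            if abs(round(w / 0.01) * 0.01 - w) > 1e-9:
                raise ValueError(f"weight {name}={w} not a multiple of 0.01")

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[f] for f in FEATURE_ORDER])

    @classmethod
    def from_array(cls, arr, min_loss=None, sweeps=0) -> "WeightSet":
        arr = np.asarray(arr, dtype=float)
        return cls(weights={f: round(float(v), 2) for f, v in zip(FEATURE_ORDER, arr)},
                   min_loss=min_loss, sweeps=sweeps)


DEFAULT_WEIGHT_SET = WeightSet.from_array(DEFAULT_WEIGHTS)


@dataclass
class TargetPool:
    """One target's model pool: feature vectors plus true GDT-TS per model."""

    target_id: str
    vectors: list[FeatureVector]
    truths: dict[str, float]


def make_pools(vectors: list[FeatureVector], truths: pd.DataFrame) -> list[TargetPool]:
    """Group feature vectors into per-target pools using a truths table."""
    by_id = {fv.model_id: fv for fv in vectors}
    pools = []
    for target_id, grp in truths.groupby("target_id", sort=True):
        vs = [by_id[m] for m in grp["model_id"] if m in by_id]
        ts = {m: float(g) for m, g in zip(grp["model_id"], grp["gdtts"]) if m in by_id}
        if len(vs) >= 2:
            pools.append(TargetPool(str(target_id), vs, ts))
        else:
            logger.warning("target %s has < 2 models with features; skipped", target_id)
    if not pools:
        raise ValueError("no usable targets in training data")
    return pools


class _LossEngine:
    """Precomputed density matrices for fast per-target loss evaluation."""

    def __init__(self, pools: list[TargetPool], stats: FeatureErrorStats,
                 config: QprobConfig = DEFAULT_CONFIG):
        if not pools:
            raise ValueError("empty dataset")
        grid = quality_grid(config)
        m_arr = stats.mean_array()
        sd_arr = stats.sd_array()
        dens, truths, slices = [], [], []
        start = 0
        for pool in pools:
            if len(pool.vectors) < 2:
                raise ValueError(f"target {pool.target_id} needs >= 2 models")
            for fv in sorted(pool.vectors, key=lambda v: v.model_id):
                values = fv.as_array()
                centers = values - m_arr
                if config.clip_adjusted:
                    centers = np.clip(centers, 0.0, 1.0)
                usable = ~np.isnan(values) & ~np.isnan(m_arr) & ~np.isnan(sd_arr)
                D = np.zeros((N_FEATURES, grid.size))
                for i in np.flatnonzero(usable):
                    D[i] = np.exp(-((grid - centers[i]) ** 2) / (2.0 * sd_arr[i] ** 2))
                dens.append(D)
                truths.append(pool.truths[fv.model_id])
            slices.append(slice(start, start + len(pool.vectors)))
            start += len(pool.vectors)
        self.dens = np.asarray(dens)          # (M, 11, G)
        self.truths = np.asarray(truths)      # (M,)
        self.slices = slices
        self.best_truth = np.array([self.truths[s].max() for s in slices])

    def _loss_from_scores(self, scores: np.ndarray) -> float:
        # scores: (M, G) combined density per model; top-1 per target by
        # argmax grid value, predicted-score ties -> first model_id
        pred = np.argmax(scores, axis=1)
        losses = []
        for s, best in zip(self.slices, self.best_truth):
            picked = int(np.argmax(pred[s]))          # first max (model_id order)
            losses.append(best - self.truths[s][picked])
        return float(np.mean(losses))

    def loss(self, w: np.ndarray) -> float:
        return self._loss_from_scores(np.einsum("mfg,f->mg", self.dens, w))

    def scan_coordinate(self, w: np.ndarray, i: int,
                        candidates: np.ndarray) -> np.ndarray:
        """Loss for every candidate value of weight i, others fixed."""
        w0 = w.copy()
        w0[i] = 0.0
        base = np.einsum("mfg,f->mg", self.dens, w0)
        Di = self.dens[:, i, :]
        out = np.empty(len(candidates))
        for k, v in enumerate(candidates):
            out[k] = self._loss_from_scores(base + v * Di)
        return out


def per_target_loss(weights, pools: list[TargetPool], stats: FeatureErrorStats,
                    config: QprobConfig = DEFAULT_CONFIG) -> float:
    """Mean over targets of (best true GDT-TS - true GDT-TS of the top-1 pick)."""
    from .scoring import _weights_array
    return _LossEngine(pools, stats, config).loss(_weights_array(weights))


def _weight_grid(config: QprobConfig) -> np.ndarray:
    n = int(round((config.weight_hi - config.weight_lo) / config.weight_step))
    return np.round(config.weight_lo + config.weight_step * np.arange(n + 1), 10)


def coordinate_descent(pools: list[TargetPool], stats: FeatureErrorStats,
                       seed: int = 42, config: QprobConfig = DEFAULT_CONFIG,
                       n_restarts: int = 1,
                       trajectory: list | None = None) -> WeightSet:
    """Grid coordinate descent on the per-target average GDT-TS loss.

    Min-Loss starts at 1.  The search descends once from the all-zero
    weight vector (a sparse deterministic start that is markedly less
    prone to noise-feature local optima) and once per restart from a
    seeded random draw on the grid; the best result wins.  Per-coordinate
    scans accept strictly-improving values; among equal-loss candidates
    the value closest to zero wins, negative before positive, and
    equal-loss moves toward zero are themselves accepted (the (loss,
    |w_i|) pair strictly decreases, so sweeps still terminate).
    ``trajectory``, when given, receives the winning run's Min-Loss value
    after every accepted update (monotone non-increasing).
    """
    engine = _LossEngine(pools, stats, config)
    candidates = _weight_grid(config)
    # order candidates by tie-break preference: |v| ascending, negative first
    order = np.lexsort((candidates > 0, np.abs(candidates)))
    scan_values = candidates[order]

    best: WeightSet | None = None
    ss = np.random.SeedSequence(seed)
    starts = [np.zeros(N_FEATURES)]
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        starts.append(rng.choice(candidates, size=N_FEATURES))
    best_traj: list[float] = []
    for w in starts:
        w = w.copy()
        traj: list[float] = []
        min_loss = 1.0
        current = engine.loss(w)
        if current < min_loss:
            min_loss = current
            traj.append(min_loss)
        sweeps = 0
        changed = True
        while changed and sweeps < config.max_sweeps:
            changed = False
            sweeps += 1
            for i in range(N_FEATURES):
                losses = engine.scan_coordinate(w, i, scan_values)
                k = int(np.argmin(losses))        # first minimum = preferred tie-break
                new_v, new_loss = scan_values[k], losses[k]
                improves = new_loss < min_loss - 1e-12
                # equal-loss moves are accepted only toward zero: the
                # (loss, |w_i|) pair strictly decreases, so sweeps terminate
                # while flat directions still get sparsified
                sparsifies = (abs(new_loss - min_loss) <= 1e-12
                              and abs(new_v) < abs(w[i]) - 1e-12)
                if improves or sparsifies:
                    w[i] = new_v
                    min_loss = min(min_loss, new_loss)
                    changed = True
                    traj.append(min_loss)
        if sweeps >= config.max_sweeps and changed:
            logger.warning("coordinate descent hit max_sweeps=%d before convergence",
                           config.max_sweeps)
        result = WeightSet.from_array(w, min_loss=min_loss, sweeps=sweeps)
        if best is None or result.min_loss < best.min_loss:
            best = result
            best_traj = traj
    if trajectory is not None:
        trajectory.extend(best_traj)
    return best


def save_weights(ws: WeightSet, path) -> None:
    data = {"weights": {f: ws.weights[f] for f in FEATURE_ORDER}}
    if ws.min_loss is not None:
        data["min_loss"] = float(ws.min_loss)
    data["sweeps"] = ws.sweeps
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_weights(path=None) -> WeightSet:
    """Load weights from YAML; with no path, the packaged default vector."""
    if path is None:
        return DEFAULT_WEIGHT_SET
    with open(path) as fh:
        data = yaml.safe_load(fh)
    block = data["weights"]
    return WeightSet(weights={k: float(v) for k, v in block.items()},
                     min_loss=data.get("min_loss"), sweeps=int(data.get("sweeps", 0)))
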