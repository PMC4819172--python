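"""Ground-truth GDT-TS and CASP-style assessment metrics.

GDT-TS is the mean over the 1/2/4/8 A distance thresholds of the largest
fraction of shared CA atoms that a rigid superposition can bring within
the threshold of their native positions.  For chains of up to 12 shared
residues the search is exact (all >= 3-residue subsets are enumerated and
Kabsch-superposed); beyond that it is heuristic — fragment-seeded
superpositions refined by iterative inclusion, approximating the LGA
search from below.

The ranking metrics are the usual per-target Pearson / Spearman /
Kendall tau-b correlations, the top-1 GDT-TS loss, paired Wilcoxon
signed-rank tests between methods, and summed per-target Z-scores of
each method's selected model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._geom import apply_transform, kabsch
from .config import DEFAULT_CONFIG, QprobConfig
from .model_io import StructuralModel

logger = logging.getLogger(__name__)

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
_SEED_FRAGMENT_LENGTHS = (3, 5, 7)
_MAX_REFINE_ROUNDS = 10


def _common_ca(model: StructuralModel, native: StructuralModel):
    native_pos = {r.index: r.ca for r in native.residues}
    xs, ys = [], []
    for r in model.residues:
        if r.index in native_pos:
            xs.append(r.ca)
            ys.append(native_pos[r.index])
    return np.asarray(xs, float), np.asarray(ys, float)


def _max_within_exact(x: np.ndarray, y: np.ndarray, threshold: float) -> int:
    """Exact max count by enumerating every >= 3-residue subset (n <= 12)."""
    import itertools
    n = len(x)
    best = 0
    thr2 = threshold * threshold
    for k in range(3, n + 1):
        for subset in itertools.combinations(range(n), k):
            sel = np.asarray(subset)
            R, t = kabsch(x[sel], y[sel])
            delta = apply_transform(x, R, t) - y
            d2 = np.einsum("ij,ij->i", delta, delta)
            best = max(best, int((d2 <= thr2 + 1e-12).sum()))
    return best


_EXACT_MAX_RESIDUES = 12


def _max_within(x: np.ndarray, y: np.ndarray, threshold: float) -> int:
    """Max count of atoms superposable within threshold.

    Exact (subset enumeration) for chains of up to 12 shared residues;
    fragment-seeded iterative superposition beyond that.
    """
    n = len(x)
    if n <= _EXACT_MAX_RESIDUES:
        return _max_within_exact(x, y, threshold)
    seeds = [np.arange(n)]
    for flen in _SEED_FRAGMENT_LENGTHS:
        for start in range(0, n - flen + 1):
            seeds.append(np.arange(start, start + flen))
    best = 0
    thr2 = threshold * threshold
    for seed in seeds:
        sel = seed
        for _ in range(_MAX_REFINE_ROUNDS):
            R, t = kabsch(x[sel], y[sel])
            delta = apply_transform(x, R, t) - y
            d2 = np.einsum("ij,ij->i", delta, delta)
            within = np.flatnonzero(d2 <= thr2 + 1e-12)
            best = max(best, len(within))
            if len(within) < 3 or (len(within) == len(sel)
                                   and np.array_equal(within, sel)):
                break
            sel = within
    return best


def gdt_ts(model: StructuralModel, native: StructuralModel) -> float:
    """GDT-TS of a model against the native structure, in [0, 1].

    Residues are matched by residue index; fractions use the native
    residue count as denominator.  At least 3 shared CA atoms required.
    """
    x, y = _common_ca(model, native)
    if len(x) < 3:
        raise ValueError("need >= 3 residues shared between model and native")
    n_native = native.length
    fractions = [_max_within(x, y, thr) / n_native for thr in GDT_THRESHOLDS]
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# ranking statistics

def _checked(pred, true):
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("prediction and truth vectors must be equal-length 1-D")
    if len(pred) < 2:
        raise ValueError("correlations need at least 2 pairs")
    return pred, true


def pearson(pred, true) -> float:
    """Pearson correlation; NaN (excluded from averages) for constant input."""
    pred, true = _checked(pred, true)
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        logger.warning("constant vector: Pearson correlation undefined")
        return float("nan")
    return float(sps.pearsonr(pred, true).statistic)


def spearman(pred, true) -> float:
    pred, true = _checked(pred, true)
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(sps.spearmanr(pred, true).statistic)


def kendall(pred, true) -> float:
    """Kendall tau-b (tie-corrected)."""
    pred, true = _checked(pred, true)
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        logger.warning("constant vector: Kendall tau undefined")
        return float("nan")
    return float(sps.kendalltau(pred, true, variant="b").statistic)


def gdt_loss(pred, true, model_ids=None) -> float:
    """True GDT-TS of the best model minus that of the predicted top-1.

    Ties in the predicted score resolve to the first model in model_id
    order (no optimistic pick).
    """
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    if len(pred) == 0:
        raise ValueError("empty pool")
    if model_ids is not None:
        order = np.argsort(np.asarray(model_ids, dtype=object), kind="stable")
        pred, true = pred[order], true[order]
    picked = int(np.argmax(pred))   # first max = model_id order
    return float(true.max() - true[picked])


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value between metric lists.

    Zero differences are dropped; exact null distribution for n <= 25,
    otherwise normal approximation with continuity correction.  Requires
    at least 6 non-zero differences.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    diffs = a - b
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        logger.warning("all paired differences are zero; p-value 1.0")
        return 1.0
    if len(nz) < 6:
        raise ValueError(f"too few pairs: {len(nz)} non-zero differences (need >= 6)")
    method = "exact" if len(nz) <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(nz, alternative="two-sided", method=method,
                           correction=(method == "approx"))
    return float(res.pvalue)


def zscore_top1(selections: pd.DataFrame, config: QprobConfig = DEFAULT_CONFIG) -> pd.Series:
    """Summed per-target Z-scores of each method's selected model.

    ``selections`` is a (target x method) table of the true GDT-TS of the
    model each method ranked first.  Per target, each method's selection
    is standardized against the mean/SD of all methods' selections for
    that target, floored at ``config.z_floor``; sums run over targets.
    Targets where all methods agree (SD = 0) contribute 0.
    """
    if selections.shape[1] < 2:
        raise ValueError("Z-scores need at least 2 methods per target")
    sums = pd.Series(0.0, index=selections.columns)
    for _, row in selections.iterrows():
        sd = row.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            continue
        z = (row - row.mean()) / sd
        sums += z.clip(lower=config.z_floor)
    return sums


@dataclass(frozen=True)
class TargetEvaluation:
    target_id: str
    n_models: int
    pearson: float
    spearman: float
    kendall: float
    loss: float


def evaluate_dataset(predictions: pd.DataFrame, truths: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-target metrics and their unweighted averages.

    ``predictions`` has columns target_id, model_id, score; ``truths`` has
    target_id, model_id, gdtts.  Single-model targets contribute to the
    average loss but are excluded from the correlation averages, as are
    constant-vector targets.
    """
    merged = predictions.merge(truths, on=["target_id", "model_id"], how="inner")
    if merged.empty:
        raise ValueError("no overlap between predictions and truths")
    rows = []
    for target_id, grp in merged.groupby("target_id", sort=True):
        grp = grp.sort_values("model_id", kind="stable")
        loss = gdt_loss(grp["score"].to_numpy(), grp["gdtts"].to_numpy())
        if len(grp) >= 2:
            p = pearson(grp["score"], grp["gdtts"])
            s = spearman(grp["score"], grp["gdtts"])
            k = kendall(grp["score"], grp["gdtts"])
        else:
            p = s = k = float("nan")
        rows.append(TargetEvaluation(str(target_id), len(grp), p, s, k, loss))
    table = pd.DataFrame([r.__dict__ for r in rows]).set_index("target_id")
    summary = pd.Series({
        "avg_pearson": table["pearson"].mean(),
        "avg_spearman": table["spearman"].mean(),
        "avg_kendall": table["kendall"].mean(),
        "avg_loss": table["loss"].mean(),
        "n_targets": float(len(table)),
    })
    return table, summary
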