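"""Per-feature error model: Gaussian fits to (feature score - true GDT-TS).

For a training pool of models with known GDT-TS, the error of feature i
on model j is FE_ij = F_ij - R_j.  Its sample mean M_i recentres the
feature at prediction time (Adjust_pre_i = pre_i - M_i) and its standard
deviation SD_i becomes the width of that feature's density in the
combined scorer.  Errors are modelled as untruncated Gaussians even
though FE is confined to [-1, 1]; the truncation bias is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .config import DEFAULT_CONFIG, FEATURE_ORDER, QprobConfig
from .normalize import FeatureVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureErrorStats:
    """Fitted per-feature error mean M_i, standard deviation SD_i and sample count.

    Features absent from ``mean`` are unusable (unknown or too few samples)
    and are skipped by the scorer.
    """

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.mean:
            if name not in FEATURE_ORDER:
                raise KeyError(f"unknown feature {name!r}")
            if abs(self.mean[name]) > 1.0:
                raise ValueError(f"|M_{name}| > 1")
            if self.sd.get(name, 0.0) <= 0.0:
                raise ValueError(f"SD_{name} must be positive")

    def mean_array(self) -> np.ndarray:
        return np.array([self.mean.get(f, np.nan) for f in FEATURE_ORDER])

    def sd_array(self) -> np.ndarray:
        return np.array([self.sd.get(f, np.nan) for f in FEATURE_ORDER])


def compute_errors(features: list[FeatureVector],
                   truths: dict[str, float]) -> dict[str, np.ndarray]:
    """Error samples FE_ij = F_ij - R_j per feature, over models with a truth value."""
    for r in truths.values():
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"true GDT-TS {r} outside [0, 1]")
    samples: dict[str, list[float]] = {f: [] for f in FEATURE_ORDER}
    matched = 0
    for fv in features:
        r = truths.get(fv.model_id)
        if r is None:
            continue
        matched += 1
        for name, value in fv.values.items():
            if not np.isnan(value):
                samples[name].append(value - r)
    if matched == 0:
        raise ValueError("no overlap between feature vectors and truth values")
    return {f: np.asarray(v) for f, v in samples.items()}


def fit_error_stats(samples: dict[str, np.ndarray],
                    config: QprobConfig = DEFAULT_CONFIG) -> FeatureErrorStats:
    """Sample mean and population SD per feature; SD floored at config.sd_floor.

    Features with fewer than ``min_error_samples`` samples are flagged
    unusable (omitted from the stats) with a warning.
    """
    mean, sd, n = {}, {}, {}
    for name, fe in samples.items():
        if len(fe) < config.min_error_samples:
            if len(fe):
                logger.warning("feature %s: only %d error samples (< %d), unusable",
                               name, len(fe), config.min_error_samples)
            continue
        mean[name] = float(np.mean(fe))
        sd[name] = float(max(np.std(fe), config.sd_floor))  # population SD
        n[name] = int(len(fe))
    return FeatureErrorStats(mean=mean, sd=sd, n=n)


def train_error_model(features: list[FeatureVector], truths: dict[str, float],
                      config: QprobConfig = DEFAULT_CONFIG) -> FeatureErrorStats:
    """compute_errors + fit_error_stats in one call."""
    return fit_error_stats(compute_errors(features, truths), config)


def serialize_stats(stats: FeatureErrorStats, path) -> None:
    """Write stats to YAML, full float precision, canonical feature order."""
    block = {
        name: {"mean": stats.mean[name], "sd": stats.sd[name],
               "n": stats.n.get(name, 0)}
        for name in FEATURE_ORDER if name in stats.mean
    }
    with open(path, "w") as fh:
        yaml.safe_dump({"feature_errors": block}, fh, sort_keys=False)


def load_stats(path) -> FeatureErrorStats:
    """Load stats from YAML; features missing from the file stay missing, not zero."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    block = data.get("feature_errors", data)
    mean, sd, n = {}, {}, {}
    for name, entry in block.items():
        if name not in FEATURE_ORDER:
            raise KeyError(f"unknown feature {name!r} in stats file")
        mean[name] = float(entry["mean"])
        sd[name] = float(entry["sd"])
        n[name] = int(entry.get("n", 0))
    return FeatureErrorStats(mean=mean, sd=sd, n=n)


#: Documentation-level default stats.  The two published error means are kept
#: verbatim (ModelEvaluator -0.0219, the closest-to-truth feature;
#: Euclidean-compact +0.4119, the largest-magnitude mean error); remaining
#: entries are neutral placeholders — retrain on your own pool for real use.
DOCUMENTED_DEFAULT_STATS = FeatureErrorStats(
    mean={
        "rf_cb_srs_od": 0.0, "ss_similarity": 0.0, "ss_penalty": 0.0,
        "euclidean_compact": 0.4119, "surface_nonpolar": 0.0,
        "exposed_mass": 0.0, "exposed_surface": 0.0, "sa_similarity": 0.0,
        "rwplus": 0.0, "modeleval": -0.0219, "dope": 0.0,
    },
    sd={f: 0.1 for f in FEATURE_ORDER},
    n={f: 0 for f in FEATURE_ORDER},
)
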