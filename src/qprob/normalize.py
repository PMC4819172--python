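"""Length-dependent normalization of raw energy scores and feature-vector assembly.

Statistical-potential magnitudes grow with protein length, so each raw
score is mapped linearly onto [0, 1] over a length-dependent range chosen
so that the best (lowest) plausible energy maps to 1 and the worst to 0.
Every normalized feature is thereby positively oriented with GDT-TS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as F
from .config import DEFAULT_CONFIG, FEATURE_ORDER, QprobConfig
from .model_io import PerResidueAnnotation, StructuralModel

MISSING = float("nan")


@dataclass
class FeatureVector:
    """The 11 combined feature scores of one model, in canonical order.

    Missing entries are NaN; downstream combination renormalizes weights
    over the present features.
    """

    model_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.values:
            if name not in FEATURE_ORDER:
                raise KeyError(f"unknown feature {name!r}")
        for name, v in self.values.items():
            if not math.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.model_id}: feature {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.values.get(n, MISSING) for n in FEATURE_ORDER])

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.as_array())

    def n_present(self) -> int:
        return int(self.present.sum())


def normalize_min_max(raw: float, lower: float, upper: float,
                      lower_is_best: bool = True) -> float:
    """Linear map of raw onto [0, 1] over [lower, upper], clipped.

    With ``lower_is_best`` the lower bound maps to 1 (lower energy =
    better model); otherwise orientation is reversed.
    """
    if upper <= lower:
        raise ValueError(f"invalid normalization range [{lower}, {upper}]")
    if lower_is_best:
        score = (upper - raw) / (upper - lower)
    else:
        score = (raw - lower) / (upper - lower)
    return float(np.clip(score, 0.0, 1.0))


def normalize_dfire2(raw: float, length: int,
                     config: QprobConfig = DEFAULT_CONFIG) -> float:
    """DFIRE2 energy normalized over [-1.971*L, 0]."""
    if length < 1:
        raise ValueError("length must be >= 1")
    slope = config.normalization["dfire2_slope"]
    return normalize_min_max(raw, slope * length, 0.0, lower_is_best=True)


def normalize_rwplus(raw: float, length: int,
                     config: QprobConfig = DEFAULT_CONFIG) -> float:
    """RWplus energy normalized over [-232.6*L, 0]."""
    if length < 1:
        raise ValueError("length must be >= 1")
    slope = config.normalization["rwplus_slope"]
    return normalize_min_max(raw, slope * length, 0.0, lower_is_best=True)


def normalize_rf(raw: float, length: int,
                 config: QprobConfig = DEFAULT_CONFIG) -> float:
    """RF_CB_SRS_OD score normalized over [0.4823*L - 300, 700]."""
    if length < 1:
        raise ValueError("length must be >= 1")
    lower = (config.normalization["rf_lower_slope"] * length
             + config.normalization["rf_lower_intercept"])
    return normalize_min_max(raw, lower, config.normalization["rf_upper"],
                             lower_is_best=True)


def normalize_dope(raw: float, length: int,
                   config: QprobConfig = DEFAULT_CONFIG) -> float:
    """Dope energy normalized over [dope_slope*L*dope_span, 0] (package constants)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    lower = config.dope_slope * length * config.dope_span
    return normalize_min_max(raw, lower, 0.0, lower_is_best=True)


def assemble_feature_vector(
    model: StructuralModel,
    sequence_length: int,
    predicted_ss: PerResidueAnnotation | None = None,
    predicted_sa: PerResidueAnnotation | None = None,
    raw_scores: pd.Series | dict | None = None,
    dssp_ss: dict[int, str] | None = None,
    dssp_acc: dict[int, float] | None = None,
    config: QprobConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Compute every computable feature for one model, canonical order.

    Structural features always; the two similarity scores and the
    secondary-structure penalty only when predictions are supplied; the
    external energies only when a raw-score row is supplied.  Raw energies
    are normalized with the sequence length (not the model's resolved
    length).  Fewer than 4 present features is an error.
    """
    n = sequence_length
    values: dict[str, float] = {}

    surf = F.residue_surface(model, config=config, dssp_acc=dssp_acc)
    values["euclidean_compact"] = F.euclidean_compact_score(model, config)
    values["surface_nonpolar"] = F.surface_nonpolar_score(surf)
    values["exposed_mass"] = F.exposed_mass_score(surf, config)
    values["exposed_surface"] = F.exposed_surface_score(surf)

    if dssp_ss is not None:
        ss_states = "".join(dssp_ss.get(r.index, "-") for r in model.residues)
    else:
        ss_states = F.assign_secondary_structure(model).states
    model_ss = F.align_to_sequence(model, ss_states, n, "model_ss")
    model_sa = F.align_to_sequence(model, F.model_sa_annotation(surf, config).states,
                                   n, "model_sa")

    if predicted_ss is not None:
        values["ss_similarity"] = F.ss_similarity_score(predicted_ss, model_ss)
        values["ss_penalty"] = F.ss_penalty_score(F.compare_ss(predicted_ss, model_ss))
    if predicted_sa is not None:
        values["sa_similarity"] = F.sa_similarity_score(predicted_sa, model_sa)

    if raw_scores is not None:
        raw = dict(raw_scores) if not isinstance(raw_scores, dict) else raw_scores

        def _get(key):
            v = raw.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        if (v := _get("rf_cb_srs_od")) is not None:
            values["rf_cb_srs_od"] = normalize_rf(v, n, config)
        if (v := _get("rwplus")) is not None:
            values["rwplus"] = normalize_rwplus(v, n, config)
        if (v := _get("dope")) is not None:
            values["dope"] = normalize_dope(v, n, config)
        if (v := _get("modeleval")) is not None:
            values["modeleval"] = float(v)

    fv = FeatureVector(model_id=model.model_id, values=values)
    if fv.n_present() < 4:
        raise ValueError(
            f"{model.model_id}: insufficient features ({fv.n_present()} present, need >= 4)"
        )
    return fv


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack FeatureVectors into a DataFrame indexed by model_id, canonical columns."""
    return pd.DataFrame([fv.as_array() for fv in vectors],
                        index=[fv.model_id for fv in vectors],
                        columns=list(FEATURE_ORDER))


def read_feature_vectors(path) -> list[FeatureVector]:
    """Read a features TSV (model_id + canonical feature columns) back into vectors."""
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str}).set_index("model_id")
    vectors = []
    for model_id, row in df.iterrows():
        values = {name: float(row[name]) for name in FEATURE_ORDER
                  if name in row and not math.isnan(row[name])}
        vectors.append(FeatureVector(model_id=model_id, values=values))
    return vectors


def write_feature_vectors(vectors: list[FeatureVector], path) -> None:
    feature_table(vectors).rename_axis("model_id").to_csv(path, sep="\t")
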