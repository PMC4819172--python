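"""Shared configuration: canonical feature order, published constants, reference tables.

Every tunable the pipeline uses lives here so that a run is reproducible
from the config alone.  The energy-normalization slopes and the default
combination weights are the published values and are kept verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

#: Canonical order of the 11 combined features.  This order indexes the
#: per-feature error means M_i, standard deviations SD_i and weights W_i
#: everywhere in the package; do not reorder.
FEATURE_ORDER: tuple[str, ...] = (
    "rf_cb_srs_od",
    "ss_similarity",
    "ss_penalty",
    "euclidean_compact",
    "surface_nonpolar",
    "exposed_mass",
    "exposed_surface",
    "sa_similarity",
    "rwplus",
    "modeleval",
    "dope",
)

N_FEATURES = len(FEATURE_ORDER)

#: Published combination weights, in canonical feature order.
DEFAULT_WEIGHTS: tuple[float, ...] = (
    0.03, 0.09, 0.04, 0.08, 0.08, 0.01, 0.03, 0.10, 0.00, 0.09, -0.02,
)

# Length-dependent normalization ranges for the raw statistical potentials.
# Lower bound is slope * L (+ intercept); lower raw energy means a better
# model, so the lower bound maps to a normalized score of 1.
DFIRE2_SLOPE = -1.971
RWPLUS_SLOPE = -232.6
RF_LOWER_SLOPE = 0.4823
RF_LOWER_INTERCEPT = -300.0
RF_UPPER = 700.0

#: Average residue masses within a peptide chain (Da).
RESIDUE_MASSES: dict[str, float] = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}

#: Maximal (Gly-X-Gly tripeptide) accessible surface per residue type (A^2),
#: used as the total-area reference ST_i and for relative accessibility.
REFERENCE_AREAS: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0,
    "CYS": 167.0, "GLN": 225.0, "GLU": 223.0, "GLY": 104.0,
    "HIS": 224.0, "ILE": 197.0, "LEU": 201.0, "LYS": 236.0,
    "MET": 224.0, "PHE": 240.0, "PRO": 159.0, "SER": 155.0,
    "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Hydrophobic residues counted as nonpolar in the surface features.
NONPOLAR_SET: frozenset[str] = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY", "CYS"}
)

#: Nonstandard -> standard residue mapping for the reference tables.
NONSTANDARD_MAP: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: van der Waals radii (A) for SASA, keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.8


@dataclass(frozen=True)
class QprobConfig:
    """All tunables of the pipeline with their defaults.

    Attributes
    ----------
    probe_radius : float
        Solvent probe radius in Angstrom for SASA.
    sasa_points : int
        Sphere-lattice points per atom in the Shrake-Rupley sampler.
    exposure_threshold : float
        Relative accessibility (S_i / ST_i) above which a residue is
        called exposed.
    compact_c, compact_s : float
        The Euclidean-compactness reference distance is
        ``compact_c * L**(1/3) * compact_s`` (radius-of-gyration scaling).
    dope_slope, dope_span : float
        The Dope raw score is normalized over ``[dope_slope*L*dope_span, 0]``;
        the published text does not print these constants, so they are
        package choices exposed here.
    sd_floor : float
        Lower bound on a fitted per-feature error SD; prevents
        delta-function densities.
    grid_step : float
        Step of the quality-score grid on [0, 1] searched by the scorer.
    clip_adjusted : bool
        Whether adjusted feature centers are clipped into [0, 1].
    weight_lo, weight_hi, weight_step : float
        Weight grid searched by the coordinate-descent trainer.
    max_sweeps : int
        Cap on full coordinate sweeps of the trainer.
    min_error_samples : int
        Minimum samples for a feature's error fit to be usable.
    z_floor : float
        Floor applied to per-target Z-scores (CASP convention).
    """

    probe_radius: float = 1.4
    sasa_points: int = 960
    exposure_threshold: float = 0.25
    compact_c: float = 5.54
    compact_s: float = 2.0
    dope_slope: float = -1.0
    dope_span: float = 100.0
    sd_floor: float = 0.01
    grid_step: float = 0.001
    clip_adjusted: bool = True
    weight_lo: float = -0.8
    weight_hi: float = 0.8
    weight_step: float = 0.01
    max_sweeps: int = 100
    min_error_samples: int = 10
    z_floor: float = -2.0
    normalization: dict = field(default_factory=lambda: {
        "dfire2_slope": DFIRE2_SLOPE,
        "rwplus_slope": RWPLUS_SLOPE,
        "rf_lower_slope": RF_LOWER_SLOPE,
        "rf_lower_intercept": RF_LOWER_INTERCEPT,
        "rf_upper": RF_UPPER,
    })

    def with_options(self, **kwargs) -> "QprobConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "QprobConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


DEFAULT_CONFIG = QprobConfig()


def canonical_index(name: str) -> int:
    """Index of a feature name in the canonical order; raises on unknown."""
    try:
        return FEATURE_ORDER.index(name)
    except ValueError:
        raise KeyError(f"unknown feature name: {name!r}") from None


def validate_feature_names(names: Iterable[str]) -> None:
    for n in names:
        canonical_index(n)
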