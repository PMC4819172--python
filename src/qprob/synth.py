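"""Synthetic fixtures: ideal backbones, perturbed decoys, noisy feature tables.

The feature-table generator mirrors the package's own modelling
assumption: each feature score is the model's true quality plus
independent Gaussian noise with a per-feature bias and spread, clipped to
[0, 1].  Defaults emulate a reduced-scale QA training set (20 targets of
30 models each, true qualities uniform on [0.2, 0.9]); the coordinate
generators produce ideal helices / extended chains and rigid decoys with
a requested CA perturbation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import place_atom
from .config import FEATURE_ORDER, N_FEATURES
from .model_io import Residue, StructuralModel
from .normalize import FeatureVector

# ideal backbone internal coordinates (bond lengths in A, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-120.0, 130.0)


def make_chain(length: int, phi: float, psi: float, residue_name: str = "ALA",
               model_id: str = "chain") -> StructuralModel:
    """Ideal backbone with constant (phi, psi) torsions and omega = 180."""
    if length < 1:
        raise ValueError("length must be >= 1")
    theta = np.radians(180.0 - _A_N_CA_C)
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    c = ca + _B_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    backbone = [(n, ca, c)]
    for _ in range(1, length):
        pn, pca, pc = backbone[-1]
        nn = place_atom(pn, pca, pc, _B_C_N, _A_CA_C_N, psi)
        nca = place_atom(pca, pc, nn, _B_N_CA, _A_C_N_CA, 180.0)
        nc = place_atom(pc, nn, nca, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((nn, nca, nc))
    residues = []
    for i, (an, aca, ac) in enumerate(backbone):
        atoms = {"N": an, "CA": aca, "C": ac}
        if i < length - 1:
            atoms["O"] = place_atom(backbone[i + 1][0], aca, ac, _B_C_O,
                                    _A_CA_C_O, 180.0)
        residues.append(Residue(name=residue_name, index=i + 1, atoms=atoms))
    return StructuralModel(model_id=model_id, residues=residues)


def make_helix(length: int, model_id: str = "helix") -> StructuralModel:
    """Ideal alpha-helix backbone (phi = -57, psi = -47)."""
    return make_chain(length, *HELIX_PHI_PSI, model_id=model_id)


def make_extended(length: int, model_id: str = "extended") -> StructuralModel:
    """Fully extended backbone (phi = -120, psi = 130)."""
    return make_chain(length, *EXTENDED_PHI_PSI, model_id=model_id)


def make_decoy(native: StructuralModel, rms_target: float, seed: int,
               model_id: str | None = None) -> StructuralModel:
    """Decoy with coordinates perturbed by seeded Gaussian noise.

    Per-coordinate noise SD is rms_target / sqrt(3), so the expected CA
    RMSD to the native approximates ``rms_target``; larger values give
    stochastically lower GDT-TS.
    """
    if rms_target < 0:
        raise ValueError("rms_target must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = rms_target / np.sqrt(3.0)
    residues = []
    for res in native.residues:
        atoms = {name: xyz + rng.normal(0.0, sigma, size=3)
                 for name, xyz in res.atoms.items()}
        residues.append(Residue(name=res.name, index=res.index, icode=res.icode,
                                atoms=atoms))
    return StructuralModel(model_id=model_id or f"{native.model_id}_decoy",
                           residues=residues)


@dataclass
class SyntheticSpec:
    """Conditions for a synthetic QA training/evaluation set.

    Per-feature noise parameters are in canonical feature order; the
    defaults (zero bias, SD 0.1, qualities uniform on [0.2, 0.9]) give a
    moderately informative feature set at a 20-target x 30-model scale.
    """

    seed: int = 0
    n_targets: int = 20
    models_per_target: int = 30
    length: int = 50
    q_lo: float = 0.2
    q_hi: float = 0.9
    mu: np.ndarray = field(default_factory=lambda: np.zeros(N_FEATURES))
    sigma: np.ndarray = field(default_factory=lambda: np.full(N_FEATURES, 0.1))
    decoy_rms: float = 5.0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.mu.shape != (N_FEATURES,) or self.sigma.shape != (N_FEATURES,):
            raise ValueError(f"mu and sigma must have length {N_FEATURES}")
        if np.any(self.sigma < 0.01):
            raise ValueError("per-feature sigma must be >= 0.01")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not (0.0 <= self.q_lo < self.q_hi <= 1.0):
            raise ValueError("need 0 <= q_lo < q_hi <= 1")


def make_feature_dataset(spec: SyntheticSpec
                         ) -> tuple[list[FeatureVector], pd.DataFrame]:
    """Noisy feature vectors around per-model true qualities.

    For each model, a true quality R ~ U[q_lo, q_hi] is drawn and feature
    i takes the value clip(R + Normal(mu_i, sigma_i), 0, 1).  Returns the
    feature vectors and a truths table (target_id, model_id, gdtts).
    Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    vectors, rows = [], []
    for t in range(spec.n_targets):
        target_id = f"T{t:04d}"
        for j in range(spec.models_per_target):
            model_id = f"{target_id}_m{j:03d}"
            r = rng.uniform(spec.q_lo, spec.q_hi)
            noisy = np.clip(r + rng.normal(spec.mu, spec.sigma), 0.0, 1.0)
            vectors.append(FeatureVector(
                model_id=model_id,
                values={name: float(v) for name, v in zip(FEATURE_ORDER, noisy)},
            ))
            rows.append((target_id, model_id, r))
    truths = pd.DataFrame(rows, columns=["target_id", "model_id", "gdtts"])
    return vectors, truths


def write_dataset(spec: SyntheticSpec, outdir) -> None:
    """Write features.tsv / truths.tsv plus native + decoy PDBs for one target."""
    from pathlib import Path

    from .model_io import write_pdb
    from .normalize import write_feature_vectors

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vectors, truths = make_feature_dataset(spec)
    write_feature_vectors(vectors, outdir / "features.tsv")
    truths.to_csv(outdir / "truths.tsv", sep="\t", index=False)
    native = make_helix(spec.length, model_id="native")
    write_pdb(native, outdir / "native.pdb")
    for k, scale in enumerate(np.linspace(0.0, spec.decoy_rms, 4)):
        decoy = make_decoy(native, scale, seed=spec.seed + k,
                           model_id=f"decoy{k}")
        write_pdb(decoy, outdir / f"decoy{k}.pdb")
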