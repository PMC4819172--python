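"""The seven structural / physicochemical features of a model.

Each feature maps a structural model (plus, for the similarity scores,
externally predicted per-residue annotations) onto a score in [0, 1] that
acts as a direct estimate of the model's GDT-TS.  Surface quantities come
from an internal deterministic Shrake-Rupley sampler; secondary structure
from a backbone-dihedral window assigner, with a DSSP-file override
available through :mod:`qprob.model_io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geom import dihedral, golden_sphere
from .config import (
    DEFAULT_CONFIG,
    DEFAULT_VDW_RADIUS,
    NONPOLAR_SET,
    NONSTANDARD_MAP,
    QprobConfig,
    REFERENCE_AREAS,
    RESIDUE_MASSES,
    VDW_RADII,
)
from .model_io import PerResidueAnnotation, StructuralModel

logger = logging.getLogger(__name__)


@dataclass
class ResidueSurface:
    """Per-residue surface bookkeeping for the three exposure features.

    ``exposed`` (S_i) is the computed accessible area; ``total`` (ST_i) the
    Gly-X-Gly reference area; ``exposed_nonpolar`` (SE_i) equals S_i for
    nonpolar residues and 0 otherwise, likewise ``total_nonpolar`` (STN_i);
    ``mass`` is the residue mass in Da.
    """

    residue_names: list[str]
    exposed: np.ndarray
    total: np.ndarray
    exposed_nonpolar: np.ndarray
    total_nonpolar: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        if np.any(self.exposed < -1e-9):
            raise ValueError("negative exposed area")
        if np.any(self.exposed_nonpolar - self.exposed > 1e-9):
            raise ValueError("SE_i must not exceed S_i")


@dataclass(frozen=True)
class SSComparison:
    """Counts from comparing predicted vs model 3-state secondary structure."""

    helix_matches: int     # F_H
    sheet_matches: int     # F_S
    n: int                 # sequence length N
    match_count: int       # positions with equal 3-state codes
    compared: int          # positions where both annotations are defined


def _canonical_residue(name: str) -> str:
    if name in REFERENCE_AREAS:
        return name
    mapped = NONSTANDARD_MAP.get(name)
    if mapped is None:
        logger.warning("nonstandard residue %s mapped to ALA reference values", name)
        return "ALA"
    logger.warning("nonstandard residue %s mapped to %s", name, mapped)
    return mapped


def _atom_radius(atom_name: str) -> float:
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() == "SE":
        return VDW_RADII["SE"]
    element = stripped[:1].upper()
    if element in VDW_RADII:
        return VDW_RADII[element]
    logger.warning("unknown element for atom %r; default radius %.1f A",
                   atom_name, DEFAULT_VDW_RADIUS)
    return DEFAULT_VDW_RADIUS


def compute_sasa(model: StructuralModel, probe_radius: float | None = None,
                 n_points: int | None = None,
                 config: QprobConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom is wrapped in a sphere of radius r_vdw + probe sampled on a
    deterministic Fibonacci lattice of ``n_points`` points; a point is
    accessible if it lies outside every neighbouring atom's probe-expanded
    sphere.  Deterministic given the lattice, and rotation/translation
    invariant up to lattice discretisation.
    """
    probe = config.probe_radius if probe_radius is None else probe_radius
    n_pts = config.sasa_points if n_points is None else n_points
    coords, radii, owner = [], [], []
    for ri, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            coords.append(xyz)
            radii.append(_atom_radius(name))
            owner.append(ri)
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    owner = np.asarray(owner)
    expanded = radii + probe
    lattice = golden_sphere(n_pts)
    tree = cKDTree(coords)
    cutoff = 2.0 * expanded.max()
    areas = np.zeros(model.length)
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * lattice
        neighbours = [j for j in tree.query_ball_point(coords[i], cutoff + 1e-9)
                      if j != i]
        accessible = np.ones(n_pts, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
        frac = accessible.mean()
        areas[owner[i]] += frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def total_reference_areas(model: StructuralModel,
                          exposed: np.ndarray | None = None) -> ResidueSurface:
    """Assemble the ResidueSurface tables (ST_i, STN_i, SE_i, masses) for a model."""
    names = [r.name for r in model.residues]
    canon = [_canonical_residue(n) for n in names]
    total = np.array([REFERENCE_AREAS[c] for c in canon])
    mass = np.array([RESIDUE_MASSES[c] for c in canon])
    nonpolar = np.array([c in NONPOLAR_SET for c in canon])
    if exposed is None:
        exposed = np.zeros(model.length)
    exposed = np.minimum(np.asarray(exposed, dtype=float), total)
    return ResidueSurface(
        residue_names=names,
        exposed=exposed,
        total=total,
        exposed_nonpolar=np.where(nonpolar, exposed, 0.0),
        total_nonpolar=np.where(nonpolar, total, 0.0),
        mass=mass,
    )


def residue_surface(model: StructuralModel,
                    config: QprobConfig = DEFAULT_CONFIG,
                    dssp_acc: dict[int, float] | None = None) -> ResidueSurface:
    """ResidueSurface with S_i from DSSP accessibilities if given, else internal SASA."""
    if dssp_acc is not None:
        exposed = np.array([dssp_acc.get(r.index, 0.0) for r in model.residues])
    else:
        exposed = compute_sasa(model, config=config)
    return total_reference_areas(model, exposed)


# ---------------------------------------------------------------------------
# secondary structure

_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_SHEET_PHI = (-180.0, -40.0)
_SHEET_PSI_A = (50.0, 180.0)
_SHEET_PSI_B = (-180.0, -170.0)


def backbone_dihedrals(model: StructuralModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) in degrees; NaN where undefined."""
    L = model.length
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    res = model.residues
    for i in range(L):
        a = res[i].atoms
        if i > 0:
            prev = res[i - 1].atoms
            if all(k in prev for k in ("C",)) and all(k in a for k in ("N", "CA", "C")):
                phi[i] = dihedral(prev["C"], a["N"], a["CA"], a["C"])
        if i < L - 1:
            nxt = res[i + 1].atoms
            if all(k in a for k in ("N", "CA", "C")) and "N" in nxt:
                psi[i] = dihedral(a["N"], a["CA"], a["C"], nxt["N"])
    return phi, psi


def _runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = np.zeros(len(mask), dtype=bool)
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def assign_secondary_structure(model: StructuralModel) -> PerResidueAnnotation:
    """3-state secondary structure from backbone dihedral windows.

    Helix: phi in [-100, -30] and psi in [-80, -5] over runs of >= 4
    consecutive residues; sheet: phi in [-180, -40] with psi in [50, 180]
    or [-180, -170] over runs of >= 3; everything else coil.  Residues with
    missing backbone atoms (hence undefined dihedrals) are coil.
    """
    phi, psi = backbone_dihedrals(model)
    with np.errstate(invalid="ignore"):
        helix_cand = ((phi >= _HELIX_PHI[0]) & (phi <= _HELIX_PHI[1])
                      & (psi >= _HELIX_PSI[0]) & (psi <= _HELIX_PSI[1]))
        sheet_cand = ((phi >= _SHEET_PHI[0]) & (phi <= _SHEET_PHI[1])
                      & (((psi >= _SHEET_PSI_A[0]) & (psi <= _SHEET_PSI_A[1]))
                         | ((psi >= _SHEET_PSI_B[0]) & (psi <= _SHEET_PSI_B[1]))))
    helix = _runs(helix_cand, 4)
    sheet = _runs(sheet_cand & ~helix, 3)
    states = np.where(helix, "H", np.where(sheet, "E", "C"))
    return PerResidueAnnotation(kind="model_ss", states="".join(states))


def model_sa_annotation(surf: ResidueSurface,
                        config: QprobConfig = DEFAULT_CONFIG) -> PerResidueAnnotation:
    """2-state exposed/buried call from relative accessibility S_i / ST_i."""
    rel = surf.exposed / surf.total
    states = "".join("e" if r > config.exposure_threshold else "b" for r in rel)
    return PerResidueAnnotation(kind="model_sa", states=states)


def align_to_sequence(model: StructuralModel, states: str, n: int,
                      kind: str) -> PerResidueAnnotation:
    """Spread model-residue states onto sequence positions by residue_index.

    Residue numbering is taken as 1-based sequence position; unresolved
    positions get '-' and are excluded from similarity denominators.
    """
    out = ["-"] * n
    for res, s in zip(model.residues, states):
        if 1 <= res.index <= n:
            out[res.index - 1] = s
    return PerResidueAnnotation(kind=kind, states="".join(out))


# ---------------------------------------------------------------------------
# feature scores

def euclidean_compact_score(model: StructuralModel,
                            config: QprobConfig = DEFAULT_CONFIG) -> float:
    """Mean pairwise CA-CA distance over a length-dependent reference, clipped to [0, 1].

    The reference D_ref(L) = compact_c * L**(1/3) * compact_s follows the
    radius-of-gyration scaling law; higher score = less compact model.
    """
    L = model.length
    if L < 2:
        raise ValueError("compactness needs at least 2 residues")
    coords = model.ca_coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iu = np.triu_indices(L, k=1)
    mean_dist = dist[iu].mean()
    d_ref = config.compact_c * L ** (1.0 / 3.0) * config.compact_s
    return float(np.clip(mean_dist / d_ref, 0.0, 1.0))


def surface_nonpolar_score(surf: ResidueSurface) -> float:
    """Fraction of total exposed area belonging to nonpolar residues: sum SE_i / sum S_i."""
    total_exposed = surf.exposed.sum()
    if total_exposed <= 0:
        logger.warning("model has zero exposed area; nonpolar surface score set to 0")
        return 0.0
    return float(surf.exposed_nonpolar.sum() / total_exposed)


def exposed_mass_score(surf: ResidueSurface,
                       config: QprobConfig = DEFAULT_CONFIG) -> float:
    """Mass fraction of residues called exposed at the relative-accessibility threshold."""
    rel = surf.exposed / surf.total
    exposed_flag = rel > config.exposure_threshold
    return float(surf.mass[exposed_flag].sum() / surf.mass.sum())


def exposed_surface_score(surf: ResidueSurface) -> float:
    """Total exposed over total reference area: sum S_i / sum ST_i, clipped to [0, 1]."""
    return float(np.clip(surf.exposed.sum() / surf.total.sum(), 0.0, 1.0))


def _compared_positions(a: PerResidueAnnotation, b: PerResidueAnnotation):
    if len(a) != len(b):
        raise ValueError(f"annotation lengths differ: {len(a)} vs {len(b)}")
    return [(x, y) for x, y in zip(a.states, b.states) if x != "-" and y != "-"]


def ss_similarity_score(predicted: PerResidueAnnotation,
                        model_ss: PerResidueAnnotation) -> float:
    """Fraction of comparable residues whose predicted and model 3-state codes agree."""
    pairs = _compared_positions(predicted, model_ss)
    if not pairs:
        raise ValueError("no comparable residues for secondary-structure similarity")
    return sum(x == y for x, y in pairs) / len(pairs)


def compare_ss(predicted: PerResidueAnnotation,
               model_ss: PerResidueAnnotation) -> SSComparison:
    """Tally helix/sheet agreement counts between prediction and model."""
    pairs = _compared_positions(predicted, model_ss)
    return SSComparison(
        helix_matches=sum(x == y == "H" for x, y in pairs),
        sheet_matches=sum(x == y == "E" for x, y in pairs),
        n=len(predicted),
        match_count=sum(x == y for x, y in pairs),
        compared=len(pairs),
    )


def ss_penalty_score(cmp: SSComparison) -> float:
    """(F_H + F_S) / N: fraction of the sequence with confirmed helix/sheet prediction."""
    if cmp.n <= 0:
        raise ValueError("sequence length must be positive")
    return (cmp.helix_matches + cmp.sheet_matches) / cmp.n


def sa_similarity_score(predicted_sa: PerResidueAnnotation,
                        model_sa: PerResidueAnnotation) -> float:
    """Fraction of comparable residues with equal 2-state exposure codes."""
    pairs = _compared_positions(predicted_sa, model_sa)
    if not pairs:
        raise ValueError("no comparable residues for accessibility similarity")
    return sum(x == y for x, y in pairs) / len(pairs)
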