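"""Structural feature computations: SASA, secondary structure, surface ratios."""

import numpy as np
import pytest

from qprob._geom import random_rigid_transform
from qprob.config import DEFAULT_CONFIG, REFERENCE_AREAS
from qprob.features import (ResidueSurface, SSComparison,
                            assign_secondary_structure, compare_ss,
                            compute_sasa, euclidean_compact_score,
                            exposed_mass_score, exposed_surface_score,
                            model_sa_annotation, residue_surface,
                            sa_similarity_score, ss_penalty_score,
                            ss_similarity_score, surface_nonpolar_score,
                            total_reference_areas)
from qprob.model_io import PerResidueAnnotation, Residue, StructuralModel


def _point_model(coords, name="ALA"):
    """Model whose residues each carry a single CA pseudo-atom."""
    return StructuralModel("pts", [
        Residue(name=name, index=i + 1, atoms={"CA": np.asarray(c, float)})
        for i, c in enumerate(coords)
    ])


def _transformed(model, seed=0):
    rng = np.random.default_rng(seed)
    R, t = random_rigid_transform(rng)
    return StructuralModel(model.model_id, [
        Residue(r.name, r.index, r.icode,
                {n: R @ xyz + t for n, xyz in r.atoms.items()})
        for r in model.residues
    ])


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        model = _point_model([[0.0, 0.0, 0.0]])
        area = compute_sasa(model)[0]
        exact = 4.0 * np.pi * (1.7 + 1.4) ** 2     # carbon vdW + probe
        assert area == pytest.approx(exact, rel=0.02)

    def test_occlusion_monotonicity_for_coincident_atoms(self):
        single = compute_sasa(_point_model([[0.0, 0.0, 0.0]])).sum()
        double = compute_sasa(_point_model([[0.0, 0.0, 0.0],
                                            [0.0, 0.0, 0.0]])).sum()
        assert double <= single + 1e-9

    def test_cluster_agrees_with_denser_lattice_oracle(self, rng):
        coords = rng.uniform(-4.0, 4.0, size=(10, 3))
        model = _point_model(coords)
        coarse = compute_sasa(model, n_points=960)
        dense = compute_sasa(model, n_points=10000)
        mask = dense > 1.0
        assert np.all(np.abs(coarse[mask] - dense[mask]) / dense[mask] < 0.05)

    def test_rigid_transform_invariance(self, helix12):
        base = compute_sasa(helix12)
        moved = compute_sasa(_transformed(helix12, seed=3))
        assert np.abs(moved.sum() - base.sum()) / base.sum() < 0.005


class TestSecondaryStructure:
    def test_ideal_helix_interior_all_h(self, helix12):
        states = assign_secondary_structure(helix12).states
        # terminal residues lack phi or psi and stay coil
        assert states[1:-1] == "H" * 10

    def test_extended_chain_interior_all_e(self, extended10):
        states = assign_secondary_structure(extended10).states
        assert states[1:-1] == "E" * 8

    def test_short_helix_fragment_below_run_length_is_coil(self):
        from qprob.synth import make_helix
        assert assign_secondary_structure(make_helix(4)).states == "CCCC"

    def test_missing_backbone_assigned_coil(self):
        model = _point_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                              [11.4, 0, 0], [15.2, 0, 0]])
        assert assign_secondary_structure(model).states == "CCCCC"


class TestReferenceAreas:
    def test_nonpolar_residue_has_stn_equal_st(self):
        surf = total_reference_areas(_point_model([[0, 0, 0]], name="ALA"))
        assert surf.total[0] == REFERENCE_AREAS["ALA"]
        assert surf.total_nonpolar[0] == surf.total[0]

    def test_polar_residue_has_zero_stn(self):
        surf = total_reference_areas(_point_model([[0, 0, 0]], name="ASP"))
        assert surf.total_nonpolar[0] == 0.0

    def test_mse_maps_to_met(self):
        surf = total_reference_areas(_point_model([[0, 0, 0]], name="MSE"))
        assert surf.total[0] == REFERENCE_AREAS["MET"]


class TestCompactScore:
    def test_two_residue_hand_computed_value(self):
        model = _point_model([[0, 0, 0], [11.08, 0, 0]])
        # mean distance 11.08 over D_ref = 5.54 * 2^(1/3) * 2.0 = 13.96
        assert euclidean_compact_score(model) == pytest.approx(0.794, abs=5e-4)

    def test_coincident_atoms_score_zero(self):
        assert euclidean_compact_score(_point_model([[0, 0, 0]] * 5)) == 0.0

    def test_long_extended_chain_clips_to_one(self):
        coords = [[3.8 * i, 0, 0] for i in range(100)]
        assert euclidean_compact_score(_point_model(coords)) == 1.0

    def test_rigid_invariance(self, helix12):
        a = euclidean_compact_score(helix12)
        b = euclidean_compact_score(_transformed(helix12, seed=1))
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_residue_is_error(self):
        with pytest.raises(ValueError):
            euclidean_compact_score(_point_model([[0, 0, 0]]))


def _surf(exposed, total, nonpolar_mask, mass=None):
    exposed = np.asarray(exposed, float)
    total = np.asarray(total, float)
    nonpolar = np.asarray(nonpolar_mask, bool)
    mass = np.ones_like(exposed) if mass is None else np.asarray(mass, float)
    return ResidueSurface(
        residue_names=["ALA" if np_ else "ASP" for np_ in nonpolar],
        exposed=exposed, total=total,
        exposed_nonpolar=np.where(nonpolar, exposed, 0.0),
        total_nonpolar=np.where(nonpolar, total, 0.0), mass=mass)


class TestSurfaceScores:
    def test_nonpolar_fraction_arithmetic(self):
        assert surface_nonpolar_score(
            _surf([10, 30], [40, 40], [True, False])) == pytest.approx(0.25)

    def test_all_nonpolar_gives_one_none_gives_zero(self):
        assert surface_nonpolar_score(_surf([5, 5], [40, 40], [1, 1])) == 1.0
        assert surface_nonpolar_score(_surf([5, 5], [40, 40], [0, 0])) == 0.0

    def test_exposed_surface_ratio(self):
        assert exposed_surface_score(_surf([20, 20], [40, 40], [0, 0])) == 0.5
        assert exposed_surface_score(_surf([40, 40], [40, 40], [0, 0])) == 1.0
        assert exposed_surface_score(_surf([0, 0], [40, 40], [0, 0])) == 0.0

    def test_exposed_mass_threshold(self):
        # one of two equal-mass residues above the 0.25 relative threshold
        surf = _surf([30, 5], [100, 100], [0, 0], mass=[50, 50])
        assert exposed_mass_score(surf) == 0.5
        assert exposed_mass_score(_surf([90], [100], [0])) == 1.0
        assert exposed_mass_score(_surf([0], [100], [0])) == 0.0

    def test_scores_invariant_to_residue_reordering(self, rng):
        exposed = rng.uniform(0, 50, 6)
        total = exposed + rng.uniform(1, 50, 6)
        nonpolar = rng.random(6) > 0.5
        perm = rng.permutation(6)
        a = _surf(exposed, total, nonpolar)
        b = _surf(exposed[perm], total[perm], nonpolar[perm])
        assert surface_nonpolar_score(a) == pytest.approx(surface_nonpolar_score(b))
        assert exposed_surface_score(a) == pytest.approx(exposed_surface_score(b))


def _ann(kind, s):
    return PerResidueAnnotation(kind=kind, states=s)


class TestSimilarityScores:
    def test_ss_similarity_cases(self):
        assert ss_similarity_score(_ann("predicted_ss", "HHCC"),
                                   _ann("model_ss", "HHCC")) == 1.0
        assert ss_similarity_score(_ann("predicted_ss", "HHEC"),
                                   _ann("model_ss", "CCHE")) == 0.0
        assert ss_similarity_score(_ann("predicted_ss", "HHCC"),
                                   _ann("model_ss", "HECC")) == 0.75

    def test_gaps_excluded_from_denominator(self):
        score = ss_similarity_score(_ann("predicted_ss", "HHCC"),
                                    _ann("model_ss", "H-CC"))
        assert score == 1.0

    def test_all_gaps_is_error(self):
        with pytest.raises(ValueError):
            ss_similarity_score(_ann("predicted_ss", "HH"), _ann("model_ss", "--"))

    def test_ss_penalty(self):
        assert ss_penalty_score(SSComparison(10, 0, 10, 10, 10)) == 1.0
        assert ss_penalty_score(SSComparison(0, 0, 10, 4, 10)) == 0.0
        assert ss_penalty_score(SSComparison(2, 3, 10, 5, 10)) == 0.5

    def test_compare_ss_counts(self):
        cmp = compare_ss(_ann("predicted_ss", "HHEECC"),
                         _ann("model_ss", "HCEECC"))
        assert cmp.helix_matches == 1 and cmp.sheet_matches == 2
        assert cmp.match_count == 5 and cmp.n == 6

    def test_sa_similarity_cases(self):
        assert sa_similarity_score(_ann("predicted_sa", "eebb"),
                                   _ann("model_sa", "eebb")) == 1.0
        assert sa_similarity_score(_ann("predicted_sa", "eebb"),
                                   _ann("model_sa", "bbee")) == 0.0
        assert sa_similarity_score(_ann("predicted_sa", "eebb"),
                                   _ann("model_sa", "ebbb")) == 0.75


class TestFeatureRanges:
    def test_all_structural_features_in_unit_interval(self, helix12):
        surf = residue_surface(helix12)
        scores = [
            euclidean_compact_score(helix12),
            surface_nonpolar_score(surf),
            exposed_mass_score(surf),
            exposed_surface_score(surf),
        ]
        assert all(0.0 <= s <= 1.0 for s in scores)
        sa = model_sa_annotation(surf)
        assert set(sa.states) <= set("eb")
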