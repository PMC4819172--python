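"""GDT-TS, rank statistics and CASP-style evaluation, checked against
independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qprob._geom import apply_transform, kabsch, random_rigid_transform
from qprob.evaluate import (GDT_THRESHOLDS, evaluate_dataset, gdt_loss,
                            gdt_ts, kendall, pearson, spearman,
                            wilcoxon_signed_rank, zscore_top1)
from qprob.model_io import Residue, StructuralModel
from qprob.synth import make_decoy, make_helix


def _model(coords, model_id="m", start_index=1):
    return StructuralModel(model_id, [
        Residue("ALA", start_index + i, atoms={"CA": np.asarray(c, float)})
        for i, c in enumerate(coords)
    ])


def _transform_model(model, seed):
    rng = np.random.default_rng(seed)
    R, t = random_rigid_transform(rng)
    return _model([R @ r.ca + t for r in model.residues], "moved",
                  start_index=model.residues[0].index)


def exhaustive_gdt(model, native):
    """Subset-enumeration GDT-TS oracle for tiny instances (n <= 10).

    For every threshold and every >= 3-residue subset of the shared CAs,
    superpose on the subset (Kabsch) and count all shared CAs within the
    threshold; the maximum count over subsets gives the threshold's
    fraction (native-length denominator).
    """
    native_pos = {r.index: r.ca for r in native.residues}
    xs = np.array([r.ca for r in model.residues if r.index in native_pos])
    ys = np.array([native_pos[r.index] for r in model.residues
                   if r.index in native_pos])
    n = len(xs)
    assert n <= 10, "oracle is exponential"
    fractions = []
    for thr in GDT_THRESHOLDS:
        best = 0
        for k in range(3, n + 1):
            for subset in itertools.combinations(range(n), k):
                sel = np.asarray(subset)
                R, t = kabsch(xs[sel], ys[sel])
                d = np.linalg.norm(apply_transform(xs, R, t) - ys, axis=1)
                best = max(best, int((d <= thr + 1e-12).sum()))
        fractions.append(best / native.length)
    return float(np.mean(fractions))


class TestGdtTs:
    def test_identity_is_one(self, rng):
        native = _model(rng.uniform(-10, 10, (8, 3)))
        assert gdt_ts(native, native) == 1.0

    def test_rigid_transform_invariance(self, rng):
        native = _model(rng.uniform(-10, 10, (9, 3)))
        moved = _transform_model(native, seed=4)
        assert gdt_ts(moved, native) == pytest.approx(1.0, abs=1e-6)

    def test_half_displaced_toy_scores_half(self, rng):
        coords = rng.uniform(-8, 8, (10, 3))
        native = _model(coords)
        decoy_coords = coords.copy()
        decoy_coords[5:] += 20.0   # displace 5 of 10 residues far away
        decoy = _model(decoy_coords)
        assert gdt_ts(decoy, native) == pytest.approx(0.5)
        assert exhaustive_gdt(decoy, native) == pytest.approx(0.5)

    @pytest.mark.parametrize("noise", [0.0, 0.5, 1.5, 3.0, 6.0])
    def test_heuristic_equals_exhaustive_oracle_on_toys(self, noise):
        rng = np.random.default_rng(int(noise * 10) + 1)
        coords = rng.uniform(-8, 8, (8, 3))
        native = _model(coords)
        decoy = _model(coords + rng.normal(0, noise / np.sqrt(3), (8, 3)))
        assert gdt_ts(decoy, native) == pytest.approx(
            exhaustive_gdt(decoy, native), abs=1e-12)

    def test_partial_model_uses_native_denominator(self, rng):
        coords = rng.uniform(-8, 8, (8, 3))
        native = _model(coords)
        partial = _model(coords[:4])   # half the residues, perfectly placed
        assert gdt_ts(partial, native) == pytest.approx(0.5)

    def test_fragment_heuristic_bounded_by_exact_search(self, monkeypatch, rng):
        """The fragment-seeded search never exceeds the exact optimum and
        matches it on mildly perturbed chains."""
        import qprob.evaluate as ev
        coords = np.cumsum(rng.normal(0, 2.2, (12, 3)), axis=0)  # chain-like
        native = _model(coords)
        for noise, seed in ((0.0, 1), (0.3, 1), (1.0, 2), (2.5, 3)):
            srng = np.random.default_rng(seed)
            decoy = _model(coords + srng.normal(0, noise / np.sqrt(3), (12, 3)))
            exact = gdt_ts(decoy, native)
            monkeypatch.setattr(ev, "_EXACT_MAX_RESIDUES", 0)
            heuristic = gdt_ts(decoy, native)
            monkeypatch.undo()
            assert heuristic <= exact + 1e-12
            assert heuristic >= exact - 0.1       # gap stays small
            if noise == 0.0:
                assert heuristic == exact == 1.0

    def test_too_few_common_residues_is_error(self, rng):
        native = _model(rng.uniform(-8, 8, (6, 3)))
        far = _model(rng.uniform(-8, 8, (3, 3)), start_index=100)
        with pytest.raises(ValueError):
            gdt_ts(far, native)


class TestCorrelations:
    def test_identical_and_reversed_rankings(self):
        x = [0.1, 0.4, 0.7, 0.9]
        assert spearman(x, x) == 1.0
        assert kendall(x, x) == 1.0
        assert spearman(x, x[::-1]) == -1.0
        assert kendall(x, x[::-1]) == -1.0
        assert pearson(x, x) == pytest.approx(1.0)

    def test_kendall_matches_concordance_count_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            n = len(a)
            conc = disc = 0
            for i in range(n):
                for j in range(i + 1, n):
                    s = np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
                    conc += s > 0
                    disc += s < 0
            tau_oracle = (conc - disc) / (n * (n - 1) / 2)
            assert kendall(a, b) == pytest.approx(tau_oracle, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [0.1, 0.5, 0.9]))
        assert np.isnan(spearman([1.0, 1.0, 1.0], [0.1, 0.5, 0.9]))

    def test_spearman_is_pearson_of_ranks(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        from scipy.stats import rankdata
        assert spearman(a, b) == pytest.approx(
            pearson(rankdata(a), rankdata(b)), abs=1e-12)


class TestGdtLoss:
    def test_perfect_pick_is_zero(self):
        assert gdt_loss([0.9, 0.2], [0.8, 0.3]) == 0.0

    def test_wrong_pick_costs_gap(self):
        assert gdt_loss([0.1, 0.9], [0.9, 0.6]) == pytest.approx(0.3)

    def test_single_model_is_zero(self):
        assert gdt_loss([0.4], [0.7]) == 0.0

    def test_ties_resolve_by_model_id_not_optimistically(self):
        # both models predicted equal; the lexicographically first ("a") is
        # picked even though "b" has the better truth
        loss = gdt_loss([0.5, 0.5], [0.2, 0.9], model_ids=["a", "b"])
        assert loss == pytest.approx(0.7)

    def test_never_negative(self, rng):
        for _ in range(50):
            pred = rng.uniform(0, 1, 10)
            true = rng.uniform(0, 1, 10)
            assert gdt_loss(pred, true) >= 0.0


class TestWilcoxon:
    def test_identical_lists_give_p_one(self):
        a = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_matches_exact_sign_enumeration(self, rng):
        from scipy.stats import rankdata
        for _ in range(5):
            d = rng.normal(0.1, 1.0, 10)
            ranks = rankdata(np.abs(d))
            wplus = ranks[d > 0].sum()
            ws = np.array([
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([0, 1], repeat=10)])
            p_oracle = min(1.0, 2 * min((ws <= wplus).mean(),
                                        (ws >= wplus).mean()))
            assert wilcoxon_signed_rank(d, np.zeros(10)) == pytest.approx(
                p_oracle, abs=1e-12)

    def test_too_few_nonzero_differences_is_error(self):
        with pytest.raises(ValueError, match="too few"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 3.5])

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.normal(0.2, 1.0, 40)
        b = rng.normal(0.0, 1.0, 40)
        p = wilcoxon_signed_rank(a, b)
        assert 0.0 < p <= 1.0


class TestZScores:
    def test_unanimous_methods_sum_to_zero(self):
        sel = pd.DataFrame({"m1": [0.5, 0.7], "m2": [0.5, 0.7]})
        assert (zscore_top1(sel) == 0.0).all()

    def test_two_methods_symmetric(self):
        sel = pd.DataFrame({"better": [0.8, 0.9], "worse": [0.4, 0.5]})
        sums = zscore_top1(sel)
        assert sums["better"] == pytest.approx(-sums["worse"])
        assert sums["better"] > 0

    def test_matches_direct_recomputation(self, rng):
        sel = pd.DataFrame(rng.uniform(0, 1, (10, 5)),
                           columns=[f"m{i}" for i in range(5)])
        sums = zscore_top1(sel)
        expected = np.zeros(5)
        for _, row in sel.iterrows():
            v = row.to_numpy()
            sd = v.std()
            if sd > 0:
                expected += np.maximum((v - v.mean()) / sd, -2.0)
        np.testing.assert_allclose(sums.to_numpy(), expected, atol=1e-12)

    def test_floor_applied(self):
        sel = pd.DataFrame({"a": [0.0], "b": [0.5], "c": [0.5], "d": [0.5],
                            "e": [0.5], "f": [0.5], "g": [0.5], "h": [0.5]})
        sums = zscore_top1(sel)
        assert sums["a"] == pytest.approx(-2.0)


class TestEvaluateDataset:
    @staticmethod
    def _tables():
        preds = pd.DataFrame({
            "target_id": ["t1"] * 3 + ["t2"] * 3 + ["t3"],
            "model_id": ["a", "b", "c"] * 2 + ["a"],
            "score": [0.9, 0.5, 0.1, 0.2, 0.8, 0.5, 0.4],
        })
        truths = pd.DataFrame({
            "target_id": ["t1"] * 3 + ["t2"] * 3 + ["t3"],
            "model_id": ["a", "b", "c"] * 2 + ["a"],
            "gdtts": [0.8, 0.5, 0.2, 0.3, 0.7, 0.5, 0.6],
        })
        return preds, truths

    def test_summary_layout_and_count(self):
        table, summary = evaluate_dataset(*self._tables())
        assert len(table) == 3
        assert summary["n_targets"] == 3.0
        assert summary["avg_pearson"] == pytest.approx(1.0)  # both targets exact rank

    def test_single_model_target_counts_loss_not_correlation(self):
        table, _ = evaluate_dataset(*self._tables())
        assert table.loc["t3", "loss"] == 0.0
        assert np.isnan(table.loc["t3", "pearson"])

    def test_empty_overlap_is_error(self):
        preds, truths = self._tables()
        truths["model_id"] = "zzz"
        with pytest.raises(ValueError):
            evaluate_dataset(preds, truths)
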