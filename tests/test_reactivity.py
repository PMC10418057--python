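"""Hit calling, fold test, PhAR scores, and evaluation summaries."""

import numpy as np
import pandas as pd
import pytest

from epistitch.reactivity import (
    alanine_epitope_profile,
    call_hits,
    cost_effectiveness,
    hit_foldchange,
    mass_width,
    pharscore,
    protein_recovery,
    reactive_fraction,
    simple_fold_test,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestCallHits:
    def test_threshold_conjunction(self):
        counts = _frame([[16, 16, 15, 16]])
        log2fc = _frame([[np.log2(5.1), np.log2(4.9), np.log2(100.0), np.log2(6.0)]])
        pvals = _frame([[0.0009, 0.0009, 1e-9, 0.001]])
        hits = call_hits(counts, log2fc, pvals)
        # hit; fc too low; count at boundary (strict); p at boundary (strict)
        assert hits.to_numpy().tolist() == [[True, False, False, False]]

    def test_all_zero_counts_no_hits(self):
        z = _frame(np.zeros((5, 3)))
        assert not call_hits(z, z, z + 1).to_numpy().any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            call_hits(_frame(np.zeros((2, 2))), _frame(np.zeros((3, 2))),
                      _frame(np.ones((2, 2))))


class TestSimpleFoldTest:
    def test_null_center(self):
        mock = _frame(np.full((4, 3), 100.0), prefix="m")
        counts = _frame(np.full((4, 2), 100.0))
        log2fc, pvals = simple_fold_test(counts, mock)
        assert np.allclose(log2fc.to_numpy(), 0.0, atol=0.05)
        assert (pvals.to_numpy() >= 0.5).all()

    def test_tenfold_enrichment(self):
        mock = _frame(np.full((100, 2), 100.0), prefix="m")
        c = np.full((100, 1), 100.0)
        c[0, 0] = 1000.0
        counts = _frame(c)
        log2fc, pvals = simple_fold_test(counts, mock)
        # depth scaling: one peptide at 10x barely shifts the column total
        assert 2 ** log2fc.iloc[0, 0] == pytest.approx(10.0, rel=0.1)
        assert pvals.iloc[0, 0] < 1e-6

    def test_pseudocount_shrinks_low_count_fold_changes(self):
        mock = _frame(np.full((2, 2), 2.0), prefix="m")
        counts = _frame([[8.0], [2.0]])
        fc1, _ = simple_fold_test(counts, mock, pseudocount=1)
        fc2, _ = simple_fold_test(counts, mock, pseudocount=2)
        assert abs(fc2.iloc[0, 0]) < abs(fc1.iloc[0, 0])

    def test_requires_mock_columns(self):
        counts = _frame(np.ones((3, 2)))
        with pytest.raises(ValueError, match="mock"):
            simple_fold_test(counts, counts.iloc[:, :0])


class TestReactiveFraction:
    def test_single_reactive_sample_flags_peptide(self):
        m = np.zeros((1, 51))
        m[0, 17] = 2.0
        flags, frac = reactive_fraction(_frame(m))
        assert bool(flags.iloc[0]) and frac == 1.0

    def test_all_zero_matrix(self):
        _, frac = reactive_fraction(_frame(np.zeros((10, 4))))
        assert frac == 0.0

    def test_planted_rate_recovered(self):
        rng = np.random.default_rng(0)
        n = 5000
        reactive = rng.random(n) < 0.30
        m = np.zeros((n, 8))
        m[reactive, 0] = 1.5
        _, frac = reactive_fraction(_frame(m))
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reactive_fraction(pd.DataFrame())


def _phage_map(assignments):
    """assignments: {phage: [peptide indices]} -> peptide->phages mapping."""
    out = {}
    for ph, idxs in assignments.items():
        for i in idxs:
            out.setdefault(f"p{i}", []).append(ph)
    return out


class TestPharscore:
    def test_constant_matrix_scores_zero(self):
        log2fc = _frame(np.full((200, 3), 1.7))
        pmap = _phage_map({"phA": range(30), "phB": range(50, 90)})
        tab = pharscore(log2fc, pmap, n_draws=200, seed=1)
        assert np.allclose(tab.scores.to_numpy(), 0.0)

    def test_planted_phage_detected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (800, 4))
        vals[:30] += 2.0   # phage A's peptides strongly enriched
        log2fc = _frame(vals)
        pmap = _phage_map({"phA": range(30), "phB": range(100, 140)})
        tab = pharscore(log2fc, pmap, n_draws=500, seed=3)
        assert (tab.scores.loc["phA"] > 1).all()
        assert tab.scores.loc["phB"].abs().mean() < 1.5
        assert tab.iterations_used <= 7

    def test_reactive_phages_leave_pool_by_iteration_two(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (600, 3))
        vals[:30] += 2.5
        vals[20:55] += 2.5  # overlapping membership with phA
        log2fc = _frame(vals)
        pmap = _phage_map({"phA": range(30), "phB": range(20, 55),
                           "phC": range(200, 230)})
        tab = pharscore(log2fc, pmap, n_draws=500, seed=5)
        flagged = set()
        for it in tab.removal_log[:2]:
            for phages in it.values():
                flagged.update(phages)
        assert {"phA", "phB"} <= flagged
        assert tab.iterations_used <= 7

    def test_min_peptide_eligibility(self):
        log2fc = _frame(np.zeros((100, 2)))
        pmap = _phage_map({"small": range(10), "big": range(20, 50)})
        tab = pharscore(log2fc, pmap, min_peptides=25, n_draws=100, seed=6)
        assert list(tab.scores.index) == ["big"]

    def test_no_eligible_phage_rejected(self):
        log2fc = _frame(np.zeros((30, 2)))
        with pytest.raises(ValueError, match=">= 25"):
            pharscore(log2fc, _phage_map({"tiny": range(5)}))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        log2fc = _frame(rng.normal(0, 1, (400, 3)))
        pmap = _phage_map({"phA": range(30), "phB": range(50, 80)})
        t1 = pharscore(log2fc, pmap, n_draws=300, seed=9)
        t2 = pharscore(log2fc, pmap, n_draws=300, seed=9)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)

    def test_pool_never_grows_and_flagged_set_monotone(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (500, 4))
        vals[:40] += 1.0
        log2fc = _frame(vals)
        pmap = _phage_map({f"ph{k}": range(40 * k, 40 * k + 40) for k in range(6)})
        tab = pharscore(log2fc, pmap, n_draws=300, seed=10)
        seen: set = set()
        for it in tab.removal_log:
            newly = {(s, p) for s, phs in it.items() for p in phs}
            assert not (newly & seen)   # removals are new, pool only shrinks
            seen |= newly


class TestCostEffectiveness:
    def _hits(self):
        rng = np.random.default_rng(0)
        return _frame(rng.random((40, 6)) < 0.2)

    def test_endpoint_conserved_under_reordering(self):
        hits = self._hits()
        fwd = cost_effectiveness(hits, list(hits.index))
        rev = cost_effectiveness(hits, list(hits.index)[::-1])
        assert fwd[-1] == rev[-1] == hits.to_numpy().sum()
        assert (np.diff(fwd) >= 0).all()

    def test_step_function_when_one_peptide_has_all_hits(self):
        m = np.zeros((5, 3), dtype=bool)
        m[0] = True
        curve = cost_effectiveness(_frame(m), [f"p{i}" for i in range(5)])
        assert curve.tolist() == [3, 3, 3, 3, 3]

    def test_probability_ordering_dominates_random(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(20):
            probs = rng.random(60)
            hits = _frame((rng.random((60, 5)).T < probs * 0.5).T)
            ids = list(hits.index)
            ordered = [ids[i] for i in np.argsort(-probs)]
            shuffled = list(rng.permutation(ids))
            if cost_effectiveness(hits, ordered).sum() >= cost_effectiveness(
                    hits, shuffled).sum():
                wins += 1
        assert wins >= 18

    def test_non_permutation_rejected(self):
        hits = self._hits()
        with pytest.raises(ValueError, match="permutation"):
            cost_effectiveness(hits, list(hits.index)[:-1])


class TestProteinRecovery:
    def test_identical_patterns_perfect_metrics(self):
        rng = np.random.default_rng(2)
        truth = _frame(rng.random((30, 4)) < 0.4)
        m = protein_recovery(truth, truth.copy())
        assert np.allclose(m.per_sample["accuracy"], 1.0)
        assert np.allclose(m.per_sample["recall"], 1.0)
        assert np.allclose(m.per_sample["precision"], 1.0)

    def test_missing_proteins_cap_full_universe_recall(self):
        truth = _frame(np.ones((10, 2), dtype=bool))
        test = truth.iloc[:5].copy()
        m = protein_recovery(truth, test)
        assert len(m.missing_proteins) == 5
        assert np.allclose(m.full_universe_recall, 0.5)
        assert np.allclose(m.per_sample["recall"], 1.0)  # shared universe

    def test_empty_truth_gives_nan_recall(self):
        truth = _frame(np.zeros((5, 2), dtype=bool))
        test = _frame(np.zeros((5, 2), dtype=bool))
        m = protein_recovery(truth, test)
        assert m.per_sample["recall"].isna().all()

    def test_invariant_to_orderings(self):
        rng = np.random.default_rng(3)
        truth = _frame(rng.random((20, 5)) < 0.3)
        test = _frame(rng.random((20, 5)) < 0.3)
        base = protein_recovery(truth, test).per_sample
        perm = rng.permutation(truth.index)
        again = protein_recovery(truth.loc[perm], test.loc[perm]).per_sample
        pd.testing.assert_frame_equal(base, again)

    def test_no_shared_proteins_rejected(self):
        truth = _frame(np.ones((3, 2), dtype=bool))
        test = truth.copy()
        test.index = ["x0", "x1", "x2"]
        with pytest.raises(ValueError, match="shared"):
            protein_recovery(truth, test)


class TestAlanineProfile:
    @staticmethod
    def _tables(epi_start=20, width=14, wt_value=2.5, n_samples=1):
        """Noise-free scan: disruption iff the 3-mer intersects the epitope."""
        rows = []
        samples = {f"s{j}": wt_value for j in range(n_samples)}
        for pos in range(54):
            disrupted = pos + 3 > epi_start and pos < epi_start + width
            rows.append({"wildtype_id": "wt0", "pos": pos,
                         **{k: 0.0 if disrupted else wt_value for k in samples}})
        variants = pd.DataFrame(rows)
        wildtype = pd.DataFrame([{"wildtype_id": "wt0", **samples}])
        return variants, wildtype

    def test_noise_free_disruption_positions(self):
        variants, wildtype = self._tables(epi_start=20, width=14)
        prof = alanine_epitope_profile(variants, wildtype)
        assert prof.n_curves == 1
        disrupted = np.flatnonzero(~np.isnan(prof.curves[0]) & (prof.curves[0] > 1))
        assert len(disrupted) == 16   # width + 2 from the 3-mer window
        assert prof.width == mass_width(np.nan_to_num(prof.curves[0]), 53)

    def test_flat_curves_excluded(self):
        variants, wildtype = self._tables()
        variants.loc[:, "s0"] = 2.5    # no disruption anywhere
        prof = alanine_epitope_profile(variants, wildtype)
        assert prof.n_curves == 0 and np.isnan(prof.width)
        assert "no single-epitope" in prof.diagnostic

    def test_two_disruption_regions_excluded(self):
        variants, wildtype = self._tables(epi_start=5, width=10)
        # add a second disrupted region far away
        far = (variants["pos"] >= 40) & (variants["pos"] < 45)
        variants.loc[far, "s0"] = 0.0
        prof = alanine_epitope_profile(variants, wildtype)
        assert prof.n_curves == 0

    def test_nonreactive_wildtype_sample_skipped(self):
        variants, wildtype = self._tables(n_samples=2)
        wildtype.loc[0, "s1"] = 0.0
        prof = alanine_epitope_profile(variants, wildtype)
        assert prof.n_curves == 1


class TestMassWidth:
    def test_flat_run_width(self):
        curve = np.zeros(107)
        curve[45:61] = 1.0   # 16 positions of equal mass
        assert mass_width(curve, 53, 0.8) == 13  # ceil(0.8 * 16)

    def test_point_mass(self):
        curve = np.zeros(21)
        curve[10] = 5.0
        assert mass_width(curve, 10) == 1

    def test_all_zero_is_nan(self):
        assert np.isnan(mass_width(np.zeros(11), 5))


def test_hit_foldchange_zeroes_non_hits():
    log2fc = _frame([[2.0, 3.0]])
    hits = _frame([[True, False]])
    out = hit_foldchange(log2fc, hits)
    assert out.to_numpy().tolist() == [[2.0, 0.0]]
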