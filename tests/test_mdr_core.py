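import math

import numpy as np
import pytest

import epimdr as em
from epimdr.mdr import EMPTY, HIGH, LOW, MdrError

import _oracle as bf
from conftest import make_cohort, random_small_cohort


class TestMakeFolds:
    def test_balanced_stratified_folds(self):
        c = make_cohort({"L": ["AA"] * 40}, [1] * 20 + [0] * 20)
        plan = em.make_folds(c, k=10, seed=1)
        phen = c.phenotype
        for f in range(10):
            assert ((plan.fold_index == f) & (phen == 1)).sum() == 2
            assert ((plan.fold_index == f) & (phen == 0)).sum() == 2

    def test_deterministic_and_partitioning(self):
        c = make_cohort({"L": ["AA", "AB", "BB"] * 10}, [0, 1] * 15)
        a = em.make_folds(c, k=5, seed=7)
        b = em.make_folds(c, k=5, seed=7)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)
        assert set(a.fold_index) == set(range(5))  # union covers, disjoint by construction

    def test_small_class_rejected(self):
        c = make_cohort({"L": ["AA"] * 12}, [1] * 2 + [0] * 10)
        with pytest.raises(MdrError, match="fewer than"):
            em.make_folds(c, k=5, seed=0)


class TestLabelCells:
    def test_cases_without_controls_is_high(self):
        c = make_cohort({"L": ["AA"] * 10 + ["BB"] * 10},
                        [1] * 10 + [0] * 10)
        lab = em.label_cells(c, "L")
        assert lab.label_of(("AA",), c) == HIGH
        assert lab.label_of(("BB",), c) == LOW
        assert lab.label_of(("AB",), c) == EMPTY

    def test_threshold_tie_is_high(self):
        # cell ratio exactly T = 1.0 -> high (closed half-line)
        c = make_cohort({"L": ["AA", "AA", "BB", "BB"]}, [1, 0, 1, 0])
        lab = em.label_cells(c, "L")
        assert lab.label_of(("AA",), c) == HIGH and lab.label_of(("BB",), c) == HIGH

    def test_hand_enumerated_two_by_two(self):
        # cells with case:control ratios 2.0, 0.5, 1.0 and one empty, T=1
        geno_a = ["AA"] * 3 + ["AB"] * 3 + ["BB"] * 2
        phen = [1, 1, 0] + [1, 0, 0] + [1, 0]
        c = make_cohort({"L": geno_a}, phen)
        lab = em.label_cells(c, "L")
        assert lab.label_of(("AA",), c) == HIGH      # 2:1 >= 1
        assert lab.label_of(("AB",), c) == LOW       # 1:2 < 1
        assert lab.label_of(("BB",), c) == HIGH      # 1:1 tie

    def test_every_high_cell_meets_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            c = random_small_cohort(rng, 2, 28)
            lab = em.label_cells(c, ("L0", "L1"))
            high = lab.labels == HIGH
            # exact rule, directly assertable on the labeling data
            assert (lab.case_counts[high] * c.n_controls
                    >= c.n_cases * lab.control_counts[high]).all()
            low = lab.labels == LOW
            assert (lab.case_counts[low] * c.n_controls
                    < c.n_cases * lab.control_counts[low]).all()


class TestReduce:
    def test_all_high_labeling_gives_all_ones(self):
        c = make_cohort({"L": ["AA", "BB", "AB", "AA"]}, [1, 1, 1, 0])
        lab = em.label_cells(c, "L")
        lab.labels[:] = HIGH
        rec = em.reduce(c, lab)
        assert rec.indicator.tolist() == [1, 1, 1, 1]

    def test_low_cell_individual_is_zero(self, reconstruction):
        lab = em.label_cells(reconstruction, ("ACE", "FGB_T148C"))
        rec = em.reduce(reconstruction, lab)
        d = reconstruction.data
        in_low = (d["ACE"] == "ID") & (d["FGB_T148C"] == "CT")
        assert (rec.indicator[in_low.to_numpy()] == 0).all()

    def test_recode_margins_equal_class_sizes(self):
        rng = np.random.default_rng(3)
        c = random_small_cohort(rng, 2, 30)
        lab = em.label_cells(c, ("L0", "L1"))
        rec = em.reduce(c, lab)
        tab = em.classify_individuals(c, lab)
        assert tab.counts[:, 0].sum() == c.n_cases
        assert tab.counts[:, 1].sum() == c.n_controls
        assert tab.counts[0, 0] == rec.indicator[c.phenotype == 1].sum()

    def test_missing_genotype_excluded(self):
        c = make_cohort({"L": ["AA", "NA", "BB"]}, [1, 0, 1])
        lab = em.label_cells(c, "L")
        rec = em.reduce(c, lab)
        assert rec.n_missing == 1 and not rec.used[1]


class TestBalancedAccuracy:
    def test_perfect_prediction(self):
        assert em.balanced_accuracy([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_constant_prediction_is_chance(self):
        assert em.balanced_accuracy([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_hand_computed_mixture(self):
        # TP=3 FN=1 TN=2 FP=2 -> (0.75 + 0.5)/2
        pred = [1, 1, 1, 0, 0, 0, 1, 1]
        phen = [1, 1, 1, 1, 0, 0, 0, 0]
        assert em.balanced_accuracy(pred, phen) == pytest.approx(0.625)

    def test_length_mismatch(self):
        with pytest.raises(MdrError):
            em.balanced_accuracy([1, 0], [1])


class TestSignTest:
    def test_all_folds_above_chance(self):
        ev = em.ModelEvaluation(("L",), np.ones(10), np.full(10, 0.6), 10, 1.0)
        assert em.sign_test(ev) == pytest.approx(2 ** -10)

    def test_half_folds(self):
        acc = np.array([0.6] * 5 + [0.4] * 5)
        ev = em.ModelEvaluation(("L",), acc, acc, 10, 1.0)
        assert em.sign_test(ev) == pytest.approx(0.623046875)

    def test_no_fold_above_chance(self):
        ev = em.ModelEvaluation(("L",), np.ones(10), np.full(10, 0.5), 10, 1.0)
        assert em.sign_test(ev) == pytest.approx(1.0)  # exactly 0.5 counts as failure


class TestCvEvaluate:
    def test_matches_bruteforce_on_tiny_cohort(self):
        rng = np.random.default_rng(5)
        c = random_small_cohort(rng, 2, 12)
        folds = em.make_folds(c, k=2, seed=9)
        ev = em.cv_evaluate(c, ("L0", "L1"), folds)
        tr, te = bf.fold_accuracies_bf(bf.rows_of(c), ("L0", "L1"), folds.fold_index, 2)
        np.testing.assert_allclose(ev.train_accuracy, [float(x) for x in tr], atol=1e-12)
        np.testing.assert_allclose(ev.test_accuracy, [float(x) for x in te], atol=1e-12)
        assert ev.prediction_error == pytest.approx(1 - ev.mean_test_accuracy)

    def test_planted_pair_beats_chance(self):
        cfg = em.default_config(n_cases=1000, n_controls=1000, seed=21,
                                interaction_log_or=math.log(3.0),
                                include_covariates=False)
        c = em.generate(cfg)
        folds = em.make_folds(c, k=10, seed=2)
        ev = em.cv_evaluate(c, ("ACE", "FGB_T148C"), folds)
        assert ev.mean_test_accuracy > 0.55

    def test_shuffled_labels_near_chance(self):
        cfg = em.default_config(n_cases=500, n_controls=500, seed=22,
                                interaction_log_or=math.log(3.0),
                                include_covariates=False)
        base = em.generate(cfg)
        accs = []
        for fs in range(8):  # average over shuffle realizations: E[BA] = 0.5
            c = em.null_shuffle(base, seed=13 + fs)
            folds = em.make_folds(c, k=10, seed=fs)
            accs.append(em.cv_evaluate(c, ("ACE", "FGB_T148C"), folds).mean_test_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.03


class TestSearch:
    def test_determinism(self):
        rng = np.random.default_rng(8)
        c = random_small_cohort(rng, 3, 30)
        r1 = em.mdr_search(c, orders=(1, 2, 3), k=3, fold_seed=4)
        r2 = em.mdr_search(c, orders=(1, 2, 3), k=3, fold_seed=4)
        for o in r1.per_order:
            assert r1.per_order[o].combo == r2.per_order[o].combo
            assert r1.per_order[o].cv_consistency == r2.per_order[o].cv_consistency
            np.testing.assert_array_equal(r1.per_order[o].test_accuracy,
                                          r2.per_order[o].test_accuracy)

    def test_planted_pair_selected_at_order_two(self):
        cfg = em.default_config(n_cases=1000, n_controls=1000, seed=31,
                                interaction_log_or=math.log(3.0),
                                include_covariates=False)
        c = em.generate(cfg)
        res = em.mdr_search(c, orders=(1, 2), fold_seed=5)
        assert res.per_order[2].combo == ("ACE", "FGB_T148C")

    def test_single_locus_planted_effect(self):
        cfg = em.default_config(n_cases=800, n_controls=800, seed=32,
                                interaction_log_or=0.0, include_covariates=False,
                                main_effects={"ENOS_G894T": {"TT": 1.5, "GT": 0.9}})
        c = em.generate(cfg)
        res = em.mdr_search(c, orders=(1,), fold_seed=6)
        assert res.per_order[1].combo == ("ENOS_G894T",)

    def test_monotone_in_planted_effect(self):
        accs = []
        for or_ in (1.0, 1.5, 2.0, 3.0):
            cfg = em.default_config(n_cases=1500, n_controls=1500, seed=77,
                                    interaction_log_or=math.log(or_),
                                    include_covariates=False)
            c = em.generate(cfg)
            folds = em.make_folds(c, k=10, seed=7)
            accs.append(em.cv_evaluate(c, ("ACE", "FGB_T148C"), folds).mean_test_accuracy)
        assert accs == sorted(accs)


class TestPermutationTest:
    def test_add_one_floor(self):
        # strong effect: observed accuracy should beat every shuffle
        cfg = em.default_config(n_cases=300, n_controls=300, seed=41,
                                interaction_log_or=math.log(4.0),
                                include_covariates=False)
        c = em.generate(cfg)
        p, res = em.permutation_test(c, orders=(2,), n_perm=99, seed=5)
        assert p == pytest.approx(0.01)
        assert res.best.permutation_p == p

    def test_consistent_with_explicit_null_shuffle(self):
        # the internal shuffle must be the same operation null_shuffle does
        cfg = em.default_config(n_cases=50, n_controls=50, seed=42,
                                interaction_log_or=0.0, include_covariates=False)
        c = em.generate(cfg)
        shuffled = em.null_shuffle(c, seed=123)
        assert shuffled.n_cases == c.n_cases
        res_a = em.mdr_search(shuffled, orders=(1, 2), fold_seed=3)
        assert 0.0 <= res_a.best.mean_test_accuracy <= 1.0

    def test_add_one_p_bounds(self):
        cfg = em.default_config(n_cases=30, n_controls=30, seed=43,
                                interaction_log_or=0.0, include_covariates=False)
        c = em.generate(cfg)
        with pytest.raises(MdrError):
            em.permutation_test(c, orders=(1,), n_perm=0, seed=6, k=5)
        p, _ = em.permutation_test(c, orders=(1,), n_perm=9, seed=6, k=5)
        assert 1 / 10 <= p <= 1.0  # add-one estimator floor at 1/(n_perm+1)


class TestOracleEquivalence:
    def test_search_matches_bruteforce_small_cohorts(self):
        rng = np.random.default_rng(2024)
        for trial in range(20):
            n_loci = int(rng.integers(2, 4))
            n = int(rng.integers(12, 31))
            c = random_small_cohort(rng, n_loci, n)
            k = 3
            folds = em.make_folds(c, k=k, seed=trial)
            res = em.mdr_search(c, orders=(1, 2), folds=folds)
            oracle = bf.search_bf(bf.rows_of(c), [l.name for l in c.loci],
                                  (1, 2), folds.fold_index, k)
            for order in (1, 2):
                combo, wins, (tr, te) = oracle[order]
                ev = res.per_order[order]
                assert ev.combo == combo, f"trial {trial} order {order}"
                assert ev.cv_consistency == wins
                np.testing.assert_allclose(ev.train_accuracy, [float(x) for x in tr],
                                           atol=1e-12)
                np.testing.assert_allclose(ev.test_accuracy, [float(x) for x in te],
                                           atol=1e-12)
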