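"""David's scores: dyadic indices, normalization, rank classes, stability."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_win_matrix
from stressrank.behavior_io import InteractionMatrix, ValidationError
from stressrank.dominance import (
    DegenerateHierarchyError,
    DyadicIndexVariant,
    RankClass,
    WinMatrix,
    ZeroDyadPolicy,
    build_win_matrix,
    compute_dominance,
    david_score,
    dyadic_index,
    hierarchy_stability,
    normalize_ds,
    partition_hr_lr,
)


def win(W, subjects=None):
    W = np.asarray(W, dtype=float)
    subjects = subjects or [f"s{i}" for i in range(W.shape[0])]
    return WinMatrix(subjects=subjects, W=W)


class TestBuildWinMatrix:
    def make(self, behavior, M):
        return InteractionMatrix(behavior, "OBS1", [f"s{i}" for i in range(len(M))], np.asarray(M))

    def test_aggression_plus_reversed_submission(self):
        agg = self.make("AGG", [[0, 2], [0, 0]])
        sub = self.make("SUB", [[0, 0], [3, 0]])
        W = build_win_matrix(agg, sub)
        assert W.W[0, 1] == 5 and W.W[1, 0] == 0

    def test_zero_inputs_give_zero_wins(self):
        W = build_win_matrix(self.make("AGG", np.zeros((3, 3))), self.make("SUB", np.zeros((3, 3))))
        assert not W.W.any()

    def test_total_wins_equal_total_behavior_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            A = rng.integers(0, 9, (n, n)).astype(float)
            S = rng.integers(0, 9, (n, n)).astype(float)
            np.fill_diagonal(A, 0)
            np.fill_diagonal(S, 0)
            W = build_win_matrix(self.make("AGG", A), self.make("SUB", S))
            assert W.W.sum() == A.sum() + S.sum()

    def test_roster_mismatch_rejected(self):
        agg = self.make("AGG", np.zeros((2, 2)))
        sub = InteractionMatrix("SUB", "OBS1", ["x", "y"], np.zeros((2, 2)))
        with pytest.raises(ValidationError, match="roster"):
            build_win_matrix(agg, sub)


class TestDyadicIndex:
    def test_raw_proportions(self):
        comp = dyadic_index(win([[0, 4], [0, 0]]), DyadicIndexVariant.RAW)
        assert comp.index_matrix[0, 1] == 1.0 and comp.index_matrix[1, 0] == 0.0

    def test_chance_corrected_shrinks_toward_half(self):
        # P = 1 over 4 interactions: 1 - 0.5/5 = 0.9
        comp = dyadic_index(win([[0, 4], [0, 0]]), DyadicIndexVariant.CHANCE_CORRECTED)
        assert comp.index_matrix[0, 1] == pytest.approx(0.9)
        assert comp.index_matrix[1, 0] == pytest.approx(0.1)

    def test_zero_dyad_policies(self):
        comp = dyadic_index(win(np.zeros((2, 2))), zero_dyad=ZeroDyadPolicy.ZERO)
        assert not comp.index_matrix.any()
        comp = dyadic_index(win(np.zeros((2, 2))), zero_dyad=ZeroDyadPolicy.HALF)
        assert comp.index_matrix[0, 1] == comp.index_matrix[1, 0] == 0.5

    def test_directions_sum_to_one_for_active_dyads(self):
        rng = np.random.default_rng(1)
        W = random_win_matrix(rng)
        for variant in DyadicIndexVariant:
            idx = dyadic_index(win(W), variant).index_matrix
            active = (W + W.T) > 0
            np.testing.assert_allclose((idx + idx.T)[active], 1.0)


class TestDavidScore:
    def test_two_subject_hand_computation(self):
        # W = 4-0, RAW: w = [1, 0], w2 = [0, 0], l = [0, 1], l2 = [0, 0]
        comp = david_score(dyadic_index(win([[0, 4], [0, 0]]), DyadicIndexVariant.RAW))
        np.testing.assert_allclose(comp.w, [1, 0])
        np.testing.assert_allclose(comp.l, [0, 1])
        np.testing.assert_allclose(comp.ds, [1, -1])

    def test_fully_tied_group_scores_zero(self):
        W = np.full((4, 4), 3.0)
        np.fill_diagonal(W, 0)
        comp = david_score(dyadic_index(win(W)))
        np.testing.assert_allclose(comp.ds, 0, atol=1e-12)

    @pytest.mark.parametrize("variant", list(DyadicIndexVariant))
    def test_scores_sum_to_zero(self, variant):
        rng = np.random.default_rng(2)
        for _ in range(50):
            comp = david_score(dyadic_index(win(random_win_matrix(rng)), variant))
            assert abs(comp.ds.sum()) < 1e-9


class TestNormalizeDs:
    def test_direct_evaluation(self):
        res = normalize_ds([2.0, 0.0, -2.0])
        np.testing.assert_allclose(res.norm_ds, [1.0, 0.5, 0.0])
        assert res.ds_min == -2.0 and res.ds_prime_max == 4.0

    def test_extremes_map_to_one_and_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ds = rng.normal(size=rng.integers(2, 10))
            ds[0] += 10  # ensure non-degenerate
            res = normalize_ds(ds)
            assert res.norm_ds.max() == pytest.approx(1.0)
            assert res.norm_ds.min() == pytest.approx(0.0)

    def test_invariant_to_additive_shift(self):
        ds = np.array([1.4, -0.2, 0.9, -3.0])
        np.testing.assert_allclose(normalize_ds(ds).norm_ds, normalize_ds(ds + 17.3).norm_ds)

    def test_degenerate_hierarchy_rejected(self):
        with pytest.raises(DegenerateHierarchyError):
            normalize_ds([3.0, 3.0, 3.0])


class TestPartitionHrLr:
    def test_classes_and_ranks(self):
        res = partition_hr_lr(normalize_ds([5, 3, 1, -1, -3, -5]))
        assert [k.value for k in res.klass] == ["HR", "HR", "HR", "LR", "LR", "LR"]
        assert list(res.ordinal_rank) == [1, 2, 3, 4, 5, 6]

    def test_boundary_flagged_at_exactly_half(self):
        res = partition_hr_lr(normalize_ds([2.0, 0.0, -2.0]))
        assert res.klass[1] is RankClass.BOUNDARY


class TestRecoveryProperties:
    @pytest.mark.parametrize("variant", list(DyadicIndexVariant))
    def test_transitive_tournament_recovers_planted_order(self, variant):
        for n in (4, 7):
            W = np.triu(np.full((n, n), 6.0), 1)
            res = compute_dominance(win(W), variant=variant)
            assert list(res.ordinal_rank) == list(range(1, n + 1))

    def test_variants_agree_ordinally_on_balanced_designs(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n, m = int(rng.integers(3, 8)), int(rng.integers(2, 25))
            W = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    w = rng.binomial(m, rng.uniform())
                    W[i, j], W[j, i] = w, m - w
            ds_raw = david_score(dyadic_index(win(W), "RAW")).ds
            ds_cc = david_score(dyadic_index(win(W), "CHANCE_CORRECTED")).ds
            # equal n_ij makes the two scores proportional; compare tie-aware ranks
            np.testing.assert_array_equal(
                stats.rankdata(np.round(ds_raw, 9)), stats.rankdata(np.round(ds_cc, 9))
            )


class TestHierarchyStability:
    def result(self, norm):
        return partition_hr_lr(normalize_ds(norm, subjects=[f"s{i}" for i in range(len(norm))]))

    def test_identical_orders(self):
        a = self.result([3, 2, 1, 0])
        rep = hierarchy_stability(a, self.result([30, 20, 10, 0]))
        assert rep.tau == pytest.approx(1.0) and not rep.switched_pairs

    def test_reversed_orders(self):
        rep = hierarchy_stability(self.result([3, 2, 1, 0]), self.result([0, 1, 2, 3]))
        assert rep.tau == pytest.approx(-1.0)

    def test_single_adjacent_swap_on_seven(self):
        a = self.result([7, 6, 5, 4, 3, 2, 1])
        b = self.result([7, 6, 5, 3, 4, 2, 1])  # ranks 4 and 5 switch
        rep = hierarchy_stability(a, b)
        assert rep.tau == pytest.approx(19 / 21)
        assert rep.switched_pairs == [("s3", "s4")]

    def test_roster_mismatch_rejected(self):
        a = self.result([1, 0])
        b = partition_hr_lr(normalize_ds([1, 0], subjects=["x", "y"]))
        with pytest.raises(ValidationError):
            hierarchy_stability(a, b)
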