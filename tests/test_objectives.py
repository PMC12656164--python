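"""Pair-mask semantics and loss numerics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from autograd import grad

from supconhar.objectives import (
    PairMask,
    brute_force_supcon,
    build_pair_mask,
    cross_entropy,
    sibling_view_map,
    supcon_loss,
    total_loss,
    xnent_loss,
)


def _unit_rows(rng, n, d):
    Z = rng.normal(size=(n, d))
    return Z / np.linalg.norm(Z, axis=1, keepdims=True)


def _rule_table_masks(y_act, y_user, view_map, strategy):
    """Independent elementwise enumeration of the strategy definitions."""
    n = len(y_act)
    pos = np.zeros((n, n), dtype=bool)
    cand = np.zeros((n, n), dtype=bool)
    for i, j in itertools.product(range(n), range(n)):
        if i == j:
            continue
        same_a = y_act[i] == y_act[j]
        same_u = y_user[i] == y_user[j]
        if strategy == "instance":
            pos[i, j] = view_map[i] == j
            cand[i, j] = True
        elif strategy == "activity":
            pos[i, j] = same_a
            cand[i, j] = True
        else:
            pos[i, j] = same_a and not same_u
            cand[i, j] = pos[i, j] or (same_u and not same_a)
    return pos, cand


class TestPairMask:
    def test_hard_strategy_worked_example(self):
        # act [A,A,B,B], user [1,2,1,2]: P(0)={1}, hard negatives(0)={2}
        m = build_pair_mask(np.array([0, 0, 1, 1]), np.array([1, 2, 1, 2]),
                            None, "activity_user_hard")
        assert set(np.flatnonzero(m.pos[0])) == {1}
        assert set(np.flatnonzero(m.cand[0])) == {1, 2}

    def test_activity_strategy_worked_example(self):
        m = build_pair_mask(np.array([0, 0, 1, 1]), np.array([1, 2, 1, 2]),
                            None, "activity")
        assert set(np.flatnonzero(m.pos[0])) == {1}
        assert set(np.flatnonzero(m.cand[0])) == {1, 2, 3}

    def test_single_user_hard_strategy_has_no_valid_anchor(self):
        m = build_pair_mask(np.array([0, 1, 0, 1]), np.array([9, 9, 9, 9]),
                            None, "activity_user_hard")
        assert not m.anchor_valid.any()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            build_pair_mask(np.zeros(4), np.zeros(3), None, "activity")

    @pytest.mark.parametrize("strategy", ["instance", "activity", "activity_user_hard"])
    def test_masks_match_rule_table_on_exhaustive_grids(self, strategy):
        """All label assignments for 3 source windows x 2 views, up to 3
        users and 3 activities, against an independent enumeration."""
        B = 3
        vm = sibling_view_map(2 * B)
        for acts in itertools.product(range(3), repeat=B):
            for users in itertools.product(range(3), repeat=B):
                y_act = np.array(acts + acts)
                y_user = np.array(users + users)
                m = build_pair_mask(y_act, y_user, vm, strategy)
                pos, cand = _rule_table_masks(y_act, y_user, vm, strategy)
                np.testing.assert_array_equal(m.pos, pos)
                np.testing.assert_array_equal(m.cand, cand)
                # structural invariants
                assert not m.pos.diagonal().any()
                assert not m.cand.diagonal().any()
                assert not (m.pos & ~m.cand).any()
                np.testing.assert_array_equal(m.pos, m.pos.T)
                np.testing.assert_array_equal(m.cand, m.cand.T)
                np.testing.assert_array_equal(m.anchor_valid, m.pos.any(axis=1))

    def test_hard_positives_subset_of_activity_positives(self, rng):
        for _ in range(20):
            y_act = rng.integers(0, 3, 8)
            y_user = rng.integers(0, 3, 8)
            hard = build_pair_mask(y_act, y_user, None, "activity_user_hard")
            act = build_pair_mask(y_act, y_user, None, "activity")
            assert not (hard.pos & ~act.pos).any()

    def test_relaxed_flags_recover_standard_supcon(self):
        y_act = np.array([0, 0, 1, 1])
        y_user = np.array([1, 1, 2, 2])
        relaxed = build_pair_mask(y_act, y_user, None, "activity_user_hard",
                                  strict_positives=False,
                                  restrict_denominator=False)
        std = build_pair_mask(y_act, y_user, None, "activity")
        np.testing.assert_array_equal(relaxed.pos, std.pos)
        np.testing.assert_array_equal(relaxed.cand, std.cand)


class TestSupConLoss:
    def test_uniform_similarity_closed_form(self):
        # all embeddings identical and cand == pos: every log-ratio is
        # log(1/|A(i)|) so the loss is log|A(i)|
        Z = np.tile(np.array([[1.0, 0.0]]), (4, 1))
        pos = ~np.eye(4, dtype=bool)
        mask = PairMask(pos=pos, cand=pos.copy(), strategy="activity",
                        view_map=None, anchor_valid=pos.any(axis=1))
        val = supcon_loss(Z, mask, tau=0.5)
        assert val == pytest.approx(math.log(3), abs=1e-9)

    def test_worked_right_angle_example_matches_oracle(self):
        theta = np.array([0.0, 0.5, 1.0, 1.5]) * np.pi
        Z = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        mask = build_pair_mask(np.array([0, 0, 1, 1]), np.array([1, 2, 1, 2]),
                               None, "activity_user_hard")
        assert supcon_loss(Z, mask, 0.1) == pytest.approx(
            brute_force_supcon(Z, mask, 0.1), abs=1e-6)

    @pytest.mark.parametrize("strategy", ["instance", "activity", "activity_user_hard"])
    @pytest.mark.parametrize("tau", [0.05, 0.1, 0.5])
    def test_vectorized_equals_brute_force(self, strategy, tau):
        rng = np.random.default_rng(17)
        checked = 0
        trials = 0
        while checked < 25 and trials < 200:
            trials += 1
            B = int(rng.integers(2, 17))
            Z = _unit_rows(rng, 2 * B, int(rng.integers(2, 9)))
            y = rng.integers(0, 3, B)
            u = rng.integers(0, 3, B)
            mask = build_pair_mask(np.concatenate([y, y]), np.concatenate([u, u]),
                                   sibling_view_map(2 * B), strategy)
            if not mask.anchor_valid.any():
                continue
            assert supcon_loss(Z, mask, tau) == pytest.approx(
                brute_force_supcon(Z, mask, tau), abs=1e-6)
            checked += 1
        assert checked == 25

    def test_permutation_of_rows_only_changes_via_mask_topology(self, rng):
        Z = _unit_rows(rng, 8, 4)
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        u = np.array([1, 2, 1, 2, 2, 1, 2, 1])
        mask = build_pair_mask(y, u, None, "activity_user_hard")
        perm = rng.permutation(8)
        mask_p = build_pair_mask(y[perm], u[perm], None, "activity_user_hard")
        assert supcon_loss(Z[perm], mask_p, 0.2) == pytest.approx(
            supcon_loss(Z, mask, 0.2), abs=1e-10)

    def test_scale_invariance_through_normalization(self, rng):
        """Scaling pre-normalization projector outputs cannot change the
        loss: only directions survive the l2 normalization."""
        H = rng.normal(size=(6, 4))
        y = np.array([0, 0, 0, 1, 1, 1])
        u = np.array([1, 2, 3, 1, 2, 3])
        mask = build_pair_mask(y, u, None, "activity_user_hard")
        z1 = H / np.linalg.norm(H, axis=1, keepdims=True)
        H10 = 10.0 * H
        z2 = H10 / np.linalg.norm(H10, axis=1, keepdims=True)
        assert supcon_loss(z2, mask, 0.1) == pytest.approx(
            supcon_loss(z1, mask, 0.1), abs=1e-12)

    def test_pulling_a_positive_closer_decreases_loss(self):
        y = np.array([0, 0, 1, 1])
        u = np.array([1, 2, 1, 2])
        mask = build_pair_mask(y, u, None, "activity_user_hard")

        def z(angle):
            th = np.array([0.0, angle, np.pi, np.pi + 0.3])
            return np.stack([np.cos(th), np.sin(th)], axis=1)

        losses = [supcon_loss(z(a), mask, 0.1) for a in (1.2, 0.8, 0.4, 0.1)]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_no_valid_anchor_raises_with_guidance(self):
        Z = np.eye(4)
        mask = build_pair_mask(np.array([0, 1, 0, 1]), np.array([5, 5, 5, 5]),
                               None, "activity_user_hard")
        with pytest.raises(ValueError, match="stratified"):
            supcon_loss(Z, mask, 0.1)

    def test_gradient_flows_through_embeddings(self, rng):
        Z = _unit_rows(rng, 6, 3)
        mask = build_pair_mask(np.array([0, 0, 0, 1, 1, 1]),
                               np.array([1, 2, 3, 1, 2, 3]),
                               None, "activity_user_hard")
        g = grad(lambda z: supcon_loss(z, mask, 0.1))(Z)
        assert np.isfinite(g).all() and np.abs(g).max() > 0


class TestXNent:
    def test_equals_supcon_under_instance_mask(self, rng):
        for _ in range(10):
            B = int(rng.integers(2, 12))
            Z = _unit_rows(rng, 2 * B, 5)
            vm = sibling_view_map(2 * B)
            mask = build_pair_mask(np.zeros(2 * B), np.zeros(2 * B), vm, "instance")
            assert xnent_loss(Z, vm, 0.1) == pytest.approx(
                supcon_loss(Z, mask, 0.1), abs=1e-8)

    def test_high_temperature_limit_is_log_n_minus_1(self, rng):
        B = 5
        Z = _unit_rows(rng, B, 4)
        Z = np.concatenate([Z, Z])  # identical sibling views
        val = xnent_loss(Z, sibling_view_map(2 * B), tau=1e4)
        assert val == pytest.approx(math.log(2 * B - 1), abs=1e-3)

    def test_perfectly_separated_pairs_give_zero_loss(self):
        # sibling similarity +1, everyone else -1, sharp temperature
        pairs = np.array([[1.0, 0.0], [-1.0, 0.0]])
        Z = np.concatenate([pairs, pairs])
        assert xnent_loss(Z, sibling_view_map(4), 0.1) < 1e-6

    def test_odd_row_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            xnent_loss(np.eye(3), np.arange(3), 0.1)


class TestCrossEntropyAndTotal:
    def test_uniform_logits_log_C(self):
        val = cross_entropy(np.zeros((4, 5)), np.array([0, 1, 2, 3]))
        assert val == pytest.approx(math.log(5), abs=1e-12)

    def test_confident_correct_prediction_approaches_zero(self):
        logits = np.array([[100.0, 0.0], [0.0, 100.0]])
        assert cross_entropy(logits, np.array([0, 1])) < 1e-12

    def test_hand_computed_two_sample_batch(self):
        logits = np.array([[2.0, 1.0, 0.0], [0.0, 0.0, 3.0]])
        y = np.array([0, 2])
        expected = np.mean([
            -math.log(math.exp(2) / (math.exp(2) + math.exp(1) + 1)),
            -math.log(math.exp(3) / (2 + math.exp(3))),
        ])
        assert cross_entropy(logits, y) == pytest.approx(expected, abs=1e-12)

    def test_total_loss_weighting(self):
        lb = total_loss(1.0, 2.0, 0.2)
        assert lb.L_total == pytest.approx(1.4, abs=1e-15)
        assert total_loss(1.5, 3.0, 0.0).L_total == 1.5
        assert total_loss(1.5, 3.0, 1.0).L_total == 4.5
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.5)


class TestBruteForceOracleSelfChecks:
    def test_degenerate_single_positive(self, rng):
        Z = _unit_rows(rng, 4, 3)
        mask = build_pair_mask(np.array([0, 0, 1, 2]), np.array([1, 2, 1, 2]),
                               None, "activity_user_hard")
        assert supcon_loss(Z, mask, 0.2) == pytest.approx(
            brute_force_supcon(Z, mask, 0.2), abs=1e-8)

    def test_identical_embeddings(self):
        Z = np.tile([[0.0, 1.0]], (6, 1))
        mask = build_pair_mask(np.array([0, 0, 0, 1, 1, 1]),
                               np.array([1, 2, 3, 1, 2, 3]),
                               None, "activity")
        assert supcon_loss(Z, mask, 0.1) == pytest.approx(
            brute_force_supcon(Z, mask, 0.1), abs=1e-8)
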