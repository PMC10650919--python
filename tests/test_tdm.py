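"""Loss algebra for distribution matching: hand values, simplex contracts, gradients."""

import numpy as np
import pytest

from doapred import autodiff as ad
from doapred import tdm


class TestInitImportance:
    def test_uniform(self):
        np.testing.assert_allclose(tdm.init_importance(4), [0.25] * 4)
        np.testing.assert_allclose(tdm.init_importance(1), [1.0])

    @pytest.mark.parametrize("v", [1, 3, 120])
    def test_sums_to_one(self, v):
        assert tdm.init_importance(v).sum() == pytest.approx(1.0)

    def test_invalid_v(self):
        with pytest.raises(ValueError):
            tdm.init_importance(0)


class TestImportanceNet:
    def test_zero_weights_uniform(self):
        rng = np.random.default_rng(0)
        h_i = ad.tensor(rng.normal(size=(6, 4)))
        h_j = ad.tensor(rng.normal(size=(6, 4)))
        alpha = tdm.importance_net(h_i, h_j, tdm.init_importance_net(4))
        np.testing.assert_allclose(alpha.data, 1 / 6, atol=1e-15)

    def test_simplex_contract_random_draws(self):
        rng = np.random.default_rng(1)
        params = tdm.init_importance_net(5)
        params["W"].data[:] = rng.normal(size=(10, 1))
        for _ in range(100):
            h_i = ad.tensor(rng.normal(size=(8, 5)))
            h_j = ad.tensor(rng.normal(size=(8, 5)))
            a = tdm.importance_net(h_i, h_j, params).data
            assert np.all(a >= 0) and a.sum() == pytest.approx(1.0)

    def test_hand_softmax(self):
        # logits (0, ln 3) -> (0.25, 0.75)
        logits = ad.tensor([0.0, np.log(3.0)])
        np.testing.assert_allclose(ad.softmax(logits, axis=0).data, [0.25, 0.75])

    def test_dimension_mismatch(self):
        h = ad.tensor(np.ones((4, 3)))
        with pytest.raises(ValueError, match="weight"):
            tdm.importance_net(h, h, tdm.init_importance_net(5))

    def test_differentiable_in_weights(self):
        rng = np.random.default_rng(2)
        params = tdm.init_importance_net(4, seed=0)
        params["W"].data[:] = rng.normal(size=(8, 1)) * 0.1
        h_i = ad.tensor(rng.normal(size=(5, 4)))
        h_j = ad.tensor(rng.normal(size=(5, 4)))
        alpha = tdm.importance_net(h_i, h_j, params)
        loss = (alpha * ad.tensor(rng.normal(size=5))).sum()
        ad.backward(loss)
        assert np.abs(params["W"].grad).max() > 0


class TestPairLoss:
    def test_identical_states_zero(self):
        h = ad.tensor(np.random.default_rng(0).normal(size=(5, 3)))
        val = tdm.tdm_pair_loss(h, h, tdm.init_importance(5))
        assert val.item() == pytest.approx(0.0, abs=1e-9)

    def test_zero_alpha_zero_loss(self):
        rng = np.random.default_rng(1)
        h_i, h_j = ad.tensor(rng.normal(size=(4, 3))), ad.tensor(rng.normal(size=(4, 3)))
        assert tdm.tdm_pair_loss(h_i, h_j, np.zeros(4)).item() == 0.0

    def test_weighted_sum_by_hand(self):
        # states with cosine distances 0.2 and 0.4, alpha (0.5, 0.5) -> 0.3
        def vec_with_distance(d):
            # unit vectors at angle arccos(1-d)
            ang = np.arccos(1 - d)
            return np.array([np.cos(ang), np.sin(ang)])

        h_i = ad.tensor(np.array([[1.0, 0.0], [1.0, 0.0]]))
        h_j = ad.tensor(np.stack([vec_with_distance(0.2), vec_with_distance(0.4)]))
        val = tdm.tdm_pair_loss(h_i, h_j, np.array([0.5, 0.5]))
        assert val.item() == pytest.approx(0.3, abs=1e-9)

    def test_v_mismatch(self):
        with pytest.raises(ValueError):
            tdm.tdm_pair_loss(ad.tensor(np.ones((3, 2))), ad.tensor(np.ones((4, 2))),
                              np.ones(3) / 3)


class TestPredLoss:
    def test_perfect_predictions_zero(self):
        batches = [(ad.tensor([40.0, 50.0]), np.array([40.0, 50.0]))]
        assert tdm.pred_loss(batches).item() == 0.0

    def test_single_sample_hand_value(self):
        batches = [(ad.tensor([42.0]), np.array([40.0]))]
        assert tdm.pred_loss(batches).item() == pytest.approx(4.0)

    def test_mean_of_equal_period_mses(self):
        batches = [(ad.tensor([1.0, 3.0]), np.array([0.0, 2.0]))] * 5  # each MSE 1
        assert tdm.pred_loss(batches).item() == pytest.approx(1.0)

    def test_periods_weighted_equally(self):
        # one period with MSE 0 (many samples), one with MSE 8 (one sample) -> 4
        batches = [
            (ad.tensor(np.zeros(100)), np.zeros(100)),
            (ad.tensor([np.sqrt(8.0)]), np.array([0.0])),
        ]
        assert tdm.pred_loss(batches).item() == pytest.approx(4.0)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            tdm.pred_loss([(ad.tensor([1.0]), np.array([]))])


class TestCombinedLoss:
    def test_lambda_zero_is_pred_loss(self):
        lp = ad.tensor(1.7)
        pairs = [ad.tensor(9.0)]
        assert tdm.combined_loss(lp, pairs, 0.0, 2).item() == pytest.approx(1.7)

    def test_k2_single_pair(self):
        lp = ad.tensor(1.0)
        out = tdm.combined_loss(lp, [ad.tensor(0.4)], 0.5, 2)
        assert out.item() == pytest.approx(1.0 + 0.5 * 0.4)

    def test_zero_pairs_reduce_to_pred(self):
        lp = ad.tensor(2.0)
        pairs = [ad.tensor(0.0)] * 3
        assert tdm.combined_loss(lp, pairs, 0.05, 3).item() == pytest.approx(2.0)

    def test_pair_count_mismatch(self):
        with pytest.raises(ValueError, match="pair"):
            tdm.combined_loss(ad.tensor(1.0), [ad.tensor(1.0)], 0.1, 3)

    def test_monotone_in_pair_losses_and_lambda(self):
        lp = ad.tensor(1.0)
        low = tdm.combined_loss(lp, [ad.tensor(0.1)], 0.5, 2).item()
        high = tdm.combined_loss(lp, [ad.tensor(0.2)], 0.5, 2).item()
        higher_lam = tdm.combined_loss(lp, [ad.tensor(0.2)], 1.0, 2).item()
        assert low < high < higher_lam


class TestBoosting:
    def test_unchanged_distances_keep_alpha(self):
        a = np.array([0.2, 0.3, 0.5])
        d = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(tdm.boosting_importance_update(a, d, d), a)

    def test_growing_state_gains_weight(self):
        a = tdm.init_importance(3)
        d0 = np.array([1.0, 1.0, 1.0])
        d1 = np.array([1.0, 2.0, 1.0])
        out = tdm.boosting_importance_update(a, d1, d0)
        assert out[1] > a[1]
        assert out.sum() == pytest.approx(1.0)

    def test_uniform_doubling_stays_uniform(self):
        a = tdm.init_importance(4)
        d0 = np.full(4, 0.5)
        out = tdm.boosting_importance_update(a, 2 * d0, d0)
        np.testing.assert_allclose(out, a)

    def test_v_mismatch(self):
        with pytest.raises(ValueError):
            tdm.boosting_importance_update(np.ones(3) / 3, np.ones(2), np.ones(2))


def test_minimizing_pair_loss_reduces_distance():
    """Gradient steps on the TDM pair loss shrink a planted mean shift."""
    rng = np.random.default_rng(3)
    base = rng.normal(size=(6, 4))
    shift = ad.tensor(rng.normal(size=(6, 4)) * 2.0, requires_grad=True)
    h_i = ad.tensor(base)
    alpha = tdm.init_importance(6)
    before = tdm.tdm_pair_loss(h_i, h_i + shift, alpha).item()
    for _ in range(200):
        shift.grad = None
        loss = tdm.tdm_pair_loss(h_i, h_i + shift, alpha)
        ad.backward(loss)
        shift.data -= 0.5 * shift.grad
    after = tdm.tdm_pair_loss(h_i, h_i + shift, alpha).item()
    assert after < before * 0.5
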