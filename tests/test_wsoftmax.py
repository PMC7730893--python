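"""w-softmax loss: reduction to softmax at gamma=0, biased-weight geometry,
probability normalisation, closed-form cases and gradient correctness."""

import numpy as np
import pytest

from plumvision.wsoftmax import (
    ClassifierWeights,
    WSoftmaxLoss,
    bias_negative_weights,
    normalize_rows,
    softmax_cross_entropy,
    wsoftmax_loss,
    wsoftmax_probabilities,
)


class TestBiasNegativeWeights:
    def test_gamma_zero_leaves_weights_unchanged(self, rng):
        W = normalize_rows(rng.normal(size=(5, 8)))
        Wb = bias_negative_weights(ClassifierWeights(W, c=2, gamma=0.0))
        assert np.allclose(Wb, W, atol=1e-12)

    def test_two_dimensional_hand_example(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        Wb = bias_negative_weights(ClassifierWeights(W, c=0, gamma=1.0))
        assert np.allclose(Wb[0], [1.0, 0.0], atol=1e-15)
        assert np.allclose(Wb[1], [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)

    def test_large_gamma_collapses_onto_positive_weight(self, rng):
        W = normalize_rows(rng.normal(size=(4, 6)))
        Wb = bias_negative_weights(ClassifierWeights(W, c=1, gamma=1e6))
        for i in range(4):
            assert Wb[i] @ W[1] > 1 - 1e-6

    def test_all_biased_rows_unit_norm(self, rng):
        for _ in range(20):
            W = normalize_rows(rng.normal(size=(5, 16)))
            gamma = rng.uniform(0, 5)
            Wb = bias_negative_weights(ClassifierWeights(W, c=0, gamma=gamma))
            assert np.allclose(np.linalg.norm(Wb, axis=1), 1.0, atol=1e-12)

    def test_antipodal_degeneracy_raises(self):
        W = np.array([[1.0, 0.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            bias_negative_weights(ClassifierWeights(W, c=0, gamma=1.0))

    def test_unnormalised_input_rejected(self):
        W = np.array([[2.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            bias_negative_weights(ClassifierWeights(W, c=0, gamma=1.0))


class TestProbabilities:
    def test_zero_feature_gives_uniform(self, rng):
        W = normalize_rows(rng.normal(size=(5, 7)))
        p = wsoftmax_probabilities(np.zeros(7), ClassifierWeights(W, 1, 0.8))
        assert np.allclose(p, 0.2, atol=1e-12)

    def test_gamma_zero_equals_plain_softmax(self, rng):
        W = normalize_rows(rng.normal(size=(5, 7)))
        x = rng.normal(size=7)
        p = wsoftmax_probabilities(x, ClassifierWeights(W, 3, 0.0))
        z = W @ x
        ref = np.exp(z) / np.exp(z).sum()
        assert np.allclose(p, ref, atol=1e-12)

    def test_matches_direct_exponentiation_oracle(self, rng):
        W = normalize_rows(rng.normal(size=(3, 2)))
        x = rng.normal(size=2)
        c, gamma = 1, 0.7
        p = wsoftmax_probabilities(x, ClassifierWeights(W, c, gamma))
        # oracle: evaluate the biased weights and the softmax by hand
        logits = np.empty(3)
        for j in range(3):
            if j == c:
                logits[j] = W[c] @ x
            else:
                b = gamma * W[c] + W[j]
                logits[j] = (b / np.linalg.norm(b)) @ x
        ref = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(p, ref, atol=1e-10)

    def test_probabilities_normalise_over_many_draws(self, rng):
        for _ in range(1000):
            C, d = int(rng.integers(2, 7)), int(rng.integers(2, 10))
            W = normalize_rows(rng.normal(size=(C, d)))
            x = rng.normal(size=d) * rng.uniform(0.1, 10)
            p = wsoftmax_probabilities(
                x, ClassifierWeights(W, int(rng.integers(C)), rng.uniform(0, 3)))
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p > 0) and np.all(p < 1)

    def test_non_finite_feature_rejected(self, rng):
        W = normalize_rows(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            wsoftmax_probabilities(np.array([np.nan, 0, 0]),
                                   ClassifierWeights(W, 0, 1.0))


class TestLoss:
    def test_gamma_zero_equals_cross_entropy_loss_and_gradients(self, rng):
        C, d, n = 5, 12, 16
        V = normalize_rows(rng.normal(size=(C, d)))
        X = rng.normal(size=(n, d))
        y = rng.integers(0, C, n)
        wl = WSoftmaxLoss(0.0)
        l1 = wl.forward(X, y, V)
        dX1, dW1 = wl.backward()
        l2, dX2, dW2 = softmax_cross_entropy(X, y, V)
        # the raw-weight gradient of the normalised loss is the tangential
        # projection of the plain cross-entropy weight gradient
        dW2p = dW2 - (dW2 * V).sum(axis=1, keepdims=True) * V
        assert abs(l1 - l2) < 1e-8
        assert np.abs(dX1 - dX2).max() < 1e-8
        assert np.abs(dW1 - dW2p).max() < 1e-8

    def test_closed_form_two_class_example(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        x = np.array([[1.0, 0.0]])
        loss = wsoftmax_loss(x, [0], W, 0.0)
        assert abs(loss - np.log(1 + np.exp(-1))) < 1e-12

    def test_bias_increases_loss_on_correct_samples(self, rng):
        """For correctly oriented samples, gamma=1 never lowers the loss."""
        C, d = 5, 8
        count = 0
        while count < 1000:
            V = normalize_rows(rng.normal(size=(C, d)))
            X = rng.normal(size=(20, d))
            z = X @ V.T
            y = z.argmax(axis=1)       # correctly oriented by construction
            l0 = wsoftmax_loss(X, y, V, 0.0)
            l1 = wsoftmax_loss(X, y, V, 1.0)
            assert l1 >= l0 - 1e-12
            count += len(X)

    def test_out_of_range_label_rejected(self, rng):
        V = normalize_rows(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            wsoftmax_loss(rng.normal(size=(2, 4)), [0, 3], V, 1.0)

    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    def test_finite_difference_gradients(self, gamma, rng):
        C, d, n = 4, 6, 5
        V = rng.normal(size=(C, d))
        X = rng.normal(size=(n, d))
        y = rng.integers(0, C, n)
        wl = WSoftmaxLoss(gamma)
        wl.forward(X, y, V)
        dX, dW = wl.backward()
        eps = 1e-6
        for arr, grad in ((X, dX), (V, dW)):
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp = wsoftmax_loss(X, y, V, gamma)
                arr[i] = old - eps
                lm = wsoftmax_loss(X, y, V, gamma)
                arr[i] = old
                num[i] = (lp - lm) / (2 * eps)
            rel = np.abs(grad - num).max() / max(np.abs(num).max(), 1e-12)
            assert rel < 1e-4
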