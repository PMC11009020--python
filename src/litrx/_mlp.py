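"""A compact feed-forward neural-network regressor for bounded targets.

Architecture and training schedule: stacked fully connected layers with
ReLU activations and inverted dropout after each hidden layer, a sigmoid
output unit (predictions confined to (0,1), matching AAC), mean-squared
error loss, and plain SGD with momentum.  Training runs a fixed number of
epochs and is restarted several times from fresh initializations; the
restart with the best validation loss is kept.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


class MLPRegressorSGD(BaseEstimator, RegressorMixin):
    """Sigmoid-output MLP trained with momentum SGD.

    Parameters
    ----------
    hidden_layer_sizes : widths of the hidden layers.
    learning_rate, momentum : SGD schedule (constant rate).
    dropout : drop probability after each hidden layer.
    epochs : passes over the training data per restart.
    restarts : independent initializations; best validation MSE wins.
    val_fraction : share of the training data held out for restart choice.
    """

    def __init__(
        self,
        hidden_layer_sizes=(256, 64),
        learning_rate=0.01,
        momentum=0.9,
        dropout=0.2,
        epochs=15,
        restarts=6,
        batch_size=32,
        val_fraction=0.2,
        random_state=0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout = dropout
        self.epochs = epochs
        self.restarts = restarts
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _init_weights(self, rng, n_in):
        sizes = [n_in, *self.hidden_layer_sizes, 1]
        weights, biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            weights.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            biases.append(np.zeros(b))
        return weights, biases

    def _forward(self, x, weights, biases, rng=None):
        """Returns activations per layer; applies dropout when rng given."""
        acts = [x]
        h = x
        for li in range(len(weights) - 1):
            h = np.maximum(h @ weights[li] + biases[li], 0.0)
            if rng is not None and self.dropout > 0:
                keep = rng.random(h.shape) >= self.dropout
                h = h * keep / (1.0 - self.dropout)
            acts.append(h)
        z = h @ weights[-1] + biases[-1]
        out = 1.0 / (1.0 + np.exp(-z))
        acts.append(out)
        return acts

    def _train_once(self, x, y, rng):
        n, d = x.shape
        weights, biases = self._init_weights(rng, d)
        vel_w = [np.zeros_like(w) for w in weights]
        vel_b = [np.zeros_like(b) for b in biases]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                acts = self._forward(xb, weights, biases, rng=rng)
                out = acts[-1][:, 0]
                # MSE through the sigmoid output
                delta = ((out - yb) * out * (1.0 - out) * 2.0 / len(idx))[:, None]
                grads_w, grads_b = [None] * len(weights), [None] * len(weights)
                for li in range(len(weights) - 1, -1, -1):
                    grads_w[li] = acts[li].T @ delta
                    grads_b[li] = delta.sum(axis=0)
                    if li > 0:
                        delta = (delta @ weights[li].T) * (acts[li] > 0)
                for li in range(len(weights)):
                    vel_w[li] = self.momentum * vel_w[li] - self.learning_rate * grads_w[li]
                    vel_b[li] = self.momentum * vel_b[li] - self.learning_rate * grads_b[li]
                    weights[li] += vel_w[li]
                    biases[li] += vel_b[li]
        return weights, biases

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        n_val = max(1, int(self.val_fraction * n)) if n > 4 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx = perm
        best_loss = np.inf
        for _ in range(self.restarts):
            weights, biases = self._train_once(x[tr_idx], y[tr_idx], rng)
            eval_idx = val_idx if n_val else tr_idx
            pred = self._forward(x[eval_idx], weights, biases)[-1][:, 0]
            loss = float(np.mean((pred - y[eval_idx]) ** 2))
            if loss < best_loss:
                best_loss = loss
                self.weights_, self.biases_ = weights, biases
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        return self._forward(x, self.weights_, self.biases_)[-1][:, 0]
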