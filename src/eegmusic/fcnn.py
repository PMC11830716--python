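"""Fully connected neural network (MLP) classifier, implemented directly.

Architecture as used for the emotion-classification task: 5 LDA inputs,
five hidden layers of 512/1024/512/512/256 units, 6-way softmax output.
Forward pass per layer: ``z = W a + b``, ``a = sigma(z)``; training
minimises cross-entropy (mean-squared error available) with Adam on
shuffled mini-batches.  Per-epoch accuracy on an evaluation set is
recorded and the best-epoch parameters are retained alongside the
final-epoch ones, since held-out accuracy peaks mid-training on this
task.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

HIDDEN_DEFAULT = (512, 1024, 512, 512, 256)


def _one_hot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    T = np.zeros((y_idx.size, n_classes))
    T[np.arange(y_idx.size), y_idx] = 1.0
    return T


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


class FCNNClassifier(ClassifierMixin, BaseEstimator):
    """Multilayer perceptron with softmax output, trained with Adam.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden-layer widths (default 512, 1024, 512, 512, 256).
    activation : {"relu", "sigmoid"}
    loss : {"cross_entropy", "mse"}
    epochs, batch_size, lr : training-loop parameters (50 / 32 / 1e-3).
    use_best_epoch : bool
        Predict with the parameters from the epoch of highest
        evaluation accuracy (falls back to final epoch when no
        evaluation set was given).
    random_state : int
        Seeds initialisation and batch shuffling; same seed, same run.
    """

    def __init__(self, hidden_layer_sizes: tuple[int, ...] = HIDDEN_DEFAULT,
                 activation: str = "relu", loss: str = "cross_entropy",
                 epochs: int = 50, batch_size: int = 32, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 use_best_epoch: bool = True, random_state: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.loss = loss
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.use_best_epoch = use_best_epoch
        self.random_state = random_state

    # -- forward machinery -------------------------------------------------
    def _act(self, Z):
        if self.activation == "relu":
            return np.maximum(Z, 0.0)
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-Z))
        raise ValueError(f"unknown activation {self.activation!r}")

    def _act_grad(self, Z, A):
        if self.activation == "relu":
            return (Z > 0).astype(float)
        return A * (1.0 - A)

    def _forward(self, X, weights, biases):
        """Returns (probabilities, per-layer pre-activations, activations)."""
        A = X
        Zs, As = [], [A]
        for li, (W, b) in enumerate(zip(weights, biases)):
            Z = A @ W.T + b
            Zs.append(Z)
            A = _softmax(Z) if li == len(weights) - 1 else self._act(Z)
            As.append(A)
        return A, Zs, As

    # -- training ----------------------------------------------------------
    def fit(self, X, y, eval_set: tuple | None = None):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes in the training set")
        n, d = X.shape
        c = len(self.classes_)
        dims = [d, *self.hidden_layer_sizes, c]
        rng = np.random.default_rng(self.random_state)

        # He-style initialisation
        weights = [rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i + 1], dims[i]))
                   for i in range(len(dims) - 1)]
        biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        mW = [np.zeros_like(w) for w in weights]
        vW = [np.zeros_like(w) for w in weights]
        mb = [np.zeros_like(b) for b in biases]
        vb = [np.zeros_like(b) for b in biases]

        T = _one_hot(y_idx, c)
        if eval_set is not None:
            Xev = check_array(eval_set[0], dtype=float)
            yev = np.asarray(eval_set[1])

        self.history_ = []
        best_acc, best_params, best_epoch = -np.inf, None, None
        step = 0
        for epoch in range(1, self.epochs + 1):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                Xb, Tb = X[idx], T[idx]
                P, Zs, As = self._forward(Xb, weights, biases)
                if self.loss == "cross_entropy":
                    dZ = (P - Tb) / len(idx)
                elif self.loss == "mse":
                    G = 2.0 * (P - Tb) / (len(idx) * c)
                    dZ = P * (G - np.sum(G * P, axis=1, keepdims=True))
                else:
                    raise ValueError(f"unknown loss {self.loss!r}")
                step += 1
                for li in range(len(weights) - 1, -1, -1):
                    gW = dZ.T @ As[li]
                    gb = dZ.sum(axis=0)
                    if li > 0:
                        dA = dZ @ weights[li]
                        dZ = dA * self._act_grad(Zs[li - 1], As[li])
                    # Adam update
                    mW[li] = self.beta1 * mW[li] + (1 - self.beta1) * gW
                    vW[li] = self.beta2 * vW[li] + (1 - self.beta2) * gW**2
                    mb[li] = self.beta1 * mb[li] + (1 - self.beta1) * gb
                    vb[li] = self.beta2 * vb[li] + (1 - self.beta2) * gb**2
                    bc1 = 1 - self.beta1**step
                    bc2 = 1 - self.beta2**step
                    weights[li] -= self.lr * (mW[li] / bc1) / (np.sqrt(vW[li] / bc2) + self.eps)
                    biases[li] -= self.lr * (mb[li] / bc1) / (np.sqrt(vb[li] / bc2) + self.eps)

            record = {"epoch": epoch}
            P, _, _ = self._forward(X, weights, biases)
            record["train_loss"] = float(-np.mean(np.sum(T * np.log(P + 1e-12), axis=1)))
            record["train_accuracy"] = float(
                np.mean(self.classes_[P.argmax(axis=1)] == y)
            )
            if eval_set is not None:
                Pe, _, _ = self._forward(Xev, weights, biases)
                acc = float(np.mean(self.classes_[Pe.argmax(axis=1)] == yev))
                record["eval_accuracy"] = acc
                if acc > best_acc:
                    best_acc = acc
                    best_epoch = epoch
                    best_params = ([w.copy() for w in weights],
                                   [b.copy() for b in biases])
            self.history_.append(record)

        self.final_weights_ = weights
        self.final_biases_ = biases
        if best_params is not None:
            self.best_epoch_ = best_epoch
            self.best_eval_accuracy_ = best_acc
            bw, bb = best_params
        else:
            self.best_epoch_ = self.epochs
            bw, bb = weights, biases
        if self.use_best_epoch:
            self.weights_, self.biases_ = bw, bb
        else:
            self.weights_, self.biases_ = weights, biases
        self.n_features_in_ = d
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        P, _, _ = self._forward(X, self.weights_, self.biases_)
        return P

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def forward(model: FCNNClassifier, x: np.ndarray) -> np.ndarray:
    """Class probabilities for a single input vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return model.predict_proba(x[None, :])[0]
    return model.predict_proba(x)


def train(model: FCNNClassifier, X_train, y_train, X_eval=None, y_eval=None):
    """Fit with optional per-epoch evaluation; returns the fitted model."""
    eval_set = (X_eval, y_eval) if X_eval is not None else None
    return model.fit(X_train, y_train, eval_set=eval_set)
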