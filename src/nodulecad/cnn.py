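"""Small convolutional network for 3-class nodule attenuation patches.

The network is deliberately tiny -- two convolutional layers (5x5 kernels,
stride 2, 6 and 16 feature maps), each followed by 2x2 stride-2 max
pooling, one hidden fully-connected layer of 84 units, and a 3-way softmax
-- because the task is patch-level texture discrimination, not object
recognition, and the training sets are a few thousand ROIs.  Training is
plain mini-batch SGD on the softmax cross-entropy with the learning rate
held constant at 0.05 throughout.

The forward/backward passes are written directly in numpy (im2col
convolutions, bincount scatter for the convolution input gradient), which
is ample for this architecture on a CPU and keeps the package free of a
deep-learning framework dependency.  Penultimate-layer activations are
exposed for the downstream random-forest score regression.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["SmallCNNClassifier", "build_model", "train"]

_DTYPE = np.float32


def _conv_out_side(side: int, kernel: int, stride: int) -> int:
    return (side - kernel) // stride + 1


def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*K*K, OH*OW) patch matrix."""
    windows = sliding_window_view(x, (kernel, kernel), axis=(2, 3))[
        :, :, ::stride, ::stride
    ]
    b, c, oh, ow = windows.shape[:4]
    return (
        windows.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kernel * kernel, oh * ow),
        (oh, ow),
    )


def _col_indices(c: int, h: int, w: int, kernel: int, stride: int) -> np.ndarray:
    """Flat target index in (C, H, W) for every im2col entry."""
    oh = _conv_out_side(h, kernel, stride)
    ow = _conv_out_side(w, kernel, stride)
    ci, ki, kj = np.meshgrid(
        np.arange(c), np.arange(kernel), np.arange(kernel), indexing="ij"
    )
    oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
    base = (oi * stride).ravel()[None, :] * w + (oj * stride).ravel()[None, :]
    per_tap = (ci.ravel() * h * w + ki.ravel() * w + kj.ravel())[:, None]
    return per_tap + base  # (C*K*K, OH*OW)


class SmallCNNClassifier(BaseEstimator, ClassifierMixin):
    """Patch classifier with fit / predict_proba / extract_features.

    Parameters
    ----------
    input_size : int
        Side of the square [0, 1] input patch.
    conv1_maps, conv2_maps : int
        Feature maps of the two convolutional layers.
    kernel_size, conv_stride : int
        Convolution geometry (5x5, stride 2).
    pool_size, pool_stride : int
        Max-pooling geometry (2x2, stride 2).
    fc_hidden : int
        Width of the hidden fully-connected layer; its post-ReLU
        activations are the feature vector for the regression head.
    learning_rate : float
        SGD step size, constant across all epochs.
    epochs, patience, min_delta, val_fraction :
        Training length and early stopping on validation loss; with
        ``patience=0`` all epochs run.  If no validation set is supplied
        to :meth:`fit`, ``val_fraction`` of the training data is held out.
    random_state : int
        Seeds initialisation, the internal validation split and the
        per-epoch mini-batch shuffles; identical seeds give identical
        fitted parameters.
    """

    def __init__(
        self,
        input_size: int = 64,
        conv1_maps: int = 6,
        conv2_maps: int = 16,
        kernel_size: int = 5,
        conv_stride: int = 2,
        pool_size: int = 2,
        pool_stride: int = 2,
        fc_hidden: int = 84,
        n_classes: int = 3,
        learning_rate: float = 0.05,
        batch_size: int = 32,
        epochs: int = 100,
        patience: int = 10,
        min_delta: float = 1e-4,
        val_fraction: float = 0.1,
        grad_clip: float | None = 5.0,
        label_smoothing: float = 0.0,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.conv1_maps = conv1_maps
        self.conv2_maps = conv2_maps
        self.kernel_size = kernel_size
        self.conv_stride = conv_stride
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.fc_hidden = fc_hidden
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.min_delta = min_delta
        self.val_fraction = val_fraction
        self.grad_clip = grad_clip
        self.label_smoothing = label_smoothing
        self.random_state = random_state

    # -- architecture -----------------------------------------------------

    def layer_output_sides(self) -> dict[str, int]:
        """Spatial side of every layer output; raises if the chain breaks.

        With the default 64x64 input: conv1 30, pool1 15, conv2 6, pool2 3,
        flattened width 16 * 3 * 3 = 144.
        """
        s1 = _conv_out_side(self.input_size, self.kernel_size, self.conv_stride)
        p1 = _conv_out_side(s1, self.pool_size, self.pool_stride)
        s2 = _conv_out_side(p1, self.kernel_size, self.conv_stride)
        p2 = _conv_out_side(s2, self.pool_size, self.pool_stride)
        sides = {"conv1": s1, "pool1": p1, "conv2": s2, "pool2": p2}
        if min(sides.values()) < 1:
            raise ValueError(
                f"input size {self.input_size} incompatible with stride chain; "
                f"layer sides would be {sides}"
            )
        sides["flat"] = self.conv2_maps * p2 * p2
        return sides

    def learning_rate_at(self, epoch: int) -> float:
        """The lr schedule is constant: every epoch trains at the base rate."""
        return self.learning_rate

    # -- parameters -------------------------------------------------------

    def initialize(self, random_state: int | None = None) -> "SmallCNNClassifier":
        """Draw initial weights (Gaussian, scaled by fan-in) deterministically."""
        sides = self.layer_output_sides()
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        k = self.kernel_size

        def gauss(shape, fan_in):
            # He scaling: keeps activation variance stable through ReLUs
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DTYPE)

        self.params_ = {
            "W1": gauss((self.conv1_maps, k * k), k * k),
            "b1": np.zeros(self.conv1_maps, dtype=_DTYPE),
            "W2": gauss((self.conv2_maps, self.conv1_maps * k * k), self.conv1_maps * k * k),
            "b2": np.zeros(self.conv2_maps, dtype=_DTYPE),
            "W3": gauss((self.fc_hidden, sides["flat"]), sides["flat"]),
            "b3": np.zeros(self.fc_hidden, dtype=_DTYPE),
            "W4": gauss((self.n_classes, self.fc_hidden), self.fc_hidden),
            "b4": np.zeros(self.n_classes, dtype=_DTYPE),
        }
        self._sides = sides
        return self

    # -- forward / backward ----------------------------------------------

    @staticmethod
    def _check_normalized(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must be (n_patches, side, side)")
        if X.size and (X.min() < -1e-6 or X.max() > 1 + 1e-6):
            raise ValueError("patches must be normalized to [0, 1]")
        return X.astype(_DTYPE)

    def _pool(self, x: np.ndarray):
        b, c, h, w = x.shape
        p = self.pool_size
        oh, ow = h // p, w // p
        windows = x[:, :, : oh * p, : ow * p].reshape(b, c, oh, p, ow, p)
        flat = windows.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, oh, ow, p * p)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return out, (arg, (b, c, h, w))

    def _pool_backward(self, dout: np.ndarray, cache) -> np.ndarray:
        arg, (b, c, h, w) = cache
        p = self.pool_size
        oh, ow = dout.shape[2], dout.shape[3]
        flat = np.zeros((b, c, oh, ow, p * p), dtype=_DTYPE)
        np.put_along_axis(flat, arg[..., None], dout[..., None], axis=-1)
        windows = flat.reshape(b, c, oh, ow, p, p).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((b, c, h, w), dtype=_DTYPE)
        dx[:, :, : oh * p, : ow * p] = windows.reshape(b, c, oh * p, ow * p)
        return dx

    def _conv_forward(self, x: np.ndarray, W: np.ndarray, bias: np.ndarray):
        cols, (oh, ow) = _im2col(x, self.kernel_size, self.conv_stride)
        out = np.matmul(W, cols).reshape(x.shape[0], -1, oh, ow)
        out += bias[None, :, None, None]
        return out, (cols, x.shape)

    def _conv_backward(self, dout: np.ndarray, W: np.ndarray, cache, need_dx=True):
        cols, x_shape = cache
        b, f = dout.shape[:2]
        dflat = dout.reshape(b, f, -1)
        dW = np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0)
        db = dflat.sum(axis=(0, 2))
        if not need_dx:
            return None, dW, db
        dcols = np.matmul(W.T, dflat)
        _, c, h, w = x_shape
        key = (c, h, w)
        idx = self._idx_cache.get(key)
        if idx is None:
            idx = _col_indices(c, h, w, self.kernel_size, self.conv_stride)
            self._idx_cache[key] = idx
        full = (np.arange(b)[:, None, None] * (c * h * w) + idx).ravel()
        dx = np.bincount(
            full, weights=dcols.ravel(), minlength=b * c * h * w
        ).reshape(b, c, h, w).astype(_DTYPE)
        return dx, dW, db

    def _forward(self, X: np.ndarray, need_cache: bool = True):
        P = self.params_
        x = X[:, None, :, :]
        z1, c1 = self._conv_forward(x, P["W1"], P["b1"])
        a1 = np.maximum(z1, 0)
        q1, pc1 = self._pool(a1)
        z2, c2 = self._conv_forward(q1, P["W2"], P["b2"])
        a2 = np.maximum(z2, 0)
        q2, pc2 = self._pool(a2)
        flat = q2.reshape(X.shape[0], -1)
        z3 = flat @ P["W3"].T + P["b3"]
        h = np.maximum(z3, 0)
        logits = h @ P["W4"].T + P["b4"]
        cache = (x, z1, c1, pc1, q1, z2, c2, pc2, q2, flat, z3, h) if need_cache else None
        return logits, h, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache) -> dict:
        P = self.params_
        (x, z1, c1, pc1, q1, z2, c2, pc2, q2, flat, z3, h) = cache
        b = probs.shape[0]
        dlogits = (probs - y_onehot).astype(_DTYPE) / b
        grads = {}
        grads["W4"] = dlogits.T @ h
        grads["b4"] = dlogits.sum(axis=0)
        dh = dlogits @ P["W4"]
        dz3 = dh * (z3 > 0)
        grads["W3"] = dz3.T @ flat
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ P["W3"]
        dq2 = dflat.reshape(q2.shape)
        da2 = self._pool_backward(dq2, pc2)
        dz2 = da2 * (z2 > 0)
        dq1, grads["W2"], grads["b2"] = self._conv_backward(dz2, P["W2"], c2)
        da1 = self._pool_backward(dq1, pc1)
        dz1 = da1 * (z1 > 0)
        # the input gradient of the first convolution is never used
        _, grads["W1"], grads["b1"] = self._conv_backward(
            dz1, P["W1"], c1, need_dx=False
        )
        return grads

    def _proba_internal(self, X: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(X), 256):
            logits, _, _ = self._forward(X[start : start + 256], need_cache=False)
            out.append(self._softmax(logits))
        return np.concatenate(out)

    def _batch_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self._proba_internal(X)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # -- scikit-learn surface ---------------------------------------------

    def fit(self, X, y, validation_data=None, val_groups=None):
        """Train by SGD at the fixed base learning rate.

        ``validation_data=(X_val, y_val)`` supplies the early-stopping set
        explicitly (used by the cross-validation driver, whose validation
        folds are nodule-disjoint); otherwise ``val_fraction`` of the
        patches is held out.

        ``val_groups`` optionally assigns each validation patch to a
        nodule id.  When given, checkpoint selection and early stopping
        use the *nodule-level* validation accuracy under softmax-average
        consensus (ties broken by the mean consensus probability of the
        true class, a smooth sharpness signal) instead of the patch-level
        loss — the quantity the deployed model is judged on.
        Patch-level validation loss rewards maximally uncertain outputs
        on the many intrinsically ambiguous peripheral slices and is a
        poor proxy for consensus behaviour.
        """
        X = self._check_normalized(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        present = np.unique(y)
        if not np.all(np.isin(present, np.arange(self.n_classes))):
            raise ValueError("labels must be integers in [0, n_classes)")
        if present.size < self.n_classes:
            raise ValueError("need at least one sample of every class")
        self.classes_ = np.arange(self.n_classes)

        self.initialize()
        self._idx_cache: dict = {}
        rng = np.random.default_rng(self.random_state)

        group_index = group_labels = None
        if validation_data is not None:
            X_val = self._check_normalized(validation_data[0])
            y_val = np.asarray(validation_data[1], dtype=int)
            if val_groups is not None:
                if len(val_groups) != len(X_val):
                    raise ValueError("val_groups must map one group per patch")
                uniq = list(dict.fromkeys(val_groups))
                lookup = {g: i for i, g in enumerate(uniq)}
                group_index = np.array([lookup[g] for g in val_groups])
                group_labels = np.zeros(len(uniq), dtype=int)
                for g, lab in zip(group_index, y_val):
                    group_labels[g] = lab
        elif self.patience and self.val_fraction > 0 and len(X) >= 10:
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            val_idx, train_idx = order[:n_val], order[n_val:]
            X, y, X_val, y_val = X[train_idx], y[train_idx], X[val_idx], y[val_idx]
        else:
            X_val = y_val = None

        eps = float(self.label_smoothing)
        eye = np.eye(self.n_classes, dtype=_DTYPE)
        if eps > 0.0:
            eye = eye * (1.0 - eps) + eps / self.n_classes
        best_val = np.inf
        best_acc = -1.0
        best_params = None
        stall = 0
        self.loss_trace_: list[float] = []
        self.val_loss_trace_: list[float] = []
        self.val_consensus_trace_: list[float] = []
        n = len(X)
        for epoch in range(self.epochs):
            lr = self.learning_rate_at(epoch)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                logits, _, cache = self._forward(xb)
                probs = self._softmax(logits)
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; inspect the input "
                        "scaling or lower the learning rate"
                    )
                epoch_loss += float(loss) * len(yb)
                grads = self._backward(probs, eye[yb], cache)
                if self.grad_clip is not None:
                    # at a fixed, non-decaying step size an occasional huge
                    # mini-batch gradient can eject the weights from a good
                    # basin; global-norm clipping caps the step length
                    norm = np.sqrt(
                        sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values())
                    )
                    if norm > self.grad_clip:
                        scale = self.grad_clip / norm
                        grads = {k: g * scale for k, g in grads.items()}
                for name, g in grads.items():
                    self.params_[name] -= (lr * g).astype(_DTYPE)
            self.loss_trace_.append(epoch_loss / n)

            if X_val is not None and len(X_val):
                val_probs = self._proba_internal(X_val)
                val_loss = float(
                    -np.mean(np.log(val_probs[np.arange(len(y_val)), y_val] + 1e-12))
                )
                self.val_loss_trace_.append(val_loss)
                if group_index is not None:
                    cons = np.zeros((len(group_labels), self.n_classes))
                    np.add.at(cons, group_index, val_probs)
                    cons /= cons.sum(axis=1, keepdims=True)
                    acc = float((cons.argmax(axis=1) == group_labels).mean())
                    # sharpness: consensus probability mass on the true class
                    conf = float(
                        cons[np.arange(len(group_labels)), group_labels].mean()
                    )
                    self.val_consensus_trace_.append(acc)
                    improved = acc > best_acc or (
                        acc == best_acc and conf > best_val + self.min_delta
                    )
                    criterion = conf
                else:
                    acc = best_acc
                    improved = val_loss < best_val - self.min_delta
                    criterion = val_loss
                if improved:
                    best_val = criterion
                    best_acc = acc
                    best_params = {k: v.copy() for k, v in self.params_.items()}
                    stall = 0
                else:
                    stall += 1
                    if self.patience and stall >= self.patience:
                        break
        if best_params is not None:
            self.params_ = best_params
        self.n_epochs_run_ = len(self.loss_trace_)
        return self

    def _require_params(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model has no parameters; call fit() or initialize()")

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities on the simplex, row per patch."""
        self._require_params()
        X = self._check_normalized(X)
        out = []
        for start in range(0, len(X), 256):
            logits, _, _ = self._forward(X[start : start + 256], need_cache=False)
            out.append(self._softmax(logits))
        return np.concatenate(out).astype(np.float64)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def extract_features(self, X) -> np.ndarray:
        """Post-ReLU activations of the hidden FC layer, (n, fc_hidden)."""
        self._require_params()
        X = self._check_normalized(X)
        out = []
        for start in range(0, len(X), 256):
            _, h, _ = self._forward(X[start : start + 256], need_cache=False)
            out.append(h)
        return np.concatenate(out).astype(np.float64)


def build_model(**config) -> SmallCNNClassifier:
    """Construct (and eagerly shape-check) a classifier from config keys."""
    model = SmallCNNClassifier(**config)
    model.layer_output_sides()
    return model


def train(model: SmallCNNClassifier, X, y, validation_data=None) -> SmallCNNClassifier:
    """Thin functional wrapper over :meth:`SmallCNNClassifier.fit`."""
    return model.fit(X, y, validation_data=validation_data)
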