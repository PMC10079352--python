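"""A compact, fully deterministic numpy CNN classifier.

This is the trainable model behind the active-learning loop: a trunk of
strided 3x3 (or arbitrary-kernel) convolutions with ReLU, optional max
pooling, global average pooling into a feature vector, then a dropout +
dense softmax head.  It deliberately implements exactly the capabilities
the acquisition machinery needs:

* deterministic inference (``predict_proba``),
* dropout-active stochastic inference for MC sampling
  (``mc_predict_proba``) with one fresh dropout mask per pass, shared
  across items within a pass,
* a penultimate-feature extractor (``features``, the post-GAP activations),
* from-scratch training with Adam (``fit``), optionally with on-the-fly
  augmentation,
* weight initialization fully determined by a seed.

Convolutions use 'same' padding and im2col matrix multiplication; all
arithmetic is plain numpy, so runs are bit-reproducible on a fixed BLAS.
Inputs to the public methods are N x H x W x 3 arrays in [0, 1]; resizing to
the model's input resolution and per-patch channel standardization happen
internally.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize


def _standardize_batch(x: np.ndarray) -> np.ndarray:
    """Per-image, per-channel standardization to mean 0 / std 1 (vectorized)."""
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    out = (x - mu) / sd
    return np.where(x.std(axis=(1, 2), keepdims=True) == 0, 0.0, out)


class _Conv:
    """3x3/arbitrary-kernel convolution, 'same' padding, ReLU folded in."""

    def __init__(self, kh, kw, cin, cout, stride, rng):
        fan_in = kh * kw * cin
        self.W = (rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.kh, self.kw, self.cin, self.cout, self.stride = kh, kw, cin, cout, stride

    def out_shape(self, h, w):
        s = self.stride
        return -(-h // s), -(-w // s)

    def _cols(self, x):
        n, h, w, c = x.shape
        s = self.stride
        ho, wo = self.out_shape(h, w)
        ph = max((ho - 1) * s + self.kh - h, 0)
        pw = max((wo - 1) * s + self.kw - w, 0)
        pt, pl = ph // 2, pw // 2
        xp = np.pad(x, ((0, 0), (pt, ph - pt), (pl, pw - pl), (0, 0)))
        cols = np.empty((n, ho, wo, self.kh, self.kw, c), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, :, i, j, :] = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
        return cols, (xp.shape, pt, pl, h, w)

    def forward(self, x, store=False):
        cols, geom = self._cols(x)
        n, ho, wo = cols.shape[:3]
        z = cols.reshape(n * ho * wo, -1) @ self.W + self.b
        a = np.maximum(z, 0.0).reshape(n, ho, wo, self.cout)
        if store:
            self._cols_cache, self._geom, self._relu_mask = cols, geom, (z > 0)
        return a

    def backward(self, da):
        n, ho, wo, _ = da.shape
        dz = da.reshape(-1, self.cout) * self._relu_mask
        cols2d = self._cols_cache.reshape(n * ho * wo, -1)
        self.dW = cols2d.T @ dz
        self.db = dz.sum(axis=0)
        dcols = (dz @ self.W.T).reshape(self._cols_cache.shape)
        xp_shape, pt, pl, h, w = self._geom
        s = self.stride
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += dcols[:, :, :, i, j, :]
        self._cols_cache = None
        return dxp[:, pt:pt + h, pl:pl + w, :]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _MaxPool:
    """k x k max pooling with stride k (input padded with -inf to a multiple)."""

    def __init__(self, k):
        self.k = k

    def out_shape(self, h, w):
        return -(-h // self.k), -(-w // self.k)

    def forward(self, x, store=False):
        n, h, w, c = x.shape
        k = self.k
        ho, wo = self.out_shape(h, w)
        xp = np.full((n, ho * k, wo * k, c), -np.inf, dtype=np.float32)
        xp[:, :h, :w, :] = x
        windows = xp.reshape(n, ho, k, wo, k, c)
        out = windows.max(axis=(2, 4))
        if store:
            self._windows, self._out, self._in_shape = windows, out, (h, w)
        return out

    def backward(self, dout):
        n, ho, wo, c = dout.shape
        k = self.k
        mask = self._windows == self._out[:, :, None, :, None, :]
        d = mask * dout[:, :, None, :, None, :]
        d = d.reshape(n, ho * k, wo * k, c)
        h, w = self._in_shape
        self._windows = None
        return d[:, :h, :w, :].astype(np.float32)

    def params(self):
        return []


class ConvNetClassifier:
    """Trunk of conv/pool layers + GAP + dropout + dense softmax head."""

    def __init__(self, layer_plan, input_size: int, n_classes: int,
                 dropout_rate: float, seed: int):
        """``layer_plan``: list of ("conv", kh, kw, cout, stride) / ("pool", k)."""
        if not (0.0 <= dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        self.input_size = int(input_size)
        self.n_classes = int(n_classes)
        self.dropout_rate = float(dropout_rate)
        self.seed = int(seed)
        self.is_trained = False
        self.loss_history: list[float] = []

        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.layers = []
        cin = 3
        h = w = self.input_size
        for item in layer_plan:
            if item[0] == "conv":
                _, kh, kw, cout, stride = item
                if h < kh or w < kw:
                    raise ValueError(
                        f"spatial size {h}x{w} underflows kernel {kh}x{kw}")
                self.layers.append(_Conv(kh, kw, cin, cout, stride, rng))
                h, w = self.layers[-1].out_shape(h, w)
                cin = cout
            elif item[0] == "pool":
                self.layers.append(_MaxPool(item[1]))
                h, w = self.layers[-1].out_shape(h, w)
            else:
                raise ValueError(f"unknown layer kind {item[0]!r}")
        if h < 1 or w < 1:
            raise ValueError("spatial size collapsed below 1 in the trunk")
        self.feature_dim = cin
        self.head_W = (rng.standard_normal((cin, n_classes))
                       * np.sqrt(1.0 / cin)).astype(np.float32)
        self.head_b = np.zeros(n_classes, dtype=np.float32)

    # ---------------------------------------------------------------- plumbing

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError(f"expected N x H x W x 3, got {x.shape}")
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            x = _sk_resize(
                x, (x.shape[0], self.input_size, self.input_size, 3),
                order=1, mode="reflect", anti_aliasing=False, preserve_range=True,
            ).astype(np.float32)
        return _standardize_batch(x).astype(np.float32)

    def _trunk(self, x: np.ndarray, store=False) -> np.ndarray:
        a = x
        for layer in self.layers:
            a = layer.forward(a, store=store)
        self._pre_gap_shape = a.shape
        return a.mean(axis=(1, 2))          # global average pool -> (N, feature_dim)

    def _softmax(self, logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _batched(self, x, fn, chunk=256):
        outs = [fn(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)

    # ---------------------------------------------------------------- inference

    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate (post-GAP) activations; deterministic, dropout off."""
        return self._batched(images, lambda b: self._trunk(self._prepare(b)))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Deterministic class probabilities, dropout off."""
        def fn(b):
            f = self._trunk(self._prepare(b))
            return self._softmax(f @ self.head_W + self.head_b)
        return self._batched(images, fn)

    def mc_predict_proba(self, images: np.ndarray, F: int,
                         rng: np.random.Generator) -> np.ndarray:
        """F dropout-active passes -> F x N x C tensor.

        One inverted-dropout mask is drawn per pass on the feature vector and
        applied to every item, so each pass is a single sampled network.
        With ``dropout_rate`` 0 all passes coincide with the deterministic
        prediction.
        """
        feats = self.features(images)
        p = self.dropout_rate
        out = np.empty((F, feats.shape[0], self.n_classes), dtype=np.float64)
        for f in range(F):
            if p > 0:
                mask = (rng.random(self.feature_dim) >= p) / (1.0 - p)
                fm = feats * mask.astype(np.float32)
            else:
                fm = feats
            out[f] = self._softmax(fm @ self.head_W + self.head_b)
        return out

    # ---------------------------------------------------------------- training

    def fit(self, images: np.ndarray, y: np.ndarray, *, epochs: int,
            learning_rate: float, batch_size: int = 32,
            rng: np.random.Generator | None = None,
            augment_fn=None) -> "ConvNetClassifier":
        """Minibatch Adam training with cross-entropy loss.

        ``augment_fn(image, rng) -> image`` (if given) is applied to each
        raw [0, 1] training image anew every epoch, so the model never sees
        the same tensor twice.  Standardization happens after augmentation.
        """
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError(
                "training labels contain a single class; acquire a larger "
                "initial batch so both classes are present")
        rng = rng if rng is not None else np.random.default_rng(self.seed + 1)
        x_raw = np.asarray(images, dtype=np.float32)
        n = len(x_raw)

        # Adam state per trainable array, keyed by identity
        adam: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for layer in self.layers:
            for _name, arr, _gname in layer.params():
                adam[id(arr)] = (np.zeros_like(arr), np.zeros_like(arr))
        head_mW = np.zeros_like(self.head_W); head_vW = np.zeros_like(self.head_W)
        head_mb = np.zeros_like(self.head_b); head_vb = np.zeros_like(self.head_b)
        t = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        p_drop = self.dropout_rate
        self.loss_history = []

        def adam_step(arr, grad, state, t):
            m, v = state
            m *= b1; m += (1 - b1) * grad
            v *= b2; v += (1 - b2) * grad * grad
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            arr -= (learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(arr.dtype)

        for _epoch in range(epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                xb = x_raw[idx]
                if augment_fn is not None:
                    xb = np.stack([augment_fn(im, rng) for im in xb]).astype(np.float32)
                xb = self._prepare(xb)
                yb = y[idx]

                feats = self._trunk_store(xb)
                if p_drop > 0:
                    mask = (rng.random(feats.shape) >= p_drop) / (1.0 - p_drop)
                    fdrop = feats * mask.astype(np.float32)
                else:
                    mask = None
                    fdrop = feats
                logits = fdrop @ self.head_W + self.head_b
                probs = self._softmax(logits)
                eps_p = 1e-12
                epoch_loss += -np.log(probs[np.arange(len(yb)), yb] + eps_p).sum()

                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                dW_head = fdrop.T @ dlogits
                db_head = dlogits.sum(axis=0)
                dfeat = dlogits @ self.head_W.T
                if mask is not None:
                    dfeat = dfeat * mask
                t += 1
                adam_step(self.head_W, dW_head.astype(np.float32), (head_mW, head_vW), t)
                adam_step(self.head_b, db_head.astype(np.float32), (head_mb, head_vb), t)

                # backprop through GAP into the trunk
                n_, h_, w_, c_ = self._pre_gap_shape
                da = np.broadcast_to(
                    dfeat[:, None, None, :].astype(np.float32), (n_, h_, w_, c_)
                ) / (h_ * w_)
                da = np.ascontiguousarray(da)
                for layer in reversed(self.layers):
                    da = layer.backward(da)
                    for (name, arr, gname) in layer.params():
                        grad = getattr(layer, gname)
                        adam_step(arr, grad, adam[id(arr)], t)
            self.loss_history.append(epoch_loss / n)
        self.is_trained = True
        return self

    def _trunk_store(self, x):
        a = x
        for layer in self.layers:
            a = layer.forward(a, store=True)
        self._pre_gap_shape = a.shape
        return a.mean(axis=(1, 2))
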