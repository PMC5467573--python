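"""One-hidden-layer CNN for candidate-pair classification.

Architecture: the encoded instance matrix ``X in R^{n x D}`` (word vectors
concatenated with two position vectors, ``D = me + 2 md``) is convolved with a
bank of filters of several window widths ``w`` (``m`` filters per width),
passed through a ReLU, max-pooled over time into a single feature per filter,
regularized with dropout, and classified by a fully connected softmax layer.

Training minimizes the summed cross-entropy over shuffled mini-batches with an
l2 penalty on the softmax weights, using the Adam update rule.  All gradients
are computed analytically in NumPy and are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .corpus import ClassLabel, N_CLASSES
from .embeddings import Vocabulary, build_vocabulary, encode_indices, init_random_embeddings, load_pretrained
from .preprocess import BlindedInstance, pad_to_length, pad_instances


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def convolve(X: np.ndarray, f: np.ndarray, b: float = 0.0, g=relu) -> np.ndarray:
    """Score sequence of one filter over one input matrix.

    ``X`` has shape ``(n, D)``, ``f`` shape ``(w, D)``; the result has length
    ``n - w + 1`` with ``s_i = g(sum_j <f_j, x_{i+j-1}> + b)``.  This is the
    single-filter reference path; the estimator uses a vectorized equivalent.
    """
    n, D = X.shape
    w = f.shape[0]
    if w > n:
        raise ValueError(f"filter width {w} exceeds input length {n}")
    s = np.empty(n - w + 1, dtype=X.dtype)
    for i in range(n - w + 1):
        s[i] = np.sum(f * X[i : i + w]) + b
    return g(s)


def pool_max(s: Sequence[float]) -> float:
    """Max-over-time pooling: the single most-activated window per filter."""
    s = np.asarray(s)
    if s.size == 0:
        raise ValueError("cannot max-pool an empty score sequence")
    return float(s.max())


def softmax(o: np.ndarray) -> np.ndarray:
    shifted = o - o.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# batched forward / backward over index arrays


def _windows(X: np.ndarray, w: int) -> np.ndarray:
    """(B, n, D) -> (B, n-w+1, w*D) sliding windows, rows ordered (j, dim)."""
    v = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)  # (B, L, D, w)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        X.shape[0], X.shape[1] - w + 1, w * X.shape[2]
    )


def _build_X(batch: dict[str, np.ndarray], params: dict[str, np.ndarray]) -> np.ndarray:
    parts = [params["We"][batch["word"]]]
    if "Wd1" in params and params["Wd1"].shape[1] > 0:
        parts.append(params["Wd1"][batch["q1"]])
        parts.append(params["Wd2"][batch["q2"]])
    return np.concatenate(parts, axis=2)


def forward(
    batch: dict[str, np.ndarray],
    params: dict[str, np.ndarray],
    filter_sizes: Sequence[int],
    train: bool = False,
    dropout: float = 0.5,
    dropout_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Full forward pass; returns a trace with every intermediate tensor.

    In train mode pooled features are dropped with probability ``dropout``
    using the inverted convention (kept units scaled by ``1/(1-p)``), so eval
    mode applies no rescaling: the test-time vector z is classified directly.
    """
    X = _build_X(batch, params)
    trace: dict = {"X": X, "s": {}, "argmax": {}, "windows": {}}
    pooled = []
    for w in filter_sizes:
        Xw = _windows(X, w)
        pre = Xw @ params[f"F{w}"].T + params[f"b{w}"]
        s = relu(pre)
        idx = s.argmax(axis=1)
        trace["windows"][w] = Xw
        trace["s"][w] = s
        trace["argmax"][w] = idx
        pooled.append(np.take_along_axis(s, idx[:, None, :], axis=1)[:, 0, :])
    z = np.concatenate(pooled, axis=1)
    if train and dropout > 0:
        if dropout_mask is None:
            if rng is None:
                raise ValueError("train-mode forward needs a dropout mask or an rng")
            dropout_mask = (rng.random(z.shape) >= dropout) / (1.0 - dropout)
        zd = z * dropout_mask
    else:
        dropout_mask = np.ones_like(z)
        zd = z
    o = zd @ params["Ws"] + params["d"]
    trace.update(z=z, mask=dropout_mask, zd=zd, o=o, probs=softmax(o))
    return trace


def loss_and_grads(
    batch: dict[str, np.ndarray],
    params: dict[str, np.ndarray],
    filter_sizes: Sequence[int],
    l2: float = 0.0,
    dropout: float = 0.0,
    dropout_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    return_grads: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    """Summed negative log-likelihood + l2 penalty on Ws, with gradients.

    ``J = -sum_i log p(y_i | x_i, theta) + l2 * ||Ws||_2^2``; log-probabilities
    are computed through a log-sum-exp so underflow cannot occur.
    """
    y = batch["y"]
    train = dropout > 0 or dropout_mask is not None
    trace = forward(
        batch, params, filter_sizes, train=train, dropout=dropout,
        dropout_mask=dropout_mask, rng=rng,
    )
    o = trace["o"]
    B = o.shape[0]
    lse = o.max(axis=1) + np.log(np.exp(o - o.max(axis=1, keepdims=True)).sum(axis=1))
    logp = o[np.arange(B), y] - lse
    J = float(-logp.sum() + l2 * np.sum(params["Ws"] ** 2))
    if not return_grads:
        return J, None

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dO = trace["probs"].copy()
    dO[np.arange(B), y] -= 1.0
    grads["Ws"] = trace["zd"].T @ dO + 2.0 * l2 * params["Ws"]
    grads["d"] = dO.sum(axis=0)
    dz = (dO @ params["Ws"].T) * trace["mask"]

    md = params["Wd1"].shape[1] if "Wd1" in params else 0
    me = params["We"].shape[1]
    dX = np.zeros_like(trace["X"])
    offset = 0
    for w in filter_sizes:
        m = params[f"F{w}"].shape[0]
        dz_w = dz[:, offset : offset + m]
        offset += m
        s = trace["s"][w]
        idx = trace["argmax"][w]
        dS = np.zeros_like(s)
        np.put_along_axis(dS, idx[:, None, :], dz_w[:, None, :], axis=1)
        dS *= s > 0  # ReLU gradient (pre > 0 iff post > 0 here)
        Xw = trace["windows"][w]
        grads[f"F{w}"] = dS.reshape(-1, m).T @ Xw.reshape(-1, Xw.shape[2])
        grads[f"b{w}"] = dS.sum(axis=(0, 1))
        dXw = (dS @ params[f"F{w}"]).reshape(B, -1, w, trace["X"].shape[2])
        L = dXw.shape[1]
        for j in range(w):
            dX[:, j : j + L, :] += dXw[:, :, j, :]

    np.add.at(grads["We"], batch["word"], dX[:, :, :me])
    if md > 0:
        np.add.at(grads["Wd1"], batch["q1"], dX[:, :, me : me + md])
        np.add.at(grads["Wd2"], batch["q2"], dX[:, :, me + md :])
    return J, grads


class Adam:
    """Adam update rule over a dict of parameter tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _micro_f1(gold: np.ndarray, pred: np.ndarray) -> float:
    """Micro F1 over the four positive classes (index of OTHER excluded)."""
    other = ClassLabel.OTHER.index
    tp = int(np.sum((gold == pred) & (gold != other)))
    fp = int(np.sum((pred != other) & (gold != pred)))
    fn = int(np.sum((gold != other) & (gold != pred)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


class CNNDDIClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style CNN classifier over blinded instances.

    Parameters mirror the study's fixed settings: 200 filters per window
    width, widths (3, 4, 5) for the baseline, dropout 0.5, l2 coefficient 3 on
    the softmax weights, mini-batches of 50, 25 epochs, ReLU nonlinearity,
    300-dimensional word vectors initialized uniform on (-1, 1) and
    fine-tuned, and position embeddings of dimension ``md`` (0 disables them).

    ``max_len`` caps the padded length ``n``; the fitted ``n_`` is the longest
    training instance, as the padding length is a property of the dataset.

    Fitted attributes end in an underscore: ``vocab_``, ``params_``, ``n_``,
    ``history_`` (per-epoch learning curve), ``classes_``.
    """

    def __init__(
        self,
        max_len: int = 128,
        me: int = 300,
        md: int = 5,
        filter_sizes: tuple[int, ...] = (3, 4, 5),
        n_filters: int = 200,
        dropout: float = 0.5,
        l2: float = 3.0,
        batch_size: int = 50,
        epochs: int = 25,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_eps: float = 1e-8,
        init_scale: float = 0.1,
        pretrained_path: str | None = None,
        seed: int = 0,
        dtype: str = "float32",
        track_curve: bool = True,
    ):
        self.max_len = max_len
        self.me = me
        self.md = md
        self.filter_sizes = filter_sizes
        self.n_filters = n_filters
        self.dropout = dropout
        self.l2 = l2
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.init_scale = init_scale
        self.pretrained_path = pretrained_path
        self.seed = seed
        self.dtype = dtype
        self.track_curve = track_curve

    # -- internal helpers --------------------------------------------------

    def _validate_hyper(self, n: int) -> None:
        if not self.filter_sizes:
            raise ValueError("at least one filter width is required")
        for w in self.filter_sizes:
            if not (1 <= w <= n):
                raise ValueError(f"filter width {w} outside [1, n={n}]")
        if len(set(self.filter_sizes)) != len(self.filter_sizes):
            raise ValueError("filter widths must be distinct")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.l2 < 0 or self.n_filters < 1 or self.me < 1 or self.md < 0:
            raise ValueError("invalid hyper-parameter value")

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        dt = np.dtype(self.dtype)
        D = self.me + 2 * self.md
        params: dict[str, np.ndarray] = {}
        if self.pretrained_path is not None:
            We, self.pretrained_coverage_ = load_pretrained(
                self.pretrained_path, self.vocab_, self.me, rng
            )
            params["We"] = We.astype(dt)
        else:
            params["We"] = init_random_embeddings(self.vocab_.size, self.me, rng).astype(dt)
        if self.md > 0:
            shape = (2 * self.n_ - 1, self.md)
            params["Wd1"] = rng.uniform(-1, 1, shape).astype(dt)
            params["Wd2"] = rng.uniform(-1, 1, shape).astype(dt)
        a = self.init_scale
        for w in self.filter_sizes:
            params[f"F{w}"] = rng.uniform(-a, a, (self.n_filters, w * D)).astype(dt)
            params[f"b{w}"] = np.zeros(self.n_filters, dtype=dt)
        m_total = self.n_filters * len(self.filter_sizes)
        params["Ws"] = rng.uniform(-a, a, (m_total, N_CLASSES)).astype(dt)
        params["d"] = np.zeros(N_CLASSES, dtype=dt)
        return params

    def _encode_batchable(self, instances: Sequence[BlindedInstance]) -> dict[str, np.ndarray]:
        n = self.n_
        word = np.empty((len(instances), n), dtype=np.int64)
        q1 = np.empty_like(word)
        q2 = np.empty_like(word)
        y = np.empty(len(instances), dtype=np.int64)
        for i, inst in enumerate(instances):
            enc = encode_indices(inst, self.vocab_, n)
            word[i] = enc.word_indices
            # shift to 0-based rows of the (2n-1)-row position tables
            q1[i] = enc.pos1_indices - 1
            q2[i] = enc.pos2_indices - 1
            y[i] = enc.label_index
        return {"word": word, "q1": q1, "q2": q2, "y": y}

    def _pad_for_predict(self, instances: Iterable[BlindedInstance]) -> list[BlindedInstance]:
        """Pad/truncate without dropping: every input gets a prediction."""
        from dataclasses import replace

        out = []
        for inst in instances:
            padded = pad_to_length(inst.tokens, self.n_, inst.p1, inst.p2)
            p1 = padded.p1 if padded.p1 is not None else 0
            p2 = padded.p2 if padded.p2 is not None else self.n_ - 1
            out.append(replace(inst, tokens=padded.tokens, p1=p1, p2=p2,
                               true_length=padded.true_length))
        return out

    # -- estimator API ------------------------------------------------------

    def fit(self, X: Sequence[BlindedInstance], y=None, validation=None):
        """Train on blinded instances (labels are carried by the instances).

        ``validation`` may be a second instance list; per-epoch train and
        validation micro-F1 are then recorded in ``history_``.
        """
        instances = list(X)
        if not instances:
            raise ValueError("cannot fit on an empty training set")
        longest = max(inst.true_length for inst in instances)
        self.n_ = max(min(longest, self.max_len), max(self.filter_sizes))
        self._validate_hyper(self.n_)
        padded, self.pad_stats_ = pad_instances(instances, self.n_)
        if not padded:
            raise ValueError("no instance survived padding/truncation")
        self.vocab_ = build_vocabulary(padded)
        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(rng)
        self.classes_ = np.arange(N_CLASSES)
        train_batch = self._encode_batchable(padded)
        val_batch = None
        if validation is not None:
            val_batch = self._encode_batchable(self._pad_for_predict(validation))

        opt = Adam(self.params_, self.learning_rate, self.beta1, self.beta2, self.adam_eps)
        T = len(padded)
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(T)
            for start in range(0, T, self.batch_size):
                sel = order[start : start + self.batch_size]
                batch = {k: v[sel] for k, v in train_batch.items()}
                _, grads = loss_and_grads(
                    batch, self.params_, self.filter_sizes,
                    l2=self.l2, dropout=self.dropout, rng=rng,
                )
                opt.step(self.params_, grads)
            if self.track_curve:
                row = {"epoch": epoch + 1}
                row["train_f1"] = _micro_f1(
                    train_batch["y"], self._predict_indices_batched(train_batch)
                )
                if val_batch is not None:
                    row["val_f1"] = _micro_f1(
                        val_batch["y"], self._predict_indices_batched(val_batch)
                    )
                self.history_.append(row)
        return self

    def _predict_indices_batched(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        out = np.empty(batch["word"].shape[0], dtype=np.int64)
        bs = max(self.batch_size, 1)
        for start in range(0, out.shape[0], bs):
            sub = {k: v[start : start + bs] for k, v in batch.items() if k != "y"}
            sub["y"] = np.zeros(sub["word"].shape[0], dtype=np.int64)
            trace = forward(sub, self.params_, self.filter_sizes, train=False)
            out[start : start + bs] = trace["probs"].argmax(axis=1)
        return out

    def predict_proba(self, X: Sequence[BlindedInstance]) -> np.ndarray:
        batch = self._encode_batchable(self._pad_for_predict(X))
        probs = []
        bs = max(self.batch_size, 1)
        for start in range(0, batch["word"].shape[0], bs):
            sub = {k: v[start : start + bs] for k, v in batch.items()}
            trace = forward(sub, self.params_, self.filter_sizes, train=False)
            probs.append(trace["probs"])
        return np.concatenate(probs, axis=0)

    def predict(self, X: Sequence[BlindedInstance]) -> list[ClassLabel]:
        """Argmax class per instance; ties break toward the lowest index."""
        probs = self.predict_proba(X)
        return [ClassLabel.from_index(int(i)) for i in probs.argmax(axis=1)]

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> Path:
        """Single-archive checkpoint: all tensors + hyper-params + vocabulary."""
        meta = {
            "hyper": self.get_params(),
            "vocab": self.vocab_.index,
            "n": self.n_,
        }
        buf = io.BytesIO()
        np.savez(buf, **self.params_)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("params.npz", buf.getvalue())
        return Path(path)

    @classmethod
    def load(cls, path) -> "CNNDDIClassifier":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            npz = np.load(io.BytesIO(zf.read("params.npz")))
            params = {k: npz[k] for k in npz.files}
        hyper = meta["hyper"]
        hyper["filter_sizes"] = tuple(hyper["filter_sizes"])
        est = cls(**hyper)
        est.vocab_ = Vocabulary(dict(meta["vocab"]))
        est.n_ = int(meta["n"])
        est.params_ = params
        est.classes_ = np.arange(N_CLASSES)
        est.history_ = []
        return est
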