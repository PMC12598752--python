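"""Compact numpy implementation of the pair-scoring convolutional network.

Architecture (per forward pass):

1. a trainable embedding matrix (one row per protein, same width as the
   sequence representation) is added to the sequence region of the static
   input, giving the effective input ``X`` of shape (N, L) with
   L = cfms_len + seq_len (200 + 256 = 456 by default);
2. a length-preserving 1-D convolution with F filters over the L axis gives
   a feature map (N, L, F); the raw input row is reintroduced into every
   filter channel (residual connection) after the ReLU;
3. for each protein pair (i, j) the feature difference H_i - H_j (L, F) and
   the input difference X_i - X_j (L, 1) are taken (elementwise absolute
   value by default, making the score symmetric in the pair order),
   concatenated along the channel axis to (L, F+1) and flattened;
4. three fully connected layers end in a single logistic-sigmoid unit.

Because convolution acts on proteins, not pairs, its cost scales with the
number of proteins N rather than with the number of pairs, and its weight
count (kernel_width x F + F biases) is independent of how many pairs are
scored.  Training minimizes binary cross-entropy with Adam, inverted
dropout on the hidden FC activations, and L2 weight decay on the
convolution and FC weights; every source of randomness is driven by one
integer seed, so identical runs produce identical losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "PairScoringNetwork", "default_fc_sizes"]


def default_fc_sizes(flat_dim: int) -> tuple[int, int, int]:
    """Geometric taper from the flattened pair feature down to one unit."""
    h1 = max(8, int(round(flat_dim ** (2.0 / 3.0))))
    h2 = max(4, int(round(flat_dim ** (1.0 / 3.0))))
    return (h1, h2, 1)


@dataclass
class ModelConfig:
    """Hyperparameters of the pair classifier.

    ``kernel_width`` must be odd so the 'same'-padded convolution preserves
    the input length, which the residual connection requires.
    """

    n_filters: int = 32
    kernel_width: int = 5
    fc_sizes: tuple[int, int, int] | None = None
    dropout_rate: float = 0.2
    weight_decay: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0
    symmetrize: str = "abs"  # "abs" or "signed"
    use_embedding: bool = True

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd (length-preserving conv)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.symmetrize not in {"abs", "signed"}:
            raise ValueError("symmetrize must be 'abs' or 'signed'")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class PairScoringNetwork:
    """Trainable network over a fixed set of proteins.

    Parameters
    ----------
    n_proteins : int
        Number of protein rows; fixes the embedding shape.
    input_len : int
        Width of the static input rows (CF-MS + sequence regions).
    seq_offset : int
        Column where the sequence region starts; the embedding is added to
        columns [seq_offset, input_len).
    config : ModelConfig
    """

    def __init__(
        self,
        n_proteins: int,
        input_len: int = 456,
        seq_offset: int = 200,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        cfg = self.config
        self.n_proteins = n_proteins
        self.input_len = input_len
        self.seq_offset = seq_offset
        self.rng = np.random.default_rng(cfg.seed)
        F, k = cfg.n_filters, cfg.kernel_width
        flat = input_len * (F + 1)
        fc_sizes = cfg.fc_sizes or default_fc_sizes(flat)
        if len(fc_sizes) != 3 or fc_sizes[-1] != 1:
            raise ValueError("fc_sizes must be three layer widths ending in 1")
        self.fc_sizes = tuple(fc_sizes)

        self.params: dict[str, np.ndarray] = {}
        self.params["conv_w"] = self.rng.normal(0.0, np.sqrt(2.0 / k), (F, k))
        self.params["conv_b"] = np.zeros(F)
        dims = [flat, *fc_sizes]
        for layer in range(3):
            fan_in = dims[layer]
            self.params[f"fc_w{layer}"] = self.rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (fan_in, dims[layer + 1])
            )
            self.params[f"fc_b{layer}"] = np.zeros(dims[layer + 1])
        if cfg.use_embedding:
            # small init keeps the CF-MS signal dominant early in training
            self.params["embedding"] = self.rng.uniform(
                -0.01, 0.01, (n_proteins, input_len - seq_offset)
            )
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0
        self.n_conv_calls_ = 0
        self.loss_history_: list[float] = []
        self.fitted_ = False

    # -- forward ----------------------------------------------------------

    @property
    def embedding(self) -> np.ndarray | None:
        return self.params.get("embedding")

    def conv_parameter_count(self) -> int:
        return self.params["conv_w"].size + self.params["conv_b"].size

    def _effective_input(self, X_static: np.ndarray) -> np.ndarray:
        X = np.array(X_static, dtype=float)
        if self.config.use_embedding:
            if X.shape[0] != self.n_proteins:
                raise ValueError("row count does not match the embedding")
            X[:, self.seq_offset:] += self.params["embedding"]
        return X

    def _conv_forward(self, X: np.ndarray):
        k = self.config.kernel_width
        pad = k // 2
        Xp = np.pad(X, ((0, 0), (pad, pad)))
        win = sliding_window_view(Xp, k, axis=1)  # (N, L, k)
        pre = win @ self.params["conv_w"].T + self.params["conv_b"]
        H = _relu(pre) + X[:, :, None]  # residual into every channel
        self.n_conv_calls_ += X.shape[0]
        return win, pre, H

    def _pair_forward(self, X, H, pairs, train_rng=None):
        cfg = self.config
        pairs = np.asarray(pairs, dtype=np.intp)
        if pairs.size and (pairs.min() < 0 or pairs.max() >= X.shape[0]):
            raise IndexError("pair index out of range")
        i, j = pairs[:, 0], pairs[:, 1]
        dh = H[i] - H[j]
        dx = X[i] - X[j]
        if cfg.symmetrize == "abs":
            sh, sx = np.sign(dh), np.sign(dx)
            dh, dx = np.abs(dh), np.abs(dx)
        else:
            sh = sx = None
        Z = np.concatenate([dh, dx[:, :, None]], axis=2)
        B = Z.shape[0]
        a = Z.reshape(B, -1)
        cache = {"pairs": pairs, "sh": sh, "sx": sx, "Z_shape": Z.shape, "acts": [a],
                 "masks": []}
        for layer in range(3):
            z = a @ self.params[f"fc_w{layer}"] + self.params[f"fc_b{layer}"]
            if layer < 2:
                a = _relu(z)
                if train_rng is not None and cfg.dropout_rate > 0:
                    keep = 1.0 - cfg.dropout_rate
                    mask = (train_rng.random(a.shape) < keep) / keep
                    a = a * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
                cache["acts"].append(a)
            else:
                logit = z[:, 0]
        p = _sigmoid(logit)
        cache["logit"], cache["p"] = logit, p
        return p, cache

    def score_pairs(
        self, X_static: np.ndarray, pairs, chunk: int = 4096
    ) -> np.ndarray:
        """Interaction scores in (0, 1) for an array of (i, j) index pairs.

        The convolution runs once over the proteins; pairs are scored in
        chunks to bound the flattened pair-feature memory.
        """
        X = self._effective_input(X_static)
        _, _, H = self._conv_forward(X)
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), chunk):
            p, _ = self._pair_forward(X, H, pairs[start: start + chunk])
            out[start: start + len(p)] = p
        return out

    def protein_representations(self, X_static: np.ndarray) -> np.ndarray:
        """Post-residual feature map flattened along filters: (N, L*F)."""
        X = self._effective_input(X_static)
        _, _, H = self._conv_forward(X)
        return H.reshape(H.shape[0], -1)

    # -- backward ---------------------------------------------------------

    def _backward(self, X, win, pre, H, cache, dlogit, want_input_grad=False):
        """Backprop from d(loss)/d(logit); returns parameter grads (and dX)."""
        cfg = self.config
        F = cfg.n_filters
        grads = {}
        B = dlogit.shape[0]
        da = dlogit[:, None]
        for layer in (2, 1, 0):
            a_prev = cache["acts"][layer]
            grads[f"fc_w{layer}"] = a_prev.T @ da
            grads[f"fc_b{layer}"] = da.sum(axis=0)
            da = da @ self.params[f"fc_w{layer}"].T
            if layer > 0:
                mask = cache["masks"][layer - 1]
                if mask is not None:
                    da = da * mask
                da = da * (cache["acts"][layer] > 0)
        dZ = da.reshape(cache["Z_shape"])  # (B, L, F+1)
        ddh, ddx = dZ[:, :, :F], dZ[:, :, F]
        if cfg.symmetrize == "abs":
            ddh = ddh * cache["sh"]
            ddx = ddx * cache["sx"]
        pairs = cache["pairs"]
        i, j = pairs[:, 0], pairs[:, 1]
        dH = np.zeros_like(H)
        np.add.at(dH, i, ddh)
        np.add.at(dH, j, -ddh)
        dX = np.zeros_like(X)
        np.add.at(dX, i, ddx)
        np.add.at(dX, j, -ddx)
        # residual path: H = relu(pre) + X broadcast over channels
        dX += dH.sum(axis=2)
        dpre = dH * (pre > 0)
        grads["conv_w"] = np.einsum("nlk,nlf->fk", win, dpre)
        grads["conv_b"] = dpre.sum(axis=(0, 1))
        k = cfg.kernel_width
        pad = k // 2
        tmp = dpre @ self.params["conv_w"]  # (N, L, k)
        dXp = np.zeros((X.shape[0], X.shape[1] + k - 1))
        for t in range(k):
            dXp[:, t: t + X.shape[1]] += tmp[:, :, t]
        dX += dXp[:, pad: pad + X.shape[1]]
        if cfg.use_embedding:
            grads["embedding"] = dX[:, self.seq_offset:]
        if want_input_grad:
            return grads, dX
        return grads

    def _adam_step(self, grads):
        cfg = self.config
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            if cfg.weight_decay > 0 and name in {"conv_w", "fc_w0", "fc_w1", "fc_w2"}:
                g = g + cfg.weight_decay * self.params[name]
            m = self._adam_m[name]
            v = self._adam_v[name]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[name] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, X_static, pairs, y, train_rng) -> float:
        """One minibatch update; returns the batch BCE loss."""
        X = self._effective_input(X_static)
        win, pre, H = self._conv_forward(X)
        p, cache = self._pair_forward(X, H, pairs, train_rng=train_rng)
        y = np.asarray(y, dtype=float)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogit = (p - y) / len(y)
        grads = self._backward(X, win, pre, H, cache, dlogit)
        self._adam_step(grads)
        return loss

    def fit(self, X_static, pairs, y, epochs: int | None = None) -> "PairScoringNetwork":
        """Full training loop over shuffled minibatches of labeled pairs."""
        cfg = self.config
        pairs = np.asarray(pairs, dtype=np.intp)
        y = np.asarray(y, dtype=float)
        if len(pairs) != len(y):
            raise ValueError("pairs and labels must align")
        train_rng = np.random.default_rng(self.rng.integers(2**31))
        n_epochs = epochs if epochs is not None else cfg.epochs
        for epoch in range(n_epochs):
            order = train_rng.permutation(len(pairs))
            losses = []
            for start in range(0, len(pairs), cfg.batch_size):
                sel = order[start: start + cfg.batch_size]
                loss = self.train_step(X_static, pairs[sel], y[sel], train_rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training loss diverged (non-finite) at epoch {epoch}"
                    )
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        self.fitted_ = True
        return self

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights and configuration to a .npz archive."""
        import dataclasses

        meta = dict(
            dataclasses.asdict(self.config),
            n_proteins=self.n_proteins,
            input_len=self.input_len,
            seq_offset=self.seq_offset,
            fitted=int(self.fitted_),
        )
        meta["fc_sizes"] = self.fc_sizes
        np.savez(
            path,
            __meta__=np.array([repr(meta)], dtype=object),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "PairScoringNetwork":
        import ast

        with np.load(path, allow_pickle=True) as archive:
            meta = ast.literal_eval(str(archive["__meta__"][0]))
            params = {k: archive[k] for k in archive.files if k != "__meta__"}
        fitted = bool(meta.pop("fitted"))
        n_proteins = meta.pop("n_proteins")
        input_len = meta.pop("input_len")
        seq_offset = meta.pop("seq_offset")
        meta["fc_sizes"] = tuple(meta["fc_sizes"])
        net = cls(
            n_proteins=n_proteins,
            input_len=input_len,
            seq_offset=seq_offset,
            config=ModelConfig(**meta),
        )
        for name, value in params.items():
            net.params[name] = np.asarray(value, dtype=float)
        net.fitted_ = fitted
        return net

    def input_gradient(self, X_static, pair) -> tuple[np.ndarray, np.ndarray]:
        """d(score)/d(input row) for the two proteins of one pair."""
        X = self._effective_input(X_static)
        win, pre, H = self._conv_forward(X)
        pairs = np.asarray([pair], dtype=np.intp)
        p, cache = self._pair_forward(X, H, pairs)
        dlogit = p * (1 - p)  # d sigmoid / d logit
        _, dX = self._backward(X, win, pre, H, cache, dlogit, want_input_grad=True)
        i, j = pair
        return dX[i].copy(), dX[j].copy()
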