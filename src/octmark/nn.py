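"""A small, fully deterministic dense auto-encoder.

Symmetric encoder/decoder built from fully connected layers with tanh
activations on hidden layers (including the bottleneck, so codes are
bounded in (-1, 1)) and a linear output. Trained with mini-batch Adam on
mean squared reconstruction error. All randomness flows through an
explicit :class:`numpy.random.Generator`, and computation is pure numpy,
so identical seed + data + config reproduce the parameter trajectory
bit-for-bit on any platform.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


class DenseAutoencoder:
    """Symmetric dense auto-encoder ``input -> hidden... -> code -> ... -> input``.

    Parameters
    ----------
    input_dim:
        Length of one input vector.
    hidden:
        Sizes of the encoder hidden layers (mirrored in the decoder).
    code_dim:
        Bottleneck size; the learned representation.
    rng:
        Generator used for weight initialisation.
    lr, beta1, beta2, eps:
        Adam hyper-parameters.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: tuple[int, ...] = (256, 64),
        code_dim: int = 20,
        rng: np.random.Generator | None = None,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if code_dim < 1:
            raise ValidationError("code_dim must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.input_dim = int(input_dim)
        self.code_dim = int(code_dim)
        self.hidden = tuple(int(h) for h in hidden)
        dims = [self.input_dim, *self.hidden, self.code_dim, *reversed(self.hidden), self.input_dim]
        self.dims = dims
        self.n_encoder_layers = len(self.hidden) + 1  # layers up to and incl. the bottleneck
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        # Glorot-uniform init
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for din, dout in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (din + dout))
            self.W.append(rng.uniform(-limit, limit, size=(din, dout)))
            self.b.append(np.zeros(dout))
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    # ------------------------------------------------------------------
    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Return the list of layer activations, input first, output last."""
        acts = [x]
        n_layers = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ w + b
            acts.append(z if i == n_layers - 1 else np.tanh(z))
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Map (n, input_dim) inputs to (n, code_dim) bottleneck codes."""
        x = self._check(x, self.input_dim)
        h = x
        for i in range(self.n_encoder_layers):
            h = np.tanh(h @ self.W[i] + self.b[i])
        return h

    def decode(self, codes: np.ndarray) -> np.ndarray:
        """Map (n, code_dim) codes back to (n, input_dim) reconstructions."""
        codes = self._check(codes, self.code_dim)
        h = codes
        n_layers = len(self.W)
        for i in range(self.n_encoder_layers, n_layers):
            z = h @ self.W[i] + self.b[i]
            h = z if i == n_layers - 1 else np.tanh(z)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(self._check(x, self.input_dim))[-1]

    def reconstruction_mse(self, x: np.ndarray) -> float:
        x = self._check(x, self.input_dim)
        r = self.reconstruct(x)
        return float(np.mean((r - x) ** 2))

    @staticmethod
    def _check(x: np.ndarray, dim: int) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2 or x.shape[1] != dim:
            raise ValidationError(f"expected (n, {dim}) array, got shape {x.shape}")
        return x

    # ------------------------------------------------------------------
    def train_epoch(self, x: np.ndarray, batch_size: int, rng: np.random.Generator) -> float:
        """One shuffled pass over ``x``; returns the mean batch loss."""
        x = self._check(x, self.input_dim)
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            batch = x[order[start : start + batch_size]]
            losses.append(self._step(batch))
        return float(np.mean(losses))

    def _step(self, batch: np.ndarray) -> float:
        acts = self._forward(batch)
        out = acts[-1]
        n = batch.shape[0]
        loss = float(np.mean((out - batch) ** 2))
        # backprop of MSE through linear output + tanh hiddens
        delta = 2.0 * (out - batch) / (n * self.input_dim)
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - acts[i] ** 2)
        self._t += 1
        t = self._t
        for i in range(len(self.W)):
            for g, p, m, v in (
                (gW[i], self.W[i], self._mW[i], self._vW[i]),
                (gb[i], self.b[i], self._mb[i], self._vb[i]),
            ):
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g**2
                mhat = m / (1 - self.beta1**t)
                vhat = v / (1 - self.beta2**t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return loss

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            state[f"W{i}"] = w
            state[f"b{i}"] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i in range(len(self.W)):
            w, b = np.asarray(state[f"W{i}"]), np.asarray(state[f"b{i}"])
            if w.shape != self.W[i].shape or b.shape != self.b[i].shape:
                raise ValidationError("checkpoint shapes do not match architecture")
            self.W[i] = w.astype(np.float64)
            self.b[i] = b.astype(np.float64)
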