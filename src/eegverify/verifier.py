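"""Per-claimant verification network trained with Levenberg-Marquardt.

The verifier is deliberately tiny: a feed-forward network with one tanh
hidden neuron (configurable) and two linear output neurons, one per class
(claimant, impostor), trained to one-hot targets under mean squared error.
With a single hidden unit the decision boundary is one hyperplane in
normalized feature space, which is all a two-class spectral verification
problem needs and keeps the ~860 parameters trainable from a few dozen
segments.

Training uses damped Gauss-Newton (Levenberg-Marquardt): the damping
``mu`` starts at 1e-3, grows 10x on a rejected step and shrinks 10x on an
accepted one; training stops on a max-epoch budget, ``mu`` overflow, a
vanishing gradient, or six consecutive validation-loss increases, and the
weights from the best validation epoch are returned. When the sample count
is smaller than the parameter count the normal equations are solved in the
dual (Woodbury) form for speed.

Inputs are min-max normalized to [-1, 1] with an affine map fitted on the
training fold only — the map is stored inside the model, so there is no
leakage and a serialized model is self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import DataError

__all__ = ["VerifierNetwork", "train_lm", "predict", "best_of_n"]


@dataclass
class VerifierNetwork:
    """Weights plus the input normalization fitted at training time."""

    w_hidden: np.ndarray  # (H, D)
    b_hidden: np.ndarray  # (H,)
    w_out: np.ndarray  # (2, H)
    b_out: np.ndarray  # (2,)
    norm_scale: np.ndarray  # (D,) affine map x -> x*scale + offset
    norm_offset: np.ndarray  # (D,)
    training_meta: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def hidden_units(self) -> int:
        return self.w_hidden.shape[0]

    def outputs(self, X: np.ndarray) -> np.ndarray:
        """Raw (claimant, impostor) linear outputs, shape ``(n, 2)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise DataError(
                f"feature dimension {X.shape[1]} != input_dim {self.input_dim}"
            )
        Xn = X * self.norm_scale + self.norm_offset
        h = np.tanh(Xn @ self.w_hidden.T + self.b_hidden)
        return h @ self.w_out.T + self.b_out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "norm_scale": self.norm_scale.tolist(),
            "norm_offset": self.norm_offset.tolist(),
            "training_meta": self.training_meta,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "VerifierNetwork":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            w_hidden=np.array(d["w_hidden"], dtype=float),
            b_hidden=np.array(d["b_hidden"], dtype=float),
            w_out=np.array(d["w_out"], dtype=float),
            b_out=np.array(d["b_out"], dtype=float),
            norm_scale=np.array(d["norm_scale"], dtype=float),
            norm_offset=np.array(d["norm_offset"], dtype=float),
            training_meta=d.get("training_meta", {}),
        )


def _fit_minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine map sending per-feature [min, max] to [-1, 1].

    Constant features map to 0 (scale and offset both zero for the scale
    term) so they carry no information instead of exploding.
    """
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    ok = span > 0
    scale = np.where(ok, 2.0 / np.where(ok, span, 1.0), 0.0)
    offset = np.where(ok, -1.0 - scale * lo, 0.0)
    return scale, offset


def _one_hot(y: np.ndarray) -> np.ndarray:
    """Targets: claimant (True) -> [1, 0]; impostor -> [0, 1]."""
    y = np.asarray(y, dtype=bool)
    T = np.zeros((len(y), 2))
    T[y, 0] = 1.0
    T[~y, 1] = 1.0
    return T


def _unpack(theta: np.ndarray, H: int, D: int):
    wh = theta[: H * D].reshape(H, D)
    bh = theta[H * D: H * D + H]
    wo = theta[H * D + H: H * D + H + 2 * H].reshape(2, H)
    bo = theta[H * D + 3 * H:]
    return wh, bh, wo, bo


def _forward(theta: np.ndarray, Xn: np.ndarray, H: int):
    wh, bh, wo, bo = _unpack(theta, H, Xn.shape[1])
    h = np.tanh(Xn @ wh.T + bh)
    return h @ wo.T + bo, h


def _jacobian(theta: np.ndarray, Xn: np.ndarray, h: np.ndarray, H: int) -> np.ndarray:
    """Jacobian of the flattened outputs w.r.t. the parameter vector.

    Rows ordered sample-major ((n, o) -> row 2n + o), columns in the
    ``theta`` packing order.
    """
    N, D = Xn.shape
    _, _, wo, _ = _unpack(theta, H, D)
    dtanh = 1.0 - h * h  # (N, H)
    J = np.empty((2 * N, theta.size))
    # hidden weights: d y[n,o] / d wh[j,d] = wo[o,j] * dtanh[n,j] * Xn[n,d]
    hidden_block = np.einsum("oj,nj,nd->nojd", wo, dtanh, Xn)
    J[:, : H * D] = hidden_block.reshape(2 * N, H * D)
    # hidden biases
    J[:, H * D: H * D + H] = np.einsum("oj,nj->noj", wo, dtanh).reshape(2 * N, H)
    # output weights: d y[n,o] / d wo[o',j] = delta(o,o') * h[n,j]
    out_block = np.zeros((N, 2, 2, H))
    out_block[:, 0, 0, :] = h
    out_block[:, 1, 1, :] = h
    J[:, H * D + H: H * D + 3 * H] = out_block.reshape(2 * N, 2 * H)
    # output biases
    bias_block = np.zeros((N, 2, 2))
    bias_block[:, 0, 0] = 1.0
    bias_block[:, 1, 1] = 1.0
    J[:, H * D + 3 * H:] = bias_block.reshape(2 * N, 2)
    return J


def _lm_step(J: np.ndarray, r: np.ndarray, mu: float) -> np.ndarray:
    """Solve ``(J'J + mu I) delta = J' r``, in the dual form when N < P."""
    n_rows, n_params = J.shape
    if n_rows < n_params:
        G = J @ J.T
        G[np.diag_indices_from(G)] += mu
        return J.T @ np.linalg.solve(G, r)
    A = J.T @ J
    A[np.diag_indices_from(A)] += mu
    return np.linalg.solve(A, J.T @ r)


def train_lm(train_X: np.ndarray, train_y: np.ndarray, val_X: np.ndarray,
             val_y: np.ndarray, hidden_units: int = 1, seed: int = 0, *,
             max_epochs: int = 100, mu0: float = 1e-3, mu_inc: float = 10.0,
             mu_dec: float = 0.1, mu_max: float = 1e10,
             grad_tol: float = 1e-7, patience: int = 6) -> VerifierNetwork:
    """Train one verifier with Levenberg-Marquardt and early stopping.

    Deterministic given the data and ``seed`` (weight init is uniform in
    [-0.5, 0.5]). Returns the weights from the epoch with the lowest
    validation MSE.
    """
    train_X = np.asarray(train_X, dtype=float)
    val_X = np.asarray(val_X, dtype=float)
    train_y = np.asarray(train_y, dtype=bool)
    val_y = np.asarray(val_y, dtype=bool)
    for name, y in (("train", train_y), ("val", val_y)):
        if y.all() or not y.any():
            raise DataError(f"{name} set must contain both classes")
    H, D = hidden_units, train_X.shape[1]
    scale, offset = _fit_minmax(train_X)
    Xn = train_X * scale + offset
    Vn = val_X * scale + offset
    T = _one_hot(train_y)
    Tv = _one_hot(val_y)

    rng = np.random.default_rng(seed)
    theta = rng.uniform(-0.5, 0.5, size=H * D + 3 * H + 2)

    def train_loss(th):
        y, h = _forward(th, Xn, H)
        r = (T - y).reshape(-1)
        return float(np.mean(r * r)), r, h

    def val_loss(th):
        y, _ = _forward(th, Vn, H)
        return float(np.mean((Tv - y) ** 2))

    loss, r, h = train_loss(theta)
    best_theta = theta.copy()
    best_val = val_loss(theta)
    fails = 0
    mu = mu0
    epochs_run = 0
    stop = "max_epochs"
    for epoch in range(1, max_epochs + 1):
        J = _jacobian(theta, Xn, h, H)  # d y / d theta
        grad = J.T @ r  # (1/2) d SSE / d theta, up to sign
        if np.max(np.abs(grad)) < grad_tol:
            stop = "gradient"
            break
        accepted = False
        while mu <= mu_max:
            try:
                delta = _lm_step(J, r, mu)
            except np.linalg.LinAlgError:
                mu *= mu_inc
                continue
            cand = theta + delta
            cand_loss, cand_r, cand_h = train_loss(cand)
            if np.isfinite(cand_loss) and cand_loss < loss:
                theta, loss, r, h = cand, cand_loss, cand_r, cand_h
                mu = max(mu * mu_dec, 1e-20)
                accepted = True
                break
            mu *= mu_inc
        epochs_run = epoch
        if not accepted:
            stop = "mu_overflow"
            break
        v = val_loss(theta)
        if v < best_val:
            best_val = v
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            if fails >= patience:
                stop = "early_stopping"
                break

    wh, bh, wo, bo = _unpack(best_theta, H, D)
    return VerifierNetwork(
        w_hidden=wh, b_hidden=bh, w_out=wo, b_out=bo,
        norm_scale=scale, norm_offset=offset,
        training_meta={
            "seed": int(seed),
            "epochs_run": int(epochs_run),
            "stop_reason": stop,
            "final_validation_loss": float(best_val),
        },
    )


def predict(net: VerifierNetwork, features: np.ndarray):
    """Decide claimant vs impostor for one or many feature vectors.

    The score is the difference of the two linear outputs
    (claimant - impostor); positive means claimant, a tie (score == 0)
    resolves to impostor. Returns ``(decisions, scores)``; scalars for a
    single 1-D input.
    """
    arr = np.asarray(getattr(features, "values", features), dtype=float)
    single = arr.ndim == 1
    y = net.outputs(np.atleast_2d(arr))
    scores = y[:, 0] - y[:, 1]
    decisions = scores > 0.0
    if single:
        return bool(decisions[0]), float(scores[0])
    return decisions, scores


def best_of_n(train_X, train_y, val_X, val_y, n: int = 10,
              base_seed: int = 0, **train_kwargs) -> VerifierNetwork:
    """Train ``n`` networks with seeds ``base_seed..base_seed+n-1`` and keep
    the one with the lowest validation MSE (ties break to the lowest seed)."""
    if n < 1:
        raise DataError("n must be >= 1")
    best: VerifierNetwork | None = None
    for k in range(n):
        net = train_lm(train_X, train_y, val_X, val_y,
                       seed=base_seed + k, **train_kwargs)
        if (best is None or net.training_meta["final_validation_loss"]
                < best.training_meta["final_validation_loss"]):
            best = net
    assert best is not None
    return best
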