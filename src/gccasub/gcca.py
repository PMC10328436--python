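"""Deep generalized canonical correlation analysis.

Generalized CCA finds a shared representation ``G`` (r x N, orthonormal rows)
and per-view projections ``U_v`` minimizing

    sum_v w_v || G - U_v^T Y_v ||_F^2      subject to  G G^T = I,

where ``Y_v`` is the (centered, missing-view-masked) output of view ``v``.
With ridge-regularized covariances ``C_v = Y_v Y_v^T + rho I`` the optimum is
closed-form: ``G``'s rows are the top-r eigenvectors of
``M = sum_v w_v Y_v^T C_v^{-1} Y_v`` and ``U_v = C_v^{-1} Y_v G^T``.

The deep variant feeds each view through a small two-layer fully connected
network and trains the networks by full-batch gradient descent on the GCCA
objective (plus L1/L2 weight penalties), using the envelope gradient
``dJ/dY_v = 2 w_v (U_v U_v^T Y_v - U_v G)`` at the per-step optimum.

Missing views are handled by masking: a sample absent from view v contributes
a zero column to Y_v and is excluded from that view's covariance, centering
and residual; the shared representation still covers every sample.  The
eigenproblem is solved on ``D^{-1/2} M D^{-1/2}`` with ``D`` the diagonal of
per-sample present-view weight sums, so samples observed in fewer views are
not shrunk toward zero in G; with no missing views this is an exact rescaling
and G equals the plain eigenvectors of M.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO

import numpy as np
import scipy.linalg

from .views import MultiOmicsDataset

__all__ = [
    "ViewNetworkConfig",
    "GccaConfig",
    "GccaSolution",
    "ViewNetwork",
    "TrainedDgcca",
    "gcca_solve",
    "gcca_loss_and_grads",
    "train_dgcca",
    "embed_samples",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("relu", "tanh", "identity")


@dataclass
class ViewNetworkConfig:
    """Architecture and penalties of one view's two-layer network."""

    hidden_units: int = 500
    output_units: int = 100
    activation: str = "relu"
    l1: float = 0.001
    l2: float = 0.0001

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalties must be nonnegative")
        if self.hidden_units < 1 or self.output_units < 1:
            raise ValueError("layer sizes must be positive")


@dataclass
class GccaConfig:
    """Shared-representation parameters.

    embedding_dim is the dimension r of the learned representation;
    view_rank bounds the rank of the (optionally truncated) view matrices;
    cov_reg is the ridge added to each view covariance.
    """

    embedding_dim: int = 100
    view_rank: int = 100
    cov_reg: float = 1e-6
    view_weights: list[float] | None = None
    epochs: int = 20
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.view_rank < self.embedding_dim:
            raise ValueError("need 1 <= embedding_dim <= view_rank")
        if self.cov_reg < 0:
            raise ValueError("cov_reg must be nonnegative")
        if self.view_weights is not None and any(w < 0 for w in self.view_weights):
            raise ValueError("view weights must be nonnegative")

    def weights(self, n_views: int) -> np.ndarray:
        if self.view_weights is None:
            return np.ones(n_views)
        if len(self.view_weights) != n_views:
            raise ValueError(
                f"{len(self.view_weights)} view weights for {n_views} views"
            )
        return np.asarray(self.view_weights, dtype=float)


@dataclass
class GccaSolution:
    """Closed-form GCCA optimum for one set of view outputs."""

    G: np.ndarray                     # r x N, orthonormal rows
    U: list[np.ndarray]               # per view: output_units x r
    objective: float
    per_view_residuals: list[float]
    eigenvalues: np.ndarray           # top-r eigenvalues of M, descending


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: first nonzero entry positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def _prepare_views(outputs, presence, view_rank):
    """Center each output over its present samples, zero absent columns,
    optionally replace by a rank-truncated SVD approximation."""
    n = outputs[0].shape[1]
    if presence is None:
        presence = np.ones((n, len(outputs)), dtype=bool)
    ys = []
    for v, z in enumerate(outputs):
        z = np.asarray(z, dtype=float)
        if z.shape[1] != n:
            raise ValueError("all view outputs must share the sample dimension")
        pres = presence[:, v]
        y = np.zeros_like(z)
        if pres.any():
            mean = z[:, pres].mean(axis=1, keepdims=True)
            y[:, pres] = z[:, pres] - mean
        if view_rank < min(y.shape):
            u, s, vt = np.linalg.svd(y, full_matrices=False)
            s[view_rank:] = 0.0
            y = (u * s) @ vt
        ys.append(y)
    return ys, presence


def gcca_solve(outputs, presence=None, cfg: GccaConfig | None = None) -> GccaSolution:
    """Closed-form GCCA on a list of V >= 2 view output matrices (units x N).

    Centering over present samples is part of this operation; absent samples'
    columns are zeroed and excluded from covariances and residuals.
    """
    cfg = cfg or GccaConfig()
    if len(outputs) < 2:
        raise ValueError("GCCA requires at least 2 views")
    n = np.asarray(outputs[0]).shape[1]
    r = cfg.embedding_dim
    if r > n:
        raise ValueError(f"embedding_dim {r} exceeds number of samples {n}")
    w = cfg.weights(len(outputs))
    ys, presence = _prepare_views(outputs, presence, cfg.view_rank)

    m = np.zeros((n, n))
    cinv_ys = []
    for wv, y in zip(w, ys):
        c = y @ y.T + cfg.cov_reg * np.eye(y.shape[0])
        cinv_y = scipy.linalg.solve(c, y, assume_a="pos")
        cinv_ys.append(cinv_y)
        m += wv * (y.T @ cinv_y)

    # Normalize by each sample's total present-view weight so samples with
    # missing views are not shrunk toward zero in the eigenvectors; with full
    # presence this divides M by the constant sum(w) and leaves G unchanged.
    d = (presence * w).sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("every sample must be present in >= 1 positively weighted view")
    dinv = 1.0 / np.sqrt(d)
    evals_n, evecs = scipy.linalg.eigh(m * dinv[:, None] * dinv[None, :])
    order = np.argsort(-evals_n, kind="stable")[:r]  # descending, stable ties
    top = _fix_signs(evecs[:, order])
    g = top.T                                        # r x N
    # eigenvalues reported on the scale of M itself (Rayleigh quotients of G;
    # exact eigenvalues of M whenever presence is full)
    evals = ((g @ m) * g).sum(axis=1)

    us, residuals = [], []
    for wv, y, cinv_y, pres in zip(w, ys, cinv_ys, presence.T):
        u = cinv_y @ g.T
        diff = (g - u.T @ y)[:, pres]
        residuals.append(float(np.sum(diff * diff)))
        us.append(u)
    objective = float(np.dot(w, residuals))
    return GccaSolution(
        G=g, U=us, objective=objective,
        per_view_residuals=residuals, eigenvalues=evals,
    )


def gcca_loss_and_grads(outputs, presence=None, cfg: GccaConfig | None = None):
    """GCCA objective and its gradient w.r.t. each view's output matrix.

    With G and U_v held at their per-step optimum the envelope gradient is
    ``2 w_v (U_v U_v^T Y_v - U_v G)`` with absent samples' columns zeroed;
    the centering Jacobian is applied so the gradients refer to the raw
    (uncentered) outputs.
    """
    cfg = cfg or GccaConfig()
    sol = gcca_solve(outputs, presence, cfg)
    ys, presence = _prepare_views(outputs, presence, cfg.view_rank)
    w = cfg.weights(len(outputs))
    grads = []
    for wv, y, u, pres in zip(w, ys, sol.U, presence.T):
        g_y = 2.0 * wv * (u @ (u.T @ y) - u @ sol.G)
        g_y[:, ~pres] = 0.0
        if pres.any():  # back through per-row centering over present columns
            g_y[:, pres] -= g_y[:, pres].mean(axis=1, keepdims=True)
        grads.append(g_y)
    return sol.objective, grads, sol


def _activate(name, a):
    if name == "relu":
        return np.maximum(a, 0.0)
    if name == "tanh":
        return np.tanh(a)
    return a


def _activate_grad(name, a):
    if name == "relu":
        return (a > 0).astype(float)
    if name == "tanh":
        t = np.tanh(a)
        return 1.0 - t * t
    return np.ones_like(a)


class ViewNetwork:
    """Two-layer fully connected network with a linear output layer.

    hidden = act(W1 x + b1); output = W2 hidden + b2.  The output layer is
    linear so the GCCA loss sees an unconstrained range.
    """

    def __init__(self, input_dim: int, cfg: ViewNetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.input_dim = input_dim
        s1 = 1.0 / np.sqrt(input_dim)
        s2 = 1.0 / np.sqrt(cfg.hidden_units)
        self.W1 = rng.normal(0.0, s1, size=(cfg.hidden_units, input_dim))
        self.b1 = np.zeros((cfg.hidden_units, 1))
        self.W2 = rng.normal(0.0, s2, size=(cfg.output_units, cfg.hidden_units))
        self.b2 = np.zeros((cfg.output_units, 1))

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        if x.shape[0] != self.input_dim:
            raise ValueError(
                f"network expects {self.input_dim} input features, got {x.shape[0]}"
            )
        a1 = self.W1 @ x + self.b1
        h = _activate(self.cfg.activation, a1)
        z = self.W2 @ h + self.b2
        if cache is not None:
            cache.update(x=x, a1=a1, h=h)
        return z

    def backward(self, cache: dict, dz: np.ndarray) -> dict:
        """Gradients of a scalar loss w.r.t. the parameters, given dL/doutput."""
        dW2 = dz @ cache["h"].T
        db2 = dz.sum(axis=1, keepdims=True)
        dh = self.W2.T @ dz
        da1 = dh * _activate_grad(self.cfg.activation, cache["a1"])
        dW1 = da1 @ cache["x"].T
        db1 = da1.sum(axis=1, keepdims=True)
        return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    def penalty(self) -> float:
        c = self.cfg
        return float(
            c.l1 * (np.abs(self.W1).sum() + np.abs(self.W2).sum())
            + c.l2 * ((self.W1 ** 2).sum() + (self.W2 ** 2).sum())
        )

    def sgd_step(self, grads: dict, lr: float) -> None:
        c = self.cfg
        self.W1 -= lr * (grads["W1"] + c.l1 * np.sign(self.W1) + 2 * c.l2 * self.W1)
        self.W2 -= lr * (grads["W2"] + c.l1 * np.sign(self.W2) + 2 * c.l2 * self.W2)
        self.b1 -= lr * grads["b1"]
        self.b2 -= lr * grads["b2"]


@dataclass
class TrainedDgcca:
    networks: list[ViewNetwork]
    final_solution: GccaSolution
    loss_history: list[float]
    cfg: GccaConfig = field(default_factory=GccaConfig)
    net_cfgs: list[ViewNetworkConfig] = field(default_factory=list)
    feature_ids: list[list[str]] = field(default_factory=list)


def _input_matrices(dataset: MultiOmicsDataset):
    """Aligned per-view matrices with absent/unobserved columns zero-filled."""
    xs = []
    for j, view in enumerate(dataset.views):
        x = view.values.copy()
        x[~np.isfinite(x)] = 0.0
        x[:, ~dataset.presence[:, j]] = 0.0
        xs.append(x)
    return xs


def train_dgcca(
    dataset: MultiOmicsDataset,
    net_cfgs: list[ViewNetworkConfig] | ViewNetworkConfig | None = None,
    cfg: GccaConfig | None = None,
) -> TrainedDgcca:
    """Full-batch gradient descent of the per-view networks on the GCCA loss.

    Each epoch forwards every view, solves the GCCA problem in closed form,
    backpropagates the envelope gradient plus L1/L2 penalties, and applies one
    full-batch update.  The returned solution is re-solved on the final
    network outputs over all samples.
    """
    cfg = cfg or GccaConfig()
    nv = dataset.n_views
    if nv < 2:
        raise ValueError("DGCCA needs at least 2 views")
    if isinstance(net_cfgs, ViewNetworkConfig) or net_cfgs is None:
        net_cfgs = [net_cfgs or ViewNetworkConfig()] * nv
    if len(net_cfgs) != nv:
        raise ValueError(f"{len(net_cfgs)} network configs for {nv} views")
    rng = np.random.default_rng(cfg.seed)
    xs = _input_matrices(dataset)
    nets = [ViewNetwork(x.shape[0], c, rng) for x, c in zip(xs, net_cfgs)]

    history: list[float] = []
    for epoch in range(cfg.epochs):
        caches = [dict() for _ in range(nv)]
        outputs = [net.forward(x, cache) for net, x, cache in zip(nets, xs, caches)]
        objective, grads, _ = gcca_loss_and_grads(outputs, dataset.presence, cfg)
        loss = objective + sum(net.penalty() for net in nets)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite DGCCA loss at epoch {epoch + 1}; try a smaller "
                f"learning rate than {cfg.learning_rate}"
            )
        history.append(float(loss))
        # full-batch update on the mean per-sample gradient, so the learning
        # rate is comparable across cohort sizes
        n = dataset.n_samples
        for net, cache, dz in zip(nets, caches, grads):
            net.sgd_step(net.backward(cache, dz / n), cfg.learning_rate)

    final_outputs = [net.forward(x) for net, x in zip(nets, xs)]
    final = gcca_solve(final_outputs, dataset.presence, cfg)
    return TrainedDgcca(
        networks=nets,
        final_solution=final,
        loss_history=history,
        cfg=cfg,
        net_cfgs=list(net_cfgs),
        feature_ids=[list(v.feature_ids) for v in dataset.views],
    )


def embed_samples(model: TrainedDgcca, dataset: MultiOmicsDataset) -> np.ndarray:
    """Shared embedding, one row per sample in the universe (N x r = G^T)."""
    for net, view, fids in zip(model.networks, dataset.views, model.feature_ids):
        if list(view.feature_ids) != fids:
            missing = sorted(set(fids) - set(view.feature_ids))
            raise ValueError(
                f"view {view.name!r} does not match the trained model's features"
                + (f"; missing: {missing[:5]}..." if missing else " (order differs)")
            )
    xs = _input_matrices(dataset)
    outputs = [net.forward(x) for net, x in zip(model.networks, xs)]
    sol = gcca_solve(outputs, dataset.presence, model.cfg)
    return sol.G.T


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_SCHEMA = 1


def save_model(model: TrainedDgcca, path) -> None:
    """Write a versioned zip archive of weights, configs and the final G."""
    meta = {
        "schema": _SCHEMA,
        "cfg": asdict(model.cfg),
        "net_cfgs": [asdict(c) for c in model.net_cfgs],
        "loss_history": model.loss_history,
        "feature_ids": model.feature_ids,
        "objective": model.final_solution.objective,
        "per_view_residuals": model.final_solution.per_view_residuals,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        arrays = {"G": model.final_solution.G,
                  "eigenvalues": model.final_solution.eigenvalues}
        for i, (net, u) in enumerate(zip(model.networks, model.final_solution.U)):
            arrays.update({f"W1_{i}": net.W1, f"b1_{i}": net.b1,
                           f"W2_{i}": net.W2, f"b2_{i}": net.b2, f"U_{i}": u})
        buf = BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())


def load_model(path) -> TrainedDgcca:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["schema"] != _SCHEMA:
            raise ValueError(f"unsupported model schema {meta['schema']}")
        arrays = np.load(BytesIO(zf.read("arrays.npz")))
    cfg = GccaConfig(**meta["cfg"])
    net_cfgs = [ViewNetworkConfig(**c) for c in meta["net_cfgs"]]
    nets, us = [], []
    rng = np.random.default_rng(0)
    for i, c in enumerate(net_cfgs):
        net = ViewNetwork(arrays[f"W1_{i}"].shape[1], c, rng)
        net.W1, net.b1 = arrays[f"W1_{i}"], arrays[f"b1_{i}"]
        net.W2, net.b2 = arrays[f"W2_{i}"], arrays[f"b2_{i}"]
        nets.append(net)
        us.append(arrays[f"U_{i}"])
    sol = GccaSolution(
        G=arrays["G"], U=us, objective=meta["objective"],
        per_view_residuals=meta["per_view_residuals"],
        eigenvalues=arrays["eigenvalues"],
    )
    return TrainedDgcca(nets, sol, meta["loss_history"], cfg, net_cfgs,
                        meta["feature_ids"])
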