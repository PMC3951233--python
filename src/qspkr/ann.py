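"""Small feed-forward regression network trained by Levenberg-Marquardt.

The architecture is the classic three-layer perceptron used for QSPkR
modelling: an input layer over the selected descriptors, one hidden layer
(tanh by default) and a single output neuron (logistic by default, since
targets are min-max scaled to [0, 1]); every layer carries a bias.

Training minimises the sum of squared residuals with the damped
Gauss-Newton (Levenberg-Marquardt) update: solve

    (J'J + mu * I) delta = J' r

where ``J`` is the analytic Jacobian of the predictions with respect to all
weights (the back-propagated derivatives) and ``r = y - yhat``. A step is
accepted only if it lowers the SSE, in which case the damping ``mu``
shrinks; otherwise ``mu`` grows and the step is retried. One epoch is one
accepted (or finally rejected) update over the full batch — with a few
dozen training compounds there is no reason to mini-batch.

A plain gradient-descent trainer is provided as a secondary option, and
``analytic_gradient_check`` validates the Jacobian against central finite
differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANNConfig",
    "ANNModel",
    "init_network",
    "forward",
    "train_levenberg_marquardt",
    "train_gradient_descent",
    "analytic_gradient_check",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

_ACT = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda a: a * (1.0 - a),
    ),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class ANNConfig:
    """Architecture and trainer settings.

    ``n_hidden`` defaults to 2: with ~33 training compounds and up to 15
    inputs, two hidden units (35 free parameters) are enough to capture the
    monotone nonlinearities seen in PK data while keeping the parameter
    count at the sample count; larger layers interpolate the training fold
    and generalize visibly worse at this data size. ``epochs`` defaults
    to 50.
    """

    n_hidden: int = 2
    epochs: int = 50
    activation_hidden: str = "tanh"
    activation_output: str = "logistic"
    lm_damping_init: float = 1e-3
    lm_damping_increase: float = 10.0
    lm_damping_decrease: float = 0.1
    lm_damping_max: float = 1e10
    max_step_retries: int = 30
    weight_init_scale: float = 0.5
    learning_rate: float = 0.1  # only used by the gradient-descent trainer
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        for name in (self.activation_hidden, self.activation_output):
            if name not in _ACT:
                raise ValueError(f"unknown activation {name!r}")
        if min(self.lm_damping_init, self.lm_damping_increase,
               self.lm_damping_decrease) <= 0:
            raise ValueError("damping factors must be > 0")
        if self.weight_init_scale < 0:
            raise ValueError("weight_init_scale must be >= 0")


@dataclass
class ANNModel:
    """Weights and biases of the three-layer network plus a training trace."""

    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    config: ANNConfig
    trace: list[dict] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + 1

    def copy(self) -> "ANNModel":
        return ANNModel(self.w1.copy(), self.b1.copy(), self.w2.copy(),
                        float(self.b2), self.config, [dict(t) for t in self.trace])


def init_network(n_inputs: int, config: ANNConfig | None = None) -> ANNModel:
    """Uniform random weights in [-weight_init_scale, +weight_init_scale]."""
    config = config or ANNConfig()
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(config.seed)
    s = config.weight_init_scale
    return ANNModel(
        w1=rng.uniform(-s, s, size=(config.n_hidden, n_inputs)),
        b1=rng.uniform(-s, s, size=config.n_hidden),
        w2=rng.uniform(-s, s, size=config.n_hidden),
        b2=float(rng.uniform(-s, s)),
        config=config,
    )


def _forward_full(model: ANNModel, X: np.ndarray):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, network expects {model.n_inputs}"
        )
    g_hid, _ = _ACT[model.config.activation_hidden]
    g_out, _ = _ACT[model.config.activation_output]
    h = g_hid(X @ model.w1.T + model.b1)      # (n, n_hidden)
    z2 = h @ model.w2 + model.b2              # (n,)
    return g_out(z2), h, X


def forward(model: ANNModel, X: np.ndarray) -> np.ndarray:
    """Row-wise predictions ``g_out(w2 . g_hid(W1 x + b1) + b2)``."""
    yhat, _, _ = _forward_full(model, X)
    return yhat


def _pack(model: ANNModel) -> np.ndarray:
    return np.concatenate([model.w1.ravel(), model.b1, model.w2, [model.b2]])


def _unpack(theta: np.ndarray, model: ANNModel) -> ANNModel:
    nh, ni = model.w1.shape
    out = model.copy()
    k = nh * ni
    out.w1 = theta[:k].reshape(nh, ni)
    out.b1 = theta[k:k + nh]
    out.w2 = theta[k + nh:k + 2 * nh]
    out.b2 = float(theta[-1])
    return out


def prediction_jacobian(model: ANNModel, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d yhat_i / d theta_p, shape (n_rows, n_parameters).

    Parameter order matches ``_pack``: W1 row-major, b1, w2, b2. These are
    the back-propagated (delta-rule) derivatives arranged as a matrix.
    """
    yhat, h, X = _forward_full(model, X)
    _, dg_hid = _ACT[model.config.activation_hidden]
    _, dg_out = _ACT[model.config.activation_output]
    go = dg_out(yhat)                     # (n,)
    dz1 = (go[:, None] * model.w2[None, :]) * dg_hid(h)   # (n, nh)
    n, nh, ni = X.shape[0], model.n_hidden, model.n_inputs
    J = np.empty((n, model.n_parameters))
    J[:, : nh * ni] = (dz1[:, :, None] * X[:, None, :]).reshape(n, nh * ni)
    J[:, nh * ni: nh * ni + nh] = dz1
    J[:, nh * ni + nh: nh * ni + 2 * nh] = go[:, None] * h
    J[:, -1] = go
    return J


def _sse(model: ANNModel, X: np.ndarray, y: np.ndarray) -> float:
    r = y - forward(model, X)
    return float(r @ r)


def train_levenberg_marquardt(model: ANNModel, X: np.ndarray, y: np.ndarray,
                              config: ANNConfig | None = None) -> ANNModel:
    """Train by damped Gauss-Newton for ``config.epochs`` accepted updates.

    The SSE over accepted steps is non-increasing by construction. Training
    stops early when the damping exceeds ``lm_damping_max`` (no downhill
    step exists at any trust-region size the solver will try).
    """
    config = config or model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on row count")
    cur = model.copy()
    cur.trace = [dict(t) for t in model.trace]
    mu = config.lm_damping_init
    sse = _sse(cur, X, y)
    if not np.isfinite(sse):
        raise FloatingPointError("non-finite loss before epoch 0")
    for epoch in range(config.epochs):
        theta = _pack(cur)
        r = y - forward(cur, X)
        J = prediction_jacobian(cur, X)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        for _ in range(config.max_step_retries):
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(theta.size), Jtr)
            except np.linalg.LinAlgError:
                mu *= config.lm_damping_increase
                continue
            trial = _unpack(theta + delta, cur)
            trial_sse = _sse(trial, X, y)
            if not np.isfinite(trial_sse):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            if trial_sse < sse:
                trial.trace = cur.trace
                cur, sse = trial, trial_sse
                mu = max(mu * config.lm_damping_decrease, 1e-15)
                accepted = True
                break
            mu *= config.lm_damping_increase
            if mu > config.lm_damping_max:
                break
        cur.trace.append(
            {"epoch": epoch, "sse": sse, "damping": mu, "accepted": accepted}
        )
        if not accepted and mu > config.lm_damping_max:
            break
    return cur


def train_gradient_descent(model: ANNModel, X: np.ndarray, y: np.ndarray,
                           config: ANNConfig | None = None) -> ANNModel:
    """Plain full-batch gradient descent on the SSE (secondary trainer)."""
    config = config or model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    cur = model.copy()
    for epoch in range(config.epochs):
        r = y - forward(cur, X)
        grad = -2.0 * prediction_jacobian(cur, X).T @ r
        cur = _unpack(_pack(cur) - config.learning_rate * grad, cur)
        cur.trace.append({"epoch": epoch, "sse": float(r @ r), "accepted": True})
    return cur


def analytic_gradient_check(model: ANNModel, X: np.ndarray,
                            step: float = 1e-6) -> float:
    """Max relative deviation of the analytic Jacobian from central finite
    differences; near machine precision when back-propagation is correct."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    J = prediction_jacobian(model, X)
    theta = _pack(model)
    J_fd = np.empty_like(J)
    for p in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[p] += step
        tm[p] -= step
        J_fd[:, p] = (forward(_unpack(tp, model), X)
                      - forward(_unpack(tm, model), X)) / (2 * step)
    scale = np.maximum(np.abs(J) + np.abs(J_fd), 1.0)
    return float(np.max(np.abs(J - J_fd) / scale))


def model_to_dict(model: ANNModel) -> dict:
    cfg = model.config
    return {
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "config": {
            "n_hidden": cfg.n_hidden, "epochs": cfg.epochs,
            "activation_hidden": cfg.activation_hidden,
            "activation_output": cfg.activation_output,
            "lm_damping_init": cfg.lm_damping_init,
            "lm_damping_increase": cfg.lm_damping_increase,
            "lm_damping_decrease": cfg.lm_damping_decrease,
            "lm_damping_max": cfg.lm_damping_max,
            "max_step_retries": cfg.max_step_retries,
            "weight_init_scale": cfg.weight_init_scale,
            "learning_rate": cfg.learning_rate,
            "seed": cfg.seed,
        },
        "trace": model.trace,
    }


def model_from_dict(d: dict) -> ANNModel:
    return ANNModel(
        w1=np.asarray(d["w1"], dtype=float),
        b1=np.asarray(d["b1"], dtype=float),
        w2=np.asarray(d["w2"], dtype=float),
        b2=float(d["b2"]),
        config=ANNConfig(**d["config"]),
        trace=list(d.get("trace", [])),
    )


def save_model(model: ANNModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)


def load_model(path) -> ANNModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
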