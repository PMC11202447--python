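"""Model-agnostic meta-learning core over flat named-parameter dicts.

The inner loop is plain gradient descent with step size ``alpha``; the outer
(meta) objective is the sum over tasks of the loss at the adapted parameters,
evaluated on held-out query data:

    min_theta  Σ_i  L_i( theta - alpha * grad L_i(theta; support_i); query_i )

Any model exposing ``loss(params, batch) -> float`` and
``loss_and_grad(params, batch) -> (float, grads)`` can be meta-learned; the
segmentation wrapper lives in :mod:`mamlseg.meta`, and tiny analytic models
(quadratics) exercise the same code paths in the test-suite.

Second-order meta-gradients propagate through the inner update via the
factorization  d/dtheta L_q(theta') = Π_t (I - alpha * H_t) · grad L_q(theta'),
where each Hessian-vector product ``H_t v`` is computed by central finite
differences of the analytic support gradient in float64.  A first-order
switch drops the Hessian term (the common CPU-scale approximation).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "LossModel",
    "AdaptResult",
    "inner_adapt_params",
    "outer_objective_params",
    "meta_gradient",
    "EarlyStopper",
]

ParamDict = "OrderedDict[str, np.ndarray]"


class LossModel(Protocol):
    def loss(self, params: ParamDict, batch) -> float: ...

    def loss_and_grad(self, params: ParamDict, batch) -> tuple[float, ParamDict]: ...


def _axpy(params, grads, alpha: float):
    return OrderedDict((k, params[k] - alpha * grads[k]) for k in params)


@dataclass
class AdaptResult:
    """Adapted parameters theta' plus the trajectory needed for meta-gradients."""

    params: "OrderedDict[str, np.ndarray]"
    trajectory: list  # theta_0 .. theta_{T-1}
    support_losses: list


def inner_adapt_params(model: LossModel, theta, batch, alpha: float,
                       steps: int = 1) -> AdaptResult:
    """``steps`` plain gradient-descent updates of step size ``alpha``.

    The incoming ``theta`` is never mutated; each step allocates new arrays.
    """
    if steps < 1:
        raise ValueError("inner steps must be >= 1")
    cur = theta
    trajectory, losses = [], []
    for _ in range(steps):
        loss, grads = model.loss_and_grad(cur, batch)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite inner loss: {loss}")
        trajectory.append(cur)
        losses.append(loss)
        cur = _axpy(cur, grads, alpha)
    return AdaptResult(params=cur, trajectory=trajectory, support_losses=losses)


def outer_objective_params(model: LossModel, theta,
                           episodes: Sequence[tuple], alpha: float,
                           steps: int = 1) -> float:
    """Meta-loss  Σ_i L_i(theta_i'; query_i)  for episodes (support, query)."""
    total = 0.0
    for support, query in episodes:
        adapted = inner_adapt_params(model, theta, support, alpha, steps)
        total += model.loss(adapted.params, query)
    return total


def _hvp_fd(model: LossModel, theta, batch, v, eps_scale: float = 1e-4):
    """Hessian-vector product of the support loss by central differences."""
    vnorm = float(np.sqrt(sum(float((x * x).sum()) for x in v.values())))
    if vnorm == 0.0:
        return OrderedDict((k, np.zeros_like(x)) for k, x in v.items())
    eps = eps_scale / vnorm
    plus = OrderedDict((k, theta[k] + eps * v[k]) for k in theta)
    minus = OrderedDict((k, theta[k] - eps * v[k]) for k in theta)
    _, gp = model.loss_and_grad(plus, batch)
    _, gm = model.loss_and_grad(minus, batch)
    return OrderedDict((k, (gp[k] - gm[k]) / (2.0 * eps)) for k in theta)


def meta_gradient(model: LossModel, theta, episodes: Sequence[tuple],
                  alpha: float, steps: int = 1, first_order: bool = False,
                  hvp_eps: float = 1e-4):
    """Meta-loss and its gradient with respect to ``theta``.

    Returns ``(meta_loss, grads, per_episode_query_losses)``.  With
    ``first_order=True`` the gradient is simply the query gradient at the
    adapted parameters; otherwise each inner step contributes its
    ``(I - alpha H_t)`` factor via finite-difference Hessian-vector products.
    """
    total_loss = 0.0
    acc: "OrderedDict[str, np.ndarray] | None" = None
    q_losses = []
    for support, query in episodes:
        adapted = inner_adapt_params(model, theta, support, alpha, steps)
        q_loss, v = model.loss_and_grad(adapted.params, query)
        if not np.isfinite(q_loss):
            raise FloatingPointError(f"non-finite query loss: {q_loss}")
        total_loss += q_loss
        q_losses.append(q_loss)
        if not first_order:
            for theta_t in reversed(adapted.trajectory):
                hv = _hvp_fd(model, theta_t, support, v, hvp_eps)
                v = OrderedDict((k, v[k] - alpha * hv[k]) for k in v)
        if acc is None:
            acc = OrderedDict((k, x.copy()) for k, x in v.items())
        else:
            for k in acc:
                acc[k] += v[k]
    assert acc is not None, "meta_gradient requires at least one episode"
    return total_loss, acc, q_losses


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement.

    Tracks the best value of a score to *maximize* (use ``mode="min"`` for
    losses); ``update`` returns True when training should halt, i.e. exactly
    ``patience`` epochs have elapsed since the best one.
    """

    def __init__(self, patience: int, mode: str = "max") -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.patience = patience
        self.sign = 1.0 if mode == "max" else -1.0
        self.best: float | None = None
        self.best_epoch: int | None = None
        self.bad_epochs = 0

    def update(self, value: float, epoch: int) -> bool:
        if self.best is None or self.sign * value > self.sign * self.best:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience
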