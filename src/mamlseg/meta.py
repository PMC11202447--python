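"""Episodic meta-learning for few-shot 3D segmentation.

Three phases:

1. **meta-training** — episodic MAML over several source segmentation tasks
   ("organs"): per outer step, one episode (support + query set) is sampled
   from each task, the inner loop adapts a copy of theta on each support set,
   and theta is updated by Adam on the summed query losses;
2. **meta-testing** — the learned initialization theta' is fine-tuned on a
   held-out task with k shots by ordinary Adam training on the Dice loss;
3. **final testing** — the fine-tuned theta'' is evaluated on unseen images of
   the held-out task (DSC, IoU, HD95 per case and mean).

Early stopping in phase 1 monitors the mean evaluation-set DSC of the current
(unadapted) theta; in phase 2 it monitors the mean training-shot loss.  Both
return the best checkpoint seen, not the last.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import maml
from .backbone import Backbone, BackboneConfig, ModelState, get_engine
from .metrics import CaseMetrics, MetricReport, aggregate, dice_loss_grad, evaluate_case
from .nn.optim import AdamState, adam_step
from .volume_io import BinaryMask, Volume

__all__ = [
    "MetaConfig",
    "SegTask",
    "Episode",
    "ExperimentPlan",
    "MetaTrainTask",
    "MetaTestTask",
    "SegLossModel",
    "sample_episode",
    "inner_adapt",
    "outer_objective",
    "meta_step",
    "meta_train",
    "fine_tune",
    "final_test",
    "predict_mask",
]

Pair = tuple[Volume, BinaryMask]


@dataclass
class MetaConfig:
    """Hyperparameters of the meta-learning loops.

    ``inner_lr`` (alpha) is the plain gradient-descent step of the inner loop;
    ``outer_lr`` (beta) the Adam learning rate of the meta-update.  Defaults
    follow the reference experimental settings (alpha 1e-4, beta 1e-6, weight
    decay 1e-5, batch size 1, patience 20/10).  ``fine_tune_lr`` defaults to
    ``inner_lr``.  ``first_order=True`` drops the second-order term of the
    meta-gradient (a common CPU-scale approximation).
    """

    inner_lr: float = 1e-4
    outer_lr: float = 1e-6
    inner_steps: int = 1
    weight_decay: float = 1e-5
    batch_size: int = 1
    patience_meta_train: int = 20
    patience_fine_tune: int = 10
    outer_optimizer: str = "adam"
    first_order: bool = False
    seed: int = 0
    max_epochs_meta: int = 200
    max_epochs_fine_tune: int = 100
    steps_per_epoch: int = 1
    fine_tune_lr: float | None = None
    hvp_eps: float = 1e-4

    def __post_init__(self) -> None:
        if self.inner_lr <= 0 or self.outer_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.inner_steps < 1:
            raise ValueError("inner_steps must be >= 1")
        if self.patience_meta_train < 1 or self.patience_fine_tune < 1:
            raise ValueError("patience must be >= 1")
        if self.outer_optimizer != "adam":
            raise ValueError("only the Adam outer optimizer is supported")

    @property
    def ft_lr(self) -> float:
        return self.inner_lr if self.fine_tune_lr is None else self.fine_tune_lr


@dataclass
class SegTask:
    """One segmentation problem: a named pool of (volume, mask) pairs."""

    name: str
    pool: list

    def __post_init__(self) -> None:
        if not self.pool:
            raise ValueError(f"task {self.name!r} has an empty pool")
        shape = self.pool[0][0].data.shape
        for v, m in self.pool:
            if v.data.shape != shape or m.data.shape != shape:
                raise ValueError(f"task {self.name!r} has shape-inconsistent pairs")


@dataclass
class Episode:
    """A support/query split sampled from one task; the sets are disjoint."""

    task_name: str
    support: list
    query: list


@dataclass
class MetaTrainTask:
    """A meta-training task: episode pool plus held-aside evaluation pairs."""

    task: SegTask
    n_support: int = 10
    n_query: int = 10
    eval_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.task.pool) < self.n_support + self.n_query:
            raise ValueError(
                f"task {self.task.name!r}: pool of {len(self.task.pool)} cannot "
                f"supply {self.n_support}+{self.n_query} support+query pairs")


@dataclass
class MetaTestTask:
    """The held-out task: k training shots and disjoint test pairs."""

    name: str
    train_pairs: list
    test_pairs: list

    def __post_init__(self) -> None:
        if not self.train_pairs or not self.test_pairs:
            raise ValueError("meta-test task needs both training shots and test pairs")


@dataclass
class ExperimentPlan:
    """Meta-train tasks plus one held-out meta-test task."""

    meta_train_tasks: list
    meta_test: MetaTestTask

    def __post_init__(self) -> None:
        names = [t.task.name for t in self.meta_train_tasks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate meta-train task names: {names}")
        if self.meta_test.name in names:
            raise ValueError(
                f"meta-test task {self.meta_test.name!r} also appears in meta-training")


def sample_episode(task: SegTask, k_support: int, k_query: int,
                   rng: np.random.Generator) -> Episode:
    """Disjoint uniform support/query draw without replacement."""
    need = k_support + k_query
    if len(task.pool) < need:
        raise ValueError(
            f"task {task.name!r}: pool of {len(task.pool)} pairs cannot supply "
            f"an episode of {k_support} support + {k_query} query")
    idx = rng.permutation(len(task.pool))[:need]
    support = [task.pool[i] for i in idx[:k_support]]
    query = [task.pool[i] for i in idx[k_support:]]
    return Episode(task_name=task.name, support=support, query=query)


class SegLossModel:
    """Dice-loss model over the U-Net backbone, in the flat-parameter protocol.

    The loss of a batch of pairs is the mean per-pair soft Dice loss of the
    softmax foreground probability.  ``train=True`` enables dropout (driven by
    ``rng``); gradient computations default to evaluation mode so they are
    deterministic functions of the parameters.
    """

    def __init__(self, cfg: BackboneConfig, train: bool = False,
                 rng: np.random.Generator | None = None,
                 smooth: float = 1e-5) -> None:
        self.engine: Backbone = get_engine(cfg)
        self.cfg = cfg
        self.train = train
        self.rng = rng
        self.smooth = smooth

    def _x(self, vol: Volume) -> np.ndarray:
        return vol.data[None, None].astype(self.cfg.np_dtype)

    def loss(self, params, batch) -> float:
        total = 0.0
        for vol, mask in batch:
            logits = self.engine.forward(params, self._x(vol), train=False)
            probs = _softmax_fg(logits)
            loss, _ = dice_loss_grad(probs, mask.data, self.smooth)
            total += loss
        return total / len(batch)

    def loss_and_grad(self, params, batch):
        total = 0.0
        acc: "OrderedDict[str, np.ndarray] | None" = None
        for vol, mask in batch:
            logits = self.engine.forward(params, self._x(vol),
                                         train=self.train, rng=self.rng)
            probs = _softmax_fg(logits)
            loss, gprobs = dice_loss_grad(probs, mask.data, self.smooth)
            total += loss
            glogits = _softmax_fg_backward(logits, probs, gprobs)
            grads = self.engine.backward(glogits)
            if acc is None:
                acc = OrderedDict((k, g.copy()) for k, g in grads.items())
            else:
                for k in acc:
                    acc[k] += grads[k]
        n = len(batch)
        for k in acc:
            acc[k] /= n
        return total / n, acc


def _softmax_fg(logits: np.ndarray) -> np.ndarray:
    """Foreground probability from 2-channel logits, shape (D, H, W)."""
    z = logits[0] - logits[0].max(axis=0, keepdims=True)
    e = np.exp(z)
    return e[1] / e.sum(axis=0)


def _softmax_fg_backward(logits: np.ndarray, probs: np.ndarray,
                         gprobs: np.ndarray) -> np.ndarray:
    """d(loss)/d(logits) given d(loss)/d(foreground probability)."""
    glogits = np.empty_like(logits)
    common = gprobs * probs * (1.0 - probs)
    glogits[0, 1] = common
    glogits[0, 0] = -common
    return glogits


def predict_mask(state: ModelState, vol: Volume) -> BinaryMask:
    """Evaluation-mode forward pass + per-voxel argmax over the two channels."""
    engine = get_engine(state.config)
    logits = engine.forward(state.params, vol.data[None, None].astype(state.config.np_dtype))
    fg = (logits[0, 1] > logits[0, 0]).astype(np.uint8)
    return BinaryMask(data=fg, spacing=vol.spacing, affine=vol.affine,
                      meta=dict(vol.meta))


@dataclass
class AdaptedState(ModelState):
    """theta_i' plus the information needed to differentiate through it."""

    adapt: maml.AdaptResult = None  # type: ignore[assignment]
    support: list = field(default_factory=list)


def _model_for(state: ModelState, cfg: MetaConfig,
               train: bool = False, rng=None) -> SegLossModel:
    return SegLossModel(state.config, train=train, rng=rng)


def inner_adapt(state: ModelState, support: Sequence[Pair],
                cfg: MetaConfig, rng: np.random.Generator | None = None
                ) -> AdaptedState:
    """theta_i' = theta - alpha * grad L(theta; support), ``inner_steps`` times.

    The incoming state is untouched; the result carries its adaptation
    trajectory so the meta-gradient can differentiate through it.
    """
    if not support:
        raise ValueError("inner_adapt requires a nonempty support set")
    model = _model_for(state, cfg, train=rng is not None, rng=rng)
    res = maml.inner_adapt_params(model, state.params, list(support),
                                  cfg.inner_lr, cfg.inner_steps)
    return AdaptedState(config=state.config, params=res.params,
                        adapt=res, support=list(support))


def outer_objective(state: ModelState, episodes: Sequence[Episode],
                    cfg: MetaConfig) -> float:
    """Σ_i query loss at the episode-adapted parameters."""
    if not episodes:
        raise ValueError("outer_objective requires at least one episode")
    model = _model_for(state, cfg)
    return maml.outer_objective_params(
        model, state.params, [(e.support, e.query) for e in episodes],
        cfg.inner_lr, cfg.inner_steps)


def meta_step(state: ModelState, episodes: Sequence[Episode], cfg: MetaConfig,
              opt_state: AdamState | None = None,
              rng: np.random.Generator | None = None
              ) -> tuple[ModelState, AdamState, dict]:
    """One Adam update of theta on the meta-loss gradient.

    Returns the updated state, the optimizer state, and a record with the
    meta-loss and per-episode query losses.
    """
    if not episodes:
        raise ValueError("meta_step requires at least one episode")
    opt_state = opt_state or AdamState()
    model = _model_for(state, cfg, train=rng is not None, rng=rng)
    meta_loss, grads, q_losses = maml.meta_gradient(
        model, state.params, [(e.support, e.query) for e in episodes],
        cfg.inner_lr, cfg.inner_steps, first_order=cfg.first_order,
        hvp_eps=cfg.hvp_eps)
    new_params = adam_step(state.params, grads, opt_state, lr=cfg.outer_lr,
                           weight_decay=cfg.weight_decay)
    info = {"meta_loss": meta_loss,
            "query_losses": {e.task_name: q for e, q in zip(episodes, q_losses)}}
    return ModelState(state.config, new_params), opt_state, info


def _eval_dsc(state: ModelState, pairs: Sequence[Pair]) -> float:
    scores = []
    for vol, mask in pairs:
        pred = predict_mask(state, vol)
        scores.append(_dsc_arrays(pred.data, mask.data))
    return float(np.mean(scores))


def _adapted_eval_dsc(state: ModelState, task: MetaTrainTask, cfg: MetaConfig,
                      rng: np.random.Generator) -> float:
    """Few-shot evaluation of theta on one task: adapt on a freshly sampled
    support set, then score DSC on the task's evaluation pairs."""
    episode = sample_episode(task.task, task.n_support, task.n_query, rng)
    adapted = inner_adapt(state, episode.support, cfg)
    return _eval_dsc(adapted, task.eval_pairs or episode.query)


def _dsc_arrays(p: np.ndarray, g: np.ndarray) -> float:
    ps, gs = int(p.sum()), int(g.sum())
    if ps == 0 and gs == 0:
        return 1.0
    return 2.0 * int((p.astype(bool) & g.astype(bool)).sum()) / (ps + gs)


def meta_train(plan: ExperimentPlan, cfg: MetaConfig,
               backbone_cfg: BackboneConfig | None = None,
               init_state: ModelState | None = None
               ) -> tuple[ModelState, pd.DataFrame]:
    """Episodic MAML meta-training with DSC-based early stopping.

    Per epoch: ``steps_per_epoch`` outer updates, each consuming one freshly
    sampled episode per meta-train task; then theta's few-shot capability is
    scored per task — adapt on a freshly sampled support set, evaluate DSC on
    the task's evaluation pairs with the adapted parameters.  Stops when the
    mean adapted evaluation DSC has not improved for ``patience_meta_train``
    epochs or at ``max_epochs_meta``; returns the best-scoring (unadapted)
    checkpoint and the per-epoch history.
    """
    from .backbone import build_backbone

    backbone_cfg = backbone_cfg or BackboneConfig()
    rng = np.random.default_rng(cfg.seed)
    state = init_state.copy() if init_state is not None else build_backbone(
        backbone_cfg, rng_seed=cfg.seed)
    drop_rng = np.random.default_rng(rng.integers(2 ** 31))
    opt_state = AdamState()
    stopper = maml.EarlyStopper(cfg.patience_meta_train, mode="max")
    best_state = state.copy()
    rows = []
    for epoch in range(cfg.max_epochs_meta):
        info = {}
        for _ in range(cfg.steps_per_epoch):
            episodes = [sample_episode(t.task, t.n_support, t.n_query, rng)
                        for t in plan.meta_train_tasks]
            state, opt_state, info = meta_step(
                state, episodes, cfg, opt_state,
                rng=drop_rng if state.config.dropout > 0 else None)
        eval_dscs = {t.task.name: _adapted_eval_dsc(state, t, cfg, rng)
                     for t in plan.meta_train_tasks}
        mean_dsc = float(np.mean(list(eval_dscs.values())))
        row = {"epoch": epoch, "meta_loss": info.get("meta_loss", np.nan),
               "mean_eval_dsc": mean_dsc}
        row.update({f"dsc_{k}": v for k, v in eval_dscs.items()})
        row.update({f"qloss_{k}": v for k, v in info.get("query_losses", {}).items()})
        rows.append(row)
        improved = stopper.best is None or mean_dsc > stopper.best
        stop = stopper.update(mean_dsc, epoch)
        if improved:
            best_state = state.copy()
        if stop:
            break
    return best_state, pd.DataFrame(rows)


def fine_tune(theta_prime: ModelState, task: SegTask | Sequence[Pair], k: int,
              cfg: MetaConfig, shots: Sequence[Pair] | None = None
              ) -> tuple[ModelState, pd.DataFrame]:
    """Meta-test fine-tuning: ordinary Adam Dice-loss training on k shots.

    ``shots`` may pin the exact training pairs; otherwise the first ``k``
    pairs of the task pool are used.  One Adam step per shot per epoch
    (batch size 1); early stopping monitors the epoch-mean training loss with
    ``patience_fine_tune`` and the best checkpoint is returned.
    """
    if shots is None:
        pool = task.pool if isinstance(task, SegTask) else list(task)
        if len(pool) < k:
            raise ValueError(f"need {k} fine-tuning shots, pool has {len(pool)}")
        shots = pool[:k]
    else:
        shots = list(shots)
        if len(shots) != k:
            raise ValueError(f"got {len(shots)} shots, expected k={k}")
    model = SegLossModel(theta_prime.config)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    train_model = SegLossModel(theta_prime.config,
                               train=theta_prime.config.dropout > 0, rng=drop_rng)
    params = OrderedDict((key, v.copy()) for key, v in theta_prime.params.items())
    opt_state = AdamState()
    stopper = maml.EarlyStopper(cfg.patience_fine_tune, mode="min")
    best = OrderedDict((key, v.copy()) for key, v in params.items())
    rows = []
    for epoch in range(cfg.max_epochs_fine_tune):
        losses = []
        for pair in shots:
            loss, grads = train_model.loss_and_grad(params, [pair])
            losses.append(loss)
            params = adam_step(params, grads, opt_state, lr=cfg.ft_lr,
                               weight_decay=cfg.weight_decay)
        mean_loss = float(np.mean(losses))
        rows.append({"epoch": epoch, "train_loss": mean_loss})
        improved = stopper.best is None or mean_loss < stopper.best
        stop = stopper.update(mean_loss, epoch)
        if improved:
            best = OrderedDict((key, v.copy()) for key, v in params.items())
        if stop:
            break
    return ModelState(theta_prime.config, best), pd.DataFrame(rows)


def final_test(theta_dd: ModelState, test_pairs: Sequence[Pair]) -> MetricReport:
    """Evaluation-mode prediction and per-case DSC/IoU/HD95 on held-out pairs."""
    cases: list[CaseMetrics] = []
    for i, (vol, mask) in enumerate(test_pairs):
        pred = predict_mask(theta_dd, vol)
        case_id = vol.meta.get("case_id", f"case{i:03d}")
        cases.append(evaluate_case(str(case_id), pred, mask, spacing=vol.spacing))
    return aggregate(cases)
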