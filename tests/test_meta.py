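"""Episodic sampling, adaptation, meta-gradients and the training loops
on the segmentation model itself."""

from collections import Counter, OrderedDict

import numpy as np
import pytest

from mamlseg.backbone import BackboneConfig, build_backbone
from mamlseg.meta import (Episode, MetaConfig, SegLossModel, SegTask,
                          final_test, fine_tune, inner_adapt, meta_train,
                          outer_objective, sample_episode)
from mamlseg.maml import meta_gradient
from mamlseg.phantoms import build_plan, default_families
from mamlseg.volume_io import BinaryMask, Volume

from conftest import blob_mask


def make_pairs(rng, n, shape=(8, 8, 8)):
    pairs = []
    for _ in range(n):
        mask = blob_mask(rng.integers(2, 6, 3), rng.integers(1, 3), shape=shape)
        data = 0.35 + 0.3 * mask.data + rng.normal(0, 0.05, shape)
        pairs.append((Volume(data=np.clip(data, 0, 1)), mask))
    return pairs


def make_task(rng, n, name="toy", shape=(8, 8, 8)):
    return SegTask(name=name, pool=make_pairs(rng, n, shape))


@pytest.fixture
def micro_cfg():
    """Smallest legal backbone in float64 for gradient work."""
    return BackboneConfig(channels=(2, 3), strides=(2,), num_res_units=1,
                          dropout=0.0, dtype="float64")


class TestSampleEpisode:
    def test_support_query_partition_pool(self, rng):
        task = make_task(rng, 20)
        ep = sample_episode(task, 10, 10, rng)
        ids = {id(p[0]) for p in ep.support} | {id(p[0]) for p in ep.query}
        assert len(ep.support) == 10 and len(ep.query) == 10
        assert ids == {id(p[0]) for p in task.pool}
        assert not ({id(p[0]) for p in ep.support} & {id(p[0]) for p in ep.query})

    def test_same_seed_identical_episode(self, rng):
        task = make_task(rng, 8)
        e1 = sample_episode(task, 3, 3, np.random.default_rng(5))
        e2 = sample_episode(task, 3, 3, np.random.default_rng(5))
        assert [id(p[0]) for p in e1.support] == [id(p[0]) for p in e2.support]
        assert [id(p[0]) for p in e1.query] == [id(p[0]) for p in e2.query]

    def test_uniform_support_frequency(self, rng):
        """Each of 4 pool items lands in the 1-shot support ~1/4 of the time
        (binomial oracle, 3 standard errors)."""
        task = make_task(rng, 4)
        draw_rng = np.random.default_rng(77)
        counts = Counter()
        n = 10_000
        for _ in range(n):
            ep = sample_episode(task, 1, 1, draw_rng)
            counts[id(ep.support[0][0])] += 1
        se = np.sqrt(n * 0.25 * 0.75)
        for item in task.pool:
            assert abs(counts[id(item[0])] - n / 4) <= 3 * se

    def test_pool_too_small_names_task(self, rng):
        with pytest.raises(ValueError, match="toy"):
            sample_episode(make_task(rng, 3), 2, 2, rng)


class TestInnerAdapt:
    def test_theta_untouched_and_matches_manual_gd(self, micro_cfg, rng):
        state = build_backbone(micro_cfg, 0)
        frozen = {k: v.copy() for k, v in state.params.items()}
        support = make_pairs(rng, 2)
        cfg = MetaConfig(inner_lr=0.05, first_order=True)
        adapted = inner_adapt(state, support, cfg)
        for k in frozen:  # purity
            np.testing.assert_array_equal(state.params[k], frozen[k])
        model = SegLossModel(micro_cfg)
        _, g = model.loss_and_grad(state.params, support)
        for k in frozen:
            np.testing.assert_allclose(adapted.params[k],
                                       frozen[k] - 0.05 * g[k], rtol=1e-12)

    def test_empty_support_rejected(self, micro_cfg):
        state = build_backbone(micro_cfg, 0)
        with pytest.raises(ValueError):
            inner_adapt(state, [], MetaConfig())


class TestSecondOrderMetaGradient:
    def test_matches_finite_differences_of_outer_objective(self, micro_cfg, rng):
        """Full second-order meta-gradient vs central differences on a
        few-hundred-parameter network, 1e-3 relative on random directions."""
        state = build_backbone(micro_cfg, 3)
        model = SegLossModel(micro_cfg)
        episodes = [(make_pairs(rng, 2, (6, 6, 6)), make_pairs(rng, 2, (6, 6, 6)))
                    for _ in range(2)]
        for steps in (1, 2):
            alpha = 0.1
            _, grad, _ = meta_gradient(model, state.params, episodes, alpha,
                                       steps=steps, first_order=False)
            def outer(params):
                from mamlseg.maml import outer_objective_params
                return outer_objective_params(model, params, episodes, alpha, steps)
            for trial in range(3):
                u = {k: rng.normal(size=v.shape) for k, v in state.params.items()}
                unorm = np.sqrt(sum((x ** 2).sum() for x in u.values()))
                u = {k: x / unorm for k, x in u.items()}
                h = 1e-5
                plus = OrderedDict((k, state.params[k] + h * u[k]) for k in u)
                minus = OrderedDict((k, state.params[k] - h * u[k]) for k in u)
                fd = (outer(plus) - outer(minus)) / (2 * h)
                an = sum(float((grad[k] * u[k]).sum()) for k in u)
                assert an == pytest.approx(fd, rel=1e-3), f"steps={steps} trial={trial}"

    def test_alpha_zero_equals_pooled_query_gradient(self, micro_cfg, rng):
        """With alpha = 0 the meta-gradient is joint training on the query sets."""
        state = build_backbone(micro_cfg, 1)
        model = SegLossModel(micro_cfg)
        episodes = [(make_pairs(rng, 1), make_pairs(rng, 2)) for _ in range(2)]
        _, grad, _ = meta_gradient(model, state.params, episodes, alpha=0.0)
        expected = None
        for _, query in episodes:
            _, g = model.loss_and_grad(state.params, query)
            if expected is None:
                expected = {k: v.copy() for k, v in g.items()}
            else:
                for k in expected:
                    expected[k] += g[k]
        for k in expected:
            np.testing.assert_allclose(grad[k], expected[k], rtol=1e-9, atol=1e-12)


class TestOuterObjective:
    def test_single_task_alpha_zero_is_plain_query_loss(self, micro_cfg, rng):
        state = build_backbone(micro_cfg, 0)
        model = SegLossModel(micro_cfg)
        support, query = make_pairs(rng, 2), make_pairs(rng, 2)
        ep = Episode("t", support, query)
        cfg = MetaConfig(inner_lr=1e-30)  # effectively zero adaptation
        assert outer_objective(state, [ep], cfg) == pytest.approx(
            model.loss(state.params, query), abs=1e-9)

    def test_two_identical_episodes_additivity(self, micro_cfg, rng):
        state = build_backbone(micro_cfg, 0)
        ep = Episode("t", make_pairs(rng, 2), make_pairs(rng, 2))
        cfg = MetaConfig(inner_lr=0.01)
        one = outer_objective(state, [ep], cfg)
        two = outer_objective(state, [ep, ep], cfg)
        assert two == pytest.approx(2 * one, rel=1e-12)


def tiny_plan(seed=0):
    return build_plan(default_families(), 3, 2, seed=seed, shape=(16, 16, 16),
                      n_support=2, n_query=2, n_eval=2, n_test=2)


def tiny_cfg(**kw):
    base = dict(inner_lr=1e-2, outer_lr=1e-3, first_order=True, seed=0,
                max_epochs_meta=3, steps_per_epoch=1, patience_meta_train=2,
                max_epochs_fine_tune=4, patience_fine_tune=2, fine_tune_lr=1e-3)
    base.update(kw)
    return MetaConfig(**base)


def tiny_backbone():
    return BackboneConfig(channels=(4, 8), strides=(2,), num_res_units=1, dropout=0.1)


class TestMetaTrain:
    def test_fixed_seed_identical_history(self):
        plan = tiny_plan()
        s1, h1 = meta_train(plan, tiny_cfg(), backbone_cfg=tiny_backbone())
        s2, h2 = meta_train(plan, tiny_cfg(), backbone_cfg=tiny_backbone())
        assert h1.equals(h2)
        for k in s1.params:
            np.testing.assert_array_equal(s1.params[k], s2.params[k])

    def test_early_stop_within_patience_of_best(self):
        cfg = tiny_cfg(max_epochs_meta=10, patience_meta_train=2)
        _, hist = meta_train(tiny_plan(), cfg, backbone_cfg=tiny_backbone())
        best_epoch = int(hist["mean_eval_dsc"].idxmax())
        assert len(hist) - 1 - best_epoch <= cfg.patience_meta_train
        if len(hist) < cfg.max_epochs_meta:  # stopped early: exactly patience after best
            assert len(hist) - 1 - best_epoch == cfg.patience_meta_train

    def test_history_schema(self):
        _, hist = meta_train(tiny_plan(), tiny_cfg(), backbone_cfg=tiny_backbone())
        assert {"epoch", "meta_loss", "mean_eval_dsc"} <= set(hist.columns)
        assert len(hist) >= 1


class TestFineTune:
    def test_early_stop_bound_and_determinism(self):
        plan = tiny_plan()
        theta = build_backbone(tiny_backbone(), 0)
        cfg = tiny_cfg(max_epochs_fine_tune=8, patience_fine_tune=2)
        s1, h1 = fine_tune(theta, None, 2, cfg, shots=plan.meta_test.train_pairs)
        s2, h2 = fine_tune(theta, None, 2, cfg, shots=plan.meta_test.train_pairs)
        assert h1.equals(h2)
        for k in s1.params:
            np.testing.assert_array_equal(s1.params[k], s2.params[k])
        best_epoch = int(h1["train_loss"].idxmin())
        assert len(h1) - 1 - best_epoch <= cfg.patience_fine_tune

    def test_returns_best_not_last(self, micro_cfg, rng):
        """With dropout off, the returned checkpoint's training loss is no
        worse than the first epoch's (best-checkpoint contract)."""
        shots = make_pairs(rng, 2, (8, 8, 8))
        theta = build_backbone(micro_cfg, 0)
        cfg = tiny_cfg(max_epochs_fine_tune=10, patience_fine_tune=3)
        best, hist = fine_tune(theta, None, 2, cfg, shots=shots)
        model = SegLossModel(micro_cfg)
        assert model.loss(best.params, shots) <= hist["train_loss"].iloc[0] + 1e-8

    def test_shot_count_validated(self, micro_cfg, rng):
        theta = build_backbone(micro_cfg, 0)
        with pytest.raises(ValueError, match="shots"):
            fine_tune(theta, None, 5, tiny_cfg(), shots=make_pairs(rng, 3))


class TestFinalTest:
    def test_constant_background_predictor(self, micro_cfg, rng):
        """All-zero parameters emit equal logits -> all-background prediction:
        DSC 0 on nonempty masks, HD95 undefined for every case."""
        state = build_backbone(micro_cfg, 0)
        for k in state.params:
            state.params[k] = np.zeros_like(state.params[k])
        pairs = make_pairs(rng, 3)
        rep = final_test(state, pairs)
        assert rep.means["dsc"] == 0.0
        assert np.isnan(rep.means["hd95"])
        assert rep.n_hd95_excluded == 3

    def test_means_equal_hand_average(self, micro_cfg, rng):
        state = build_backbone(micro_cfg, 2)
        rep = final_test(state, make_pairs(rng, 4))
        assert rep.means["dsc"] == pytest.approx(
            np.mean([c.dsc for c in rep.per_case]))
        assert rep.means["iou"] == pytest.approx(
            np.mean([c.iou for c in rep.per_case]))
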