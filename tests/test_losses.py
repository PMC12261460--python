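import numpy as np
import pytest
from autograd import grad, value_and_grad
from hypothesis import given, settings
from hypothesis import strategies as st

from difi import nn
from difi.config import DIFIConfig
from difi.errors import ValidationError
from difi.feature_maps import FeatureMap, top_percentile_mask
from difi.knowledge_maps import KnowledgeMap
from difi.losses import (
    activation_based_difi_loss,
    gradient_based_difi_loss,
    masked_distance,
    sparse_attention_transfer_loss,
)
from difi.models import ClassifierSpec, make_classifier

from conftest import LinearSoftmax


def _km(scores, mask):
    scores = np.asarray(scores, float)
    return KnowledgeMap(tuple(range(len(scores))), scores, np.asarray(mask, float))


class TestMaskedDistance:
    def test_identical_masked_vectors_zero(self):
        km = _km([1.0, 2.0, 0.0], [1, 1, 0])
        fm = FeatureMap(np.array([1.0, 2.0, 9.0]), source="saliency")
        assert masked_distance(fm, km, "l2_squared") == 0.0
        assert masked_distance(fm, km, "cosine") == pytest.approx(0.0, abs=1e-12)

    def test_unit_l2_case(self):
        km = _km([0.0, 0.0, 0.0], [1, 1, 1])
        fm = FeatureMap(np.array([1.0, 0.0, 0.0]), source="saliency")
        assert masked_distance(fm, km, "l2_squared") == 1.0

    def test_orthogonal_cosine_penalty_one(self):
        km = _km([0.0, 1.0], [1, 1])
        fm = FeatureMap(np.array([1.0, 0.0]), source="saliency")
        assert masked_distance(fm, km, "cosine") == pytest.approx(1.0)

    def test_all_zero_mask_returns_zero(self):
        km = _km([5.0, 5.0], [0, 0])
        fm = FeatureMap(np.array([1.0, 2.0]), source="saliency")
        assert masked_distance(fm, km, "l2_squared") == 0.0
        assert masked_distance(fm, km, "cosine") == 0.0

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            masked_distance(np.ones(3), _km([1.0, 2.0], [1, 1]))

    def test_invariant_to_masked_out_scores(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(10)
        mask = (rng.random(10) < 0.4).astype(float)
        base = rng.standard_normal(10)
        altered = base + (1 - mask) * rng.standard_normal(10) * 100
        for metric in ("l2_squared", "cosine"):
            a = masked_distance(w, _km(base, mask), metric)
            b = masked_distance(w, _km(altered, mask), metric)
            assert a == pytest.approx(b, rel=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20).flatmap(
        lambda w: st.tuples(
            st.just(w),
            st.lists(st.floats(-50, 50), min_size=len(w), max_size=len(w)),
            st.lists(st.sampled_from([0, 1]), min_size=len(w), max_size=len(w)),
        )
    ))
    @settings(max_examples=200, deadline=None)
    def test_cosine_bounded_l2_nonnegative(self, wkm):
        w, k, mask = (np.asarray(v, float) for v in wkm)
        km = _km(k, mask)
        assert masked_distance(w, km, "l2_squared") >= 0.0
        assert -1e-9 <= masked_distance(w, km, "cosine") <= 2.0 + 1e-9


class TestGradientBasedLoss:
    def test_alpha_zero_equals_cross_entropy(self, tiny_model):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((6, 8))
        y = rng.integers(0, 3, 6)
        km = {c: _km(rng.random(8), np.ones(8)) for c in range(3)}
        loss = gradient_based_difi_loss(tiny_model, x, y, km,
                                        DIFIConfig(mode="gradient", alpha=0.0))
        ce = nn.cross_entropy(tiny_model.forward(tiny_model.params, x), y)
        assert float(loss) == float(ce)

    def test_saliency_matching_km_adds_nothing(self, linear_model):
        from difi.feature_maps import saliency_map
        x = np.array([0.4, -0.2, 1.0, 0.0, 0.3, -1.0])
        y = 1
        j = np.abs(saliency_map(linear_model, x, y).weights)
        km = {1: _km(j, np.ones(6))}
        cfg = DIFIConfig(mode="gradient", alpha=5.0)
        loss = gradient_based_difi_loss(linear_model, x[None], np.array([y]), km, cfg)
        ce = nn.cross_entropy(linear_model.forward(linear_model.params, x[None]),
                              np.array([y]))
        assert float(loss) == pytest.approx(float(ce), rel=1e-12)

    def test_label_without_map_contributes_ce_only(self, tiny_model):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 8))
        y = np.array([0, 1, 2, 1])
        km = {}  # nobody has a map
        cfg = DIFIConfig(mode="gradient", alpha=2.0)
        loss = gradient_based_difi_loss(tiny_model, x, y, km, cfg)
        ce = nn.cross_entropy(tiny_model.forward(tiny_model.params, x), y)
        assert float(loss) == float(ce)

    def test_parameter_gradient_matches_finite_differences(self):
        # 2-parameter toy: logistic model over 2 features
        w = np.array([[0.7], [-0.4]])  # (2 features, 1 logit) + fixed zero logit

        class TwoParam(LinearSoftmax):
            def forward(self, params, x):
                import autograd.numpy as anp
                z = anp.dot(x, params[0])
                return anp.concatenate([z, anp.zeros_like(z)], axis=1)

        model = TwoParam(np.zeros((2, 2)), np.zeros(2))
        model.params = [w]
        x = np.array([[0.5, -1.0], [1.5, 0.3]])
        y = np.array([0, 1])
        km = {0: _km([1.0, 0.2], [1, 1]), 1: _km([0.3, -0.1], [1, 0])}
        cfg = DIFIConfig(mode="gradient", alpha=1.3)

        def sim_term(params):
            full = gradient_based_difi_loss(model, x, y, km, cfg, params=params)
            ce = nn.cross_entropy(model.forward(params, x), y)
            return full - ce

        g = grad(sim_term)([w])[0]
        eps = 1e-6
        for i in range(2):
            wp, wm = w.copy(), w.copy()
            wp[i, 0] += eps
            wm[i, 0] -= eps
            fd = (float(sim_term([wp])) - float(sim_term([wm]))) / (2 * eps)
            assert fd == pytest.approx(g[i, 0], rel=1e-3, abs=1e-9)

    def test_similarity_term_has_parameter_gradient(self, tiny_model):
        # double-backprop contract: the saliency stays on the parameter graph
        rng = np.random.default_rng(7)
        x = rng.standard_normal((3, 8))
        y = np.array([0, 1, 2])
        km = {c: _km(rng.random(8), np.ones(8)) for c in range(3)}
        cfg = DIFIConfig(mode="gradient", alpha=1.0)

        def sim_term(params):
            full = gradient_based_difi_loss(tiny_model, x, y, km, cfg, params=params)
            return full - nn.cross_entropy(tiny_model.forward(params, x), y)

        grads = grad(sim_term)(tiny_model.params)
        assert any(np.abs(g).max() > 1e-8 for g in grads)


class TestActivationBasedLoss:
    @pytest.fixture
    def seq_model(self):
        spec = ClassifierSpec("resnet_sequence", 2, (20, 40),
                              taps=("group3", "group4"), width=4)
        return make_classifier(spec, seed=3)

    def test_alpha_zero_equals_cross_entropy(self, seq_model):
        rng = np.random.default_rng(0)
        x = rng.random((4, 20, 40))
        y = np.array([0, 1, 0, 1])
        kms = [_km(rng.random(40), np.ones(40)) for _ in range(4)]
        cfg = DIFIConfig(mode="activation", alpha=0.0, tap="group3", metric="cosine")
        loss = activation_based_difi_loss(seq_model, x, y, kms, cfg)
        ce = nn.cross_entropy(seq_model.forward(seq_model.params, x), y)
        assert float(loss) == float(ce)

    def test_mapless_batch_equals_cross_entropy(self, seq_model):
        rng = np.random.default_rng(0)
        x = rng.random((4, 20, 40))
        y = np.array([0, 1, 0, 1])
        cfg = DIFIConfig(mode="activation", alpha=3.0, tap="group3", metric="cosine")
        loss = activation_based_difi_loss(seq_model, x, y, [None] * 4, cfg)
        ce = nn.cross_entropy(seq_model.forward(seq_model.params, x), y)
        assert float(loss) == float(ce)

    def test_all_masked_out_map_contributes_zero(self, seq_model):
        rng = np.random.default_rng(0)
        x = rng.random((2, 20, 40))
        y = np.array([1, 1])
        kms = [_km(np.ones(40), np.zeros(40)), None]
        cfg = DIFIConfig(mode="activation", alpha=3.0, tap="group3", metric="cosine")
        loss = activation_based_difi_loss(seq_model, x, y, kms, cfg)
        ce = nn.cross_entropy(seq_model.forward(seq_model.params, x), y)
        assert float(loss) == float(ce)

    def test_training_decreases_masked_distance(self, seq_model):
        # 50 Adam steps on a frozen probe batch shrink the similarity term
        from difi.nn import Adam
        rng = np.random.default_rng(9)
        x = rng.random((8, 20, 40))
        y = rng.integers(0, 2, 8)
        kms = []
        for _ in range(8):
            mask = np.zeros(40)
            sites = rng.choice(40, 3, replace=False)
            scores = np.zeros(40)
            scores[sites] = 1.0
            mask[sites] = 1.0
            kms.append(_km(scores, mask))
        cfg = DIFIConfig(mode="activation", alpha=3.0, tap="group3", metric="cosine")

        def sim_only(params):
            full = activation_based_difi_loss(seq_model, x, y, kms, cfg, params=params)
            return full - nn.cross_entropy(seq_model.forward(params, x), y)

        def full_loss(params):
            return activation_based_difi_loss(seq_model, x, y, kms, cfg, params=params)

        start = float(sim_only(seq_model.params))
        opt = Adam(seq_model.params, lr=1e-3)
        params = seq_model.params
        for _ in range(50):
            _, g = value_and_grad(full_loss)(params)
            params = opt.step(params, g)
        assert float(sim_only(params)) < start

    def test_unknown_tap_rejected(self, seq_model):
        cfg = DIFIConfig(mode="activation", alpha=1.0, tap="group7")
        with pytest.raises(ValidationError):
            activation_based_difi_loss(
                seq_model, np.zeros((1, 20, 40)), np.array([0]),
                [_km(np.ones(40), np.ones(40))], cfg,
            )


class TestSparseAttentionTransfer:
    def test_identical_models_zero_similarity(self, rng):
        w = rng.standard_normal((5, 2))
        b = rng.standard_normal(2)
        student = LinearSoftmax(w, b)
        teacher = LinearSoftmax(w.copy(), b.copy())
        x = rng.standard_normal((6, 5))
        y = rng.integers(0, 2, 6)
        loss = sparse_attention_transfer_loss(student, teacher, x, y, 50.0)
        ce = nn.cross_entropy(student.forward(student.params, x), y)
        assert float(loss) == pytest.approx(float(ce), rel=1e-12)

    def test_full_percent_reduces_to_full_transfer(self, rng):
        from difi.feature_maps import batch_saliency
        student = LinearSoftmax(rng.standard_normal((5, 2)), rng.standard_normal(2))
        teacher = LinearSoftmax(rng.standard_normal((5, 2)), rng.standard_normal(2))
        x = rng.standard_normal((4, 5))
        y = rng.integers(0, 2, 4)
        loss = sparse_attention_transfer_loss(student, teacher, x, y, 100.0)
        js = batch_saliency(student, student.params, x, y)
        jt = batch_saliency(teacher, teacher.params, x, y)
        expected = float(nn.cross_entropy(student.forward(student.params, x), y)
                         + np.mean(np.sum((js - jt) ** 2, axis=1)))
        assert float(loss) == pytest.approx(expected, rel=1e-12)

    def test_mask_support_size_per_sample(self, rng):
        from difi.feature_maps import batch_saliency, batch_top_percentile_masks
        teacher = LinearSoftmax(rng.standard_normal((10, 3)), rng.standard_normal(3))
        x = rng.standard_normal((5, 10))
        y = rng.integers(0, 3, 5)
        jt = batch_saliency(teacher, teacher.params, x, y)
        masks = batch_top_percentile_masks(np.abs(jt), 30.0)
        assert np.all(masks.sum(axis=1) == int(np.ceil(0.3 * 10)))

    def test_shape_mismatch_rejected(self, rng):
        student = LinearSoftmax(rng.standard_normal((5, 2)), np.zeros(2))
        teacher = LinearSoftmax(rng.standard_normal((7, 2)), np.zeros(2))
        with pytest.raises(ValidationError):
            sparse_attention_transfer_loss(
                student, teacher, np.zeros((2, 5)), np.array([0, 1]), 50.0
            )
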