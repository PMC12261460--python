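"""Training objectives that pull a model's feature map toward a knowledge map.

Three objectives, all of the form ``cross-entropy + similarity penalty``:

* gradient-based: penalize the masked distance between the per-sample input
  gradient (saliency) and the sample's class knowledge map. The penalty's
  parameter gradient flows through the saliency itself (double
  backpropagation: second-order mixed partials of the cross-entropy).
* activation-based: penalize the masked distance between a channel-averaged
  activation profile at a chosen tap and a per-sample knowledge map; samples
  without a map contribute only cross-entropy.
* sparse attention transfer: match the student's saliency to a frozen
  teacher's, restricted to the teacher's top-percentile entries per sample.

Batches reduce by the arithmetic mean of per-sample terms.
"""

from __future__ import annotations

import logging

import autograd.numpy as anp
import numpy as np
from autograd import grad

from . import nn
from .config import DIFIConfig
from .errors import ValidationError
from .feature_maps import FeatureMap, batch_saliency, batch_top_percentile_masks
from .knowledge_maps import KnowledgeMap

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# masked distance kernels


def masked_distance(fm, km, metric: str = "l2_squared") -> float:
    """Distance between Hadamard-filtered feature and knowledge vectors.

    ``l2_squared`` -> ``||fm*theta - K*theta||^2``; ``cosine`` -> 1 - cosine
    similarity of the masked vectors. Returns 0 when the mask is all zero,
    and 0 (with a warning) for a degenerate zero-norm masked vector under the
    cosine metric. Accepts FeatureMap/KnowledgeMap objects or raw vectors
    (raw ``km`` is paired with an all-ones mask).
    """
    w = fm.weights if isinstance(fm, FeatureMap) else np.asarray(fm, dtype=float)
    if isinstance(km, KnowledgeMap):
        k, theta = km.scores, km.mask
    else:
        k = np.asarray(km, dtype=float)
        theta = np.ones_like(k)
    if w.shape != k.shape:
        raise ValidationError(f"feature axis mismatch: {w.shape} vs {k.shape}")
    if metric == "l2_squared":
        return float(np.sum((w * theta - k * theta) ** 2))
    if metric != "cosine":
        raise ValidationError(f"unknown metric {metric!r}")
    wm, km_vec = w * theta, k * theta
    nw, nk = np.linalg.norm(wm), np.linalg.norm(km_vec)
    if theta.sum() == 0:
        return 0.0
    if nw == 0 or nk == 0:
        logger.warning("zero-norm masked vector under cosine metric; penalty defined as 0")
        return 0.0
    return float(1.0 - np.dot(wm, km_vec) / (nw * nk))


def _graph_l2(w_masked, k_masked, normalize: bool):
    if normalize:
        w_masked = w_masked / (anp.sqrt(anp.sum(w_masked ** 2, axis=-1, keepdims=True)) + _EPS)
        k_masked = k_masked / (np.linalg.norm(k_masked, axis=-1, keepdims=True) + _EPS)
    return anp.sum((w_masked - k_masked) ** 2, axis=-1)


def _graph_cosine(w_masked, k_masked):
    # eps-stabilised so the term stays smooth through an all-zero activation
    nw = anp.sqrt(anp.sum(w_masked ** 2, axis=-1) + _EPS)
    nk = np.linalg.norm(k_masked, axis=-1) + _EPS
    return 1.0 - anp.sum(w_masked * k_masked, axis=-1) / (nw * nk)


def _similarity(w_masked, k_masked, cfg: DIFIConfig):
    """Per-sample similarity penalties for (B, d) masked stacks."""
    if cfg.metric == "cosine":
        return _graph_cosine(w_masked, k_masked)
    return _graph_l2(w_masked, k_masked, cfg.normalize_maps)


# ---------------------------------------------------------------------------
# objectives


def _check_km_axis(km: KnowledgeMap, d: int):
    if len(km) != d:
        raise ValidationError(f"knowledge map length {len(km)} != feature axis {d}")


def gradient_based_difi_loss(model, x, labels, km_lookup, cfg: DIFIConfig, params=None):
    """Cross-entropy plus masked saliency/knowledge distance.

    ``km_lookup`` maps a class label to its KnowledgeMap; a label without a
    map contributes only cross-entropy (logged once). The returned scalar is
    autograd-traceable in ``params``, including through the saliency term.
    With ``alpha == 0`` the saliency branch is skipped entirely and the value
    equals plain cross-entropy exactly.
    """
    params = model.params if params is None else params
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    ce = nn.cross_entropy(model.forward(params, x), labels)
    if cfg.alpha == 0:
        return ce

    have_km = []
    k_rows, theta_rows = [], []
    for i, lab in enumerate(labels):
        km = km_lookup.get(lab) if hasattr(km_lookup, "get") else km_lookup(lab)
        if km is None:
            logger.debug("label %r has no knowledge map; CE-only sample", lab)
            continue
        _check_km_axis(km, model.n_features)
        have_km.append(i)
        k_rows.append(km.scores)
        theta_rows.append(km.mask)
    if not have_km:
        return ce

    j = batch_saliency(model, params, x, labels)
    if model.input_kind == "one_hot":
        j = anp.sum(anp.abs(j), axis=1)  # (B, L)
    else:
        # knowledge scores are nonnegative importances; compare against the
        # gradient magnitude so the penalty rewards sensitivity at asserted
        # features instead of constraining the sign of the gradient
        j = anp.abs(j)
    j = j[np.array(have_km)]
    k = np.stack(k_rows)
    theta = np.stack(theta_rows)
    sim = anp.mean(_similarity(j * theta, k * theta, cfg))
    return ce + cfg.alpha * sim


def activation_based_difi_loss(model, x, labels, km_list, cfg: DIFIConfig, params=None):
    """Cross-entropy plus masked activation-profile/knowledge distance.

    ``km_list`` aligns with the batch; ``None`` entries (samples carrying no
    knowledge, e.g. non-enzymes) contribute only cross-entropy. The
    activation profile is the channel mean of absolute activations at
    ``cfg.tap``, linearly resized to the input length using only
    non-trainable operations.
    """
    params = model.params if params is None else params
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if len(km_list) != len(labels):
        raise ValidationError("km_list must align with the batch")
    logits, taps = model.forward_with_taps(params, x)
    ce = nn.cross_entropy(logits, labels)
    if cfg.alpha == 0:
        return ce
    if cfg.tap not in taps:
        raise ValidationError(f"unknown tap {cfg.tap!r}; model exposes {sorted(taps)}")

    have_km, k_rows, theta_rows = [], [], []
    for i, km in enumerate(km_list):
        if km is None:
            continue
        _check_km_axis(km, model.n_features)
        if km.mask.sum() == 0:
            continue  # all-masked-out map: similarity term 0 for the sample
        have_km.append(i)
        k_rows.append(km.scores)
        theta_rows.append(km.mask)
    if not have_km:
        return ce

    a = taps[cfg.tap]
    profile = anp.mean(anp.abs(a), axis=1)  # (B, L_tap)
    resize = nn.interp_matrix(profile.shape[1], model.n_features)
    q = anp.dot(profile, resize.T)  # (B, L)
    q = q[np.array(have_km)]
    k = np.stack(k_rows)
    theta = np.stack(theta_rows)
    sim = anp.mean(_similarity(q * theta, k * theta, cfg))
    return ce + cfg.alpha * sim


def sparse_attention_transfer_loss(
    student, teacher, x, labels, sparsity_percent: float,
    alpha: float = 1.0, params=None, normalize: bool = False,
):
    """Student cross-entropy plus masked student/teacher saliency distance.

    The per-sample mask keeps the top-``sparsity_percent`` teacher-saliency
    magnitudes (100 reduces to full attention transfer). The teacher is
    frozen; its saliency is a constant of the student's parameter graph.
    The printed objective carries no coefficient on the similarity term, so
    ``alpha`` defaults to 1.

    With ``normalize`` both saliency vectors are scaled to unit l2 norm
    before masking (the attention-transfer convention); raw gradients of a
    converged classifier are tiny, so the unnormalized term can be
    negligible against the cross-entropy.
    """
    params = student.params if params is None else params
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if student.input_kind != teacher.input_kind or student.n_features != teacher.n_features:
        raise ValidationError(
            "student and teacher must share input kind and feature axis "
            f"({student.input_kind}/{student.n_features} vs "
            f"{teacher.input_kind}/{teacher.n_features})"
        )
    ce = nn.cross_entropy(student.forward(params, x), labels)
    if alpha == 0 or sparsity_percent is None:
        return ce

    j_teacher = batch_saliency(teacher, teacher.params, x, labels)  # plain ndarray
    j_student = batch_saliency(student, params, x, labels)
    if student.input_kind == "one_hot":
        j_teacher = np.sum(np.abs(j_teacher), axis=1)
        j_student = anp.sum(anp.abs(j_student), axis=1)
    theta = batch_top_percentile_masks(np.abs(j_teacher), sparsity_percent)
    if normalize:
        j_teacher = j_teacher / (np.linalg.norm(j_teacher, axis=-1, keepdims=True) + _EPS)
        j_student = j_student / anp.sqrt(
            anp.sum(j_student ** 2, axis=-1, keepdims=True) + _EPS
        )
    sim = anp.mean(anp.sum((theta * (j_student - j_teacher)) ** 2, axis=-1))
    return ce + alpha * sim


# ---------------------------------------------------------------------------
# dispatch used by the training loop


def objective(model, x, labels, cfg: DIFIConfig, *, km_lookup=None, km_list=None,
              teacher=None, params=None):
    """Evaluate the configured objective; plain cross-entropy when mode is None."""
    if cfg.mode is None:
        params = model.params if params is None else params
        return nn.cross_entropy(model.forward(params, np.asarray(x, dtype=float)),
                                np.asarray(labels))
    if cfg.mode == "gradient":
        return gradient_based_difi_loss(model, x, labels, km_lookup or {}, cfg, params)
    if cfg.mode == "activation":
        if km_list is None:
            km_list = [None] * len(labels)
        return activation_based_difi_loss(model, x, labels, km_list, cfg, params)
    if cfg.mode == "transfer":
        if teacher is None or cfg.sparsity_percent is None:
            params = model.params if params is None else params
            return nn.cross_entropy(model.forward(params, np.asarray(x, dtype=float)),
                                    np.asarray(labels))
        return sparse_attention_transfer_loss(
            model, teacher, x, labels, cfg.sparsity_percent, cfg.alpha, params,
            normalize=cfg.normalize_maps,
        )
    raise ValidationError(f"unknown mode {cfg.mode!r}")


def cross_entropy_value(model, x, labels, params=None) -> float:
    """Plain cross-entropy of the model on a batch (no graph)."""
    params = model.params if params is None else params
    return float(nn.cross_entropy(model.forward(params, np.asarray(x, dtype=float)),
                                  np.asarray(labels)))
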