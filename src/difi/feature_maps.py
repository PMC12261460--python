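"""Model-derived feature maps: input-gradient saliency and activation profiles.

Both map types assign one weight per input feature (gene, or residue
position) and share the feature axis with knowledge maps, so the two can be
compared directly. Saliency keeps the signed gradient (the regularized
distance needs signed values); magnitudes are used only when aggregating
one-hot channels and when ranking features for percentile masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from autograd import grad

from . import nn
from .errors import ValidationError


@dataclass(frozen=True)
class FeatureMap:
    """Per-input-feature weights from a model."""

    weights: np.ndarray
    source: str  # 'saliency' | 'activation'
    tap: str | None = None
    feature_ids: tuple | None = None

    def __post_init__(self):
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        if weights.ndim != 1:
            raise ValidationError("feature-map weights must be a 1-D vector")
        if not np.all(np.isfinite(weights)):
            raise ValidationError("feature-map weights must be finite")
        if self.source not in ("saliency", "activation"):
            raise ValidationError(f"unknown feature-map source {self.source!r}")
        if self.source == "activation" and np.any(weights < 0):
            raise ValidationError("activation-derived weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.weights)


def saliency_map(model, sample: np.ndarray, label: int) -> FeatureMap:
    """Gradient of the cross-entropy loss at ``label`` w.r.t. the input.

    For flat vector inputs the weights are the signed per-feature gradient.
    For one-hot sequence inputs the per-residue weight is the sum over
    alphabet channels of the absolute per-element gradients.
    """
    sample = np.asarray(sample, dtype=float)
    if not (0 <= int(label) < model.spec.n_classes):
        raise ValidationError(f"label {label} outside [0, {model.spec.n_classes})")
    x = sample[None]
    y = np.array([int(label)])

    def loss(x_):
        return nn.cross_entropy(model.forward(model.params, x_), y, reduction="sum")

    g = grad(loss)(x)[0]
    if model.input_kind == "one_hot":
        weights = np.sum(np.abs(g), axis=0)
    else:
        weights = g
    return FeatureMap(weights, source="saliency")


def batch_saliency(model, params, x: np.ndarray, labels: np.ndarray):
    """Per-sample input gradients for a whole batch, autograd-traceable.

    Returns an array shaped like ``x`` whose i-th slice is the gradient of
    sample i's cross-entropy at its own label (samples are independent, so
    the gradient of the summed loss separates per sample). When ``params``
    is an autograd box the result stays connected to the parameter graph,
    which is what lets the training loss differentiate through the saliency.
    """

    def summed_ce(x_):
        return nn.cross_entropy(model.forward(params, x_), labels, reduction="sum")

    return grad(summed_ce)(x)


def activation_map(model, sample: np.ndarray, tap: str) -> FeatureMap:
    """Channel-aggregated spatial profile of an intermediate activation.

    The tapped tensor (C, L_tap) is reduced by the mean of absolute values
    across channels and linearly interpolated back to the input spatial
    length. The result is nonnegative and aligned with the input feature
    axis; the aggregation uses only non-trainable operations.
    """
    sample = np.asarray(sample, dtype=float)
    _, taps = model.forward_with_taps(model.params, sample[None])
    if tap not in taps:
        raise ValidationError(
            f"unknown tap {tap!r}; model exposes {sorted(taps)}"
        )
    profile = np.mean(np.abs(taps[tap][0]), axis=0)
    resize = nn.interp_matrix(len(profile), model.n_features)
    return FeatureMap(resize @ profile, source="activation", tap=tap)


def top_percentile_mask(fm, percent: float) -> np.ndarray:
    """Binary mask over the ``ceil(percent/100 * d)`` largest-magnitude weights.

    Ties are broken by lower index. Accepts a FeatureMap or a raw vector.
    """
    weights = fm.weights if isinstance(fm, FeatureMap) else np.asarray(fm, dtype=float)
    if weights.size == 0:
        raise ValidationError("feature map must be nonempty")
    if not (0 < percent <= 100):
        raise ValidationError(f"percent must lie in (0, 100], got {percent}")
    count = math.ceil(percent / 100.0 * len(weights))
    return _top_k_mask(np.abs(weights), count)


def _top_k_mask(magnitudes: np.ndarray, count: int) -> np.ndarray:
    """Mask of the ``count`` largest entries, ties to the lower index."""
    order = np.lexsort((np.arange(len(magnitudes)), -magnitudes))
    mask = np.zeros(len(magnitudes))
    mask[order[:count]] = 1.0
    return mask


def batch_top_percentile_masks(weights: np.ndarray, percent: float) -> np.ndarray:
    """Row-wise :func:`top_percentile_mask` for a (B, d) weight matrix."""
    return np.stack([top_percentile_mask(row, percent) for row in weights])
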