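"""Evaluation: classification error, feature-weight ROC-AUC, alanine scans.

Interpretability is quantified by a rank-based ROC-AUC of per-feature
weights against known important positions; perturbation sensitivity by the
percentage of true-positive sequences whose prediction flips to negative
after substituting selected residues with alanine (percent conversion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .feature_maps import FeatureMap, activation_map, saliency_map
from .models import encode_one_hot


@dataclass(frozen=True)
class PerturbationCurve:
    """Percent conversion indexed by the number of substituted residues."""

    k_values: tuple[int, ...]
    percent_conversion: tuple[float, ...]
    rank_source: str  # 'top' | 'bottom'

    def __post_init__(self):
        if self.rank_source not in ("top", "bottom"):
            raise ValidationError(f"rank_source must be top|bottom, got {self.rank_source!r}")
        if len(self.k_values) != len(self.percent_conversion):
            raise ValidationError("k_values and percent_conversion must align")
        for k, pc in zip(self.k_values, self.percent_conversion):
            if not (0.0 <= pc <= 100.0):
                raise ValidationError("percent conversion must lie in [0, 100]")
            if k == 0 and pc != 0.0:
                raise ValidationError("zero substitutions cannot convert predictions")


def classification_error(model, x, labels) -> float:
    """Percent error: 100 * (1 - accuracy)."""
    preds = model.predict(np.asarray(x, dtype=float))
    return float(100.0 * np.mean(preds != np.asarray(labels)))


def feature_weight_auc(fm, positives) -> float:
    """Rank-based ROC-AUC of feature weights for positive vs other positions.

    Equivalent to the Mann-Whitney U statistic normalised by the number of
    (positive, negative) pairs; tied weights contribute 1/2. Invariant under
    any strictly monotone transform of the weights.
    """
    weights = fm.weights if isinstance(fm, FeatureMap) else np.asarray(fm, dtype=float)
    pos = np.asarray(sorted(set(int(p) for p in positives)), dtype=int)
    if len(pos) == 0:
        raise ValidationError("positive set must be nonempty")
    if len(pos) >= len(weights):
        raise ValidationError("positive set must be a proper subset of positions")
    if pos.min() < 0 or pos.max() >= len(weights):
        raise ValidationError("positive positions out of range")
    ranks = rankdata(weights)  # average ranks: ties count 1/2 per pair
    n_pos = len(pos)
    n_neg = len(weights) - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def proximity_site_labels(dist: np.ndarray, catalytic, radius: float = 3.0) -> set[int]:
    """Positions whose minimum distance to any catalytic residue is <= radius.

    Catalytic sites themselves are included (distance 0 on the diagonal).
    """
    dist = np.asarray(dist, dtype=float)
    catalytic = sorted(set(int(p) for p in catalytic))
    if not catalytic:
        raise ValidationError("catalytic set must be nonempty")
    if min(catalytic) < 0 or max(catalytic) >= dist.shape[0]:
        raise ValidationError("catalytic positions out of range")
    min_dist = dist[:, catalytic].min(axis=1)
    return set(np.flatnonzero(min_dist <= radius).tolist())


def _substitution_weights(model, sequence: str, tap: str | None, weight_source: str):
    encoded = encode_one_hot(sequence)
    if weight_source == "activation":
        fm = activation_map(model, encoded, tap or "group3")
    else:
        label = int(model.predict(encoded[None])[0])
        fm = saliency_map(model, encoded, label)
    return fm.weights[: len(sequence)]


def alanine_scan_conversion(
    model,
    true_positives,
    k: int,
    rank_source: str = "top",
    tap: str | None = "group3",
    weight_source: str = "activation",
    negative_label: int = 0,
    weights_fn=None,
) -> float:
    """Percent of positive-predicted sequences flipped by alanine substitution.

    For each sequence the ``k`` highest- (``top``) or lowest- (``bottom``)
    weighted residues that are not already alanine are replaced with alanine;
    the model re-predicts, and the fraction flipped to ``negative_label`` is
    reported as a percentage. ``k`` larger than the number of eligible
    residues substitutes them all; ``k == 0`` is exactly 0%.

    ``weights_fn`` (sequence -> per-position weights) overrides the
    model-derived ranking when given.
    """
    true_positives = list(true_positives)
    if rank_source not in ("top", "bottom"):
        raise ValidationError(f"rank_source must be top|bottom, got {rank_source!r}")
    if k == 0 or not true_positives:
        return 0.0
    flipped = 0
    for seq in true_positives:
        if weights_fn is not None:
            weights = np.asarray(weights_fn(seq), dtype=float)[: len(seq)]
        else:
            weights = _substitution_weights(model, seq, tap, weight_source)
        eligible = [i for i, res in enumerate(seq) if res != "A"]
        if not eligible:
            continue
        order = sorted(eligible, key=lambda i: (-weights[i], i) if rank_source == "top"
                       else (weights[i], i))
        chosen = order[: min(k, len(order))]
        mutated = list(seq)
        for i in chosen:
            mutated[i] = "A"
        pred = int(model.predict(encode_one_hot("".join(mutated))[None])[0])
        if pred == negative_label:
            flipped += 1
    return float(100.0 * flipped / len(true_positives))


def perturbation_curve(
    model, true_positives, k_values, rank_source: str = "top", **kwargs
) -> PerturbationCurve:
    """Run :func:`alanine_scan_conversion` over a grid of k values."""
    values = tuple(
        alanine_scan_conversion(model, true_positives, int(k), rank_source, **kwargs)
        for k in k_values
    )
    return PerturbationCurve(tuple(int(k) for k in k_values), values, rank_source)
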