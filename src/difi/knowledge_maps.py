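"""Knowledge maps: sparse a-priori feature-importance vectors.

A knowledge map holds a score vector ``K`` over the input feature axis and a
binary mask ``theta`` marking which entries are asserted; consumers only ever
see the Hadamard-filtered product ``K * theta``. Builders exist for three
provenances:

* ``dge`` — expression biomarkers: per-class one-vs-rest differential
  expression, keeping significantly overexpressed genes and using their
  standardized effects as scores;
* ``catalytic`` — residue positions known to be functionally important get
  score 1; a seeded sample of the remaining positions gets a low score
  (default 0.01) so the labeled sites keep relatively higher weight, and
  that low-score support can be re-drawn every epoch;
* ``random_control`` — score-1 positions placed uniformly at random,
  matching the cardinality of a true catalytic map (negative control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


class Provenance(str, Enum):
    DGE = "dge"
    CATALYTIC = "catalytic"
    RANDOM_CONTROL = "random_control"
    USER = "user"


@dataclass(frozen=True)
class KnowledgeMap:
    """Per-feature knowledge scores with an assertion mask.

    Scores at ``mask == 0`` positions are ignored by every consumer.
    """

    feature_ids: tuple
    scores: np.ndarray
    mask: np.ndarray
    provenance: Provenance = Provenance.USER

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        mask = np.asarray(self.mask, dtype=float)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "mask", mask)
        if not (len(self.feature_ids) == len(scores) == len(mask)):
            raise ValidationError(
                "feature_ids, scores and mask must have equal length "
                f"({len(self.feature_ids)}, {len(scores)}, {len(mask)})"
            )
        if not np.all(np.isin(mask, (0.0, 1.0))):
            raise ValidationError("mask entries must be 0 or 1")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be finite")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def masked_scores(self) -> np.ndarray:
        """Hadamard-filtered scores ``K * theta`` (idempotent under mask)."""
        return self.scores * self.mask

    @property
    def support(self) -> np.ndarray:
        """Indices where the mask is 1."""
        return np.flatnonzero(self.mask)


@dataclass(frozen=True)
class DGEResult:
    """One-vs-rest differential expression: per-gene effect and p-value.

    ``effect`` is the difference of class means on the (already log-scale)
    values, i.e. a log fold change.
    """

    gene_ids: tuple
    effect: np.ndarray
    p_value: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "effect", np.asarray(self.effect, dtype=float))
        object.__setattr__(self, "p_value", np.asarray(self.p_value, dtype=float))
        if not (len(self.gene_ids) == len(self.effect) == len(self.p_value)):
            raise ValidationError("gene_ids, effect and p_value must have equal length")
        if not np.all(np.isfinite(self.effect)):
            raise ValidationError("effect values must be finite")
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValidationError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# operations


def apply_mask(values, mask) -> np.ndarray:
    """Hadamard filter: elementwise product of a value vector and a 0/1 mask."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if values.shape != mask.shape:
        raise ValidationError(f"shape mismatch: values {values.shape} vs mask {mask.shape}")
    if not np.all(np.isin(mask, (0.0, 1.0))):
        raise ValidationError("mask entries must be 0 or 1")
    return values * mask


def dge_scores(expr: pd.DataFrame, labels, target_class) -> DGEResult:
    """One-vs-rest Welch t-test per gene on log-scale expression values.

    ``expr`` is samples x genes; ``labels`` aligns with its rows. The effect
    is ``mean(target) - mean(rest)``. A gene with zero variance in both
    groups gets p-value 1. Deterministic given inputs.
    """
    labels = np.asarray(labels)
    if len(labels) != len(expr):
        raise ValidationError("labels length does not match number of samples")
    in_target = labels == target_class
    if not in_target.any():
        raise ValidationError(f"class {target_class!r} absent from labels")
    n_t, n_r = int(in_target.sum()), int((~in_target).sum())
    if n_t < 2 or n_r < 2:
        raise ValidationError(
            f"need >= 2 samples in target class and complement (got {n_t}/{n_r})"
        )
    values = expr.to_numpy(dtype=float)
    target = values[in_target]
    rest = values[~in_target]
    effect = target.mean(axis=0) - rest.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's precision warning; they get p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(target, rest, equal_var=False, axis=0)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance genes
    return DGEResult(tuple(expr.columns), effect, pvals)


def _standardize(effects: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Z-score over the selected set, shifted to be >= ``floor``.

    One selected gene (or a degenerate all-equal set) maps to score 1.
    """
    if len(effects) == 1:
        return np.ones(1)
    sd = effects.std(ddof=0)
    if sd == 0:
        return np.ones_like(effects)
    z = (effects - effects.mean()) / sd
    return z - z.min() + floor


def build_expression_knowledge_map(
    dge: DGEResult, n_biomarkers: int, p_threshold: float = 0.05
) -> KnowledgeMap:
    """Select the top overexpressed significant genes as knowledge scores.

    The mask is 1 exactly on the top-``n_biomarkers`` genes ranked by effect
    among those with ``p < p_threshold`` and ``effect > 0`` (fewer if fewer
    qualify). Ties are broken by smaller p-value, then lexicographic gene id.
    Selected scores are the standardized effects; everything else is masked
    out. An empty qualifying set yields an empty-mask map with a warning.
    """
    if n_biomarkers < 1:
        raise ValidationError("n_biomarkers must be positive")
    qualifying = np.flatnonzero((dge.effect > 0) & (dge.p_value < p_threshold))
    d = len(dge.effect)
    scores = np.zeros(d)
    mask = np.zeros(d)
    if len(qualifying) == 0:
        warnings.warn("no gene qualifies (effect > 0 and p < threshold); empty knowledge map")
        return KnowledgeMap(dge.gene_ids, scores, mask, Provenance.DGE)
    order = sorted(
        qualifying,
        key=lambda i: (-dge.effect[i], dge.p_value[i], str(dge.gene_ids[i])),
    )
    chosen = np.array(order[:n_biomarkers])
    scores[chosen] = _standardize(dge.effect[chosen])
    mask[chosen] = 1.0
    return KnowledgeMap(dge.gene_ids, scores, mask, Provenance.DGE)


def build_catalytic_knowledge_map(
    seq_length: int,
    catalytic_positions,
    n_random_low: int,
    low_score: float = 0.01,
    rng: np.random.Generator | None = None,
) -> KnowledgeMap:
    """Score-1 catalytic sites plus a random sample of low-score positions.

    Positions are 0-based. Exactly ``n_random_low`` distinct non-catalytic
    positions, drawn uniformly, get ``low_score`` and mask 1; the remaining
    unlabeled positions are masked out (excluded from any distance).
    """
    rng = rng or np.random.default_rng()
    catalytic = np.asarray(sorted(set(int(p) for p in catalytic_positions)), dtype=int)
    if len(catalytic) and (catalytic.min() < 0 or catalytic.max() >= seq_length):
        raise ValidationError(
            f"catalytic positions must lie in [0, {seq_length}), got {catalytic.tolist()}"
        )
    free = np.setdiff1d(np.arange(seq_length), catalytic)
    if n_random_low > len(free):
        raise ValidationError(
            f"cannot place {n_random_low} low-score positions among {len(free)} unlabeled ones"
        )
    scores = np.zeros(seq_length)
    mask = np.zeros(seq_length)
    scores[catalytic] = 1.0
    mask[catalytic] = 1.0
    if n_random_low:
        low = rng.choice(free, size=n_random_low, replace=False)
        scores[low] = low_score
        mask[low] = 1.0
    return KnowledgeMap(tuple(range(seq_length)), scores, mask, Provenance.CATALYTIC)


def rerandomize_low_scores(km: KnowledgeMap, rng: np.random.Generator) -> KnowledgeMap:
    """Redraw the low-score support among unlabeled positions (per epoch).

    The score-1 (catalytic) support never moves; the low-score support is
    redrawn with the same cardinality and score value from the non-catalytic
    positions, letting unlabeled residues take turns being dampened.
    """
    if km.provenance != Provenance.CATALYTIC:
        raise ValidationError("rerandomize_low_scores requires a catalytic knowledge map")
    catalytic = np.flatnonzero((km.mask == 1) & (km.scores == 1.0))
    low = np.flatnonzero((km.mask == 1) & (km.scores != 1.0))
    if len(low) == 0:
        return km
    low_score = float(km.scores[low[0]])
    free = np.setdiff1d(np.arange(len(km)), catalytic)
    new_low = rng.choice(free, size=len(low), replace=False)
    scores = np.zeros(len(km))
    mask = np.zeros(len(km))
    scores[catalytic] = 1.0
    mask[catalytic] = 1.0
    scores[new_low] = low_score
    mask[new_low] = 1.0
    return replace(km, scores=scores, mask=mask)


def random_control_knowledge_map(
    seq_length: int, n_sites: int, rng: np.random.Generator | None = None
) -> KnowledgeMap:
    """Score-1 mask at ``n_sites`` uniformly random positions (Ran control)."""
    rng = rng or np.random.default_rng()
    if n_sites > seq_length:
        raise ValidationError(f"n_sites {n_sites} exceeds sequence length {seq_length}")
    scores = np.zeros(seq_length)
    mask = np.zeros(seq_length)
    if n_sites:
        sites = rng.choice(seq_length, size=n_sites, replace=False)
        scores[sites] = 1.0
        mask[sites] = 1.0
    return KnowledgeMap(tuple(range(seq_length)), scores, mask, Provenance.RANDOM_CONTROL)
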