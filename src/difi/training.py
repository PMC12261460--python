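"""Seeded training loops, stratified splits and grid search.

The loop wires the configured objective, refreshes catalytic knowledge maps
at every epoch start (only the low-score support moves; the labeled sites
are asserted unchanged each epoch), logs both loss components, and selects
the model state with the best validation error.

Two independent RNG streams are derived from the seed — one for data
shuffling, one for knowledge-map refreshes — so enabling or disabling the
similarity term never perturbs the batch order. With ``alpha == 0`` (or no
mode) the loop is bit-identical to a plain supervised baseline under the
same seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from autograd import value_and_grad
from sklearn.model_selection import train_test_split

from .config import DIFIConfig
from .errors import DivergenceError, ValidationError
from .evaluation import classification_error
from .knowledge_maps import KnowledgeMap, Provenance, rerandomize_low_scores
from .losses import cross_entropy_value, objective
from .nn import Adam

#: offsets mixed into the seed for the auxiliary RNG streams
_KM_STREAM = 0xD1F1
_AUG_STREAM = 0xA6A6


@dataclass
class LabeledDataset:
    """Samples, labels and their knowledge-map assignments.

    Expression tasks attach maps per class (``km_by_class``); protein tasks
    attach maps per sample (``km_by_sample``, ``None`` for samples carrying
    no knowledge). ``sequences`` optionally keeps the raw residue strings
    alongside their one-hot encodings.
    """

    x: np.ndarray
    y: np.ndarray
    km_by_class: dict | None = None
    km_by_sample: list | None = None
    sequences: list | None = None
    feature_ids: tuple | None = None
    #: per-sample position sets that augmentation must never touch
    #: (e.g. ground-truth sites of a synthetic benchmark)
    protected_positions: list | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        if len(self.x) != len(self.y):
            raise ValidationError("x and y must have equal length")
        if self.km_by_sample is not None and len(self.km_by_sample) != len(self.y):
            raise ValidationError("km_by_sample must align with samples")
        if (self.protected_positions is not None
                and len(self.protected_positions) != len(self.y)):
            raise ValidationError("protected_positions must align with samples")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            x=self.x[indices],
            y=self.y[indices],
            km_by_class=self.km_by_class,
            km_by_sample=None if self.km_by_sample is None
            else [self.km_by_sample[i] for i in indices],
            sequences=None if self.sequences is None
            else [self.sequences[i] for i in indices],
            feature_ids=self.feature_ids,
            protected_positions=None if self.protected_positions is None
            else [self.protected_positions[i] for i in indices],
        )


def split_dataset(ds: LabeledDataset, seed: int,
                  fractions: tuple[float, float, float] = (0.72, 0.18, 0.10)):
    """Stratified 72/18/10 train/validation/test split.

    Implemented as a 90/10 split followed by carving 20% of the training
    portion into validation. Deterministic under the seed; partitions are
    disjoint and their union is the full set.
    """
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValidationError("split fractions must sum to 1")
    y = ds.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        raise ValidationError(
            f"every class needs >= 10 samples to stratify; smallest has {counts.min()}"
        )
    idx = np.arange(len(ds))
    trainval_idx, test_idx = train_test_split(
        idx, test_size=f_test, stratify=y, random_state=seed
    )
    val_share = f_val / (f_train + f_val)
    train_idx, val_idx = train_test_split(
        trainval_idx, test_size=val_share, stratify=y[trainval_idx], random_state=seed
    )
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx)


@dataclass
class TrainRun:
    """Record of one training run: per-epoch history and the selected model."""

    config: dict
    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_error: float = float("inf")
    seed: int = 0
    model: object = None
    final_params: list | None = None

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def _refresh_catalytic_maps(km_by_sample, rng) -> None:
    """Per-epoch re-randomization of low-score supports, in place.

    Asserts every epoch that the labeled (score-1) sites never move.
    """
    for i, km in enumerate(km_by_sample):
        if km is None or km.provenance != Provenance.CATALYTIC:
            continue
        refreshed = rerandomize_low_scores(km, rng)
        before = np.flatnonzero(km.scores == 1.0)
        after = np.flatnonzero(refreshed.scores == 1.0)
        if not np.array_equal(before, after):  # pragma: no cover - invariant guard
            raise ValidationError("knowledge-map refresh moved a labeled site")
        km_by_sample[i] = refreshed


def _substitute_residues(x_batch: np.ndarray, n_sub: int, rng,
                         protected=None, alanine_index: int = 0) -> np.ndarray:
    """Alanine-block substitution noise for one-hot samples (augmentation).

    Each sample gets one contiguous block of up to ``n_sub`` residues
    replaced by alanine, mimicking the alanine-scanning perturbation so that
    alanine runs are in-distribution and carry no class evidence of their
    own. ``protected`` positions (per sample) are never substituted, so the
    noise cannot silently corrupt label-defining sites.
    """
    x_batch = x_batch.copy()
    for s, sample in enumerate(x_batch):
        real = np.flatnonzero(sample.sum(axis=0) > 0)
        if len(real) == 0:
            continue
        length = int(real.max()) + 1
        start = int(rng.integers(0, max(length - n_sub + 1, 1)))
        block = [p for p in range(start, min(start + n_sub, length))
                 if protected is None or p not in protected[s]]
        if not block:
            continue
        sample[:, block] = 0.0
        sample[alanine_index, block] = 1.0
    return x_batch


def train(
    model,
    train_ds: LabeledDataset,
    val_ds: LabeledDataset,
    cfg: DIFIConfig,
    epochs: int,
    batch_size: int,
    seed: int,
    lr: float = 1e-3,
    teacher=None,
    augment_substitutions: int = 0,
) -> TrainRun:
    """Mini-batch Adam training with the configured objective.

    Per-epoch history records the cross-entropy term, the (alpha-weighted)
    similarity term and the validation error. The model is left holding the
    parameters of the epoch with the lowest validation error (ties to the
    earlier epoch); the last-epoch parameters are kept in ``final_params``.

    ``augment_substitutions`` > 0 re-draws that many residues per one-hot
    training sample each time it is visited (substitution-noise robustness
    training); it uses its own RNG stream and applies identically under
    every objective, so mode comparisons stay seed-matched.
    """
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    if augment_substitutions and model.input_kind != "one_hot":
        raise ValidationError("substitution augmentation requires one-hot inputs")
    rng_data = np.random.default_rng(seed)
    rng_km = np.random.default_rng((seed, _KM_STREAM))
    rng_aug = np.random.default_rng((seed, _AUG_STREAM))
    opt = Adam(model.params, lr=lr)
    km_by_sample = None if train_ds.km_by_sample is None else list(train_ds.km_by_sample)
    run = TrainRun(
        config=dict(cfg.to_dict(), epochs=epochs, batch_size=batch_size, lr=lr),
        seed=seed, model=model,
    )
    best_params = [p.copy() for p in model.params]
    plain = cfg.mode is None or (cfg.mode != "transfer" and cfg.alpha == 0)

    for epoch in range(epochs):
        if km_by_sample is not None:
            _refresh_catalytic_maps(km_by_sample, rng_km)
        perm = rng_data.permutation(len(train_ds))
        ce_acc, sim_acc, n_batches = 0.0, 0.0, 0
        for start in range(0, len(perm), batch_size):
            batch = perm[start:start + batch_size]
            xb, yb = train_ds.x[batch], train_ds.y[batch]
            if augment_substitutions:
                prot = (None if train_ds.protected_positions is None
                        else [train_ds.protected_positions[i] for i in batch])
                xb = _substitute_residues(xb, augment_substitutions, rng_aug, prot)
            kml = None if km_by_sample is None else [km_by_sample[i] for i in batch]

            def loss_fn(p):
                return objective(model, xb, yb, cfg, km_lookup=train_ds.km_by_class,
                                 km_list=kml, teacher=teacher, params=p)

            loss_val, grads = value_and_grad(loss_fn)(model.params)
            loss_val = float(loss_val)
            if not np.isfinite(loss_val):
                raise DivergenceError(
                    f"non-finite loss {loss_val} at epoch {epoch} batch {n_batches} "
                    f"(config {cfg.to_dict()})"
                )
            ce_val = loss_val if plain else cross_entropy_value(model, xb, yb)
            model.params = opt.step(model.params, grads)
            ce_acc += ce_val
            sim_acc += loss_val - ce_val
            n_batches += 1

        val_error = classification_error(model, val_ds.x, val_ds.y)
        run.history.append(dict(
            epoch=epoch,
            loss=(ce_acc + sim_acc) / n_batches,
            ce=ce_acc / n_batches,
            similarity=sim_acc / n_batches,
            val_error=val_error,
        ))
        if val_error < run.best_val_error:
            run.best_val_error = val_error
            run.best_epoch = epoch
            best_params = [p.copy() for p in model.params]

    run.final_params = model.params
    model.params = best_params
    return run


def grid_search(space: dict, evaluate, base_cfg: DIFIConfig | None = None):
    """Exhaustive search over a config-field grid.

    ``space`` maps DIFIConfig field names to candidate value lists;
    ``evaluate`` is a callable ``cfg -> validation error`` closing over the
    datasets and seed. Returns ``(best_cfg, table)`` where the table has one
    row per combination. Best = minimal validation error; ties prefer the
    smaller alpha, then the earlier row.
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValidationError("search space must be nonempty")
    base_cfg = base_cfg or DIFIConfig()
    keys = sorted(space)
    rows = []
    best = None
    for combo in itertools.product(*(space[k] for k in keys)):
        cfg = base_cfg.with_(**dict(zip(keys, combo)))
        err = float(evaluate(cfg))
        rows.append(dict(zip(keys, combo), val_error=err))
        key = (err, cfg.alpha)
        if best is None or key < best[0]:
            best = (key, cfg)
    table = pd.DataFrame(rows)
    return best[1], table
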