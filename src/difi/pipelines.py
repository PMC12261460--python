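"""End-to-end task assembly shared by the CLI and the evaluation scripts.

These helpers wire generators/readers, knowledge-map builders, splits and
the training loop into the two reference tasks (expression and protein) so
that callers only choose a config and a seed. Knowledge maps are always
derived from the training portion only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DIFIConfig
from .errors import ValidationError
from .knowledge_maps import (
    build_catalytic_knowledge_map,
    build_expression_knowledge_map,
    dge_scores,
    random_control_knowledge_map,
)
from .models import (
    ClassifierSpec,
    encode_one_hot,
    make_classifier,
)
from .training import LabeledDataset, split_dataset, train


def prepare_expression_datasets(
    expr: pd.DataFrame,
    labels,
    n_biomarkers: int,
    seed: int,
    p_threshold: float = 0.05,
    center: bool = False,
):
    """Split, run one-vs-rest DGE on the training portion, attach class maps.

    With ``center`` the expression values fed to the model are centered per
    gene using training-split means (differential expression always runs on
    the raw log-scale values); centering removes large constant per-gene
    offsets that a shared-kernel convolution cannot absorb.
    """
    labels = np.asarray(labels)
    ds = LabeledDataset(expr.to_numpy(dtype=float), labels,
                        feature_ids=tuple(expr.columns))
    train_ds, val_ds, test_ds = split_dataset(ds, seed)
    train_frame = pd.DataFrame(train_ds.x, columns=expr.columns)
    km_by_class = {}
    for c in np.unique(labels):
        dge = dge_scores(train_frame, train_ds.y, c)
        km_by_class[c] = build_expression_knowledge_map(dge, n_biomarkers, p_threshold)
    if center:
        mu = train_ds.x.mean(axis=0)
        for part in (train_ds, val_ds, test_ds):
            part.x = part.x - mu
    for part in (train_ds, val_ds, test_ds):
        part.km_by_class = km_by_class
    return train_ds, val_ds, test_ds


def prepare_protein_datasets(
    records,
    labels,
    sites: dict,
    seed: int,
    max_len: int,
    n_random_low: int,
    random_control: bool = False,
    low_score: float = 0.01,
):
    """Encode sequences, attach per-sample catalytic (or control) maps, split.

    ``sites`` maps positive accessions to 0-based catalytic positions. With
    ``random_control`` the per-sample maps place the same number of score-1
    sites uniformly at random instead (the negative control); no low scores
    are drawn in that case.
    """
    labels = np.asarray(labels)
    if len(records) != len(labels):
        raise ValidationError("records and labels must align")
    rng = np.random.default_rng((seed, 0xC0DE))
    x = np.stack([encode_one_hot(seq, max_len) for _, seq in records])
    km_by_sample = []
    sequences = []
    protected = []
    for (acc, seq), label in zip(records, labels):
        sequences.append(seq)
        true_positions = [p for p in sites.get(acc, ()) if p < max_len]
        protected.append(set(true_positions))
        if label == 1 and acc in sites:
            if random_control:
                km = random_control_knowledge_map(max_len, len(true_positions), rng)
            else:
                km = build_catalytic_knowledge_map(
                    max_len, true_positions, n_random_low, low_score, rng
                )
            km_by_sample.append(km)
        else:
            km_by_sample.append(None)
    ds = LabeledDataset(x, labels, km_by_sample=km_by_sample, sequences=sequences,
                        protected_positions=protected)
    return split_dataset(ds, seed)


def run_expression_training(
    expr, labels, cfg: DIFIConfig, seed: int,
    n_biomarkers: int = 3, epochs: int = 10, batch_size: int = 128,
    lr: float = 1e-3, size_preset: str = "student",
):
    """Train the 1-D expression CNN under ``cfg``; returns (run, test_ds)."""
    train_ds, val_ds, test_ds = prepare_expression_datasets(
        expr, labels, n_biomarkers, seed
    )
    spec = ClassifierSpec(
        "cnn1d_expression", n_classes=len(np.unique(labels)),
        input_shape=(expr.shape[1],), size_preset=size_preset,
    )
    model = make_classifier(spec, seed=seed)
    run = train(model, train_ds, val_ds, cfg, epochs, batch_size, seed, lr=lr)
    return run, test_ds


def run_protein_training(
    records, labels, sites, cfg: DIFIConfig, seed: int,
    max_len: int, epochs: int = 8, batch_size: int = 64, lr: float = 1e-3,
    width: int = 8, random_control: bool = False, augment_substitutions: int = 0,
):
    """Train the sequence ResNet under ``cfg``; returns (run, test_ds)."""
    n_random_low = cfg.n_random_low if cfg.n_random_low is not None else 0
    train_ds, val_ds, test_ds = prepare_protein_datasets(
        records, labels, sites, seed, max_len, n_random_low,
        random_control=random_control,
    )
    spec = ClassifierSpec(
        "resnet_sequence", n_classes=2, input_shape=(20, max_len),
        taps=("group3", "group4"), width=width,
    )
    model = make_classifier(spec, seed=seed)
    run = train(model, train_ds, val_ds, cfg, epochs, batch_size, seed, lr=lr,
                augment_substitutions=augment_substitutions)
    return run, test_ds
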