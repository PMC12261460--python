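"""Reference classifier families with input-gradient support and activation taps.

Three families:

* ``cnn1d_expression`` — shallow 1-D CNN over a flat gene-expression vector:
  1-D kernels, max pooling over the (channel x position) plane of the conv
  output, then fully connected layers. ``teacher``/``student`` presets differ
  in width (teacher strictly larger).
* ``resnet_sequence`` — residual network over one-hot protein sequences:
  four groups of convolutional layers, two residual blocks per group, skip
  connections bypassing two convolutions. Activation taps are exposed after
  groups 3 and 4.
* ``tiny_cnn`` — a minimal two-layer model for gradient-oracle tests.

All families are pure functions of ``(params, x)`` and therefore support
gradients with respect to the input as well as higher-order terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from . import nn
from .errors import EncodingError, ValidationError

#: canonical amino-acid alphabet (padding is the all-zero column)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: default maximum protein length; longer sequences keep the N-terminal prefix
MAX_PROTEIN_LENGTH = 300


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of a classifier instance."""

    family: str  # cnn1d_expression | resnet_sequence | tiny_cnn
    n_classes: int
    input_shape: tuple[int, ...]  # (n_genes,) or (alphabet, max_len)
    size_preset: str = "student"  # teacher | student
    taps: tuple[str, ...] = ()
    width: int | None = None  # overrides the preset base width

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.family not in ("cnn1d_expression", "resnet_sequence", "tiny_cnn"):
            raise ValidationError(f"unknown model family: {self.family!r}")
        if self.size_preset not in ("teacher", "student"):
            raise ValidationError(f"unknown size preset: {self.size_preset!r}")


def encode_one_hot(sequence: str, max_len: int = MAX_PROTEIN_LENGTH) -> np.ndarray:
    """One-hot encode a residue string to shape (20, max_len).

    Exactly one 1 per real-residue column; padding columns are all zero.
    Sequences longer than ``max_len`` are truncated to the N-terminal prefix.
    Mixed case is normalised to upper. Symbols outside the 20-letter alphabet
    raise :class:`EncodingError` naming the offending position (0-based).
    """
    sequence = sequence.upper()[:max_len]
    out = np.zeros((len(AMINO_ACIDS), max_len))
    for pos, res in enumerate(sequence):
        idx = _AA_INDEX.get(res)
        if idx is None:
            raise EncodingError(
                f"illegal residue {res!r} at position {pos} (alphabet {AMINO_ACIDS})"
            )
        out[idx, pos] = 1.0
    return out


def decode_one_hot(encoded: np.ndarray) -> str:
    """Inverse of :func:`encode_one_hot` (padding columns terminate)."""
    chars = []
    for col in range(encoded.shape[1]):
        column = encoded[:, col]
        if not column.any():
            break
        chars.append(AMINO_ACIDS[int(np.argmax(column))])
    return "".join(chars)


class Classifier:
    """Base class: a parameter list plus a pure forward function."""

    input_kind: str  # 'vector' | 'one_hot'

    def __init__(self, spec: ClassifierSpec, params: list[np.ndarray]):
        self.spec = spec
        self.params = params

    # -- pure functions (differentiable) ------------------------------------
    def forward(self, params, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def forward_with_taps(self, params, x):
        """Default: no taps."""
        return self.forward(params, x), {}

    # -- convenience wrappers ----------------------------------------------
    @property
    def n_features(self) -> int:
        """Length of the input feature axis (genes, or residue positions)."""
        return self.spec.input_shape[-1]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(self.params, np.atleast_2d(x) if self.input_kind == "vector" else x)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == (1 if self.input_kind == "vector" else 2):
            x = x[None]
        preds = []
        for start in range(0, len(x), batch_size):
            preds.append(np.argmax(self.forward(self.params, x[start:start + batch_size]), axis=1))
        return np.concatenate(preds)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, *self.params)
        meta = dict(
            family=self.spec.family, n_classes=self.spec.n_classes,
            input_shape=list(self.spec.input_shape), size_preset=self.spec.size_preset,
            taps=list(self.spec.taps), width=self.spec.width,
        )
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "Classifier":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        spec = ClassifierSpec(
            family=meta["family"], n_classes=meta["n_classes"],
            input_shape=tuple(meta["input_shape"]), size_preset=meta["size_preset"],
            taps=tuple(meta["taps"]), width=meta["width"],
        )
        model = make_classifier(spec, seed=0)
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
            model.params = [data[k] for k in data.files]
        return model


# ---------------------------------------------------------------------------
# expression CNN


class ExpressionCNN(Classifier):
    """Shallow 1-D CNN over a gene-expression vector.

    conv1d -> relu -> max pool over the (channel x position) plane ->
    [optional hidden dense] -> dense -> logits.
    """

    input_kind = "vector"

    _PRESETS = {
        # channels, kernel, stride, pool (chan, pos), hidden width
        "teacher": dict(channels=32, kernel=9, stride=2, pool=(2, 2), hidden=256),
        "student": dict(channels=8, kernel=9, stride=4, pool=(2, 2), hidden=None),
    }

    def __init__(self, spec: ClassifierSpec, seed: int):
        hp = dict(self._PRESETS[spec.size_preset])
        if spec.width is not None:
            hp["channels"] = spec.width
        d = spec.input_shape[0]
        if d < hp["kernel"]:
            raise ValidationError(f"input length {d} shorter than kernel {hp['kernel']}")
        self.hp = hp
        rng = np.random.default_rng(seed)
        c, k, s = hp["channels"], hp["kernel"], hp["stride"]
        n_conv_out = (d - k) // s + 1
        n_flat = (c // hp["pool"][0]) * (n_conv_out // hp["pool"][1])
        params = [
            nn.he_normal(rng, (c, 1, k), fan_in=k),
            np.zeros(c),
        ]
        # final layer starts at zero so initial logits are uninformative
        if hp["hidden"]:
            params += [
                nn.he_normal(rng, (n_flat, hp["hidden"]), fan_in=n_flat),
                np.zeros(hp["hidden"]),
                np.zeros((hp["hidden"], spec.n_classes)),
                np.zeros(spec.n_classes),
            ]
        else:
            params += [
                np.zeros((n_flat, spec.n_classes)),
                np.zeros(spec.n_classes),
            ]
        super().__init__(spec, params)

    def forward(self, params, x):
        hp = self.hp
        h = anp.reshape(x, (x.shape[0], 1, x.shape[1]))
        h = nn.relu(nn.conv1d(h, params[0], params[1], stride=hp["stride"]))
        h = nn.max_pool_plane(h, *hp["pool"])
        h = nn.flatten(h)
        if hp["hidden"]:
            h = nn.relu(nn.dense(h, params[2], params[3]))
            return nn.dense(h, params[4], params[5])
        return nn.dense(h, params[2], params[3])


# ---------------------------------------------------------------------------
# sequence ResNet


class SequenceResNet(Classifier):
    """Residual CNN over one-hot sequences with taps after groups 3 and 4.

    Four groups of convolutional layers, each holding two residual blocks;
    a skip connection bypasses the two convolutions of every block. Groups
    2-4 halve the spatial length and double the channel width. The head is a
    global average pool followed by a dense layer.
    """

    input_kind = "one_hot"
    TAPS = ("group3", "group4")

    def __init__(self, spec: ClassifierSpec, seed: int):
        base = spec.width or 8
        alpha_size, length = spec.input_shape
        rng = np.random.default_rng(seed)
        self.base = base
        params: list[np.ndarray] = [
            nn.he_normal(rng, (base, alpha_size, 5), fan_in=alpha_size * 5),
            np.zeros(base),
        ]
        self._layout: list[tuple] = []  # (group, block, downsample?)
        c_in = base
        for group in range(1, 5):
            c_out = base * (2 ** (group - 1))
            for block in range(2):
                down = group > 1 and block == 0
                # two 3-wide convs per block
                params += [
                    nn.he_normal(rng, (c_out, c_in, 3), fan_in=c_in * 3),
                    np.zeros(c_out),
                    nn.he_normal(rng, (c_out, c_out, 3), fan_in=c_out * 3),
                    np.zeros(c_out),
                ]
                if down:
                    # 1x1 projection on the skip path
                    params += [nn.he_normal(rng, (c_out, c_in, 1), fan_in=c_in), np.zeros(c_out)]
                self._layout.append((group, block, down))
                c_in = c_out
        self.head_channels = c_in
        # zero-init head keeps the initial loss at log(n_classes)
        params += [
            np.zeros((c_in, spec.n_classes)),
            np.zeros(spec.n_classes),
        ]
        super().__init__(spec, params)

    def forward_with_taps(self, params, x):
        h = nn.relu(nn.conv1d(x, params[0], params[1], stride=1, padding=2))
        i = 2
        taps = {}
        for group, block, down in self._layout:
            stride = 2 if down else 1
            w1, b1, w2, b2 = params[i], params[i + 1], params[i + 2], params[i + 3]
            i += 4
            out = nn.relu(nn.conv1d(h, w1, b1, stride=stride, padding=1))
            out = nn.conv1d(out, w2, b2, stride=1, padding=1)
            if down:
                ws, bs = params[i], params[i + 1]
                i += 2
                shortcut = nn.conv1d(h, ws, bs, stride=2, padding=0)
            else:
                shortcut = h
            h = nn.relu(out + shortcut)
            if block == 1 and f"group{group}" in self.TAPS:
                taps[f"group{group}"] = h
        logits = nn.dense(nn.global_avg_pool(h), params[i], params[i + 1])
        return logits, taps

    def forward(self, params, x):
        return self.forward_with_taps(params, x)[0]


# ---------------------------------------------------------------------------
# tiny model for oracles


class TinyCNN(Classifier):
    """Two-layer model (conv -> dense) over short vectors; for gradient tests."""

    input_kind = "vector"

    def __init__(self, spec: ClassifierSpec, seed: int):
        d = spec.input_shape[0]
        rng = np.random.default_rng(seed)
        c, k = spec.width or 4, 3
        n_out = d - k + 1
        params = [
            nn.he_normal(rng, (c, 1, k), fan_in=k),
            np.zeros(c),
            nn.he_normal(rng, (c * n_out, spec.n_classes), fan_in=c * n_out),
            np.zeros(spec.n_classes),
        ]
        super().__init__(spec, params)

    def forward(self, params, x):
        h = anp.reshape(x, (x.shape[0], 1, x.shape[1]))
        h = nn.relu(nn.conv1d(h, params[0], params[1]))
        return nn.dense(nn.flatten(h), params[2], params[3])


# ---------------------------------------------------------------------------
# factories


def make_expression_cnn(spec: ClassifierSpec, seed: int = 0) -> ExpressionCNN:
    if spec.family != "cnn1d_expression":
        raise ValidationError(f"expected family cnn1d_expression, got {spec.family}")
    return ExpressionCNN(spec, seed)


def make_sequence_resnet(spec: ClassifierSpec, seed: int = 0) -> SequenceResNet:
    if spec.family != "resnet_sequence":
        raise ValidationError(f"expected family resnet_sequence, got {spec.family}")
    return SequenceResNet(spec, seed)


def make_classifier(spec: ClassifierSpec, seed: int = 0) -> Classifier:
    if spec.family == "cnn1d_expression":
        return ExpressionCNN(spec, seed)
    if spec.family == "resnet_sequence":
        return SequenceResNet(spec, seed)
    return TinyCNN(spec, seed)
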