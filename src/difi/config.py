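"""Run configuration for the knowledge-regularized objectives."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml

from .errors import ValidationError

MODES = ("gradient", "activation", "transfer")
METRICS = ("l2_squared", "cosine")


@dataclass(frozen=True)
class DIFIConfig:
    """Which objective to train with, and its knobs.

    mode
        ``gradient`` | ``activation`` | ``transfer`` | ``None`` (plain
        cross-entropy baseline).
    alpha
        Nonnegative weight of the feature-map/knowledge-map similarity term.
        The transfer objective carries no printed coefficient; ``alpha``
        defaults to 1 there.
    metric
        ``l2_squared`` or ``cosine`` (penalty = 1 - cosine similarity).
    tap
        Activation tap for ``activation`` mode (e.g. ``group3``).
    sparsity_percent
        Teacher-saliency percentile kept in ``transfer`` mode.
    n_random_low
        Number of low-score positions drawn per catalytic knowledge map.
    normalize_maps
        Optional per-sample unit-normalisation of both maps before the
        distance (off by default: raw vectors, as printed).
    """

    mode: str | None = None
    alpha: float = 1.0
    metric: str = "l2_squared"
    tap: str | None = None
    sparsity_percent: float | None = None
    n_random_low: int | None = None
    normalize_maps: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode is not None and self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES} or None, got {self.mode!r}")
        if not (self.alpha >= 0):
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.sparsity_percent is not None and not (0 < self.sparsity_percent <= 100):
            raise ValidationError("sparsity_percent must lie in (0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "DIFIConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "DIFIConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_(self, **kwargs) -> "DIFIConfig":
        return replace(self, **kwargs)
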