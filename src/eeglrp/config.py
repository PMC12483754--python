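"""Run configuration and network hyperparameters.

Defaults reproduce the reference analysis settings: learning rate 0.001,
dropout 0.5, batch size 2, 200 epochs, a 4:1 train:validation split inside
each leave-one-out fold, ten channel-count settings and eight data lengths
(an 80-cell evaluation grid).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_CHANNEL_COUNTS = (1, 2, 3, 4, 5, 10, 15, 20, 25, 62)
DEFAULT_DATA_LENGTHS_S = (10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


@dataclass(frozen=True)
class NetSpec:
    """Shallow ConvNet dimensions.

    Temporal convolution (``n_temporal_filters`` kernels of
    ``temporal_kernel`` samples per channel), spatial convolution collapsing
    the channel axis, ReLU, mean pooling, dropout, dense softmax output.
    The defaults are the reference shallow architecture's dimensions at
    200 Hz: 40 temporal filters of 25 samples (0.125 s), 40 spatial filters,
    pooling 75 samples with stride 15.
    """

    n_temporal_filters: int = 40
    temporal_kernel: int = 25
    n_spatial_filters: int = 40
    pool_length: int = 75
    pool_stride: int = 15
    dropout: float = 0.5
    activation: str = "relu"  # "relu" (as stated) or "square_log" variant
    n_classes: int = 2

    def __post_init__(self) -> None:
        if min(self.n_temporal_filters, self.n_spatial_filters) < 1:
            raise ValueError("filter counts must be positive")
        if self.temporal_kernel < 1 or self.pool_length < 1 or self.pool_stride < 1:
            raise ValueError("kernel/pool dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.activation not in ("relu", "square_log"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.n_classes != 2:
            raise ValueError("binary diagnosis only: n_classes must be 2")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run."""

    learning_rate: float = 0.001
    dropout: float = 0.5
    batch_size: int = 2
    epochs: int = 200
    val_fraction: float = 0.2  # 4:1 train:validation
    channel_counts: tuple[int, ...] = DEFAULT_CHANNEL_COUNTS
    data_lengths_s: tuple[float, ...] = DEFAULT_DATA_LENGTHS_S
    lrp_epsilon: float = 1e-6  # scale of the stabiliser, relative to mean |z|
    seed: int = 0
    net: NetSpec = field(default_factory=NetSpec)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.lrp_epsilon <= 0:
            raise ValueError("lrp_epsilon must be positive")
        if any(k < 1 for k in self.channel_counts):
            raise ValueError("channel counts must be >= 1")
        if any(l <= 0 for l in self.data_lengths_s):
            raise ValueError("data lengths must be positive")
        object.__setattr__(self, "channel_counts", tuple(int(k) for k in self.channel_counts))
        object.__setattr__(self, "data_lengths_s", tuple(float(l) for l in self.data_lengths_s))

    def net_spec(self) -> NetSpec:
        """The network spec with this run's dropout applied."""
        return dataclasses.replace(self.net, dropout=self.dropout)

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_counts"] = list(self.channel_counts)
        d["data_lengths_s"] = list(self.data_lengths_s)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "net" in d and isinstance(d["net"], dict):
            net_known = {f.name for f in dataclasses.fields(NetSpec)}
            bad = set(d["net"]) - net_known
            if bad:
                raise ValueError(f"unknown net config keys: {sorted(bad)}")
            d["net"] = NetSpec(**d["net"])
        for key in ("channel_counts", "data_lengths_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)
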