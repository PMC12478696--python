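"""Model configuration and feature-map geometry.

Defaults reproduce the published hyperparameter set: 128 convolution
filters of width 40, non-overlapping max pooling 20/20, dropout 0.5, a
16-head transformer block with feed-forward widths 255 -> 128, a 246-wide
hierarchical attention layer, one sigmoid output unit and batch size 64.
Under these defaults a 3000-bp enhancer branch pools to 148 positions and a
2000-bp promoter branch to 98, so the merged representation (and every
attention head) spans 246 positions.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import yaml


class ConfigError(ValueError):
    pass


def pooled_length(L: int, kernel: int, pool: int, stride: int) -> int:
    """Position-axis length after valid-padding stride-1 convolution (kernel
    width ``kernel``) followed by max pooling (window ``pool``, stride
    ``stride``):  floor(((L - kernel + 1) - pool) / stride) + 1.
    """
    if L < kernel:
        raise ConfigError(f"input length {L} shorter than kernel {kernel}")
    if pool < 1 or stride < 1:
        raise ConfigError("pool and stride must be >= 1")
    conv_len = L - kernel + 1
    if conv_len < pool:
        raise ConfigError(f"conv output {conv_len} shorter than pool window {pool}")
    return (conv_len - pool) // stride + 1


@dataclass
class ModelConfig:
    """Every tunable of the network plus derived geometry.

    All fields are overridable so scaled-down configurations (short
    sequences, few filters) remain valid for CPU-sized experiments; the
    invariants (ffn_dense2 == conv_filters for the residual add,
    conv_filters divisible by n_heads) are checked in :meth:`validate`.
    """

    enh_len: int = 3000
    prom_len: int = 2000
    conv_filters: int = 128
    conv_kernel: int = 40
    pool_size: int = 20
    pool_stride: int = 20
    dropout: float = 0.5
    n_heads: int = 16
    ffn_dense1: int = 255
    ffn_dense2: int = 128
    attn_hidden: int = 246
    output_units: int = 1
    batch_size: int = 64
    encoding: str = "onehot"          # {"onehot", "dna2vec"}
    kmer_k: int = 6
    embed_dim: int = 100
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.conv_filters % self.n_heads != 0:
            raise ConfigError(
                f"conv_filters ({self.conv_filters}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.ffn_dense2 != self.conv_filters:
            raise ConfigError(
                f"ffn_dense2 ({self.ffn_dense2}) must equal conv_filters "
                f"({self.conv_filters}) for the residual add"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0,1), got {self.dropout}")
        if self.encoding not in ("onehot", "dna2vec"):
            raise ConfigError(f"unknown encoding {self.encoding!r}")
        # geometry must be realizable
        self.enh_pooled_len
        self.prom_pooled_len

    # ----- derived geometry -------------------------------------------------

    @property
    def input_channels(self) -> int:
        return 4 if self.encoding == "onehot" else self.embed_dim

    def _branch_input_len(self, seq_len: int) -> int:
        if self.encoding == "onehot":
            return seq_len
        return seq_len - self.kmer_k + 1

    @property
    def enh_pooled_len(self) -> int:
        return pooled_length(self._branch_input_len(self.enh_len),
                             self.conv_kernel, self.pool_size, self.pool_stride)

    @property
    def prom_pooled_len(self) -> int:
        return pooled_length(self._branch_input_len(self.prom_len),
                             self.conv_kernel, self.pool_size, self.pool_stride)

    @property
    def merged_len(self) -> int:
        return self.enh_pooled_len + self.prom_pooled_len

    @property
    def head_dim(self) -> int:
        return self.conv_filters // self.n_heads

    # ----- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ModelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


def scaled_test_config(**overrides) -> ModelConfig:
    """A small CPU-friendly configuration used throughout the test suite:
    300/200 bp inputs, 16 filters of width 8, pooling 4/4, 4 heads."""
    base = dict(
        enh_len=300, prom_len=200,
        conv_filters=16, conv_kernel=8, pool_size=4, pool_stride=4,
        n_heads=4, ffn_dense1=32, ffn_dense2=16, attn_hidden=32,
        dropout=0.1, batch_size=64,
    )
    base.update(overrides)
    return ModelConfig(**base)
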