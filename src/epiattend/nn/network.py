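"""The interaction network: two conv/pool branches, merge, transformer
block, hierarchical attention, sigmoid output.

Per branch (enhancer E of 3000 bp, promoter P of 2000 bp under defaults):

    Eo = MaxPool(ReLU(Conv(Embed(E))))        # (L_enh, filters), 148 x 128
    Po = MaxPool(ReLU(Conv(Embed(P))))        # (L_prom, filters),  98 x 128
    M  = concat(Eo, Po) along positions       # (246, 128), enhancer rows first

then one transformer block

    H = LN2( FFN(LN1(MHA(M) + M)) + LN1(MHA(M) + M) )

with dropout after the merge, after the attention and after the FFN, and a
hierarchical-attention readout producing a single vector S that a one-unit
sigmoid layer maps to the interaction probability.  The embedding tables
(one-hot lookup or k-mer vectors) are frozen: they are not Parameters and
never receive updates.
"""

from __future__ import annotations

import numpy as np

from ..config import ModelConfig
from ..encodings import NucleotideLookup, KmerVectorTable, seq_to_indices, embed_onehot
from .layers import (
    Conv1D, MaxPool1D, Dense, Dropout, LayerNorm,
    MultiHeadSelfAttention, HierarchicalAttention, Parameter, sigmoid,
)


class EPINetwork:
    """Callable network with explicit forward/backward for training on CPU."""

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 kmer_table: KmerVectorTable | None = None,
                 dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        self.lookup = NucleotideLookup()
        if cfg.encoding == "dna2vec":
            if kmer_table is None:
                raise ValueError("dna2vec encoding requires a KmerVectorTable")
            if kmer_table.dim != cfg.embed_dim:
                raise ValueError(
                    f"k-mer table width {kmer_table.dim} != configured embed_dim {cfg.embed_dim}")
        self.kmer_table = kmer_table

        rng = np.random.default_rng(seed)
        C = cfg.input_channels
        F = cfg.conv_filters
        self.conv_enh = Conv1D(C, F, cfg.conv_kernel, rng, name="conv_enh")
        self.conv_prom = Conv1D(C, F, cfg.conv_kernel, rng, name="conv_prom")
        self.pool_enh = MaxPool1D(cfg.pool_size, cfg.pool_stride)
        self.pool_prom = MaxPool1D(cfg.pool_size, cfg.pool_stride)
        self.drop_merge = Dropout(cfg.dropout)
        self.mha = MultiHeadSelfAttention(F, cfg.n_heads, rng)
        self.drop_attn = Dropout(cfg.dropout)
        self.ln1 = LayerNorm(F, "ln1")
        self.ffn1 = Dense(F, cfg.ffn_dense1, rng, activation="relu", name="ffn1")
        self.ffn2 = Dense(cfg.ffn_dense1, cfg.ffn_dense2, rng, activation=None, name="ffn2")
        self.drop_ffn = Dropout(cfg.dropout)
        self.ln2 = LayerNorm(F, "ln2")
        self.hier = HierarchicalAttention(F, cfg.attn_hidden, rng)
        self.out = Dense(F, cfg.output_units, rng, activation=None, name="out")

        self._layers = [self.conv_enh, self.conv_prom, self.ln1, self.ln2,
                        self.mha, self.ffn1, self.ffn2, self.hier, self.out]
        # single-precision arithmetic halves memory traffic on CPU; standalone
        # layers default to float64 for tight small-instance checks
        self.dtype = np.dtype(dtype)
        for p in self.parameters():
            p.astype(self.dtype)

    # ----- parameters / weights --------------------------------------------

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for layer in self._layers:
            params.extend(layer.parameters())
        return params

    def get_weights(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = weights[p.name]

    def save(self, path) -> None:
        np.savez(path, **self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights({k: data[k] for k in data.files})

    # ----- encoding ---------------------------------------------------------

    def encode_batch(self, seqs: list[str], role: str) -> np.ndarray:
        """Sequences -> (B, L, C) float input for one branch."""
        want = self.cfg.enh_len if role == "enhancer" else self.cfg.prom_len
        for s in seqs:
            if len(s) != want:
                raise ValueError(f"{role} length {len(s)} != configured {want}")
        if self.cfg.encoding == "onehot":
            idx = np.stack([seq_to_indices(s) for s in seqs])
            return embed_onehot(idx, self.lookup).astype(self.dtype)
        return np.stack([self.kmer_table.encode(s) for s in seqs]).astype(self.dtype)

    # ----- forward / backward ----------------------------------------------

    def forward(self, xe: np.ndarray, xp: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                capture_attention: bool = False):
        """Run the network on encoded inputs.

        Returns probabilities (B,), and additionally the per-head attention
        maps (B, heads, L_merged, L_merged) when ``capture_attention`` is
        set.
        """
        eo = self.pool_enh.forward(self.conv_enh.forward(xe))
        po = self.pool_prom.forward(self.conv_prom.forward(xp))
        self._L_enh = eo.shape[1]
        m = np.concatenate([eo, po], axis=1)
        m = self.drop_merge.forward(m, training, rng)
        a = self.mha.forward(m)
        a = self.drop_attn.forward(a, training, rng)
        n1 = self.ln1.forward(a + m)
        f = self.ffn2.forward(self.ffn1.forward(n1))
        f = self.drop_ffn.forward(f, training, rng)
        h = self.ln2.forward(f + n1)
        self._H = h
        s, alpha = self.hier.forward(h)
        logits = self.out.forward(s)[:, 0]
        self._probs = sigmoid(logits)
        if capture_attention:
            return self._probs, self.mha.attention.copy()
        return self._probs

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        ds = self.out.backward(dlogits[:, None])
        dh = self.hier.backward(ds)
        dr2 = self.ln2.backward(dh)
        df = self.drop_ffn.backward(dr2)
        dn1 = self.ffn1.backward(self.ffn2.backward(df)) + dr2
        dr1 = self.ln1.backward(dn1)
        da = self.drop_attn.backward(dr1)
        dm = self.mha.backward(da) + dr1
        dm = self.drop_merge.backward(dm)
        de, dp = dm[:, :self._L_enh, :], dm[:, self._L_enh:, :]
        self.conv_enh.backward(self.pool_enh.backward(de))
        self.conv_prom.backward(self.pool_prom.backward(dp))

    def loss_and_grad(self, probs: np.ndarray, y: np.ndarray,
                      sample_weight: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        """Weighted binary cross-entropy (mean over batch) and d(loss)/d(logits)."""
        B = y.shape[0]
        w = np.ones(B) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
        probs = np.asarray(probs, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        eps = 1e-12
        loss = -np.mean(w * (y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
        dlogits = (w * (probs - y) / B).astype(self.dtype)
        return float(loss), dlogits

    # ----- branch activations (for motif extraction) ------------------------

    def branch_conv_activations(self, x: np.ndarray, role: str) -> np.ndarray:
        """(B, L_conv, filters) post-ReLU conv activations for one branch."""
        conv = self.conv_enh if role == "enhancer" else self.conv_prom
        return conv.forward(x)
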