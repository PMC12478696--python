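"""Sequence encoders: frozen-lookup one-hot ("embed-OneHot") and k-mer vectors.

Two encoding modes sit behind one interface:

* ``onehot`` — each base indexes a frozen 5x4 lookup table whose rows for
  A, C, G, T are the standard basis vectors and whose row for N is all-zero.
  The table is never trained; the dataset on disk stores raw strings and the
  one-hot matrix is materialized on the fly, so storage stays ~1 byte/base.
* ``dna2vec`` — overlapping k-mers (default k=6, stride 1) are looked up in a
  table of pretrained distributed vectors (word2vec text format, width 100 by
  convention); tokens containing N, or absent from the table, map to the zero
  vector.  A deterministic random-frozen table is available when no vector
  file is supplied.
"""

from __future__ import annotations

import hashlib
import os

import numpy as np

BASE_ORDER = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
N_INDEX = 4

_LOOKUP_TABLE = np.zeros((5, 4))
_LOOKUP_TABLE[:4] = np.eye(4)
_LOOKUP_TABLE.setflags(write=False)


class EncodingError(ValueError):
    pass


class NucleotideLookup:
    """Frozen 5x4 embedding table realizing one-hot encoding.

    Rows 0..3 (A, C, G, T) are the four standard basis vectors; row 4 (N) is
    the all-zero vector, so undetermined bases contribute nothing to
    downstream convolution sums.  ``trainable`` is always False and the table
    is write-locked; :meth:`checksum` lets callers assert frozen-ness across
    training.
    """

    trainable: bool = False

    def __init__(self):
        self.table = _LOOKUP_TABLE

    @property
    def width(self) -> int:
        return 4

    def checksum(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.table).tobytes()).hexdigest()

    def __call__(self, indices: np.ndarray) -> np.ndarray:
        return embed_onehot(indices, self)


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A->0, C->1, G->2, T->3, N->4.

    Input is case-folded to upper case; any other character raises with the
    offending 0-based position.
    """
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    bad = np.flatnonzero(out < 0)
    if bad.size:
        pos = int(bad[0])
        raise EncodingError(f"invalid character {seq[pos]!r} at position {pos}")
    return out


def embed_onehot(indices: np.ndarray, lookup: NucleotideLookup | None = None) -> np.ndarray:
    """Lookup-table one-hot: row i of the result is the table row of indices[i]."""
    lookup = lookup or NucleotideLookup()
    indices = np.asarray(indices)
    if indices.size and (indices.min() < 0 or indices.max() > N_INDEX):
        raise EncodingError("indices must lie in [0, 4]")
    return lookup.table[indices]


def encode_onehot(seq: str, lookup: NucleotideLookup | None = None) -> np.ndarray:
    """Convenience: string -> L x 4 one-hot matrix through the frozen lookup."""
    return embed_onehot(seq_to_indices(seq), lookup)


# ---------------------------------------------------------------------------
# k-mer (DNA2Vec-style) encoding
# ---------------------------------------------------------------------------

UNKNOWN_TOKEN = "<unk>"


def kmer_tokenize(seq: str, k: int = 6) -> list[str]:
    """Overlapping k-mers, stride 1: len(seq) - k + 1 tokens.

    Tokens containing N (or any non-ACGT character after case folding) are
    replaced by the unknown token.
    """
    seq = seq.upper()
    if len(seq) < k:
        raise EncodingError(f"sequence length {len(seq)} shorter than k={k}")
    tokens = []
    for i in range(len(seq) - k + 1):
        tok = seq[i:i + k]
        tokens.append(tok if set(tok) <= set("ACGT") else UNKNOWN_TOKEN)
    return tokens


class KmerVectorTable:
    """Token -> vector table for distributed k-mer encoding.

    Unknown tokens (including the N-containing unknown token) map to the zero
    vector.  The table is frozen: it is built once and never updated by
    training.
    """

    def __init__(self, vectors: dict[str, np.ndarray], k: int, source: str):
        widths = {v.shape[0] for v in vectors.values()}
        if len(widths) > 1:
            raise EncodingError(f"inconsistent vector widths {sorted(widths)}")
        self.k = k
        self.dim = widths.pop() if widths else 0
        self.source = source
        self._vectors = {t: np.asarray(v, dtype=np.float64) for t, v in vectors.items()}
        self._zero = np.zeros(self.dim)

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, token: str) -> bool:
        return token in self._vectors

    def vector(self, token: str) -> np.ndarray:
        return self._vectors.get(token, self._zero)

    def encode(self, seq: str) -> np.ndarray:
        """String -> (L - k + 1) x dim matrix of token vectors."""
        toks = kmer_tokenize(seq, self.k)
        return np.stack([self.vector(t) for t in toks])

    def checksum(self) -> str:
        h = hashlib.sha256()
        for tok in sorted(self._vectors):
            h.update(tok.encode())
            h.update(np.ascontiguousarray(self._vectors[tok]).tobytes())
        return h.hexdigest()


def load_kmer_vectors(path: str | os.PathLike, k: int = 6, expect_dim: int | None = 100) -> KmerVectorTable:
    """Read a word2vec text file ("V d" header, one token + d floats per line).

    Raises on ragged rows (with line number) and, when ``expect_dim`` is set,
    on a width that disagrees with the configured embedding dimension.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EncodingError(f"{path}:1: expected 'V d' header, got {header!r}")
        n_tokens, dim = int(header[0]), int(header[1])
        if expect_dim is not None and dim != expect_dim:
            raise EncodingError(f"{path}: vector width {dim} != expected {expect_dim}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            tok, vals = parts[0].upper(), parts[1:]
            if len(vals) != dim:
                raise EncodingError(f"{path}:{lineno}: expected {dim} floats, got {len(vals)}")
            vectors[tok] = np.array([float(v) for v in vals])
    if len(vectors) != n_tokens:
        raise EncodingError(f"{path}: header declared {n_tokens} tokens, parsed {len(vectors)}")
    return KmerVectorTable(vectors, k=k, source="file")


def random_frozen_kmer_table(k: int = 6, dim: int = 100, seed: int = 0) -> KmerVectorTable:
    """Deterministic random table over all 4**k k-mers (frozen, for when no
    pretrained vector file is available)."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    toks = [""]
    for _ in range(k):
        toks = [t + b for t in toks for b in bases]
    mat = rng.normal(0.0, 1.0, size=(len(toks), dim))
    return KmerVectorTable({t: mat[i] for i, t in enumerate(toks)}, k=k, source="random-frozen")
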