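"""Shared machinery for sequence feature encoders.

Encoders are scikit-learn transformers whose samples are RNA window
sequences (a :class:`~rnam5c.windows.Dataset`, a list of strings, or a
2-D uint8 code matrix).  ``transform`` returns a dense float array;
``get_feature_names_out`` returns the frozen, documented feature names.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..windows import ALPHABET, Dataset, seq_to_codes


def as_code_matrix(X) -> np.ndarray:
    """Coerce input samples to an (n, L) uint8 code matrix."""
    if isinstance(X, Dataset):
        return X.codes()
    arr = np.asarray(X)
    if arr.dtype.kind in "Uu" and arr.ndim <= 1 or isinstance(X, (list, tuple)):
        seqs = list(X.sequences() if isinstance(X, Dataset) else X)
        if not seqs:
            raise ValueError("no sequences to encode")
        mat = np.vstack([seq_to_codes(s) for s in seqs])
        return mat
    if arr.ndim != 2:
        raise ValueError("expected a Dataset, list of sequences, or 2-D code matrix")
    return arr.astype(np.uint8, copy=False)


def kmer_names(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic order over (A, C, G, U)."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def kmer_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 index of the k-mer starting at each position.

    codes: (n, L) uint8 -> (n, L-k+1) int64 indices into the
    lexicographic k-mer ordering.
    """
    n, L = codes.shape
    if L < k:
        raise ValueError(f"windows of length {L} are shorter than k={k}")
    idx = np.zeros((n, L - k + 1), dtype=np.int64)
    for t in range(k):
        idx += codes[:, t:L - k + 1 + t].astype(np.int64) * 4 ** (k - 1 - t)
    return idx


class SequenceEncoder(TransformerMixin, BaseEstimator):
    """Base class: stateless encoders only need ``transform``."""

    def fit(self, X, y=None):  # noqa: D102 - stateless by default
        return self

    def encode(self, seq: str) -> np.ndarray:
        """Encode a single sequence (convenience wrapper)."""
        return self.transform([seq])[0]

    def _more_tags(self):
        return {"X_types": ["string"]}
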