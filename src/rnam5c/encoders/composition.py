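"""Fit-free frequency encoders: Kmer (NAC/DNC/TNC), ENAC, and gapped k-mers.

All three are pure functions of a single window: the same sequence always
yields the same vector regardless of dataset context.

* Kmer: overall frequencies of overlapping k-mers (k = 1, 2, 3 give the
  4-, 16- and 64-dimensional NAC, DNC and TNC blocks; concatenated, 84).
* ENAC: nucleotide frequencies inside a length-5 window slid 5'->3' with
  stride 1; (L-4) placements x 4 bases = 148 components at L=41.
* xxKGap: frequencies of gapped patterns, cumulative over gap sizes
  g = 1..kgap.  Families: mM counts X<g>Y (16 per g), mD counts X<g>YZ
  (64 per g), dM counts XY<g>Z (64 per g).  Each g-block is normalized
  by its own number of valid placements, so each block sums to 1.
"""

from __future__ import annotations

import numpy as np
from sklearn.utils.validation import check_is_fitted

from ..windows import ALPHABET
from .base import SequenceEncoder, as_code_matrix, kmer_indices, kmer_names

GAP_FAMILIES = ("mM", "mD", "dM")


def _kmer_block(codes: np.ndarray, k: int, counts: bool) -> np.ndarray:
    idx = kmer_indices(codes, k)
    n, n_place = idx.shape
    out = np.zeros((n, 4 ** k))
    np.add.at(out, (np.repeat(np.arange(n), n_place), idx.ravel()), 1.0)
    if not counts:
        out /= n_place
    return out


def encode_kmer(seq: str, k: int, *, counts: bool = False) -> np.ndarray:
    """Frequencies of the 4**k overlapping k-mers (sum to 1)."""
    return _kmer_block(as_code_matrix([seq]), k, counts)[0]


class KmerEncoder(SequenceEncoder):
    """Overlapping k-mer composition for one or more k, concatenated.

    ``ks=(1, 2, 3)`` gives the 84-dimensional NAC+DNC+TNC block.
    With ``counts=True`` raw counts are emitted instead of frequencies
    (diagnostic use only).
    """

    _BLOCK = {1: "NAC", 2: "DNC", 3: "TNC"}

    def __init__(self, ks: tuple[int, ...] = (1, 2, 3), counts: bool = False):
        self.ks = ks
        self.counts = counts

    def transform(self, X) -> np.ndarray:
        codes = as_code_matrix(X)
        return np.hstack([_kmer_block(codes, k, self.counts) for k in self.ks])

    def get_feature_names_out(self, input_features=None):
        names = []
        for k in self.ks:
            tag = self._BLOCK.get(k, f"K{k}")
            names.extend(f"{tag}:{m}" for m in kmer_names(k))
        return np.asarray(names, dtype=object)


def encode_enac(seq: str, win: int = 5) -> np.ndarray:
    """Per-placement nucleotide frequencies of a sliding window."""
    return EnacEncoder(win=win).transform([seq])[0]


class EnacEncoder(SequenceEncoder):
    """Enhanced nucleic acid composition (sliding-window base frequencies).

    The number of features depends on the sequence length, so ``fit``
    records L (``length`` may also be given up front, default 41).
    """

    def __init__(self, win: int = 5, length: int | None = None):
        self.win = win
        self.length = length

    def fit(self, X, y=None):
        self.length_ = self.length or as_code_matrix(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        codes = as_code_matrix(X)
        n, L = codes.shape
        if self.win > L:
            raise ValueError(f"ENAC window {self.win} exceeds sequence length {L}")
        n_place = L - self.win + 1
        onehot = np.eye(4)[codes]                      # (n, L, 4)
        csum = np.concatenate(
            [np.zeros((n, 1, 4)), np.cumsum(onehot, axis=1)], axis=1)
        blocks = (csum[:, self.win:, :] - csum[:, :-self.win, :])[:, :n_place, :]
        return (blocks / self.win).reshape(n, n_place * 4)

    def get_feature_names_out(self, input_features=None):
        L = getattr(self, "length_", None) or self.length or 41
        n_place = L - self.win + 1
        # placement index is 1-based along the 5'->3' sweep
        return np.asarray(
            [f"ENAC:w{i + 1}:{b}" for i in range(n_place) for b in ALPHABET],
            dtype=object)


class GappedKmerEncoder(SequenceEncoder):
    """Gapped k-mer (xxKGap) composition, cumulative over gaps 1..kgap.

    family:
      - "mM": X _g_ Y patterns, 16 features per gap size;
      - "mD": X _g_ YZ patterns, 64 per gap size;
      - "dM": XY _g_ Z patterns, 64 per gap size.
    Feature count is (16 or 64) * kgap; e.g. mM with kgap=2 gives 32.
    """

    def __init__(self, family: str = "mM", kgap: int = 2):
        self.family = family
        self.kgap = kgap

    def _parts(self) -> tuple[int, int]:
        """(left k-mer size, right k-mer size) of the pattern."""
        if self.family not in GAP_FAMILIES:
            raise ValueError(f"family must be one of {GAP_FAMILIES}")
        return {"mM": (1, 1), "mD": (1, 2), "dM": (2, 1)}[self.family]

    def transform(self, X) -> np.ndarray:
        codes = as_code_matrix(X)
        n, L = codes.shape
        kl, kr = self._parts()
        blocks = []
        for g in range(1, self.kgap + 1):
            width = kl + g + kr
            if width > L:
                raise ValueError(
                    f"gapped pattern of width {width} exceeds length {L}")
            n_place = L - width + 1
            left = kmer_indices(codes, kl)[:, :n_place]
            right = kmer_indices(codes, kr)[:, kl + g:kl + g + n_place]
            pair = left * 4 ** kr + right
            block = np.zeros((n, 4 ** (kl + kr)))
            np.add.at(block, (np.repeat(np.arange(n), n_place), pair.ravel()), 1.0)
            blocks.append(block / n_place)
        return np.hstack(blocks)

    def get_feature_names_out(self, input_features=None):
        kl, kr = self._parts()
        names = []
        for g in range(1, self.kgap + 1):
            for a in kmer_names(kl):
                for b in kmer_names(kr):
                    names.append(f"{self.family}{self.kgap}Gap:{a}_{g}_{b}")
        return np.asarray(names, dtype=object)


def encode_xxkgap(seq: str, family: str, kgap: int) -> np.ndarray:
    """Cumulative gapped-pattern frequencies (see GappedKmerEncoder)."""
    return GappedKmerEncoder(family=family, kgap=kgap).transform([seq])[0]
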