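"""Position-specific propensity (PSP) encoders.

The PSP family encodes how strongly each k-mer at each window position
discriminates methylated from unmethylated sites.  From a labeled
training set, per-position k-mer frequencies are tabulated separately
for positives (``Z+``) and negatives (``Z-``); their difference
``Z = Z+ - Z-`` is the propensity matrix.  A window is encoded by
looking up, at every position, the propensity of the k-mer it actually
carries:

* PSNP (k=1): mononucleotide propensities, L components;
* PSDP (k=2): dinucleotide propensities, L-1 components;
* PSTP (k=3): trinucleotide propensities, L-2 components.

At the default L=41 the concatenation PSNP+PSDP+PSTP has 41+40+39 = 120
components.  Because the encoding is fit on labels, propensity matrices
must be re-fit inside each cross-validation training fold (the default
here) or the encoded features leak held-out labels.

Frequencies are raw (no smoothing): a k-mer never seen in a class at a
position simply contributes 0, mirroring the plain frequency-difference
definition.  K-mer rows are ordered lexicographically over (A, C, G, U);
this ordering is frozen for reproducibility of saved matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.utils.validation import check_is_fitted

from ..windows import Dataset, DatasetError, POSITIVE, NEGATIVE, offsets
from .base import SequenceEncoder, as_code_matrix, kmer_indices, kmer_names

ORDER_NAMES = {1: "PSNP", 2: "PSDP", 3: "PSTP"}


@dataclass
class PropensityMatrix:
    """Class-differential per-position k-mer frequency table.

    ``pos_freq`` and ``neg_freq`` have shape (4**k, L-k+1); each column
    sums to 1.  ``diff`` (= pos_freq - neg_freq) has zero column sums
    and entries in [-1, 1].
    """

    order: int
    pos_freq: np.ndarray
    neg_freq: np.ndarray
    kmer_index: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError("order must be 1, 2 or 3")
        self.pos_freq = np.asarray(self.pos_freq, dtype=float)
        self.neg_freq = np.asarray(self.neg_freq, dtype=float)
        expected_rows = 4 ** self.order
        if self.pos_freq.shape != self.neg_freq.shape:
            raise ValueError("pos_freq and neg_freq shapes differ")
        if self.pos_freq.shape[0] != expected_rows:
            raise ValueError(
                f"expected {expected_rows} rows for order {self.order}")
        if self.kmer_index is None:
            self.kmer_index = tuple(kmer_names(self.order))

    @property
    def diff(self) -> np.ndarray:
        return self.pos_freq - self.neg_freq

    @property
    def n_positions(self) -> int:
        return self.pos_freq.shape[1]

    @property
    def window_length(self) -> int:
        """Window length L this matrix was fit on."""
        return self.n_positions + self.order - 1

    def to_tsv(self, path: str | Path) -> None:
        """Save as TSV: matrix ('pos'/'neg'), k-mer label, one column per position."""
        cols = [f"p{j}" for j in range(self.n_positions)]
        frames = []
        for name, mat in (("pos", self.pos_freq), ("neg", self.neg_freq)):
            df = pd.DataFrame(mat, columns=cols)
            df.insert(0, "kmer", list(self.kmer_index))
            df.insert(0, "matrix", name)
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropensityMatrix":
        df = pd.read_csv(path, sep="\t")
        kmers = tuple(df.loc[df["matrix"] == "pos", "kmer"])
        order = len(kmers[0])
        vals = {name: sub.drop(columns=["matrix", "kmer"]).to_numpy(dtype=float)
                for name, sub in df.groupby("matrix")}
        return cls(order, vals["pos"], vals["neg"], kmers)


def fit_propensity(train: Dataset, order: int) -> PropensityMatrix:
    """Tabulate per-position k-mer frequencies by class and difference them.

    Raises :class:`~rnam5c.windows.DatasetError` when either class is
    absent (the propensity difference is then undefined).
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    labels = train.labels() if len(train) else np.array([])
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise DatasetError(
            "propensity fitting needs at least one positive and one "
            "negative window")
    codes = train.codes()
    idx = kmer_indices(codes, order)
    n_rows, n_cols = 4 ** order, idx.shape[1]
    freqs = {}
    for cls, val in ((POSITIVE, 1), (NEGATIVE, 0)):
        sub = idx[labels == val]
        counts = np.zeros((n_rows, n_cols), dtype=float)
        flat = sub * n_cols + np.arange(n_cols)
        np.add.at(counts.reshape(-1), flat.ravel(), 1.0)
        freqs[cls] = counts / sub.shape[0]
    return PropensityMatrix(order, freqs[POSITIVE], freqs[NEGATIVE])


def encode_psp(window, matrix: PropensityMatrix) -> np.ndarray:
    """Per-position propensity lookup for one window (length L-k+1)."""
    codes = as_code_matrix([window.seq if hasattr(window, "seq") else window])
    return _encode_codes(codes, matrix)[0]


def _encode_codes(codes: np.ndarray, matrix: PropensityMatrix) -> np.ndarray:
    idx = kmer_indices(codes, matrix.order)
    if idx.shape[1] != matrix.n_positions:
        raise ValueError(
            f"window length {codes.shape[1]} does not match matrix fit on "
            f"length {matrix.window_length}")
    return matrix.diff[idx, np.arange(matrix.n_positions)]


class PositionPropensityEncoder(SequenceEncoder):
    """Sklearn transformer for PSNP/PSDP/PSTP and their concatenation.

    Parameters
    ----------
    orders : tuple of int
        K-mer orders to fit and concatenate, each in {1, 2, 3}.
        ``(1, 2, 3)`` yields the 120-dimensional PSP block at L=41.
    """

    def __init__(self, orders: tuple[int, ...] = (1, 2, 3)):
        self.orders = orders

    def fit(self, X, y=None):
        dataset = _as_labeled_dataset(X, y)
        self.matrices_ = {k: fit_propensity(dataset, k) for k in self.orders}
        self.n_features_out_ = sum(m.n_positions for m in self.matrices_.values())
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "matrices_")
        codes = as_code_matrix(X)
        blocks = [_encode_codes(codes, self.matrices_[k]) for k in self.orders]
        return np.hstack(blocks)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "matrices_")
        names = []
        for k in self.orders:
            L = self.matrices_[k].window_length
            offs = offsets(L)[: L - k + 1]
            names.extend(f"{ORDER_NAMES[k]}:{off:+d}" for off in offs)
        return np.asarray(names, dtype=object)


def _as_labeled_dataset(X, y) -> Dataset:
    from ..windows import RnaWindow  # local to avoid cycle at import time

    if isinstance(X, Dataset) and y is None:
        return X
    if y is None:
        raise ValueError(
            "propensity encoders need labels: pass a labeled Dataset or y")
    y = np.asarray(y)
    if isinstance(X, Dataset):
        seqs, ids = X.sequences(), X.ids()
    else:
        seqs = list(X)
        ids = [f"s{i}" for i in range(len(seqs))]
    windows = [RnaWindow(i, s, POSITIVE if lab == 1 else NEGATIVE)
               for i, s, lab in zip(ids, seqs, y)]
    return Dataset(windows)


def plot_propensity(matrix: PropensityMatrix, ax=None):
    """Plain heat map of the propensity difference Z (positions on x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2 + 0.15 * 4 ** matrix.order))
    L = matrix.window_length
    offs = offsets(L)[: matrix.n_positions]
    im = ax.imshow(matrix.diff, aspect="auto", cmap="RdBu_r",
                   vmin=-np.abs(matrix.diff).max() or 1e-9,
                   vmax=np.abs(matrix.diff).max() or 1e-9)
    ax.set_xticks(range(0, matrix.n_positions, 5))
    ax.set_xticklabels(offs[::5])
    ax.set_yticks(range(len(matrix.kmer_index)))
    ax.set_yticklabels(matrix.kmer_index, fontsize=6)
    ax.set_xlabel("position relative to candidate C")
    ax.set_ylabel(f"{ORDER_NAMES[matrix.order]} k-mer")
    ax.figure.colorbar(im, ax=ax, label="Z = Z+ - Z-")
    return ax
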