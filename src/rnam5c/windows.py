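"""Fixed-length RNA windows and labeled datasets.

Every encoder in this package operates on cytosine-centered RNA windows of
odd length ``L = 2*xi + 1`` (default ``xi = 20``, so ``L = 41``) over the
strict alphabet {A, C, G, U}.  This module owns the alphabet, coordinate
and validation conventions: DNA-style ``T`` is normalized to ``U`` on
input, degenerate IUPAC codes are rejected (the frequency-based encoders
have no sound way to impute ambiguity), and in strict mode the central
position must be the candidate cytosine.

Positions are 0-based internally; user-facing coordinates run from
``-xi`` to ``+xi`` with 0 at the candidate cytosine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
#: label constants
POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
LABELS = (POSITIVE, NEGATIVE, UNLABELED)

DEFAULT_XI = 20
DEFAULT_LENGTH = 2 * DEFAULT_XI + 1

# byte-value -> 0..3 code; 255 marks invalid characters
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i


class WindowError(ValueError):
    """A sequence violates the window invariants (length/alphabet/center)."""


class DatasetError(ValueError):
    """A dataset-level invariant is violated (empty, mixed lengths, ...)."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert T to U (DNA-style input is accepted)."""
    return seq.upper().replace("T", "U")


def validate_seq(seq: str, *, length: int | None = None,
                 strict_center: bool = True) -> None:
    """Raise :class:`WindowError` if ``seq`` is not a valid window.

    ``seq`` must already be normalized.  ``length`` fixes the expected
    window length; if None, any odd length is accepted.
    """
    n = len(seq)
    if length is not None and n != length:
        raise WindowError(f"expected window of length {length}, got {n}")
    if n % 2 == 0 or n == 0:
        raise WindowError(f"window length must be odd and positive, got {n}")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise WindowError(
            f"invalid characters {sorted(bad)} (alphabet is A/C/G/U; "
            "degenerate IUPAC codes are not supported)")
    if strict_center and seq[n // 2] != "C":
        raise WindowError(
            f"central position must be C in strict mode, got {seq[n // 2]!r}")


@dataclass(frozen=True)
class RnaWindow:
    """One fixed-length RNA window with an optional class label."""

    id: str
    seq: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def xi(self) -> int:
        """Half-window radius; the candidate site sits at offset 0."""
        return len(self.seq) // 2

    def codes(self) -> np.ndarray:
        """Sequence as uint8 codes over (A, C, G, U) = (0, 1, 2, 3)."""
        return seq_to_codes(self.seq)


def seq_to_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted(set(seq) - set(ALPHABET))
        raise WindowError(f"invalid characters {bad} in sequence")
    return codes


@dataclass
class Dataset:
    """An ordered collection of equal-length windows with class counts."""

    windows: list[RnaWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise DatasetError(f"windows have mixed lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[RnaWindow]:
        return iter(self.windows)

    def __getitem__(self, idx):
        if isinstance(idx, (slice, list, np.ndarray)):
            if isinstance(idx, slice):
                return Dataset(self.windows[idx])
            return Dataset([self.windows[i] for i in np.asarray(idx)])
        return self.windows[idx]

    @property
    def length(self) -> int:
        """Common window length L."""
        if not self.windows:
            raise DatasetError("empty dataset has no window length")
        return len(self.windows[0])

    @property
    def n_pos(self) -> int:
        return sum(1 for w in self.windows if w.label == POSITIVE)

    @property
    def n_neg(self) -> int:
        return sum(1 for w in self.windows if w.label == NEGATIVE)

    def sequences(self) -> list[str]:
        return [w.seq for w in self.windows]

    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    def labels(self) -> np.ndarray:
        """Numeric labels: positive=1, negative=0, unlabeled=-1."""
        m = {POSITIVE: 1, NEGATIVE: 0, UNLABELED: -1}
        return np.array([m[w.label] for w in self.windows], dtype=int)

    def codes(self) -> np.ndarray:
        """(n_windows, L) uint8 code matrix."""
        if not self.windows:
            raise DatasetError("empty dataset has no code matrix")
        return np.vstack([w.codes() for w in self.windows])

    def subset(self, labels: Iterable[str]) -> "Dataset":
        keep = set(labels)
        return Dataset([w for w in self.windows if w.label in keep])

    def to_manifest(self, path: str | Path, source: str = "-") -> None:
        """Write a provenance manifest (TSV: id, label, source)."""
        with open(path, "w") as fh:
            fh.write("id\tlabel\tsource\n")
            for w in self.windows:
                fh.write(f"{w.id}\t{w.label}\t{source}\n")


def concat(datasets: Sequence[Dataset]) -> Dataset:
    windows: list[RnaWindow] = []
    for d in datasets:
        windows.extend(d.windows)
    return Dataset(windows)


def read_fasta(path: str | Path, label: str = UNLABELED, *,
               strict_center: bool = True, length: int | None = None,
               on_invalid: str = "error") -> Dataset:
    """Read a FASTA file of fixed-length RNA windows.

    Parameters
    ----------
    path : file path
        Multi-record FASTA, any line width.  T is normalized to U.
    label : str
        Class label attached to every record.
    strict_center : bool
        Require the central base to be C (the candidate site).
    length : int, optional
        Expected window length; defaults to the length of the first
        valid record (all records must agree).
    on_invalid : {"error", "skip"}
        In "error" mode an invalid record aborts the parse; in "skip"
        (lenient) mode it is dropped with a logged warning.

    Raises
    ------
    DatasetError
        If the file contains no (valid) records.
    WindowError
        On the first invalid record in "error" mode.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError("on_invalid must be 'error' or 'skip'")
    path = Path(path)
    windows: list[RnaWindow] = []
    expected = length
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        try:
            validate_seq(seq, length=expected, strict_center=strict_center)
        except WindowError as exc:
            if on_invalid == "error":
                raise WindowError(f"record {rec.id!r} in {path}: {exc}") from exc
            logger.warning("skipping record %r in %s: %s", rec.id, path, exc)
            continue
        if expected is None:
            expected = len(seq)
        windows.append(RnaWindow(rec.id, seq, label))
    if not windows:
        raise DatasetError(f"no valid FASTA records in {path}")
    return Dataset(windows)


def write_fasta(dataset: Dataset, path: str | Path, *, width: int = 60) -> None:
    """Write a dataset to FASTA; round-trips exactly through read_fasta."""
    if not len(dataset):
        raise DatasetError("refusing to write an empty dataset")
    ids = dataset.ids()
    if len(set(ids)) != len(ids):
        warnings.warn("dataset contains duplicate ids; written as-is")
    records = [SeqRecord(Seq(w.seq), id=w.id, description="") for w in dataset]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def offsets(length: int) -> np.ndarray:
    """User-facing coordinates -xi..+xi for a window of the given length."""
    xi = length // 2
    return np.arange(-xi, xi + 1)
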