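"""Property-based encoders: EIIP, PseEIIP, PC-PseDNC, one-hot, NCP+ND.

EIIP assigns each base its electron-ion interaction pseudopotential
(A 0.1260, C 0.1340, G 0.0806, U 0.1335 -- U inherits the thymine
value); the per-position lookup gives an L-dimensional vector.  PseEIIP
weights the 64 trinucleotide frequencies by summed EIIP values:
component XYZ = (EIIP_X + EIIP_Y + EIIP_Z) * f_XYZ.

PC-PseDNC (parallel-correlation pseudo-dinucleotide composition) mixes
the 16 dinucleotide frequencies with lambda correlation tiers computed
from physicochemical property differences:

    Theta(Da, Db) = (1/mu) * sum_u (P_u(Da) - P_u(Db))^2
    theta_g = mean of Theta over all dinucleotide pairs at lag g
    d_k     = f_k / (1 + w * sum(theta))          k = 1..16
    d_16+g  = w * theta_g / (1 + w * sum(theta))  g = 1..lambda

where the mu property scales P_u are standardized (mean 0, variance 1
over the 16 dinucleotides) before use.  All 16+lambda components sum
to 1.  The bundled 22-property table is a stand-in compilation (see
:data:`DEFAULT_PROPERTY_FILE`); any table with the same TSV layout can
be substituted.

BE is plain position-major one-hot (4L components, exactly L ones).
NCP+ND emits, per position, three chemical-property indicators -- ring
structure (purine: A/G), functional group (amino: A/C), hydrogen
bonding (weak: A/U) -- plus the cumulative density of the current base,
i.e. its frequency among positions 1..i.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ..windows import ALPHABET
from .base import SequenceEncoder, as_code_matrix, kmer_indices, kmer_names
from .composition import _kmer_block

#: dimensionless electron-ion interaction pseudopotentials per base
EIIP_VALUES = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}

DEFAULT_PROPERTY_FILE = "dinuc_properties_rna22_synthetic.tsv"


@dataclass(frozen=True)
class EiipTable:
    """EIIP value per nucleotide; all four must be present and positive."""

    A: float = EIIP_VALUES["A"]
    C: float = EIIP_VALUES["C"]
    G: float = EIIP_VALUES["G"]
    U: float = EIIP_VALUES["U"]

    def __post_init__(self) -> None:
        for b in ALPHABET:
            if getattr(self, b) <= 0:
                raise ValueError(f"EIIP value for {b} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.C, self.G, self.U])

    def trinucleotide_sums(self) -> np.ndarray:
        """EIIP_XYZ = EIIP_X + EIIP_Y + EIIP_Z for the 64 trinucleotides."""
        v = self.as_array()
        idx = np.array([[i, j, k] for i in range(4) for j in range(4)
                        for k in range(4)])
        return v[idx].sum(axis=1)


class EiipEncoder(SequenceEncoder):
    """Per-position EIIP lookup (L components)."""

    def __init__(self, table: EiipTable | None = None):
        self.table = table

    def _values(self) -> np.ndarray:
        return (self.table or EiipTable()).as_array()

    def transform(self, X) -> np.ndarray:
        return self._values()[as_code_matrix(X)]

    def get_feature_names_out(self, input_features=None):
        L = getattr(self, "length_", None) or 41
        xi = L // 2
        return np.asarray([f"EIIP:{o:+d}" for o in range(-xi, xi + 1)],
                          dtype=object)

    def fit(self, X, y=None):
        self.length_ = as_code_matrix(X).shape[1]
        return self


class PseEiipEncoder(SequenceEncoder):
    """Trinucleotide frequencies weighted by summed EIIP values (64 dims)."""

    def __init__(self, table: EiipTable | None = None):
        self.table = table

    def transform(self, X) -> np.ndarray:
        tnc = _kmer_block(as_code_matrix(X), 3, counts=False)
        return tnc * (self.table or EiipTable()).trinucleotide_sums()

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"PseEIIP:{m}" for m in kmer_names(3)], dtype=object)


class DinucPropertyTable:
    """22 (configurable) physicochemical scales over the 16 RNA dinucleotides.

    Rows are properties, columns are the lexicographically ordered
    dinucleotides.  ``standardize()`` brings each property row to mean 0
    and variance 1 across the 16 dinucleotides (population variance),
    which is how the correlation factors consume it.
    """

    def __init__(self, values: pd.DataFrame, standardized: bool = False):
        expected = kmer_names(2)
        if list(values.columns) != expected:
            raise ValueError(
                "property table columns must be the 16 dinucleotides in "
                f"lexicographic order {expected}")
        self.values = values.astype(float)
        self.standardized = standardized

    @property
    def n_properties(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DinucPropertyTable":
        df = pd.read_csv(path, sep="\t").set_index("property")
        df.index.name = None
        return cls(df)

    @classmethod
    def default(cls) -> "DinucPropertyTable":
        ref = resources.files("rnam5c") / "data" / DEFAULT_PROPERTY_FILE
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def standardize(self) -> "DinucPropertyTable":
        if self.standardized:
            return self
        vals = self.values.to_numpy()
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        if (sd == 0).any():
            raise ValueError("constant property row cannot be standardized")
        out = (vals - vals.mean(axis=1, keepdims=True)) / sd
        return DinucPropertyTable(
            pd.DataFrame(out, index=self.values.index,
                         columns=self.values.columns),
            standardized=True)

    def theta_matrix(self) -> np.ndarray:
        """16x16 squared-difference correlation Theta, averaged over properties."""
        p = self.standardize().values.to_numpy()      # (mu, 16)
        diff = p[:, :, None] - p[:, None, :]
        return (diff ** 2).mean(axis=0)


class PcPseDncEncoder(SequenceEncoder):
    """Parallel-correlation pseudo-dinucleotide composition (16+lambda dims).

    Parameters
    ----------
    lam : int
        Highest correlation tier (lag); 1 <= lam <= L-2.
    w : float
        Weight of the correlation tail, 0 < w <= 1.
    table : DinucPropertyTable, optional
        Property scales; defaults to the bundled 22-property table.
    """

    def __init__(self, lam: int = 3, w: float = 0.2,
                 table: DinucPropertyTable | None = None):
        self.lam = lam
        self.w = w
        self.table = table

    def _check_params(self, L: int) -> None:
        if not 1 <= self.lam <= L - 2:
            raise ValueError(f"lambda must be in [1, {L - 2}], got {self.lam}")
        if not 0 < self.w <= 1:
            raise ValueError(f"w must be in (0, 1], got {self.w}")

    def _theta_matrix(self) -> np.ndarray:
        if not hasattr(self, "_theta_cache_"):
            table = self.table or DinucPropertyTable.default()
            self._theta_cache_ = table.theta_matrix()
        return self._theta_cache_

    def transform(self, X) -> np.ndarray:
        codes = as_code_matrix(X)
        n, L = codes.shape
        self._check_params(L)
        theta_m = self._theta_matrix()
        dinuc = kmer_indices(codes, 2)                # (n, L-1)
        f = _kmer_block(codes, 2, counts=False)       # sums to 1
        thetas = np.empty((n, self.lam))
        n_dinuc = L - 1
        for g in range(1, self.lam + 1):
            pairs = theta_m[dinuc[:, : n_dinuc - g], dinuc[:, g:]]
            thetas[:, g - 1] = pairs.mean(axis=1)
        denom = 1.0 + self.w * thetas.sum(axis=1, keepdims=True)
        return np.hstack([f / denom, self.w * thetas / denom])

    def get_feature_names_out(self, input_features=None):
        names = [f"PseDNC:{m}" for m in kmer_names(2)]
        names += [f"PseDNC:theta{g}" for g in range(1, self.lam + 1)]
        return np.asarray(names, dtype=object)


class BinaryEncoder(SequenceEncoder):
    """Position-major one-hot encoding (4L components, exactly L ones)."""

    def transform(self, X) -> np.ndarray:
        codes = as_code_matrix(X)
        n, L = codes.shape
        return np.eye(4)[codes].reshape(n, 4 * L)

    def fit(self, X, y=None):
        self.length_ = as_code_matrix(X).shape[1]
        return self

    def get_feature_names_out(self, input_features=None):
        L = getattr(self, "length_", None) or 41
        xi = L // 2
        return np.asarray([f"BE:{o:+d}:{b}" for o in range(-xi, xi + 1)
                           for b in ALPHABET], dtype=object)


class NcpNdEncoder(SequenceEncoder):
    """Nucleotide chemical properties + cumulative density, position-major.

    Per position i: (ring, functional group, hydrogen bond, density) where
    ring=1 for purines A/G, group=1 for amino bases A/C, bond=1 for the
    weakly pairing A/U, and density is the prefix frequency of the base
    at i among positions 1..i (always 1 at the first position).
    """

    #: rows indexed by base code A,C,G,U -> (x, y, z)
    _NCP = np.array([[1, 1, 1],
                     [0, 1, 0],
                     [1, 0, 0],
                     [0, 0, 1]], dtype=float)

    def transform(self, X) -> np.ndarray:
        codes = as_code_matrix(X)
        n, L = codes.shape
        ncp = self._NCP[codes]                            # (n, L, 3)
        onehot = np.eye(4)[codes]                         # (n, L, 4)
        prefix = np.cumsum(onehot, axis=1)
        dens = np.take_along_axis(
            prefix, codes[:, :, None].astype(int), axis=2)[:, :, 0]
        dens /= np.arange(1, L + 1)
        out = np.concatenate([ncp, dens[:, :, None]], axis=2)
        return out.reshape(n, 4 * L)

    def fit(self, X, y=None):
        self.length_ = as_code_matrix(X).shape[1]
        return self

    def get_feature_names_out(self, input_features=None):
        L = getattr(self, "length_", None) or 41
        xi = L // 2
        parts = ("ring", "group", "bond", "density")
        return np.asarray([f"NCPND:{o:+d}:{p}" for o in range(-xi, xi + 1)
                           for p in parts], dtype=object)


# -- thin functional wrappers ------------------------------------------------

def encode_eiip(seq: str, table: EiipTable | None = None) -> np.ndarray:
    return EiipEncoder(table=table).transform([seq])[0]


def encode_pseeiip(seq: str, table: EiipTable | None = None) -> np.ndarray:
    return PseEiipEncoder(table=table).transform([seq])[0]


def encode_pc_psednc(seq: str, lam: int = 3, w: float = 0.2,
                     table: DinucPropertyTable | None = None) -> np.ndarray:
    return PcPseDncEncoder(lam=lam, w=w, table=table).transform([seq])[0]


def encode_be(seq: str) -> np.ndarray:
    return BinaryEncoder().transform([seq])[0]


def encode_ncp_nd(seq: str) -> np.ndarray:
    return NcpNdEncoder().transform([seq])[0]
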