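"""Encoder registry, feature fusion, and the named preset combinations.

A :class:`FeatureSpec` is an ordered list of encoder steps; fusing a
dataset concatenates the per-window encodings in spec order.  The named
presets carry their expected fused dimensionality at the default window
length L=41 and fusion validates against it, e.g. the best-performing
combination "PSP + Kmer + PseEIIP + PC-PseDNC" fuses to 287 columns
(120 + 84 + 64 + 19).

Propensity (PSP) steps are supervised: they must be fit on labeled
training data before (or while) encoding, and the fitted matrices are
what :class:`FeatureFusion` stores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .encoders.base import SequenceEncoder, as_code_matrix
from .encoders.composition import EnacEncoder, GappedKmerEncoder, KmerEncoder
from .encoders.physchem import (BinaryEncoder, EiipEncoder, NcpNdEncoder,
                                PcPseDncEncoder, PseEiipEncoder)
from .encoders.psp import PositionPropensityEncoder
from .windows import Dataset, NEGATIVE, POSITIVE


class UnknownEncoderError(KeyError):
    pass


class FusionError(ValueError):
    pass


#: encoder id -> factory(**params); ids are the registry surface of the CLI
ENCODER_REGISTRY: dict[str, Callable[..., SequenceEncoder]] = {
    "psnp": lambda **p: PositionPropensityEncoder(orders=(1,), **p),
    "psdp": lambda **p: PositionPropensityEncoder(orders=(2,), **p),
    "pstp": lambda **p: PositionPropensityEncoder(orders=(3,), **p),
    "psp": lambda **p: PositionPropensityEncoder(orders=(1, 2, 3), **p),
    "nac": lambda **p: KmerEncoder(ks=(1,), **p),
    "dnc": lambda **p: KmerEncoder(ks=(2,), **p),
    "tnc": lambda **p: KmerEncoder(ks=(3,), **p),
    "kmer": lambda **p: KmerEncoder(ks=(1, 2, 3), **p),
    "enac": EnacEncoder,
    "mm1gap": lambda **p: GappedKmerEncoder("mM", 1, **p),
    "mm2gap": lambda **p: GappedKmerEncoder("mM", 2, **p),
    "mm3gap": lambda **p: GappedKmerEncoder("mM", 3, **p),
    "md1gap": lambda **p: GappedKmerEncoder("mD", 1, **p),
    "md2gap": lambda **p: GappedKmerEncoder("mD", 2, **p),
    "md3gap": lambda **p: GappedKmerEncoder("mD", 3, **p),
    "dm1gap": lambda **p: GappedKmerEncoder("dM", 1, **p),
    "dm2gap": lambda **p: GappedKmerEncoder("dM", 2, **p),
    "dm3gap": lambda **p: GappedKmerEncoder("dM", 3, **p),
    "eiip": EiipEncoder,
    "pseeiip": PseEiipEncoder,
    "pc_psednc": PcPseDncEncoder,
    "be": BinaryEncoder,
    "ncp_nd": NcpNdEncoder,
}

#: encoder ids whose fit consumes class labels
SUPERVISED_ENCODERS = frozenset({"psnp", "psdp", "pstp", "psp"})


@dataclass(frozen=True)
class EncoderStep:
    name: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def build(self) -> SequenceEncoder:
        if self.name not in ENCODER_REGISTRY:
            raise UnknownEncoderError(
                f"unknown encoder {self.name!r}; valid ids: "
                f"{sorted(ENCODER_REGISTRY)}")
        return ENCODER_REGISTRY[self.name](**dict(self.params))

    @property
    def supervised(self) -> bool:
        return self.name in SUPERVISED_ENCODERS


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered encoder steps plus an optional expected fused dimension."""

    steps: tuple[EncoderStep, ...]
    expected_dim: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.steps]
        if len(set(names)) != len(names):
            raise FusionError(f"duplicate encoder ids in spec: {names}")

    @classmethod
    def parse(cls, items: Sequence[str], expected_dim: int | None = None,
              name: str = "") -> "FeatureSpec":
        """Parse step strings like "kmer" or "pc_psednc:lam=3,w=0.2"."""
        steps = []
        for item in items:
            enc, _, rest = item.partition(":")
            params: dict[str, Any] = {}
            if rest:
                for kv in rest.split(","):
                    k, _, v = kv.partition("=")
                    try:
                        params[k] = int(v)
                    except ValueError:
                        try:
                            params[k] = float(v)
                        except ValueError:
                            params[k] = v
            steps.append(EncoderStep(enc.strip().lower(), params))
        return cls(tuple(steps), expected_dim=expected_dim, name=name)

    @property
    def needs_labels(self) -> bool:
        return any(s.supervised for s in self.steps)

    def without_validation(self) -> "FeatureSpec":
        return replace(self, expected_dim=None)


_PRESET_TABLE: dict[str, tuple[list[str], int]] = {
    "PSP": (["psp"], 120),
    "Kmer": (["kmer"], 84),
    "PSP+Kmer": (["psp", "kmer"], 204),
    "PSP+Kmer+ENAC": (["psp", "kmer", "enac"], 352),
    "PSP+Kmer+ENAC+mM2Gap": (["psp", "kmer", "enac", "mm2gap"], 384),
    "PseEIIP+PseDNC": (["pseeiip", "pc_psednc:lam=3,w=0.2"], 83),
    "BEST": (["psp", "kmer", "pseeiip", "pc_psednc:lam=3,w=0.2"], 287),
    "BEST+mM2Gap": (["psp", "kmer", "pseeiip", "pc_psednc:lam=3,w=0.2",
                     "mm2gap"], 319),
    "BEST+ENAC": (["psp", "kmer", "pseeiip", "pc_psednc:lam=3,w=0.2",
                   "enac"], 435),
}

PRESET_NAMES = tuple(_PRESET_TABLE)


def preset(name: str) -> FeatureSpec:
    """Return a named feature combination with its expected dimension.

    Expected dimensions hold at the default window length L=41; for other
    lengths use ``preset(name).without_validation()``.
    """
    key = {k.lower(): k for k in _PRESET_TABLE}.get(name.lower())
    if key is None:
        raise UnknownEncoderError(
            f"unknown preset {name!r}; valid presets: {list(_PRESET_TABLE)}")
    items, dim = _PRESET_TABLE[key]
    return FeatureSpec.parse(items, expected_dim=dim, name=key)


def as_spec(spec: FeatureSpec | str | Sequence[str]) -> FeatureSpec:
    if isinstance(spec, FeatureSpec):
        return spec
    if isinstance(spec, str):
        return preset(spec)
    return FeatureSpec.parse(spec)


class FeatureFusion(TransformerMixin, BaseEstimator):
    """Concatenate encoder outputs in spec order (sklearn transformer).

    ``fit(X, y)`` fits every step (propensity steps consume ``y`` or the
    labels of a labeled :class:`Dataset`); ``transform`` returns the
    fused matrix and validates ``expected_dim`` when the spec carries
    one.
    """

    def __init__(self, spec: FeatureSpec | str | Sequence[str] = "BEST"):
        self.spec = spec

    def fit(self, X, y=None):
        sp = as_spec(self.spec)
        self.spec_ = sp
        self.encoders_ = []
        for step in sp.steps:
            enc = step.build()
            enc.fit(X, y if step.supervised else None)
            self.encoders_.append((step, enc))
        dim = sum(e.transform(_probe(X)).shape[1] for _, e in self.encoders_)
        if sp.expected_dim is not None and dim != sp.expected_dim:
            raise FusionError(
                f"fused dimension {dim} != expected {sp.expected_dim} "
                f"for spec {sp.name or sp.steps}")
        self.n_features_out_ = dim
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "encoders_")
        return np.hstack([enc.transform(X) for _, enc in self.encoders_])

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "encoders_")
        names: list[str] = []
        for step, enc in self.encoders_:
            names.extend(f"{step.name}:{n}" for n in enc.get_feature_names_out())
        return np.asarray(names, dtype=object)


def _probe(X):
    """A one-row slice of X, to measure output dimension cheaply."""
    if isinstance(X, Dataset):
        return Dataset(X.windows[:1])
    if isinstance(X, (list, tuple)):
        return X[:1]
    return np.asarray(X)[:1]


@dataclass
class FeatureMatrix:
    """Fused per-window features with ids, labels and global column names."""

    X: np.ndarray
    ids: list[str]
    labels: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise FusionError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.column_names):
            raise FusionError("column_names length does not match matrix width")
        if self.X.shape[0] != len(self.ids) or self.X.shape[0] != len(self.labels):
            raise FusionError("row metadata length does not match matrix height")

    @property
    def shape(self):
        return self.X.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.iloc[:, 2:].to_numpy(float), list(df["id"].astype(str)),
                   df["label"].to_numpy(int), list(df.columns[2:]))


def fuse(dataset: Dataset, spec: FeatureSpec | str | Sequence[str],
         fitted: FeatureFusion | None = None) -> FeatureMatrix:
    """Fuse a dataset under a spec; fit supervised steps on it if needed.

    Pass ``fitted`` (a fit :class:`FeatureFusion`) to encode with
    propensity matrices fit elsewhere, e.g. on a training split only.
    An empty dataset is legal only with a ``fitted`` fusion (there is
    nothing to fit on) and yields an empty matrix with the right columns.
    """
    sp = as_spec(spec)
    if fitted is None:
        if not len(dataset):
            raise FusionError("cannot fit a fusion on an empty dataset; "
                              "pass a fitted FeatureFusion instead")
        if sp.needs_labels and (dataset.n_pos == 0 or dataset.n_neg == 0):
            raise FusionError(
                "spec contains propensity encoders but the dataset does not "
                "carry both classes; fit on labeled data or pass `fitted`")
        fitted = FeatureFusion(sp).fit(dataset)
    names = list(fitted.get_feature_names_out())
    if not len(dataset):
        return FeatureMatrix(np.empty((0, fitted.n_features_out_)), [],
                             np.array([], dtype=int), names)
    return FeatureMatrix(fitted.transform(dataset), dataset.ids(),
                         dataset.labels(), names)
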