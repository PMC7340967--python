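"""Synthetic benchmark generator with planted position-specific signal.

Real m5C training data show class-dependent per-position nucleotide
frequencies: C and U are enriched upstream of methylated sites (about 5%
for C on average) while A and G are enriched in non-methylated windows,
with a much weaker (~1.4%) differential downstream.  The generator
emulates exactly that structure and nothing else: each position of each
class draws independently from its own nucleotide distribution, the
central position is always the candidate C, and a signed per-position
enrichment map plants a controllable frequency difference ``delta``
between the classes.

For a designated nucleotide with weight ``w`` at a position, the
positive class gets probability ``base + w*delta/2`` and the negative
class ``base - w*delta/2``; the added mass is redistributed evenly over
the non-designated nucleotides so each column remains a distribution.
The realized between-class frequency difference is therefore exactly
``w*delta``, which is what a propensity matrix fit on the sample should
recover (up to binomial noise).

The default enrichment map plants weight +1.0 on C and U at the 20
upstream positions (enriched in positives) and weight -0.3 on A and G
at the 20 downstream positions (enriched in negatives), mirroring the
upstream-strong/downstream-weak asymmetry of real data.

An optional first-order Markov mode (``markov_rho > 0``) repeats the
previous base with probability rho instead of drawing fresh, creating
genuine neighbor correlations so that dinucleotide-level encoders see
non-trivial structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .windows import (ALPHABET, Dataset, NEGATIVE, POSITIVE, RnaWindow,
                      write_fasta)


class GeneratorError(ValueError):
    pass


def default_enrichment(length: int = 41) -> dict[int, dict[str, float]]:
    """Signed enrichment weights per 0-based position.

    Positive weight = enriched in the positive class, negative weight =
    enriched in the negative class.  Upstream C/U at full weight,
    downstream A/G at 0.3 weight; the center is never touched.
    """
    xi = length // 2
    emap: dict[int, dict[str, float]] = {}
    for j in range(xi):                     # upstream: offsets -xi..-1
        emap[j] = {"C": 1.0, "U": 1.0}
    for j in range(xi + 1, length):         # downstream: offsets +1..+xi
        emap[j] = {"A": -0.3, "G": -0.3}
    return emap


@dataclass
class GeneratorModel:
    """Generating distribution for labeled 41-nt window datasets."""

    length: int = 41
    base_freq: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    delta: float = 0.05
    enriched_map: dict[int, dict[str, float]] | None = None
    seed: int = 0
    markov_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.length % 2 == 0 or self.length < 3:
            raise GeneratorError("length must be odd and >= 3")
        if abs(sum(self.base_freq) - 1.0) > 1e-9 or min(self.base_freq) < 0:
            raise GeneratorError("base_freq must be a distribution")
        if not 0.0 <= self.markov_rho < 1.0:
            raise GeneratorError("markov_rho must be in [0, 1)")
        if self.enriched_map is None:
            self.enriched_map = default_enrichment(self.length)
        self.position_probs(POSITIVE)  # validate probabilities eagerly
        self.position_probs(NEGATIVE)

    def position_probs(self, label: str) -> np.ndarray:
        """(L, 4) per-position nucleotide probabilities for one class."""
        sign = {POSITIVE: 1.0, NEGATIVE: -1.0}[label]
        probs = np.tile(np.asarray(self.base_freq, dtype=float),
                        (self.length, 1))
        center = self.length // 2
        for j, weights in self.enriched_map.items():
            if not 0 <= j < self.length:
                raise GeneratorError(f"enriched position {j} outside window")
            if j == center:
                raise GeneratorError(
                    "the central candidate C cannot carry enrichment")
            designated = [ALPHABET.index(b) for b in weights]
            others = [i for i in range(4) if i not in designated]
            shift = 0.0
            for b, w in weights.items():
                d = sign * w * self.delta / 2.0
                probs[j, ALPHABET.index(b)] += d
                shift += d
            if others:
                probs[j, others] -= shift / len(others)
        # candidate site: always C
        probs[center] = 0.0
        probs[center, ALPHABET.index("C")] = 1.0
        if (probs < -1e-12).any() or (probs > 1 + 1e-12).any():
            raise GeneratorError(
                f"delta={self.delta} drives a position probability outside "
                "[0, 1]; reduce delta or the enrichment weights")
        probs = np.clip(probs, 0.0, 1.0)
        return probs / probs.sum(axis=1, keepdims=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "length": self.length,
            "base_freq": list(self.base_freq),
            "delta": self.delta,
            "enriched_map": {str(k): v for k, v in self.enriched_map.items()},
            "seed": self.seed,
            "markov_rho": self.markov_rho,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorModel":
        d = json.loads(Path(path).read_text())
        d["enriched_map"] = {int(k): v for k, v in d["enriched_map"].items()}
        d["base_freq"] = tuple(d["base_freq"])
        return cls(**d)


def _draw(probs: np.ndarray, n: int, rng: np.random.Generator,
          rho: float) -> np.ndarray:
    """Sample n sequences as an (n, L) code matrix."""
    L = probs.shape[0]
    cum = probs.cumsum(axis=1)
    u = rng.random((n, L))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)
    if rho > 0.0:
        repeat = rng.random((n, L)) < rho
        for j in range(1, L):
            if j == L // 2:     # center stays C
                continue
            codes[repeat[:, j], j] = codes[repeat[:, j], j - 1]
    return codes


def generate(model: GeneratorModel, n_pos: int, n_neg: int,
             seed: int | None = None) -> Dataset:
    """Draw a labeled dataset; reproducible under a fixed seed."""
    if n_pos < 0 or n_neg < 0:
        raise GeneratorError("counts must be non-negative")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    windows: list[RnaWindow] = []
    for label, n, tag in ((POSITIVE, n_pos, "pos"), (NEGATIVE, n_neg, "neg")):
        if n == 0:
            continue
        probs = model.position_probs(label)
        codes = _draw(probs, n, rng, model.markov_rho)
        for i, row in enumerate(codes):
            seq = "".join(ALPHABET[c] for c in row)
            windows.append(RnaWindow(f"{tag}_{i + 1:05d}", seq, label))
    return Dataset(windows)


def simulate_to_fasta(model: GeneratorModel, n_pos: int, n_neg: int,
                      out_dir: str | Path,
                      seed: int | None = None) -> dict[str, Path]:
    """Write pos/neg FASTA files plus a JSON sidecar of the model.

    Output bytes are identical across runs and platforms for a fixed
    seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = generate(model, n_pos, n_neg, seed=seed)
    paths = {}
    for label, name in ((POSITIVE, "pos.fasta"), (NEGATIVE, "neg.fasta")):
        sub = data.subset([label])
        if len(sub):
            write_fasta(sub, out_dir / name)
            paths[label] = out_dir / name
    model.to_json(out_dir / "model.json")
    paths["model"] = out_dir / "model.json"
    return paths
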