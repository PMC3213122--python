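"""Planted-motif synthetic datasets.

Generates two-class sequence data with a known discriminative signal: a
planted word inserted into a controllable fraction of the positive
class, with a controllable mutation load, against an i.i.d. background.
Two regime presets emulate the shapes of real benchmark data: balanced
fixed-length DNA (2 x 1000 sequences of length 50, nucleosome-occupancy
style) and balanced variable-length protein (lengths spanning 15-1963,
solubility style).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .seq_io import Alphabet, DNA, Dataset, LabeledSequence, NEGATIVE, POSITIVE, PROTEIN, \
    reverse_complement

NUCLEOSOME_WORD = "GATTACCA"      # planted 8-mer, not reverse-complement symmetric
PROTEIN_WORD = "WKYR"             # planted tetramer

FIXED = "fixed"
LOG_UNIFORM = "loguniform"


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a planted-motif generation run.

    ``q`` is the planting probability (fraction of positives receiving
    one instance); ``d`` the number of substitutions applied to each
    planted instance; ``strand_plant`` plants on a uniformly random
    strand (DNA only).
    """

    n_pos: int
    n_neg: int
    alphabet: Alphabet = DNA
    length_model: str = FIXED
    length: int = 50                  # L0 for fixed
    length_range: tuple[int, int] = (15, 1963)   # for log-uniform
    background: tuple[float, ...] | None = None  # None = uniform
    word: str = NUCLEOSOME_WORD
    q: float = 0.9
    d: int = 0
    strand_plant: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("plant probability q must be in [0, 1]")
        if self.d > len(self.word):
            raise ValueError("mutation load d cannot exceed the planted word length")
        if self.background is not None:
            bg = np.asarray(self.background)
            if bg.size != self.alphabet.size or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be a probability vector over the alphabet")
        if self.length_model not in (FIXED, LOG_UNIFORM):
            raise ValueError(f"unknown length model {self.length_model!r}")
        if self.strand_plant and not self.alphabet.complementable:
            raise ValueError("strand planting requires a DNA alphabet")

    def min_length(self) -> int:
        return self.length if self.length_model == FIXED else self.length_range[0]

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return np.full(self.alphabet.size, 1.0 / self.alphabet.size)
        return np.asarray(self.background, dtype=float)


@dataclass
class PlantRecord:
    """Ground truth for one positive sequence."""

    id: str
    planted: bool
    position: int = -1
    strand: str = "+"
    instance: str = ""


def _random_sequence(rng: np.random.Generator, length: int, alphabet: Alphabet,
                     bg: np.ndarray) -> str:
    codes = rng.choice(alphabet.size, size=length, p=bg)
    return "".join(alphabet.symbols[c] for c in codes)


def _mutate(rng: np.random.Generator, word: str, d: int, alphabet: Alphabet) -> str:
    if d == 0:
        return word
    positions = rng.choice(len(word), size=d, replace=False)
    out = list(word)
    for pos in positions:
        others = [s for s in alphabet.symbols if s != out[pos]]
        out[pos] = others[rng.integers(len(others))]
    return "".join(out)


def generate(spec: SyntheticSpec) -> tuple[Dataset, list[PlantRecord]]:
    """Generate the dataset plus per-positive ground-truth plant records.

    Negatives are pure background.  Each positive receives, with
    probability q, one planted instance at a uniform random position
    (uniform strand if strand planting), carrying exactly d random
    substitutions.  Deterministic given the spec's seed.
    """
    if len(spec.word) > spec.min_length():
        raise ValueError(
            f"planted word length {len(spec.word)} exceeds minimum sequence "
            f"length {spec.min_length()}"
        )
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_vector()
    alphabet = spec.alphabet

    def draw_length() -> int:
        if spec.length_model == FIXED:
            return spec.length
        lo, hi = spec.length_range
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))).clip(lo, hi))

    sequences: list[LabeledSequence] = []
    truth: list[PlantRecord] = []
    for i in range(spec.n_pos):
        sid = f"pos_{i:05d}"
        length = draw_length()
        residues = _random_sequence(rng, length, alphabet, bg)
        record = PlantRecord(sid, planted=False)
        if rng.random() < spec.q:
            instance = _mutate(rng, spec.word, spec.d, alphabet)
            strand = "+"
            if spec.strand_plant and rng.random() < 0.5:
                instance = reverse_complement(instance)
                strand = "-"
            pos = int(rng.integers(0, length - len(instance) + 1))
            residues = residues[:pos] + instance + residues[pos + len(instance):]
            record = PlantRecord(sid, True, pos, strand, instance)
        sequences.append(LabeledSequence(sid, residues, POSITIVE))
        truth.append(record)
    for i in range(spec.n_neg):
        length = draw_length()
        sequences.append(LabeledSequence(f"neg_{i:05d}",
                                         _random_sequence(rng, length, alphabet, bg),
                                         NEGATIVE))
    return Dataset(sequences, alphabet), truth


def nucleosome_like(n_per_class: int = 1000, word: str = NUCLEOSOME_WORD,
                    q: float = 0.9, d: int = 0, seed: int = 0) -> SyntheticSpec:
    """Fixed-length DNA regime: balanced classes of 50-mers."""
    return SyntheticSpec(n_pos=n_per_class, n_neg=n_per_class, alphabet=DNA,
                         length_model=FIXED, length=50, word=word, q=q, d=d,
                         strand_plant=True, seed=seed)


def protein_like(n_per_class: int = 8704, word: str = PROTEIN_WORD,
                 q: float = 0.9, d: int = 0, seed: int = 0) -> SyntheticSpec:
    """Variable-length protein regime: balanced classes, lengths 15-1963."""
    return SyntheticSpec(n_pos=n_per_class, n_neg=n_per_class, alphabet=PROTEIN,
                         length_model=LOG_UNIFORM, length_range=(15, 1963),
                         word=word, q=q, d=d, strand_plant=False, seed=seed)


def regime_presets() -> dict[str, SyntheticSpec]:
    """Named presets at full and reduced (<= 1/5) sizes."""
    return {
        "nucleosome-full": nucleosome_like(1000),
        "nucleosome-reduced": nucleosome_like(200),
        "protein-full": protein_like(8704),
        "protein-reduced": protein_like(400),
    }


def write_truth_json(path: str | Path, spec: SyntheticSpec,
                     truth: list[PlantRecord]) -> None:
    payload = {
        "spec": {k: v for k, v in asdict(spec).items() if k != "alphabet"}
        | {"alphabet": spec.alphabet.name},
        "plants": [asdict(t) for t in truth],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
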