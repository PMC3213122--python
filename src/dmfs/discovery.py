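"""Reference discriminative word finder.

The motif-discovery stage is pluggable: any callable mapping a discovery
``Dataset`` to a ranked motif list can be dropped into the pipeline.  The
reference finder implemented here is enumerative-discriminative: it
enumerates all words of length ``min_len..max_len`` present in the
discovery sequences, counts per-class *presence* (number of sequences
containing the word at least once — robust to length heterogeneity),
scores each word with a hypergeometric enrichment tail, and keeps the
top-K after a redundancy filter.  For DNA under the double-strand policy
a word and its reverse complement are merged under the lexicographically
smaller representative (so e.g. AAAA/TTTT is a single motif).

PWMs can optionally be built from the discrete motifs' matched sites in
the discovery positives, for downstream threshold-gated scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
from scipy.stats import hypergeom

from .seq_io import Alphabet, DNA, Dataset, NEGATIVE, POSITIVE, reverse_complement

STRAND_BOTH = "both"
STRAND_SINGLE = "single"

DNA_MIN_LEN = 5
DNA_MAX_LEN = 7
PROTEIN_MIN_LEN = 3
PROTEIN_MAX_LEN = 4
DEFAULT_N_MOTIFS = 50
DNA_PSEUDOCOUNT = 0.25
PROTEIN_PSEUDOCOUNT = 0.05


@dataclass(frozen=True)
class DiscreteMotif:
    """A word motif with its discovery-set presence counts and enrichment p-value."""

    word: str
    n_pos: int
    n_neg: int
    score: float          # hypergeometric enrichment p-value; lower = more discriminative
    enriched: int         # class the word is enriched in (POSITIVE or NEGATIVE)
    rank: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.score <= 1.0:
            raise ValueError(f"motif {self.word!r}: p-value {self.score} outside (0, 1]")


@dataclass
class PWM:
    """Position weight matrix in log2-odds form against a background.

    ``log_odds`` has shape (width, |alphabet|); ``probs`` holds the
    underlying position probabilities (rows sum to 1).  ``threshold`` is
    set later by the scoring stage from a match p-value.
    """

    log_odds: np.ndarray
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float
    alphabet: Alphabet
    source_word: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.width < 1:
            raise ValueError("PWM width must be >= 1")
        if self.probs.shape != self.log_odds.shape:
            raise ValueError("probs and log_odds shapes differ")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM position-probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def name(self) -> str:
        return self.source_word or f"pwm_w{self.width}"

    def consensus(self) -> str:
        return "".join(self.alphabet.symbols[j] for j in self.log_odds.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


@dataclass(frozen=True)
class DiscoveryConfig:
    """Tuning knobs for the reference finder.

    ``max_len`` is the maximum motif length (length-7 words for 50-mer
    DNA, length-4 for protein, by default); ``n_motifs`` (K) caps the
    ranked list after redundancy filtering.
    """

    min_len: int = DNA_MIN_LEN
    max_len: int = DNA_MAX_LEN
    n_motifs: int = DEFAULT_N_MOTIFS
    strand: str = STRAND_BOTH

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        if self.strand not in (STRAND_BOTH, STRAND_SINGLE):
            raise ValueError(f"unknown strand policy {self.strand!r}")

    @staticmethod
    def for_alphabet(alphabet: Alphabet, **overrides) -> "DiscoveryConfig":
        if alphabet.complementable:
            cfg = DiscoveryConfig(DNA_MIN_LEN, DNA_MAX_LEN, DEFAULT_N_MOTIFS, STRAND_BOTH)
        else:
            cfg = DiscoveryConfig(PROTEIN_MIN_LEN, PROTEIN_MAX_LEN, DEFAULT_N_MOTIFS,
                                  STRAND_SINGLE)
        return replace(cfg, **overrides) if overrides else cfg


def canonical_word(word: str, strand: str) -> str:
    """Double-strand representative: lexicographic min of word and its revcomp."""
    if strand == STRAND_BOTH:
        return min(word, reverse_complement(word))
    return word


def enumerate_word_stats(discovery: Dataset, min_len: int, max_len: int,
                         strand: str = STRAND_BOTH) -> dict[str, tuple[int, int]]:
    """Per-class presence counts for every word of length min_len..max_len.

    Counts sequences containing >= 1 occurrence (presence, not total
    frequency).  Words containing N are excluded.  Under the DNA
    double-strand policy counts are pooled onto the canonical
    (lexicographically smaller) strand representative.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3 for discovery")
    discovery.require_both_classes()
    if strand == STRAND_BOTH and not discovery.alphabet.complementable:
        raise ValueError("double-strand policy requires a complementable (DNA) alphabet")
    counts: dict[str, list[int]] = {}
    longest = max((len(s) for s in discovery.residues), default=0)
    if max_len > longest:
        warnings.warn(
            f"max motif length {max_len} exceeds every sequence length (max {longest})",
            stacklevel=2,
        )
    for seq in discovery.sequences:
        residues = seq.residues
        seen: set[str] = set()
        for L in range(min_len, max_len + 1):
            for i in range(len(residues) - L + 1):
                word = residues[i:i + L]
                if "N" in word:
                    continue
                seen.add(canonical_word(word, strand))
        col = 0 if seq.label == POSITIVE else 1
        for word in seen:
            counts.setdefault(word, [0, 0])[col] += 1
    return {w: (c[0], c[1]) for w, c in counts.items()}


def discrimination_score(n_pos: int, n_neg: int, N_pos: int, N_neg: int) -> float:
    """Hypergeometric upper-tail p-value for enrichment in positives.

    Probability of seeing >= n_pos positive sequences among the
    n_pos + n_neg sequences containing the word, drawing without
    replacement from N_pos + N_neg.  Degenerate inputs return 1.
    """
    if not (0 <= n_pos <= N_pos and 0 <= n_neg <= N_neg):
        raise ValueError("counts exceed class sizes")
    k = n_pos + n_neg
    if k == 0 or N_pos == 0 or N_neg == 0:
        return 1.0
    p = float(hypergeom.sf(n_pos - 1, N_pos + N_neg, N_pos, k))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def enrichment(n_pos: int, n_neg: int, N_pos: int, N_neg: int) -> tuple[float, int]:
    """Best-of-both-directions enrichment: (p-value, enriched class).

    The positive-direction tail and its mirror (enrichment in negatives)
    are computed; the smaller wins, with ties going to the positive
    class.
    """
    p_pos = discrimination_score(n_pos, n_neg, N_pos, N_neg)
    p_neg = discrimination_score(n_neg, n_pos, N_neg, N_pos)
    if p_neg < p_pos:
        return p_neg, NEGATIVE
    return p_pos, POSITIVE


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _strand_variants(word: str, strand: str) -> tuple[str, ...]:
    if strand == STRAND_BOTH:
        rc = reverse_complement(word)
        return (word,) if rc == word else (word, rc)
    return (word,)


def _redundant(candidate: str, selected: Sequence[str], strand: str) -> bool:
    """Candidate is redundant if it shares a substring relation (either
    direction, either strand) with a selected motif, or is within Hamming
    distance 1 of an equal-length selected motif (either strand)."""
    cand_variants = _strand_variants(candidate, strand)
    for kept in selected:
        for kv in _strand_variants(kept, strand):
            for cv in cand_variants:
                if cv in kv or kv in cv:
                    return True
                if len(cv) == len(kv) and _hamming(cv, kv) <= 1:
                    return True
    return False


def select_motifs(stats: Mapping[str, tuple[int, int]], config: DiscoveryConfig,
                  N_pos: int, N_neg: int) -> list[DiscreteMotif]:
    """Rank words by enrichment p-value and keep the top-K non-redundant ones.

    Sorting is by ascending p-value with lexicographic tie-break; the
    redundancy filter then drops candidates related to an already-kept
    motif by substring containment (either strand for DNA) or by Hamming
    distance <= 1 at equal length.
    """
    if not stats:
        raise ValueError("no word statistics to select from")
    scored = []
    for word, (n_pos, n_neg) in stats.items():
        p, enriched = enrichment(n_pos, n_neg, N_pos, N_neg)
        scored.append((p, word, n_pos, n_neg, enriched))
    scored.sort(key=lambda t: (t[0], t[1]))
    selected: list[DiscreteMotif] = []
    kept_words: list[str] = []
    for p, word, n_pos, n_neg, enriched in scored:
        if len(selected) >= config.n_motifs:
            break
        if _redundant(word, kept_words, config.strand):
            continue
        selected.append(DiscreteMotif(word, n_pos, n_neg, p, enriched,
                                      rank=len(selected) + 1))
        kept_words.append(word)
    return selected


def discover_motifs(discovery: Dataset, config: DiscoveryConfig | None = None) -> list[DiscreteMotif]:
    """Run the full reference finder: enumerate, score, select."""
    if config is None:
        config = DiscoveryConfig.for_alphabet(discovery.alphabet)
    stats = enumerate_word_stats(discovery, config.min_len, config.max_len, config.strand)
    if not stats:
        return []
    return select_motifs(stats, config, discovery.class_size(POSITIVE),
                         discovery.class_size(NEGATIVE))


def empirical_background(data: Dataset) -> np.ndarray:
    """Residue frequencies pooled over all sequences (N excluded for DNA)."""
    symbols = data.alphabet.symbols
    counts = np.zeros(len(symbols))
    index = {s: i for i, s in enumerate(symbols)}
    for seq in data.sequences:
        for ch in seq.residues:
            j = index.get(ch)
            if j is not None:
                counts[j] += 1
    if counts.sum() == 0:
        raise ValueError("no countable residues for background estimation")
    return counts / counts.sum()


def build_pwm(motif: DiscreteMotif | str, positives: Iterable[str], m: int,
              pseudocount: float, background: np.ndarray, alphabet: Alphabet = DNA,
              strand: str = STRAND_BOTH) -> PWM:
    """Build a PWM from a discrete motif's matched sites in discovery positives.

    Every window of the positives within Hamming distance ``m`` of the
    word (or of its reverse complement under the double-strand policy;
    such windows are strand-normalized to the representative
    orientation) contributes to the count matrix.  ``pseudocount`` is
    added to every cell before row normalization and log2-odds against
    ``background``.  Windows containing N are skipped.  Zero matched
    sites is an error.
    """
    word = motif.word if isinstance(motif, DiscreteMotif) else motif
    L = len(word)
    background = np.asarray(background, dtype=float)
    index = {s: i for i, s in enumerate(alphabet.symbols)}
    targets = [(word, False)]
    if strand == STRAND_BOTH and alphabet.complementable:
        rc = reverse_complement(word)
        if rc != word:
            targets.append((rc, True))
    counts = np.zeros((L, alphabet.size))
    n_sites = 0
    for residues in positives:
        for i in range(len(residues) - L + 1):
            window = residues[i:i + L]
            if "N" in window:
                continue
            for target, flip in targets:
                if _hamming(window, target) <= m:
                    site = reverse_complement(window) if flip else window
                    for j, ch in enumerate(site):
                        counts[j, index[ch]] += 1
                    n_sites += 1
                    break
    if n_sites == 0:
        raise ValueError(f"no occurrences of {word!r} within {m} mismatches; cannot build PWM")
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / background)
    return PWM(log_odds, probs, background, pseudocount, alphabet, source_word=word)


def write_motifs_tsv(path: str | Path, motifs: Sequence[DiscreteMotif]) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tword\tenriched_class\tn_pos\tn_neg\tp_value\n")
        for mo in motifs:
            cls = "positive" if mo.enriched == POSITIVE else "negative"
            fh.write(f"{mo.rank}\t{mo.word}\t{cls}\t{mo.n_pos}\t{mo.n_neg}\t{mo.score:.6e}\n")


def read_motifs_tsv(path: str | Path) -> list[DiscreteMotif]:
    motifs: list[DiscreteMotif] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["rank", "word", "enriched_class", "n_pos", "n_neg", "p_value"]
        if header != expected:
            raise ValueError(f"{path}: unexpected motif TSV header {header}")
        for line in fh:
            rank, word, cls, n_pos, n_neg, p = line.rstrip("\n").split("\t")
            motifs.append(DiscreteMotif(word, int(n_pos), int(n_neg), float(p),
                                        POSITIVE if cls == "positive" else NEGATIVE,
                                        rank=int(rank)))
    return motifs


def write_meme_minimal(path: str | Path, pwms: Sequence[PWM]) -> None:
    """Write PWMs in MEME minimal motif format (position probabilities)."""
    if not pwms:
        raise ValueError("no PWMs to write")
    alphabet = pwms[0].alphabet
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {''.join(alphabet.symbols)}\n\n")
        if alphabet.complementable:
            fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{s} {b:.4f}" for s, b in zip(alphabet.symbols, pwms[0].background)))
        fh.write("\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= {alphabet.size} "
                     f"w= {pwm.width} nsites= 1 E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
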