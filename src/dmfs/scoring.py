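"""Motif scoring: mismatch-tolerant counts and threshold-gated PWM scans.

Discrete motifs are scored by counting every start position (overlaps
allowed) where the word matches within ``m`` mismatches, on both strands
for DNA.  PWMs are scored by sliding the matrix along the sequence (both
strands for DNA) and summing the log-odds score of every window at or
above a threshold derived from a match p-value; the threshold comes from
an exact dynamic program over the discretized per-position score
distribution under the background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .discovery import (DiscreteMotif, PWM, STRAND_BOTH, STRAND_SINGLE)
from .seq_io import Alphabet, DNA, Dataset, reverse_complement

DNA_MISMATCHES = 1
PROTEIN_MISMATCHES = 0
DEFAULT_PWM_PVALUE = 1e-3
SCORE_GRANULARITY = 1e-3   # log2 units; threshold DP discretization


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring-stage knobs: mismatches m, PWM match p-value, strand policy."""

    mismatches: int = DNA_MISMATCHES
    pvalue: float = DEFAULT_PWM_PVALUE
    strand: str = STRAND_BOTH

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("mismatch allowance m must be >= 0")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("PWM match p-value must be in (0, 1]")
        if self.strand not in (STRAND_BOTH, STRAND_SINGLE):
            raise ValueError(f"unknown strand policy {self.strand!r}")

    @staticmethod
    def for_alphabet(alphabet: Alphabet, **overrides) -> "ScoringConfig":
        if alphabet.complementable:
            cfg = ScoringConfig(DNA_MISMATCHES, DEFAULT_PWM_PVALUE, STRAND_BOTH)
        else:
            cfg = ScoringConfig(PROTEIN_MISMATCHES, DEFAULT_PWM_PVALUE, STRAND_SINGLE)
        return replace(cfg, **overrides) if overrides else cfg


def _encode(s: str, alphabet: Alphabet) -> np.ndarray:
    """Map residues to small integer codes; anything else (e.g. N) to 255,
    which never equals a motif code, so N-vs-motif always mismatches."""
    table = np.full(256, 255, dtype=np.uint8)
    for i, sym in enumerate(alphabet.symbols):
        table[ord(sym)] = i
    return table[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _forward_count(seq_codes: np.ndarray, word_codes: np.ndarray, m: int) -> int:
    L = word_codes.size
    if seq_codes.size < L:
        return 0
    windows = sliding_window_view(seq_codes, L)
    mismatches = (windows != word_codes).sum(axis=1)
    return int((mismatches <= m).sum())


def count_occurrences(seq: str, word: str, m: int, strand: str = STRAND_BOTH,
                      alphabet: Alphabet = DNA) -> int:
    """Count start positions where ``word`` occurs within ``m`` mismatches.

    Overlapping occurrences all count.  Under the double-strand policy
    reverse-complement matches are added, except for palindromic words
    (word == revcomp(word)), which are counted once per position to
    avoid systematic doubling.  Sequences shorter than the word score 0.
    """
    if len(word) < 1:
        raise ValueError("motif word must be non-empty")
    seq_codes = _encode(seq, alphabet)
    word_codes = _encode(word, alphabet)
    if (word_codes == 255).any():
        raise ValueError(f"motif {word!r} contains symbols outside the {alphabet.name} alphabet")
    total = _forward_count(seq_codes, word_codes, m)
    if strand == STRAND_BOTH:
        if not alphabet.complementable:
            raise ValueError("double-strand scoring requires a DNA alphabet")
        rc = reverse_complement(word)
        if rc != word:
            total += _forward_count(seq_codes, _encode(rc, alphabet), m)
    return total


def _discretize(log_odds: np.ndarray, granularity: float) -> np.ndarray:
    return np.round(np.asarray(log_odds, dtype=float) / granularity).astype(np.int64)


def pwm_threshold(pwm: PWM, p: float, granularity: float = SCORE_GRANULARITY,
                  background: np.ndarray | None = None) -> float:
    """Score threshold t such that P(window score >= t) <= p under the background.

    The per-position log-odds scores are discretized to ``granularity``
    (log2 units) and the exact distribution of the total score of a
    random i.i.d.-background window is built by dynamic programming
    (convolution over positions).  t is the smallest *achievable*
    discretized score whose upper tail is <= p; if even the single best
    word exceeds p, t is the maximal achievable score.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    scores_int = _discretize(pwm.log_odds, granularity)
    # dist: discretized total score -> probability
    dist: dict[int, float] = {0: 1.0}
    for row in scores_int:
        nxt: dict[int, float] = {}
        for total, prob in dist.items():
            for s, b in zip(row, bg):
                key = total + int(s)
                nxt[key] = nxt.get(key, 0.0) + prob * float(b)
        dist = nxt
    support = sorted(dist)
    # walk from the top accumulating tail mass; keep the smallest score
    # whose tail stays within p
    tail = 0.0
    t_int = support[-1]
    found = False
    for s in reversed(support):
        tail += dist[s]
        if tail <= p + 1e-12:
            t_int = s
            found = True
        else:
            break
    if not found:
        t_int = support[-1]
    return float(t_int * granularity)


def _pwm_score_matrix(pwm: PWM, reverse: bool) -> np.ndarray:
    """Log-odds matrix for scanning; the reverse-strand matrix is the
    row-reversed, complement-permuted forward matrix."""
    M = pwm.log_odds
    if not reverse:
        return M
    symbols = pwm.alphabet.symbols
    comp = [symbols.index(reverse_complement(s)) for s in symbols]
    return M[::-1][:, comp]


def _naive_strand_scan(seq_codes: np.ndarray, M: np.ndarray, t: float) -> float:
    """Sum of window scores >= t; window scores accumulated position by
    position (same addition order as the lookahead scan, so the two
    paths are bit-identical)."""
    L = M.shape[0]
    n = seq_codes.size
    if n < L:
        return 0.0
    windows = sliding_window_view(seq_codes, L)
    valid = ~(windows == 255).any(axis=1)
    scores = np.zeros(windows.shape[0])
    for j in range(L):
        col = windows[:, j].astype(np.intp)
        scores = scores + np.where(valid, M[j][np.clip(col, 0, M.shape[1] - 1)], 0.0)
    hits = valid & (scores >= t)
    return float(scores[hits].sum())


def _lookahead_strand_scan(seq_codes: np.ndarray, M: np.ndarray, t: float) -> float:
    L = M.shape[0]
    n = seq_codes.size
    if n < L:
        return 0.0
    # best achievable score of the remaining suffix, per prefix length
    row_max = M.max(axis=1)
    suffix_best = np.concatenate([np.cumsum(row_max[::-1])[::-1][1:], [0.0]])
    total = 0.0
    for i in range(n - L + 1):
        window = seq_codes[i:i + L]
        if (window == 255).any():
            continue
        score = 0.0
        pruned = False
        for j in range(L):
            score = score + M[j, window[j]]
            if score + suffix_best[j] < t:
                pruned = True
                break
        if not pruned and score >= t:
            total += score
    return total


def pwm_scan_sum(seq: str, pwm: PWM, t: float | None = None,
                 strand: str = STRAND_BOTH, method: str = "lookahead") -> float:
    """Running sum of all window scores >= t along the sequence.

    Both strands are scanned under the DNA double-strand policy.
    ``method='lookahead'`` abandons a window as soon as the running
    prefix score plus the best achievable suffix score falls below t;
    this pruning never changes the result (``method='naive'`` is the
    unpruned reference).  Windows containing N are skipped.
    """
    if t is None:
        t = pwm.threshold
    if t is None:
        raise ValueError("PWM has no threshold set; pass t or call pwm_threshold first")
    seq_codes = _encode(seq, pwm.alphabet)
    scan = _lookahead_strand_scan if method == "lookahead" else _naive_strand_scan
    if method not in ("lookahead", "naive"):
        raise ValueError(f"unknown scan method {method!r}")
    total = scan(seq_codes, _pwm_score_matrix(pwm, reverse=False), t)
    if strand == STRAND_BOTH:
        if not pwm.alphabet.complementable:
            raise ValueError("double-strand scanning requires a DNA alphabet")
        total += scan(seq_codes, _pwm_score_matrix(pwm, reverse=True), t)
    return float(total)


@dataclass
class FeatureMatrix:
    """Classification-set sequences x motifs score table."""

    ids: list[str]
    labels: np.ndarray
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )
        if self.labels.shape[0] != len(self.ids):
            raise ValueError("labels misaligned with rows")

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tlabel\t" + "\t".join(self.columns) + "\n")
            for sid, lab, row in zip(self.ids, self.labels, self.values):
                cells = "\t".join(format(v, ".10g") for v in row)
                fh.write(f"{sid}\t{int(lab)}\t{cells}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["id", "label"]:
                raise ValueError(f"{path}: unexpected feature TSV header")
            columns = header[2:]
            ids, labels, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                labels.append(int(parts[1]))
                rows.append([float(v) for v in parts[2:]])
        return cls(ids, np.array(labels), columns,
                   np.array(rows, dtype=float).reshape(len(ids), len(columns)))


def build_feature_matrix(classification: Dataset,
                         motifs: Sequence[DiscreteMotif | PWM],
                         config: ScoringConfig | None = None) -> FeatureMatrix:
    """Score every classification-set sequence against every motif.

    Discrete-motif columns hold mismatch-tolerant occurrence counts; PWM
    columns hold threshold-gated running sums (thresholds derived from
    ``config.pvalue`` if not already set on the PWM).  Row order is
    input order; all-zero columns are preserved.
    """
    if not motifs:
        raise ValueError("motif list is empty")
    if config is None:
        config = ScoringConfig.for_alphabet(classification.alphabet)
    alphabet = classification.alphabet
    symbols = set(alphabet.symbols)
    columns: list[str] = []
    values = np.zeros((len(classification), len(motifs)))
    for j, motif in enumerate(motifs):
        if isinstance(motif, PWM):
            if motif.alphabet.name != alphabet.name:
                raise ValueError(
                    f"PWM {motif.name} alphabet {motif.alphabet.name} does not match "
                    f"dataset alphabet {alphabet.name}"
                )
            if motif.threshold is None:
                motif.threshold = pwm_threshold(motif, config.pvalue)
            columns.append(f"{motif.name}|pwm")
            for i, residues in enumerate(classification.residues):
                values[i, j] = pwm_scan_sum(residues, motif, motif.threshold, config.strand)
        else:
            word = motif.word if isinstance(motif, DiscreteMotif) else str(motif)
            if not symbols.issuperset(word):
                raise ValueError(
                    f"motif {word!r} has symbols outside the {alphabet.name} alphabet"
                )
            columns.append(word)
            for i, residues in enumerate(classification.residues):
                values[i, j] = count_occurrences(residues, word, config.mismatches,
                                                 config.strand, alphabet)
    return FeatureMatrix(list(classification.ids),
                         np.array(classification.labels), columns, values)
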