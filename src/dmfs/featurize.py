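"""MotifFeaturizer: the discovery + scoring stages as a sklearn transformer.

``fit(X, y)`` runs the reference discriminative word finder on the given
sequences and labels (the *discovery* data); ``transform(X)`` scores any
sequences against the fitted motifs, yielding the numeric feature matrix
consumed by downstream classifiers.  X is a list/array of residue
strings; y is binary (1 = positive class).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .discovery import (DiscoveryConfig, DNA_PSEUDOCOUNT, PROTEIN_PSEUDOCOUNT,
                        build_pwm, discover_motifs, empirical_background)
from .scoring import ScoringConfig, build_feature_matrix, pwm_threshold
from .seq_io import Dataset, LabeledSequence, get_alphabet


def _as_dataset(X, y, alphabet) -> Dataset:
    labels = np.asarray(y, dtype=int)
    if labels.shape[0] != len(X):
        raise ValueError("X and y lengths differ")
    seqs = [LabeledSequence(f"seq_{i:06d}", str(s).upper(), int(lab))
            for i, (s, lab) in enumerate(zip(X, labels))]
    return Dataset(seqs, alphabet)


class MotifFeaturizer(TransformerMixin, BaseEstimator):
    """Discover discriminative motifs on (X, y) and score sequences with them.

    Parameters
    ----------
    alphabet : 'dna' or 'protein'
    min_motif_len, max_motif_len : int or None
        Word length range for discovery; None picks the alphabet default
        (DNA 5..7, protein 3..4).
    n_motifs : int
        Maximum motifs retained (K).
    mismatches : int or None
        Mismatch allowance m for discrete scoring; None picks the
        alphabet default (DNA 1, protein 0).
    use_pwm : bool
        Build a PWM from each motif's matched discovery sites and score
        with threshold-gated running sums instead of counts.
    pvalue : float
        PWM match p-value for the score threshold.
    pseudocount : float or None
        PWM pseudocount per cell; None picks the alphabet default.
    strand : 'both', 'single' or None
        None = both strands for DNA, single for protein.

    Attributes
    ----------
    motifs_ : list of DiscreteMotif, ranked by enrichment p-value.
    pwms_ : list of PWM (only when use_pwm), thresholds set.
    background_ : residue frequencies of the fit data (pooled classes).
    """

    def __init__(self, alphabet: str = "dna", min_motif_len: int | None = None,
                 max_motif_len: int | None = None, n_motifs: int = 50,
                 mismatches: int | None = None, use_pwm: bool = False,
                 pvalue: float = 1e-3, pseudocount: float | None = None,
                 strand: str | None = None):
        self.alphabet = alphabet
        self.min_motif_len = min_motif_len
        self.max_motif_len = max_motif_len
        self.n_motifs = n_motifs
        self.mismatches = mismatches
        self.use_pwm = use_pwm
        self.pvalue = pvalue
        self.pseudocount = pseudocount
        self.strand = strand

    def _configs(self) -> tuple[DiscoveryConfig, ScoringConfig]:
        alph = get_alphabet(self.alphabet)
        d_over = {}
        if self.min_motif_len is not None:
            d_over["min_len"] = self.min_motif_len
        if self.max_motif_len is not None:
            d_over["max_len"] = self.max_motif_len
        d_over["n_motifs"] = self.n_motifs
        if self.strand is not None:
            d_over["strand"] = self.strand
        s_over = {"pvalue": self.pvalue}
        if self.mismatches is not None:
            s_over["mismatches"] = self.mismatches
        if self.strand is not None:
            s_over["strand"] = self.strand
        return (DiscoveryConfig.for_alphabet(alph, **d_over),
                ScoringConfig.for_alphabet(alph, **s_over))

    def fit(self, X, y):
        alph = get_alphabet(self.alphabet)
        data = _as_dataset(X, y, alph)
        data.require_both_classes()
        disc_cfg, score_cfg = self._configs()
        self.discovery_config_ = disc_cfg
        self.scoring_config_ = score_cfg
        self.motifs_ = discover_motifs(data, disc_cfg)
        if not self.motifs_:
            raise ValueError("no motifs discovered; sequences may be shorter than min_motif_len")
        self.background_ = empirical_background(data)
        if self.use_pwm:
            pc = self.pseudocount
            if pc is None:
                pc = DNA_PSEUDOCOUNT if alph.complementable else PROTEIN_PSEUDOCOUNT
            positives = [s.residues for s in data.sequences if s.label == 1]
            self.pwms_ = []
            for motif in self.motifs_:
                pwm = build_pwm(motif, positives, score_cfg.mismatches, pc,
                                self.background_, alph, disc_cfg.strand)
                pwm.threshold = pwm_threshold(pwm, self.pvalue)
                self.pwms_.append(pwm)
        self.n_features_in_ = 1   # sequences come in as a single column of strings
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "motifs_")
        alph = get_alphabet(self.alphabet)
        data = _as_dataset(X, np.zeros(len(X), dtype=int), alph)
        motifs = self.pwms_ if self.use_pwm else self.motifs_
        fm = self._feature_matrix(data, motifs)
        return fm.values

    def _feature_matrix(self, data: Dataset, motifs):
        return build_feature_matrix(data, motifs, self.scoring_config_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "motifs_")
        if self.use_pwm:
            return np.asarray([f"{p.name}|pwm" for p in self.pwms_], dtype=object)
        return np.asarray([m.word for m in self.motifs_], dtype=object)
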