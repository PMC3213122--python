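import math

import numpy as np
import pytest

from dmfs import (DNA, PROTEIN, Dataset, LabeledSequence, build_pwm,
                  discover_motifs, discrimination_score, empirical_background,
                  enrichment, enumerate_word_stats, reverse_complement,
                  select_motifs)
from dmfs.discovery import DiscoveryConfig, STRAND_BOTH, STRAND_SINGLE

from conftest import random_dna, random_protein


def brute_force_presence(sequences, labels, min_len, max_len, strand):
    """Independent O(n*L*w) substring-scan oracle for presence counts."""
    counts = {}
    for residues, label in zip(sequences, labels):
        seen = set()
        for L in range(min_len, max_len + 1):
            for i in range(len(residues) - L + 1):
                w = residues[i:i + L]
                if "N" in w:
                    continue
                if strand == STRAND_BOTH:
                    w = min(w, reverse_complement(w))
                seen.add(w)
        for w in seen:
            c = counts.setdefault(w, [0, 0])
            c[0 if label == 1 else 1] += 1
    return {w: tuple(c) for w, c in counts.items()}


class TestEnumerateWordStats:
    def test_single_strand_enumeration(self):
        data = Dataset([LabeledSequence("p", "ACGTT", 1),
                        LabeledSequence("n", "GGGGG", 0)], DNA)
        stats = enumerate_word_stats(data, 4, 4, STRAND_SINGLE)
        assert stats == {"ACGT": (1, 0), "CGTT": (1, 0), "GGGG": (0, 1)}

    def test_double_strand_merges_onto_canonical(self):
        data = Dataset([LabeledSequence("p", "TTTT", 1),
                        LabeledSequence("n", "CCCC", 0)], DNA)
        stats = enumerate_word_stats(data, 4, 4, STRAND_BOTH)
        # TTTT counted under AAAA; CCCC under its revcomp GGGG
        assert stats == {"AAAA": (1, 0), "CCCC": (0, 1)}

    def test_presence_not_frequency(self):
        data = Dataset([LabeledSequence("p", "AAAAAAAA", 1),
                        LabeledSequence("n", "CGCG", 0)], DNA)
        stats = enumerate_word_stats(data, 4, 4, STRAND_BOTH)
        assert stats["AAAA"] == (1, 0)  # many occurrences, one sequence

    def test_words_with_n_excluded(self):
        data = Dataset([LabeledSequence("p", "ACNGT", 1),
                        LabeledSequence("n", "GGGGG", 0)], DNA)
        stats = enumerate_word_stats(data, 3, 3, STRAND_SINGLE)
        assert "CNG" not in stats and "ACN" not in stats

    @pytest.mark.parametrize("strand", [STRAND_SINGLE, STRAND_BOTH])
    def test_matches_bruteforce_oracle_dna(self, rng, strand):
        seqs = [random_dna(rng, int(rng.integers(8, 30)), with_n=True)
                for _ in range(10)]
        labels = [1] * 5 + [0] * 5
        data = Dataset([LabeledSequence(f"s{i}", s, lab)
                        for i, (s, lab) in enumerate(zip(seqs, labels))], DNA)
        assert enumerate_word_stats(data, 3, 6, strand) == \
            brute_force_presence(seqs, labels, 3, 6, strand)

    def test_matches_bruteforce_oracle_protein(self, rng):
        seqs = [random_protein(rng, int(rng.integers(10, 40))) for _ in range(8)]
        labels = [1] * 4 + [0] * 4
        data = Dataset([LabeledSequence(f"s{i}", s, lab)
                        for i, (s, lab) in enumerate(zip(seqs, labels))], PROTEIN)
        assert enumerate_word_stats(data, 3, 4, STRAND_SINGLE) == \
            brute_force_presence(seqs, labels, 3, 4, STRAND_SINGLE)

    def test_oversized_max_len_warns_empty(self):
        data = Dataset([LabeledSequence("p", "ACG", 1),
                        LabeledSequence("n", "TTT", 0)], DNA)
        with pytest.warns(UserWarning, match="exceeds"):
            stats = enumerate_word_stats(data, 5, 8, STRAND_SINGLE)
        assert stats == {}


def hypergeom_tail_bruteforce(n_pos, n_neg, N_pos, N_neg):
    """Direct summation of the hypergeometric pmf upper tail."""
    k = n_pos + n_neg
    N = N_pos + N_neg
    total = 0.0
    for x in range(n_pos, min(k, N_pos) + 1):
        total += (math.comb(N_pos, x) * math.comb(N_neg, k - x)) / math.comb(N, k)
    return total


class TestDiscriminationScore:
    def test_no_discrimination_at_symmetry(self):
        assert discrimination_score(5, 5, 10, 10) >= 0.5

    def test_perfect_separation_exact_value(self):
        # all 10 positives contain the word, no negatives: p = 1 / C(20,10)
        p = discrimination_score(10, 0, 10, 10)
        assert p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-12)
        assert p == pytest.approx(5.41e-6, rel=1e-2)

    def test_matches_bruteforce_summation(self, rng):
        for _ in range(200):
            N_pos = int(rng.integers(1, 30))
            N_neg = int(rng.integers(1, 30))
            n_pos = int(rng.integers(0, N_pos + 1))
            n_neg = int(rng.integers(0, N_neg + 1))
            expected = hypergeom_tail_bruteforce(n_pos, n_neg, N_pos, N_neg)
            if n_pos + n_neg == 0:
                expected = 1.0
            assert discrimination_score(n_pos, n_neg, N_pos, N_neg) == \
                pytest.approx(expected, rel=1e-9)

    def test_monotone_in_n_pos(self):
        for n_neg in (0, 3, 7):
            ps = [discrimination_score(n_pos, n_neg, 20, 20) for n_pos in range(21)]
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_degenerate_inputs_return_one(self):
        assert discrimination_score(0, 0, 10, 10) == 1.0
        assert discrimination_score(0, 5, 0, 10) == 1.0

    def test_counts_exceeding_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            discrimination_score(11, 0, 10, 10)

    def test_enrichment_tags_direction(self):
        p_pos, cls_pos = enrichment(9, 1, 10, 10)
        p_neg, cls_neg = enrichment(1, 9, 10, 10)
        assert cls_pos == 1 and cls_neg == 0
        assert p_pos == pytest.approx(p_neg)  # mirrored situations


class TestSelectMotifs:
    def test_ties_break_lexicographically(self):
        stats = {"TTGG": (5, 0), "AACC": (5, 0)}
        motifs = select_motifs(stats, DiscoveryConfig(3, 4, 10, STRAND_SINGLE), 10, 10)
        assert [m.word for m in motifs] == ["AACC", "TTGG"]

    def test_superstring_of_selected_dropped(self):
        stats = {"AAAA": (9, 0), "AAAAT": (8, 0)}
        motifs = select_motifs(stats, DiscoveryConfig(3, 5, 10, STRAND_SINGLE), 10, 10)
        assert [m.word for m in motifs] == ["AAAA"]

    def test_substring_of_selected_dropped(self):
        stats = {"AAAAT": (9, 0), "AAAA": (8, 0)}
        motifs = select_motifs(stats, DiscoveryConfig(3, 5, 10, STRAND_SINGLE), 10, 10)
        assert [m.word for m in motifs] == ["AAAAT"]

    def test_hamming_one_neighbour_dropped(self):
        stats = {"ACGT": (9, 0), "ACTT": (8, 0), "GGCC": (7, 0)}
        motifs = select_motifs(stats, DiscoveryConfig(3, 4, 10, STRAND_SINGLE), 10, 10)
        assert [m.word for m in motifs] == ["ACGT", "GGCC"]

    def test_revcomp_substring_dropped_under_both_strands(self):
        # revcomp(TTTT) = AAAA is a substring of AAAAG
        stats = {"AAAAG": (9, 0), "TTTT": (8, 0)}
        motifs = select_motifs(stats, DiscoveryConfig(3, 5, 10, STRAND_BOTH), 10, 10)
        assert [m.word for m in motifs] == ["AAAAG"]

    def test_k_caps_output(self):
        stats = {w: (5, 0) for w in ("AACC", "GGTT", "CCAA", "TTGG", "AGCT")}
        motifs = select_motifs(stats, DiscoveryConfig(3, 4, 2, STRAND_SINGLE), 10, 10)
        assert len(motifs) == 2
        assert [m.rank for m in motifs] == [1, 2]

    def test_planted_word_ranks_first(self, rng):
        # 20 positives carry a planted word, negatives are background
        planted = "GGATCCGT"
        seqs, labels = [], []
        for i in range(20):
            s = random_dna(rng, 40)
            pos = int(rng.integers(0, 40 - 8))
            seqs.append(s[:pos] + planted + s[pos + 8:])
            labels.append(1)
        for i in range(20):
            seqs.append(random_dna(rng, 40))
            labels.append(0)
        data = Dataset([LabeledSequence(f"s{i}", s, lab)
                        for i, (s, lab) in enumerate(zip(seqs, labels))], DNA)
        motifs = discover_motifs(data, DiscoveryConfig(5, 8, 10, STRAND_BOTH))
        top = motifs[0].word
        variants = (top, reverse_complement(top))
        assert any(t in planted or planted in t for t in variants)


class TestBuildPwm:
    def test_single_occurrence_zero_pseudocount(self):
        bg = np.full(4, 0.25)
        pwm = build_pwm("ACG", ["TACGT"], m=0, pseudocount=0.0, background=bg,
                        alphabet=DNA, strand=STRAND_SINGLE)
        for j, sym in enumerate("ACG"):
            row = pwm.log_odds[j]
            k = DNA.index(sym)
            assert row[k] == pytest.approx(np.log2(4.0))
            assert all(np.isneginf(row[i]) for i in range(4) if i != k)

    def test_pseudocount_makes_entries_finite(self):
        bg = np.full(4, 0.25)
        pwm = build_pwm("ACG", ["TACGT"], m=0, pseudocount=0.25, background=bg,
                        alphabet=DNA, strand=STRAND_SINGLE)
        assert np.isfinite(pwm.log_odds).all()

    def test_count_accumulation_oracle(self, rng):
        # column sums of the count matrix all equal n_sites + |A| * c
        word = "ACGT"
        positives = [random_dna(rng, 30) for _ in range(10)]
        bg = np.full(4, 0.25)
        c = 0.5
        pwm = build_pwm(word, positives, m=1, pseudocount=c, background=bg,
                        alphabet=DNA, strand=STRAND_BOTH)
        # reconstruct counts from probs: rows were normalized by the same total
        n_sites = 0
        for s in positives:
            for i in range(len(s) - 4 + 1):
                win = s[i:i + 4]
                if sum(a != b for a, b in zip(win, word)) <= 1 or \
                   sum(a != b for a, b in zip(win, reverse_complement(word))) <= 1:
                    n_sites += 1
        total = n_sites + 4 * c
        counts = pwm.probs * total
        assert np.allclose(counts.sum(axis=1), total)

    def test_consensus_scan_achieves_max(self, rng):
        from dmfs import pwm_scan_sum
        word = "GATTAC"
        positives = [("T" + word + "T") for _ in range(3)]
        bg = np.full(4, 0.25)
        pwm = build_pwm(word, positives, m=0, pseudocount=0.1, background=bg,
                        alphabet=DNA, strand=STRAND_SINGLE)
        top = pwm_scan_sum(pwm.consensus(), pwm, t=pwm.max_score(), strand=STRAND_SINGLE)
        assert top == pytest.approx(pwm.max_score())

    def test_zero_occurrences_errors(self):
        bg = np.full(4, 0.25)
        with pytest.raises(ValueError, match="no occurrences"):
            build_pwm("AAAA", ["CCCCCC"], m=0, pseudocount=0.1, background=bg,
                      alphabet=DNA, strand=STRAND_SINGLE)


class TestBackground:
    def test_empirical_frequencies(self):
        data = Dataset([LabeledSequence("p", "AACC", 1),
                        LabeledSequence("n", "GGTT", 0)], DNA)
        bg = empirical_background(data)
        assert bg == pytest.approx([0.25, 0.25, 0.25, 0.25])

    def test_n_excluded_from_background(self):
        data = Dataset([LabeledSequence("p", "AANN", 1),
                        LabeledSequence("n", "CC", 0)], DNA)
        bg = empirical_background(data)
        assert bg == pytest.approx([0.5, 0.5, 0.0, 0.0])
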