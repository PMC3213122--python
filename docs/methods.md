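# Methods

## Model and procedure

`dmfs` treats sequence-based two-class classification as a three-level
resampling problem.  The labelled data is first split, stratified by
class, into a *discovery* set (fraction *f*) and a *classification*
set.  Motifs are selected using labels in the discovery set only; the
classification set is then scored with those motifs and handed to a
conventional classifier, whose own resampling (bootstrap/out-of-bag for
the random forest, stratified k-fold cross-validation for the SVM)
provides the training/validation level.  Because the label information
used for feature selection never re-enters training or validation, the
reported AUC is an honest estimate: permuting labels before the split
must, and in our tests does, drive it to ≈ 0.5.

No separate held-out validation set is reserved beyond this:
resampling-based evaluation (OOB, CV) makes one unnecessary, and the
classification set stays as large as possible.

### The reference motif finder

The discovery stage is a contract — any callable mapping a discovery
dataset to a ranked motif list plugs in (`run_once(..., finder=...)`).
The built-in reference finder is enumerative-discriminative:

* **Candidates.** All substrings of length `min_len..max_len` occurring
  in the discovery sequences.  Words containing the DNA ambiguity
  symbol N are excluded.  Under the double-strand policy a word and its
  reverse complement are pooled under the lexicographically smaller
  representative, so one feature represents the AAAA/TTTT pair.
* **Statistic.** Per-class *presence* counts (number of sequences
  containing ≥ 1 occurrence), not total frequency — presence is robust
  to the extreme length heterogeneity of protein data (15–1963
  residues), where long sequences would otherwise dominate frequency
  statistics.  Each word is scored by the hypergeometric tail:
  the probability that, of the `n⁺ + n⁻` containing sequences drawn
  from `N⁺ + N⁻`, at least `n⁺` are positive.  The mirrored tail scores
  enrichment in negatives; the smaller tail wins and tags the motif
  with its enriched class.  Both directions compete in one ranking:
  depletion in positives is as usable a feature as enrichment.
* **Selection.** Ascending p-value, ties broken lexicographically (so
  ranking is fully deterministic), then a redundancy filter: a
  candidate related to an already-kept motif by substring containment
  (either direction, either strand for DNA) or by Hamming distance ≤ 1
  at equal length is dropped.  The first `K` survivors are kept.

### Scoring

Discrete motifs are counted at every start position with Hamming
distance ≤ m, overlaps included, on both strands for DNA.  A motif
equal to its own reverse complement is counted once per position —
otherwise every palindrome hit would be doubled.  A position aligning a
motif symbol against N counts as a mismatch (conservative, deterministic
treatment of ambiguity; N is only a wildcard for DNA — in protein
sequences N is asparagine and matches normally).

PWMs are built from a motif's matched sites in the discovery positives
(windows within m mismatches of the word or its reverse complement,
strand-normalized to the representative orientation), with a
pseudocount added to every cell before row normalization and log₂-odds
against the discovery-set background (both classes pooled — discovery
information only, respecting partition isolation).  Scanning adds every
window whose total log-odds score reaches the threshold to a running
sum; both strands are scanned for DNA.

### PWM threshold

The match threshold for p-value `p` is the smallest achievable total
score `t` with `P(score ≥ t) ≤ p` for a window drawn i.i.d. from the
background.  The distribution is built by exact dynamic programming
over per-position scores discretized to 10⁻³ log₂ units; at that
granularity the discretization error of an L-position window score is
bounded by L·5·10⁻⁴ — far below typical gaps between achievable scores
— and exhaustive enumeration over all 4^L words (the test oracle)
confirms exactness on the discretized grid.  When `p` is below the
probability of even the single best word, only the optimum is matched.
The lookahead scan (abandon a window when prefix score + best
achievable suffix < t) accumulates scores in the same position order as
the naive scan, making the two paths float-identical, not merely close.

## Parameters

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| f | discovery fraction | 0.10 | leaves 90% of data for classification while a 2×1000-sequence dataset still yields 200 discovery sequences; a key tuning knob that should be explored per dataset |
| min/max motif length | word lengths enumerated | DNA 5–7, protein 3–4 | heptamers suit 50-mer DNA; the 20-letter alphabet forces shorter protein words (20⁴ already = 160 000 patterns) |
| K | motifs retained | 50 | keeps the feature set small relative to enumerative counts (10³–10⁴) while giving the classifier room beyond the top hit |
| m | mismatches in discrete scoring | DNA 1, protein 0 | with w = 7 and m = 1 the expected number of spurious neighbourhood matches stays below ~1 per 50-mer; protein words are too short to loosen |
| p | PWM match p-value | 10⁻³ | conventional scanner operating point |
| pseudocount | PWM smoothing per cell | DNA 0.25, protein 0.05 | Laplace smoothing proportional to 1/alphabet size |
| RF | 500 trees, mtry = ⌈P/3⌉ | — | classic forest defaults; OOB AUC needs no extra split |
| SVM | RBF width 1/P, cost 1 | — | LIBSVM-style defaults; features standardized with training-fold statistics (RBF kernels need comparable scales; the forest is scale-invariant and gets raw counts) |
| tuning grids | RF mtry ∈ {⌈P/3⌉, ⌈√P⌉, P}; SVM cost ∈ {0.1,1,10,100}, width ∈ {0.1,1,10}/P | — | modest, symmetric around the defaults; ties break toward the default |

Per-class discovery counts are `floor(f·n + 0.5)`; an `f` that gives a
class zero discovery sequences (or consumes a whole class) is an error
rather than being silently clamped.

Seeds: a master seed spawns independent per-run and per-component
streams via `numpy.random.SeedSequence`, so repeat runs are
reproducible, independent of thread count and completion order, and
never reuse a stream across components.

## Evaluation choices

* **AUC** is computed by the rank (Mann–Whitney) formulation with ties
  contributing 1/2 — identical to the O(n²) pairwise definition.
* **RF:** a row's score is its out-of-bag positive-vote fraction; rows
  never out of bag (probability ≈ (1/e)⁰·⁵ᵏ, negligible at 500 trees)
  are excluded with a warning.  The bagging loop is implemented in the
  package so per-tree in-bag masks, OOB vote fractions and per-tree OOB
  fractions (≈ 1 − 1/e ≈ 0.368) are explicit fitted attributes; the
  trees are scikit-learn's.
* **SVM:** decision values from the k held-out folds are pooled into a
  single AUC/ROC rather than averaging per-fold AUCs — one curve per
  run, and no small-fold variance inflation.
* **Aggregation** over R repeated partitions reports mean and
  sample SD (ddof = 1; SD = 0 when R = 1).  Grid tuning, when enabled,
  is re-run within each repeat.

## What the simulator does and does not emulate

The generator reproduces the *shape* of the two benchmark regimes —
balanced fixed-length DNA 50-mers, and balanced variable-length protein
with log-uniform lengths on 15–1963 — with an i.i.d. (default uniform)
background and at most one planted instance per positive (probability
q, d substitutions, uniform position and strand).  It does not model
composition bias unless given a skewed background, nor positional
preference, motif co-occurrence, phylogenetic correlation between
sequences, or the biophysics of real nucleosome sequence preference
(e.g. dinucleotide periodicity).  Passing planted-motif tests therefore
demonstrates that the pipeline recovers and exploits a genuine
discriminative signal and reports honestly under the null — not that
any particular real-data AUC will be attained.

Test problem sizes (300 sequences per class, 20 repeat partitions) were
chosen as the smallest at which the planted signal is comfortably in
the stable regime — recovery and AUC results plateau well below these
sizes.

## Numerical and degenerate-input conventions

* Hypergeometric tails come from `scipy.stats.hypergeom.sf`; degenerate
  inputs (no containing sequences, an empty class) score 1, and
  p-values are clamped into (0, 1].
* Positions are 0-based half-open internally; only counts and sums are
  emitted, so no coordinate convention leaks into outputs.
* Sequences shorter than a motif score 0; PWM windows containing N are
  skipped.
* The running PWM sum is non-increasing in the threshold only on t ≥ 0:
  lowering t below zero admits negative-score windows that reduce the
  sum.  Thresholds at practically relevant p-values are positive.
* Feature matrices re-serialize bit-identically (fixed `%.10g`
  formatting), making repeat runs auditable by byte comparison.

## Known limitations

* The reference finder is exhaustive over `|A|^w` words; protein
  max_len beyond 5 becomes memory-heavy.  Plug in a heuristic finder
  for longer protein motifs.
* No gapped/spaced motifs, IUPAC consensus merging, or EM refinement.
* Multi-class and continuous outcomes are out of scope.
* Grid tuning maximizes the same OOB/CV estimate it reports, so tuned
  AUCs carry mild selection optimism; the repeated-partition SD makes
  this visible.
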