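"""Pipeline orchestration over repeated random partitions.

Each run: stratified discovery/classification split -> motif discovery
on the discovery set only -> scoring of the classification set ->
classifier evaluation (OOB AUC for RF, pooled k-fold CV AUC for SVM).
Runs are repeated over independent random partitions (to wash out
file-ordering artifacts and give a robust mean/SD of AUC) and recovery
of reference motifs across runs can be counted.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .classify_eval import ClassifierSpec, RF, RunResult, evaluate, grid_tune
from .discovery import (DiscoveryConfig, DiscreteMotif, STRAND_BOTH,
                        write_motifs_tsv)
from .featurize import MotifFeaturizer
from .partition import SplitSpec, spawn_seed, stratified_split, write_partition_tsv
from .scoring import FeatureMatrix, ScoringConfig
from .seq_io import Dataset, get_alphabet, reverse_complement

logger = logging.getLogger("dmfs")

MotifFinder = Callable[[Dataset], list[DiscreteMotif]]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one full multi-run pipeline execution needs."""

    alphabet: str = "dna"
    discovery_fraction: float = 0.1
    min_motif_len: int | None = None
    max_motif_len: int | None = None
    n_motifs: int = 50
    mismatches: int | None = None
    use_pwm: bool = False
    pvalue: float = 1e-3
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    tune: bool = False
    n_runs: int = 1
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("number of runs must be >= 1")

    def featurizer(self) -> MotifFeaturizer:
        return MotifFeaturizer(
            alphabet=self.alphabet, min_motif_len=self.min_motif_len,
            max_motif_len=self.max_motif_len, n_motifs=self.n_motifs,
            mismatches=self.mismatches, use_pwm=self.use_pwm, pvalue=self.pvalue,
        )


@dataclass
class AggregateResult:
    """Per-run results plus mean/SD of AUC over repeated partitions."""

    runs: list[RunResult]
    mean_auc: float
    sd_auc: float
    failures: list[tuple[int, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_runs": len(self.runs),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "per_run_auc": [r.auc for r in self.runs],
            "failures": [{"run": i, "error": msg} for i, msg in self.failures],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def aggregate(runs: Sequence[RunResult],
              failures: Sequence[tuple[int, str]] = ()) -> AggregateResult:
    aucs = np.array([r.auc for r in runs])
    mean = float(aucs.mean())
    sd = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
    return AggregateResult(list(runs), mean, sd, list(failures))


def run_once(data: Dataset, config: PipelineConfig, run_seed: int,
             outdir: str | Path | None = None,
             finder: MotifFinder | None = None) -> RunResult:
    """One full pipeline pass at a single random partition.

    A custom ``finder`` (discovery Dataset -> ranked DiscreteMotif list)
    may replace the reference discriminative word finder; everything
    else in the pipeline is unchanged — the discovery stage is a
    pluggable component.
    """
    t0 = time.perf_counter()
    stage = "partition"
    try:
        split = stratified_split(data, SplitSpec(config.discovery_fraction,
                                                 spawn_seed(run_seed, 0)))
        discovery = data.subset(split.discovery_ids)
        classification = data.subset(split.classification_ids)
        if len(classification) < len(discovery):
            warnings.warn(
                f"classification set ({len(classification)}) smaller than discovery "
                f"set ({len(discovery)}); consider a smaller discovery fraction",
                stacklevel=2,
            )
        stage = "discovery"
        featurizer = config.featurizer()
        if finder is not None:
            motifs = finder(discovery)
            if not motifs:
                raise ValueError("pluggable finder returned no motifs")
            featurizer.fit(discovery.residues, discovery.labels)  # configs + background
            featurizer.motifs_ = motifs
        else:
            featurizer.fit(discovery.residues, discovery.labels)
            motifs = featurizer.motifs_
        stage = "scoring"
        scoring_cfg = featurizer.scoring_config_
        fm = featurizer._feature_matrix(
            classification, featurizer.pwms_ if config.use_pwm else motifs)
        # anti-leakage contract: no discovery id may reach the classifier
        leaked = set(split.discovery_ids) & set(fm.ids)
        assert not leaked, f"discovery ids leaked into the feature matrix: {sorted(leaked)[:5]}"
        stage = "classification"
        eval_seed = spawn_seed(run_seed, 1)
        if config.tune:
            _, result = grid_tune(fm, config.classifier, seed=eval_seed)
        else:
            result = evaluate(fm, config.classifier, eval_seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed (run seed {run_seed}): {exc}") from exc
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_partition_tsv(outdir / "partition.tsv", split)
        write_motifs_tsv(outdir / "motifs.tsv", motifs)
        fm.to_tsv(outdir / "features.tsv")
        result.to_json(outdir / "result.json")
        result.roc_to_tsv(outdir / "roc.tsv")
    logger.info("run seed=%d auc=%.4f (%.1fs)", run_seed, result.auc,
                time.perf_counter() - t0)
    return result


def run_repeats(data: Dataset, config: PipelineConfig,
                outdir: str | Path | None = None,
                finder: MotifFinder | None = None) -> AggregateResult:
    """Repeat ``run_once`` over R independent random partitions.

    Per-run seeds derive from the master seed and run index, so results
    are identical whatever the thread count or completion order.  Failed
    runs are recorded and excluded; more than 10% failures raises.
    """
    seeds = [spawn_seed(config.seed, r) for r in range(config.n_runs)]

    def one(r: int, s: int):
        sub = None if outdir is None else Path(outdir) / f"run_{r}"
        try:
            return r, run_once(data, config, s, sub, finder), None
        except Exception as exc:  # recorded, not fatal per-run
            return r, None, str(exc)

    outcomes = Parallel(n_jobs=config.n_jobs)(
        delayed(one)(r, s) for r, s in enumerate(seeds))
    outcomes.sort(key=lambda t: t[0])
    runs = [res for _, res, err in outcomes if err is None]
    failures = [(r, err) for r, _, err in outcomes if err is not None]
    if not runs or len(failures) > 0.1 * config.n_runs:
        raise RuntimeError(
            f"{len(failures)}/{config.n_runs} pipeline runs failed: "
            + "; ".join(msg for _, msg in failures[:3])
        )
    agg = aggregate(runs, failures)
    if outdir is not None:
        agg.to_json(Path(outdir) / "summary.json")
    return agg


def count_motif_recovery(reference: Sequence[str],
                         runs: Sequence[Sequence[DiscreteMotif | str]],
                         strand: str = STRAND_BOTH,
                         alphabet: str = "dna") -> dict[str, int]:
    """How many runs rediscovered each reference word.

    A reference word is recovered in a run when it occurs as a substring
    of at least one discovered motif — on either strand under the DNA
    policy, so e.g. the pair GAAA/TTTC counts as one motif and TTTC is
    found inside a GAAA-containing word via its reverse complement.
    """
    alph = get_alphabet(alphabet)
    counts: dict[str, int] = {}
    for ref in reference:
        targets = {ref}
        if strand == STRAND_BOTH and alph.complementable:
            targets.add(reverse_complement(ref))
        n = 0
        for run_motifs in runs:
            words = [m.word if isinstance(m, DiscreteMotif) else str(m)
                     for m in run_motifs]
            if any(t in w for w in words for t in targets):
                n += 1
        counts[ref] = n
    return counts
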