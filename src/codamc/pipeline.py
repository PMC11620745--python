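"""End-to-end convenience wrappers: synthetic dataset -> activities ->
covariation map -> annealed consensus structure."""

from __future__ import annotations

from dataclasses import dataclass

from .activity import (
    CAPTURE,
    ActivityTable,
    CountTable,
    relative_activity_capture,
    relative_activity_cleavage,
)
from .coda import ClassifierParams, PairProbabilityMap, coda_pipeline
from .fixtures import GroundTruth
from .mcfold import (
    EnsembleResult,
    McConfig,
    SecondaryStructure,
    consensus_structure,
    ensemble_pair_frequencies,
)
from .structools import element_decomposition
from .synth import ChannelDesign, LibraryConfig, generate_dataset

__all__ = [
    "RecoveryResult",
    "activity_from_counts",
    "recover_structure",
    "stem_sizes",
    "largest_stem_size",
]


def activity_from_counts(
    counts: CountTable, min_reads: int = 20, max_mutations: int | None = 3
) -> ActivityTable:
    """Dispatch to the RA or RA' estimator by channel semantics."""
    if counts.mode == CAPTURE:
        return relative_activity_capture(counts, min_reads, max_mutations)
    return relative_activity_cleavage(counts, min_reads, max_mutations)


@dataclass
class RecoveryResult:
    table: ActivityTable
    probs: PairProbabilityMap
    ensemble: EnsembleResult
    consensus: SecondaryStructure


def recover_structure(
    truth: GroundTruth,
    seed: int = 0,
    lib_config: LibraryConfig | None = None,
    design: ChannelDesign | None = None,
    mc_config: McConfig | None = None,
    classifier_params: ClassifierParams | None = None,
    freq_threshold: float = 0.8,
    min_reads: int = 20,
) -> RecoveryResult:
    """One full synthetic recovery: generate, estimate activities, score
    covariation, anneal an ensemble, and take the consensus structure."""
    counts = generate_dataset(truth, lib_config, design, seed=seed)
    table = activity_from_counts(counts, min_reads=min_reads)
    probs = coda_pipeline(table, params=classifier_params, seed=seed)
    ensemble = ensemble_pair_frequencies(
        truth.sequence, probs, mc_config or McConfig(), seed=(seed * 1000 + 1) % 2**31
    )
    cons = consensus_structure(ensemble, freq_threshold)
    return RecoveryResult(table, probs, ensemble, cons)


def stem_sizes(s: SecondaryStructure) -> list[int]:
    """Pair counts of all stems, largest first."""
    els = element_decomposition(s)
    return sorted(
        (e.length for e in els.elements if e.kind == "stem"), reverse=True
    )


def largest_stem_size(s: SecondaryStructure) -> int:
    sizes = stem_sizes(s)
    return sizes[0] if sizes else 0
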