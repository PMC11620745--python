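"""Synthetic deep-mutational-scanning data with a planted secondary structure.

The generator emulates the statistical structure the downstream analysis
relies on, without any read-level detail:

* a mutant library from either a chemically synthesised *doped* pool
  (independent per-position substitution at a fixed doping rate, 6% by
  default) or an *error-prone PCR* pool whose substitutions are biased toward
  A/U template positions and toward transitions;
* cleavage activities from a multiplicative lesion model on the planted
  structure, with compensatory rescue: a double substitution that restores
  Watson-Crick, wobble or the planted non-canonical identity at a true pair
  pays no penalty, and converting a wobble pair to Watson-Crick *raises*
  activity above wild type;
* two sequencing designs: cleaved/uncleaved counting of the RNA pool, or
  DNA-seq/RNA-seq counting after selective capture of cleaved molecules.

Everything is deterministic given the seeds carried in the configs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import CAPTURE, CHANNEL_COLUMNS, CLEAVED_UNCLEAVED, CountTable
from .fixtures import GroundTruth, make_ground_truth, pair_class_of
from .variants import WT_KEY, InconsistentVariant, parse_key

__all__ = [
    "LibraryConfig",
    "ChannelDesign",
    "simulate_activity",
    "sample_library",
    "sample_counts",
    "generate_dataset",
    "save_dataset",
    "write_ground_truth",
    "make_ground_truth",
]

_PURINES = {"A": "G", "G": "A"}
_PYRIMIDINES = {"C": "U", "U": "C"}
_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class LibraryConfig:
    """Mutation spectrum and size of the variant library.

    ``doping_rate`` is the per-position substitution probability (exact in
    doped mode; the across-position mean in error-prone mode, where A/U
    positions are ``ep_at_bias`` times as mutable as G/C positions and
    transitions are ``ep_transition_bias`` times as likely as each
    transversion).
    """

    spectrum: str = "doped"  # doped | error_prone
    doping_rate: float = 0.06
    ep_transition_bias: float = 3.0
    ep_at_bias: float = 2.0
    n_molecules: int = 500_000
    max_mutations_kept: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectrum not in ("doped", "error_prone"):
            raise ValueError(f"unknown spectrum {self.spectrum!r}")
        if not (0 <= self.doping_rate < 1):
            raise ValueError("doping_rate must be in [0,1)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass(frozen=True)
class ChannelDesign:
    """Sequencing design producing the two count channels.

    ``cleaved_uncleaved``: one RNA pool of ``depth_rna`` reads is drawn
    multinomially over variants; each variant's reads then split into cleaved
    vs uncleaved with its cleavage probability (``depth_dna`` is unused — both
    channels come from the same pool).  ``capture``: ``depth_dna`` DNA-seq
    reads follow library abundance and ``depth_rna`` RNA-seq reads follow
    abundance x cleavage probability x ``capture_efficiency``.
    """

    mode: str = CAPTURE
    depth_dna: int = 5_000_000
    depth_rna: int = 5_000_000
    capture_efficiency: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in CHANNEL_COLUMNS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.depth_dna < 1 or self.depth_rna < 1:
            raise ValueError("channel depths must be >= 1")
        if not (0 < self.capture_efficiency <= 1):
            raise ValueError("capture_efficiency must be in (0,1]")


def simulate_activity(mutations: dict[int, str], truth: GroundTruth) -> float:
    """Cleavage activity of a variant relative to wild type (wild type = 1).

    Multiplicative over independent lesions: each disrupted true pair
    contributes ``delta_pair_break``; each mutated conserved-loop position
    contributes ``delta_loop``; a substitution set that leaves a true pair
    Watson-Crick, wobble, or at its planted non-canonical identity pays no
    penalty, and a wobble pair converted to Watson-Crick contributes
    ``wobble_gain`` (> 1).  The product is capped at ``activity_cap``.
    """
    p = truth.activity_params
    wt = truth.sequence
    for pos, alt in mutations.items():
        if not (1 <= pos <= len(wt)):
            raise InconsistentVariant(f"position {pos} out of range")
        if alt == wt[pos - 1]:
            raise InconsistentVariant(f"alt equals wild type at {pos}")
    a = 1.0
    for i, j, cls in truth.true_pairs:
        if i not in mutations and j not in mutations:
            continue
        xi = mutations.get(i, wt[i - 1])
        xj = mutations.get(j, wt[j - 1])
        new_cls = pair_class_of(xi, xj)
        if new_cls == "watson_crick":
            a *= p.wobble_gain if cls == "wobble" else 1.0
        elif new_cls == "wobble":
            pass  # still paired
        elif cls == "noncanonical" and (xi, xj) == (wt[i - 1], wt[j - 1]):
            pass  # planted identity restored
        else:
            a *= p.delta_pair_break
    for pos in mutations:
        if pos in truth.loop_conserved:
            a *= p.delta_loop
    return min(a, p.activity_cap)


def _position_rates_and_alt_weights(
    truth: GroundTruth, config: LibraryConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position mutation probability, alternative letters (L x 3) and
    cumulative alternative-choice probabilities (L x 3)."""
    L = truth.length
    wt = truth.sequence
    alts = np.empty((L, 3), dtype="<U1")
    alt_w = np.ones((L, 3))
    for idx, ref in enumerate(wt):
        others = [b for b in "ACGU" if b != ref]
        alts[idx] = others
        if config.spectrum == "error_prone":
            transition = _PURINES.get(ref) or _PYRIMIDINES.get(ref)
            alt_w[idx] = [
                config.ep_transition_bias if b == transition else 1.0 for b in others
            ]
    if config.spectrum == "doped":
        rates = np.full(L, config.doping_rate)
    else:
        w = np.array(
            [config.ep_at_bias if b in "AU" else 1.0 for b in wt], dtype=float
        )
        rates = config.doping_rate * w / w.mean()
    cum = np.cumsum(alt_w, axis=1)
    cum /= cum[:, -1:]
    return rates, alts, cum


def sample_library(
    truth: GroundTruth, config: LibraryConfig
) -> list[tuple[str, int]]:
    """Draw ``n_molecules`` variant molecules; return (variant key, count) pairs.

    Positions mutate independently; counts sum to ``n_molecules`` exactly.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = truth.length
    wt = truth.sequence
    rates, alts, cum = _position_rates_and_alt_weights(truth, config)
    counts: dict[str, int] = {}
    chunk = 100_000
    remaining = config.n_molecules
    refs = np.array(list(wt))
    pos_labels = np.array([f"{refs[k]}{k + 1}" for k in range(L)])
    while remaining > 0:
        n = min(chunk, remaining)
        remaining -= n
        mask = rng.random((n, L)) < rates[None, :]
        n_wt = int((~mask.any(axis=1)).sum())
        if n_wt:
            counts[WT_KEY] = counts.get(WT_KEY, 0) + n_wt
        rows, poss = np.nonzero(mask)
        if rows.size == 0:
            continue
        u = rng.random(rows.size)
        alt_idx = (u[:, None] > cum[poss]).sum(axis=1)
        alt = alts[poss, alt_idx]
        tokens = np.char.add(pos_labels[poss], alt)
        df = pd.DataFrame({"row": rows, "token": tokens})
        keys = df.groupby("row", sort=False)["token"].agg(";".join)
        for key, cnt in keys.value_counts().items():
            counts[key] = counts.get(key, 0) + int(cnt)
    return sorted(counts.items())


def _activities(library: list[tuple[str, int]], truth: GroundTruth) -> np.ndarray:
    return np.array(
        [simulate_activity(parse_key(k, truth.sequence), truth) for k, _ in library]
    )


def sample_counts(
    library: list[tuple[str, int]],
    truth: GroundTruth,
    design: ChannelDesign,
    seed: int = 0,
) -> CountTable:
    """Sequence the library under a channel design; returns a CountTable.

    Cleavage probability of a variant is ``min(activity * p_wt, 1)``.
    Multinomial read draws at the configured depths; deterministic given
    ``seed``.
    """
    if not library:
        raise ValueError("library is empty")
    rng = np.random.default_rng(seed)
    keys = [k for k, _ in library]
    m = np.array([c for _, c in library], dtype=float)
    act = _activities(library, truth)
    p_cleave = np.minimum(act * truth.activity_params.p_wt, 1.0)
    if design.mode == CLEAVED_UNCLEAVED:
        total = rng.multinomial(design.depth_rna, m / m.sum())
        cleaved = rng.binomial(total, p_cleave)
        c1, c2 = cleaved, total
    else:
        dna = rng.multinomial(design.depth_dna, m / m.sum())
        w = m * p_cleave * design.capture_efficiency
        if w.sum() == 0:
            raise ValueError("no cleavable molecules; RNA channel undefined")
        rna = rng.multinomial(design.depth_rna, w / w.sum())
        c1, c2 = dna, rna
    cols = CHANNEL_COLUMNS[design.mode]
    df = pd.DataFrame({"variant": keys, cols[0]: c1, cols[1]: c2})
    return CountTable(df, design.mode, truth.sequence)


def generate_dataset(
    truth: GroundTruth,
    config: LibraryConfig | None = None,
    design: ChannelDesign | None = None,
    seed: int | None = None,
) -> CountTable:
    """Library sampling followed by sequencing, in one deterministic call.

    ``seed`` (if given) overrides ``config.seed`` and also seeds sequencing.
    """
    config = config or LibraryConfig()
    design = design or ChannelDesign()
    if seed is not None:
        config = LibraryConfig(**{**asdict(config), "seed": seed})
    library = sample_library(truth, config)
    return sample_counts(library, truth, design, seed=config.seed + 1)


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Serialise a fixture: FASTA, dot-bracket, and a TSV of non-canonical pairs."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .mcfold import SecondaryStructure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = SeqRecord(Seq(truth.sequence), id=truth.name, description="")
    SeqIO.write([rec], outdir / f"{truth.name}.fasta", "fasta")
    ss = SecondaryStructure(
        truth.sequence,
        frozenset((i, j) for i, j, _ in truth.true_pairs),
        whitelist=frozenset(
            (i, j) for i, j, cls in truth.true_pairs if cls == "noncanonical"
        ),
    )
    (outdir / f"{truth.name}.db").write_text(
        f">{truth.name}\n{truth.sequence}\n{ss.to_dotbracket()}\n"
    )
    nc = [(i, j) for i, j, cls in truth.true_pairs if cls == "noncanonical"]
    with open(outdir / f"{truth.name}.noncanonical.tsv", "w") as fh:
        fh.write("i\tj\n")
        for i, j in nc:
            fh.write(f"{i}\t{j}\n")


def save_dataset(
    counts: CountTable,
    outdir: str | Path,
    config: LibraryConfig,
    design: ChannelDesign,
    seed: int | None = None,
) -> None:
    """Write counts.tsv plus a JSON sidecar recording config and seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.write_tsv(outdir / "counts.tsv")
    meta = {
        "library_config": asdict(config),
        "channel_design": asdict(design),
        "seed": config.seed if seed is None else seed,
        "wt_sequence": counts.wt_sequence,
        "mode": counts.mode,
    }
    (outdir / "counts.json").write_text(json.dumps(meta, indent=2) + "\n")
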