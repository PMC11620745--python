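"""Monte-Carlo simulated annealing over secondary structures with a
covariation scoring term (CODA+MC).

A structure is scored by

    score(S) = E(S) - w * sum_{(i,j) in S} logit(P(i,j))

where ``E`` is a simplified stacking-based energy (shipped constants: each
adjacent pair of stacked base pairs contributes minus the mean of the two
pairs' strengths) and ``P(i,j)`` is the covariation-derived posterior pairing
probability, clipped away from 0 and 1 before the logit.  Lower scores are
better: well-supported pairs (P near 1) are rewarded, unsupported ones
(P below the pairing prior) are penalised, and with ``w = 0`` the search
reduces to pure energy minimisation.  Short-range pairs (|i-j| < 6) have
their covariation term halved, since local rescue signals are unreliable.

Structures are pseudoknot-free, each position pairs at most once, hairpin
loops keep >= 3 unpaired bases, and paired letters must be Watson-Crick or
wobble unless a pair is explicitly whitelisted (which the annealer does for
pairs whose posterior clears ``whitelist_threshold`` — the only route by
which non-canonical pairs such as A·A can enter a model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log
from pathlib import Path

import numpy as np

from .fixtures import pair_class_of

__all__ = [
    "SecondaryStructure",
    "McConfig",
    "EnsembleResult",
    "structure_score",
    "mc_anneal",
    "ensemble_pair_frequencies",
    "consensus_structure",
    "enumerate_structures",
    "read_dotbracket",
    "write_dotbracket",
]

#: helix stability units per pair type; non-canonical (whitelisted) pairs
#: stack but contribute no strength of their own
PAIR_STRENGTH = {
    ("G", "C"): 3.3,
    ("C", "G"): 3.3,
    ("A", "U"): 2.2,
    ("U", "A"): 2.2,
    ("G", "U"): 1.4,
    ("U", "G"): 1.4,
}

MIN_HAIRPIN = 3  # unpaired bases enclosed by an innermost pair
LOCAL_SPAN = 6  # |i-j| below this -> covariation term halved
_EPS = 0.01  # probability clip for the logit


class InvalidStructure(ValueError):
    pass


def _check_nested(pairs: list[tuple[int, int]]) -> None:
    stack: list[int] = []
    opens = {i: j for i, j in pairs}
    closes = {j: i for i, j in pairs}
    for pos in sorted(set(opens) | set(closes)):
        if pos in opens:
            stack.append(opens[pos])
        else:
            if not stack or stack[-1] != pos:
                raise InvalidStructure("crossing pairs (pseudoknot)")
            stack.pop()


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs (1-based, i<j) over a sequence."""

    sequence: str
    pairs: frozenset[tuple[int, int]]
    whitelist: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise InvalidStructure(f"pair ({i},{j}) out of range")
            if j - i <= MIN_HAIRPIN:
                raise InvalidStructure(f"hairpin loop under ({i},{j}) too small")
            if i in seen or j in seen:
                raise InvalidStructure(f"position paired twice at ({i},{j})")
            seen.update((i, j))
            if (
                pair_class_of(self.sequence[i - 1], self.sequence[j - 1]) is None
                and (i, j) not in self.whitelist
            ):
                raise InvalidStructure(
                    f"non-canonical letters {self.sequence[i - 1]}·"
                    f"{self.sequence[j - 1]} at ({i},{j}) not whitelisted"
                )
        _check_nested(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i], out[j] = j, i
        return out

    def to_dotbracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i - 1], s[j - 1] = "(", ")"
        return "".join(s)

    @classmethod
    def from_dotbracket(cls, sequence: str, db: str) -> "SecondaryStructure":
        if len(db) != len(sequence):
            raise InvalidStructure("dot-bracket length mismatch")
        stack: list[int] = []
        pairs = set()
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise InvalidStructure("unbalanced brackets")
                pairs.add((stack.pop(), pos))
            elif ch != ".":
                raise InvalidStructure(f"unexpected character {ch!r}")
        if stack:
            raise InvalidStructure("unbalanced brackets")
        wl = frozenset(
            (i, j)
            for i, j in pairs
            if pair_class_of(sequence[i - 1], sequence[j - 1]) is None
        )
        return cls(sequence, frozenset(pairs), whitelist=wl)


def write_dotbracket(s: SecondaryStructure, path: str | Path, name: str = "seq") -> None:
    Path(path).write_text(f">{name}\n{s.sequence}\n{s.to_dotbracket()}\n")


def read_dotbracket(path: str | Path) -> SecondaryStructure:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise InvalidStructure("expected sequence and structure lines")
    return SecondaryStructure.from_dotbracket(lines[0].upper().replace("T", "U"), lines[1])


@dataclass(frozen=True)
class McConfig:
    """Annealing schedule and covariation weighting.

    Geometric cooling from ``t_start`` to ``t_end`` by ``cooling`` with
    ``steps_per_temp`` proposals at each temperature; ``coda_weight`` is the
    weighting factor w (default 2) on the covariation term; pairs with
    posterior >= ``whitelist_threshold`` may enter a model even with
    non-canonical letters.
    """

    coda_weight: float = 2.0
    t_start: float = 2.0
    t_end: float = 0.05
    cooling: float = 0.95
    steps_per_temp: int = 100
    n_runs: int = 25
    whitelist_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.coda_weight < 0:
            raise ValueError("coda_weight must be >= 0")
        if not (self.t_start > self.t_end > 0):
            raise ValueError("require t_start > t_end > 0")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0,1)")


def _logit(p: float) -> float:
    p = min(max(p, _EPS), 1.0 - _EPS)
    return log(p / (1.0 - p))


def _prob_getter(probs, length: int):
    """Normalise a probability source to a callable (i,j)->P.

    Accepts None (no covariation term), a plain dict, or any object with a
    ``prob_of(i, j)`` method (e.g. coda.PairProbabilityMap).  Pairs absent
    from a dict default to the pairing prior 2/L.
    """
    if probs is None:
        return None
    if hasattr(probs, "prob_of"):
        return probs.prob_of
    prior = 2.0 / length
    return lambda i, j: probs.get((i, j), prior)


def _stack_energy(s1: float, s2: float) -> float:
    return -0.5 * (s1 + s2)


def _pair_strength(seq: str, i: int, j: int) -> float:
    return PAIR_STRENGTH.get((seq[i - 1], seq[j - 1]), 0.0)


def structure_score(
    s: SecondaryStructure,
    seq: str | None = None,
    probs=None,
    w: float = 2.0,
) -> float:
    """Energy minus weighted covariation support; lower is better."""
    seq = seq or s.sequence
    partner = s.partner()
    e = 0.0
    for i, j in s.pairs:
        if partner.get(i + 1) == j - 1:
            e += _stack_energy(_pair_strength(seq, i, j), _pair_strength(seq, i + 1, j - 1))
    getp = _prob_getter(probs, len(seq))
    coda = 0.0
    if getp is not None and w != 0.0:
        for i, j in s.pairs:
            term = _logit(getp(i, j))
            if j - i < LOCAL_SPAN:
                term *= 0.5
            coda += term
    return e - w * coda


def _candidates(
    seq: str, getp, whitelist_threshold: float
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], float], set[tuple[int, int]]]:
    n = len(seq)
    cands: list[tuple[int, int]] = []
    strength: dict[tuple[int, int], float] = {}
    wl: set[tuple[int, int]] = set()
    for i in range(1, n + 1):
        for j in range(i + MIN_HAIRPIN + 1, n + 1):
            canonical = pair_class_of(seq[i - 1], seq[j - 1]) is not None
            if not canonical:
                if getp is None or getp(i, j) < whitelist_threshold:
                    continue
                wl.add((i, j))
            cands.append((i, j))
            strength[(i, j)] = _pair_strength(seq, i, j)
    return cands, strength, wl


def mc_anneal(
    seq: str,
    probs=None,
    config: McConfig | None = None,
    seed: int = 0,
) -> SecondaryStructure:
    """Metropolis simulated annealing; returns the best structure visited.

    Moves: add a candidate pair, remove a pair, or slide one end of a pair by
    one position.  Deterministic given ``seed``.
    """
    config = config or McConfig()
    if len(seq) < 8:
        raise ValueError("sequence too short to fold (need >= 8 nt)")
    rng = np.random.default_rng(seed)
    getp = _prob_getter(probs, len(seq))
    cands, strength, wl = _candidates(seq, getp, config.whitelist_threshold)
    w = config.coda_weight
    bonus: dict[tuple[int, int], float] = {}
    for ij in cands:
        if getp is None or w == 0.0:
            bonus[ij] = 0.0
        else:
            term = _logit(getp(*ij))
            if ij[1] - ij[0] < LOCAL_SPAN:
                term *= 0.5
            bonus[ij] = w * term

    partner: dict[int, int] = {}
    pairs: set[tuple[int, int]] = set()

    def add_delta(i: int, j: int) -> float:
        d = -bonus[(i, j)]
        if partner.get(i - 1) == j + 1:
            d += _stack_energy(strength[(i - 1, j + 1)], strength[(i, j)])
        if partner.get(i + 1) == j - 1:
            d += _stack_energy(strength[(i, j)], strength[(i + 1, j - 1)])
        return d

    def can_add(i: int, j: int) -> bool:
        if i in partner or j in partner:
            return False
        # nestedness against current pairs
        for k, l in pairs:
            if (k < i < l < j) or (i < k < j < l):
                return False
        return True

    def apply_add(i: int, j: int) -> None:
        pairs.add((i, j))
        partner[i], partner[j] = j, i

    def apply_remove(i: int, j: int) -> None:
        pairs.discard((i, j))
        del partner[i], partner[j]

    score = 0.0
    best_score = 0.0
    best_pairs: frozenset[tuple[int, int]] = frozenset()

    n_temps = 0
    t = config.t_start
    while t > config.t_end:
        n_temps += 1
        t *= config.cooling
    temps = config.t_start * config.cooling ** np.arange(n_temps)

    n_cands = len(cands)
    for t in temps:
        for _ in range(config.steps_per_temp):
            move = rng.random()
            if move < 0.45 or not pairs:
                i, j = cands[int(rng.integers(n_cands))]
                if not can_add(i, j):
                    continue
                d = add_delta(i, j)
                if d <= 0 or rng.random() < exp(-d / t):
                    apply_add(i, j)
                    score += d
            elif move < 0.9:
                plist = list(pairs)
                i, j = plist[int(rng.integers(len(plist)))]
                apply_remove(i, j)
                d = -add_delta(i, j)
                if d <= 0 or rng.random() < exp(-d / t):
                    score += d
                else:
                    apply_add(i, j)
            else:
                plist = list(pairs)
                i, j = plist[int(rng.integers(len(plist)))]
                di, dj = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, 1), (1, -1))[
                    int(rng.integers(6))
                ]
                ni, nj = i + di, j + dj
                if (ni, nj) not in bonus:  # not a valid candidate pair
                    continue
                apply_remove(i, j)
                d_rm = -add_delta(i, j)
                if not can_add(ni, nj):
                    apply_add(i, j)
                    continue
                d_add = add_delta(ni, nj)
                d = d_rm + d_add
                if d <= 0 or rng.random() < exp(-d / t):
                    apply_add(ni, nj)
                    score += d
                else:
                    apply_add(i, j)
            if score < best_score - 1e-12:
                best_score = score
                best_pairs = frozenset(pairs)

    return SecondaryStructure(
        seq, best_pairs, whitelist=frozenset(p for p in best_pairs if p in wl)
    )


@dataclass
class EnsembleResult:
    """Final structures of repeated annealing runs and per-pair frequencies."""

    structures: list[tuple[SecondaryStructure, float]]
    pair_freq: dict[tuple[int, int], float]
    n_runs: int

    def freq_of(self, i: int, j: int) -> float:
        return self.pair_freq.get((i, j), 0.0)


def ensemble_pair_frequencies(
    seq: str,
    probs=None,
    config: McConfig | None = None,
    seed: int = 0,
) -> EnsembleResult:
    """Run ``n_runs`` annealings with distinct seeds; frequency of a pair is
    the fraction of final structures containing it."""
    config = config or McConfig()
    if config.n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    structures = []
    counts: dict[tuple[int, int], int] = {}
    for k in range(config.n_runs):
        s = mc_anneal(seq, probs, config, seed=seed + k)
        structures.append((s, structure_score(s, seq, probs, config.coda_weight)))
        for p in s.pairs:
            counts[p] = counts.get(p, 0) + 1
    freq = {p: c / config.n_runs for p, c in counts.items()}
    return EnsembleResult(structures, freq, config.n_runs)


def consensus_structure(
    ensemble: EnsembleResult, freq_threshold: float = 0.8
) -> SecondaryStructure:
    """Pairs appearing in at least ``freq_threshold`` of runs, repaired to a
    valid nested structure by dropping the lowest-frequency conflicts."""
    if not (0.5 < freq_threshold <= 1.0):
        raise ValueError("freq_threshold must be in (0.5, 1]")
    seq = ensemble.structures[0][0].sequence
    wl = set().union(*(s.whitelist for s, _ in ensemble.structures))
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    ranked = sorted(
        (p for p, f in ensemble.pair_freq.items() if f >= freq_threshold),
        key=lambda p: (-ensemble.pair_freq[p], p),
    )
    for i, j in ranked:
        if i in used or j in used:
            continue
        if any((k < i < l < j) or (i < k < j < l) for k, l in chosen):
            continue
        chosen.append((i, j))
        used.update((i, j))
    return SecondaryStructure(
        seq,
        frozenset(chosen),
        whitelist=frozenset(p for p in chosen if p in wl),
    )


def enumerate_structures(
    seq: str, whitelist: frozenset[tuple[int, int]] = frozenset()
) -> list[SecondaryStructure]:
    """Exhaustively enumerate all valid nested structures (test oracle).

    Guarded to sequences of <= 16 nt; same validity rules as the annealer.
    """
    n = len(seq)
    if n > 16:
        raise ValueError("enumeration limited to sequences of <= 16 nt")

    def allowed(i: int, j: int) -> bool:
        return (
            pair_class_of(seq[i - 1], seq[j - 1]) is not None or (i, j) in whitelist
        )

    def rec(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        if j - i < MIN_HAIRPIN + 1:
            return [frozenset()]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if allowed(i, k):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return out

    return [
        SecondaryStructure(seq, ps, whitelist=whitelist & ps) for ps in rec(1, n)
    ]
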