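"""Ground-truth ribozyme fixtures for the synthetic deep-mutational-scanning pipeline.

Each fixture bundles a wild-type sequence, its planted secondary structure
(the "true" base pairs the covariation analysis is supposed to recover), the
conserved C·A cleavage dinucleotide, the catalytic-loop positions whose
identity is required for activity, and the parameters of the multiplicative
activity model used by the generator.

``LINE1_rbz`` and ``OR4K15_rbz`` are synthetic stand-ins for the functional
regions of the human LINE-1 and OR4K15 self-cleaving ribozymes: the published
figures constrain the element architecture (two stems P1/P2, two catalytic
internal loops, a mutation-insensitive stem-loop region SL2, stem sizes 6/5
and 5/4 base pairs, one non-Watson-Crick pair per ribozyme, a conserved C·A
cleavage site inside the longer loop) but not the full nucleotide sequence,
so the sequences here were designed to satisfy exactly those constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

PAIR_CLASSES = ("watson_crick", "wobble", "noncanonical")


def pair_class_of(x: str, y: str) -> str | None:
    """Classify a letter pair as watson_crick, wobble, or None (unpaired-able)."""
    if (x, y) in WATSON_CRICK:
        return "watson_crick"
    if (x, y) in WOBBLE:
        return "wobble"
    return None


@dataclass(frozen=True)
class ActivityModelParams:
    """Parameters of the multiplicative lesion model behind simulate_activity.

    Each disrupted true pair multiplies activity by ``delta_pair_break``; each
    mutated conserved-loop position multiplies it by ``delta_loop``; converting
    a wobble true pair into a Watson-Crick pair multiplies it by
    ``wobble_gain`` (> 1, the G14A/U33C-style stabilisation); activity is
    capped at ``activity_cap``.
    """

    delta_pair_break: float = 0.1
    delta_loop: float = 0.05
    wobble_gain: float = 1.6
    activity_cap: float = 2.0
    p_wt: float = 0.5  # wild-type cleavage probability (free parameter)

    def __post_init__(self) -> None:
        if not (0 < self.delta_pair_break < 1):
            raise ValueError("delta_pair_break must be in (0,1)")
        if not (0 <= self.delta_loop < 1):
            raise ValueError("delta_loop must be in [0,1)")
        if self.wobble_gain < 1:
            raise ValueError("wobble_gain must be >= 1")
        if self.activity_cap <= 0 or self.p_wt <= 0 or self.p_wt > 1:
            raise ValueError("activity_cap and p_wt must be positive (p_wt <= 1)")


@dataclass(frozen=True)
class GroundTruth:
    """A ribozyme with a planted nested secondary structure.

    Positions are 1-based.  ``true_pairs`` holds (i, j, pair_class) with i<j;
    ``cleavage_site`` is the ordered position pair of the conserved C·A
    dinucleotide (both unpaired and adjacent); ``loop_conserved`` are positions
    whose identity is required for catalysis.
    """

    name: str
    sequence: str
    true_pairs: tuple[tuple[int, int, str], ...]
    cleavage_site: tuple[int, int]
    loop_conserved: frozenset[int]
    activity_params: ActivityModelParams = field(default_factory=ActivityModelParams)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if set(self.sequence) - set("ACGU"):
            raise ValueError("sequence must be RNA (A/C/G/U)")
        seen: set[int] = set()
        for i, j, cls in self.true_pairs:
            if not (1 <= i < j <= n):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair: ({i},{j})")
            seen.update((i, j))
            if cls not in PAIR_CLASSES:
                raise ValueError(f"unknown pair class {cls!r}")
        # nestedness: no crossing pairs
        ij = sorted((i, j) for i, j, _ in self.true_pairs)
        for a, (i, j) in enumerate(ij):
            for k, l in ij[a + 1 :]:
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")
        c1, c2 = self.cleavage_site
        if c2 != c1 + 1:
            raise ValueError("cleavage_site positions must be adjacent")
        if c1 in seen or c2 in seen:
            raise ValueError("cleavage_site positions must be unpaired")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def pair_partner(self) -> dict[int, int]:
        """Map position -> partner over all true pairs (both directions)."""
        out: dict[int, int] = {}
        for i, j, _ in self.true_pairs:
            out[i] = j
            out[j] = i
        return out

    def canonical_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, cls in self.true_pairs if cls != "noncanonical"}

    def all_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.true_pairs}


def _mk_line1() -> GroundTruth:
    # Layout (1-based): P1 5' arm 1-6 | catalytic loop 7-12 (cleavage C10-A11)
    # | P2 5' arm 13-17 | SL2 loop 18-30 | P2 3' arm 31-35 | loop 36-40
    # | P1 3' arm 41-46.  P1 = 6 pairs incl. the noncanonical A6·A41,
    # P2 = 5 pairs; loop sides 6 and 5 nt.
    seq = "GGCACA" "GCUCAA" "GAGAG" "AACAACAAACAAA" "CUCUC" "GCUAG" "AGUGCC"
    pairs = (
        (1, 46, "watson_crick"),
        (2, 45, "watson_crick"),
        (3, 44, "watson_crick"),
        (4, 43, "watson_crick"),
        (5, 42, "watson_crick"),
        (6, 41, "noncanonical"),  # A·A closing P1, weak-signal pair
        (13, 35, "watson_crick"),
        (14, 34, "watson_crick"),
        (15, 33, "watson_crick"),
        (16, 32, "watson_crick"),
        (17, 31, "watson_crick"),
    )
    conserved = frozenset({7, 8, 9, 10, 11, 12, 36, 37, 39, 40})  # U38 tolerant
    return GroundTruth("LINE1_rbz", seq, pairs, (10, 11), conserved)


def _mk_or4k15() -> GroundTruth:
    # Circular-permuted lantern: P1 5' arm 1-5 | loop 6-10 (C8 tolerant)
    # | P2 5' arm 11-14 (wobble G14·U33) | SL2 loop 15-32 | P2 3' arm 33-36
    # | catalytic loop 37-42 (cleavage C40-A41) | P1 3' arm 43-47.
    # The catalytic loop is identical to LINE1_rbz's; the 5-nt loop differs
    # from LINE1_rbz's by the single base C8 (U38 there).
    seq = "UGUCG" "GCCAG" "GCAG" "AACAAACAAACAAACAAA" "UUGC" "GCUCAA" "CGACA"
    pairs = (
        (1, 47, "watson_crick"),
        (2, 46, "watson_crick"),
        (3, 45, "watson_crick"),
        (4, 44, "watson_crick"),
        (5, 43, "watson_crick"),
        (11, 36, "watson_crick"),
        (12, 35, "watson_crick"),
        (13, 34, "watson_crick"),
        (14, 33, "wobble"),  # G14·U33 -> G14A / U33C singles raise activity
    )
    conserved = frozenset({6, 7, 9, 10, 37, 38, 39, 40, 41, 42})  # C8 tolerant
    return GroundTruth("OR4K15_rbz", seq, pairs, (40, 41), conserved)


def _mk_toy() -> GroundTruth:
    # 12-nt hairpin for enumeration-oracle tests: 4-pair stem, CAAA loop.
    seq = "GGGCCAAAGCCC"
    pairs = (
        (1, 12, "watson_crick"),
        (2, 11, "watson_crick"),
        (3, 10, "watson_crick"),
        (4, 9, "watson_crick"),
    )
    return GroundTruth("toy_hairpin", seq, pairs, (5, 6), frozenset({5, 6}))


_FIXTURES = {"LINE1_rbz": _mk_line1, "OR4K15_rbz": _mk_or4k15, "toy_hairpin": _mk_toy}


class FixtureNotFound(KeyError):
    pass


def make_ground_truth(name: str) -> GroundTruth:
    """Return a shipped ground-truth fixture by name.

    Known names: ``LINE1_rbz``, ``OR4K15_rbz``, ``toy_hairpin``.
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise FixtureNotFound(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return factory()
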