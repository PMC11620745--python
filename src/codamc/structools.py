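"""Downstream characterisation of inferred ribozyme structures.

Covers the consensus sequence of functional mutants with conservation
classes, decomposition of a secondary structure into its cyclic string of
elements, circular-permutation detection between two such strings,
RNAbob-style descriptor matching, and first-order cleavage-kinetics fitting
(F = A - B·exp(-k_obs·t)).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .activity import ActivityTable
from .fixtures import WATSON_CRICK, WOBBLE
from .mcfold import SecondaryStructure
from .variants import parse_key

__all__ = [
    "ConsensusModel",
    "Element",
    "ElementString",
    "MotifDescriptor",
    "KineticsTrace",
    "KineticsFit",
    "consensus_sequence",
    "element_decomposition",
    "is_circular_permutation",
    "match_descriptor",
    "ts_like_descriptor",
    "fit_first_order",
    "read_kinetics_tsv",
]

_COMPLEMENT_OK = WATSON_CRICK | WOBBLE

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "W": "AU", "S": "CG", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


# ---------------------------------------------------------------- consensus

@dataclass
class ConsensusModel:
    """Per-position consensus over functional mutants.

    Columns: position, consensus (IUPAC symbol, R/Y for ambiguous
    purine/pyrimidine splits), fraction (conservation of the top base),
    klass in {none, c95, c98, c100}.
    """

    data: pd.DataFrame
    n_sequences: int

    def symbol_string(self) -> str:
        return "".join(self.data["consensus"])

    def positions_in_class(self, klass: str) -> set[int]:
        thr = {"c95": 0.95, "c98": 0.98, "c100": 1.0}[klass]
        sel = self.data[self.data["fraction"] >= thr]
        return set(sel["position"].astype(int))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def consensus_sequence(
    table: ActivityTable, ra_threshold: float = 0.5
) -> ConsensusModel:
    """Positional base frequencies over variants with RA >= threshold.

    The library is substitution-only, so the "alignment" is gapless
    positional stacking; each variant counts once.  The symbol is the most
    frequent base, or R/Y when the top two bases are both purines or both
    pyrimidines, jointly reach 95%, and neither alone does.
    """
    wt = table.wt_sequence
    L = len(wt)
    active = table.data[table.data["relative_activity"] >= ra_threshold]
    n = len(active)
    if n == 0:
        raise ValueError("no variants pass the activity threshold")
    base_idx = {b: k for k, b in enumerate("ACGU")}
    freq = np.zeros((L, 4), dtype=float)
    for pos, b in enumerate(wt):
        freq[pos, base_idx[b]] = n
    for key in active["variant"]:
        for pos, alt in parse_key(key).items():
            freq[pos - 1, base_idx[wt[pos - 1]]] -= 1
            freq[pos - 1, base_idx[alt]] += 1
    freq /= n
    rows = []
    for pos in range(L):
        order = np.argsort(freq[pos])[::-1]
        top, second = order[0], order[1]
        f_top = freq[pos, top]
        symbol = "ACGU"[top]
        pair = {"ACGU"[top], "ACGU"[second]}
        if f_top < 0.95 and freq[pos, top] + freq[pos, second] >= 0.95:
            if pair <= {"A", "G"}:
                symbol = "R"
            elif pair <= {"C", "U"}:
                symbol = "Y"
        if f_top >= 1.0:
            klass = "c100"
        elif f_top >= 0.98:
            klass = "c98"
        elif f_top >= 0.95:
            klass = "c95"
        else:
            klass = "none"
        rows.append((pos + 1, symbol, f_top, klass))
    return ConsensusModel(
        pd.DataFrame(rows, columns=["position", "consensus", "fraction", "klass"]), n
    )


# ----------------------------------------------------------------- elements

@dataclass(frozen=True)
class Element:
    kind: str  # stem | internal_loop_side | hairpin_loop | external
    length: int  # pairs for stems, nucleotides otherwise


@dataclass
class ElementString:
    """Cyclic ordered list of structural elements in 5'->3' traversal order.

    Stems appear once (at their 5' arm); the decomposition partitions the
    sequence positions.
    """

    elements: list[Element]

    def kinds(self) -> list[str]:
        return [e.kind for e in self.elements]

    def reduced(self) -> list[Element]:
        """Elements relevant to the catalytic lantern: hairpin loops are
        collapsed onto their closing stem and external segments dropped."""
        return [
            e for e in self.elements if e.kind not in ("hairpin_loop", "external")
        ]


def _helices(pairs: set[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal stacked helices."""
    rest = sorted(pairs)
    helices = []
    pairset = set(pairs)
    used: set[tuple[int, int]] = set()
    for p in rest:
        if p in used:
            continue
        helix = [p]
        used.add(p)
        i, j = p
        while (i + 1, j - 1) in pairset:
            i, j = i + 1, j - 1
            helix.append((i, j))
            used.add((i, j))
        helices.append(helix)
    # remove helices that are suffixes of longer ones
    out = []
    starts = {h[0] for h in helices}
    for h in helices:
        i, j = h[0]
        if (i - 1, j + 1) in pairset:
            continue
        out.append(h)
    return out


def element_decomposition(s: SecondaryStructure) -> ElementString:
    """Decompose a structure into stems and the loops between them."""
    n = len(s.sequence)
    partner = s.partner()
    helices = _helices(set(s.pairs))
    helix_at: dict[int, int] = {}
    for idx, h in enumerate(helices):
        for i, j in h:
            helix_at[i] = idx
            helix_at[j] = idx
    elements: list[Element] = []
    emitted: set[int] = set()
    pos = 1
    while pos <= n:
        if pos in partner:
            h = helix_at[pos]
            if h not in emitted:
                elements.append(Element("stem", len(helices[h])))
                emitted.add(h)
            pos += 1
            continue
        run_start = pos
        while pos <= n and pos not in partner:
            pos += 1
        run_end = pos - 1
        left = run_start - 1
        right = run_end + 1
        if left < 1 or right > n:
            kind = "external"
        elif partner.get(left) == right:
            kind = "hairpin_loop"
        else:
            kind = "internal_loop_side"
        elements.append(Element(kind, run_end - run_start + 1))
    if not s.pairs:
        return ElementString([Element("external", n)])
    return ElementString(elements)


def is_circular_permutation(
    a: ElementString, b: ElementString, len_tol: int = 1
) -> int | None:
    """Smallest rotation of b's reduced cyclic element list matching a's.

    External segments and hairpin loops are dropped before comparison (the
    variable stem-loop collapses onto its closing stem); kinds must match
    exactly and per-element lengths may differ by at most ``len_tol``.
    Returns the rotation offset, or None.
    """
    ra, rb = a.reduced(), b.reduced()
    if len(ra) != len(rb) or not ra:
        return None
    m = len(ra)
    for off in range(m):
        rot = rb[off:] + rb[:off]
        if all(
            x.kind == y.kind and abs(x.length - y.length) <= len_tol
            for x, y in zip(ra, rot)
        ):
            return off
    return None


# -------------------------------------------------------------- descriptors

@dataclass(frozen=True)
class _DescElement:
    kind: str  # helix_open | helix_close | strand
    name: str
    min_len: int = 0
    max_len: int = 0
    max_mismatch: int = 0
    pattern: str | None = None


@dataclass
class MotifDescriptor:
    """An ordered RNAbob-like pattern of helices and strands.

    Text grammar (whitespace-separated tokens):

    * ``h1(3:6)`` or ``h1(3:6,1)`` — open helix ``h1``, 3-6 pairs, up to 1
      non-complementary pair;
    * ``h1'`` — the matching closing arm;
    * ``s1(4:6)`` or ``s1(4:4,GAAA)`` — unpaired strand, optionally with a
      degenerate IUPAC constraint (its length fixes the segment length).

    Helices must close in last-opened-first-closed order (nested pattern).
    """

    elements: list[_DescElement]

    _TOKEN = re.compile(
        r"^(?:(?P<close>h(?P<cname>\w+)')|"
        r"(?P<helix>h(?P<hname>\w+)\((?P<h1>\d+):(?P<h2>\d+)(?:,(?P<mm>\d+))?\))|"
        r"(?P<strand>s(?P<sname>\w+)\((?P<s1>\d+):(?P<s2>\d+)(?:,(?P<pat>[A-Z]+))?\)))$"
    )

    @classmethod
    def parse(cls, text: str) -> "MotifDescriptor":
        elements: list[_DescElement] = []
        open_stack: list[str] = []
        for tok in text.split():
            m = cls._TOKEN.match(tok)
            if not m:
                raise ValueError(f"malformed descriptor token {tok!r}")
            if m.group("helix"):
                name = m.group("hname")
                lo, hi = int(m.group("h1")), int(m.group("h2"))
                if lo > hi or lo < 1:
                    raise ValueError(f"bad helix range in {tok!r}")
                mm = int(m.group("mm") or 0)
                elements.append(_DescElement("helix_open", name, lo, hi, mm))
                open_stack.append(name)
            elif m.group("close"):
                name = m.group("cname")
                if not open_stack or open_stack[-1] != name:
                    raise ValueError(f"helix {name!r} closed out of order")
                open_stack.pop()
                elements.append(_DescElement("helix_close", name))
            else:
                name = m.group("sname")
                lo, hi = int(m.group("s1")), int(m.group("s2"))
                pat = m.group("pat")
                if pat is not None:
                    if any(ch not in _IUPAC for ch in pat):
                        raise ValueError(f"non-IUPAC letter in pattern {pat!r}")
                    lo = hi = len(pat)
                if lo > hi or lo < 0:
                    raise ValueError(f"bad strand range in {tok!r}")
                elements.append(_DescElement("strand", name, lo, hi, 0, pat))
        if open_stack:
            raise ValueError(f"unclosed helices: {open_stack}")
        return cls(elements)


def _complementary(x: str, y: str) -> bool:
    return (x, y) in _COMPLEMENT_OK


def _matches_pattern(segment: str, pattern: str) -> bool:
    return all(s in _IUPAC[p] for s, p in zip(segment, pattern))


def match_descriptor(seq: str, d: MotifDescriptor | str) -> list[dict[str, tuple[int, int]]]:
    """All placements of the descriptor on ``seq`` (1-based coordinates).

    A hit maps each element name (``hN`` arms as ``hN`` and ``hN'``) to its
    (start, end) span.  Exhaustive within the length ranges; helix arms must
    be reverse-complementary (Watson-Crick or wobble) up to the allowed
    mismatches.
    """
    if isinstance(d, str):
        d = MotifDescriptor.parse(d)
    n = len(seq)
    hits: list[dict[str, tuple[int, int]]] = []
    elems = d.elements

    def rec(idx: int, pos: int, open_helices: dict[str, tuple[int, int]],
            placed: dict[str, tuple[int, int]]) -> None:
        if idx == len(elems):
            hits.append(dict(placed))
            return
        el = elems[idx]
        if el.kind == "strand":
            for ln in range(el.min_len, el.max_len + 1):
                if pos + ln - 1 > n:
                    break
                segment = seq[pos - 1 : pos - 1 + ln]
                if el.pattern is not None and not _matches_pattern(segment, el.pattern):
                    continue
                placed[f"s{el.name}"] = (pos, pos + ln - 1)
                rec(idx + 1, pos + ln, open_helices, placed)
                del placed[f"s{el.name}"]
        elif el.kind == "helix_open":
            for ln in range(el.min_len, el.max_len + 1):
                if pos + ln - 1 > n:
                    break
                open_helices[el.name] = (pos, pos + ln - 1)
                placed[f"h{el.name}"] = (pos, pos + ln - 1)
                rec(idx + 1, pos + ln, open_helices, placed)
                del open_helices[el.name]
                del placed[f"h{el.name}"]
        else:  # helix_close
            start, end = open_helices[el.name]
            ln = end - start + 1
            if pos + ln - 1 > n:
                return
            arm5 = seq[start - 1 : end]
            arm3 = seq[pos - 1 : pos - 1 + ln]
            mm = sum(
                0 if _complementary(x, y) else 1 for x, y in zip(arm5, arm3[::-1])
            )
            spec = next(
                e for e in elems if e.kind == "helix_open" and e.name == el.name
            )
            if mm > spec.max_mismatch:
                return
            placed[f"h{el.name}'"] = (pos, pos + ln - 1)
            rec(idx + 1, pos + ln, open_helices, placed)
            del placed[f"h{el.name}'"]

    for start in range(1, n + 2):
        rec(0, start, {}, {})
    # deduplicate identical placements found from different window starts
    seen = set()
    uniq = []
    for h in hits:
        key = tuple(sorted(h.items()))
        if key not in seen:
            seen.add(key)
            uniq.append(h)
    return uniq


def ts_like_descriptor() -> MotifDescriptor:
    """Two-stem/two-internal-loop lantern pattern of the TS-like ribozymes:
    stem P1 (5-6 pairs, one mismatch tolerated for the non-canonical closing
    pair), catalytic loop, stem P2 (4-5 pairs), variable stem-loop region,
    and the second loop side back to P1."""
    return MotifDescriptor.parse(
        "h1(5:6,1) s1(5:6) h2(4:5) s2(10:20) h2' s3(4:6) h1'"
    )


# ----------------------------------------------------------------- kinetics

@dataclass
class KineticsTrace:
    """Fluorescence cleavage trace: times in minutes, arbitrary F units."""

    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.f.shape:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class KineticsFit:
    a: float  # fluorescence at completion
    b: float  # amplitude of the observable phase
    k_obs: float  # first-order rate constant, min^-1
    residual_norm: float
    ok: bool
    message: str = ""


def read_kinetics_tsv(path: str | Path) -> KineticsTrace:
    df = pd.read_csv(path, sep="\t")
    return KineticsTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def _model(t: np.ndarray, a: float, b: float, k: float) -> np.ndarray:
    return a - b * np.exp(-k * t)


def fit_first_order(
    trace: KineticsTrace, control_f0: float | None = None
) -> KineticsFit:
    """Least-squares fit of F = A - B·exp(-k_obs·t).

    ``control_f0`` (the no-divalent-ion control at t = 0) normalises the
    trace before fitting when given.  Starting values come from a log-linear
    transform of the approach to plateau.  Returns ``ok=False`` (with the
    reason in ``message``) when the fit does not converge or the amplitude is
    indistinguishable from zero (k_obs unidentifiable).
    """
    t, f = trace.t, trace.f
    if control_f0 is not None:
        if control_f0 <= 0:
            raise ValueError("control_f0 must be positive")
        f = f / control_f0
    if t.size < 5:
        return KineticsFit(np.nan, np.nan, np.nan, np.nan, False, "need >= 5 points")
    scale = max(np.ptp(f), abs(float(np.max(np.abs(f)))), 1e-12)
    a0 = float(f[-1])
    b0 = float(f[-1] - f[0])
    if abs(b0) < 1e-3 * scale or np.ptp(f) < 1e-6 * scale:
        return KineticsFit(
            a0, 0.0, np.nan, float(np.linalg.norm(f - a0)), False,
            "no signal change; k_obs unidentifiable",
        )
    # log-linear start for k: log(A - F) = log(B) - k t on the rising part
    resid0 = a0 + 0.05 * abs(b0) - f
    mask = resid0 > 1e-9 * scale
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid0[mask]), 1)[0]
        k0 = max(-slope, 1e-4)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-9)
    try:
        popt, _ = curve_fit(
            _model, t, f, p0=[a0, b0, k0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return KineticsFit(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    a, b, k = (float(x) for x in popt)
    rnorm = float(np.linalg.norm(f - _model(t, a, b, k)))
    if abs(b) < 1e-3 * scale:
        return KineticsFit(a, b, np.nan, rnorm, False, "amplitude ~ 0")
    return KineticsFit(a, b, k, rnorm, True)
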