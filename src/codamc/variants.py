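"""Variant-key handling.

A variant is a set of point substitutions on the wild-type sequence and is
named by semicolon-joined ``refPOSalt`` tokens sorted by position (1-based),
e.g. ``"G14A;U33C"``; the wild type itself is ``"WT"``.
"""

from __future__ import annotations

import re

WT_KEY = "WT"

_TOKEN = re.compile(r"^([ACGU])(\d+)([ACGU])$")


class InconsistentVariant(ValueError):
    """Raised when a token's reference letter disagrees with the wild type."""


def make_key(mutations: dict[int, str], wt: str) -> str:
    """Canonical key for a {position: alt} substitution set."""
    if not mutations:
        return WT_KEY
    toks = []
    for pos in sorted(mutations):
        alt = mutations[pos]
        ref = wt[pos - 1]
        if alt == ref:
            raise InconsistentVariant(f"alt equals reference at {pos}")
        toks.append(f"{ref}{pos}{alt}")
    return ";".join(toks)


def parse_key(key: str, wt: str | None = None) -> dict[int, str]:
    """Parse a variant key into {position: alt}; validates refs when wt given."""
    if key == WT_KEY:
        return {}
    out: dict[int, str] = {}
    for tok in key.split(";"):
        m = _TOKEN.match(tok)
        if not m:
            raise ValueError(f"malformed variant token {tok!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if pos in out:
            raise ValueError(f"duplicate position {pos} in {key!r}")
        if wt is not None:
            if not (1 <= pos <= len(wt)):
                raise InconsistentVariant(f"position {pos} out of range")
            if wt[pos - 1] != ref:
                raise InconsistentVariant(
                    f"token {tok}: wild type has {wt[pos - 1]} at {pos}"
                )
        out[pos] = alt
    return out


def n_mutations(key: str) -> int:
    return 0 if key == WT_KEY else key.count(";") + 1


def apply_mutations(wt: str, mutations: dict[int, str]) -> str:
    """Full sequence of a variant (substitution-only, gapless)."""
    s = list(wt)
    for pos, alt in mutations.items():
        s[pos - 1] = alt
    return "".join(s)
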