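"""From sequencing counts to relative activities, sensitivity profiles and
essential segments.

Two experimental designs are supported.  In the *cleaved/uncleaved* design the
RNA-seq pool contains both cleavage products, and a variant's relative
activity is the ratio of its cleaved fraction to the wild type's:

    RA(var) = [N_cleaved(var) / N_total(var)] / [N_cleaved(wt) / N_total(wt)]

In the *capture* design cleaved molecules are selectively ligated (RtcB) and
enriched, so activity is estimated from RNA-seq vs DNA-seq library counts:

    RA'(var) = [N_RNAseq(var) / N_DNAseq(var)] / [N_RNAseq(wt) / N_DNAseq(wt)]

Both are exact ratio-of-ratios; RA(wt) = 1 by construction and RA' may exceed
1 (e.g. wobble-to-Watson-Crick stabilising substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import WT_KEY, n_mutations

CLEAVED_UNCLEAVED = "cleaved_uncleaved"
CAPTURE = "capture"

#: column names per channel semantics (channel1, channel2)
CHANNEL_COLUMNS = {
    CLEAVED_UNCLEAVED: ("n_cleaved", "n_total"),
    CAPTURE: ("n_dnaseq", "n_rnaseq"),
}


class UndefinedBaseline(ValueError):
    """Wild-type counts cannot normalise the table (missing row or zero)."""


@dataclass
class CountTable:
    """Per-variant read counts in two named channels."""

    data: pd.DataFrame  # columns: variant + the two channel columns
    mode: str
    wt_sequence: str

    def __post_init__(self) -> None:
        if self.mode not in CHANNEL_COLUMNS:
            raise ValueError(f"unknown channel mode {self.mode!r}")
        c1, c2 = CHANNEL_COLUMNS[self.mode]
        for col in ("variant", c1, c2):
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
        counts = self.data[[c1, c2]].to_numpy()
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.mode == CLEAVED_UNCLEAVED and (
            self.data[c1].to_numpy() > self.data[c2].to_numpy()
        ).any():
            raise ValueError("n_cleaved must not exceed n_total")

    @property
    def channels(self) -> tuple[str, str]:
        return CHANNEL_COLUMNS[self.mode]

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, mode: str, wt_sequence: str) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t"), mode, wt_sequence)


@dataclass
class ActivityTable:
    """Per-variant relative activity with mutation-count annotations.

    ``data`` columns: variant, n_mut, relative_activity.  ``flag`` records the
    estimator ("RA" for cleaved/uncleaved, "RA_prime" for capture).
    """

    data: pd.DataFrame
    wt_sequence: str
    flag: str

    def ra_of(self, key: str) -> float:
        row = self.data.loc[self.data["variant"] == key, "relative_activity"]
        if row.empty:
            raise KeyError(key)
        return float(row.iloc[0])

    def singles(self) -> pd.DataFrame:
        return self.data[self.data["n_mut"] == 1]

    def doubles(self) -> pd.DataFrame:
        return self.data[self.data["n_mut"] == 2]

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, wt_sequence: str, flag: str) -> "ActivityTable":
        return cls(pd.read_csv(path, sep="\t"), wt_sequence, flag)


@dataclass
class PositionProfile:
    """Mean relative activity of observed single mutants per 1-based position.

    Positions with no observed single mutant are *missing* (NaN mean,
    n_singles 0), never zero.
    """

    data: pd.DataFrame  # columns: position, mean_ra, n_singles
    length: int

    def mean_at(self, pos: int) -> float:
        return float(self.data.loc[self.data["position"] == pos, "mean_ra"].iloc[0])


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based, inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _relative_activity(
    counts: CountTable,
    min_reads: int,
    max_mutations: int | None,
    num_col: str,
    den_col: str,
    flag: str,
) -> ActivityTable:
    df = counts.data
    wt = df[df["variant"] == WT_KEY]
    if wt.empty:
        raise UndefinedBaseline("wild-type row missing from count table")
    wt_num = float(wt[num_col].iloc[0])
    wt_den = float(wt[den_col].iloc[0])
    if wt_num <= 0 or wt_den <= 0:
        raise UndefinedBaseline(
            f"wild-type counts ({num_col}={wt_num:g}, {den_col}={wt_den:g}) "
            "cannot define the activity baseline"
        )
    keep = df[den_col] >= min_reads
    sub = df[keep].copy()
    nm = sub["variant"].map(n_mutations)
    if max_mutations is not None:
        sub = sub[nm <= max_mutations]
        nm = nm[nm <= max_mutations]
    ratio = sub[num_col].to_numpy(float) / sub[den_col].to_numpy(float)
    ra = ratio / (wt_num / wt_den)
    out = pd.DataFrame(
        {
            "variant": sub["variant"].to_numpy(),
            "n_mut": nm.to_numpy(),
            "relative_activity": ra,
        }
    )
    # the wild type defines the scale; force exact 1 even if it failed min_reads
    if WT_KEY not in set(out["variant"]):
        out = pd.concat(
            [
                pd.DataFrame(
                    {"variant": [WT_KEY], "n_mut": [0], "relative_activity": [1.0]}
                ),
                out,
            ],
            ignore_index=True,
        )
    return ActivityTable(out.reset_index(drop=True), counts.wt_sequence, flag)


def relative_activity_cleavage(
    counts: CountTable, min_reads: int = 20, max_mutations: int | None = 3
) -> ActivityTable:
    """RA from a cleaved/uncleaved count table (ratio-of-ratios).

    Variants with ``n_total < min_reads`` or more than ``max_mutations``
    substitutions are dropped.
    """
    if counts.mode != CLEAVED_UNCLEAVED:
        raise ValueError("count table does not have cleaved/uncleaved semantics")
    return _relative_activity(
        counts, min_reads, max_mutations, "n_cleaved", "n_total", "RA"
    )


def relative_activity_capture(
    counts: CountTable, min_reads: int = 20, max_mutations: int | None = 3
) -> ActivityTable:
    """RA' from a DNA-seq/RNA-seq capture count table (ratio-of-ratios).

    Variants with ``n_dnaseq < min_reads`` are dropped; RA' may exceed 1.
    """
    if counts.mode != CAPTURE:
        raise ValueError("count table does not have capture semantics")
    return _relative_activity(
        counts, min_reads, max_mutations, "n_rnaseq", "n_dnaseq", "RA_prime"
    )


def position_profile(table: ActivityTable) -> PositionProfile:
    """Arithmetic mean RA of observed single mutants at each position."""
    L = len(table.wt_sequence)
    sums = np.zeros(L + 1)
    ns = np.zeros(L + 1, dtype=int)
    singles = table.singles()
    positions = singles["variant"].str.extract(r"^[ACGU](\d+)[ACGU]$")[0].astype(int)
    for pos, ra in zip(positions, singles["relative_activity"]):
        sums[pos] += ra
        ns[pos] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(ns[1:] > 0, sums[1:] / np.maximum(ns[1:], 1), np.nan)
    df = pd.DataFrame(
        {"position": np.arange(1, L + 1), "mean_ra": means, "n_singles": ns[1:]}
    )
    return PositionProfile(df, L)


def find_essential_segments(
    profile: PositionProfile,
    ra_threshold: float = 0.5,
    min_len: int = 5,
    max_gap: int = 2,
) -> list[Segment]:
    """Maximal runs of mutation-sensitive positions (mean RA < threshold).

    Runs may bridge up to ``max_gap`` consecutive non-qualifying or missing
    positions; runs shorter than ``min_len`` are discarded.  Missing positions
    never qualify on their own but do not break a run if within the gap
    allowance.
    """
    mean = profile.data["mean_ra"].to_numpy()
    observed = profile.data["n_singles"].to_numpy() > 0
    qualifies = observed & np.where(np.isnan(mean), False, mean < ra_threshold)
    segments: list[Segment] = []
    start = None
    last_hit = None
    for idx, q in enumerate(qualifies):
        pos = idx + 1
        if q:
            if start is None:
                start = pos
            elif pos - last_hit - 1 > max_gap:
                if last_hit - start + 1 >= min_len:
                    segments.append(Segment(start, last_hit))
                start = pos
            last_hit = pos
    if start is not None and last_hit - start + 1 >= min_len:
        segments.append(Segment(start, last_hit))
    return segments


def coverage_stats(table: ActivityTable, L: int) -> tuple[float, float]:
    """Fractions of possible single (3L) and double (9·C(L,2)) variants observed."""
    if L < 2:
        raise ValueError("region length must be >= 2")
    n_single = table.singles()["variant"].nunique()
    n_double = table.doubles()["variant"].nunique()
    return n_single / (3 * L), n_double / (9 * comb(L, 2))
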