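import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codamc.activity import (
    ActivityTable,
    CountTable,
    Segment,
    UndefinedBaseline,
    coverage_stats,
    find_essential_segments,
    position_profile,
    relative_activity_capture,
    relative_activity_cleavage,
)
from codamc.synth import ChannelDesign, LibraryConfig, sample_counts, sample_library

WT12 = "GGCACAGCUCAA"


def cleav_table(rows):
    df = pd.DataFrame(rows, columns=["variant", "n_cleaved", "n_total"])
    return CountTable(df, "cleaved_uncleaved", WT12)


def capt_table(rows):
    df = pd.DataFrame(rows, columns=["variant", "n_dnaseq", "n_rnaseq"])
    return CountTable(df, "capture", WT12)


class TestRelativeActivityCleavage:
    def test_ratio_of_ratios(self):
        ct = cleav_table([("WT", 60, 100), ("G1A", 30, 100), ("G2A", 90, 100)])
        t = relative_activity_cleavage(ct, min_reads=1)
        assert t.ra_of("G1A") == pytest.approx(0.5)
        assert t.ra_of("G2A") == pytest.approx(90 / 100 / (60 / 100))

    def test_identical_counts_give_one_and_wt_exactly_one(self):
        ct = cleav_table([("WT", 37, 91), ("G1A", 37, 91)])
        t = relative_activity_cleavage(ct, min_reads=1)
        assert t.ra_of("WT") == 1.0
        assert t.ra_of("G1A") == 1.0

    def test_double_ratio_example(self):
        ct = cleav_table([("WT", 45, 100), ("G1A", 90, 100)])
        assert relative_activity_cleavage(ct, min_reads=1).ra_of("G1A") == 2.0

    def test_min_reads_filter_drops_variants(self):
        ct = cleav_table([("WT", 60, 100), ("G1A", 3, 10)])
        t = relative_activity_cleavage(ct, min_reads=20)
        with pytest.raises(KeyError):
            t.ra_of("G1A")

    def test_zero_wild_type_cleaved_is_undefined(self):
        ct = cleav_table([("WT", 0, 100), ("G1A", 10, 100)])
        with pytest.raises(UndefinedBaseline):
            relative_activity_cleavage(ct)

    def test_missing_wild_type_row_is_an_error(self):
        ct = cleav_table([("G1A", 10, 100)])
        with pytest.raises(UndefinedBaseline):
            relative_activity_cleavage(ct)

    def test_cleaved_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            cleav_table([("WT", 101, 100)])


class TestRelativeActivityCapture:
    def test_ratio_of_ratios(self):
        ct = capt_table([("WT", 100, 20), ("G1A", 100, 10)])
        assert relative_activity_capture(ct, min_reads=1).ra_of("G1A") == 0.5

    def test_can_exceed_one(self):
        ct = capt_table([("WT", 100, 20), ("G1A", 100, 50)])
        assert relative_activity_capture(ct, min_reads=1).ra_of("G1A") == 2.5

    def test_zero_wild_type_channel_is_undefined(self):
        ct = capt_table([("WT", 100, 0), ("G1A", 100, 10)])
        with pytest.raises(UndefinedBaseline):
            relative_activity_capture(ct)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=1000))
    def test_invariant_under_uniform_channel_scaling(self, scale):
        base = [("WT", 100, 20), ("G1A", 200, 15), ("G2C", 50, 40)]
        scaled = [(v, d * scale, r) for v, d, r in base]
        t1 = relative_activity_capture(capt_table(base), min_reads=1)
        t2 = relative_activity_capture(capt_table(scaled), min_reads=scale)
        for v in ("G1A", "G2C"):
            assert t1.ra_of(v) == pytest.approx(t2.ra_of(v))

    def test_ra_and_ra_prime_agree_on_shared_singles(self, line1):
        """Same library sequenced under both designs: single-mutant RA vs RA'
        correlate strongly (the study saw r=0.66 on real data; synthetic
        deep-coverage data should be well above that)."""
        lib = sample_library(line1, LibraryConfig(n_molecules=100_000, seed=31))
        deep = 1_000_000
        ra = relative_activity_cleavage(
            sample_counts(
                lib, line1, ChannelDesign(mode="cleaved_uncleaved", depth_rna=deep), 1
            )
        )
        rap = relative_activity_capture(
            sample_counts(
                lib, line1, ChannelDesign(depth_dna=deep, depth_rna=deep), 2
            )
        )
        s1 = ra.singles().set_index("variant")["relative_activity"]
        s2 = rap.singles().set_index("variant")["relative_activity"]
        shared = s1.index.intersection(s2.index)
        assert len(shared) > 100
        r = np.corrcoef(s1[shared], s2[shared])[0, 1]
        assert r > 0.9


def mk_activity(rows, wt=WT12):
    df = pd.DataFrame(rows, columns=["variant", "n_mut", "relative_activity"])
    return ActivityTable(df, wt, "RA")


class TestPositionProfile:
    def test_mean_over_singles(self):
        t = mk_activity(
            [("WT", 0, 1.0), ("G1A", 1, 0.2), ("G1C", 1, 0.4), ("G2A", 1, 0.7)]
        )
        prof = position_profile(t)
        assert prof.mean_at(1) == pytest.approx(0.3)
        assert prof.mean_at(2) == pytest.approx(0.7)

    def test_unobserved_positions_are_missing_not_zero(self):
        t = mk_activity([("WT", 0, 1.0), ("G1A", 1, 0.2)])
        prof = position_profile(t)
        row = prof.data[prof.data["position"] == 3].iloc[0]
        assert row["n_singles"] == 0
        assert np.isnan(row["mean_ra"])


def profile_from_values(values):
    """Build a PositionProfile directly from per-position means (None=missing)."""
    from codamc.activity import PositionProfile

    rows = [
        (k + 1, np.nan if v is None else v, 0 if v is None else 3)
        for k, v in enumerate(values)
    ]
    return PositionProfile(
        pd.DataFrame(rows, columns=["position", "mean_ra", "n_singles"]), len(values)
    )


class TestEssentialSegments:
    def test_two_planted_segments(self):
        vals = [1.0] * 110
        for p in list(range(54, 72)) + list(range(83, 100)):
            vals[p - 1] = 0.1
        segs = find_essential_segments(profile_from_values(vals))
        assert [(s.start, s.end) for s in segs] == [(54, 71), (83, 99)]
        assert [s.length for s in segs] == [18, 17]

    def test_all_high_profile_has_no_segments(self):
        assert find_essential_segments(profile_from_values([1.0] * 40)) == []

    def test_gap_merging_traced_by_hand(self):
        vals = [1.0] * 30
        for p in range(10, 21):
            vals[p - 1] = 0.1
        vals[15 - 1] = 1.0  # single non-qualifying interior position
        segs = find_essential_segments(profile_from_values(vals), max_gap=1)
        assert [(s.start, s.end) for s in segs] == [(10, 20)]

    def test_gap_larger_than_max_gap_splits(self):
        vals = [1.0] * 40
        for p in list(range(5, 12)) + list(range(15, 22)):
            vals[p - 1] = 0.1
        segs = find_essential_segments(profile_from_values(vals), max_gap=2)
        assert [(s.start, s.end) for s in segs] == [(5, 11), (15, 21)]

    def test_invariant_to_values_at_missing_positions(self):
        vals = [1.0] * 30
        for p in range(8, 18):
            vals[p - 1] = 0.1
        prof_a = profile_from_values(vals)
        prof_b = profile_from_values(vals)
        # poison the stored means at missing rows; n_singles stays 0
        prof_b.data.loc[prof_b.data["position"] > 25, "n_singles"] = 0
        prof_a.data.loc[prof_a.data["position"] > 25, "n_singles"] = 0
        prof_b.data.loc[prof_b.data["position"] > 25, "mean_ra"] = 0.0
        a = find_essential_segments(prof_a)
        b = find_essential_segments(prof_b)
        assert a == b

    def test_runs_shorter_than_min_len_discarded(self):
        vals = [1.0] * 20
        for p in range(5, 8):
            vals[p - 1] = 0.1
        assert find_essential_segments(profile_from_values(vals), min_len=5) == []

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            Segment(5, 4)


class TestCoverage:
    def test_complete_singles(self):
        rows = [("WT", 0, 1.0)]
        for pos in range(1, 3):
            ref = WT12[pos - 1]
            for alt in "ACGU":
                if alt != ref:
                    rows.append((f"{ref}{pos}{alt}", 1, 1.0))
        t = mk_activity(rows, WT12[:2])
        single, double = coverage_stats(t, 2)
        assert single == 1.0
        assert double == 0.0

    def test_partial_doubles_enumeration(self):
        rows = [("WT", 0, 1.0)]
        for key in ("G1A;G2A", "G1A;G2C", "G1C;G2U"):
            rows.append((key, 2, 1.0))
        t = mk_activity(rows, WT12[:2])
        assert coverage_stats(t, 2) == (0.0, 3 / 9)

    def test_empty_table(self):
        t = mk_activity([])
        assert coverage_stats(t, 12) == (0.0, 0.0)


def test_synthetic_profile_low_in_stems_high_in_stem_loop(line1, line1_table):
    """Planted stems and catalytic loops are mutation-sensitive; the SL2
    stem-loop region is insensitive."""
    prof = position_profile(line1_table)
    stem_pos = [p for i, j, _ in line1.true_pairs for p in (i, j)]
    loop_pos = sorted(line1.loop_conserved)
    sl2 = [p for p in range(18, 31)]
    mean = dict(zip(prof.data["position"], prof.data["mean_ra"]))
    assert np.mean([mean[p] for p in stem_pos]) < 0.3
    assert np.mean([mean[p] for p in loop_pos]) < 0.3
    for p in sl2:
        assert mean[p] == pytest.approx(1.0, abs=0.15)
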