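import numpy as np
import pandas as pd
import pytest

from codamc.activity import ActivityTable
from codamc.fixtures import pair_class_of
from codamc.mcfold import SecondaryStructure
from codamc.structools import (
    Element,
    ElementString,
    KineticsTrace,
    MotifDescriptor,
    consensus_sequence,
    element_decomposition,
    fit_first_order,
    is_circular_permutation,
    match_descriptor,
    ts_like_descriptor,
)


def truth_structure(tr):
    return SecondaryStructure(
        tr.sequence,
        frozenset((i, j) for i, j, _ in tr.true_pairs),
        whitelist=frozenset(
            (i, j) for i, j, c in tr.true_pairs if c == "noncanonical"
        ),
    )


def mk_table(rows, wt):
    return ActivityTable(
        pd.DataFrame(rows, columns=["variant", "n_mut", "relative_activity"]), wt, "RA"
    )


class TestConsensusSequence:
    def test_identical_active_sequences_are_all_c100(self):
        wt = "GGCA"
        t = mk_table([("WT", 0, 1.0), ("G1A", 1, 0.1)], wt)
        model = consensus_sequence(t, 0.5)
        assert model.n_sequences == 1
        assert list(model.data["klass"]) == ["c100"] * 4
        assert model.symbol_string() == wt

    def test_c95_threshold_arithmetic(self):
        """24 of 25 active sequences keep G at position 1 -> G, class c95."""
        wt = "GAAAAA"
        rows = [("WT", 0, 1.0)]
        rows += [
            (f"A{p}{alt}", 1, 1.0) for p in range(2, 7) for alt in "CGU"
        ]  # 15 singles away from position 1
        doubles = [
            "A2C;A3C", "A2C;A4C", "A2C;A5C", "A2C;A6C",
            "A3C;A4C", "A3C;A5C", "A3C;A6C", "A4C;A5C",
        ]
        rows += [(k, 2, 1.0) for k in doubles]
        rows.append(("G1A", 1, 1.0))  # the lone divergent sequence
        model = consensus_sequence(mk_table(rows, wt), 0.5)
        assert model.n_sequences == 25
        top = model.data.iloc[0]
        assert top["consensus"] == "G"
        assert top["fraction"] == pytest.approx(0.96)
        assert top["klass"] == "c95"

    def test_purine_split_gives_r_symbol(self):
        wt = "GA"
        rows = [("WT", 0, 1.0), ("G1A", 1, 1.0)]
        model = consensus_sequence(mk_table(rows, wt), 0.5)
        # 50% G / 50% A, jointly 100% purine, neither alone >= 95% -> R
        assert model.data.iloc[0]["consensus"] == "R"
        assert model.data.iloc[0]["klass"] == "none"

    def test_conservation_classes_nest(self, line1, line1_table):
        model = consensus_sequence(line1_table, 0.5)
        c100 = model.positions_in_class("c100")
        c98 = model.positions_in_class("c98")
        c95 = model.positions_in_class("c95")
        assert c100 <= c98 <= c95

    def test_catalytic_loop_more_conserved_than_stem_loop(self, line1, line1_table):
        """Active mutants keep the catalytic loops; SL2 drifts freely."""
        model = consensus_sequence(line1_table, 0.5)
        frac = dict(zip(model.data["position"], model.data["fraction"]))
        loop = np.mean([frac[p] for p in sorted(line1.loop_conserved)])
        sl2 = np.mean([frac[p] for p in range(19, 30)])
        assert loop > 0.98
        assert sl2 < loop

    def test_empty_active_set_is_an_error(self):
        t = mk_table([("WT", 0, 1.0), ("G1A", 1, 0.1)], "GGCA")
        with pytest.raises(ValueError):
            consensus_sequence(t, ra_threshold=5.0)


class TestElementDecomposition:
    def test_line1_elements(self, line1):
        els = element_decomposition(truth_structure(line1))
        kinds = [(e.kind, e.length) for e in els.elements]
        assert kinds == [
            ("stem", 6),
            ("internal_loop_side", 6),
            ("stem", 5),
            ("hairpin_loop", 13),
            ("internal_loop_side", 5),
        ]

    def test_or4k15_elements(self, or4k15):
        els = element_decomposition(truth_structure(or4k15))
        stems = sorted((e.length for e in els.elements if e.kind == "stem"), reverse=True)
        loops = sorted(e.length for e in els.elements if e.kind == "internal_loop_side")
        assert stems == [5, 4]
        assert loops == [5, 6]

    def test_simple_hairpin(self, toy):
        els = element_decomposition(truth_structure(toy))
        assert [(e.kind, e.length) for e in els.elements] == [
            ("stem", 4),
            ("hairpin_loop", 4),
        ]

    def test_empty_structure_is_one_external_element(self):
        s = SecondaryStructure("GGGAAACCC", frozenset())
        els = element_decomposition(s)
        assert [(e.kind, e.length) for e in els.elements] == [("external", 9)]

    def test_round_trip_through_dotbracket(self, line1):
        s = truth_structure(line1)
        back = SecondaryStructure.from_dotbracket(s.sequence, s.to_dotbracket())
        a = element_decomposition(s).elements
        b = element_decomposition(back).elements
        assert a == b


class TestCircularPermutation:
    def test_reflexive(self, line1):
        e = element_decomposition(truth_structure(line1))
        assert is_circular_permutation(e, e, len_tol=0) == 0

    def test_fixtures_are_circular_permutations(self, line1, or4k15):
        ea = element_decomposition(truth_structure(line1))
        eb = element_decomposition(truth_structure(or4k15))
        assert is_circular_permutation(ea, eb, len_tol=1) is not None

    def test_symmetry(self, line1, or4k15):
        ea = element_decomposition(truth_structure(line1))
        eb = element_decomposition(truth_structure(or4k15))
        m = len(ea.reduced())
        off_ab = is_circular_permutation(ea, eb, len_tol=1)
        off_ba = is_circular_permutation(eb, ea, len_tol=1)
        assert off_ab is not None and off_ba is not None
        assert (off_ab + off_ba) % m == 0  # inverse rotations

    def test_kind_mismatch_returns_none(self, toy):
        hairpin = element_decomposition(truth_structure(toy))
        lantern = ElementString(
            [
                Element("stem", 4),
                Element("internal_loop_side", 4),
                Element("stem", 4),
                Element("hairpin_loop", 4),
                Element("internal_loop_side", 4),
            ]
        )
        assert is_circular_permutation(hairpin, lantern, len_tol=2) is None


class TestMatchDescriptor:
    def test_constructed_match(self):
        hits = match_descriptor("GGGGAAACCC", "h1(3:3) s1(4:4,GAAA) h1'")
        assert hits == [{"h1": (1, 3), "s1": (4, 7), "h1'": (8, 10)}]

    def test_no_complementarity_no_hits(self):
        assert match_descriptor("AAAAAAAAAA", "h1(3:3) s1(4:4,GAAA) h1'") == []

    def test_malformed_descriptor_rejected(self):
        with pytest.raises(ValueError):
            MotifDescriptor.parse("h1(3:3) s1(4:4) h2'")
        with pytest.raises(ValueError):
            MotifDescriptor.parse("garbage")

    def test_ts_like_descriptor_hits_fixtures_at_annotated_coordinates(
        self, line1, or4k15
    ):
        d = ts_like_descriptor()
        hits1 = match_descriptor(line1.sequence, d)
        assert {
            "h1": (1, 6), "s1": (7, 12), "h2": (13, 17), "s2": (18, 30),
            "h2'": (31, 35), "s3": (36, 40), "h1'": (41, 46),
        } in hits1
        hits2 = match_descriptor(or4k15.sequence, d)
        assert {
            "h1": (1, 5), "s1": (6, 10), "h2": (11, 14), "s2": (15, 32),
            "h2'": (33, 36), "s3": (37, 42), "h1'": (43, 47),
        } in hits2

    def test_agrees_with_brute_force_enumerator(self):
        """Exhaustive reference placement of a one-helix descriptor."""
        seqs = ["GGGAAACCCGGG", "GCAGAAACUGCAGAAA", "ACGUACGUACGUACG"]
        desc = "h1(2:3) s1(3:5) h1'"
        for seq in seqs:
            n = len(seq)
            expected = set()
            for start in range(1, n + 1):
                for hl in (2, 3):
                    for sl in (3, 4, 5):
                        end = start + 2 * hl + sl - 1
                        if end > n:
                            continue
                        arm5 = seq[start - 1 : start - 1 + hl]
                        arm3 = seq[start - 1 + hl + sl : end]
                        if all(
                            pair_class_of(x, y) is not None
                            for x, y in zip(arm5, arm3[::-1])
                        ):
                            expected.add(
                                (
                                    (start, start + hl - 1),
                                    (start + hl, start + hl + sl - 1),
                                    (start + hl + sl, end),
                                )
                            )
            got = {
                (h["h1"], h["s1"], h["h1'"]) for h in match_descriptor(seq, desc)
            }
            assert got == expected


class TestKinetics:
    def test_recovers_planted_parameters_on_noise_free_trace(self):
        t = np.arange(0.0, 181.0, 6.0)
        f = 1.0 - 1.0 * np.exp(-0.05 * t)
        fit = fit_first_order(KineticsTrace(t, f))
        assert fit.ok
        assert fit.a == pytest.approx(1.0, rel=1e-3)
        assert fit.b == pytest.approx(1.0, rel=1e-3)
        assert fit.k_obs == pytest.approx(0.05, rel=1e-3)

    def test_constant_trace_fails_explicitly(self):
        t = np.arange(0.0, 60.0, 5.0)
        fit = fit_first_order(KineticsTrace(t, np.full_like(t, 2.0)))
        assert not fit.ok
        assert "unidentifiable" in fit.message

    def test_normalisation_by_control(self):
        t = np.arange(0.0, 181.0, 6.0)
        f = 4.0 * (1.0 - np.exp(-0.05 * t)) + 0.4
        fit = fit_first_order(KineticsTrace(t, f), control_f0=2.0)
        assert fit.ok
        assert fit.k_obs == pytest.approx(0.05, rel=1e-3)
        assert fit.a == pytest.approx((4.0 + 0.4) / 2.0, rel=1e-3)

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            KineticsTrace(np.array([0.0, 2.0, 1.0]), np.zeros(3))
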