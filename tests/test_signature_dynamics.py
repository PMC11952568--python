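"""Fold changes, ID-83 classification, motif minima, replication timing and
neoantigen propensity."""

import numpy as np
import pandas as pd
import pytest

from tumorchrono.core_io import AttributionTable
from tumorchrono.signature_dynamics import (
    classify_id83,
    clonality_fold_change,
    min_homopolymer_by_signature,
    neoantigen_propensity,
    replication_timing_correlation,
)


def _attr(rows, sigs=("S1", "S2")):
    """rows: list of (sample, key, clonality, probs...)"""
    idx = pd.MultiIndex.from_tuples([(r[0], r[1]) for r in rows])
    probs = pd.DataFrame([r[3] for r in rows], index=idx, columns=list(sigs))
    labels = pd.Series([r[2] for r in rows], index=idx)
    return AttributionTable(probs), labels


class TestFoldChange:
    def test_equal_proportions_give_unit_fold_change(self):
        rows = []
        for i in range(10):
            rows.append(("s", f"c{i}", "clonal_unspecified", [0.6, 0.4]))
            rows.append(("s", f"u{i}", "subclonal", [0.6, 0.4]))
        attr, labels = _attr(rows)
        rec, _ = clonality_fold_change(attr, labels, min_clonal_mass=1.0)
        assert np.allclose(rec["fold_change"], 1.0)

    def test_ratio_arithmetic(self):
        rows = []
        for i in range(50):
            rows.append(("s", f"c{i}", "clonal_unspecified", [0.1, 0.9]))
        for i in range(50):
            rows.append(("s", f"u{i}", "subclonal", [0.4, 0.6]))
        attr, labels = _attr(rows)
        rec, _ = clonality_fold_change(attr, labels, min_clonal_mass=4.0)
        fc = rec.set_index("signature")["fold_change"]
        assert fc["S1"] == pytest.approx(4.0)

    def test_sample_without_subclonal_mutations_excluded(self):
        rows = [("s", f"c{i}", "clonal_unspecified", [0.5, 0.5]) for i in range(20)]
        attr, labels = _attr(rows)
        rec, _ = clonality_fold_change(attr, labels)
        assert len(rec) == 0

    def test_low_clonal_mass_signature_excluded(self):
        rows = ([("s", f"c{i}", "clonal_unspecified", [0.95, 0.05])
                 for i in range(20)]
                + [("s", f"u{i}", "subclonal", [0.5, 0.5]) for i in range(5)])
        attr, labels = _attr(rows)
        rec, _ = clonality_fold_change(attr, labels, min_clonal_mass=5.0)
        assert set(rec["signature"]) == {"S1"}   # S2 mass = 1 < 5

    def test_doubled_subclonal_activity_recovered_in_cohort_median(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(40):
            n_c, n_s = 120, 60
            z_c = rng.random(n_c) < 0.25    # clonal: 25% signature S1
            z_s = rng.random(n_s) < 0.50    # subclonal: doubled
            for i in range(n_c):
                rows.append((f"s{s}", f"c{i}", "clonal_unspecified",
                             [1.0, 0.0] if z_c[i] else [0.0, 1.0]))
            for i in range(n_s):
                rows.append((f"s{s}", f"u{i}", "subclonal",
                             [1.0, 0.0] if z_s[i] else [0.0, 1.0]))
        attr, labels = _attr(rows)
        _, summary = clonality_fold_change(attr, labels)
        med = summary.set_index("signature").loc["S1", "median_fc"]
        assert 1.7 <= med <= 2.3


class TestClassifyId83:
    def test_insertion_next_to_run_of_five(self):
        ch = classify_id83("A", "AT", "GCGCGCGCA", "TTTTTAGCGC")
        assert (ch.kind, ch.subtype, ch.unit_class) == ("Ins", "T", "5+")
        assert ch.homopolymer_length == 5

    def test_deletion_from_run_of_six(self):
        ch = classify_id83("AT", "A", "GCGCGCGCA", "TTTTTAGCGC")
        assert (ch.kind, ch.subtype, ch.unit_class) == ("Del", "T", "6+")
        assert ch.homopolymer_length == 6

    def test_singleton_deletion(self):
        ch = classify_id83("AT", "A", "GCGCGCGCA", "AGCGCGCGC")
        assert (ch.kind, ch.subtype, ch.unit_class) == ("Del", "T", "1")
        assert ch.homopolymer_length == 1

    def test_purine_base_normalized_to_pyrimidine(self):
        # deleting an A counts as a T-deletion on the opposite strand
        ch = classify_id83("CA", "C", "GCGCGCGTC", "AAAAAGCGCG")
        assert ch.subtype == "T"
        assert ch.homopolymer_length == 6

    def test_run_spans_both_flanks(self):
        # anchor T joins the run: 2 left + anchor + deleted + 2 right = 6
        ch = classify_id83("TT", "T", "GCGCGCGTT", "TTAGCGCGC")
        assert ch.homopolymer_length == 6

    def test_repeat_deletion_counts_units_including_deleted_copy(self):
        ch = classify_id83("TACG", "T", "GCGCGCGCT", "ACGACGTTGC")
        assert (ch.kind, ch.subtype, ch.size_class, ch.unit_class) == \
               ("Del", "rep", "3", "3")

    def test_microhomology_deletion(self):
        ch = classify_id83("TACGT", "T", "GCGCGCGCT", "ACTTGCGCGC")
        assert (ch.kind, ch.subtype, ch.size_class, ch.unit_class) == \
               ("Del", "mh", "4", "2")

    def test_short_context_unclassified(self):
        with pytest.raises(ValueError, match="unclassified"):
            classify_id83("AT", "A", "GCA", "TTTTTTTTTT")

    def test_generator_channels_recovered(self):
        """classify_id83 inverts simulate_indels on every channel family."""
        from tumorchrono.synthetic_cohort import simulate_indels

        mix = {"Del:T:1": 1, "Del:T:4": 1, "Del:T:6+": 1, "Ins:T:0": 1,
               "Ins:T:3": 1, "Ins:T:5+": 1, "Del:C:2": 1, "Ins:C:1": 1,
               "Del:rep:2:2": 1, "Del:rep:4:6+": 1, "Ins:rep:3:2": 1,
               "Del:mh:5+:3": 1}
        sims = simulate_indels(mix, 2000, seed=3)
        agree = sum(
            classify_id83(s.ref, s.alt, s.left_flank, s.right_flank).name
            == s.channel
            for s in sims
        )
        assert agree / len(sims) >= 0.99


class TestMotifMinima:
    def test_minimum_tracks_attributed_channel(self):
        from tumorchrono.synthetic_cohort import simulate_indels

        ins = simulate_indels({"Ins:T:5+": 1.0}, 100, seed=1)
        dele = simulate_indels({"Del:T:6+": 1.0}, 100, seed=2)
        channels = [
            classify_id83(s.ref, s.alt, s.left_flank, s.right_flank)
            for s in ins + dele
        ]
        attr = pd.DataFrame(
            [[1.0, 0.0]] * 100 + [[0.0, 1.0]] * 100, columns=["ID1", "ID2"])
        mins = min_homopolymer_by_signature(channels, attr)
        assert mins == {"ID1": 5, "ID2": 6}

    def test_unattributed_signature_absent(self):
        ch = classify_id83("AT", "A", "GCGCGCGCA", "AGCGCGCGC")
        attr = pd.DataFrame([[0.3, 0.7]], columns=["ID1", "ID2"])
        mins = min_homopolymer_by_signature([ch], attr)
        assert "ID1" not in mins and mins["ID2"] == 1


class TestReplicationTiming:
    def test_exact_collinearity(self):
        counts = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        timing = pd.Series([2.0, 4, 6, 8], index=list("abcd"))
        r, p = replication_timing_correlation(counts, timing)
        assert r == pytest.approx(1.0)

    def test_negative_collinearity(self):
        counts = pd.Series([10.0, 8, 6, 4], index=list("abcd"))
        timing = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, _ = replication_timing_correlation(counts, timing)
        assert r == pytest.approx(-1.0)

    def test_degenerate_and_short_inputs_error(self):
        idx = list("abcd")
        with pytest.raises(ValueError, match="zero variance"):
            replication_timing_correlation(
                pd.Series([3.0] * 4, index=idx),
                pd.Series([1.0, 2, 3, 4], index=idx))
        with pytest.raises(ValueError, match=">= 3"):
            replication_timing_correlation(
                pd.Series([1.0, 2], index=["a", "b"]),
                pd.Series([1.0, 2], index=["a", "b"]))


class TestNeoantigenPropensity:
    def test_extremes_and_arithmetic(self):
        attr = pd.DataFrame({"S1": [1.0] * 4 + [0.0] * 12,
                             "S2": [0.0] * 4 + [1.0] * 12})
        neo = [True, False, False, False] + [True] * 12
        out = neoantigen_propensity(attr, neo, min_mass=1.0)
        assert out["S1"] == pytest.approx(250.0)
        assert out["S2"] == pytest.approx(1000.0)

    def test_none_neoantigenic_is_zero(self):
        attr = pd.DataFrame({"S1": [1.0] * 15})
        out = neoantigen_propensity(attr, [False] * 15)
        assert out["S1"] == 0.0

    def test_low_mass_signature_suppressed(self):
        attr = pd.DataFrame({"S1": [1.0] * 15, "S2": [0.0] * 15})
        out = neoantigen_propensity(attr, [True] * 15)
        assert "S2" not in out

    def test_invariant_under_duplication(self):
        attr = pd.DataFrame({"S1": [1.0, 1.0, 0.5] * 5})
        neo = [True, False, True] * 5
        once = neoantigen_propensity(attr, neo, min_mass=1.0)
        twice = neoantigen_propensity(
            pd.concat([attr, attr], ignore_index=True), neo + neo, min_mass=1.0)
        assert once["S1"] == pytest.approx(twice["S1"])
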