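import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_sequence
from oracles import (
    g4_present_brute,
    ggc_repeat_brute,
    max_pairs_exhaustive,
    paired_ggagg_brute,
)
from translatome.utr import (
    GC_RICH_MOTIF,
    MaxPairingFolder,
    UTRRecord,
    ViennaFolder,
    compile_motif,
    compute_features,
    count_uaugs,
    fold_energy,
    gc_content,
    longest_utr_per_gene,
    normalize_sequence,
    scan_g4,
    scan_motif,
    scan_paired_ggagg,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestBasicFeatures:
    @pytest.mark.parametrize(
        "seq, expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCNN", 1.0), ("AANN", 0.0)],
    )
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_gc_all_n_is_missing(self):
        assert np.isnan(gc_content("NNNN"))

    @pytest.mark.parametrize(
        "seq, expected", [("AAATGAA", 1), ("ATGATG", 2), ("CCCCCC", 0), ("AUGAUG", 2)]
    )
    def test_count_uaugs(self, seq, expected):
        assert count_uaugs(seq) == expected

    def test_normalize_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            normalize_sequence("ACGX")
        with pytest.raises(ValueError):
            normalize_sequence("")

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_case_and_ut_invariance(self, seq):
        rna = seq.replace("T", "u").lower()
        assert gc_content(seq) == gc_content(rna)
        assert count_uaugs(seq) == count_uaugs(rna)
        assert scan_g4(seq) == scan_g4(rna)
        assert scan_paired_ggagg(seq) == scan_paired_ggagg(rna)


class TestScanners:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GGAGGAGGAGG", True),  # three 1-nt loops, GG tracts
            ("GGGAGGGAGGGAGGG", True),  # GGG tracts
            ("ATATATATATAT", False),
            ("GGTTTTTTTTGGTGGTGGTGG", True),  # first loop too long, later chain works
            ("GGTTTTTTTTGGTTTTTTTTGGTTTTTTTTGG", False),  # all loops 8 nt
        ],
    )
    def test_g4_examples(self, seq, expected):
        assert scan_g4(seq) is expected

    def test_g4_intervals_leftmost_shortest(self):
        present, intervals = scan_g4("AAGGAGGAGGAGGTTT", with_intervals=True)
        assert present and intervals[0] == (2, 13)

    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GGAGGAAAAGGAGG", True),  # 4-nt linker
            ("GGAGGAAAGGAGG", False),  # 3-nt linker
            ("GGAGG" + "A" * 11 + "GGAGG", False),  # linker > 10
            ("GGAGG" + "A" * 10 + "GGAGG", True),
        ],
    )
    def test_paired_ggagg_examples(self, seq, expected):
        assert scan_paired_ggagg(seq) is expected

    @pytest.mark.parametrize(
        "seq, pattern, expected",
        [
            ("GCGGCGGCGGCG", "GC(GGC){3}G", True),
            ("GCGGCGGCG", "GC(GGC){3}G", False),  # only two GGC repeats
            ("TTTTTTT", "U{6,}", True),
            ("TTTTT", "U{6,}", False),
            ("AGGAGGA", "GGAGG", True),
            ("AGGAGA", "GGAGG", False),
            ("GACA", "RY", True),  # IUPAC codes: purine then pyrimidine
        ],
    )
    def test_scan_motif(self, seq, pattern, expected):
        assert scan_motif(seq, pattern) is expected

    @pytest.mark.parametrize("pattern", ["GC(GGC{3}", "{3}GGC", "GC-GGC", "QQ", "G)("])
    def test_malformed_pattern_rejected(self, pattern):
        with pytest.raises(ValueError):
            compile_motif(pattern)

    def test_scanners_agree_with_brute_force(self, rng):
        """Regex scanners vs independent enumeration oracles on random
        sequences across a GC gradient: zero discrepancies."""
        for i in range(2000):
            seq = random_sequence(rng, 100, p_gc=0.3 + 0.5 * (i % 5) / 4)
            assert scan_g4(seq) == g4_present_brute(seq)
            assert scan_paired_ggagg(seq) == paired_ggagg_brute(seq)
            assert scan_motif(seq, GC_RICH_MOTIF) == ggc_repeat_brute(seq)

    @given(dna, dna)
    @settings(max_examples=200, deadline=None)
    def test_g4_monotone_under_concatenation(self, a, b):
        if scan_g4(a):
            assert scan_g4(a + b)


class TestFolding:
    def test_unpairable_sequence_scores_zero(self):
        folder = MaxPairingFolder()
        assert folder.fold("AAAAAAAA") == 0.0
        assert fold_energy("CCCCCCCC", folder) == 0.0

    def test_hairpin_pair_count(self):
        # GGGG AAAA CCCC: four GC pairs around a 4-nt hairpin loop
        folder = MaxPairingFolder(pair_energy=1.0)
        assert folder.fold("GGGGAAAACCCC") == -4.0
        assert MaxPairingFolder(pair_energy=2.5).fold("GGGGAAAACCCC") == -10.0

    def test_matches_exhaustive_structure_enumeration(self, rng):
        """DP pair maximization equals explicit enumeration of every
        non-crossing structure on short sequences."""
        folder = MaxPairingFolder()
        for _ in range(40):
            n = int(rng.integers(4, 15))
            seq = random_sequence(rng, n)
            assert folder.max_pairs(seq) == max_pairs_exhaustive(seq)

    def test_energy_is_nonpositive(self, rng):
        folder = MaxPairingFolder()
        for _ in range(20):
            assert folder.fold(random_sequence(rng, 30)) <= 0.0

    def test_vienna_folder_contract(self):
        folder = ViennaFolder()
        assert fold_energy("A" * 20, folder) == 0.0
        mfe = fold_energy("GGGGGGAAAACCCCCC", folder)
        assert mfe < -3.0  # stable hairpin

    def test_engine_failure_flagged_not_raised(self):
        class Broken:
            def fold(self, seq):
                raise RuntimeError("boom")

        assert np.isnan(fold_energy("ACGT", Broken()))


class TestLongestUtrPerGene:
    def test_longest_kept(self):
        recs = [
            UTRRecord("t1", "g1", "A" * 100),
            UTRRecord("t2", "g1", "A" * 250),
            UTRRecord("t3", "g2", "A" * 50),
        ]
        kept = longest_utr_per_gene(recs)
        assert [(r.gene_id, r.transcript_id) for r in kept] == [("g1", "t2"), ("g2", "t3")]

    def test_length_tie_broken_by_id(self):
        recs = [UTRRecord("tB", "g1", "A" * 100), UTRRecord("tA", "g1", "C" * 100)]
        assert longest_utr_per_gene(recs)[0].transcript_id == "tA"

    def test_collapse_count(self, rng):
        # 175 transcripts over 156 genes collapse to one record per gene
        recs = []
        genes = [f"g{i:03d}" for i in range(156)]
        for i in range(175):
            gene = genes[i] if i < 156 else genes[int(rng.integers(0, 156))]
            recs.append(UTRRecord(f"t{i:03d}", gene, random_sequence(rng, 30)))
        assert len(longest_utr_per_gene(recs)) == 156


def test_compute_features_table(rng):
    recs = [
        UTRRecord("t1", "g1", "GCGGCGGCGGCGATG"),
        UTRRecord("t2", "g2", "ATATATATATATAT"),
    ]
    feats = compute_features(recs, folder=MaxPairingFolder())
    assert list(feats.index) == ["t1", "t2"]
    assert feats.loc["t1", "has_ggc_motif"] and not feats.loc["t2", "has_ggc_motif"]
    assert feats.loc["t1", "n_uaug"] == 1
    assert feats.loc["t1", "gc"] > feats.loc["t2", "gc"]
    assert (feats["dG"] <= 0).all()
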