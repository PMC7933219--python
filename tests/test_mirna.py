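import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from diffconn import datasets, mirna
from diffconn.mirna import (
    SeedMatchSite,
    TargetPredictionSet,
    find_seed_matches,
    intersect_target_sets,
    reverse_complement,
)

MIR124 = datasets.MIR_124_3P


def tset(name, ids):
    return TargetPredictionSet.from_ids(name, ids)


class TestIntersection:
    def test_three_set_example(self):
        res = intersect_target_sets(
            [tset("s1", "abc"), tset("s2", "bcd"), tset("s3", "cde")]
        )
        assert res.common == {"c"}
        assert sum(res.region_counts.values()) == 5  # |union|
        assert res.region_counts[("s1", "s2", "s3")] == 1
        assert res.region_counts[("s1",)] == 1  # 'a' only

    def test_identical_sets_fully_common(self):
        res = intersect_target_sets([tset("x", "abc"), tset("y", "abc")])
        assert res.common == {"a", "b", "c"}
        assert res.region_counts[("x", "y")] == 3

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_target_sets([tset("only", "ab")])

    def test_order_invariance(self, rng):
        ids = [f"m{i}" for i in range(50)]
        sets = [
            tset(name, rng.choice(ids, size=20, replace=False))
            for name in ("a", "b", "c")
        ]
        r1 = intersect_target_sets(sets)
        r2 = intersect_target_sets(sets[::-1])
        assert r1.common == r2.common and r1.region_counts == r2.region_counts

    def test_database_scale_counts_match_brute_force(self, rng):
        """Region counts on sets sized like the three miRNA databases
        (67 / 372 / 1715) equal exhaustive membership tabulation."""
        pool = [f"miR-{i}" for i in range(2500)]
        sizes = {"targetscan": 67, "mirdb": 372, "rna22": 1715}
        sets = [
            tset(name, rng.choice(pool, size=k, replace=False))
            for name, k in sizes.items()
        ]
        res = intersect_target_sets(sets)
        members = {s.source_name: s.members for s in sets}
        union = set().union(*members.values())
        for combo, count in res.region_counts.items():
            expected = sum(
                1
                for el in union
                if all(el in members[n] for n in combo)
                and all(el not in members[n] for n in members if n not in combo)
            )
            assert count == expected
        assert len(res.common) == res.region_counts[tuple(sorted(sizes))]


class TestReverseComplement:
    def test_mir124_antisense_identity(self):
        """rc of the miR-124-3p cDNA equals the published antisense
        knockdown sequence."""
        assert (
            reverse_complement("TAAGGCACGCGGTGAATGCC", "DNA")
            == datasets.MIR_124_3P_ANTISENSE_DNA
        )

    def test_single_base_alphabets(self):
        assert reverse_complement("A", "DNA") == "T"
        assert reverse_complement("A", "RNA") == "U"

    def test_invalid_character_position_reported(self):
        with pytest.raises(ValueError, match="position 3"):
            reverse_complement("ACXGT", "DNA")

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq, "DNA"), "DNA") == seq


class TestSeedScanner:
    def test_mir124_8mer_site_positions(self):
        """rc of miR-124-3p nt 2-8 is GUGCCUU; followed by A it forms an
        8mer at UTR positions 3-10 of NNGUGCCUUANN."""
        sites = find_seed_matches(MIR124, "NNGUGCCUUANN")
        assert sites == [SeedMatchSite(3, 10, "8mer")]

    def test_no_complementary_hexamer_empty(self):
        assert find_seed_matches(MIR124, "AAAAAAAAAAAA") == []

    @pytest.mark.parametrize(
        "utr,expected",
        [
            ("NNGUGCCUUGNN", [SeedMatchSite(3, 9, "7mer-m8")]),
            ("NNUGCCUUANN", [SeedMatchSite(3, 9, "7mer-A1")]),
            ("NNUGCCUUGNN", [SeedMatchSite(3, 8, "6mer")]),
        ],
    )
    def test_site_type_taxonomy(self, utr, expected):
        assert find_seed_matches(MIR124, utr) == expected

    def test_dna_utr_equivalent_to_rna(self):
        rna_sites = find_seed_matches(MIR124, "NNGUGCCUUANN")
        dna_sites = find_seed_matches(MIR124, "nngtgccttann")
        assert rna_sites == dna_sites

    def test_translation_invariance(self):
        base = "GGUGCCUUAGG"
        shifted = "ACGU" + base
        s1 = find_seed_matches(MIR124, base)
        s2 = find_seed_matches(MIR124, shifted)
        assert [(s.utr_position_start + 4, s.utr_position_end + 4, s.site_type) for s in s1] == [
            (s.utr_position_start, s.utr_position_end, s.site_type) for s in s2
        ]

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            find_seed_matches("ACGUACG", "ACGUACGUACGU")

    def test_invalid_utr_character_rejected(self):
        with pytest.raises(ValueError, match="position"):
            find_seed_matches(MIR124, "ACGU!ACGU")

    def test_random_utrs_match_naive_oracle(self, rng):
        """Site lists on random UTRs equal the regex-based oracle scan for
        random miRNAs too."""
        bases = np.array(list("ACGU"))
        for _ in range(60):
            mir = "".join(rng.choice(bases, size=20))
            # enrich the UTR with seed-complement copies so matches occur
            seed_site = oracles._rc_rna(mir[1:8])
            chunks = ["".join(rng.choice(bases, size=30)) for _ in range(4)]
            utr = chunks[0] + seed_site + chunks[1] + seed_site[1:] + "A" + chunks[2] + seed_site[1:] + chunks[3]
            got = [(s.utr_position_start, s.utr_position_end, s.site_type) for s in find_seed_matches(mir, utr)]
            assert got == oracles.naive_seed_scan(mir, utr)

    def test_reported_substrings_are_the_expected_patterns(self, rng):
        """Post-hoc verification: the UTR substring of every reported site
        is exactly the pattern its type implies."""
        bases = np.array(list("ACGU"))
        mir = MIR124
        site7 = oracles._rc_rna(mir[1:8])
        hex6 = site7[1:]
        expected_pattern = {
            "8mer": site7 + "A",
            "7mer-m8": site7,
            "7mer-A1": hex6 + "A",
            "6mer": hex6,
        }
        for _ in range(20):
            utr = "".join(rng.choice(bases, size=400))
            for s in find_seed_matches(mir, utr):
                sub = utr[s.utr_position_start - 1 : s.utr_position_end]
                assert sub == expected_pattern[s.site_type]
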