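"""Seeds, seed families, and the canonical site scanner."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmodule.catalog import (
    AlphabetError,
    MatureMiRNA,
    SeedLengthError,
    assign_families,
    extract_seed,
    read_predictions,
    scan_utr_sites,
)

from conftest import random_mirna, random_utr


class TestExtractSeed:
    def test_slice_positions_2_to_8(self):
        assert extract_seed("ACGUACGUACGUACGUACGUAC") == "CGUACGU"

    @given(st.text(alphabet="ACGU", min_size=8, max_size=26))
    @settings(derandomize=True, max_examples=50)
    def test_any_sequence_gives_7nt_slice(self, seq):
        seed = extract_seed(seq)
        assert len(seed) == 7
        assert seed == seq[1:8]

    def test_too_short_raises_length_error(self):
        with pytest.raises(SeedLengthError):
            extract_seed("ACGUACG")

    def test_dna_character_raises_alphabet_error(self):
        with pytest.raises(AlphabetError):
            extract_seed("ACGTACGTACGT")


class TestFamilies:
    def test_identical_seeds_share_family(self):
        a = MatureMiRNA("miR-279-3p", "UGACUAGAUCCACACUCAUUAA")
        b = MatureMiRNA("miR-996-3p", "UGACUAGAUUUCAUGCUCGUCU")
        assert a.seed == b.seed
        fam = assign_families([a, b])
        assert fam["miR-279-3p"] == fam["miR-996-3p"] == "miR-279-3p/miR-996-3p"

    def test_distinct_seeds_distinct_families(self):
        rng = np.random.default_rng(1)
        mirnas = []
        while len(mirnas) < 10:
            m = random_mirna(rng, f"miR-d{len(mirnas)}")
            if all(m.seed != o.seed for o in mirnas):
                mirnas.append(m)
        fam = assign_families(mirnas)
        assert len(set(fam.values())) == len(mirnas)

    def test_sixteen_mirnas_three_shared_pairs_make_13_families(self):
        rng = np.random.default_rng(7)
        mirnas = []
        while len(mirnas) < 16:
            m = random_mirna(rng, f"miR-p{len(mirnas):02d}")
            if all(m.seed != o.seed for o in mirnas):
                mirnas.append(m)
        # overwrite three to pair seeds: (0,1), (2,3), (4,5)
        for a, b in ((0, 1), (2, 3), (4, 5)):
            mirnas[b] = MatureMiRNA(
                mirnas[b].name, mirnas[a].sequence[:8] + mirnas[b].sequence[8:]
            )
        fam = assign_families(mirnas)
        assert len(set(fam.values())) == 13

    def test_family_grouping_is_equivalence_relation(self):
        rng = np.random.default_rng(3)
        mirnas = [random_mirna(rng, f"miR-e{i}") for i in range(8)]
        # force a 3-member class
        for i in (1, 2):
            mirnas[i] = MatureMiRNA(
                mirnas[i].name, mirnas[0].sequence[:8] + mirnas[i].sequence[8:]
            )
        fam = assign_families(mirnas)
        for a in mirnas:
            assert fam[a.name] == fam[a.name]  # reflexive
            for b in mirnas:
                same = fam[a.name] == fam[b.name]
                assert same == (a.seed == b.seed)  # seed identity <-> same class

    def test_duplicate_names_rejected(self):
        m = random_mirna(np.random.default_rng(0), "miR-x")
        with pytest.raises(ValueError, match="duplicate"):
            assign_families([m, m])


# ---------------------------------------------------------------------------
# scanner
# ---------------------------------------------------------------------------

def brute_force_sites(utr: str, mirna: MatureMiRNA) -> list[tuple[str, int, int]]:
    """Independent oracle: enumerate all pattern occurrences, then apply the
    same left-to-right greedy best-type resolution by explicit sweeping."""
    patterns = [(t, mirna.site_string(t)) for t in ("8mer", "7mer-m8", "7mer-A1")]
    out = []
    i = 0
    while i < len(utr):
        best = None
        for site_type, pat in patterns:
            if utr[i : i + len(pat)] == pat:
                best = (site_type, i + 1, i + len(pat))
                break
        if best is None:
            i += 1
        else:
            out.append(best)
            i = best[2]
    return out


class TestScanner:
    def test_8mer_example(self, example_mirna):
        sites = scan_utr_sites("AAATGGACTGAAA", example_mirna)
        assert [(s.site_type, s.start, s.end) for s in sites] == [("8mer", 4, 11)]

    def test_7mer_m8_example(self, example_mirna):
        sites = scan_utr_sites("AAATGGACTGCCC", example_mirna)
        assert [(s.site_type, s.start, s.end) for s in sites] == [("7mer-m8", 4, 10)]

    def test_7mer_a1_example(self, example_mirna):
        # core6 GGACTG followed by A, not preceded by T (which would make 8mer)
        sites = scan_utr_sites("CCGGACTGACC", example_mirna)
        assert [(s.site_type, s.start, s.end) for s in sites] == [("7mer-A1", 3, 9)]

    def test_no_match(self, example_mirna):
        assert scan_utr_sites("CCCCCCCC", example_mirna) == []

    def test_empty_utr_returns_empty(self, example_mirna):
        assert scan_utr_sites("", example_mirna) == []

    def test_invalid_alphabet_rejected(self, example_mirna):
        with pytest.raises(AlphabetError):
            scan_utr_sites("ACGU", example_mirna)

    def test_oracle_equivalence_on_random_pairs(self):
        """Scanner equals a brute-force enumeration oracle on >= 1000 pairs."""
        rng = np.random.default_rng(2024)
        n_with_sites = 0
        for trial in range(1000):
            mirna = random_mirna(rng, "miR-o")
            utr = random_utr(rng, int(rng.integers(20, 300)))
            # plant occasional sites so matches are not vanishingly rare
            if trial % 3 == 0:
                site = mirna.site_string(
                    ["8mer", "7mer-m8", "7mer-A1"][int(rng.integers(3))]
                )
                pos = int(rng.integers(0, len(utr)))
                utr = utr[:pos] + site + utr[pos:]
            got = [(s.site_type, s.start, s.end) for s in scan_utr_sites(utr, mirna)]
            expected = brute_force_sites(utr, mirna)
            assert got == expected
            n_with_sites += bool(got)
        assert n_with_sites > 200  # the comparison was not vacuous

    def test_appending_8mer_increases_count_by_one(self, example_mirna):
        rng = np.random.default_rng(9)
        for _ in range(20):
            utr = random_utr(rng, 100)
            before = len(scan_utr_sites(utr, example_mirna))
            extended = utr + "CC" + example_mirna.site_string("8mer")
            after = len(scan_utr_sites(extended, example_mirna))
            assert after == before + 1

    def test_best_type_resolution_prefers_8mer(self, example_mirna):
        # TGGACTGA admits 8mer at 1 and 7mer-A1 at 2; greedy takes the 8mer
        sites = scan_utr_sites("TGGACTGA", example_mirna)
        assert [(s.site_type, s.start, s.end) for s in sites] == [("8mer", 1, 8)]


# ---------------------------------------------------------------------------
# prediction readers
# ---------------------------------------------------------------------------

class TestReadPredictions:
    def test_count_matrix_row_total(self, tmp_path):
        path = tmp_path / "matrix.tsv"
        path.write_text("gene\tfamA\tfamB\tfamC\nprospero\t3\t5\t0\n")
        records = read_predictions(path, "count_matrix")
        assert sum(r.site_count for r in records if r.gene == "prospero") == 8
        # zero cells yield no record
        assert all(r.site_count > 0 for r in records)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("gene\tfamily\tsite_type\tstart\tend\n")
        assert read_predictions(path, "site_table") == []

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("gene\tfamA\ng1\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_predictions(path, "count_matrix")

    def test_missing_columns_is_format_error(self, tmp_path):
        from mirmodule.catalog import PredictionFormatError

        path = tmp_path / "bad.tsv"
        path.write_text("gene\tfamily\nprospero\tfamA\n")
        with pytest.raises(PredictionFormatError, match="missing"):
            read_predictions(path, "site_table")

    def test_site_table_tolerates_crlf_and_comments(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_bytes(
            b"# comment line\r\ngene\tfamily\tsite_type\tstart\tend\r\n"
            b"prospero\tfamA\t8mer\t4\t11\r\n"
        )
        records = read_predictions(path, "site_table")
        assert len(records) == 1 and records[0].site_count == 1
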