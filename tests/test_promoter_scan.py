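"""5'UTR extraction, motif scanning and promoter architecture."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igloci.locus_model import LocusSequence, reverse_complement
from igloci.promoter_scan import (
    ELEMENT_PATTERNS,
    ElementDefinition,
    ElementMatch,
    PromoterAnnotation,
    annotate_promoter,
    default_element_set,
    extract_5utr,
    scan_element,
    subgroup_architecture,
)

OCT = ElementDefinition("OCTAMER", ELEMENT_PATTERNS["OCTAMER"])
DEC = ElementDefinition("DECAMER", ELEMENT_PATTERNS["DECAMER"])
EBOX = ElementDefinition("E_BOX", ELEMENT_PATTERNS["E_BOX"])
PENTA = ElementDefinition("PENTADECAMER", ELEMENT_PATTERNS["PENTADECAMER"])


def _utr_with(planted: dict[int, str], length: int = 500, seed: int = 0) -> str:
    """Background with a G every third base (no spurious core motifs), with
    ``planted`` = {offset of 5' base: element sequence}."""
    rng = random.Random(seed)
    utr = [("G" if i % 3 == 0 else rng.choice("ACGT")) for i in range(length)]
    for off, seq in planted.items():
        start = length - off
        for k, ch in enumerate(seq):
            utr[start + k] = ch
        for j in (start - 2, start - 1, start + len(seq), start + len(seq) + 1):
            if 0 <= j < length:
                utr[j] = "G"  # stop A/T runs and pyrimidine tracts extending
    return "".join(utr)


class TestMotifTable:
    def test_octamer_decamer_inverted_complementary(self):
        """The light-chain decamer is the heavy-chain octamer in inverted
        complementary form with two extra 5' nucleotides."""
        assert reverse_complement(ELEMENT_PATTERNS["OCTAMER"]) == \
            ELEMENT_PATTERNS["DECAMER"][2:]


class TestExtract5utr:
    def _locus(self, seq):
        return LocusSequence("IGK", "c", 1, len(seq), "FWD", seq)

    def test_short_window_flagged(self):
        seq = "C" * 200 + "ATG" + "T" * 10
        utr, short = extract_5utr(self._locus(seq), 201, window=500)
        assert len(utr) == 200 and short

    def test_marker_lands_at_expected_window_position(self):
        """A marker 100 nt upstream of the ATG occupies window position 401
        of 500 (index arithmetic oracle)."""
        marker = "TTTTT"
        left = "C" * 600
        seq = left[:500] + marker + "C" * (100 - len(marker)) + "ATG" + "AA"
        utr, short = extract_5utr(self._locus(seq), 601, window=500)
        assert not short and len(utr) == 500
        assert utr[400:405] == marker

    def test_inverted_gene_window_is_revcomp_of_downstream_flank(self):
        flank = "ACGTTGCA" * 10
        seq = "GG" + reverse_complement("ATG") + flank + "TT"
        locus = self._locus(seq)
        atg = 5  # A of ATG on the inverted strand sits at the label's 3' end
        utr, short = extract_5utr(locus, atg, window=80, inverted=True)
        assert utr == reverse_complement(seq[5 : 5 + 80])
        assert utr.endswith(reverse_complement(flank[:3]))

    def test_error_when_no_atg(self):
        with pytest.raises(ValueError, match="no ATG"):
            extract_5utr(self._locus("CCCCCCCC"), 3)


class TestScan:
    def test_octamer_at_offset(self):
        utr = _utr_with({120: "ATGCAAAT"})
        [m] = scan_element(utr, OCT)
        assert (m.offset, m.sequence, m.mismatches) == (120, "ATGCAAAT", 0)

    def test_decamer_matches_printed_consensus(self):
        assert scan_element("AGATTTGCAT", DEC)[0].mismatches == 0

    def test_ebox_pattern(self):
        assert scan_element("CAGGTG", EBOX)
        assert not scan_element("CAGGTA", EBOX)

    def test_pentadecamer_contains_inner_ebox(self):
        penta = "TGCAACTGTGTCCAG"
        assert scan_element(penta, PENTA)
        inner = [m for m in scan_element(penta, EBOX)]
        assert any(m.sequence == "CAACTG" for m in inner)

    def test_degenerate_n_never_counts_as_mismatch(self):
        m = scan_element("GGATTTGCAT", DEC)  # NN positions differ freely
        assert m and m[0].mismatches == 0

    def test_mismatch_budget(self):
        loose = ElementDefinition("OCTAMER", "ATGCAAAT", max_mismatches=1)
        assert not scan_element("ATGCAATA", OCT)
        hits = scan_element("ATGCAAAA", loose)
        assert hits and hits[0].mismatches == 1

    @given(st.text(alphabet="ACGT", min_size=8, max_size=80), st.integers(0, 50))
    @settings(max_examples=60, derandomize=True)
    def test_exact_scan_equals_sliding_window_oracle(self, utr, seed):
        """Zero-mismatch scanning equals a naive sliding-window comparison."""
        pattern = "ATGCAAAT"
        got = {m.offset for m in scan_element(utr, OCT)}
        expected = {
            len(utr) - i
            for i in range(len(utr) - len(pattern) + 1)
            if utr[i : i + len(pattern)] == pattern
        }
        assert got == expected

    def test_pyrimidine_rich_rule(self):
        pyr = ElementDefinition("PYRIMIDINE_RICH", kind="pyrimidine", min_len=10)
        utr = _utr_with({60: "TCCTCCTCCTCCTT"}, length=120, seed=3)
        matches = scan_element(utr, pyr)
        assert any(m.offset == 60 and len(m.sequence) >= 10 for m in matches)

    def test_tata_is_maximal_at_run(self):
        tata = ElementDefinition("TATA_BOX", kind="tata", min_len=5)
        utr = _utr_with({50: "TATAAAT"}, length=100, seed=1)
        matches = scan_element(utr, tata)
        assert [m.offset for m in matches] == [50]
        assert matches[0].sequence == "TATAAAT"


class TestAnnotate:
    def test_kappa_style_core_chain(self):
        """Planted pentadecamer-decamer-CCCT-TATA architecture is recovered
        in order with strictly increasing offsets."""
        planted = {
            "TATA_BOX": 46, "CCCT": 77, "DECAMER": 104,
            "CCCT.2": 144, "PENTADECAMER": 186,
        }
        seqs = {"TATA_BOX": "TATAAAT", "CCCT": "CCCT", "DECAMER": "AGATTTGCAT",
                "CCCT.2": "CCCT", "PENTADECAMER": "TGCAACTGTGTCCAG"}
        utr = _utr_with({off: seqs[k] for k, off in planted.items()}, seed=6)
        ann = annotate_promoter(utr, default_element_set("IGK"))
        assert ann.architecture_key == "TATA_BOX-CCCT-DECAMER-CCCT-PENTADECAMER"
        offsets = [m.offset for _, m in ann.elements]
        assert offsets == sorted(offsets) and len(set(offsets)) == len(offsets)
        assert ann.offset_of("DECAMER") == 104
        assert ann.offset_of("CCCT", occurrence=2) == 144

    def test_heavy_style_tata_between_atg_and_octamer(self):
        utr = _utr_with({32: "TATAAAT", 80: "ATGCAAAT", 180: "TCCTCCTCCTCCTT"},
                        seed=9)
        ann = annotate_promoter(utr, default_element_set("IGH"))
        found = dict((n, m.offset) for n, m in ann.elements)
        assert found["TATA_BOX"] < found["OCTAMER"]
        assert "HEPTANUCLEOTIDE" in ann.missing  # no consensus configured

    def test_missing_elements_are_data_not_errors(self):
        utr = _utr_with({46: "TATAAAT", 104: "AGATTTGCAT"}, seed=2)
        ann = annotate_promoter(utr, default_element_set("IGL"))
        assert "PENTADECAMER" in ann.missing
        assert "DECAMER" in ann.architecture_key

    def test_offsets_strictly_increase(self):
        utr = _utr_with({46: "TATAAAT", 77: "CCCT", 104: "AGATTTGCAT",
                         144: "CCCT", 186: "TGCAACTGTGTCCAG"}, seed=12)
        ann = annotate_promoter(utr, default_element_set("IGK"))
        offsets = [m.offset for _, m in ann.elements]
        assert all(a < b for a, b in zip(offsets, offsets[1:]))


class TestSubgroupArchitecture:
    def test_fixed_offset_full_presence(self):
        anns = []
        for i in range(6):
            utr = _utr_with({104: "AGATTTGCAT", 46: "TATAAAT"}, seed=i)
            anns.append(annotate_promoter(utr, default_element_set("IGL"),
                                          allele_ref=f"g{i}*01"))
        summary = subgroup_architecture({"IGLV1": anns})
        dec = summary["IGLV1"]["DECAMER"]
        assert dec["presence"] == 1.0
        assert dec["min_offset"] == dec["max_offset"] == 104
        assert dec["consensus"] == "AGATTTGCAT"

    def test_jittered_tata_mean_recovered(self):
        """TATA planted at mean offset 53 with +-3 jitter over 30 promoters:
        the recovered mean is within 1 nt (fixed seed)."""
        rng = random.Random(77)
        anns = []
        for i in range(30):
            off = 53 + rng.randint(-3, 3)
            utr = _utr_with({off: "TATAAAT", 120: "AGATTTGCAT"}, seed=1000 + i)
            anns.append(annotate_promoter(utr, default_element_set("IGK")))
        summary = subgroup_architecture({"IGKV1": anns})
        assert abs(summary["IGKV1"]["TATA_BOX"]["mean_offset"] - 53) <= 1.0

    def test_mixed_presence_fraction(self):
        present = ElementMatch(100, "AGATTTGCAT", 0)
        anns = [PromoterAnnotation(f"g{i}", [("DECAMER", present)]) for i in range(7)]
        anns += [PromoterAnnotation(f"h{i}", []) for i in range(3)]
        summary = subgroup_architecture({"sg": anns})
        assert summary["sg"]["DECAMER"]["presence"] == pytest.approx(0.7)

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError):
            subgroup_architecture({"sg": []})
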