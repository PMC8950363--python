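"""Translation, IMGT-grid numbering, CDR lengths and protein displays."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igloci.imgt_numbering import (
    HYDROPHOBIC,
    TEMPLATES,
    NumberingError,
    cdr_lengths,
    conserved_residues,
    format_cdr_lengths,
    number_v_domain,
    protein_display,
    translate_v_region,
)

# independent codon-table oracle: the standard genetic code, written out
_CODE = {}
for aa, codons in [
    ("F", "TTT TTC"), ("L", "TTA TTG CTT CTC CTA CTG"),
    ("I", "ATT ATC ATA"), ("M", "ATG"), ("V", "GTT GTC GTA GTG"),
    ("S", "TCT TCC TCA TCG AGT AGC"), ("P", "CCT CCC CCA CCG"),
    ("T", "ACT ACC ACA ACG"), ("A", "GCT GCC GCA GCG"),
    ("Y", "TAT TAC"), ("*", "TAA TAG TGA"), ("H", "CAT CAC"),
    ("Q", "CAA CAG"), ("N", "AAT AAC"), ("K", "AAA AAG"),
    ("D", "GAT GAC"), ("E", "GAA GAG"), ("C", "TGT TGC"),
    ("W", "TGG"), ("R", "CGT CGC CGA CGG AGA AGG"),
    ("G", "GGT GGC GGA GGG"),
]:
    for codon in codons.split():
        _CODE[codon] = aa

AA_NO_CW = "ADEFGHIKLMNPQRSTVY"


def _make_domain_aa(template, c1, c2, c3, rng=None, w41="W", res104="C",
                    res23="C", res89="L"):
    """Assemble a V-domain amino-acid sequence with the pivotal residues at
    their template slots and CDRs of the requested lengths."""
    rng = rng or random.Random(0)
    fr1 = [rng.choice(AA_NO_CW) for _ in template.fr_positions("FR1")]
    fr1[template.fr_positions("FR1").index(23)] = res23
    fr2 = [rng.choice(AA_NO_CW) for _ in template.fr_positions("FR2")]
    fr2[template.fr_positions("FR2").index(41)] = w41
    fr3 = [rng.choice(AA_NO_CW) for _ in template.fr_positions("FR3")]
    fr3[template.fr_positions("FR3").index(89)] = res89
    fr3[template.fr_positions("FR3").index(104)] = res104
    rand = lambda n: "".join(rng.choice(AA_NO_CW) for _ in range(n))
    return "".join(fr1) + rand(c1) + "".join(fr2) + rand(c2) + "".join(fr3) + rand(c3)


class TestTranslate:
    def test_standard_code(self):
        tr = translate_v_region("TGTGCC")
        assert tr.aa == "CA"
        assert not tr.has_stop and tr.trailing_nt == 0

    def test_stop_flagged_at_codon(self):
        tr = translate_v_region("TAA")
        assert tr.stop_codons == [0]

    def test_trailing_nt_reported_not_error(self):
        tr = translate_v_region("TGTGCCAA")
        assert tr.aa == "CA"
        assert tr.trailing_nt == 2

    def test_ambiguous_codon_flagged(self):
        tr = translate_v_region("TGTNNNGCC")
        assert tr.aa == "CXA"
        assert tr.untranslatable == [1]

    def test_frames(self):
        assert translate_v_region("ATGTGCC", frame=1).aa == "CA"

    def test_against_codon_table_oracle(self):
        rng = random.Random(21)
        codons = [c for c, aa in _CODE.items() if aa != "*"]
        seq = "".join(rng.choice(codons) for _ in range(100))
        tr = translate_v_region(seq)
        expected = "".join(_CODE[seq[i : i + 3]] for i in range(0, 300, 3))
        assert tr.aa == expected


class TestNumbering:
    def test_kappa_template_637(self):
        """Kappa-type grid: 26 FR1 residues, FR3 gaps at 73/81/82, a
        [6.3.7] domain fills 6 of 12 CDR1 columns and 3 of 10 CDR2."""
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7)
        dom = number_v_domain(aa, t)
        assert cdr_lengths(dom) == (6, 3, 7)
        assert format_cdr_lengths(cdr_lengths(dom)) == "[6.3.7]"
        assert len(dom.region_labels("FR1")) == 26
        for gap_pos in (73, 81, 82):
            assert dom.positions[str(gap_pos)] == "."
        cdr1 = [dom.positions[l] for l in dom.region_labels("CDR1")]
        assert sum(r != "." for r in cdr1) == 6 and len(cdr1) == 12

    def test_lambda_template_fr1_gap_at_10(self):
        t = TEMPLATES["IGLV"]
        aa = _make_domain_aa(t, 9, 3, 9)
        dom = number_v_domain(aa, t)
        assert dom.positions["10"] == "."
        fr1_residues = [dom.positions[l] for l in dom.region_labels("FR1")]
        assert sum(r != "." for r in fr1_residues) == 25

    def test_fr2_always_17_columns(self):
        for t in TEMPLATES.values():
            aa = _make_domain_aa(t, 8, 7, 4)
            dom = number_v_domain(aa, t)
            assert len(dom.region_labels("FR2")) == 17

    def test_fr1_insertion_gets_lettered_label(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7)
        # one extra FR1 residue after position 15
        k = t.fr_positions("FR1").index(15) + 1
        aa_ins = aa[:k] + "Q" + aa[k:]
        dom = number_v_domain(aa_ins, t, insertions=["15A"])
        assert dom.positions["15A"] == "Q"
        assert cdr_lengths(dom) == (6, 3, 7)

    def test_middle_out_gap_placement(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7)
        dom = number_v_domain(aa, t)
        # CDR1 of 6 in window 27-38: residues at 27-29 and 36-38, gaps between
        for p in (27, 28, 29, 36, 37, 38):
            assert dom.positions[str(p)] != "."
        for p in range(30, 36):
            assert dom.positions[str(p)] == "."

    def test_too_short_sequence_is_numbering_error(self):
        with pytest.raises(NumberingError):
            number_v_domain("CASW", TEMPLATES["IGKV"])

    @given(
        c1=st.integers(5, 12),
        c2=st.integers(3, 10),
        c3=st.integers(2, 13),
        template=st.sampled_from(sorted(TEMPLATES)),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_roundtrip_and_planted_lengths(self, c1, c2, c3, template, seed):
        """Stripping gaps returns the input sequence exactly and the CDR
        triplet equals the planted lengths, across the germline ranges."""
        t = TEMPLATES[template]
        aa = _make_domain_aa(t, c1, c2, c3, rng=random.Random(seed))
        dom = number_v_domain(aa, t)
        assert dom.sequence == aa
        assert cdr_lengths(dom) == (c1, c2, c3)

    def test_explicit_cdr_override(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7, w41="R")  # replaced W41: anchors fail
        with pytest.raises(NumberingError):
            number_v_domain(aa, t)
        dom = number_v_domain(aa, t, cdr_lengths_override=(6, 3, 7))
        assert dom.residue(41) == "R"


class TestConservedResidues:
    def test_all_pass(self):
        t = TEMPLATES["IGKV"]
        dom = number_v_domain(_make_domain_aa(t, 6, 3, 7), t)
        report = conserved_residues(dom)
        assert report.all_pass
        assert report.c23 == ("C", True)
        assert report.h89[0] in HYDROPHOBIC

    def test_arginine_at_104_fails(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7, res104="R")
        dom = number_v_domain(aa, t, cdr_lengths_override=(6, 3, 7))
        report = conserved_residues(dom)
        assert report.c104 == ("R", False)
        assert not report.all_pass

    def test_phenylalanine_at_23_fails(self):
        t = TEMPLATES["IGKV"]
        dom = number_v_domain(_make_domain_aa(t, 6, 3, 7, res23="F"), t)
        assert conserved_residues(dom).c23 == ("F", False)

    def test_missing_position_is_fail(self):
        t = TEMPLATES["IGKV"]
        dom = number_v_domain(_make_domain_aa(t, 6, 3, 7), t)
        dom.positions["104"] = "."  # truncated display
        report = conserved_residues(dom)
        assert report.c104 == ("missing", False)


class TestProteinDisplay:
    def test_single_domain_row_and_width(self):
        t = TEMPLATES["IGKV"]
        dom = number_v_domain(_make_domain_aa(t, 6, 3, 7), t)
        text = protein_display({"IGKV1-1*01": dom})
        lines = text.splitlines()
        assert len(lines) == 2
        assert len(lines[1].split("  ", 1)[1]) == len(dom.positions)

    def test_insertion_adds_column_with_gap_in_other_row(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7)
        k = t.fr_positions("FR1").index(15) + 1
        dom_plain = number_v_domain(aa, t)
        dom_ins = number_v_domain(aa[:k] + "Q" + aa[k:], t, insertions=["15A"])
        text = protein_display([("plain", dom_plain), ("ins", dom_ins)])
        cols = sorted(set(dom_plain.positions) | set(dom_ins.positions),
                      key=lambda l: (int("".join(ch for ch in l if ch.isdigit())), l))
        idx = cols.index("15A")
        rows = [line[len("plain") + 2 :] for line in text.splitlines()[1:]]
        assert rows[0][idx] == "."
        assert rows[1][idx] == "Q"

    def test_stop_rendered_as_star(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7)
        aa = aa[:40] + "*" + aa[41:]  # in-frame stop inside the domain
        dom = number_v_domain(aa, t)
        text = protein_display({"p*01": dom})
        assert "*" in text.splitlines()[1]

    def test_column_order_numeric_then_letter(self):
        t = TEMPLATES["IGKV"]
        aa = _make_domain_aa(t, 6, 3, 7)
        k = t.fr_positions("FR1").index(15) + 1
        dom = number_v_domain(aa[:k] + "Q" + aa[k:], t, insertions=["15A"])
        labels = list(dom.positions)
        assert labels.index("15") < labels.index("15A") < labels.index("16")
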