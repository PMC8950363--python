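"""Identity, subgroup clustering, nomenclature and functionality rules."""

import random

import pytest

from igloci.gene_classify import (
    FunctionalityCall,
    assign_gene_names,
    classify_functionality,
    cluster_subgroups,
    gene_functionality_label,
    match_allele,
    percent_identity,
)
from igloci.locus_model import Allele


def _mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_three_of_four(self):
        assert percent_identity("AAAA", "AAAT") == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACGT")

    def test_symmetric(self):
        rng = random.Random(3)
        a = "".join(rng.choice("ACGT") for _ in range(40))
        b = _mutate(a, range(0, 40, 5), rng)
        assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    def test_constructed_substitutions_and_deletion(self):
        """60-nt pair with 10 planted substitutions and one 3-nt deletion:
        the optimal global alignment is the planted one (heavy gap costs),
        so identity = (60 - 10 - 3) / 60 by construction."""
        rng = random.Random(11)
        a = "".join(rng.choice("ACGT") for _ in range(60))
        sub_positions = rng.sample([i for i in range(60) if not 30 <= i < 33], 10)
        b = _mutate(a, sub_positions, rng)
        b = b[:30] + b[33:]  # 3-nt deletion
        assert percent_identity(a, b) == pytest.approx(47 / 60)

    def test_internal_gap_columns_count_against_identity(self):
        # a clean 4-nt internal deletion: both flanks stay matched through
        # the gap, so identity is 56 matches over 60 columns
        rng = random.Random(29)
        a = "".join(rng.choice("ACGT") for _ in range(60))
        b = a[:30] + a[34:]
        assert percent_identity(a, b) == pytest.approx(56 / 60)

    def test_case_insensitive(self):
        assert percent_identity("acgt", "ACGT") == 1.0


class TestClustering:
    def test_identical_sequences_one_subgroup(self):
        seqs = {f"g{i}": "ACGTACGTACGTACGTACGT" for i in range(5)}
        assert cluster_subgroups(seqs) == [frozenset(seqs)]

    def test_two_families(self):
        """Within-family identity >= 0.9, cross-family <= 0.5 (independent
        pairwise identity matrix confirms) -> exactly two subgroups."""
        rng = random.Random(5)
        base1 = "".join(rng.choice("ACGT") for _ in range(60))
        base2 = "".join(rng.choice("ACGT") for _ in range(60))
        seqs = {
            "a1": base1,
            "a2": _mutate(base1, rng.sample(range(60), 4), rng),
            "b1": base2,
            "b2": _mutate(base2, rng.sample(range(60), 4), rng),
        }
        for x in ("a1", "a2"):
            for y in ("b1", "b2"):
                assert percent_identity(seqs[x], seqs[y]) <= 0.5
        part = cluster_subgroups(seqs)
        assert sorted(part, key=min) == [frozenset({"a1", "a2"}), frozenset({"b1", "b2"})]

    def test_single_linkage_chain_closure(self):
        """A-B and B-C above threshold, A-C below: single linkage keeps the
        chain together as one subgroup."""
        rng = random.Random(9)
        a = "".join(rng.choice("ACGT") for _ in range(20))
        b = _mutate(a, [0, 1, 2, 3], rng)      # A-B identity 0.80
        c = _mutate(b, [4, 5, 6, 7], rng)      # B-C identity 0.80, A-C 0.60
        assert percent_identity(a, b) == pytest.approx(0.80)
        assert percent_identity(b, c) == pytest.approx(0.80)
        assert percent_identity(a, c) < 0.75
        assert cluster_subgroups({"A": a, "B": b, "C": c}) == [frozenset("ABC")]

    def test_threshold_is_strict(self):
        # exactly 75% identity does not join a subgroup
        assert cluster_subgroups({"x": "AAAA", "y": "AAAT"}) == [
            frozenset({"x"}), frozenset({"y"})
        ]

    def test_threshold_extremes(self):
        seqs = {"a": "AAAA", "b": "TTTT", "c": "AAAA"}
        assert cluster_subgroups(seqs, threshold=-0.1) == [frozenset("abc")]
        at_one = cluster_subgroups(seqs, threshold=0.999999)
        assert frozenset({"a", "c"}) in at_one  # exact duplicates still join
        assert frozenset({"b"}) in at_one

    def test_order_invariance(self):
        rng = random.Random(2)
        base = "".join(rng.choice("ACGT") for _ in range(40))
        seqs = [(f"g{i}", _mutate(base, rng.sample(range(40), 2), rng)) for i in range(6)]
        assert cluster_subgroups(dict(seqs)) == cluster_subgroups(dict(reversed(seqs)))


class TestNaming:
    def test_v_numbering_runs_3prime_to_5prime(self):
        part = [frozenset({"gA", "gB", "gC"})]
        positions = {"gA": 100, "gB": 500, "gC": 900}
        names = assign_gene_names(part, positions, "IGK", "V")
        # most 3' (largest position) gets the smallest hyphen number
        assert names == {"gC": "IGKV1-1", "gB": "IGKV1-2", "gA": "IGKV1-3"}

    def test_d_numbering_runs_5prime_to_3prime(self):
        part = [frozenset({"d1", "d2"})]
        names = assign_gene_names(part, {"d1": 10, "d2": 90}, "IGH", "D")
        assert names == {"d1": "IGHD1-1", "d2": "IGHD1-2"}

    def test_duplicated_gene_gets_terminal_d(self):
        part = [frozenset({"g1", "g1b", "g2"})]
        positions = {"g1": 300, "g1b": 400, "g2": 700}
        names = assign_gene_names(
            part, positions, "IGH", "V", duplication_groups={"g1": "dup", "g1b": "dup"}
        )
        assert names["g2"] == "IGHV1-1"
        assert names["g1b"] == "IGHV1-2"
        assert names["g1"] == "IGHV1-2D"

    def test_unlocalized_get_provisional_s_names(self):
        part = [frozenset({"g1", "u1", "u2"})]
        names = assign_gene_names(part, {"g1": 10}, "IGL", "V",
                                  unlocalized_order=["u1", "u2"])
        assert names["u1"] == "IGLV1S1"
        assert names["u2"] == "IGLV1S2"

    def test_c_genes_named_by_isotype_with_ordinal(self):
        names = assign_gene_names([], {"c1": 10, "c2": 50, "c3": 90}, "IGH", "C",
                                  isotypes={"c1": "M", "c2": "G", "c3": "G"})
        assert names == {"c1": "IGHM", "c2": "IGHG1", "c3": "IGHG2"}


class TestAlleleMatching:
    @pytest.fixture
    def directory(self):
        return {"IGKV1-5": [Allele("IGKV1-5", 1, "ATGCATGCAT")]}

    def test_exact_match_is_literature(self, directory):
        name, prov, is_new = match_allele("IGKV1-5", "atgcatgcat", directory)
        assert (name, prov, is_new) == ("IGKV1-5*01", "literature", False)

    def test_one_substitution_gets_next_number(self, directory):
        name, prov, is_new = match_allele("IGKV1-5", "ATGCATGCAA", directory)
        assert (name, prov, is_new) == ("IGKV1-5*02", "reference", True)

    def test_unseen_gene_gets_01(self, directory):
        name, prov, is_new = match_allele("IGKV1-6", "ACGT", directory)
        assert (name, prov, is_new) == ("IGKV1-6*01", "reference", True)

    def test_idempotent(self, directory):
        for _ in range(2):
            name, prov, _ = match_allele("IGKV1-5", "ATGCATGCAT", directory)
            assert (name, prov) == ("IGKV1-5*01", "literature")


class TestFunctionality:
    def test_stop_codon_is_pseudogene(self):
        call = classify_functionality("x*01", stop_codons=[12])
        assert call.call == "P"
        assert ("STOP_CODON", 12) in call.reasons

    def test_missing_init_codon_is_pseudogene(self):
        call = classify_functionality("x*01", has_init_codon=False)
        assert call.call == "P"
        assert "NO_INIT_CODON" in call.defect_codes

    def test_nonconserved_pivotal_residue_is_orf(self):
        call = classify_functionality("x*01", conserved_ok=False)
        assert (call.call, call.defect_codes) == ("ORF", ["NONCONSERVED_AA"])

    def test_noncanonical_rs_is_orf(self):
        call = classify_functionality("x*01", rs_canonical=False)
        assert (call.call, call.defect_codes) == ("ORF", ["RS_DEFECT"])

    def test_clean_allele_is_functional(self):
        assert classify_functionality("x*01").call == "F"

    def test_p_dominates_orf_defects(self):
        """Severity is monotone: adding a pseudogene-level defect to any
        allele yields P regardless of ORF-level defects."""
        call = classify_functionality("x*01", stop_codons=[3], rs_canonical=False,
                                      conserved_ok=False)
        assert call.call == "P"

    def test_orf_defect_downgrades_functional(self):
        assert classify_functionality("x*01", splice_ok=False).call == "ORF"

    def test_unresolved_frame_is_error_not_silent_p(self):
        with pytest.raises(ValueError):
            classify_functionality("x*01", frame_resolved=False)

    def test_none_checks_are_not_defects(self):
        call = classify_functionality("d*01", has_init_codon=None, splice_ok=None,
                                      rs_canonical=None, promoter_ok=None,
                                      conserved_ok=None)
        assert call.call == "F"


class TestGeneLabel:
    @pytest.mark.parametrize(
        "calls,label",
        [
            (["F", "F"], "F"),
            (["P"], "P"),
            (["F", "P"], "FP"),
            (["F", "ORF"], "FO"),
            (["ORF", "P"], "OP"),
            (["F", "ORF", "P"], "FOP"),
        ],
    )
    def test_labels(self, calls, label):
        assert gene_functionality_label(calls) == label

    def test_accepts_call_objects(self):
        calls = [FunctionalityCall("a*01", "F"), FunctionalityCall("a*02", "P")]
        assert gene_functionality_label(calls) == "FP"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_functionality_label([])
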