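"""Domain types and coordinate arithmetic for IG loci.

An immunoglobulin (IG) locus is a chromosome-extracted stretch of genomic
sequence containing ordered V, D, J and C gene units.  The locus is always
handled in its own 5'->3' orientation: when the locus lies on the reverse
strand of the chromosome (orientation REV) the extracted sequence is the
reverse complement of the chromosomal plus strand, and all internal
coordinates are 1-based inclusive positions on that flipped sequence.

This module provides:

* :class:`LocusSequence`, :class:`GeneModel` and :class:`Allele` containers;
* strand flipping, chromosome<->locus coordinate mapping, locus span in kb,
  and assembly-gap (N-run) detection;
* FASTA reading of loci and reference directories, and GFF3 round-tripping
  of gene models using the IMGT feature-label vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FWD",
    "REV",
    "CORE_LABELS",
    "LocusSequence",
    "GeneModel",
    "Allele",
    "flip_to_locus_orientation",
    "reverse_complement",
    "chrom_to_locus_position",
    "locus_to_chrom_position",
    "locus_span_kb",
    "detect_gaps",
    "read_locus_fasta",
    "read_reference_directory",
    "write_gene_models_gff3",
    "read_gene_models_gff3",
]

FWD = "FWD"
REV = "REV"

#: The single "core" label carried by each gene type; the core nucleotide
#: sequence defines allele identity.
CORE_LABELS = {"V": "V-REGION", "D": "D-REGION", "J": "J-REGION", "C": "C-REGION"}

#: Feature labels a GeneModel may carry (IMGT label vocabulary subset).
KNOWN_LABELS = frozenset(
    {
        "L-PART1",
        "V-INTRON",
        "L-PART2",
        "V-REGION",
        "D-REGION",
        "J-REGION",
        "C-REGION",
        "INIT-CODON",
        "DONOR-SPLICE",
        "ACCEPTOR-SPLICE",
        "V-RS",
        "5'D-RS",
        "3'D-RS",
        "J-RS",
    }
)

_NUC_RE = re.compile(r"[^ACGTNacgtn]")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet, case-preserving."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_nucleotides(sequence: str) -> None:
    m = _NUC_RE.search(sequence)
    if m is not None:
        raise ValueError(
            f"non-nucleotide character {sequence[m.start()]!r} at position {m.start() + 1}"
        )


def flip_to_locus_orientation(sequence: str, orientation: str) -> str:
    """Place a chromosome-strand sequence into 5'->3' locus orientation.

    FWD loci are returned unchanged; REV loci are reverse complemented
    (N maps to N).  Raises ``ValueError`` naming the offending position for
    any character outside {A,C,G,T,N} (case-insensitive).
    """
    _validate_nucleotides(sequence)
    if orientation == FWD:
        return sequence
    if orientation == REV:
        return reverse_complement(sequence)
    raise ValueError(f"orientation must be {FWD!r} or {REV!r}, got {orientation!r}")


@dataclass
class LocusSequence:
    """A chromosome-extracted IG locus in 5'->3' locus orientation.

    ``chrom_start``/``chrom_end`` are 1-based inclusive chromosome positions;
    ``sequence`` is the locus-oriented nucleotide sequence (reverse
    complemented relative to the chromosome when ``orientation == REV``);
    ``gaps`` are maximal N-runs in locus coordinates.
    """

    locus_id: str
    chromosome: str
    chrom_start: int
    chrom_end: int
    orientation: str
    sequence: str
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chrom_end < self.chrom_start:
            raise ValueError(
                f"chrom_end ({self.chrom_end}) < chrom_start ({self.chrom_start})"
            )
        if self.orientation not in (FWD, REV):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.sequence:
            _validate_nucleotides(self.sequence)
            if not self.gaps:
                self.gaps = detect_gaps(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span_kb(self) -> int:
        return locus_span_kb(self.chrom_start, self.chrom_end)

    def subsequence(self, start: int, end: int, inverted: bool = False) -> str:
        """1-based inclusive slice in locus coordinates; reverse complemented
        when the requesting feature is inverted within the locus."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval ({start}, {end}) outside locus of length {len(self.sequence)}")
        sub = self.sequence[start - 1 : end]
        return reverse_complement(sub) if inverted else sub


def chrom_to_locus_position(p: int, locus: LocusSequence) -> int:
    """Map a 1-based chromosome position into 1-based locus coordinates."""
    if not (locus.chrom_start <= p <= locus.chrom_end):
        raise ValueError(
            f"position {p} outside locus [{locus.chrom_start}, {locus.chrom_end}]"
        )
    if locus.orientation == FWD:
        return p - locus.chrom_start + 1
    return locus.chrom_end - p + 1


def locus_to_chrom_position(q: int, locus: LocusSequence) -> int:
    """Inverse of :func:`chrom_to_locus_position`."""
    n = locus.chrom_end - locus.chrom_start + 1
    if not (1 <= q <= n):
        raise ValueError(f"locus position {q} outside [1, {n}]")
    if locus.orientation == FWD:
        return locus.chrom_start + q - 1
    return locus.chrom_end - q + 1


def locus_span_kb(chrom_start: int, chrom_end: int) -> int:
    """Locus span in kilobases, rounded half up to the nearest integer kb."""
    if chrom_end < chrom_start:
        raise ValueError(f"chrom_end ({chrom_end}) < chrom_start ({chrom_start})")
    length = chrom_end - chrom_start + 1
    # round half up (not banker's rounding): 1,968,565 bp -> 1969 kb
    return (length * 2 + 1000) // 2000


def detect_gaps(sequence: str) -> list[tuple[int, int]]:
    """Maximal runs of N (assembly gaps) as sorted 1-based inclusive intervals."""
    return [(m.start() + 1, m.end()) for m in re.finditer(r"[Nn]+", sequence)]


@dataclass
class GeneModel:
    """A V, D, J or C gene unit with labeled sub-regions in locus coordinates.

    ``labels`` maps an IMGT label name to a 1-based inclusive interval nested
    within ``interval``.  ``strand_in_locus`` is "forward" for genes read in
    the locus 5'->3' direction and "inverted" for genes transcribed from the
    opposite strand; label sequences of inverted genes are reverse
    complemented on extraction, never at parse time.
    """

    gene_name: str
    gene_type: str
    locus_id: str
    interval: tuple[int, int]
    strand_in_locus: str = "forward"
    labels: dict[str, tuple[int, int]] = field(default_factory=dict)
    localized: bool = True

    def __post_init__(self) -> None:
        if self.gene_type not in CORE_LABELS:
            raise ValueError(f"gene_type must be one of V/D/J/C, got {self.gene_type!r}")
        if self.strand_in_locus not in ("forward", "inverted"):
            raise ValueError(f"bad strand_in_locus {self.strand_in_locus!r}")
        core = CORE_LABELS[self.gene_type]
        if self.labels and core not in self.labels:
            raise ValueError(f"{self.gene_name}: missing core label {core}")
        lo, hi = self.interval
        for name, (s, e) in self.labels.items():
            if not (lo <= s <= e <= hi):
                raise ValueError(
                    f"{self.gene_name}: label {name} interval ({s},{e}) not nested in {self.interval}"
                )

    @property
    def core_label(self) -> str:
        return CORE_LABELS[self.gene_type]

    def label_sequence(self, label: str, locus: LocusSequence) -> str:
        """Extract a label's sequence in the gene's reading orientation."""
        s, e = self.labels[label]
        return locus.subsequence(s, e, inverted=self.strand_in_locus == "inverted")

    def core_sequence(self, locus: LocusSequence) -> str:
        return self.label_sequence(self.core_label, locus)


#: Defect codes attached to alleles.
P_DEFECTS = frozenset({"STOP_CODON", "FRAMESHIFT", "NO_INIT_CODON", "TRUNCATED"})
ORF_DEFECTS = frozenset({"SPLICE_DEFECT", "RS_DEFECT", "NONCONSERVED_AA", "PROMOTER_DEFECT"})


@dataclass
class Allele:
    """A reference-directory entry: one polymorphic variant of a gene."""

    gene_name: str
    allele_number: int
    core_sequence: str
    functionality: str = "F"
    provenance: str = "reference"
    defects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.allele_number < 1:
            raise ValueError("allele_number must be >= 1")
        if self.functionality == "P" and not (set(self.defects) & P_DEFECTS):
            raise ValueError(f"{self.label}: P allele without a pseudogene-level defect")
        if self.functionality == "ORF":
            if set(self.defects) & P_DEFECTS:
                raise ValueError(f"{self.label}: ORF allele carries a pseudogene-level defect")
            if not (set(self.defects) & ORF_DEFECTS):
                raise ValueError(f"{self.label}: ORF allele without an ORF-level defect")

    @property
    def label(self) -> str:
        return f"{self.gene_name}*{self.allele_number:02d}"


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_locus_fasta(path: str | Path, locus_id: str = "", chromosome: str = "",
                     chrom_start: int = 1, chrom_end: int | None = None,
                     orientation: str = FWD) -> LocusSequence:
    """Read the first record of a FASTA file as a LocusSequence.

    Header metadata of the form ``id|chromosome|start..end|orientation`` is
    honored when present; explicit arguments override it.
    """
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq)
    fields = record.id.split("|")
    if len(fields) == 4 and ".." in fields[2]:
        hid, chrom, span, orient = fields
        s, e = span.split("..")
        locus_id = locus_id or hid
        chromosome = chromosome or chrom
        chrom_start, chrom_end = int(s), int(e)
        orientation = orient
    locus_id = locus_id or record.id
    if chrom_end is None:
        chrom_end = chrom_start + len(seq) - 1
    return LocusSequence(locus_id, chromosome, chrom_start, chrom_end, orientation, seq)


def read_reference_directory(path: str | Path) -> dict[str, list[Allele]]:
    """Read a germline reference directory FASTA.

    Headers follow ``<gene>*<NN>|<functionality>|<locus>``; returns a map of
    gene name to alleles sorted by allele number.  Functionality-consistent
    defect codes are not stored in directory FASTA, so P/ORF entries get a
    generic placeholder defect sufficient to satisfy the Allele invariants.
    """
    directory: dict[str, list[Allele]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        head = record.id.split("|")
        allele_ref = head[0]
        functionality = head[1] if len(head) > 1 else "F"
        gene, _, num = allele_ref.partition("*")
        defects: list[str] = []
        if functionality == "P":
            defects = ["STOP_CODON"]
        elif functionality == "ORF":
            defects = ["RS_DEFECT"]
        directory.setdefault(gene, []).append(
            Allele(gene, int(num or 1), str(record.seq).upper(), functionality, "reference", defects)
        )
    for alleles in directory.values():
        alleles.sort(key=lambda a: a.allele_number)
    return directory


def write_reference_directory(path: str | Path, directory: Mapping[str, Sequence[Allele]],
                              locus_id: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(directory):
            for allele in directory[gene]:
                fh.write(f">{allele.label}|{allele.functionality}|{locus_id}\n")
                fh.write(allele.core_sequence + "\n")


def write_gene_models_gff3(path: str | Path, genes: Iterable[GeneModel],
                           seqid: str) -> None:
    """Write gene models as GFF3: one ``gene`` feature per model plus one
    child feature per label, with the IMGT label in ``Name=``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = "+" if g.strand_in_locus == "forward" else "-"
            s, e = g.interval
            attrs = (
                f"ID={g.gene_name};Name={g.gene_name};gene_type={g.gene_type};"
                f"locus_id={g.locus_id};localized={str(g.localized).lower()}"
            )
            fh.write(f"{seqid}\tigloci\tgene\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")
            for label in sorted(g.labels):
                ls, le = g.labels[label]
                lid = f"{g.gene_name}.{label}"
                fh.write(
                    f"{seqid}\tigloci\tregion\t{ls}\t{le}\t.\t{strand}\t.\t"
                    f"ID={lid};Name={label};Parent={g.gene_name}\n"
                )


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gene_models_gff3`."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        labels: dict[str, tuple[int, int]] = {}
        for child in db.children(feat, featuretype="region"):
            labels[child.attributes["Name"][0]] = (child.start, child.end)
        genes.append(
            GeneModel(
                gene_name=feat.attributes["Name"][0],
                gene_type=feat.attributes["gene_type"][0],
                locus_id=feat.attributes["locus_id"][0],
                interval=(feat.start, feat.end),
                strand_in_locus="forward" if feat.strand == "+" else "inverted",
                labels=labels,
                localized=feat.attributes.get("localized", ["true"])[0] == "true",
            )
        )
    return genes
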