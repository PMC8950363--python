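"""Recombination signal (RS) extraction, consensus and canonicality.

V(D)J recombination is guided by conserved recombination signals flanking
the core regions: a 7-nt heptamer abutting the coding region, a 12- or
23-nt spacer, and a 9-nt nonamer.  V genes carry one RS 3' of the V-REGION,
J genes one RS 5' of the J-REGION (nonamer-spacer-heptamer order on the
locus), and D genes carry both flanks with the heptamers facing the
D-REGION.

This module extracts RS records from gene models, builds per-element
position frequency matrices (PFMs) and plurality consensus strings, counts
mismatches to a consensus, and applies the canonicality rule used for
functionality annotation: a heptamer/nonamer found in more than one
functional gene is canonical; otherwise a heptamer with at most one
mutation, or a nonamer with at most two mutations, relative to the locus
consensus is canonical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .locus_model import GeneModel, LocusSequence

__all__ = [
    "SPACER_CLASSES",
    "RsSignal",
    "extract_rs",
    "consensus",
    "consensus_report",
    "mismatch_count",
    "is_canonical_rs",
    "PositionFrequencyMatrix",
    "pfm_logo_table",
]

#: Default spacer class (12/23 rule) per (locus, gene type, side).
#: D genes use 12-nt spacers on both flanks in the heavy locus.
SPACER_CLASSES: dict[tuple[str, str], int] = {
    ("IGH", "V"): 23,
    ("IGH", "5D"): 12,
    ("IGH", "3D"): 12,
    ("IGH", "J"): 23,
    ("IGK", "V"): 12,
    ("IGK", "J"): 23,
    ("IGL", "V"): 23,
    ("IGL", "J"): 12,
}

HEPTAMER_LEN = 7
NONAMER_LEN = 9


@dataclass(frozen=True)
class RsSignal:
    """One recombination signal: heptamer + spacer + nonamer."""

    side: str                     # V-RS | 5'D-RS | 3'D-RS | J-RS
    heptamer: str
    spacer: str
    nonamer: str
    source_allele: str = ""
    source_functionality: str = "F"

    def __post_init__(self) -> None:
        if len(self.heptamer) != HEPTAMER_LEN:
            raise ValueError(f"heptamer must be 7 nt, got {len(self.heptamer)}")
        if len(self.nonamer) != NONAMER_LEN:
            raise ValueError(f"nonamer must be 9 nt, got {len(self.nonamer)}")

    def element(self, which: str) -> str:
        return {"heptamer": self.heptamer, "nonamer": self.nonamer}[which]


def extract_rs(
    gene: GeneModel,
    locus: LocusSequence,
    spacer_classes: Mapping[tuple[str, str], int] = SPACER_CLASSES,
    source_allele: str = "",
    source_functionality: str = "F",
) -> list[RsSignal]:
    """Extract the gene's RS record(s) from the locus sequence.

    When the gene model carries explicit RS labels (V-RS etc.) those are
    used; otherwise the RS is located contiguous to the core region using
    the configured spacer class.  The heptamer always abuts the core
    region.  D genes yield exactly two signals; C genes none.
    """
    if gene.gene_type == "C":
        return []

    def from_block(block: str, side: str, heptamer_first: bool, spacer_len: int) -> RsSignal:
        expected = HEPTAMER_LEN + spacer_len + NONAMER_LEN
        if len(block) < expected - 1 or len(block) > expected + 1:
            raise ValueError(
                f"{gene.gene_name}: RS block of {len(block)} nt does not fit "
                f"heptamer + {spacer_len}±1 spacer + nonamer"
            )
        if heptamer_first:
            hept = block[:HEPTAMER_LEN]
            nona = block[-NONAMER_LEN:]
            spacer = block[HEPTAMER_LEN:-NONAMER_LEN]
        else:
            nona = block[:NONAMER_LEN]
            hept = block[-HEPTAMER_LEN:]
            spacer = block[NONAMER_LEN:-HEPTAMER_LEN]
        return RsSignal(side, hept.lower(), spacer.lower(), nona.lower(),
                        source_allele or gene.gene_name, source_functionality)

    signals: list[RsSignal] = []
    if gene.gene_type == "V":
        spacer_len = spacer_classes[(gene.locus_id, "V")]
        block = _rs_block(gene, locus, "V-RS", downstream=True,
                          length=HEPTAMER_LEN + spacer_len + NONAMER_LEN)
        signals.append(from_block(block, "V-RS", heptamer_first=True, spacer_len=spacer_len))
    elif gene.gene_type == "J":
        spacer_len = spacer_classes[(gene.locus_id, "J")]
        block = _rs_block(gene, locus, "J-RS", downstream=False,
                          length=HEPTAMER_LEN + spacer_len + NONAMER_LEN)
        signals.append(from_block(block, "J-RS", heptamer_first=False, spacer_len=spacer_len))
    elif gene.gene_type == "D":
        s5 = spacer_classes[(gene.locus_id, "5D")]
        s3 = spacer_classes[(gene.locus_id, "3D")]
        block5 = _rs_block(gene, locus, "5'D-RS", downstream=False,
                           length=HEPTAMER_LEN + s5 + NONAMER_LEN)
        block3 = _rs_block(gene, locus, "3'D-RS", downstream=True,
                           length=HEPTAMER_LEN + s3 + NONAMER_LEN)
        signals.append(from_block(block5, "5'D-RS", heptamer_first=False, spacer_len=s5))
        signals.append(from_block(block3, "3'D-RS", heptamer_first=True, spacer_len=s3))
    return signals


def _rs_block(gene: GeneModel, locus: LocusSequence, label: str,
              downstream: bool, length: int) -> str:
    """The RS nucleotides in the gene's reading orientation.

    Uses the explicit RS label when present, else the flank of the core
    region (``downstream`` is relative to the gene's own 5'->3' direction).
    """
    if label in gene.labels:
        return gene.label_sequence(label, locus)
    inverted = gene.strand_in_locus == "inverted"
    s, e = gene.labels[gene.core_label]
    after_core = downstream != inverted  # XOR: locus-coordinate side
    if after_core:
        start, end = e + 1, e + length
    else:
        start, end = s - length, s - 1
    if start < 1 or end > len(locus.sequence):
        raise ValueError(f"{gene.gene_name}: sequence too short to host the {label}")
    return locus.subsequence(start, end, inverted=inverted)


# ---------------------------------------------------------------------------
# Consensus / PFM
# ---------------------------------------------------------------------------

def _element_strings(signals: Sequence[RsSignal], element: str,
                     functional_only: bool) -> list[str]:
    if element not in ("heptamer", "nonamer"):
        raise ValueError(f"element must be 'heptamer' or 'nonamer', got {element!r}")
    out = [
        s.element(element).lower()
        for s in signals
        if not functional_only or s.source_functionality == "F"
    ]
    return out


def consensus(signals: Sequence[RsSignal], element: str,
              functional_only: bool = True) -> str:
    """Column-wise plurality consensus of an RS element (lowercase).

    Ties at a column resolve to the lexicographically smallest base; use
    :func:`consensus_report` to see which columns were tied.
    """
    seq, _ = consensus_report(signals, element, functional_only)
    return seq


def consensus_report(signals: Sequence[RsSignal], element: str,
                     functional_only: bool = True) -> tuple[str, list[set[str]]]:
    """Consensus plus, per column, the set of bases tied for the maximum."""
    strings = _element_strings(signals, element, functional_only)
    if not strings:
        raise ValueError("no signals left after filtering")
    width = len(strings[0])
    chars: list[str] = []
    ties: list[set[str]] = []
    for col in range(width):
        counts = Counter(s[col] for s in strings)
        top = max(counts.values())
        tied = {b for b, c in counts.items() if c == top}
        chars.append(min(tied))
        ties.append(tied)
    return "".join(chars), ties


def mismatch_count(seq: str, consensus_seq: str) -> int:
    """Hamming distance, case-insensitive; sequences must be equal length."""
    if len(seq) != len(consensus_seq):
        raise ValueError(
            f"length mismatch: {len(seq)} vs {len(consensus_seq)}"
        )
    return sum(a != b for a, b in zip(seq.lower(), consensus_seq.lower()))


def is_canonical_rs(
    element_seq: str,
    locus_consensus: str | Sequence[str],
    functional_occurrence_count: int,
    element: str | None = None,
) -> tuple[bool, str]:
    """Apply the canonicality rule to one heptamer or nonamer.

    The element is canonical if it occurs in more than one functional gene;
    failing that, a heptamer is canonical within one mutation of the locus
    consensus and a nonamer within two.  When the locus consensus itself is
    ambiguous (a list of variants), the minimum mismatch count over the
    variants anchors the tolerance clause.
    """
    if functional_occurrence_count > 1:
        return True, f"found in {functional_occurrence_count} functional genes"
    variants = [locus_consensus] if isinstance(locus_consensus, str) else list(locus_consensus)
    if element is None:
        element = "heptamer" if len(element_seq) == HEPTAMER_LEN else "nonamer"
    allowed = 1 if element == "heptamer" else 2
    mm = min(mismatch_count(element_seq, v) for v in variants)
    if mm <= allowed:
        return True, f"{mm} mutation(s) from consensus (<= {allowed} allowed)"
    return False, (
        f"{mm} mutation(s) from consensus (> {allowed} allowed); "
        "possible rearrangement-evidence exception"
    )


@dataclass
class PositionFrequencyMatrix:
    """Column-wise nucleotide counts over a set of equal-length elements."""

    width: int
    counts: list[dict[str, int]]
    n_sequences: int

    def frequency(self, col: int, base: str) -> float:
        return self.counts[col].get(base.lower(), 0) / self.n_sequences

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table (position x base -> count), consumable by logo renderers."""
        rows = []
        for col, counter in enumerate(self.counts, start=1):
            for base in "acgt":
                rows.append({"position": col, "base": base, "count": counter.get(base, 0)})
        return pd.DataFrame(rows)


def pfm_logo_table(signals: Sequence[RsSignal], element: str,
                   functional_only: bool = False) -> PositionFrequencyMatrix:
    """Build the position frequency matrix of an RS element."""
    strings = _element_strings(signals, element, functional_only)
    if not strings:
        raise ValueError("no signals to tabulate")
    width = len(strings[0])
    if any(len(s) != width for s in strings):
        raise ValueError("non-uniform element lengths")
    counts = [dict(Counter(s[col] for s in strings)) for col in range(width)]
    return PositionFrequencyMatrix(width, counts, len(strings))
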