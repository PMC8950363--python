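"""5'UTR promoter-element scanning and per-subgroup architecture.

V-gene promoters sit in the ~500 bp immediately upstream of the leader's
initiation codon (ATG).  Heavy-chain promoters carry an octamer
(ATGCAAAT), a TATA box between the octamer and the ATG, a heptanucleotide
and a pyrimidine-rich region; light-chain promoters carry the decamer
(nnATTTGCAT — the octamer in inverted complementary form with two extra 5'
nucleotides), a TATA box, CCCT element(s) and a pentadecamer
(TGCAnCTGTGnCCAG) with an inner E-box (CAnnTG).

Offsets are counted in nucleotides upstream of the A of the ATG: an element
whose 5'-most base is the 100th base before the ATG has offset 100, so
increasing offset walks 3' -> 5' away from the gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .locus_model import LocusSequence

__all__ = [
    "ElementDefinition",
    "ELEMENT_PATTERNS",
    "default_element_set",
    "extract_5utr",
    "scan_element",
    "PromoterAnnotation",
    "annotate_promoter",
    "subgroup_architecture",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Core motif patterns (IUPAC; lowercase n = fully degenerate).
ELEMENT_PATTERNS = {
    "OCTAMER": "ATGCAAAT",
    "DECAMER": "NNATTTGCAT",
    "PENTADECAMER": "TGCANCTGTGNCCAG",
    "CCCT": "CCCT",
    "E_BOX": "CANNTG",
}


@dataclass(frozen=True)
class ElementDefinition:
    """One promoter element: a degenerate pattern or a windowed rule.

    ``kind`` selects the matcher: ``pattern`` (IUPAC with ≤ max_mismatches
    at non-N positions), ``tata`` (maximal A/T-only run of length ≥
    ``min_len``) or ``pyrimidine`` (maximal interval of length ≥ ``min_len``
    with C/T fraction ≥ ``min_frac``).  ``search_window`` bounds the offset
    of the element's 5' base relative to the ATG.
    """

    name: str
    pattern: str | None = None
    kind: str = "pattern"
    max_mismatches: int = 0
    search_window: tuple[int, int] = (1, 500)
    min_len: int = 5
    min_frac: float = 0.8

    def with_window(self, lo: int, hi: int) -> "ElementDefinition":
        return replace(self, search_window=(lo, hi))


def default_element_set(locus_id: str, subgroup: str | None = None) -> list[ElementDefinition]:
    """Canonical element set for a locus, ordered 3' -> 5' from the ATG.

    The heavy-chain heptanucleotide has no published consensus; its
    definition ships with ``pattern=None`` and is skipped until the user
    supplies one.  Windows are broad defaults, editable per subgroup.
    In the kappa locus the kappa-V subgroup 5 carries a TCCT variant of the
    CCCT element; pass ``subgroup="IGKV5"`` to scan for it.
    """
    if locus_id == "IGH":
        return [
            ElementDefinition("TATA_BOX", kind="tata", min_len=5, search_window=(10, 110)),
            ElementDefinition("OCTAMER", ELEMENT_PATTERNS["OCTAMER"], search_window=(40, 220)),
            ElementDefinition("HEPTANUCLEOTIDE", None, search_window=(80, 350)),
            ElementDefinition("PYRIMIDINE_RICH", kind="pyrimidine", min_len=10,
                              search_window=(100, 500)),
        ]
    if locus_id in ("IGK", "IGL"):
        ccct = "TCCT" if (locus_id == "IGK" and subgroup == "IGKV5") else "CCCT"
        return [
            ElementDefinition("TATA_BOX", kind="tata", min_len=5, search_window=(10, 110)),
            ElementDefinition("CCCT", ccct, search_window=(30, 160)),
            ElementDefinition("DECAMER", ELEMENT_PATTERNS["DECAMER"], search_window=(50, 260)),
            ElementDefinition("CCCT", ccct, search_window=(70, 320)),
            ElementDefinition("PENTADECAMER", ELEMENT_PATTERNS["PENTADECAMER"],
                              search_window=(80, 420)),
        ]
    raise ValueError(f"unknown locus {locus_id!r}")


def extract_5utr(
    locus: LocusSequence,
    atg_position: int,
    window: int = 500,
    inverted: bool = False,
) -> tuple[str, bool]:
    """Up to ``window`` nt immediately 5' of the initiation codon.

    ``atg_position`` is the locus coordinate of the A of the ATG on the
    gene's strand.  Returns ``(utr, short)`` where the last base of ``utr``
    abuts the A; ``short`` flags a truncated window at the locus edge.
    Raises ``ValueError`` when the stated position does not hold an ATG.
    """
    n = len(locus.sequence)
    if inverted:
        if atg_position - 2 < 1:
            raise ValueError("initiation codon runs off the locus")
        codon = locus.subsequence(atg_position - 2, atg_position, inverted=True)
    else:
        if atg_position + 2 > n:
            raise ValueError("initiation codon runs off the locus")
        codon = locus.subsequence(atg_position, atg_position + 2)
    if codon.upper() != "ATG":
        raise ValueError(f"no ATG at position {atg_position} (found {codon!r})")
    if inverted:
        end = min(n, atg_position + window)
        utr = locus.subsequence(atg_position + 1, end, inverted=True) if end > atg_position else ""
        short = end - atg_position < window
    else:
        start = max(1, atg_position - window)
        utr = locus.subsequence(start, atg_position - 1) if atg_position > 1 else ""
        short = atg_position - start < window
    return utr, short


@dataclass(frozen=True)
class ElementMatch:
    offset: int          # nt upstream of the A of ATG, to the element's 5' base
    sequence: str
    mismatches: int


def _pattern_matches(utr: str, pattern: str, max_mm: int) -> list[ElementMatch]:
    utr_u = utr.upper()
    pat = pattern.upper()
    width = len(pat)
    L = len(utr_u)
    out = []
    for i in range(L - width + 1):
        mm = 0
        for p, base in zip(pat, utr_u[i : i + width]):
            if p == "N":
                continue  # degenerate positions never count as mismatches
            if base not in IUPAC.get(p, p):
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append(ElementMatch(L - i, utr[i : i + width], mm))
    return out


def _tata_matches(utr: str, min_len: int) -> list[ElementMatch]:
    """Maximal A/T-only runs of length >= min_len."""
    import re

    return [
        ElementMatch(len(utr) - m.start(), m.group(0), 0)
        for m in re.finditer(rf"[ATat]{{{min_len},}}", utr)
    ]


def _pyrimidine_matches(utr: str, min_len: int, min_frac: float) -> list[ElementMatch]:
    """Maximal intervals of length >= min_len with C/T fraction >= min_frac,
    built by merging all qualifying sliding windows of length min_len and
    trimmed so each interval starts and ends on a pyrimidine."""
    L = len(utr)
    is_py = [c in "CTct" for c in utr]
    prefix = [0]
    for b in is_py:
        prefix.append(prefix[-1] + b)
    covered = [False] * L
    for i in range(L - min_len + 1):
        if prefix[i + min_len] - prefix[i] >= min_frac * min_len:
            for j in range(i, i + min_len):
                covered[j] = True
    out: list[ElementMatch] = []
    i = 0
    while i < L:
        if covered[i]:
            j = i
            while j < L and covered[j]:
                j += 1
            a, b = i, j
            while a < b and not is_py[a]:
                a += 1
            while b > a and not is_py[b - 1]:
                b -= 1
            if b - a >= min_len:
                out.append(ElementMatch(L - a, utr[a:b], 0))
            i = j
        else:
            i += 1
    return out


def scan_element(utr: str, element: ElementDefinition,
                 respect_window: bool = False) -> list[ElementMatch]:
    """All matches of an element in a 5'UTR, sorted by increasing offset.

    With ``respect_window`` the element's configured search window filters
    the matches; otherwise the whole UTR is scanned.
    """
    if element.kind == "pattern":
        if element.pattern is None:
            return []
        matches = _pattern_matches(utr, element.pattern, element.max_mismatches)
    elif element.kind == "tata":
        matches = _tata_matches(utr, element.min_len)
    elif element.kind == "pyrimidine":
        matches = _pyrimidine_matches(utr, element.min_len, element.min_frac)
    else:
        raise ValueError(f"unknown element kind {element.kind!r}")
    if respect_window:
        lo, hi = element.search_window
        matches = [m for m in matches if lo <= m.offset <= hi]
    return sorted(matches, key=lambda m: m.offset)


@dataclass
class PromoterAnnotation:
    allele_ref: str
    elements: list[tuple[str, ElementMatch]]   # sorted 3'->5' (increasing offset)
    missing: list[str] = field(default_factory=list)

    @property
    def architecture_key(self) -> str:
        return "-".join(name for name, _ in self.elements)

    def offset_of(self, name: str, occurrence: int = 1) -> int | None:
        seen = 0
        for n, m in self.elements:
            if n == name:
                seen += 1
                if seen == occurrence:
                    return m.offset
        return None

    def inter_element_distances(self) -> list[tuple[str, str, int]]:
        out = []
        for (n1, m1), (n2, m2) in zip(self.elements, self.elements[1:]):
            out.append((n1, n2, m2.offset - m1.offset))
        return out


def annotate_promoter(
    utr: str,
    element_set: Sequence[ElementDefinition],
    allele_ref: str = "",
) -> PromoterAnnotation:
    """Greedy 3'->5' assignment of the locus's canonical element order.

    For each element (in 3'->5' order) the match inside its search window
    and 5' of the previously placed element that lies closest to the window
    center is assigned; ties go 3'-ward (closest to the ATG).  Missing
    elements are recorded as data, not errors.
    """
    found: list[tuple[str, ElementMatch]] = []
    missing: list[str] = []
    prev_offset = 0
    for element in element_set:
        lo, hi = element.search_window
        center = (lo + hi) / 2
        candidates = [
            m for m in scan_element(utr, element)
            if lo <= m.offset <= hi and m.offset > prev_offset
        ]
        if not candidates:
            missing.append(element.name)
            continue
        best = min(candidates, key=lambda m: (abs(m.offset - center), m.offset))
        found.append((element.name, best))
        prev_offset = best.offset
    return PromoterAnnotation(allele_ref, found, missing)


def _instance_keys(annotation: PromoterAnnotation) -> list[tuple[str, ElementMatch]]:
    """Element names disambiguated by occurrence (CCCT, CCCT.2, ...)."""
    counts: Counter[str] = Counter()
    out = []
    for name, m in annotation.elements:
        counts[name] += 1
        key = name if counts[name] == 1 else f"{name}.{counts[name]}"
        out.append((key, m))
    return out


def subgroup_architecture(
    annotations_by_subgroup: Mapping[str, Sequence[PromoterAnnotation]],
) -> dict[str, dict[str, dict]]:
    """Per-subgroup promoter summary.

    For every element instance: presence fraction across the subgroup's
    annotations, mean/min/max offset, and a per-column plurality consensus
    of the matched sequences (computed over equal-length matches).
    """
    summary: dict[str, dict[str, dict]] = {}
    for subgroup, annotations in annotations_by_subgroup.items():
        if not annotations:
            raise ValueError(f"subgroup {subgroup}: no annotations")
        per_element: dict[str, list[ElementMatch]] = {}
        for ann in annotations:
            for key, m in _instance_keys(ann):
                per_element.setdefault(key, []).append(m)
        n = len(annotations)
        elements = {}
        for key, matches in per_element.items():
            offsets = [m.offset for m in matches]
            seqs = [m.sequence.upper() for m in matches]
            widths = {len(s) for s in seqs}
            if len(widths) == 1:
                width = widths.pop()
                cons = "".join(
                    min(
                        (b for b in set(col) if col.count(b) == max(col.count(x) for x in set(col)))
                    )
                    for col in ("".join(s[i] for s in seqs) for i in range(width))
                )
            else:
                cons = None
            elements[key] = {
                "presence": len(matches) / n,
                "mean_offset": sum(offsets) / len(offsets),
                "min_offset": min(offsets),
                "max_offset": max(offsets),
                "consensus": cons,
            }
        summary[subgroup] = elements
    return summary
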