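"""IMGT unique numbering for translated V-REGIONs.

The IMGT unique numbering places every V-domain residue on a fixed grid:
FR1 positions 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104 and CDR3
from 105 (germline window capped at 117 here).  Four pivotal residues sit at
fixed positions: cysteine 23, tryptophan 41, a hydrophobic residue at 89 and
cysteine 104.  When a CDR is shorter than its window, gaps are inserted
middle-out (residues pack from both ends of the window, IMGT style); when a
framework has fewer residues than columns, the missing columns are fixed
per-template gaps (e.g. lambda-type V domains have 25 FR1 residues with a
gap at position 10, kappa-type have 26 FR1 residues and FR3 gaps at
73/81/82).  Extra framework residues get lettered insertion labels (15A,
20A, 50A/50B ...) supplied as per-allele configuration.

Numbering here is template-based: the per-locus/subgroup gap template is
configuration, and region boundaries are delimited from the sequence via
the structural C23 slot, a W41 search and a constrained last-cysteine C104
search (an explicit ``cdr_lengths`` override skips the anchor search).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "REGIONS",
    "HYDROPHOBIC",
    "NumberingTemplate",
    "TEMPLATES",
    "TranslationResult",
    "translate_v_region",
    "NumberedVDomain",
    "NumberingError",
    "number_v_domain",
    "cdr_lengths",
    "format_cdr_lengths",
    "ConservedResidueReport",
    "conserved_residues",
    "protein_display",
]

#: Region windows on the numbering grid (1-based inclusive position spans).
REGIONS: dict[str, tuple[int, int]] = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
}

#: Classical hydrophobic amino-acid class used for the position-89 check.
HYDROPHOBIC = frozenset("AVLIMFWCY")

_LABEL_RE = re.compile(r"^(\d+)([A-Z]*)$")


def parse_label(label: str) -> tuple[int, str]:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"bad position label {label!r}")
    return int(m.group(1)), m.group(2)


def label_sort_key(label: str) -> tuple[int, str]:
    return parse_label(label)


def region_of(label: str) -> str:
    num, _ = parse_label(label)
    for region, (lo, hi) in REGIONS.items():
        if lo <= num <= hi:
            return region
    return "CDR3"  # lettered overflow beyond 117


@dataclass(frozen=True)
class NumberingTemplate:
    """Per-locus/subgroup gap template for the numbering grid.

    ``fr*_gaps`` are grid positions left empty in every member of the
    subgroup.  Templates are configuration, editable by the user; the
    shipped defaults encode the kappa- and lambda-type patterns.
    """

    name: str
    fr1_gaps: frozenset[int] = frozenset()
    fr2_gaps: frozenset[int] = frozenset()
    fr3_gaps: frozenset[int] = frozenset()

    def fr_positions(self, region: str) -> list[int]:
        lo, hi = REGIONS[region]
        gaps = {"FR1": self.fr1_gaps, "FR2": self.fr2_gaps, "FR3": self.fr3_gaps}[region]
        return [p for p in range(lo, hi + 1) if p not in gaps]


TEMPLATES: dict[str, NumberingTemplate] = {
    # kappa-type: 26 FR1 residues, FR3 gaps at 73/81/82
    "IGKV": NumberingTemplate("IGKV", fr3_gaps=frozenset({73, 81, 82})),
    # lambda-type: 25 FR1 residues with a gap at position 10
    "IGLV": NumberingTemplate("IGLV", fr1_gaps=frozenset({10})),
    # heavy-type default: FR1 gap at 10, FR3 gap at 73 (editable configuration)
    "IGHV": NumberingTemplate("IGHV", fr1_gaps=frozenset({10}), fr3_gaps=frozenset({73})),
}


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

@dataclass
class TranslationResult:
    aa: str
    stop_codons: list[int]           # 0-based codon indices of in-frame stops
    untranslatable: list[int]        # codon indices containing ambiguous bases
    trailing_nt: int                 # 0-2 nucleotides left over at the 3' end

    @property
    def has_stop(self) -> bool:
        return bool(self.stop_codons)


def translate_v_region(core: str, frame: int = 0) -> TranslationResult:
    """Standard-genetic-code translation of a core region.

    ``frame`` is the codon phase of the region start (0, 1 or 2).  In-frame
    stops are flagged by codon index, ambiguous codons translate to ``X``
    and are flagged, and a 3' length not divisible by 3 is reported, not an
    error.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = core.upper()[frame:]
    trailing = len(seq) % 3
    if trailing:
        seq = seq[: len(seq) - trailing]
    aa_chars: list[str] = []
    stops: list[int] = []
    untranslatable: list[int] = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if set(codon) - set("ACGT"):
            aa_chars.append("X")
            untranslatable.append(i // 3)
            continue
        aa = str(Seq(codon).translate())
        if aa == "*":
            stops.append(i // 3)
        aa_chars.append(aa)
    return TranslationResult("".join(aa_chars), stops, untranslatable, trailing)


# ---------------------------------------------------------------------------
# Numbering
# ---------------------------------------------------------------------------

class NumberingError(ValueError):
    """Raised when a sequence cannot be placed on the numbering grid."""


@dataclass
class NumberedVDomain:
    """An amino-acid V-REGION placed on the IMGT grid.

    ``positions`` maps position labels (``"23"``, ``"15A"``) to a residue or
    ``"."`` for a gap, in grid order.
    """

    positions: dict[str, str]
    template: NumberingTemplate

    def residue(self, label: str | int) -> str | None:
        r = self.positions.get(str(label), ".")
        return None if r == "." else r

    @property
    def sequence(self) -> str:
        return "".join(r for r in self.positions.values() if r != ".")

    def region_labels(self, region: str) -> list[str]:
        return [lab for lab in self.positions if region_of(lab) == region]

    def region_residues(self, region: str) -> str:
        return "".join(
            self.positions[lab] for lab in self.region_labels(region)
            if self.positions[lab] != "."
        )


def _pack_cdr(window: tuple[int, int], residues: str,
              out: dict[str, str]) -> None:
    """Middle-out packing: residues fill the window from both ends, gaps in
    the middle; overflow gets lettered insertions at the window midpoint."""
    lo, hi = window
    width = hi - lo + 1
    n = len(residues)
    if n <= width:
        front = (n + 1) // 2
        back = n - front
        idx = 0
        for p in range(lo, lo + front):
            out[str(p)] = residues[idx]; idx += 1
        for p in range(lo + front, hi - back + 1):
            out[str(p)] = "."
        for p in range(hi - back + 1, hi + 1):
            out[str(p)] = residues[idx]; idx += 1
        return
    # overflow: window full, extras become lettered insertions at midpoint
    extra = n - width
    front = (width + 1) // 2
    anchor = lo + front - 1
    idx = 0
    for p in range(lo, anchor + 1):
        out[str(p)] = residues[idx]; idx += 1
    for k in range(extra):
        out[f"{anchor}{chr(ord('A') + k)}"] = residues[idx]; idx += 1
    for p in range(anchor + 1, hi + 1):
        out[str(p)] = residues[idx]; idx += 1


def _parse_insertions(insertions: Iterable[str]) -> dict[int, list[str]]:
    by_anchor: dict[int, list[str]] = {}
    for label in insertions:
        num, letters = parse_label(label)
        if not letters:
            raise ValueError(f"insertion label {label!r} needs a letter suffix")
        by_anchor.setdefault(num, []).append(label)
    for labels in by_anchor.values():
        labels.sort(key=label_sort_key)
    return by_anchor


def _fr_labels(template: NumberingTemplate, region: str,
               ins: Mapping[int, list[str]]) -> list[str]:
    """Residue-bearing labels of a framework region, insertions included."""
    labels: list[str] = []
    for p in template.fr_positions(region):
        labels.append(str(p))
        labels.extend(ins.get(p, ()))
    return labels


def number_v_domain(
    aa: str,
    template: NumberingTemplate,
    insertions: Iterable[str] = (),
    cdr_lengths_override: tuple[int, int, int] | None = None,
) -> NumberedVDomain:
    """Place a translated V-REGION on the IMGT grid.

    Region boundaries are delimited by anchors: the structural C23 slot is
    fixed by the template, W41 is the first tryptophan at a feasible CDR1
    offset, and C104 is the last cysteine compatible with the CDR2/FR3/CDR3
    window constraints.  ``insertions`` lists lettered labels for extra
    framework residues (e.g. ``["15A"]``); ``cdr_lengths_override`` fixes
    (c1, c2, c3) directly and skips the anchor search.
    """
    aa = aa.upper()
    ins = _parse_insertions(insertions)
    fr1 = _fr_labels(template, "FR1", ins)
    fr2 = _fr_labels(template, "FR2", ins)
    fr3 = _fr_labels(template, "FR3", ins)
    n_fr1, n_fr2, n_fr3 = len(fr1), len(fr2), len(fr3)

    if len(aa) < n_fr1 + n_fr2 + n_fr3:
        raise NumberingError(
            f"sequence of {len(aa)} aa shorter than the minimal template "
            f"({n_fr1} FR1 + {n_fr2} FR2 + {n_fr3} FR3 residues)"
        )

    if cdr_lengths_override is not None:
        c1, c2, c3 = cdr_lengths_override
        if n_fr1 + c1 + n_fr2 + c2 + n_fr3 + c3 != len(aa):
            raise NumberingError(
                f"cdr lengths {cdr_lengths_override} inconsistent with sequence length {len(aa)}"
            )
    else:
        # W41 anchor: first W at a feasible CDR1 offset
        w_pre = sum(1 for lab in fr2 if parse_label(lab)[0] < 41)
        c1 = None
        for k in range(0, 13):
            idx = n_fr1 + k + w_pre
            if idx < len(aa) and aa[idx] == "W":
                c1 = k
                break
        if c1 is None:
            raise NumberingError("missing anchor: no tryptophan found for position 41")
        remaining = aa[n_fr1 + c1 + n_fr2 :]
        # C104 anchor: last cysteine compatible with the windows
        choice = None
        for j, res in enumerate(remaining):
            if res != "C":
                continue
            cand_c2 = j - (n_fr3 - 1)
            cand_c3 = len(remaining) - 1 - j
            if 0 <= cand_c2 <= 10 and 0 <= cand_c3 <= 13:
                choice = (cand_c2, cand_c3)
        if choice is None:
            raise NumberingError("missing anchor: no cysteine found for position 104")
        c2, c3 = choice

    positions: dict[str, str] = {}
    cursor = 0

    def consume_fr(region: str) -> None:
        nonlocal cursor
        lo, hi = REGIONS[region]
        gaps = {"FR1": template.fr1_gaps, "FR2": template.fr2_gaps,
                "FR3": template.fr3_gaps}[region]
        for p in range(lo, hi + 1):
            if p in gaps:
                positions[str(p)] = "."
            else:
                positions[str(p)] = aa[cursor]; cursor += 1
                for lab in ins.get(p, ()):
                    positions[lab] = aa[cursor]; cursor += 1

    consume_fr("FR1")
    _pack_cdr(REGIONS["CDR1"], aa[cursor : cursor + c1], positions); cursor += c1
    consume_fr("FR2")
    _pack_cdr(REGIONS["CDR2"], aa[cursor : cursor + c2], positions); cursor += c2
    consume_fr("FR3")
    _pack_cdr(REGIONS["CDR3"], aa[cursor:], positions)

    ordered = dict(sorted(positions.items(), key=lambda kv: label_sort_key(kv[0])))
    return NumberedVDomain(ordered, template)


def cdr_lengths(domain: NumberedVDomain) -> tuple[int, int, int]:
    """Non-gap residue counts per CDR window: the [c1.c2.c3] triplet."""
    return (
        len(domain.region_residues("CDR1")),
        len(domain.region_residues("CDR2")),
        len(domain.region_residues("CDR3")),
    )


def format_cdr_lengths(triplet: Sequence[int]) -> str:
    return "[" + ".".join(str(c) for c in triplet) + "]"


@dataclass
class ConservedResidueReport:
    c23: tuple[str, bool]
    w41: tuple[str, bool]
    h89: tuple[str, bool]
    c104: tuple[str, bool]

    @property
    def all_pass(self) -> bool:
        return all(ok for _, ok in (self.c23, self.w41, self.h89, self.c104))


def conserved_residues(domain: NumberedVDomain) -> ConservedResidueReport:
    """Check the four pivotal residues (C23, W41, hydrophobic 89, C104).

    A position that is absent or gapped (truncated domain) is reported as
    "missing" and treated as a failure.
    """

    def check(pos: int, accept) -> tuple[str, bool]:
        res = domain.residue(pos)
        if res is None:
            return ("missing", False)
        return (res, accept(res))

    return ConservedResidueReport(
        c23=check(23, lambda r: r == "C"),
        w41=check(41, lambda r: r == "W"),
        h89=check(89, lambda r: r in HYDROPHOBIC),
        c104=check(104, lambda r: r == "C"),
    )


def protein_display(
    domains: Mapping[str, NumberedVDomain] | Sequence[tuple[str, NumberedVDomain]],
) -> str:
    """Fixed-width protein display: one row per allele, columns = union of
    position labels, gaps rendered ``.``, in-frame stops rendered ``*``."""
    items = list(domains.items()) if isinstance(domains, Mapping) else list(domains)
    if not items:
        return ""
    columns: set[str] = set()
    for _, dom in items:
        columns.update(dom.positions)
    ordered = sorted(columns, key=label_sort_key)
    name_width = max(len(name) for name, _ in items)
    boundaries = {str(lo) for lo, _ in (REGIONS[r] for r in ("CDR1", "FR2", "CDR2", "FR3", "CDR3"))}
    header_marks = "".join("|" if lab in boundaries else " " for lab in ordered)
    lines = [" " * (name_width + 2) + header_marks]
    for name, dom in items:
        row = "".join(dom.positions.get(lab, ".") for lab in ordered)
        lines.append(f"{name:<{name_width}}  {row}")
    return "\n".join(lines)
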