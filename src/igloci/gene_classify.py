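"""Subgroup clustering, gene/allele nomenclature and functionality calling.

V genes are partitioned into *subgroups*: two genes belong to the same
subgroup when their V-REGION nucleotide sequences share more than 75%
identity, taken as an equivalence by single-linkage closure.  Pseudogenes
matching no subgroup are assigned to *clans* against user-supplied exemplar
sets.  Gene names follow the standard IG nomenclature
(``<locus><type><subgroup>-<position>``, duplicated genes suffixed ``D``,
unlocalized genes with provisional ``S`` numbers) and alleles are matched
against a reference directory by exact core identity (100% = same allele).

Functionality calling implements the three-level F / ORF / P rule:

* **P** (pseudogene): in-frame stop codon, frameshift, missing initiation
  codon, or truncated core region;
* **ORF**: intact open reading frame but a non-canonical recombination
  signal, splice-site defect, promoter defect, or a replaced pivotal amino
  acid (C23, W41, hydrophobic 89, C104);
* **F** (functional): none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align

from .locus_model import Allele

__all__ = [
    "percent_identity",
    "identity_matrix",
    "cluster_subgroups",
    "SubgroupAssignment",
    "assign_clans",
    "assign_gene_names",
    "match_allele",
    "FunctionalityCall",
    "classify_functionality",
    "gene_functionality_label",
]

#: Identity threshold for subgroup membership ("greater than 75%", strict).
SUBGROUP_IDENTITY_THRESHOLD = 0.75


def _make_aligner() -> Align.PairwiseAligner:
    # Global alignment on the identity scale: match 1, mismatch 0, affine
    # gaps (open 10 / extend 0.5) and free terminal gaps so identity is
    # computed over the aligned core only.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_internal_gap_score = -10.0
    aligner.extend_internal_gap_score = -0.5
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(a: str, b: str) -> float:
    """Nucleotide identity of two sequences from a global alignment.

    Identity = matches / alignment columns, excluding terminal-gap columns
    (internal gap columns count against identity).  Symmetric, in [0, 1].
    """
    if not a or not b:
        raise ValueError("percent_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    counts = _ALIGNER.align(a, b)[0].counts()
    internal_gaps = counts.internal_insertions + counts.internal_deletions
    denom = counts.identities + counts.mismatches + internal_gaps
    return counts.identities / denom if denom else 0.0


def identity_matrix(sequences: Sequence[str]) -> list[list[float]]:
    """Symmetric pairwise identity matrix (diagonal 1.0)."""
    n = len(sequences)
    mat = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(sequences[i], sequences[j])
            mat[i][j] = mat[j][i] = pid
    return mat


@dataclass
class SubgroupAssignment:
    gene_name: str
    subgroup_label: str
    evidence: list[tuple[str, float]] = field(default_factory=list)


def cluster_subgroups(
    v_regions: Mapping[str, str] | Iterable[tuple[str, str]],
    threshold: float = SUBGROUP_IDENTITY_THRESHOLD,
) -> list[frozenset[str]]:
    """Single-linkage partition of V genes by strict > threshold identity.

    Returns the partition as a list of frozensets, ordered by the smallest
    member name (so the result is independent of input order).
    """
    items = list(v_regions.items()) if isinstance(v_regions, Mapping) else list(v_regions)
    if not items:
        raise ValueError("cluster_subgroups requires at least one sequence")
    items.sort(key=lambda kv: kv[0])
    names = [k for k, _ in items]
    seqs = [v for _, v in items]
    graph = nx.Graph()
    graph.add_nodes_from(names)
    mat = identity_matrix(seqs)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if mat[i][j] > threshold:
                graph.add_edge(names[i], names[j], identity=mat[i][j])
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min(c))
    return components


def assign_clans(
    unassigned: Mapping[str, str],
    clan_exemplars: Mapping[str, Mapping[str, str]],
    threshold: float = SUBGROUP_IDENTITY_THRESHOLD,
) -> dict[str, str | None]:
    """Assign subgroup-less pseudogenes to clans via exemplar identity.

    ``clan_exemplars`` maps clan label -> {exemplar name -> sequence}; a gene
    joins the clan of its best-matching exemplar above the threshold, else
    maps to ``None``.  Clans hold pseudogenes only; the caller enforces that.
    """
    out: dict[str, str | None] = {}
    for gene, seq in unassigned.items():
        best: tuple[float, str] | None = None
        for clan, exemplars in clan_exemplars.items():
            for _, ex_seq in exemplars.items():
                pid = percent_identity(seq, ex_seq)
                if pid > threshold and (best is None or pid > best[0]):
                    best = (pid, clan)
        out[gene] = best[1] if best else None
    return out


def assign_gene_names(
    partition: Sequence[frozenset[str]],
    gene_positions: Mapping[str, int],
    locus_id: str,
    gene_type: str = "V",
    duplication_groups: Mapping[str, str] | None = None,
    unlocalized_order: Sequence[str] = (),
    subgroup_numbers: Mapping[frozenset[str], int] | None = None,
    isotypes: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Assign IMGT-style names from the subgroup partition and locus layout.

    V genes are numbered by position from 3' to 5' (the most 3' localized V
    gene gets hyphen number 1); D and J genes are numbered 5' to 3'.  Genes
    sharing a ``duplication_groups`` value share one position number, the
    second occurrence taking a terminal ``D``.  Unlocalized genes get
    provisional ``<locus><type><subgroup>S<n>`` names in the order given.
    C genes are named by isotype with an ordinal when an isotype recurs.

    Subgroup numbers default to the rank of each subgroup's most 3'
    localized member (subgroup holding the most 3' gene is 1); pass
    ``subgroup_numbers`` to pin them (e.g. to match a published homology).
    """
    duplication_groups = dict(duplication_groups or {})

    if gene_type == "C":
        isotypes = isotypes or {}
        by_isotype: dict[str, list[str]] = {}
        for gene in sorted(gene_positions, key=gene_positions.__getitem__):
            by_isotype.setdefault(isotypes.get(gene, "C"), []).append(gene)
        names: dict[str, str] = {}
        for isotype, members in by_isotype.items():
            if len(members) == 1:
                names[members[0]] = f"{locus_id}{isotype}"
            else:
                for i, gene in enumerate(members, start=1):  # 5'->3'
                    names[gene] = f"{locus_id}{isotype}{i}"
        return names

    localized = [g for s in partition for g in s if g in gene_positions]
    if gene_type == "V":
        ordered = sorted(localized, key=lambda g: -gene_positions[g])  # 3'->5'
    else:
        ordered = sorted(localized, key=lambda g: gene_positions[g])  # 5'->3'

    subgroup_of = {g: s for s in partition for g in s}
    if subgroup_numbers is None:
        # rank subgroups by their most extreme member in numbering order
        first_seen: dict[frozenset[str], int] = {}
        for idx, gene in enumerate(ordered):
            first_seen.setdefault(subgroup_of[gene], idx)
        for gene in unlocalized_order:  # subgroups with no localized member rank last
            if gene in subgroup_of:
                first_seen.setdefault(subgroup_of[gene], len(ordered) + len(first_seen))
        subgroup_numbers = {
            s: i + 1 for i, (s, _) in enumerate(sorted(first_seen.items(), key=lambda kv: kv[1]))
        }

    names = {}
    position = 0
    seen_group_position: dict[str, int] = {}
    for gene in ordered:
        group = duplication_groups.get(gene)
        if group is not None and group in seen_group_position:
            pos, suffix = seen_group_position[group], "D"
        else:
            position += 1
            pos, suffix = position, ""
            if group is not None:
                seen_group_position[group] = position
        sub = subgroup_numbers[subgroup_of[gene]]
        name = f"{locus_id}{gene_type}{sub}-{pos}{suffix}"
        if name in names.values():
            raise ValueError(f"gene name collision: {name}")
        names[gene] = name

    counters: dict[int, int] = {}
    for gene in unlocalized_order:
        sub = subgroup_numbers[subgroup_of[gene]]
        counters[sub] = counters.get(sub, 0) + 1
        names[gene] = f"{locus_id}{gene_type}{sub}S{counters[sub]}"
    return names


def match_allele(
    gene_name: str,
    core_sequence: str,
    directory: Mapping[str, Sequence[Allele]],
) -> tuple[str, str, bool]:
    """Match a core sequence against the reference directory.

    100% core identity to a stored allele returns that allele's name with
    provenance "literature"; anything else gets the next free allele number
    with provenance "reference" (``*01`` for an unseen gene).
    """
    core = core_sequence.upper()
    alleles = list(directory.get(gene_name, ()))
    hits = [a for a in alleles if a.core_sequence.upper() == core]
    if len(hits) > 1 and len({a.gene_name for a in hits}) > 1:
        raise ValueError(f"core sequence matches alleles of different genes: {hits}")
    if hits:
        return hits[0].label, "literature", False
    next_number = max((a.allele_number for a in alleles), default=0) + 1
    return f"{gene_name}*{next_number:02d}", "reference", True


@dataclass
class FunctionalityCall:
    allele_ref: str
    call: str
    reasons: list[tuple[str, int | None]] = field(default_factory=list)

    @property
    def defect_codes(self) -> list[str]:
        return [code for code, _ in self.reasons]


def classify_functionality(
    allele_ref: str,
    *,
    stop_codons: Sequence[int] = (),
    frameshift: bool = False,
    has_init_codon: bool | None = True,
    truncated: bool = False,
    splice_ok: bool | None = True,
    rs_canonical: bool | None = True,
    promoter_ok: bool | None = True,
    conserved_ok: bool | None = True,
    frame_resolved: bool = True,
) -> FunctionalityCall:
    """Apply the F / ORF / P rule to one allele given its check results.

    ``stop_codons`` lists in-frame stop codon indices in the core region;
    boolean checks may be ``None`` when not applicable (D/J/C genes have no
    initiation codon requirement).  Pseudogene-level defects dominate
    ORF-level ones; the reasons list records every triggered defect.
    """
    if not frame_resolved:
        raise ValueError(f"{allele_ref}: translation frame could not be resolved")
    reasons: list[tuple[str, int | None]] = []
    for idx in stop_codons:
        reasons.append(("STOP_CODON", idx))
    if frameshift:
        reasons.append(("FRAMESHIFT", None))
    if has_init_codon is False:
        reasons.append(("NO_INIT_CODON", None))
    if truncated:
        reasons.append(("TRUNCATED", None))
    if reasons:
        return FunctionalityCall(allele_ref, "P", reasons)
    if splice_ok is False:
        reasons.append(("SPLICE_DEFECT", None))
    if rs_canonical is False:
        reasons.append(("RS_DEFECT", None))
    if promoter_ok is False:
        reasons.append(("PROMOTER_DEFECT", None))
    if conserved_ok is False:
        reasons.append(("NONCONSERVED_AA", None))
    if reasons:
        return FunctionalityCall(allele_ref, "ORF", reasons)
    return FunctionalityCall(allele_ref, "F", [])


def gene_functionality_label(calls: Sequence[FunctionalityCall | str]) -> str:
    """Gene-level label from its allele calls: F/ORF/P, or a mixture label
    (FO = functional-or-ORF, FP = functional-or-pseudogene, OP, FOP)."""
    if not calls:
        raise ValueError("gene_functionality_label requires at least one allele call")
    letters = {c if isinstance(c, str) else c.call for c in calls}
    if not letters <= {"F", "ORF", "P"}:
        raise ValueError(f"unknown functionality in {letters}")
    if len(letters) == 1:
        return letters.pop()
    if letters == {"F", "ORF"}:
        return "FO"
    if letters == {"F", "P"}:
        return "FP"
    if letters == {"ORF", "P"}:
        return "OP"
    return "FOP"
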