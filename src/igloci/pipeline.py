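"""End-to-end locus annotation: classify -> number -> RS -> promoters.

Given a locus sequence and structural gene models (feature intervals are
input — gene finding is curation work outside this package), the pipeline:

1. extracts V/D/J/C core sequences and clusters V (and D/J) genes into
   subgroups/sets by >75% nucleotide identity;
2. assigns IMGT-style gene names (V numbered 3'->5', D/J 5'->3',
   duplicated genes suffixed D, unlocalized genes given provisional S
   names) and matches cores against a reference directory for allele
   naming;
3. translates and numbers V-REGIONs on the IMGT grid, checking the
   pivotal residues;
4. extracts recombination signals, derives locus consensus strings from
   functional genes, and applies the canonical-RS rule;
5. scans 5'UTR windows for the locus's promoter elements;
6. calls functionality per allele (F / ORF / P) and per gene.

Functionality and RS canonicality are mutually dependent (the consensus is
taken over *functional* genes), so classification runs in two passes:
coding-level defects first give a provisional functional set; the RS
consensus and occurrence counts computed from that set then settle the
ORF-level RS clause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import gene_classify as gc
from . import imgt_numbering as num
from . import promoter_scan as ps
from . import rs_analysis as rs
from .locus_model import Allele, GeneModel, LocusSequence

__all__ = ["GeneAnnotation", "LocusAnnotation", "annotate_locus"]


@dataclass
class GeneAnnotation:
    gene_id: str
    kind: str
    name: str = ""
    subgroup_label: str = ""
    position: int = 0
    localized: bool = True
    core: str = ""
    allele_name: str = ""
    provenance: str = ""
    is_new_allele: bool = True
    call: gc.FunctionalityCall | None = None
    gene_label: str = ""
    domain: num.NumberedVDomain | None = None
    cdr: tuple[int, int, int] | None = None
    in_frame: bool = True
    conserved: num.ConservedResidueReport | None = None
    signals: list[rs.RsSignal] = field(default_factory=list)
    rs_canonical: bool | None = None
    promoter: ps.PromoterAnnotation | None = None


@dataclass
class LocusAnnotation:
    locus: LocusSequence
    genes: dict[str, GeneAnnotation]
    v_partition: list[frozenset[str]]
    consensus: dict[tuple[str, str], str]          # (side, element) -> consensus
    names: dict[str, str]

    def table(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "kind": g.kind,
                    "name": g.name,
                    "subgroup": g.subgroup_label,
                    "localized": g.localized,
                    "allele": g.allele_name,
                    "provenance": g.provenance,
                    "functionality": g.call.call if g.call else "",
                    "gene_label": g.gene_label,
                    "reasons": ";".join(g.call.defect_codes) if g.call else "",
                    "cdr_lengths": num.format_cdr_lengths(g.cdr) if g.cdr else "",
                    "in_frame": g.in_frame,
                    "rs_canonical": g.rs_canonical,
                }
            )
        return pd.DataFrame(rows)


def _check_splice(gene: GeneModel, locus: LocusSequence) -> bool | None:
    if "V-INTRON" not in gene.labels:
        return None
    intron = gene.label_sequence("V-INTRON", locus).upper()
    return intron.startswith("GT") and intron.endswith("AG")


def _check_init(gene: GeneModel, locus: LocusSequence) -> bool | None:
    if "INIT-CODON" not in gene.labels:
        return None if gene.gene_type != "V" else False
    return gene.label_sequence("INIT-CODON", locus).upper() == "ATG"


def _detect_duplications(
    ordered_genes: Sequence[str],
    cores: Mapping[str, str],
    component_of: Mapping[str, frozenset[str]],
) -> dict[str, str]:
    """Adjacent same-subgroup genes with identical cores form one
    duplication group (named after the first member)."""
    groups: dict[str, str] = {}
    for a, b in zip(ordered_genes, ordered_genes[1:]):
        if component_of.get(a) is component_of.get(b) and cores[a].upper() == cores[b].upper():
            group = groups.get(a, a)
            groups[a] = group
            groups[b] = group
    return groups


def annotate_locus(
    locus: LocusSequence,
    genes: Sequence[GeneModel],
    directory: Mapping[str, Sequence[Allele]] | None = None,
    unlocalized_cores: Mapping[str, str] | None = None,
    element_sets: Mapping[str, Sequence[ps.ElementDefinition]] | None = None,
    isotypes: Mapping[str, str] | None = None,
    identity_threshold: float = gc.SUBGROUP_IDENTITY_THRESHOLD,
    utr_window: int = 500,
) -> LocusAnnotation:
    """Run the full annotation pipeline on one locus."""
    directory = directory or {}
    unlocalized_cores = dict(unlocalized_cores or {})
    template = num.TEMPLATES.get(f"{locus.locus_id}V", num.TEMPLATES["IGHV"])
    by_type: dict[str, list[GeneModel]] = {"V": [], "D": [], "J": [], "C": []}
    for g in genes:
        by_type[g.gene_type].append(g)

    ann: dict[str, GeneAnnotation] = {}
    cores: dict[str, str] = {}
    for g in genes:
        core = g.core_sequence(locus)
        cores[g.gene_name] = core
        ann[g.gene_name] = GeneAnnotation(
            g.gene_name, g.gene_type, position=g.interval[0], core=core
        )
    for gid, core in unlocalized_cores.items():
        cores[gid] = core
        ann[gid] = GeneAnnotation(gid, "V", position=0, localized=False, core=core)

    # ---- subgroups and names -------------------------------------------
    names: dict[str, str] = {}
    v_ids = [g.gene_name for g in by_type["V"]] + list(unlocalized_cores)
    v_partition: list[frozenset[str]] = []
    component_of: dict[str, frozenset[str]] = {}
    if v_ids:
        v_partition = gc.cluster_subgroups({i: cores[i] for i in v_ids}, identity_threshold)
        component_of = {gid: comp for comp in v_partition for gid in comp}
        positions = {g.gene_name: g.interval[0] for g in by_type["V"]}
        ordered = sorted(positions, key=positions.__getitem__)
        dup_groups = _detect_duplications(ordered, cores, component_of)
        names.update(
            gc.assign_gene_names(
                v_partition, positions, locus.locus_id, "V",
                duplication_groups=dup_groups,
                unlocalized_order=list(unlocalized_cores),
            )
        )
        subgroup_of_name = {}
        for gid, name in names.items():
            subgroup_of_name[gid] = name.split("-")[0].split("S")[0]
        for gid in v_ids:
            ann[gid].subgroup_label = subgroup_of_name.get(gid, "")
    for kind in ("D", "J"):
        if not by_type[kind]:
            continue
        ids = [g.gene_name for g in by_type[kind]]
        part = gc.cluster_subgroups({i: cores[i] for i in ids}, identity_threshold)
        positions = {g.gene_name: g.interval[0] for g in by_type[kind]}
        kind_names = gc.assign_gene_names(part, positions, locus.locus_id, kind)
        names.update(kind_names)
        for gid in ids:
            ann[gid].subgroup_label = kind_names[gid].split("-")[0]
    if by_type["C"]:
        positions = {g.gene_name: g.interval[0] for g in by_type["C"]}
        c_names = gc.assign_gene_names([], positions, locus.locus_id, "C",
                                       isotypes=isotypes)
        names.update(c_names)
        for gid in positions:
            ann[gid].subgroup_label = c_names[gid]
    for gid, name in names.items():
        ann[gid].name = name

    # ---- allele matching ------------------------------------------------
    for gid in ann:
        allele_name, provenance, is_new = gc.match_allele(gid, cores[gid], directory)
        a = ann[gid]
        a.allele_name, a.provenance, a.is_new_allele = allele_name, provenance, is_new

    # ---- translation, numbering, conserved residues ---------------------
    min_core_aa = sum(len(template.fr_positions(r)) for r in ("FR1", "FR2", "FR3"))
    gene_models = {g.gene_name: g for g in genes}
    subgroup_cdr: dict[frozenset[str], tuple[int, int, int]] = {}
    translations: dict[str, num.TranslationResult] = {}
    for gid in v_ids:
        tr = num.translate_v_region(cores[gid])
        translations[gid] = tr
        a = ann[gid]
        a.in_frame = tr.trailing_nt == 0
        comp = component_of.get(gid)
        domain = None
        try:
            domain = num.number_v_domain(tr.aa, template)
        except num.NumberingError:
            if comp in subgroup_cdr:
                try:
                    domain = num.number_v_domain(
                        tr.aa, template, cdr_lengths_override=subgroup_cdr[comp]
                    )
                except num.NumberingError:
                    domain = None
        if domain is not None:
            a.domain = domain
            a.cdr = num.cdr_lengths(domain)
            a.conserved = num.conserved_residues(domain)
            if comp is not None and comp not in subgroup_cdr and not tr.has_stop:
                subgroup_cdr[comp] = a.cdr
    # second chance for anchor failures once their subgroup template is known
    for gid in v_ids:
        a = ann[gid]
        if a.domain is None and component_of.get(gid) in subgroup_cdr:
            try:
                a.domain = num.number_v_domain(
                    translations[gid].aa, template,
                    cdr_lengths_override=subgroup_cdr[component_of[gid]],
                )
                a.cdr = num.cdr_lengths(a.domain)
                a.conserved = num.conserved_residues(a.domain)
            except num.NumberingError:
                pass

    # ---- RS extraction ---------------------------------------------------
    for kind in ("V", "D", "J"):
        for g in by_type[kind]:
            ann[g.gene_name].signals = rs.extract_rs(g, locus, source_allele=g.gene_name)

    # ---- provisional functionality (coding-level defects only) ----------
    def coding_call(gid: str, rs_canonical=None, promoter_ok=None) -> gc.FunctionalityCall:
        a = ann[gid]
        kind = a.kind
        g = gene_models.get(gid)
        if kind == "V":
            tr = translations[gid]
            return gc.classify_functionality(
                f"{gid}*01",
                stop_codons=tr.stop_codons,
                frameshift=tr.trailing_nt != 0,
                has_init_codon=_check_init(g, locus) if g else None,
                truncated=len(cores[gid]) // 3 < min_core_aa and tr.trailing_nt == 0,
                splice_ok=_check_splice(g, locus) if g else None,
                rs_canonical=rs_canonical,
                promoter_ok=promoter_ok,
                conserved_ok=a.conserved.all_pass if a.conserved else None,
            )
        tr = num.translate_v_region(cores[gid])
        return gc.classify_functionality(
            f"{gid}*01",
            stop_codons=tr.stop_codons,
            frameshift=tr.trailing_nt != 0 and kind != "D",
            has_init_codon=None,
            splice_ok=None,
            rs_canonical=rs_canonical if kind != "C" else None,
            promoter_ok=None,
            conserved_ok=None,
        )

    provisional: dict[str, str] = {}
    for gid in ann:
        if ann[gid].kind == "D":
            provisional[gid] = "F"  # D-REGIONs are untranslated cores
            continue
        provisional[gid] = coding_call(gid).call

    # ---- RS consensus from provisional-F genes, canonicality ------------
    all_signals: list[rs.RsSignal] = []
    for gid, a in ann.items():
        for s in a.signals:
            all_signals.append(
                rs.RsSignal(s.side, s.heptamer, s.spacer, s.nonamer, gid,
                            provisional.get(gid, "F"))
            )
    consensus: dict[tuple[str, str], str] = {}
    occurrence: dict[tuple[str, str, str], int] = {}
    sides = {s.side for s in all_signals}
    for side in sides:
        side_signals = [s for s in all_signals if s.side == side]
        for element in ("heptamer", "nonamer"):
            try:
                consensus[(side, element)] = rs.consensus(side_signals, element,
                                                          functional_only=True)
            except ValueError:
                continue
            seen: dict[str, set[str]] = {}
            for s in side_signals:
                if s.source_functionality == "F":
                    seen.setdefault(s.element(element), set()).add(s.source_allele)
            for elem_seq, genes_with in seen.items():
                occurrence[(side, element, elem_seq)] = len(genes_with)

    for gid, a in ann.items():
        if not a.signals or a.kind == "C":
            continue
        verdicts = []
        for s in a.signals:
            for element in ("heptamer", "nonamer"):
                key = (s.side, element)
                if key not in consensus:
                    continue
                occ = occurrence.get((s.side, element, s.element(element)), 0)
                canonical, _ = rs.is_canonical_rs(
                    s.element(element), consensus[key], occ, element
                )
                verdicts.append(canonical)
        a.rs_canonical = all(verdicts) if verdicts else None

    # ---- promoters -------------------------------------------------------
    element_sets = element_sets or {}
    for g in by_type["V"]:
        gid = g.gene_name
        if "INIT-CODON" not in g.labels:
            continue
        s, e = g.labels["INIT-CODON"]
        inverted = g.strand_in_locus == "inverted"
        atg = e if inverted else s
        try:
            utr, _short = ps.extract_5utr(locus, atg, utr_window, inverted)
        except ValueError:
            continue
        elements = element_sets.get(
            ann[gid].subgroup_label, ps.default_element_set(locus.locus_id)
        )
        ann[gid].promoter = ps.annotate_promoter(utr, elements, allele_ref=f"{gid}*01")

    required = "OCTAMER" if locus.locus_id == "IGH" else "DECAMER"

    # ---- final functionality --------------------------------------------
    for gid, a in ann.items():
        if a.kind == "D":
            a.call = gc.FunctionalityCall(f"{gid}*01", "F", [])
            if a.rs_canonical is False:
                a.call = gc.FunctionalityCall(f"{gid}*01", "ORF", [("RS_DEFECT", None)])
        else:
            promoter_ok = None
            if a.promoter is not None:
                found = {name for name, _ in a.promoter.elements}
                promoter_ok = required in found and "TATA_BOX" in found
            a.call = coding_call(gid, rs_canonical=a.rs_canonical,
                                 promoter_ok=promoter_ok)
        extra = [
            al.functionality
            for al in directory.get(gid, ())
            if al.core_sequence.upper() != cores[gid].upper()
        ]
        a.gene_label = gc.gene_functionality_label([a.call.call, *extra])

    return LocusAnnotation(locus, ann, v_partition, consensus, names)
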