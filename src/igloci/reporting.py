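"""Gene tables, repertoire summaries, CDR-length distributions and the
fixture consistency check.

The reporting layer aggregates annotations into the standard IG repertoire
table shapes: per-subgroup gene counts split by functionality label with
allele counts in parentheses, per-locus and overall repertoire totals, and
per-subgroup CDR-length distributions (first allele only, out-of-frame
pseudogenes excluded).  Published table fixtures ship with the package and
``consistency_check`` re-verifies every printed total against its printed
addends, flagging (never silently correcting) disagreements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .imgt_numbering import format_cdr_lengths

__all__ = [
    "GeneTable",
    "gene_table",
    "gene_table_from_fixture",
    "repertoire_summary",
    "cdr_length_table",
    "consistency_check",
    "load_fixtures",
]

FUNCTIONALITY_LABELS = ("F", "ORF", "P", "FO", "FP", "OP", "FOP")


def load_fixtures() -> dict[str, pd.DataFrame]:
    """Load the shipped published-table fixtures as DataFrames."""
    out = {}
    for name in ("loci", "gene_tables", "type_totals", "locus_totals",
                 "cdr_lengths", "rs_consensus"):
        with resources.files("igloci.data").joinpath(f"{name}.tsv").open() as fh:
            out[name] = pd.read_csv(fh, sep="\t")
    return out


@dataclass
class GeneTable:
    """Counts of genes (and alleles, in parentheses semantics) per group
    and functionality label, with conservation-checked totals."""

    rows: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def add(self, group: str, label: str, n_genes: int, n_alleles: int) -> None:
        g, a = self.rows.setdefault(group, {}).get(label, (0, 0))
        self.rows[group][label] = (g + n_genes, a + n_alleles)

    def group_total(self, group: str) -> tuple[int, int]:
        cells = self.rows.get(group, {})
        return (sum(g for g, _ in cells.values()), sum(a for _, a in cells.values()))

    def label_total(self, label: str) -> tuple[int, int]:
        g = sum(cells.get(label, (0, 0))[0] for cells in self.rows.values())
        a = sum(cells.get(label, (0, 0))[1] for cells in self.rows.values())
        return (g, a)

    @property
    def total_genes(self) -> int:
        return sum(self.group_total(g)[0] for g in self.rows)

    @property
    def total_alleles(self) -> int:
        return sum(self.group_total(g)[1] for g in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for group, cells in self.rows.items():
            entry = {"group": group}
            parts = []
            for label in FUNCTIONALITY_LABELS:
                if label in cells:
                    g, a = cells[label]
                    entry[label] = f"{g} ({a})"
                    parts.append(f"{g} {label} ({a})")
            g, a = self.group_total(group)
            entry["functionality"] = ", ".join(parts)
            entry["total"] = f"{g} ({a})"
            records.append(entry)
        return pd.DataFrame(records)


def gene_table(
    annotations: Iterable[tuple[str, str, int]] | pd.DataFrame,
    group_col: str = "subgroup",
    label_col: str = "gene_label",
    alleles_col: str = "n_alleles",
) -> GeneTable:
    """Aggregate per-gene annotations (group, functionality label, allele
    count) into a GeneTable; an empty input yields an all-zero table."""
    table = GeneTable()
    if isinstance(annotations, pd.DataFrame):
        records = (
            (r[group_col], r[label_col], int(r[alleles_col]))
            for _, r in annotations.iterrows()
        )
    else:
        records = iter(annotations)
    for group, label, n_alleles in records:
        table.add(group, label, 1, n_alleles)
    return table


def gene_table_from_fixture(fixture: pd.DataFrame, locus: str, gene_type: str) -> GeneTable:
    """Build a GeneTable from the shipped published-table fixture rows."""
    table = GeneTable()
    sel = fixture[(fixture["locus"] == locus) & (fixture["gene_type"] == gene_type)]
    for _, row in sel.iterrows():
        table.add(row["group"], row["label"], int(row["n_genes"]), int(row["n_alleles"]))
    return table


def repertoire_summary(
    tables: Mapping[tuple[str, str], GeneTable],
) -> tuple[dict[str, tuple[int, int]], tuple[int, int]]:
    """Per-locus and overall (genes, alleles) totals across gene types.

    Associative: summing per-locus summaries equals summarizing the
    concatenation of their tables.
    """
    per_locus: dict[str, tuple[int, int]] = {}
    for (locus, _gene_type), table in tables.items():
        g, a = per_locus.get(locus, (0, 0))
        per_locus[locus] = (g + table.total_genes, a + table.total_alleles)
    overall = (
        sum(g for g, _ in per_locus.values()),
        sum(a for _, a in per_locus.values()),
    )
    return per_locus, overall


def cdr_length_table(
    domains: Iterable[tuple[str, tuple[int, int, int], str, bool]],
    first_allele_only: bool = True,
    seen_alleles: set | None = None,
) -> pd.DataFrame:
    """CDR-length distribution rows: (subgroup, [c1.c2.c3]) -> counts split
    F / ORF / in-frame P.  Out-of-frame pseudogenes are excluded, so a
    subgroup whose genes are all out-of-frame P is simply absent.

    ``domains`` yields (subgroup, cdr triplet, functionality, in_frame) per
    first allele (the ``*01`` convention is the caller's responsibility
    when feeding multiple alleles; pass first_allele_only rows only).
    """
    del first_allele_only, seen_alleles  # convention documented above
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for subgroup, triplet, functionality, in_frame in domains:
        if functionality == "P" and not in_frame:
            continue
        if functionality not in ("F", "ORF", "P"):
            continue
        key = (subgroup, format_cdr_lengths(triplet))
        cell = counts.setdefault(key, {"F": 0, "ORF": 0, "in_frame_P": 0})
        cell["F" if functionality == "F" else
             "ORF" if functionality == "ORF" else "in_frame_P"] += 1
    rows = [
        {"subgroup": sg, "lengths": lengths, **cell}
        for (sg, lengths), cell in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["subgroup", "lengths", "F", "ORF", "in_frame_P"])


def consistency_check(fixtures: Mapping[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Verify every printed total against its printed addends.

    Checks, per locus and gene type, the sum of the per-group table rows
    against the printed type totals; per locus, the sum of printed type
    totals against the printed locus totals; and the sum of printed locus
    totals against the printed overall repertoire.  Disagreements are
    listed, never corrected.
    """
    fixtures = fixtures or load_fixtures()
    gene_tables = fixtures["gene_tables"]
    type_totals = fixtures["type_totals"].set_index(["locus", "gene_type"])
    locus_totals = fixtures["locus_totals"].set_index("locus")
    records = []

    def record(check: str, quantity: str, computed: int, printed: int) -> None:
        records.append(
            {
                "check": check,
                "quantity": quantity,
                "computed": computed,
                "printed": printed,
                "agree": computed == printed,
            }
        )

    for (locus, gene_type), printed in type_totals.iterrows():
        table = gene_table_from_fixture(gene_tables, locus, gene_type)
        record(f"{locus} {gene_type} table", "genes", table.total_genes, int(printed["genes"]))
        record(f"{locus} {gene_type} table", "alleles", table.total_alleles, int(printed["alleles"]))
    for locus in ("IGH", "IGL", "IGK"):
        sel = type_totals.loc[locus]
        record(f"{locus} locus total", "genes", int(sel["genes"].sum()),
               int(locus_totals.loc[locus, "genes"]))
        record(f"{locus} locus total", "alleles", int(sel["alleles"].sum()),
               int(locus_totals.loc[locus, "alleles"]))
    per_locus = locus_totals.drop(index="ALL")
    record("overall repertoire", "genes", int(per_locus["genes"].sum()),
           int(locus_totals.loc["ALL", "genes"]))
    record("overall repertoire", "alleles", int(per_locus["alleles"].sum()),
           int(locus_totals.loc["ALL", "alleles"]))
    return pd.DataFrame(records)
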