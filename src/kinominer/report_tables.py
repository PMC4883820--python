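"""Cross-tabulations of the kinome catalog with expression and DE calls.

The summary surfaces are group x condition count tables: the taxonomic
distribution of the catalog, the number of genes per group expressed at
each developmental stage, and the number up-/down-regulated under each
stressor.  Percentages are formatted half-away-from-zero, the convention
that reproduces printed summary figures such as 47.7% -> 48.

Row order is the fixed group order AGC, CAMK, CMGC, CK1, RGC, TK, TKL,
STE, Other, aPK.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression_mining import DEResult
from .io_formats import KINASE_GROUPS, Classification

GROUP_ORDER = KINASE_GROUPS


def percent(numerator: int, denominator: int, decimals: int = 0):
    """``100 * numerator / denominator`` rounded half-away-from-zero.

    Returns a float (an int-valued float when ``decimals == 0``); a zero
    denominator yields the string ``"-"``.
    """
    if denominator == 0:
        return "-"
    value = Decimal(100 * numerator) / Decimal(denominator)
    sign = -1 if value < 0 else 1
    quantum = Decimal(1).scaleb(-decimals)
    rounded = abs(value).quantize(quantum, rounding=ROUND_HALF_UP) * sign
    return float(rounded)


@dataclass
class SummaryTable:
    """A group x condition tabulation with totals and formatted percents."""

    cells: pd.DataFrame                    # int counts, index = GROUP_ORDER
    group_totals: pd.Series                # catalog size per group
    percents: pd.DataFrame | None = None   # same shape as cells, formatted
    column_percents: pd.Series | None = None  # kinome-level percent per column

    def __post_init__(self) -> None:
        self.cells = self.cells.reindex(GROUP_ORDER).fillna(0).astype(int)
        self.group_totals = self.group_totals.reindex(GROUP_ORDER).fillna(0).astype(int)

    @property
    def totals(self) -> pd.Series:
        """Per-column sums over groups."""
        return self.cells.sum(axis=0)

    @property
    def total_genes(self) -> int:
        return int(self.group_totals.sum())

    @property
    def epk_total(self) -> int:
        """Total minus the atypical kinases."""
        return self.total_genes - int(self.group_totals.get("aPK", 0))

    def validate(self) -> None:
        """Assert the structural invariant: totals equal cell sums."""
        assert (self.totals == self.cells.sum(axis=0)).all()
        if self.percents is not None:
            for col in self.cells.columns:
                for g in GROUP_ORDER:
                    expected = percent(int(self.cells.loc[g, col]),
                                       int(self.group_totals[g]))
                    assert self.percents.loc[g, col] == expected

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.copy()
        out.insert(0, "total_genes", self.group_totals)
        out.index.name = "group"
        with open(path, "w", encoding="utf-8") as fh:
            out.to_csv(fh, sep="\t")
            fh.write("Total\t" + str(self.total_genes) + "\t"
                     + "\t".join(str(int(v)) for v in self.totals) + "\n")

    def render_text(self) -> str:
        out = self.cells.copy().astype(object)
        if self.percents is not None:
            for col in out.columns:
                out[col] = [
                    f"{c} ({p}%)" if p != "-" else f"{c} (-)"
                    for c, p in zip(self.cells[col], self.percents[col])
                ]
        out.insert(0, "total", self.group_totals)
        return out.to_string()


def _group_percents(cells: pd.DataFrame,
                    group_totals: pd.Series) -> pd.DataFrame:
    data = {}
    for col in cells.columns:
        data[col] = [
            percent(int(cells.loc[g, col]), int(group_totals[g]))
            for g in GROUP_ORDER
        ]
    return pd.DataFrame(data, index=list(GROUP_ORDER))


# ---------------------------------------------------------------------------
# tabulations
# ---------------------------------------------------------------------------

def group_counts(catalog: Iterable[Classification]) -> SummaryTable:
    """Taxonomic distribution of the catalog: one count per kinase group."""
    counts = pd.Series(0, index=list(GROUP_ORDER), dtype=int)
    for c in catalog:
        if c.group in counts.index:
            counts[c.group] += 1
    cells = pd.DataFrame({"count": counts})
    return SummaryTable(cells=cells, group_totals=counts)


def stage_expression_summary(catalog: Sequence[Classification],
                             expressed: pd.DataFrame,
                             stage_grouping: Mapping[str, str],
                             stage_order: Sequence[str] | None = None,
                             ) -> SummaryTable:
    """Per group and developmental stage, the number of expressed genes.

    ``expressed`` is a boolean gene x sample matrix; a gene counts as
    expressed at a stage when it is expressed in at least one sample mapped
    to that stage by ``stage_grouping``.  Genes absent from the catalog are
    excluded with a warning.  ``column_percents`` carries the kinome-level
    percentage per stage (expressed genes over the whole catalog).
    """
    group_of = {c.protein_id: c.group for c in catalog}
    unknown = [g for g in expressed.index if g not in group_of]
    if unknown:
        warnings.warn(
            f"{len(unknown)} genes in the expression data are absent from "
            f"the catalog and were excluded (e.g. {unknown[:3]})",
            stacklevel=2,
        )
        expressed = expressed.drop(index=unknown)

    if stage_order is None:
        stage_order = list(dict.fromkeys(stage_grouping.values()))
    group_totals = pd.Series(0, index=list(GROUP_ORDER), dtype=int)
    for c in catalog:
        if c.group in group_totals.index:
            group_totals[c.group] += 1

    cells = pd.DataFrame(0, index=list(GROUP_ORDER), columns=list(stage_order))
    for stage in stage_order:
        samples = [s for s, st in stage_grouping.items()
                   if st == stage and s in expressed.columns]
        if not samples:
            continue
        stage_expressed = expressed[samples].any(axis=1)
        for gene, is_expr in stage_expressed.items():
            if is_expr:
                cells.loc[group_of[gene], stage] += 1

    table = SummaryTable(cells=cells, group_totals=group_totals)
    table.percents = _group_percents(table.cells, table.group_totals)
    table.column_percents = pd.Series(
        {stage: percent(int(table.cells[stage].sum()), table.total_genes)
         for stage in stage_order}
    )
    return table


def stressor_de_summary(catalog: Sequence[Classification],
                        de_results: Iterable[DEResult],
                        stressor_grouping: Mapping[tuple[str, str], str],
                        stressor_order: Sequence[str] | None = None,
                        ) -> SummaryTable:
    """Per group and stressor, the number of up- and down-regulated genes.

    A gene is up (down) under a stressor when its direction is up (down) in
    at least one contrast mapped to that stressor; across timepoints or
    tissues one gene may appear on both sides.  Columns come out as a
    two-level (stressor, Up/Down) MultiIndex.
    """
    group_of = {c.protein_id: c.group for c in catalog}
    if stressor_order is None:
        stressor_order = list(dict.fromkeys(stressor_grouping.values()))

    up_sets: dict[str, set[str]] = {s: set() for s in stressor_order}
    down_sets: dict[str, set[str]] = {s: set() for s in stressor_order}
    for res in de_results:
        stressor = stressor_grouping.get(tuple(res.contrast))
        if stressor is None or res.gene_id not in group_of:
            continue
        if res.direction == "up":
            up_sets[stressor].add(res.gene_id)
        elif res.direction == "down":
            down_sets[stressor].add(res.gene_id)

    group_totals = pd.Series(0, index=list(GROUP_ORDER), dtype=int)
    for c in catalog:
        if c.group in group_totals.index:
            group_totals[c.group] += 1

    columns = pd.MultiIndex.from_product([list(stressor_order), ["up", "down"]])
    cells = pd.DataFrame(0, index=list(GROUP_ORDER), columns=columns)
    for stressor in stressor_order:
        for gene in up_sets[stressor]:
            cells.loc[group_of[gene], (stressor, "up")] += 1
        for gene in down_sets[stressor]:
            cells.loc[group_of[gene], (stressor, "down")] += 1

    table = SummaryTable(cells=cells, group_totals=group_totals)
    table.percents = _group_percents(table.cells, table.group_totals)
    return table


def regulated_gene_union(de_results: Iterable[DEResult],
                         stressor_grouping: Mapping[tuple[str, str], str],
                         stressor: str | None = None) -> set[str]:
    """Genes regulated (either direction) under a stressor, or under any."""
    genes: set[str] = set()
    for res in de_results:
        s = stressor_grouping.get(tuple(res.contrast))
        if s is None or (stressor is not None and s != stressor):
            continue
        if res.direction in ("up", "down"):
            genes.add(res.gene_id)
    return genes
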