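"""Cross-condition and cross-sub-genome QTL comparison.

Pleiotropy is defined by coordinate overlap of support intervals from
different conditions on the same contig (connected components of the
overlap graph); sharing between sub-genomes is defined by ortholog gene
content, never coordinates, since homologous regions occupy different
relative positions on the two species' chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .qtlcall import QtlInterval

logger = logging.getLogger(__name__)


@dataclass
class PleiotropyGroup:
    sub_genome: str
    contig: str
    start: int
    end: int
    conditions: tuple[str, ...]
    members: list[QtlInterval]
    shared_genes: list[str]
    span_is_union: bool = False  # True when member intersection was empty

    def to_row(self) -> dict:
        return {
            "sub_genome": self.sub_genome,
            "contig": self.contig,
            "start": self.start,
            "end": self.end,
            "conditions": ";".join(self.conditions),
            "genes": ";".join(self.shared_genes),
            "span_is_union": self.span_is_union,
        }


@dataclass
class SharedQtl:
    condition: str
    interval_a: QtlInterval
    interval_b: QtlInterval
    shared_orthologs: list[tuple[str, str]]

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "sub_genome_a": self.interval_a.sub_genome,
            "region_a": f"{self.interval_a.contig}:"
            f"{self.interval_a.support_start}-{self.interval_a.support_end}",
            "sub_genome_b": self.interval_b.sub_genome,
            "region_b": f"{self.interval_b.contig}:"
            f"{self.interval_b.support_start}-{self.interval_b.support_end}",
            "orthologs": ";".join(f"{a}|{b}" for a, b in self.shared_orthologs),
        }


def _overlap(a: QtlInterval, b: QtlInterval) -> bool:
    return a.support_start <= b.support_end and b.support_start <= a.support_end


def pleiotropic_groups(intervals: list[QtlInterval]) -> list[PleiotropyGroup]:
    """Connected components of the cross-condition overlap graph.

    Within each (sub_genome, contig), support intervals from *different*
    conditions that overlap by >= 1 bp are linked; components spanning
    >= 2 distinct conditions become groups.  The group span is the
    intersection of member intervals when non-empty, else their union
    (flagged).  Shared genes are those annotated on every member.
    """
    groups: list[PleiotropyGroup] = []
    key = lambda iv: (iv.sub_genome, iv.contig)
    by_region: dict[tuple[str, str], list[QtlInterval]] = {}
    for iv in sorted(intervals, key=lambda iv: (iv.sub_genome, iv.contig,
                                                iv.support_start, iv.condition)):
        by_region.setdefault(key(iv), []).append(iv)
    for (sub_genome, contig), ivs in sorted(by_region.items()):
        g = nx.Graph()
        g.add_nodes_from(range(len(ivs)))
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                if ivs[i].condition != ivs[j].condition and _overlap(ivs[i], ivs[j]):
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            members = [ivs[i] for i in sorted(comp)]
            conditions = tuple(sorted({iv.condition for iv in members}))
            if len(conditions) < 2:
                continue
            inter_start = max(iv.support_start for iv in members)
            inter_end = min(iv.support_end for iv in members)
            if inter_start <= inter_end:
                start, end, is_union = inter_start, inter_end, False
            else:
                start = min(iv.support_start for iv in members)
                end = max(iv.support_end for iv in members)
                is_union = True
            gene_sets = [set(iv.genes) for iv in members]
            shared = set.intersection(*gene_sets) if gene_sets else set()
            order = {g: i for i, g in enumerate(members[0].genes)}
            groups.append(
                PleiotropyGroup(
                    sub_genome=sub_genome,
                    contig=contig,
                    start=start,
                    end=end,
                    conditions=conditions,
                    members=members,
                    shared_genes=sorted(shared, key=lambda g: order.get(g, 1 << 30)),
                    span_is_union=is_union,
                )
            )
    return groups


def shared_across_subgenomes(
    intervals_a: list[QtlInterval],
    intervals_b: list[QtlInterval],
    orthologs: pd.DataFrame,
    condition: str,
) -> list[SharedQtl]:
    """Pairs of same-condition intervals (one per sub-genome) whose gene
    sets contain at least one ortholog pair.

    ``orthologs`` has columns gene_a, gene_b (gene_a on the sub-genome of
    ``intervals_a``); matching is by gene identity, never coordinates.
    """
    if orthologs.empty:
        logger.warning("empty ortholog map: no shared QTLs can be detected")
        return []
    pairs = list(zip(orthologs["gene_a"], orthologs["gene_b"]))
    out: list[SharedQtl] = []
    for iva in intervals_a:
        if iva.condition != condition:
            continue
        genes_a = set(iva.genes)
        for ivb in intervals_b:
            if ivb.condition != condition:
                continue
            genes_b = set(ivb.genes)
            hits = [(a, b) for a, b in pairs if a in genes_a and b in genes_b]
            if hits:
                out.append(
                    SharedQtl(
                        condition=condition,
                        interval_a=iva,
                        interval_b=ivb,
                        shared_orthologs=sorted(set(hits)),
                    )
                )
    return out


def summarize_counts(intervals: list[QtlInterval]) -> pd.DataFrame:
    """Per condition x sub-genome: interval count, distinct gene count,
    mean +/- sample sd of support-interval length in kb."""
    rows = []
    key = lambda iv: (iv.condition, iv.sub_genome)
    seen: dict[tuple[str, str], list[QtlInterval]] = {}
    for iv in intervals:
        seen.setdefault(key(iv), []).append(iv)
    for (condition, sub_genome), ivs in sorted(seen.items()):
        lengths = np.array(
            [(iv.support_end - iv.support_start + 1) / 1000.0 for iv in ivs]
        )
        genes = {g for iv in ivs for g in iv.genes}
        rows.append(
            {
                "condition": condition,
                "sub_genome": sub_genome,
                "n_qtl": len(ivs),
                "n_genes": len(genes),
                "mean_length_kb": float(lengths.mean()) if lengths.size else np.nan,
                "sd_length_kb": float(lengths.std(ddof=1))
                if lengths.size > 1
                else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "sub_genome", "n_qtl", "n_genes",
            "mean_length_kb", "sd_length_kb",
        ],
    )
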