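"""Consensus miRNA-target voting and miRNA -> kinase -> downstream-protein
pathway assembly.

A miRNA-target edge is *high-conforming* when enough of the nine standard
prediction sources (DIANA-mT, miRanda, PICTAR5, miRDB, PITA, miRWalk, RNA22,
RNAhybrid, TargetScan) agree.  Conforming miRNA -> kinase edges are then
crossed with the kinase's predicted interaction partners carrying a chosen
annotation (e.g. ``apoptosis``) to yield candidate regulatory triples such as
(miR-1296, PIM1, STAT3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .bayes import Subnetwork

__all__ = ["PathwayTriple", "consensus_targets", "assemble_pathways", "triples_graph"]

NON_SOURCE_COLUMNS = ("mirna", "target")


@dataclass(frozen=True)
class PathwayTriple:
    """One inferred miRNA -> kinase -> downstream-protein pathway."""

    mirna: str
    kinase: str
    downstream: str
    support_count: int
    downstream_tag: str | None = None


def _source_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in NON_SOURCE_COLUMNS]


def consensus_targets(
    table: pd.DataFrame,
    min_sources: int = 5,
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Rows whose source support reaches ``min_sources``.

    ``table`` has one row per (mirna, target) with one boolean column per
    prediction source; tables carrying a subset of the nine sources are
    accepted, with ``min_sources`` validated against the actual column
    count.  Output columns: mirna, target, support_count; sorted by support
    descending then miRNA id.
    """
    sources = _source_columns(table)
    if not 1 <= min_sources <= len(sources):
        raise ValueError(
            f"min_sources must be in [1, {len(sources)}] for this table"
        )
    if table.duplicated(subset=["mirna", "target"]).any():
        raise ValueError("duplicate (mirna, target) rows")
    support = table[sources].astype(bool).sum(axis=1)
    out = pd.DataFrame(
        {
            "mirna": table["mirna"],
            "target": table["target"],
            "support_count": support,
        }
    )
    out = out[out["support_count"] >= min_sources]
    if restrict_to is not None:
        out = out[out["target"].isin(restrict_to)]
    return (
        out.sort_values(["support_count", "mirna"], ascending=[False, True])
        .reset_index(drop=True)
    )


def assemble_pathways(
    consensus: pd.DataFrame,
    subnet: Subnetwork,
    tag_filter: str | None = "apoptosis",
) -> list[PathwayTriple]:
    """Cross conforming miRNA -> kinase edges with tagged kinase neighbours.

    For every consensus row whose target is a subnetwork seed kinase, one
    triple is emitted per neighbour of that kinase carrying ``tag_filter``
    (every neighbour when the filter is None).  A consensus kinase absent
    from the subnetwork seeds is skipped with a warning.  Output is
    deduplicated and deterministically ordered by (mirna, kinase,
    downstream).
    """
    if tag_filter is not None and subnet.tag_filtered is None:
        raise ValueError(
            "subnetwork was extracted without annotations; re-extract with "
            f"tag={tag_filter!r} or pass tag_filter=None"
        )
    triples: set[PathwayTriple] = set()
    for _, row in consensus.iterrows():
        kinase = row["target"]
        if kinase not in subnet.seeds:
            warnings.warn(f"consensus kinase {kinase!r} not a subnetwork seed; skipped")
            continue
        if tag_filter is None:
            partners = subnet.neighbors[kinase]
        else:
            partners = subnet.tag_filtered[kinase]
        for down in partners:
            triples.add(
                PathwayTriple(
                    mirna=row["mirna"],
                    kinase=kinase,
                    downstream=down,
                    support_count=int(row["support_count"]),
                    downstream_tag=tag_filter,
                )
            )
    return sorted(triples, key=lambda t: (t.mirna, t.kinase, t.downstream))


def triples_graph(triples: list[PathwayTriple]) -> nx.DiGraph:
    """Tripartite miRNA / kinase / downstream graph of the pathway triples."""
    g = nx.DiGraph()
    for t in triples:
        g.add_node(t.mirna, layer="mirna")
        g.add_node(t.kinase, layer="kinase")
        g.add_node(t.downstream, layer="downstream")
        g.add_edge(t.mirna, t.kinase, support_count=t.support_count)
        g.add_edge(t.kinase, t.downstream, tag=t.downstream_tag or "")
    return g
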