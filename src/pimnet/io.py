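"""TSV / GraphML / SIF / Newick readers and writers for every pipeline stage.

The expression TSV dialect carries the class label in the header: sample
columns are named ``<sample_id>:<class>`` (e.g. ``T1:treated``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .bayes import EvidenceChannel, Pair, ReferenceSets, Subnetwork, make_pair
from .pathways import PathwayTriple
from .simulate import ExpressionMatrix, HBondSeries, RmsdSeries

__all__ = [
    "write_pairs", "read_pairs",
    "write_channels", "read_channels",
    "write_expression", "read_expression",
    "write_target_table", "read_target_table",
    "write_hbond_series", "read_hbond_series",
    "write_rmsd_series", "read_rmsd_series",
    "write_scored_pairs", "write_network_graphml", "write_network_sif",
    "write_triples",
]


# -- reference pairs --------------------------------------------------------

def write_pairs(path: str | Path, refs: ReferenceSets, unknown: Iterable[Pair] = ()) -> None:
    rows = (
        [{"protein_a": a, "protein_b": b, "label": "PRS"} for a, b in sorted(refs.prs)]
        + [{"protein_a": a, "protein_b": b, "label": "NRS"} for a, b in sorted(refs.nrs)]
        + [{"protein_a": a, "protein_b": b, "label": "unknown"} for a, b in sorted(unknown)]
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path, nrs_variant: str = "Loc") -> tuple[ReferenceSets, list[Pair]]:
    df = pd.read_csv(path, sep="\t")
    prs, nrs, unknown = set(), set(), []
    for _, r in df.iterrows():
        p = make_pair(r["protein_a"], r["protein_b"])
        if r["label"] == "PRS":
            prs.add(p)
        elif r["label"] == "NRS":
            nrs.add(p)
        else:
            unknown.append(p)
    return ReferenceSets(frozenset(prs), frozenset(nrs), nrs_variant), unknown


# -- evidence channels ------------------------------------------------------

def write_channels(path: str | Path, channels: list[EvidenceChannel]) -> None:
    pairs = sorted({p for ch in channels for p in ch.values})
    rows = []
    for a, b in pairs:
        rec = {"protein_a": a, "protein_b": b}
        for ch in channels:
            rec[ch.name] = ch.values.get((a, b), 0)
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_channels(path: str | Path, kind: str = "binary") -> list[EvidenceChannel]:
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c not in ("protein_a", "protein_b")]
    channels = []
    for name in names:
        values = {
            make_pair(a, b): int(v)
            for a, b, v in zip(df["protein_a"], df["protein_b"], df[name])
            if int(v) != 0 or kind == "binned"
        }
        channels.append(EvidenceChannel(name=name, values=values, kind=kind))
    return channels


# -- expression matrix ------------------------------------------------------

def write_expression(path: str | Path, matrix: ExpressionMatrix) -> None:
    df = matrix.values.copy()
    df.columns = [f"{c}:{matrix.class_labels[c]}" for c in df.columns]
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids, labels = [], []
    for c in df.columns:
        sid, _, lbl = c.rpartition(":")
        if not sid or lbl not in ("treated", "normal"):
            raise ValueError(f"column {c!r} lacks a '<sample>:<class>' header")
        sample_ids.append(sid)
        labels.append(lbl)
    df.columns = sample_ids
    if df.isna().any().any():
        raise ValueError("missing values in expression matrix; imputation is out of scope")
    return ExpressionMatrix(
        values=df, class_labels=pd.Series(labels, index=sample_ids, name="class")
    )


# -- target-prediction table ------------------------------------------------

def write_target_table(path: str | Path, table: pd.DataFrame) -> None:
    out = table.copy()
    sources = [c for c in out.columns if c not in ("mirna", "target")]
    out[sources] = out[sources].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_target_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    sources = [c for c in df.columns if c not in ("mirna", "target")]
    df[sources] = df[sources].astype(bool)
    return df


# -- readout series ---------------------------------------------------------

def write_hbond_series(path: str | Path, series: HBondSeries) -> None:
    pd.DataFrame(
        {"time_ps": series.time_ps, "distance": series.distance, "angle_deg": series.angle}
    ).to_csv(path, sep="\t", index=False)


def read_hbond_series(path: str | Path, label: str = "donor-H...acceptor") -> HBondSeries:
    df = pd.read_csv(path, sep="\t")
    return HBondSeries(
        time_ps=df["time_ps"].to_numpy(),
        distance=df["distance"].to_numpy(),
        angle=df["angle_deg"].to_numpy(),
        label=label,
    )


def write_rmsd_series(path: str | Path, series: RmsdSeries) -> None:
    pd.DataFrame({"time_ps": series.time_ps, "rmsd": series.rmsd}).to_csv(
        path, sep="\t", index=False
    )


def read_rmsd_series(path: str | Path) -> RmsdSeries:
    df = pd.read_csv(path, sep="\t")
    return RmsdSeries(time_ps=df["time_ps"].to_numpy(), rmsd=df["rmsd"].to_numpy())


# -- network / pathway outputs ---------------------------------------------

def write_scored_pairs(path: str | Path, scores: pd.DataFrame) -> None:
    scores.to_csv(path, sep="\t", index=False)


def write_network_graphml(path: str | Path, edges: Iterable[Pair]) -> None:
    g = nx.Graph()
    g.add_edges_from(edges)
    nx.write_graphml(g, path)


def write_network_sif(path: str | Path, edges: Iterable[Pair], relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_triples(path: str | Path, triples: list[PathwayTriple]) -> None:
    pd.DataFrame(
        [
            {
                "mirna": t.mirna,
                "kinase": t.kinase,
                "downstream": t.downstream,
                "support_count": t.support_count,
                "downstream_tag": t.downstream_tag or "",
            }
            for t in triples
        ],
        columns=["mirna", "kinase", "downstream", "support_count", "downstream_tag"],
    ).to_csv(path, sep="\t", index=False)


def write_subnetwork(path: str | Path, subnet: Subnetwork) -> None:
    subnet.to_frame().to_csv(path, sep="\t", index=False)
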