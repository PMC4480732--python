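"""Naive Bayesian integration of evidence channels into a scored PPI network.

The model follows the classic gold-standard likelihood-ratio scheme: each
evidence channel :math:`E_i` (interolog mapping, co-expression, domain-domain
interaction, smallest-shared-biological-process similarity, or any
user-defined channel) is calibrated against a positive reference set (PRS)
and a negative reference set (NRS) of protein pairs,

.. math::

    LR(E_i) = \\frac{TPR}{FPR}, \\qquad
    TPR = \\frac{|E_i \\subset PRS|}{|PRS|}, \\quad
    FPR = \\frac{|E_i \\subset NRS|}{|NRS|}.

Under the conditional-independence (naive Bayes) assumption channel LRs
multiply into a composite score, and posterior odds scale the prior odds:

.. math::

    LR(E_1, \\ldots, E_n) = \\prod_i LR(E_i), \\qquad
    O_{posterior} = O_{prior} \\times LR.

A pair is predicted to interact when its composite LR exceeds a cutoff; the
cutoff is chosen from the TP/FP-ratio curve over candidate LR cutoffs.

Usage::

    model = NaiveBayesPPI(channels, refs, alpha=0.5)
    res = model.fit()
    curve = res.roc()
    cutoff = res.select_cutoff(min_tpfp=10.0)
    edges = res.predict_edges(cutoff)
    subnet = res.extract_subnetwork(["PIM1", "PIM2", "PIM3"], cutoff=cutoff)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "Pair",
    "make_pair",
    "ReferenceSets",
    "EvidenceChannel",
    "LikelihoodEntry",
    "LikelihoodTable",
    "NaiveBayesPPI",
    "PPIResults",
    "RocCurve",
    "Subnetwork",
    "posterior_odds",
    "compute_channel_lr",
    "combine_lrs",
]

Pair = tuple[str, str]


def make_pair(a: str, b: str) -> Pair:
    """Canonical unordered protein pair: lexicographic order, no self-pairs."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid protein pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ReferenceSets:
    """Positive (PRS) and negative (NRS) gold-standard pair sets.

    ``nrs_variant`` records how the negatives were drawn: ``"Loc"`` for
    localisation-based negatives (pairs of proteins annotated to different
    cellular compartments) or ``"Ran"`` for random non-positive pairs.
    Downstream code is variant-agnostic.
    """

    prs: frozenset[Pair]
    nrs: frozenset[Pair]
    nrs_variant: str = "Loc"

    def __post_init__(self) -> None:
        overlap = self.prs & self.nrs
        if overlap:
            raise ValueError(f"PRS and NRS overlap on {len(overlap)} pairs")

    def validate_nonempty(self) -> None:
        if not self.prs or not self.nrs:
            raise ValueError("both reference sets must be non-empty for LR computation")


@dataclass
class EvidenceChannel:
    """One evidence channel over protein pairs.

    ``values`` maps a canonical pair to a flag (binary channel: 1 = evidence
    present, 0/absent = not observed) or to a bin index (binned channel).
    Binned channels must declare at least 2 bins via ``n_bins``; every
    evaluated pair maps to exactly one bin.
    """

    name: str
    values: Mapping[Pair, int]
    kind: str = "binary"  # {"binary", "binned"}
    n_bins: int = 2
    bin_edges: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "binned"):
            raise ValueError("channel kind must be 'binary' or 'binned'")
        if self.kind == "binned" and self.n_bins < 2:
            raise ValueError("binned channels need >= 2 bins")

    def bins(self) -> list[int]:
        """Bin states carrying a likelihood ratio.

        For a binary channel only the 'present' state (1) is scored; absence
        is treated as missing evidence (neutral LR 1 downstream).
        """
        if self.kind == "binary":
            return [1]
        return list(range(self.n_bins))

    def bin_of(self, pair: Pair) -> int | None:
        """Bin index for *pair*, or None when the channel has no observation."""
        v = self.values.get(pair)
        if v is None:
            return None
        if self.kind == "binary":
            return 1 if v else None
        if not 0 <= v < self.n_bins:
            raise KeyError(f"pair {pair} maps to unknown bin {v} in channel {self.name}")
        return int(v)


@dataclass(frozen=True)
class LikelihoodEntry:
    channel: str
    bin: int
    tpr: float
    fpr: float
    lr: float


@dataclass
class LikelihoodTable:
    """Per-(channel, bin) TPR/FPR/LR entries with the smoothing used."""

    entries: dict[tuple[str, int], LikelihoodEntry] = field(default_factory=dict)
    smoothing_alpha: float = 0.5

    def add(self, entry: LikelihoodEntry) -> None:
        self.entries[(entry.channel, entry.bin)] = entry

    def lr(self, channel: str, bin: int) -> float:
        key = (channel, bin)
        if key not in self.entries:
            raise KeyError(f"no likelihood entry for channel {channel!r} bin {bin}")
        return self.entries[key].lr

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": e.channel, "bin": e.bin, "tpr": e.tpr, "fpr": e.fpr, "lr": e.lr}
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=["channel", "bin", "tpr", "fpr", "lr"])


def compute_channel_lr(
    channel: EvidenceChannel,
    refs: ReferenceSets,
    smoothing_alpha: float = 0.5,
) -> list[LikelihoodEntry]:
    """Calibrate one channel against the gold standard.

    With pseudocount ``alpha``, for each scored bin

        TPR = (hits_in_PRS + alpha) / (|PRS| + 2*alpha)
        FPR = (hits_in_NRS + alpha) / (|NRS| + 2*alpha)
        LR  = TPR / FPR

    ``alpha = 0`` reproduces the raw rate ratio but raises when a bin misses
    the NRS entirely (infinite LR).
    """
    refs.validate_nonempty()
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be >= 0")
    a = smoothing_alpha
    n_prs, n_nrs = len(refs.prs), len(refs.nrs)
    entries = []
    for b in channel.bins():
        prs_hits = sum(1 for p in refs.prs if channel.bin_of(p) == b)
        nrs_hits = sum(1 for p in refs.nrs if channel.bin_of(p) == b)
        if a == 0 and nrs_hits == 0:
            raise ZeroDivisionError(
                f"channel {channel.name!r} bin {b} has zero NRS hits; "
                "use a positive smoothing_alpha to keep the LR finite"
            )
        tpr = (prs_hits + a) / (n_prs + 2 * a)
        fpr = (nrs_hits + a) / (n_nrs + 2 * a)
        entries.append(LikelihoodEntry(channel.name, b, tpr, fpr, tpr / fpr))
    return entries


def combine_lrs(
    pair: Pair,
    channels: Iterable[EvidenceChannel],
    table: LikelihoodTable,
    missing_policy: str = "neutral",
) -> float:
    """Composite LR for a pair: product of its per-channel bin LRs.

    Channels with no observation for the pair contribute a factor 1 under the
    (only) ``neutral`` missing policy, consistent with conditional
    independence of absent evidence.
    """
    if missing_policy != "neutral":
        raise ValueError("only the 'neutral' missing policy is supported")
    composite = 1.0
    for ch in channels:
        b = ch.bin_of(pair)
        if b is None:
            continue
        composite *= table.lr(ch.name, b)
    return composite


def posterior_odds(prior_odds: float, composite_lr: float) -> float:
    """O_posterior = O_prior x composite LR."""
    if prior_odds <= 0:
        raise ValueError("prior odds must be > 0")
    if composite_lr < 0:
        raise ValueError("composite LR must be >= 0")
    return prior_odds * composite_lr


@dataclass
class RocCurve:
    """ROC and TP/FP-ratio curve over LR cutoffs.

    ``points`` columns: cutoff, tp, fp, tpr, fpr, tpfp (math.inf marks FP=0).
    """

    points: pd.DataFrame
    auc: float

    def tpfp(self) -> list[tuple[float, float]]:
        return list(zip(self.points["cutoff"], self.points["tpfp"]))


def _roc_points(
    prs_scores: np.ndarray, nrs_scores: np.ndarray, cutoffs: Sequence[float]
) -> pd.DataFrame:
    rows = []
    for c in cutoffs:
        tp = int(np.sum(prs_scores > c))
        fp = int(np.sum(nrs_scores > c))
        rows.append(
            {
                "cutoff": c,
                "tp": tp,
                "fp": fp,
                "tpr": tp / len(prs_scores),
                "fpr": fp / len(nrs_scores),
                "tpfp": (tp / fp) if fp > 0 else math.inf,
            }
        )
    return pd.DataFrame(rows)


def roc_and_tpfp(
    prs_scores: np.ndarray,
    nrs_scores: np.ndarray,
    cutoffs: Sequence[float] | None = None,
) -> RocCurve:
    """ROC curve from reference-pair composite scores.

    At each cutoff TP (FP) counts PRS (NRS) pairs scoring strictly above it.
    AUC is the trapezoid area over (FPR, TPR) with (0,0)/(1,1) endpoints.
    When ``cutoffs`` is omitted, every distinct observed score is used.
    """
    prs_scores = np.asarray(prs_scores, dtype=float)
    nrs_scores = np.asarray(nrs_scores, dtype=float)
    if prs_scores.size == 0 or nrs_scores.size == 0:
        raise ValueError("both reference score sets must be non-empty")
    if cutoffs is None:
        allscores = np.concatenate([prs_scores, nrs_scores])
        cutoffs = np.unique(allscores)
    cutoffs = list(cutoffs)
    if len(cutoffs) == 0:
        raise ValueError("cutoff list must be non-empty")
    points = _roc_points(prs_scores, nrs_scores, sorted(cutoffs))
    fpr = np.concatenate([[1.0], points["fpr"].to_numpy(), [0.0]])
    tpr = np.concatenate([[1.0], points["tpr"].to_numpy(), [0.0]])
    order = np.lexsort((tpr, fpr))  # ties at a given FPR ordered by TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(points=points, auc=auc)


def select_cutoff(curve: RocCurve, min_tpfp: float) -> float:
    """Smallest cutoff whose TP/FP ratio reaches ``min_tpfp`` (inf qualifies)."""
    if min_tpfp <= 0:
        raise ValueError("min_tpfp must be > 0")
    pts = curve.points.sort_values("cutoff")
    if pts.empty:
        raise ValueError("ROC curve has no points")
    ok = pts[pts["tpfp"] >= min_tpfp]
    if ok.empty:
        best = pts["tpfp"].replace(math.inf, np.nan).max()
        raise ValueError(
            f"no cutoff reaches TP/FP >= {min_tpfp}; best attained ratio is {best}"
        )
    return float(ok["cutoff"].iloc[0])


@dataclass
class Subnetwork:
    """Seed-centred subnetwork summary."""

    seeds: list[str]
    neighbors: dict[str, list[str]]
    degrees: dict[str, int]
    shared_neighbors: list[str]
    tag_filtered: dict[str, list[str]] | None = None
    tag: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.seeds:
            for n in self.neighbors[s]:
                rows.append({"seed": s, "neighbor": n})
        return pd.DataFrame(rows, columns=["seed", "neighbor"])


def extract_subnetwork(
    edges: Iterable[Pair],
    seeds: Sequence[str],
    annotations: Mapping[str, str] | None = None,
    tag: str | None = None,
) -> Subnetwork:
    """Per-seed neighbour lists, degrees, shared neighbours, tag filter.

    A seed absent from the node universe yields a warning and an empty list.
    The shared-neighbour set is the intersection over all seeds; the tag
    filter keeps neighbours whose annotation equals ``tag``.
    """
    if not seeds:
        raise ValueError("seed list must be non-empty")
    g = nx.Graph()
    g.add_edges_from(edges)
    neighbors: dict[str, list[str]] = {}
    for s in seeds:
        if s not in g:
            warnings.warn(f"seed {s!r} absent from the network; empty neighbor list")
            neighbors[s] = []
        else:
            neighbors[s] = sorted(n for n in g.neighbors(s) if n != s)
    degrees = {s: len(neighbors[s]) for s in seeds}
    shared: set[str] = set(neighbors[seeds[0]])
    for s in seeds[1:]:
        shared &= set(neighbors[s])
    tag_filtered = None
    if tag is not None:
        ann = annotations or {}
        tag_filtered = {
            s: [n for n in neighbors[s] if ann.get(n) == tag] for s in seeds
        }
    return Subnetwork(
        seeds=list(seeds),
        neighbors=neighbors,
        degrees=degrees,
        shared_neighbors=sorted(shared),
        tag_filtered=tag_filtered,
        tag=tag,
    )


class NaiveBayesPPI:
    """Naive Bayes evidence-integration model for PPI prediction.

    Parameters
    ----------
    channels
        Evidence channels to integrate.
    refs
        Gold-standard reference sets used for calibration.
    pairs
        Candidate pair universe to score.  Defaults to the union of reference
        pairs and every pair any channel observes.
    alpha
        Additive pseudocount applied to hit counts (2*alpha on denominators)
        so that LRs stay finite; 0.5 by default.
    prior_odds
        Prior odds that a random candidate pair interacts.  Defaults to
        |PRS| / (|universe| - |PRS|), the standard gold-standard prior.
    """

    def __init__(
        self,
        channels: Sequence[EvidenceChannel],
        refs: ReferenceSets,
        pairs: Iterable[Pair] | None = None,
        alpha: float = 0.5,
        prior_odds: float | None = None,
    ) -> None:
        self.channels = list(channels)
        self.refs = refs
        if pairs is None:
            universe: set[Pair] = set(refs.prs) | set(refs.nrs)
            for ch in self.channels:
                universe.update(ch.values.keys())
            pairs = universe
        self.pairs = sorted(set(pairs))
        self.alpha = alpha
        if prior_odds is None:
            n_pos = len(refs.prs)
            n_all = len(self.pairs)
            if n_all <= n_pos:
                raise ValueError("candidate universe must exceed the PRS")
            prior_odds = n_pos / (n_all - n_pos)
        if prior_odds <= 0:
            raise ValueError("prior odds must be > 0")
        self.prior_odds = prior_odds

    def fit(self) -> "PPIResults":
        table = LikelihoodTable(smoothing_alpha=self.alpha)
        for ch in self.channels:
            for entry in compute_channel_lr(ch, self.refs, self.alpha):
                table.add(entry)

        records = []
        for p in self.pairs:
            rec: dict[str, object] = {
                "protein_a": p[0],
                "protein_b": p[1],
            }
            comp = 1.0
            for ch in self.channels:
                b = ch.bin_of(p)
                lr = 1.0 if b is None else table.lr(ch.name, b)
                rec[f"lr_{ch.name}"] = lr
                comp *= lr
            rec["composite_lr"] = comp
            rec["posterior_odds"] = posterior_odds(self.prior_odds, comp)
            records.append(rec)
        scores = pd.DataFrame(records)
        return PPIResults(model=self, likelihoods=table, scores=scores)


class PPIResults:
    """Fitted likelihood table and scored pair universe."""

    def __init__(
        self, model: NaiveBayesPPI, likelihoods: LikelihoodTable, scores: pd.DataFrame
    ) -> None:
        self.model = model
        self.likelihoods = likelihoods
        self.scores = scores
        self.prior_odds = model.prior_odds
        self._score_of = {
            make_pair(a, b): s
            for a, b, s in zip(
                scores["protein_a"], scores["protein_b"], scores["composite_lr"]
            )
        }

    # -- scoring ---------------------------------------------------------
    def composite_lr(self, pair: Pair) -> float:
        return self._score_of[pair]

    def _ref_scores(self) -> tuple[np.ndarray, np.ndarray]:
        prs = np.array([self._score_of[p] for p in sorted(self.model.refs.prs)])
        nrs = np.array([self._score_of[p] for p in sorted(self.model.refs.nrs)])
        return prs, nrs

    # -- evaluation ------------------------------------------------------
    def roc(self, cutoffs: Sequence[float] | None = None) -> RocCurve:
        prs, nrs = self._ref_scores()
        return roc_and_tpfp(prs, nrs, cutoffs)

    def select_cutoff(self, min_tpfp: float, cutoffs: Sequence[float] | None = None) -> float:
        return select_cutoff(self.roc(cutoffs), min_tpfp)

    def predict_edges(self, cutoff: float) -> set[Pair]:
        """Pairs with composite LR strictly above the cutoff."""
        if cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        return {p for p, s in self._score_of.items() if s > cutoff}

    def extract_subnetwork(
        self,
        seeds: Sequence[str],
        cutoff: float,
        annotations: Mapping[str, str] | None = None,
        tag: str | None = None,
    ) -> Subnetwork:
        return extract_subnetwork(self.predict_edges(cutoff), seeds, annotations, tag)

    def summary(self) -> str:
        lines = [
            "Naive Bayes PPI integration",
            "===========================",
            f"candidate pairs: {len(self.scores)}",
            f"|PRS| = {len(self.model.refs.prs)}  |NRS| = {len(self.model.refs.nrs)}"
            f"  (variant: {self.model.refs.nrs_variant})",
            f"prior odds: {self.prior_odds:.6g}   smoothing alpha: {self.model.alpha}",
            "",
            self.likelihoods.to_frame().to_string(index=False),
            "",
            f"composite LR range: [{self.scores['composite_lr'].min():.4g}, "
            f"{self.scores['composite_lr'].max():.4g}]",
            f"ROC AUC (reference pairs): {self.roc().auc:.4f}",
        ]
        return "\n".join(lines)
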