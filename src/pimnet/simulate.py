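"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis — likelihood-ratio calibration, SAM on a minimal
2v2 design, consensus target voting, MD post-processing readouts — can be
exercised without any external database.  The generators emit their ground
truth alongside the data; downstream recovery tests read only the data and
consult the truth solely in assertions.

Determinism: each generator op draws from its own RNG stream, derived from
the master seed by a fixed op offset, so identical configs give identical
outputs regardless of call order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .bayes import EvidenceChannel, Pair, ReferenceSets, make_pair
from .readouts import EnergyComponents

__all__ = [
    "ExpressionMatrix",
    "HBondSeries",
    "RmsdSeries",
    "gen_reference_and_evidence",
    "gen_expression_matrix",
    "gen_target_prediction_table",
    "gen_trajectory_readouts",
]

# fixed per-op offsets into the master seed stream
_OP_REFERENCE = 1
_OP_EXPRESSION = 2
_OP_TARGETS = 3
_OP_READOUTS = 4


def _rng(config: SimConfig, op_offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), op_offset])


# ---------------------------------------------------------------------------
# reference sets + evidence channels


def gen_reference_and_evidence(
    config: SimConfig,
) -> tuple[ReferenceSets, list[EvidenceChannel]]:
    """Gold-standard pair sets and binary evidence channels.

    Proteins get one synthetic compartment label each.  PRS pairs are drawn
    uniformly; Loc-NRS pairs are drawn only across differing compartments
    (mirroring localisation-based negatives), Ran-NRS uniformly from
    non-positive pairs.  Each channel then fires on PRS pairs with
    probability ``coverage`` and on NRS/unknown pairs with probability
    ``coverage / target_lr`` (clipped to [0, 1]), so its empirical LR
    converges to the configured target.
    """
    rng = _rng(config, _OP_REFERENCE)
    n = config.universe_size
    proteins = [f"P{i:04d}" for i in range(n)]
    compartments = rng.integers(0, config.n_compartments, size=n)
    comp_of = dict(zip(proteins, compartments))

    all_pairs = [make_pair(a, b) for a, b in itertools.combinations(proteins, 2)]
    order = rng.permutation(len(all_pairs))

    prs: set[Pair] = set()
    idx = 0
    while len(prs) < config.n_prs and idx < len(order):
        prs.add(all_pairs[order[idx]])
        idx += 1
    if len(prs) < config.n_prs:
        raise ValueError("cannot draw the requested number of PRS pairs")

    def loc_ok(p: Pair) -> bool:
        return comp_of[p[0]] != comp_of[p[1]]

    nrs: set[Pair] = set()
    while len(nrs) < config.n_nrs and idx < len(order):
        cand = all_pairs[order[idx]]
        idx += 1
        if cand in prs:
            continue
        if config.nrs_variant == "Loc" and not loc_ok(cand):
            continue
        nrs.add(cand)
    if len(nrs) < config.n_nrs:
        raise ValueError(
            "cannot draw the requested number of NRS pairs "
            f"(variant {config.nrs_variant}); reduce n_nrs or enlarge the universe"
        )

    unknown: list[Pair] = []
    while len(unknown) < config.n_unknown_pairs and idx < len(order):
        cand = all_pairs[order[idx]]
        idx += 1
        if cand in prs or cand in nrs:
            continue
        unknown.append(cand)

    refs = ReferenceSets(frozenset(prs), frozenset(nrs), config.nrs_variant)

    channels = []
    for spec in config.channel_specs:
        p_pos = spec.coverage
        p_neg = min(1.0, spec.coverage / spec.target_lr)
        values: dict[Pair, int] = {}
        for pair in sorted(prs):
            if rng.random() < p_pos:
                values[pair] = 1
        for pair in sorted(nrs) + unknown:
            if rng.random() < p_neg:
                values[pair] = 1
        channels.append(EvidenceChannel(name=spec.name, values=values, kind="binary"))
    return refs, channels


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """log2 expression values with per-sample class labels and spike truth.

    ``values``: features x samples DataFrame.  ``class_labels``: one of
    {"treated", "normal"} per sample column.  ``truth``: per-feature ground
    truth direction in {"up", "down", "none"} (emitted by the generator; real
    data carries no truth column).
    """

    values: pd.DataFrame
    class_labels: pd.Series
    truth: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        counts = self.class_labels.value_counts()
        if (counts < 2).any() or len(counts) != 2:
            raise ValueError("need >= 2 samples in each of exactly 2 classes")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, label: str) -> list[str]:
        return list(self.class_labels.index[self.class_labels == label])


def gen_expression_matrix(config: SimConfig) -> ExpressionMatrix:
    """Two-class spike-in matrix.

    Background features are Normal(0, noise_sd) in both classes; the first
    ``n_up`` features are shifted by +effect and the next ``n_down`` by
    -effect in the treated class only.
    """
    spec = config.expr_spec
    rng = _rng(config, _OP_EXPRESSION)
    n_samples = 2 * spec.n_per_class
    feature_ids = [f"miR-{i + 1:04d}" for i in range(spec.n_features)]
    sample_ids = [f"T{i + 1}" for i in range(spec.n_per_class)] + [
        f"N{i + 1}" for i in range(spec.n_per_class)
    ]
    labels = pd.Series(
        ["treated"] * spec.n_per_class + ["normal"] * spec.n_per_class,
        index=sample_ids,
        name="class",
    )
    vals = rng.normal(0.0, spec.noise_sd, size=(spec.n_features, n_samples))
    truth = ["none"] * spec.n_features
    for i in range(spec.n_up):
        vals[i, : spec.n_per_class] += spec.effect
        truth[i] = "up"
    for i in range(spec.n_up, spec.n_up + spec.n_down):
        vals[i, : spec.n_per_class] -= spec.effect
        truth[i] = "down"
    values = pd.DataFrame(vals, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(
        values=values,
        class_labels=labels,
        truth=pd.Series(truth, index=feature_ids, name="truth"),
    )


# ---------------------------------------------------------------------------
# miRNA target-prediction table


def gen_target_prediction_table(
    config: SimConfig,
    target: str = "PIM1",
    sources: list[str] | None = None,
) -> pd.DataFrame:
    """Boolean miRNA x source table against a single target gene.

    The tier spec maps a source-support count to the number of miRNAs at that
    tier; each row's support sources are chosen at random but row sums equal
    the assigned counts exactly.  Columns: mirna, target, then one boolean
    column per source.
    """
    spec = config.target_table_spec
    rng = _rng(config, _OP_TARGETS)
    if sources is None:
        sources = [
            "DIANA-mT", "miRanda", "PICTAR5", "miRDB", "PITA",
            "miRWalk", "RNA22", "RNAhybrid", "TargetScan",
        ][: spec.n_sources]
    if len(sources) != spec.n_sources:
        raise ValueError("source name list must match n_sources")
    rows = []
    i = 0
    for support in sorted(spec.tiers, reverse=True):
        for _ in range(spec.tiers[support]):
            i += 1
            flags = np.zeros(spec.n_sources, dtype=bool)
            on = rng.choice(spec.n_sources, size=support, replace=False)
            flags[on] = True
            rows.append({"mirna": f"miR-{i:04d}", "target": target, **dict(zip(sources, flags))})
    return pd.DataFrame(rows, columns=["mirna", "target", *sources])


# ---------------------------------------------------------------------------
# trajectory readouts


@dataclass
class HBondSeries:
    """Per-frame donor-H...acceptor geometry for one hydrogen bond."""

    time_ps: np.ndarray
    distance: np.ndarray  # Angstrom
    angle: np.ndarray     # degrees
    label: str = "donor-H...acceptor"

    def __post_init__(self) -> None:
        if np.any(self.distance <= 0):
            raise ValueError("distances must be > 0")
        if np.any((self.angle < 0) | (self.angle > 180)):
            raise ValueError("angles must be in [0, 180] degrees")


@dataclass
class RmsdSeries:
    """Backbone RMSD trace (Angstrom) over simulation time (ps)."""

    time_ps: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_ps) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.rmsd < 0):
            raise ValueError("RMSD must be >= 0")


def gen_trajectory_readouts(
    config: SimConfig,
) -> tuple[HBondSeries, RmsdSeries, EnergyComponents]:
    """Emulated MD post-processing output.

    - The hydrogen-bond series satisfies the geometric criteria
      (distance <= dist_cutoff AND angle <= angle_cutoff) in exactly
      round(occupancy% x n_frames / 100) frames.
    - The RMSD trace ramps linearly to the plateau over the configured
      equilibration time, then fluctuates around it with the configured SD.
    - The MM/GBSA component bundle satisfies
      dG_bind = dE_ele + dE_vdw + dG_sol_nopol + dG_sol_ele + (-TdS) exactly.
    """
    spec = config.readout_spec
    rng = _rng(config, _OP_READOUTS)
    n = spec.n_frames
    t = np.arange(n, dtype=float) * spec.frame_interval_ps

    n_occ = int(round(spec.occupancy_pct * n / 100.0))
    qualify = np.zeros(n, dtype=bool)
    qualify[rng.choice(n, size=n_occ, replace=False)] = True
    dist = np.where(
        qualify,
        np.clip(rng.normal(2.7, 0.15, size=n), 1.5, spec.dist_cutoff),
        rng.uniform(spec.dist_cutoff + 0.3, spec.dist_cutoff + 2.5, size=n),
    )
    angle = np.where(
        qualify,
        rng.uniform(5.0, spec.angle_cutoff, size=n),
        rng.uniform(spec.angle_cutoff + 5.0, 120.0, size=n),
    )
    hbond = HBondSeries(time_ps=t, distance=dist, angle=angle)

    if spec.equilibration_ps > 0:
        ramp = np.minimum(t / spec.equilibration_ps, 1.0) * spec.plateau
    else:
        ramp = np.full(n, spec.plateau)
    # unequilibrated frames fluctuate well beyond the stability criterion;
    # equilibrated frames fluctuate tightly around the plateau
    sd = np.where(t < spec.equilibration_ps, spec.pre_eq_noise_sd, spec.noise_sd)
    noise = rng.normal(0.0, 1.0, size=n) * sd
    rmsd = RmsdSeries(time_ps=t, rmsd=np.clip(ramp + noise, 0.0, None))

    e_int_ele = rng.normal(-40.0, 3.0)
    e_int_vdw = rng.normal(-36.0, 2.0)
    g_sol_nopol = rng.normal(-5.4, 0.3)
    g_sol_ele = rng.normal(48.0, 4.0)
    neg_t_ds = rng.normal(-9.5, 0.8)
    comp = EnergyComponents(
        complex_id="synthetic",
        e_int_ele=e_int_ele,
        e_int_vdw=e_int_vdw,
        g_sol_nopol=g_sol_nopol,
        g_sol_ele=g_sol_ele,
        neg_t_ds=neg_t_ds,
        g_sol_printed=g_sol_nopol + g_sol_ele,
        g_ele_printed=e_int_ele + g_sol_ele,
        g_bind_printed=e_int_ele + e_int_vdw + g_sol_nopol + g_sol_ele + neg_t_ds,
    )
    return hbond, rmsd, comp
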