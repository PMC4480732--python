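"""Simulation configuration for the synthetic input generators.

Every generator in :mod:`pimnet.simulate` is driven by a single
:class:`SimConfig`.  A fixed ``seed`` makes all generated artefacts
byte-identical on re-run; each generator op derives its own RNG stream from
the master seed by a fixed offset, so reordering ops never changes results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = [
    "ChannelSpec",
    "ExprSpec",
    "TargetTableSpec",
    "ReadoutSpec",
    "SimConfig",
]


@dataclass(frozen=True)
class ChannelSpec:
    """One synthetic evidence channel.

    Parameters
    ----------
    name
        Channel label (e.g. ``interolog``, ``coexpression``, ``ddi``, ``ssbp``).
    target_lr
        Likelihood ratio the channel should exhibit against the reference
        sets: the channel fires on positive-reference pairs with probability
        ``coverage`` and on negative-reference pairs with probability
        ``coverage / target_lr`` (clipped to [0, 1]).
    coverage
        Fraction of positive-reference pairs the channel covers.
    """

    name: str
    target_lr: float
    coverage: float

    def __post_init__(self) -> None:
        if self.target_lr <= 0:
            raise ValueError(f"channel {self.name!r}: target LR must be > 0")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"channel {self.name!r}: coverage must be in [0, 1]")


@dataclass(frozen=True)
class ExprSpec:
    """Two-class log2 expression matrix layout: background features are
    Normal(0, noise_sd) in both classes, spiked features are shifted by
    +/- effect in the treated class."""

    n_features: int = 70
    n_per_class: int = 2
    n_up: int = 35
    n_down: int = 2
    effect: float = 2.0  # log2 units
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if self.n_up + self.n_down > self.n_features:
            raise ValueError("n_up + n_down exceeds n_features")
        if self.effect < 0 and (self.n_up + self.n_down) > 0:
            raise ValueError("spiked features require a non-negative effect size")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class TargetTableSpec:
    """miRNA x prediction-source boolean table: ``tiers`` maps a
    source-support count to the number of miRNAs carrying it."""

    n_sources: int = 9
    tiers: dict[int, int] = field(default_factory=lambda: {9: 1, 7: 2, 5: 4, 2: 10, 0: 20})

    def __post_init__(self) -> None:
        for support, count in self.tiers.items():
            if support < 0 or support > self.n_sources:
                raise ValueError(
                    f"tier support {support} outside [0, {self.n_sources}]"
                )
            if count < 0:
                raise ValueError("tier counts must be >= 0")

    @property
    def n_mirnas(self) -> int:
        return sum(self.tiers.values())


@dataclass(frozen=True)
class ReadoutSpec:
    """Molecular-dynamics post-processing readouts to emulate: a hydrogen-bond
    geometry series with a set occupancy, an RMSD trace ramping to a plateau,
    and a self-consistent MM/GBSA component bundle."""

    n_frames: int = 1000
    occupancy_pct: float = 99.6
    dist_cutoff: float = 3.5     # Angstrom, donor-acceptor H-bond criterion
    angle_cutoff: float = 30.0   # degrees
    equilibration_ps: float = 1000.0
    plateau: float = 1.2         # Angstrom
    noise_sd: float = 0.1        # Angstrom, equilibrated-phase fluctuation
    pre_eq_noise_sd: float = 0.6  # Angstrom, unequilibrated drift/fluctuation
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        if not 0.0 <= self.occupancy_pct <= 100.0:
            raise ValueError("occupancy must be in [0, 100]")


@dataclass(frozen=True)
class SimConfig:
    """Master configuration; see the per-field spec dataclasses."""

    seed: int = 0
    universe_size: int = 200
    n_prs: int = 500
    n_nrs: int = 500
    nrs_variant: str = "Loc"  # {"Loc", "Ran"}
    n_compartments: int = 4
    n_unknown_pairs: int = 500
    channel_specs: Sequence[ChannelSpec] = field(
        default_factory=lambda: (
            ChannelSpec("interolog", 8.0, 0.4),
            ChannelSpec("coexpression", 3.0, 0.5),
            ChannelSpec("ddi", 5.0, 0.3),
            ChannelSpec("ssbp", 2.0, 0.6),
        )
    )
    expr_spec: ExprSpec = field(default_factory=ExprSpec)
    target_table_spec: TargetTableSpec = field(default_factory=TargetTableSpec)
    readout_spec: ReadoutSpec = field(default_factory=ReadoutSpec)

    def __post_init__(self) -> None:
        if self.nrs_variant not in ("Loc", "Ran"):
            raise ValueError("nrs_variant must be 'Loc' or 'Ran'")
        if self.universe_size < 4:
            raise ValueError("universe_size must be >= 4")
        n_possible = self.universe_size * (self.universe_size - 1) // 2
        if self.n_prs + self.n_nrs > n_possible:
            raise ValueError(
                f"n_prs + n_nrs = {self.n_prs + self.n_nrs} exceeds the "
                f"{n_possible} possible unordered pairs"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "channel_specs" in raw:
            raw["channel_specs"] = tuple(
                ChannelSpec(**c) for c in raw["channel_specs"]
            )
        for key, sub in (
            ("expr_spec", ExprSpec),
            ("target_table_spec", TargetTableSpec),
            ("readout_spec", ReadoutSpec),
        ):
            if key in raw:
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
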