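"""Quantitative readout formulas: MM/GBSA component bookkeeping, hydrogen-bond
occupancy, RMSD equilibration detection, snapshot scheduling, MTT inhibitory
ratio and tumor volume.

The MM/GBSA bundle follows the standard end-point decomposition

    dG_bind = dE_int_ele + dE_int_vdw + dG_sol_nopol + dG_sol_ele + (-T dS)
    dG_sol  = dG_sol_ele + dG_sol_nopol          (total solvation)
    dG_ele  = dE_int_ele + dG_sol_ele            (total electrostatics)

in kcal/mol.  When a component table also carries printed totals, the
aggregation report states the recomputed value next to the printed one and
their discrepancy — published tables are not always internally consistent,
and the discrepancy is surfaced rather than silenced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnergyComponents",
    "total_solvation",
    "total_electrostatic",
    "binding_free_energy",
    "energy_report",
    "load_reference_energy_table",
    "snapshot_count",
    "hbond_occupancy",
    "rmsd_equilibration",
    "inhibitory_ratio",
    "tumor_volume",
]


@dataclass(frozen=True)
class EnergyComponents:
    """MM/GBSA energy terms for one kinase-inhibitor complex (kcal/mol).

    ``neg_t_ds`` is the entropy term stored as -T*dS (so all five terms sum
    directly to the binding free energy).  The ``*_printed`` fields are
    optional totals as printed in a source table, kept for consistency
    checking; None when absent.
    """

    complex_id: str
    e_int_ele: float
    e_int_vdw: float
    g_sol_nopol: float
    g_sol_ele: float
    neg_t_ds: float
    g_sol_printed: float | None = None
    g_ele_printed: float | None = None
    g_bind_printed: float | None = None

    def __post_init__(self) -> None:
        for name in ("e_int_ele", "e_int_vdw", "g_sol_nopol", "g_sol_ele", "neg_t_ds"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"{self.complex_id}: component {name} must be finite")


def total_solvation(c: EnergyComponents) -> float:
    """Total solvation free energy dG_sol = dG_sol_ele + dG_sol_nopol."""
    return c.g_sol_ele + c.g_sol_nopol


def total_electrostatic(c: EnergyComponents) -> float:
    """Total electrostatics dG_ele = dE_int_ele + dG_sol_ele."""
    return c.e_int_ele + c.g_sol_ele


def binding_free_energy(c: EnergyComponents) -> float:
    """dG_bind as the sum of the five component terms."""
    return c.e_int_ele + c.e_int_vdw + c.g_sol_nopol + c.g_sol_ele + c.neg_t_ds


def energy_report(components: list[EnergyComponents]) -> pd.DataFrame:
    """Aggregation report: recomputed totals plus printed-vs-recomputed
    discrepancies (NaN where no printed total is available)."""
    rows = []
    for c in components:
        g_sol = total_solvation(c)
        g_ele = total_electrostatic(c)
        g_bind = binding_free_energy(c)
        rows.append(
            {
                "complex_id": c.complex_id,
                "g_sol": g_sol,
                "g_ele": g_ele,
                "g_bind": g_bind,
                "g_sol_printed": c.g_sol_printed,
                "g_ele_printed": c.g_ele_printed,
                "g_bind_printed": c.g_bind_printed,
                "g_sol_discrepancy": (
                    abs(c.g_sol_printed - g_sol) if c.g_sol_printed is not None else np.nan
                ),
                "g_ele_discrepancy": (
                    abs(c.g_ele_printed - g_ele) if c.g_ele_printed is not None else np.nan
                ),
                "g_bind_discrepancy": (
                    abs(c.g_bind_printed - g_bind) if c.g_bind_printed is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def load_reference_energy_table() -> list[EnergyComponents]:
    """Published MM/GBSA component table for the PI003-PIM1/2/3 complexes.

    Returns one :class:`EnergyComponents` per complex, with the printed
    totals attached for discrepancy reporting.
    """
    path = importlib.resources.files("pimnet") / "data" / "pim_energy_components.tsv"
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            EnergyComponents(
                complex_id=r["complex_id"],
                e_int_ele=r["e_int_ele"],
                e_int_vdw=r["e_int_vdw"],
                g_sol_nopol=r["g_sol_nopol"],
                g_sol_ele=r["g_sol_ele"],
                neg_t_ds=r["neg_t_ds"],
                g_sol_printed=r["g_sol_printed"],
                g_ele_printed=r["g_ele_printed"],
                g_bind_printed=r["g_bind_printed"],
            )
        )
    return out


def snapshot_count(start_ns: float, end_ns: float, interval_ps: float) -> int:
    """Snapshots extracted at ``interval_ps`` over (start_ns, end_ns].

    Start-exclusive, end-inclusive: a 1-10 ns window at 20 ps yields 450
    snapshots.
    """
    if end_ns <= start_ns:
        raise ValueError("end time must exceed start time")
    if interval_ps <= 0:
        raise ValueError("interval must be > 0")
    span_ps = (end_ns - start_ns) * 1000.0
    return int(np.floor(span_ps / interval_ps + 1e-9))


def hbond_occupancy(
    series,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> dict:
    """Hydrogen-bond occupancy over a trajectory.

    A frame qualifies when distance <= dist_cutoff (Angstrom) AND
    angle <= angle_cutoff (degrees).  Returns occupancy percent plus the
    mean distance and angle over qualifying frames only (None when no frame
    qualifies).
    """
    dist = np.asarray(series.distance, dtype=float)
    ang = np.asarray(series.angle, dtype=float)
    if dist.size == 0:
        raise ValueError("hydrogen-bond series is empty")
    ok = (dist <= dist_cutoff) & (ang <= angle_cutoff)
    pct = 100.0 * np.count_nonzero(ok) / dist.size
    if not ok.any():
        return {"occupancy_pct": 0.0, "mean_distance": None, "mean_angle": None}
    return {
        "occupancy_pct": pct,
        "mean_distance": float(dist[ok].mean()),
        "mean_angle": float(ang[ok].mean()),
    }


def rmsd_equilibration(series, window: float = 100.0, tol: float = 0.5) -> float | None:
    """Earliest time from which the RMSD trace stays within ``tol`` of its
    running window mean through the end of the trajectory.

    ``window`` is in ps, ``tol`` in Angstrom.  Scans candidate start times
    forward; the plateau must persist for at least one window (candidates
    stop ``window`` before the end), and over the tail [t, end] every value
    must deviate from the tail mean by less than ``tol``.  Returns None when
    no such time exists.
    """
    t = np.asarray(series.time_ps, dtype=float)
    r = np.asarray(series.rmsd, dtype=float)
    span = t[-1] - t[0]
    if window >= span:
        raise ValueError("window must be shorter than the series span")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    last_start = t[-1] - window
    # suffix cumulative sums give each tail mean in O(1)
    csum = np.concatenate([[0.0], np.cumsum(r[::-1])])[::-1]
    for i in range(len(t)):
        if t[i] > last_start:
            break
        n_tail = len(t) - i
        mean = csum[i] / n_tail
        if np.max(np.abs(r[i:] - mean)) < tol:
            return float(t[i])
    return None


def inhibitory_ratio(od_control: float, od_sample: float, od_blank: float) -> float:
    """MTT inhibitory ratio (%) = (OD_control - OD_sample) /
    (OD_control - OD_blank) x 100."""
    denom = od_control - od_blank
    if denom == 0:
        raise ValueError("OD_control must differ from OD_blank")
    return (od_control - od_sample) / denom * 100.0


def tumor_volume(length: float, width: float) -> float:
    """Tumor volume V = L x W^2 / 2 (mm^3); width and length are swapped
    into order when given reversed."""
    if length <= 0 or width <= 0:
        raise ValueError("tumor dimensions must be > 0")
    if width > length:
        length, width = width, length
    return length * width**2 / 2.0
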