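"""Dose-volume histograms and plan-quality metrics.

Metrics follow the conventions of stereotactic plan evaluation:
``VxRx`` is the percent of a structure's volume receiving at least x% of
the prescription dose (V100Rx, V93Rx, V110Rx for targets); ``VxGy`` is
the absolute volume in cm^3 receiving at least x Gy (V55Gy for brain
stem / chiasm / optic nerve, V45Gy for retina / cochlea, V12Gy for
lens).  Threshold comparisons are ">=" throughout.

Dose is sampled trilinearly at the structure grid's voxel centers and
weighted by fractional occupancy — the structure is never resampled onto
the coarser dose grid, which keeps sub-cm^3 organs resolvable.  Metrics
are computed from raw voxel samples, not from binned curves.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grids import VolumeGrid
from .structures import Structure


def _structure_dose_samples(d: VolumeGrid, s: Structure):
    """(dose at occupied voxel centers, occupancy weights)."""
    idx = np.argwhere(s.occupancy > 0)
    if idx.size == 0:
        raise ValueError(f"structure '{s.name}' is empty")
    weights = s.occupancy[tuple(idx.T)].astype(np.float64)
    pts = s.origin + idx * s.spacing
    doses = d.sample(pts, order=1, cval=0.0)
    return doses, weights


@dataclasses.dataclass
class DVHCurve:
    """Cumulative DVH: percent of structure volume receiving >= each dose."""

    bin_edges_gy: np.ndarray
    percent_volume: np.ndarray
    structure_name: str
    total_volume_cm3: float

    def __post_init__(self) -> None:
        assert np.isclose(self.percent_volume[0], 100.0)
        assert np.all(np.diff(self.percent_volume) <= 1e-9)

    def percent_at(self, dose_gy: float) -> float:
        """Percent volume receiving >= dose_gy, at the curve's bin resolution."""
        i = int(np.searchsorted(self.bin_edges_gy, dose_gy, side="left"))
        if i >= len(self.percent_volume):
            return 0.0
        return float(self.percent_volume[i])


def cumulative_dvh(d: VolumeGrid, s: Structure, bin_width_gy: float = 0.1) -> DVHCurve:
    """Occupancy-weighted cumulative DVH of structure ``s`` under dose ``d``."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    doses, weights = _structure_dose_samples(d, s)
    total = weights.sum()
    dmax = float(doses.max())
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    # percent of volume with dose >= edge
    order = np.argsort(doses)
    sorted_d = doses[order]
    csum = np.concatenate([[0.0], np.cumsum(weights[order])])
    below = csum[np.searchsorted(sorted_d, edges, side="left")]
    percent = 100.0 * (total - below) / total
    return DVHCurve(edges, percent, s.name, s.volume_cm3)


@dataclasses.dataclass
class DVHMetrics:
    """Plan-quality metrics for one structure in one scenario."""

    structure_name: str
    scenario: str = "original"
    v100rx_pct: float | None = None
    v93rx_pct: float | None = None
    v110rx_pct: float | None = None
    v_gy_cm3: dict[float, float] = dataclasses.field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"structure": self.structure_name, "scenario": self.scenario,
               "v100rx_pct": self.v100rx_pct, "v93rx_pct": self.v93rx_pct,
               "v110rx_pct": self.v110rx_pct}
        for thr, v in sorted(self.v_gy_cm3.items()):
            row[f"v{thr:g}gy_cm3"] = v
        return row


def v_percent_rx(d: VolumeGrid, s: Structure, pct_of_rx: float, rx_gy: float) -> float:
    """Percent of the structure receiving >= (pct_of_rx/100) * rx_gy."""
    if pct_of_rx <= 0 or rx_gy <= 0:
        raise ValueError("pct_of_rx and rx_gy must be > 0")
    doses, weights = _structure_dose_samples(d, s)
    threshold = pct_of_rx / 100.0 * rx_gy
    return float(100.0 * weights[doses >= threshold].sum() / weights.sum())


def v_abs_gy(d: VolumeGrid, s: Structure, threshold_gy: float) -> float:
    """Absolute volume (cm^3) of the structure receiving >= threshold_gy."""
    doses, weights = _structure_dose_samples(d, s)
    return float(weights[doses >= threshold_gy].sum() * s.voxel_volume_cm3)


def metrics_for_structure(d: VolumeGrid, s: Structure, rx_gy: float,
                          scenario: str = "original",
                          gy_thresholds=()) -> DVHMetrics:
    m = DVHMetrics(structure_name=s.name, scenario=scenario)
    m.v100rx_pct = v_percent_rx(d, s, 100.0, rx_gy)
    m.v93rx_pct = v_percent_rx(d, s, 93.0, rx_gy)
    m.v110rx_pct = v_percent_rx(d, s, 110.0, rx_gy)
    for thr in gy_thresholds:
        m.v_gy_cm3[float(thr)] = v_abs_gy(d, s, float(thr))
    return m


@dataclasses.dataclass
class GoalCheck:
    goal: str
    structure: str
    value: float
    limit: float
    comparison: str  # ">=" or "<="
    passed: bool
    margin: float  # positive = amount of headroom


def check_goals(metrics: dict[str, DVHMetrics], goals) -> list[GoalCheck]:
    """Evaluate coverage goals (PTV) and OAR tolerance-volume limits.

    ``metrics`` maps structure name -> :class:`DVHMetrics`.  A missing
    goal-relevant structure produces an explicit failing entry rather
    than a silent pass.
    """
    ledger: list[GoalCheck] = []

    def coverage(metric_name: str, attr: str, limit: float, ge: bool) -> None:
        if "PTV" not in metrics or getattr(metrics["PTV"], attr) is None:
            ledger.append(GoalCheck(metric_name, "PTV", float("nan"), limit,
                                    ">=" if ge else "<=", False, float("nan")))
            return
        value = getattr(metrics["PTV"], attr)
        margin = (value - limit) if ge else (limit - value)
        ledger.append(GoalCheck(metric_name, "PTV", value, limit,
                                ">=" if ge else "<=", margin >= 0, margin))

    coverage("V100Rx", "v100rx_pct", goals.v100rx_min_pct, ge=True)
    coverage("V93Rx", "v93rx_pct", goals.v93rx_min_pct, ge=True)
    coverage("V110Rx", "v110rx_pct", goals.v110rx_max_pct, ge=False)

    for name, lim in goals.oar_limits.items():
        label = f"V{lim.threshold_gy:g}Gy"
        if name not in metrics or lim.threshold_gy not in metrics[name].v_gy_cm3:
            ledger.append(GoalCheck(label, name, float("nan"), lim.max_cm3,
                                    "<=", False, float("nan")))
            continue
        value = metrics[name].v_gy_cm3[lim.threshold_gy]
        margin = lim.max_cm3 - value
        ledger.append(GoalCheck(label, name, value, lim.max_cm3, "<=",
                                margin >= 0, margin))
    return ledger


def goal_frame(ledger: list[GoalCheck]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(g) for g in ledger])
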