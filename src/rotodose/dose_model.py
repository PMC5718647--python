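"""Analytic conformal dose surrogate for plan-quality studies.

A stand-in for a clinical dose engine: the dose is a function of the
signed Euclidean distance d to the PTV surface,

    D(d) = Rx * max( plateau * Phi((d0 - d) / sigma),  bath(d) )

with Phi the standard normal CDF, ``sigma`` the penumbra scale and
``plateau`` the in-field dose level relative to the prescription Rx
(default 1.004: the plateau sits marginally above Rx so the in-field
region genuinely receives the prescription under ">=" threshold
semantics, while the hot-spot metric V110Rx stays at zero).  The falloff
is anchored so the 95%-of-plateau isodose sits at a fixed physical
standoff ``field_margin_mm`` outside the PTV surface:
steepening the penumbra then pulls the prescription isodose outward
(better coverage) and every OAR-level isodose inward (better sparing)
simultaneously.  ``bath(d)`` is a small exponentially decaying low-dose
bath emulating scatter and beam entrance dose.

The model is homogeneous and beam-free by design: under a rigid
setup-error transform, evaluating the room-fixed dose on the transformed
anatomy is exactly equivalent to recomputing dose with the original
beams on the rotated patient.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import norm

from .grids import VolumeGrid
from .structures import Structure, signed_distance


@dataclasses.dataclass
class OARLimit:
    threshold_gy: float
    max_cm3: float = 0.1


def default_oar_limits() -> dict[str, OARLimit]:
    """Tolerance-volume limits: V55Gy, V45Gy and V12Gy capped at 0.1 cm^3."""
    return {
        "brain_stem": OARLimit(55.0),
        "chiasm": OARLimit(55.0),
        "optic_nerve": OARLimit(55.0),
        "retina": OARLimit(45.0),
        "cochlea": OARLimit(45.0),
        "lens": OARLimit(12.0),
    }


@dataclasses.dataclass
class PlanGoals:
    """Prescription and plan-evaluation goals.

    Coverage goals apply to the PTV: V100Rx >= 95%, V93Rx >= 99%,
    V110Rx <= 20%.  OAR tolerance volumes are limited to 0.1 cm^3.
    """

    prescription_gy: float = 61.2
    fraction_gy: float = 1.8
    v100rx_min_pct: float = 95.0
    v93rx_min_pct: float = 99.0
    v110rx_max_pct: float = 20.0
    oar_limits: dict[str, OARLimit] = dataclasses.field(default_factory=default_oar_limits)

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        for v in (self.v100rx_min_pct, self.v93rx_min_pct, self.v110rx_max_pct):
            if not 0 <= v <= 100:
                raise ValueError("coverage goal percentages must lie in [0, 100]")
        for name, lim in self.oar_limits.items():
            if lim.max_cm3 < 0:
                raise ValueError(f"OAR limit volume for {name} must be >= 0")


class PlanningError(RuntimeError):
    """Raised when the dose surrogate cannot satisfy the plan goals."""


def plan_dose(ptv: Structure, goals: PlanGoals,
              grid_spacing_mm=(2.0, 2.0, 2.0),
              penumbra_sigma_mm: float = 3.0,
              bath_fraction: float = 0.05,
              plateau: float = 1.004,
              field_margin_mm: float = 4.0,
              bath_scale_mm: float = 40.0,
              check: bool = True) -> VolumeGrid:
    """Build a conformal dose grid around the PTV (default 2x2x2 mm).

    The dose covers the PTV's reference-grid field of view.  With
    ``check=True`` the PTV coverage goals (V100Rx/V93Rx/V110Rx) are
    verified on the fresh plan and a :class:`PlanningError` with a
    diagnostic is raised if any fails.
    """
    if penumbra_sigma_mm <= 0:
        raise ValueError("penumbra_sigma_mm must be > 0")
    if float(np.sum(ptv.occupancy)) == 0:
        raise ValueError("PTV is empty")
    dose_spacing = np.asarray(grid_spacing_mm, dtype=float)
    ref_extent = (np.array(ptv.occupancy.shape) - 1) * ptv.spacing
    dose_shape = tuple(int(np.floor(e / s)) + 1 for e, s in zip(ref_extent, dose_spacing))
    dose_origin = ptv.origin.copy()

    # PTV occupancy transported to the dose lattice, then its signed distance
    ax = [dose_origin[k] + np.arange(dose_shape[k]) * dose_spacing[k] for k in range(3)]
    xi, yi, zi = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([xi.ravel(), yi.ravel(), zi.ravel()], axis=1)
    ptv_grid = VolumeGrid(ptv.occupancy, ptv.spacing, ptv.origin)
    occ_on_dose = ptv_grid.sample(pts, order=1).reshape(dose_shape)
    d = signed_distance(occ_on_dose, dose_spacing)

    # anchor: 95%-of-plateau isodose at field_margin_mm outside the PTV
    z_pivot = norm.ppf(0.95)
    d0 = field_margin_mm + z_pivot * penumbra_sigma_mm
    conformal = plateau * norm.cdf((d0 - d) / penumbra_sigma_mm)
    bath = bath_fraction * np.exp(-np.clip(d, 0.0, None) / bath_scale_mm)
    dose = goals.prescription_gy * np.maximum(conformal, bath)
    dose_grid = VolumeGrid(dose.astype(np.float32), dose_spacing, dose_origin)

    if check:
        from .dvh import v_percent_rx

        rx = goals.prescription_gy
        v100 = v_percent_rx(dose_grid, ptv, 100.0, rx)
        v93 = v_percent_rx(dose_grid, ptv, 93.0, rx)
        v110 = v_percent_rx(dose_grid, ptv, 110.0, rx)
        problems = []
        if v100 < goals.v100rx_min_pct:
            problems.append(f"V100Rx={v100:.1f}% < {goals.v100rx_min_pct}%")
        if v93 < goals.v93rx_min_pct:
            problems.append(f"V93Rx={v93:.1f}% < {goals.v93rx_min_pct}%")
        if v110 > goals.v110rx_max_pct:
            problems.append(f"V110Rx={v110:.1f}% > {goals.v110rx_max_pct}%")
        if problems:
            raise PlanningError(
                "plan goals unsatisfiable with these settings: "
                + "; ".join(problems)
                + f" (penumbra_sigma_mm={penumbra_sigma_mm}; try a smaller sigma "
                "or a larger field_margin_mm)")
    return dose_grid


def dose_at(d: VolumeGrid, points: np.ndarray, return_outside_mask: bool = False):
    """Trilinear dose lookup at room-coordinate points (Gy).

    Points outside the dose grid return 0 Gy; a warning is emitted and
    the outside mask is available via ``return_outside_mask``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = d.sample(points, order=1, cval=0.0)
    inside = d.contains(points)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} of {len(points)} query points fall outside the "
            "dose grid; returning 0 Gy there", stacklevel=2)
    if return_outside_mask:
        return values, ~inside
    return values
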