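"""End-to-end rotational setup-error study.

For each phantom: generate anatomy, build a conformal plan, then for
every error scenario (all-axes rotations of +-1, +-3, +-5, +-7 degrees
combined with a 1 mm residual translation on each axis) transform the
image and structures, register the transformed image back to the
original (validation of the transform machinery), tabulate structure
volume changes, and evaluate DVH metrics of the transformed anatomy
against the room-fixed dose.

The dose stays fixed in room coordinates while the anatomy moves: for
the homogeneous analytic dose model this is exactly the "same beams,
dose recomputed on the rotated patient" evaluation.  Everything is
deterministic under a fixed seed; rerunning a study reproduces its CSV
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_model import PlanGoals, plan_dose
from .dvh import DVHMetrics, metrics_for_structure
from .phantom import AIR_HU, PhantomSpec, make_head_phantom
from .registration import (RecoveryReport, recovery_error, recovery_frame,
                           register_rigid)
from .rigid_transform import RigidTransform, resample_volume, transform_structure
from .structures import StructureSet, reports_to_frame, volume_difference_table

logger = logging.getLogger("rotodose")

ZERO_LABEL = "0deg/0mm"


@dataclasses.dataclass
class StudyConfig:
    """Configuration of one rotation study."""

    phantoms: list[PhantomSpec] = dataclasses.field(
        default_factory=lambda: [PhantomSpec()])
    angles_deg: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    signs: tuple[int, ...] = (1, -1)
    translation_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    goals: PlanGoals = dataclasses.field(default_factory=PlanGoals)
    penumbra_sigma_mm: float = 3.0
    bath_fraction: float = 0.05
    dose_grid_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    register: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.angles_deg:
            raise ValueError("scenario angle set must be non-empty")
        if any(abs(a) > 30 for a in self.angles_deg):
            raise ValueError("angles must stay within the +-30 deg operating range")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        if "phantoms" in raw:
            raw["phantoms"] = [PhantomSpec.from_dict(p) for p in raw["phantoms"]]
        if "goals" in raw and isinstance(raw["goals"], dict):
            from .dose_model import OARLimit

            goals = dict(raw["goals"])
            if "oar_limits" in goals:
                goals["oar_limits"] = {
                    name: lim if isinstance(lim, OARLimit) else OARLimit(**lim)
                    for name, lim in goals["oar_limits"].items()}
            raw["goals"] = PlanGoals(**goals)
        for key in ("angles_deg", "signs", "translation_mm", "dose_grid_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def build_scenarios(config: StudyConfig, isocenter) -> list[tuple[str, RigidTransform]]:
    """The error-scenario transforms: one per (magnitude, sign), all axes equal.

    Default: 4 magnitudes x 2 signs = 8 transforms, each with the same
    residual translation.  The zero scenario is handled separately.
    """
    scenarios = []
    for mag in config.angles_deg:
        if mag == 0:
            continue
        for sign in config.signs:
            a = sign * mag
            label = f"{a:+g}deg/{np.max(np.abs(config.translation_mm)):g}mm"
            scenarios.append((label, RigidTransform.from_angles(
                a, a, a, config.translation_mm, isocenter)))
    return scenarios


@dataclasses.dataclass
class ScenarioResult:
    phantom_index: int
    label: str
    transform: RigidTransform | None
    metrics: dict[str, DVHMetrics]
    volume_reports: list = dataclasses.field(default_factory=list)
    recovery: RecoveryReport | None = None
    failed: bool = False
    error: str = ""


@dataclasses.dataclass
class StudyReport:
    config: StudyConfig
    results: list[ScenarioResult]
    coverage: pd.DataFrame
    oar_doses: pd.DataFrame
    volume_differences: pd.DataFrame
    registration: pd.DataFrame

    @property
    def n_failed(self) -> int:
        return sum(r.failed for r in self.results)


def _scenario_metrics(dose, structures: StructureSet, goals: PlanGoals,
                      label: str) -> dict[str, DVHMetrics]:
    out = {}
    for s in structures:
        thresholds = ()
        if s.name in goals.oar_limits:
            thresholds = (goals.oar_limits[s.name].threshold_gy,)
        out[s.name] = metrics_for_structure(dose, s, goals.prescription_gy,
                                            scenario=label, gy_thresholds=thresholds)
    return out


def run_rotation_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Run the full study; optionally write report tables to ``outdir``."""
    results: list[ScenarioResult] = []
    reg_reports: list[RecoveryReport] = []
    reg_labels: list[str] = []

    for pi, spec in enumerate(config.phantoms):
        logger.info("phantom %d: generating (seed=%d)", pi, spec.seed)
        image, structures, isocenter = make_head_phantom(spec)
        dose = plan_dose(structures["PTV"], config.goals,
                         grid_spacing_mm=config.dose_grid_mm,
                         penumbra_sigma_mm=config.penumbra_sigma_mm,
                         bath_fraction=config.bath_fraction)
        results.append(ScenarioResult(
            phantom_index=pi, label=ZERO_LABEL, transform=None,
            metrics=_scenario_metrics(dose, structures, config.goals, ZERO_LABEL),
            volume_reports=volume_difference_table(structures, structures)))

        for label, t in build_scenarios(config, isocenter):
            logger.info("phantom %d: scenario %s", pi, label)
            try:
                moved = StructureSet([transform_structure(s, t) for s in structures])
                recovery = None
                if config.register:
                    moving_image = resample_volume(image, t, background=AIR_HU)
                    reg = register_rigid(image, moving_image, isocenter)
                    recovery = recovery_error(t, reg.transform, reg.converged,
                                              reg.final_metric)
                    reg_reports.append(recovery)
                    reg_labels.append(f"p{pi}/{label}")
                    if not reg.converged:
                        logger.warning("phantom %d %s: registration did not improve "
                                       "the metric", pi, label)
                results.append(ScenarioResult(
                    phantom_index=pi, label=label, transform=t,
                    metrics=_scenario_metrics(dose, moved, config.goals, label),
                    volume_reports=volume_difference_table(structures, moved),
                    recovery=recovery))
            except Exception as exc:  # pragma: no cover - defensive path
                logger.exception("phantom %d scenario %s failed", pi, label)
                results.append(ScenarioResult(
                    phantom_index=pi, label=label, transform=t, metrics={},
                    failed=True, error=str(exc)))

    coverage_rows, oar_rows, vol_rows = [], [], []
    for r in results:
        if r.failed:
            continue
        for name, m in r.metrics.items():
            base = {"phantom": r.phantom_index, "scenario": r.label, "structure": name}
            if name in ("CTV", "PTV"):
                coverage_rows.append({**base, "v100rx_pct": m.v100rx_pct,
                                      "v93rx_pct": m.v93rx_pct,
                                      "v110rx_pct": m.v110rx_pct})
            for thr, v in m.v_gy_cm3.items():
                oar_rows.append({**base, "threshold_gy": thr, "v_cm3": v})
        for row in r.volume_reports:
            vol_rows.append({"phantom": r.phantom_index, "scenario": r.label,
                             "structure": row.name,
                             "original_cm3": row.original_cm3,
                             "transformed_cm3": row.transformed_cm3,
                             "abs_diff_cm3": row.absolute_difference_cm3,
                             "pct_diff": row.percent_difference})

    report = StudyReport(
        config=config, results=results,
        coverage=pd.DataFrame(coverage_rows),
        oar_doses=pd.DataFrame(oar_rows),
        volume_differences=pd.DataFrame(vol_rows),
        registration=recovery_frame(reg_reports, reg_labels),
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: StudyReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format="%.6f")
    report.coverage.to_csv(outdir / "target_coverage.csv", **kw)
    report.oar_doses.to_csv(outdir / "oar_tolerance_volumes.csv", **kw)
    report.volume_differences.to_csv(outdir / "volume_differences.csv", **kw)
    report.registration.to_csv(outdir / "registration_recovery.csv", **kw)
    summarize(report.coverage, report.oar_doses).to_csv(outdir / "summary.csv", **kw)
    manifest = {
        "package_version": __version__,
        "config": report.config.to_dict(),
        "config_hash": report.config.content_hash(),
        "n_results": len(report.results),
        "n_failed": report.n_failed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _scenario_sort_key(label: str):
    if label == ZERO_LABEL:
        return (0.0, 0)
    mag = abs(float(label.split("deg")[0]))
    sign = 0 if label.startswith("+") else 1
    return (mag, sign)


def summarize(coverage: pd.DataFrame, oar_doses: pd.DataFrame | None = None,
              coverage_floor_pct: float = 95.0,
              oar_limit_cm3: float = 0.1) -> pd.DataFrame:
    """Per-scenario mean +- SD of target coverage across phantoms.

    SD is the population-style sample SD (ddof=1 when n > 1, else 0).
    Rows are flagged when mean CTV V100Rx falls below the coverage floor
    or any OAR tolerance volume exceeds its limit.
    """
    if coverage.empty:
        raise ValueError("no coverage rows to summarize")
    rows = []
    for label, grp in coverage.groupby("scenario", sort=False):
        row = {"scenario": label}
        for structure in ("CTV", "PTV"):
            sub = grp[grp.structure == structure]
            for col in ("v100rx_pct", "v93rx_pct", "v110rx_pct"):
                vals = sub[col].to_numpy(dtype=float)
                if vals.size:
                    row[f"{structure.lower()}_{col}_mean"] = float(vals.mean())
                    row[f"{structure.lower()}_{col}_sd"] = (
                        float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        breach = bool(row.get("ctv_v100rx_pct_mean", 100.0) < coverage_floor_pct)
        if oar_doses is not None and not oar_doses.empty:
            sub = oar_doses[oar_doses.scenario == label]
            breach = breach or bool((sub.v_cm3 > oar_limit_cm3).any())
        row["goal_breach"] = breach
        rows.append(row)
    rows.sort(key=lambda r: _scenario_sort_key(r["scenario"]))
    return pd.DataFrame(rows)
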