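"""Seedable digital head phantoms for setup-error studies.

The generator emulates the geometry of an intracranial stereotactic
radiotherapy population: an ellipsoidal head (air / soft tissue / skull
shell, so intensity-based registration has gradients to work with), a
CTV of class sphere / ellipse / irregular grown to a requested PTV
volume through a uniform 3 mm margin, and schematically placed organs at
risk with clinically scaled volumes (brain stem ~27.6 cm^3 down to
cochlea ~0.08 cm^3).  Default acquisition grid: 0.98 x 0.98 mm in-plane,
2 mm slice spacing along the longitudinal axis.

Everything is deterministic given the spec seed: the same
:class:`PhantomSpec` always yields byte-identical volumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import sph_harm_y

from .grids import AXIS_LABELS, VolumeGrid
from .structures import Structure, StructureSet, expand_margin, trim_overlap, volume

AIR_HU = -1000.0
BRAIN_HU = 40.0
BONE_HU = 700.0

# Mean volume (cm^3), volume SD, unit placement direction from the PTV,
# semi-axis ratios and PTV-surface standoff for the schematic OAR roster.
# Volumes follow the clinical means for this anatomy; directions are
# schematic, not atlas-based.  Default standoffs scale inversely with each
# organ's dose tolerance (the lens, limited at 12 Gy, sits farthest from
# the target), so a default plan can respect every tolerance volume.
DEFAULT_OARS: dict[str, dict] = {
    "brain_stem": {"volume": 27.6, "sd": 3.4, "direction": (0.0, -0.55, -0.835),
                   "ratios": (0.62, 1.55, 0.62), "standoff_mm": 10.0},
    "chiasm": {"volume": 0.6, "sd": 0.2, "direction": (0.0, -0.3, 0.954),
               "ratios": (1.4, 0.85, 0.85), "standoff_mm": 6.0},
    "optic_nerve": {"volume": 1.0, "sd": 0.3, "direction": (0.35, -0.2, 0.91),
                    "ratios": (0.7, 0.7, 2.0), "standoff_mm": 6.0},
    "retina": {"volume": 5.5, "sd": 0.9, "direction": (-0.55, -0.25, 0.8),
               "ratios": (1.25, 1.25, 0.64), "standoff_mm": 9.0},
    "lens": {"volume": 0.3, "sd": 0.1, "direction": (-0.6, -0.3, 0.74),
             "ratios": (1.2, 1.2, 0.69), "standoff_mm": 14.0},
    "cochlea": {"volume": 0.08, "sd": 0.02, "direction": (0.92, -0.3, -0.25),
                "ratios": (1.0, 1.0, 1.0), "standoff_mm": 9.0},
}

PTV_VOLUME_RANGE_CM3 = (90.4, 376.5)
PTV_DIMENSION_RANGE_CM = (7.2, 12.1)


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic head phantom.

    ``grid_shape``/``spacing`` default to the acquisition profile
    (0.98, 2.0, 0.98) mm in (x, y, z) order — 2 mm axial slices along
    the longitudinal axis.  Use :meth:`fast` for the coarse 2 mm CI
    profile.
    """

    grid_shape: tuple[int, int, int] = (256, 90, 256)
    spacing: tuple[float, float, float] = (0.98, 2.0, 0.98)
    ptv_volume_cm3: float = 232.5
    shape_class: str = "sphere"
    largest_dimension_cm: float | None = None
    margin_mm: float = 3.0
    isocenter_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # supratentorial target: superior-anterior of the head center, which is
    # where the schematic brainstem/orbit roster leaves room for the PTV
    ctv_offset_mm: tuple[float, float, float] = (0.0, 12.0, 14.0)
    # clearly triaxial (narrower laterally than antero-posteriorly, like a
    # real skull): every rotation axis then has strong intensity gradients
    head_semiaxes_mm: tuple[float, float, float] = (70.0, 86.0, 100.0)
    oars: dict[str, dict] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OARS.items()})
    oar_standoff_mm: float = 5.0
    irregular_amplitude: float = 0.25
    ellipse_ratio_range: tuple[float, float] = (1.25, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        # canonical nested types so specs compare equal across (de)serialization
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        for key in ("spacing", "isocenter_offset_mm", "ctv_offset_mm",
                    "head_semiaxes_mm", "ellipse_ratio_range"):
            setattr(self, key, tuple(float(v) for v in getattr(self, key)))
        if self.largest_dimension_cm is not None:
            self.largest_dimension_cm = float(self.largest_dimension_cm)
        self.oars = {
            name: {k: (tuple(float(x) for x in v) if isinstance(v, (list, tuple))
                       else float(v))
                   for k, v in entry.items()}
            for name, entry in self.oars.items()}
        lo, hi = PTV_VOLUME_RANGE_CM3
        if not (0.5 * lo <= self.ptv_volume_cm3 <= 1.5 * hi):
            raise ValueError(
                f"requested PTV volume {self.ptv_volume_cm3} cm^3 is outside the "
                f"generator's feasible range [{0.5 * lo:.0f}, {1.5 * hi:.0f}]")

    @classmethod
    def fast(cls, **overrides) -> "PhantomSpec":
        """Coarse 2 mm isotropic profile for quick tests."""
        defaults = dict(grid_shape=(112, 90, 112), spacing=(2.0, 2.0, 2.0))
        defaults.update(overrides)
        return cls(**defaults)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "spacing", "isocenter_offset_mm", "ctv_offset_mm",
                    "head_semiaxes_mm", "ellipse_ratio_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# radial shape machinery


def _random_band_limited(rng: np.random.Generator, lmax: int = 4):
    """A smooth random function on the unit sphere, max amplitude ~1.

    Built from real combinations of spherical harmonics of degree
    2..lmax with seeded Gaussian coefficients (degree-0/1 terms are
    excluded so the perturbation neither rescales nor re-centers the
    shape).
    """
    coeffs = []
    for ell in range(2, lmax + 1):
        for m in range(-ell, ell + 1):
            coeffs.append((ell, m, rng.normal(0.0, 1.0 / (1 + ell))))

    def f(ux, uy, uz):
        theta = np.arccos(np.clip(uz, -1.0, 1.0))
        phi = np.arctan2(uy, ux)
        total = np.zeros_like(theta)
        for ell, m, c in coeffs:
            y = sph_harm_y(ell, abs(m), theta, phi)
            total = total + c * (np.sqrt(2) * y.imag if m < 0
                                 else y.real if m == 0 else np.sqrt(2) * y.real)
        scale = np.max(np.abs(total))
        return total / scale if scale > 0 else total

    return f


def _radius_fn(shape_class: str, ratios, perturbation=None, amplitude: float = 0.0):
    """Directional boundary radius R(u) of a unit-scale star-shaped body."""
    a, b, c = ratios

    def r_ell(ux, uy, uz):
        return 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)

    if shape_class in ("sphere", "ellipse"):
        return r_ell
    if shape_class == "irregular":
        def r_irr(ux, uy, uz):
            return r_ell(ux, uy, uz) * (1.0 + amplitude * perturbation(ux, uy, uz))
        return r_irr
    raise ValueError(f"unknown shape class {shape_class!r}")


def _rasterize_radial(radius_fn, scale_mm: float, center_mm, spacing, shape, origin,
                      max_radius_mm: float) -> np.ndarray:
    """Fractional occupancy of a star-shaped body r(u) = scale * R(u).

    Partial-volume weighting: a smooth one-voxel-wide edge via a linear
    ramp of the approximate radial signed distance.
    """
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    center_mm = np.asarray(center_mm, dtype=float)
    occ = np.zeros(shape, dtype=np.float32)
    pad = max_radius_mm + 3.0 * float(spacing.max())
    lo = np.maximum(np.floor((center_mm - pad - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + pad - origin) / spacing).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        raise ValueError("structure lies outside the grid")
    ax = [origin[k] + np.arange(lo[k], hi[k]) * spacing[k] - center_mm[k] for k in range(3)]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij", sparse=True)
    rho = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    rho_safe = np.where(rho == 0, 1.0, rho)
    ux, uy, uz = dx / rho_safe, dy / rho_safe, dz / rho_safe
    r_boundary = scale_mm * radius_fn(ux, uy, uz)
    # edge width: voxel extent along the radial direction
    h = np.sqrt((spacing[0] * ux) ** 2 + (spacing[1] * uy) ** 2 + (spacing[2] * uz) ** 2)
    h = np.where(h == 0, float(spacing.mean()), h)
    block = np.clip((r_boundary - rho) / h + 0.5, 0.0, 1.0)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = block
    return occ


def make_structure(shape: str, volume_cm3: float, seed: int,
                   spacing=(0.98, 2.0, 0.98), grid_shape=(256, 90, 256),
                   origin=(0.0, 0.0, 0.0), center_mm=None,
                   name: str = "structure", role: str = "CTV",
                   ratios=None, largest_dimension_cm: float | None = None,
                   irregular_amplitude: float = 0.25,
                   ellipse_ratio_range=(1.25, 1.6),
                   volume_tolerance: float = 0.02) -> Structure:
    """Generate a structure of a given shape class and volume.

    The achieved fractional-occupancy volume is within
    ``volume_tolerance`` (default 2%) of the request; the rasterized
    shape is rescaled against its measured volume until it converges.
    Deterministic given ``seed``.
    """
    if volume_cm3 <= 0:
        raise ValueError("volume_cm3 must be > 0")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing, dtype=float)
    grid_shape = tuple(int(n) for n in grid_shape)
    origin = np.asarray(origin, dtype=float)
    if center_mm is None:
        center_mm = origin + (np.array(grid_shape) - 1) / 2.0 * spacing

    r_eq = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    if ratios is None:
        if shape == "sphere":
            ratios = (1.0, 1.0, 1.0)
        else:
            if largest_dimension_cm is not None:
                u = largest_dimension_cm * 10.0 / (2.0 * r_eq)
                if u < 1.0:
                    raise ValueError(
                        "largest_dimension_cm smaller than the volume-equivalent diameter")
            else:
                u = rng.uniform(*ellipse_ratio_range)
            ratios = (u, 1.0, 1.0 / u)  # volume-preserving anisotropy
    perturbation = _random_band_limited(rng) if shape == "irregular" else None
    radius = _radius_fn(shape, ratios, perturbation, irregular_amplitude)

    scale = r_eq
    occ = None
    for _ in range(5):
        max_r = scale * max(ratios) * (1.0 + (irregular_amplitude if shape == "irregular" else 0.0))
        occ = _rasterize_radial(radius, scale, center_mm, spacing, grid_shape, origin, max_r)
        achieved = float(occ.sum(dtype=np.float64)) * float(np.prod(spacing)) / 1000.0
        if achieved <= 0:
            raise ValueError("requested volume is infeasible on this grid")
        if abs(achieved / volume_cm3 - 1.0) <= 0.25 * volume_tolerance:
            break
        scale *= (volume_cm3 / achieved) ** (1.0 / 3.0)
    achieved = float(occ.sum(dtype=np.float64)) * float(np.prod(spacing)) / 1000.0
    if abs(achieved / volume_cm3 - 1.0) > volume_tolerance:
        raise ValueError(
            f"could not realize {volume_cm3} cm^3 on this grid (got {achieved:.2f})")
    return Structure(name=name, role=role, shape_class=shape, occupancy=occ,
                     spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# head phantom


def _support_mm(occ: np.ndarray, spacing, origin, center_mm, direction) -> float:
    """Extent of a structure from ``center_mm`` along ``direction`` (mm)."""
    idx = np.argwhere(occ >= 0.5)
    pts = np.asarray(origin) + idx * np.asarray(spacing) - np.asarray(center_mm)
    return float(np.max(pts @ np.asarray(direction)))


def _smooth_ellipsoid_occ(grids, center, semiaxes, edge_mm: float = 1.5) -> np.ndarray:
    """Fractional occupancy of an ellipsoid with a smooth ~edge_mm boundary.

    The boundary along a ray at radius rho with normalized quadratic form
    q lies at rho/q, so rho*(1 - 1/q) approximates the radial signed
    distance (negative inside).
    """
    x, y, z = grids
    rho = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    q = np.sqrt(((x - center[0]) / semiaxes[0]) ** 2
                + ((y - center[1]) / semiaxes[1]) ** 2
                + ((z - center[2]) / semiaxes[2]) ** 2)
    d_mm = rho * (1.0 - 1.0 / np.maximum(q, 1e-9))
    return np.clip(0.5 - d_mm / edge_mm, 0.0, 1.0)


def make_head_phantom(spec: PhantomSpec):
    """Build (image, structures, isocenter) for one synthetic head.

    Returns a CT-like :class:`VolumeGrid`, a :class:`StructureSet`
    containing CTV, PTV (3 mm uniform expansion, overlap-trimmed against
    the OARs) and the configured OAR roster, and the isocenter (PTV
    centroid plus the configured offset) in room coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = tuple(spec.grid_shape)
    origin = np.zeros(3)
    head_center = origin + (np.array(shape) - 1) / 2.0 * spacing
    semi = np.asarray(spec.head_semiaxes_mm, dtype=float)

    ax = [origin[k] + np.arange(shape[k]) * spacing[k] for k in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)

    occ_outer = _smooth_ellipsoid_occ((x, y, z), head_center, semi)
    occ_inner = _smooth_ellipsoid_occ((x, y, z), head_center, semi * 0.93)
    image = AIR_HU + occ_outer * (BONE_HU - AIR_HU) + occ_inner * (BRAIN_HU - BONE_HU)
    image = image.astype(np.float32)

    # Frontal-sinus-like air pocket: a fixed high-contrast asymmetric feature
    # (air against bone/tissue) that conditions pitch and yaw recovery the
    # way real skull anatomy does.
    sinus_center = head_center + np.array([12.0, -40.0, 0.72 * semi[2]])
    sinus = _smooth_ellipsoid_occ((x, y, z), sinus_center, (14.0, 12.0, 10.0), edge_mm=2.0)
    image += ((AIR_HU - BONE_HU) * sinus * occ_outer).astype(np.float32)

    # Seeded internal texture blobs: break the near-symmetry of the head so
    # every rotation axis is well conditioned for intensity registration.
    n_blobs = 6
    for _ in range(n_blobs):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radial = rng.uniform(0.25, 0.7)
        center = head_center + direction * radial * semi * 0.93
        axes = rng.uniform(6.0, 16.0, size=3)
        contrast = rng.uniform(-35.0, 35.0)
        blob = _smooth_ellipsoid_occ((x, y, z), center, axes, edge_mm=3.0)
        image += (contrast * blob * occ_inner).astype(np.float32)

    # CTV sized so that the 3 mm expansion hits the requested PTV volume
    ctv_center = head_center + np.asarray(spec.ctv_offset_mm, dtype=float)
    r_ptv = (3.0 * spec.ptv_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ctv_seed = int(rng.integers(0, 2 ** 31 - 1))
    ctv_volume_guess = spec.ptv_volume_cm3 * ((r_ptv - spec.margin_mm) / r_ptv) ** 3
    ctv = ptv = None
    guess = ctv_volume_guess
    for _ in range(4):
        ctv = make_structure(
            spec.shape_class, guess, ctv_seed, spacing=spacing, grid_shape=shape,
            origin=origin, center_mm=ctv_center, name="CTV", role="CTV",
            largest_dimension_cm=(None if spec.largest_dimension_cm is None else
                                  spec.largest_dimension_cm - 2 * spec.margin_mm / 10.0),
            irregular_amplitude=spec.irregular_amplitude,
            ellipse_ratio_range=spec.ellipse_ratio_range)
        ptv = expand_margin(ctv, spec.margin_mm, name="PTV", role="PTV")
        ptv.shape_class = spec.shape_class
        achieved = volume(ptv)
        if abs(achieved / spec.ptv_volume_cm3 - 1.0) <= 0.02:
            break
        r_t = (3.0 * spec.ptv_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
        r_a = (3.0 * achieved * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
        r_c = (3.0 * guess * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
        guess = 4.0 / 3.0 * np.pi * (r_c + (r_t - r_a)) ** 3 / 1000.0

    ptv_centroid = ptv.centroid()

    # OARs placed at a configurable standoff from the PTV surface
    oars = []
    for name, entry in spec.oars.items():
        vol = float(np.clip(rng.normal(entry["volume"], entry.get("sd", 0.0)),
                            0.5 * entry["volume"], 1.5 * entry["volume"]))
        direction = np.asarray(entry["direction"], dtype=float)
        direction = direction / np.linalg.norm(direction)
        ratios = tuple(entry.get("ratios", (1.0, 1.0, 1.0)))
        r_eq = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        # boundary radius of the unit-scale ellipsoid along the placement ray
        extent = r_eq / np.sqrt((direction[0] / ratios[0]) ** 2
                                + (direction[1] / ratios[1]) ** 2
                                + (direction[2] / ratios[2]) ** 2)
        ptv_support = _support_mm(ptv.occupancy, spacing, origin, ptv_centroid, direction)
        standoff = float(entry.get("standoff_mm", spec.oar_standoff_mm))
        oar_seed = int(rng.integers(0, 2 ** 31 - 1))
        inside = occ_outer >= 0.5
        distance = ptv_support + standoff + extent
        # structures may abut the skull shell but must not leave the head
        # into background air; if the nominal standoff does not fit (large
        # targets push eye-region organs against the skull) the organ is
        # walked inward, which is also what large tumors do anatomically
        min_distance = ptv_support + extent + 1.0
        oar = None
        while True:
            candidate = make_structure(
                "ellipse", vol, oar_seed, spacing=spacing, grid_shape=shape,
                origin=origin, center_mm=ptv_centroid + direction * distance,
                name=name, role="OAR", ratios=ratios)
            outside_mass = float(np.sum(candidate.occupancy * ~inside))
            if outside_mass <= 0.02 * float(np.sum(candidate.occupancy)):
                oar = candidate
                break
            if distance - 1.0 < min_distance:
                raise ValueError(
                    f"OAR '{name}' collides with the head boundary "
                    f"({100 * outside_mass / float(np.sum(candidate.occupancy)):.1f}% "
                    "outside) and cannot be placed nearer the target")
            distance -= 1.0
        oar.shape_class = "ellipse"
        oars.append(oar)

    ptv = trim_overlap(ptv, oars)
    # CTV contrast so the target itself contributes registration gradients
    image += (25.0 * ctv.occupancy).astype(np.float32)

    structures = StructureSet([ctv, ptv, *oars])
    isocenter = ptv_centroid + np.asarray(spec.isocenter_offset_mm, dtype=float)
    grid = VolumeGrid(image, spacing, origin, AXIS_LABELS)
    return grid, structures, isocenter
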