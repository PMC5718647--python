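# Methods

This note records the models, conventions and numerical choices behind
`rotodose`, and what the synthetic experiments do and do not demonstrate.

## Coordinate conventions and the rigid-transform model

Room coordinates are in mm with IEC 61217-style patient axes: x lateral
(left–right), y longitudinal (inferior–superior), z vertical
(posterior–anterior). Volumes are stored on regular axis-aligned lattices
with the voxel-center convention `p = origin + index · spacing` and 0-based
indices. Axial CT slices are perpendicular to the longitudinal axis, so the
default acquisition profile has spacing (0.98, 2.0, 0.98) mm in (x, y, z)
order.

A systematic setup error is an isocentric rigid map

    p' = R (p − c) + c + T,    R = R_pitch(x) · R_roll(y) · R_yaw(z),

with extrinsic rotations about the fixed room axes, composed in the written
order, right-hand rule for positive angles. The equivalent row-vector
formulation (`p' = p Rᵀ`) is the transpose of the same composed matrix; the
tests assert both readings agree. Angle extraction from a matrix uses the
same pitch–roll–yaw factorization; the gimbal-adjacent regime (|roll| near
90°) is rejected — the study's operating range is ±7°, and registration
inputs are restricted to ±30°.

Volume resampling uses inverse mapping onto the original lattice
(`scipy.ndimage.affine_transform`): trilinear interpolation for images,
dose and fractional structures, nearest-neighbour available for label maps.
Background fill is the CT air value (−1000 HU) for images and 0 for
structures and dose.

**Why fractional occupancy.** Structures are carried as fractional-occupancy
fields and transported with trilinear interpolation, never re-binarized.
Volume is the occupancy-weighted voxel sum. This is what makes sub-percent
volume-preservation checks meaningful: binary nearest-neighbour masks
fluctuate by several percent per rotation for sub-cm³ organs (cochlea
≈ 0.08 cm³), whereas interpolated occupancy keeps the worst-case change
within 0.5% for targets, 2% for OARs above 1 cm³ and 5% below.
Binarization at 0.5 is used only for display and distance computations.

## Digital head phantom

The generator emulates the geometry of an intracranial SRT population, not
patient-realistic anatomy:

- **Head:** a triaxial ellipsoid (default semi-axes 70 × 86 × 100 mm) of
  soft tissue (40 HU) with a skull shell (outer 7% of each semi-axis,
  700 HU) in an air background, plus a frontal-sinus-like air pocket and
  six seeded low-contrast texture blobs. The deliberate triaxiality and the
  sinus guarantee that *every* rotation axis has strong intensity
  gradients; a more symmetric head leaves roll/pitch ill-conditioned for
  intensity registration (observed directly during development: a 78 vs
  80 mm axis pair produced multi-degree recovery errors).
- **Targets:** the CTV is a sphere, ellipsoid, or "irregular" body —
  star-shaped with a band-limited random radial modulation built from
  degree-2..4 spherical harmonics, default amplitude 25% (irregularity is
  nowhere quantified clinically; the amplitude is a config knob). Requested
  volumes are realized within 2% by rescaling the shape against its
  measured fractional-occupancy volume. The PTV is the CTV plus a uniform
  3 mm Euclidean margin, then overlap-trimmed against the OARs. Default PTV
  volume 232.5 cm³ (population mean; feasible range spans the clinical
  90.4–376.5 cm³).
- **OARs:** six organs at clinical mean volumes (brain stem 27.6, retina
  5.5, optic nerve 1.0, chiasm 0.6, lens 0.3, cochlea 0.08 cm³) with
  per-seed volume jitter at clinical SDs. Placement is schematic — each
  organ sits along a fixed anatomically-motivated direction at a
  configurable standoff from the PTV surface. Default standoffs scale
  inversely with each organ's dose tolerance (brain stem 10 mm, lens 14 mm)
  so that a default plan meets all tolerance-volume limits; *proximity is
  the experimental knob* for studying OAR dose sensitivity, since OARs in
  the penumbra are where small rotations matter.
- **Determinism:** everything derives from one `numpy` generator seeded by
  the spec; identical specs give byte-identical volumes.

A coarse profile (2 mm isotropic, 112 × 90 × 112) is provided for fast
iteration; resolution-sensitive results quoted by the package use the
acquisition profile.

## Dose surrogate

No beams, fluence or heterogeneity are modelled. The dose is an analytic
function of the signed Euclidean distance `d` to the PTV surface
(negative inside), computed on a 2 × 2 × 2 mm grid:

    D(d) = Rx · max( plateau · Φ((d₀ − d)/σ),  b · e^{−max(d,0)/λ} )

- `Rx` = 61.2 Gy prescription (1.8 Gy × 34 fractions).
- `plateau` = 1.004: the in-field dose sits marginally above Rx so the
  plateau genuinely receives the prescription under "≥" threshold
  semantics while the hot-spot metric V110Rx is exactly zero.
- `σ` = 3 mm penumbra scale (realistic 80%–20% falloff of ≈ 5 mm).
- `d₀ = m + z₀.₉₅ σ` anchors the **95%-of-plateau isodose** at a fixed
  standoff `m` = 4 mm outside the PTV. This pivot level lies strictly
  between the prescription level and the highest OAR tolerance (55 Gy =
  89.9% of Rx), so sharpening the penumbra simultaneously pulls the Rx
  isodose outward (coverage cannot degrade) and every OAR-level isodose
  inward (sparing cannot degrade) — both sensitivities are monotone, which
  the tests assert. With the defaults the Rx isodose sits ≈ 1 mm outside
  the PTV: combined with the 3 mm CTV→PTV margin, the CTV has ≈ 4 mm of
  dosimetric headroom, which is exactly the margin logic the error
  scenarios probe.
- `b` = 0.05 low-dose bath with λ = 40 mm decay, standing in for scatter
  and entrance dose; the `max` keeps the profile monotone along any
  outward ray.

`plan_dose` verifies the coverage goals (V100Rx ≥ 95%, V93Rx ≥ 99%,
V110Rx ≤ 20%) on the fresh plan and raises with a diagnostic if they are
unsatisfiable for the chosen σ.

**The central modelling substitution.** Error scenarios are evaluated with
the dose *fixed in room coordinates* (anchored to the beams) while the
anatomy moves. For a homogeneous, beam-free analytic dose this is exactly
equivalent to re-computing dose with the original beams on the rotated
patient — the equivalence a TPS-based workflow obtains by re-calculation.
It is also the main limitation: effects that depend on beam path length,
heterogeneity or fluence structure are outside this model, so absolute
coverage losses here are milder than clinical per-case values and only the
qualitative orderings (angle monotonicity, shape/isocenter sensitivity,
V93 vs V100 asymmetry) transfer.

## DVH conventions

Dose is sampled trilinearly at the *structure grid's* voxel centers and
weighted by fractional occupancy; the structure is never resampled onto
the coarser dose grid, which keeps 0.08 cm³ organs resolvable. Threshold
comparisons are "≥" throughout, for VxRx and VxGy alike. Metrics are
computed from raw voxel samples, not binned curves (default curve bin
0.1 Gy is for plotting/reporting only). Points outside the dose grid
evaluate to 0 Gy with a warning.

## Registration validation

Rotated images are registered back to their originals with SimpleITK's
multi-resolution framework: mean-squared-difference metric (same-modality
synthetic CT; a mutual-information switch exists), dense deterministic
sampling, Euler3D transform centered at the declared isocenter (matching
the simulation, not the image center), regular-step gradient descent
(learning rate 2.0, relaxation 0.6, 150 iterations) over a 2-level
shrink 4/2 pyramid with 4/2 mm smoothing. The recovered matrix is
decomposed with the package's own pitch–roll–yaw factorization, so no ITK
Euler-convention coupling enters the comparison. The residual
`estimated ∘ applied⁻¹` yields per-axis rotational errors (its Euler
angles) and translational errors (its displacement of the isocenter).
"Converged" means the optimum improved on the starting metric value — the
regular-step optimizer routinely spends its full iteration budget after
reaching the optimum, so the stop condition alone is not informative.

On the 2 mm profile this recovers all sixteen study transforms (two
phantoms × eight errors) within 0.25° and 0.1 mm per axis, comfortably
inside the 0.4° / 0.8 mm acceptance bounds.

## Error scenarios and reporting

A scenario applies the same signed angle to all three axes (`±1°, ±3°,
±5°, ±7°`) plus a (+1, +1, +1) mm residual translation — eight perturbed
geometries per phantom plus the zero scenario. The equal-sign convention
and the fixed translation direction are declared choices (a full-factorial
sign mode and translation override exist in `StudyConfig`). The study
runner emits four CSV tables (registration recovery, volume differences,
target coverage, OAR tolerance volumes), a per-scenario mean ± SD summary
with goal-breach flags (coverage < 95%, OAR > 0.1 cm³), and a manifest
with the config hash. Reruns with the same config are byte-identical.

## Problem sizes used in the shipped experiments

Registration validation runs on the 2 mm fast profile (two phantoms,
sixteen registrations); volume-preservation and planning-goal checks run
on the acquisition profile (0.98 × 0.98 × 2 mm). The acceptance script
uses three phantoms spanning 90–377 cm³ for the volume tiers and a single
~220 cm³ spherical-target phantom for the margin-robustness scenario.

## Known limitations

- Anatomy is schematic: no patient-realistic shapes, no MR simulation, no
  CT artifacts; OAR placement is directional, not atlas-based.
- The dose surrogate has no beams; non-coplanar-beam OAR avoidance is
  emulated only by the smallness of the bath term.
- Deformable motion, couch/gantry kinematic emulation, and margin-recipe
  derivation are out of scope.
- Structure representation is voxelized fractional occupancy; polygon
  contours (DICOM RT-STRUCT) are a documented extension point.
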