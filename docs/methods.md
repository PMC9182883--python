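# Methods

This note documents the measurement models, algorithms, parameter
choices and known limitations of `olivemorph`. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from external measurements.

## Mesh model and units

A sample is a closed, consistently oriented triangle surface in a
right-handed frame with +Z up, coordinates in centimetres. Files are
assumed to be in cm (`read_mesh(units="mm")` rescales by 0.1, since many
scanners emit mm); silent unit guessing is deliberately avoided. On
load, vertices within 1e-9 cm are merged and degenerate faces (repeated
vertex or zero area) are dropped and counted — the tolerance sits far
below the ~0.005 cm point accuracy of desktop structured-light scanners,
so real geometry is never altered.

Validation is separated from computation. `validate_mesh` reports
watertightness (every undirected edge shared by exactly two faces) and
orientation consistency (no directed edge repeated) without raising, so
area- and dimension-only workflows run on imperfect scans; `compute_volume`
and `compute_center_of_gravity` refuse non-watertight input with the open
edge count rather than silently filling holes, because silent repair
changes answers invisibly.

STL (ascii + binary), OBJ and ascii PLY are supported. OBJ and PLY are
written with full float64 precision so write→read round trips preserve
traits to ~1e-15; STL is float32 by definition of the format, so its
round trip is accurate to ~1e-7 relative. OBJ carries the sample name in
the `o` tag.

## 3D traits

**Volume and centre of gravity** use signed tetrahedra against the
origin: `V = Σ_f v₀·(v₁×v₂)/6`, `COG = Σ_f V_f (v₀+v₁+v₂)/4 / Σ_f V_f`.
Both are exact for the polyhedron, translation/rotation invariant
(volume) or equivariant (COG), and independent of the chosen origin.
The COG assumes a uniform-density solid; olive endocarps are quasi-solid
so a shell model was not pursued.

**Up-/down-skin** is a face classification: a face is up-skin iff the
angle between its outward normal and the up axis is ≤ 45° (threshold
configurable in (0°, 90°)). The comparison is inclusive — a face at
exactly 45° counts as skin — with a 1e-12 cosine guard so the tie is
stable under float error. Areas are true surface areas; a `projected`
flag switches to plane-projected areas for users who want the
throwing-a-shadow variant. By construction up + down + lateral equals
the total area to accumulation precision (tested at 1e-9 relative on
random bodies).

**Principal dimensions.** Axes are eigenvectors of the area-weighted
covariance of face centroids about the area-weighted surface centroid;
vertex-weighted PCA would bias the frame wherever the scanner left
denser vertices. Extents are max-minus-min vertex projections per axis,
sorted descending (length ≥ width ≥ height). Determinism: each axis is
signed so the vertex with the largest-magnitude projection projects
positive, the frame is forced right-handed, and an isotropic covariance
(eigenvalue spread below 1e-9 relative, e.g. a cube) falls back to the
world X→Y→Z axes.

**Shadow area** is the area of the union of all triangles orthographically
projected on the plane perpendicular to a direction — overlaps are not
double-counted. It is computed by rasterization with pixel-centre
coverage at a configurable pitch (default 0.005 cm/px, finer than
scanner accuracy; cohort runs use 0.01 cm/px, see below). For closed
oriented meshes only front-facing triangles are drawn; their union
equals the full silhouette and halves the work. The default direction is
the third principal axis (smallest extent): that plane contains length
and width, matching the pose of a fruit photographed lying on its side;
a fixed −Z option exists for platform-style projection.

**Appendage (mucro/nipple) length** is measured on the silhouette in the
length–width principal plane with the 2D estimator below, so the 3D and
2D routes share one operational definition.

## 2D traits

Segmentation follows the manual colour-threshold workflow of image
analysis tools: a pixel is foreground iff hue, saturation and brightness
each lie in their interval (hue circularly, so red ranges may wrap
through 0°), with an `invert` flag; no smoothing or morphology, so
segmentation of a rendered mask is exactly idempotent. No automatic
threshold search is performed — thresholds are data the user supplies —
though an Otsu initializer is available and never applied silently.
Connected components below `min_area_px` (default 500 px, sized for
high-resolution frames) are treated as dust. Objects are numbered
top-most-then-left-most for reproducible tables; pipelines that lay
samples out in one row pair objects to sample ids by centroid column
instead, because sub-pixel row jitter would otherwise scramble a row.

Length is the maximum Feret diameter (largest pairwise distance between
boundary pixel centres, computed on the convex hull). Width is the
minimum caliper width (rotating calipers over hull edges). The
perpendicular-extent width was rejected after it inflated widths by up
to ~3% on near-round blunt bodies, where the longest chord tilts toward
a diagonal; the minimum caliper equals the perpendicular extent on
elliptical bodies and stays at the body width under such tilt. An
`length_method="axis"` alternative reports principal-axis extents of the
boundary (for a rectangle: side lengths rather than the diagonal).

**Appendage estimator.** The boundary is extracted at sub-pixel
precision (marching squares). An ellipse is fitted by least squares to
the *lateral* boundary only — points within ±30° of the length axis at
either end are excluded symmetrically — with up to three trimming
rounds discarding residuals above twice the median, so neither the
protrusion nor body/ellipse mismatch drags the fit. Candidate tips are
the boundary points farthest from the fitted centre within the ±30°
sector at each end. The default measurement ("mirror") is the excess of
the tip end over the opposite end: for a symmetric body with a single
apical protrusion this equals the protrusion length regardless of how
blunt or pointy the body is. Measuring instead the tip's excess over the
fitted-ellipse boundary (`method="ellipse"`) is available but biased
low by up to ~0.07 cm on blunt (sub-elliptical) bodies, which is why it
is not the default. Estimates below `zero_call_px` (default 2 px) are
reported as 0 cm, matching the many olive varieties with no mucro or
nipple; consequently appendages shorter than 2 px at the working
resolution are not detectable.

## Synthetic bodies and the germplasm simulator

Bodies are superellipsoids with the length axis along x: `x = a·cos^e1 u`,
`y = b·sin^e1 u·cos^e2 v`, `z = c·sin^e1 u·sin^e2 v` (signed powers),
meshed as a latitude–longitude grid with pole fans; `mesh_subdivisions=s`
gives 2^(s+2) latitude bands. The family covers what matters for these
traits — elongation, cross-section, bluntness — and keeps closed forms:
volume `2abc·e1·e2·B(e1/2+1, e1)·B(e2/2, e2/2)` and z-silhouette area
`4ab·Γ(1+e1/2)²/Γ(1+e1)`. The appendage is a pure along-axis
displacement of the +x pole region: vertices with cross-sectional radius
ρ < R move by `L(1−(ρ/R)²)²`, so the mesh stays watertight, the pole
moves by exactly L, and the ground-truth corrections are analytic
(volume +πR²L/3, silhouette +16LR/15, length +L). Surface area has no
closed form; a refined mesh (two extra subdivision levels, error ~16×
smaller) serves as its oracle.

The cohort simulator draws per-variety mean traits uniformly over
configured ranges and jitters replicates log-normally (relative SD
`noise_sd`, default 0.05 — a plausible within-variety biological
variation; log-normal keeps traits positive), clipping back into the
range so cohort extremes respect it. Default ranges span the printed
extremes of a 50-variety olive survey: fruit length 0.86–3.83 cm and
width 0.88–2.72 cm, endocarp length 0.87–3.38 cm and width 0.44–1.23 cm,
mucro up to 0.24 cm (present in 76% of varieties), nipple up to 0.35 cm
(present in 42%). Exponents are drawn in e1 ∈ [0.9, 1.1], e2 ∈ [0.95,
1.05]: olives are smooth ovoids, slightly blunter or pointier than an
ellipsoid but never boxy. Widths are capped at 0.9× the body length so
`a ≥ b ≥ c` always holds. The default design is 50 varieties × 5 fruits
+ 10 endocarps = 250 + 500 samples; everything derives from one integer
seed, byte-reproducibly.

What the generator does **not** emulate: scanner noise and holes, mesh
resolution anisotropy, asymmetric or lobed fruits, surface texture and
colour variation, specular highlights, shadows cast in the photo box,
and touching fruits in a frame. Passing tests therefore demonstrate the
correctness of the geometry and statistics on clean closed surfaces and
clean segmentations, not robustness to scan repair or difficult
photography.

## Statistics conventions

SD uses the n−1 denominator and is reported missing (not 0) for
singleton groups; quartiles use linear interpolation. Pearson p-values
come from the t transform with n−2 df; correlation matrices use
pairwise-complete observations (n can differ per cell — documented
because listwise deletion changes it). ANOVA is the textbook one-way
decomposition; all-constant input is reported as F = 0 with a missing
p-value rather than 0/0. The LSD test uses
`t(1−α/2, df_within)·√(MSE(1/nᵢ+1/nⱼ))` and is *protected* by default
(pairs tested only when the ANOVA p ≤ α), the conservative standard; the
compact letter display uses the insert-and-absorb procedure. Raw
p-values are reported by default; Bonferroni and Benjamini–Hochberg
adjustments are available but off, matching common practice in
germplasm surveys of reporting unadjusted per-trait correlations.

## Problem sizes and numerical settings used in validation

The validation experiments (test suite and `scripts/acceptance.py`) use:
icosphere subdivision 4 (5120 faces) for analytic-solid checks; 100
random superellipsoids at subdivision 2 for conservation/equivariance;
10 random bodies at subdivision 4 against a 0.01 cm voxel oracle
(volume within 1%, centroid within 1% of the largest semi-axis); 100
random unbalanced designs for LSD-vs-t agreement; and the full
750-sample cohort at mesh subdivision 3 with 0.01 cm/px rasters for the
2D/3D concordance study — at that resolution the pipelines recover
generator ground truth within 2% (length, width, volume, area) and
within max(5%, 2 px) for appendages, with between-method r ≥ 0.998 for
length, width, shadow area and appendage length. A 10⁷-point rejection
sampler cross-checks the closed-form superellipsoid volume.

## Known limitations

- Volume/COG require watertight scans; no hole-filling is offered.
- The appendage estimator assumes one apical protrusion on an otherwise
  approximately symmetric body; double-tipped or strongly asymmetric
  fruits would need landmark methods out of scope here.
- Shadow areas are raster approximations; errors scale with
  resolution × perimeter and are ~0.3% at the defaults.
- Skin areas depend on the mounting orientation of the scan (+Z up is
  assumed, as on a scanner turntable); they are invariant only under
  rotations about the up axis.
- HSB segmentation has no shadow/glare correction or colour constancy;
  thresholds must be chosen per lighting setup.
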