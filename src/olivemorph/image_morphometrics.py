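"""2D morphometrics of fruit/endocarp photographs.

Pipeline: HSB colour-threshold segmentation of a multi-sample photograph,
connected-component labelling with speckle suppression, then per-object
traits -- length, width, silhouette ("shadow") area and apical appendage
(mucro / nipple) length -- in centimetres via a pixel scale.

Length is by default the maximum Feret diameter (largest pairwise distance
between boundary pixel centres) and width the maximal extent perpendicular
to that axis; ``length_method='axis'`` switches to principal-axis extents,
which for elongated smooth objects agrees with Feret but differs on
rectangles (Feret returns the diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure as _measure
from skimage.color import rgb2hsv

from .errors import DegenerateObjectError, ParameterError

DEFAULT_MIN_AREA_PX = 500
DEFAULT_ZERO_CALL_PX = 2
DEFAULT_SECTOR_DEG = 30.0


@dataclass
class HSBThresholds:
    """Hue/Saturation/Brightness acceptance intervals.

    ``hue`` is in degrees on the colour circle and may wrap through 0
    (e.g. ``(350, 10)`` selects reds); saturation and brightness are on
    [0, 1].  ``invert`` selects the complement (background) instead.
    """

    hue: tuple[float, float] = (0.0, 360.0)
    saturation: tuple[float, float] = (0.0, 1.0)
    brightness: tuple[float, float] = (0.0, 1.0)
    invert: bool = False


@dataclass
class BinaryMask:
    """Boolean pixel grid (row-major, origin top-left, y down) with scale."""

    pixels: np.ndarray
    scale: float  # cm per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.scale <= 0:
            raise ParameterError("scale must be > 0 cm/px")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class ImageTraits:
    """Per-object 2D trait vector."""

    length: float
    width: float
    shadow_area: float
    appendage_length: float
    centroid_px: tuple[float, float]  # (row, col)


def calibrate_scale(reference_length_cm: float, reference_length_px: float) -> float:
    """cm-per-pixel scale from a reference object of known physical length."""
    if reference_length_cm <= 0 or reference_length_px <= 0:
        raise ParameterError("reference lengths must be positive")
    return reference_length_cm / reference_length_px


def segment_hsb(image: np.ndarray, thresholds: HSBThresholds, scale: float = 1.0) -> BinaryMask:
    """Threshold an 8-bit RGB image in HSB space.

    A pixel is foreground iff its hue, saturation and brightness each lie
    inside the corresponding interval (hue circularly); ``invert`` flips
    the selection.  Deterministic, no smoothing or morphology.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ParameterError("expected an RGB image of shape (h, w, 3)")
    hsv = rgb2hsv(image[:, :, :3])
    hue = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    bri = hsv[:, :, 2]

    h0, h1 = thresholds.hue
    if h0 <= h1:
        in_hue = (hue >= h0) & (hue <= h1)
    else:  # interval wraps through 0
        in_hue = (hue >= h0) | (hue <= h1)
    s0, s1 = thresholds.saturation
    b0, b1 = thresholds.brightness
    mask = in_hue & (sat >= s0) & (sat <= s1) & (bri >= b0) & (bri <= b1)
    if thresholds.invert:
        mask = ~mask
    return BinaryMask(mask, scale=scale)


def label_objects(
    mask: BinaryMask,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    connectivity: int = 8,
) -> list[BinaryMask]:
    """Split a segmentation into per-object masks.

    Components smaller than ``min_area_px`` (dust, speckle) are dropped.
    Objects are ordered by centroid, top-most then left-most, so sample
    numbering is deterministic across runs.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    labels = _measure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    objects: list[tuple[tuple[float, float], BinaryMask]] = []
    for region in _measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        obj = np.zeros_like(mask.pixels)
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        obj[rr, cc] = True
        objects.append((tuple(region.centroid), BinaryMask(obj, scale=mask.scale)))
    objects.sort(key=lambda item: item[0])
    return [obj for _, obj in objects]


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel boundary of the largest outline as (x, y) = (col, row)."""
    contours = _measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DegenerateObjectError("object has no measurable boundary")
    contour = max(contours, key=len)
    return contour[:, ::-1]  # (row, col) -> (x, y)


def _hull_points(points: np.ndarray) -> np.ndarray:
    if len(points) < 3:
        raise DegenerateObjectError("too few boundary points for a caliper")
    try:
        return points[ConvexHull(points).vertices]
    except Exception as exc:
        raise DegenerateObjectError(f"degenerate object: {exc}") from exc


def _feret_axis(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum Feret diameter (px) and its unit direction from 2D points."""
    hull = _hull_points(points)
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    direction = hull[j] - hull[i]
    dist = float(np.sqrt(d2[i, j]))
    if dist <= 0:
        raise DegenerateObjectError("object collapses to a point")
    return dist, direction / dist


def _min_caliper_width(points: np.ndarray) -> float:
    """Minimum caliper (minimum Feret) width in px by rotating calipers:
    the smallest support-line distance over convex-hull edge directions."""
    hull = _hull_points(points)
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.linalg.norm(edges, axis=1)
    dirs = edges[lengths > 0] / lengths[lengths > 0, None]
    normals = np.column_stack([-dirs[:, 1], dirs[:, 0]])
    proj = hull @ normals.T  # (n_hull, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def compute_object_traits(
    obj: BinaryMask,
    length_method: str = "feret",
) -> ImageTraits:
    """Length, width, area and appendage length of one segmented object.

    ``length_method='feret'``: length = max pairwise boundary distance
    (maximum Feret diameter), width = minimum caliper width (the
    "MinFeret"), which stays at the body width even when the longest
    chord tilts toward a diagonal.  ``'axis'``: extents along the
    principal axes of the boundary points (major first).  Areas are
    foreground pixel counts times scale^2.
    """
    if obj.area_px < 2:
        raise DegenerateObjectError("single-pixel object")
    pts = _boundary_points(obj.pixels)
    scale = obj.scale

    if length_method == "feret":
        length_px, axis = _feret_axis(pts)
        width_px = _min_caliper_width(pts)
    elif length_method == "axis":
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt.T
        ext = proj.max(axis=0) - proj.min(axis=0)
        length_px, width_px = float(ext[0]), float(ext[1])
        if length_px < width_px:
            length_px, width_px = width_px, length_px
    else:
        raise ParameterError(f"unknown length_method {length_method!r}")

    rows, cols = np.nonzero(obj.pixels)
    return ImageTraits(
        length=length_px * scale,
        width=width_px * scale,
        shadow_area=obj.area_px * scale * scale,
        appendage_length=appendage_length_2d(obj),
        centroid_px=(float(rows.mean()), float(cols.mean())),
    )


def _fit_trimmed_ellipse(points: np.ndarray, rounds: int = 3):
    """Least-squares ellipse fit with iterative residual trimming.

    Points whose residual exceeds twice the median are discarded each
    round, so a protruding tip does not drag the fit off the body.
    Returns the fitted :class:`skimage.measure.EllipseModel`.
    """
    model = None
    current = points
    for _ in range(rounds + 1):
        if len(current) < 20:
            break
        fitted = _measure.EllipseModel.from_estimate(current)
        if not fitted:
            raise DegenerateObjectError("ellipse fit failed")
        model = fitted
        resid = np.abs(model.residuals(current))
        med = np.median(resid)
        if med <= 0:
            break
        keep = resid <= 2.0 * med
        if keep.all():
            break
        current = current[keep]
    if model is None:
        raise DegenerateObjectError("ellipse fit failed")
    return model


def _ellipse_radius(model, ray: np.ndarray) -> float:
    """Distance from the ellipse centre to its boundary along ``ray``."""
    a, b = model.axis_lengths
    theta = model.theta
    unit = ray / np.linalg.norm(ray)
    c, s = np.cos(theta), np.sin(theta)
    # ray components in the ellipse frame
    rx = unit[0] * c + unit[1] * s
    ry = -unit[0] * s + unit[1] * c
    denom = np.hypot(rx * b, ry * a)
    if denom <= 0:
        raise DegenerateObjectError("degenerate ellipse")
    return a * b / denom


def appendage_length_2d(
    obj: BinaryMask,
    zero_call_px: int = DEFAULT_ZERO_CALL_PX,
    sector_deg: float = DEFAULT_SECTOR_DEG,
    method: str = "mirror",
) -> float:
    """Apical appendage (mucro / nipple) length of a segmented object, cm.

    An ellipse is fitted to the boundary with iterative trimming so it
    captures the body and ignores the protruding tip; its centre anchors
    the measurement.  Candidate tips are the boundary points farthest from
    the centre within ``sector_deg`` of the length (Feret) axis, one per
    end.  With ``method='mirror'`` (default) the appendage is the excess
    of the tip end over the opposite end of the body -- exact for a
    symmetric body with a single apical protrusion and unbiased even when
    the body is blunter or pointier than an ellipse.  ``method='ellipse'``
    instead measures from the fitted-ellipse boundary along the tip's
    ray, which inherits the ellipse's bias on non-elliptical bodies.
    Excesses below ``zero_call_px`` pixels are reported as 0, matching
    the many varieties with no mucro or nipple.
    """
    if method not in ("mirror", "ellipse"):
        raise ParameterError(f"unknown appendage method {method!r}")
    pts = _boundary_points(obj.pixels)
    if len(pts) < 20:
        raise DegenerateObjectError("fewer than 20 boundary points")
    _, axis = _feret_axis(pts)

    # fit the body ellipse on the lateral boundary only: both polar
    # sectors are excluded symmetrically, so a protrusion at either end
    # cannot drag the fitted centre along the axis
    c0 = pts.mean(axis=0)
    rel0 = pts - c0
    d0 = np.linalg.norm(rel0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos0 = np.abs(rel0 @ axis) / np.where(d0 > 0, d0, np.inf)
    lateral = cos0 < np.cos(np.radians(sector_deg))
    fit_pts = pts[lateral] if lateral.sum() >= 20 else pts
    model = _fit_trimmed_ellipse(fit_pts)
    center = np.asarray(model.center, dtype=float)

    rel = pts - center
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(rel @ axis) / np.where(dist > 0, dist, np.inf)
    in_sector = cosang >= np.cos(np.radians(sector_deg))

    reach: list[float] = []
    excess_vs_ellipse: list[float] = []
    for sign in (1.0, -1.0):
        side = in_sector & ((rel @ axis) * sign > 0)
        if not side.any():
            continue
        tip_idx = np.flatnonzero(side)[np.argmax(dist[side])]
        reach.append(float(dist[tip_idx]))
        excess_vs_ellipse.append(float(dist[tip_idx] - _ellipse_radius(model, rel[tip_idx])))

    if method == "mirror":
        best = max(reach) - min(reach) if len(reach) == 2 else 0.0
    else:
        best = max(excess_vs_ellipse) if excess_vs_ellipse else 0.0
    if best < zero_call_px:
        return 0.0
    return float(best * obj.scale)


def extract_image_traits(
    image: np.ndarray,
    thresholds: HSBThresholds,
    scale: float,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    connectivity: int = 8,
    length_method: str = "feret",
) -> list[ImageTraits]:
    """Segment a photograph and measure every object, in deterministic order."""
    mask = segment_hsb(image, thresholds, scale=scale)
    return [
        compute_object_traits(obj, length_method=length_method)
        for obj in label_objects(mask, min_area_px=min_area_px, connectivity=connectivity)
    ]
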