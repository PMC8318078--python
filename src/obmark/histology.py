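"""Laminar-depth and particle quantification for olfactory bulb sections.

The coordinate system: the mitral cell layer (MCL) boundary is normalized
depth 0 and the lower glomerular-layer (GL) boundary is depth 1, so the
external plexiform layer (EPL) spans [0, 1].  For a point between the
boundaries the depth is d_MCL / (d_MCL + d_GL), the nearest-point distances
to each polyline — well defined for curved layers.  Points on the far side
of the MCL get negative depths; points beyond the GL get depths above 1.

Particle detection follows the round-object convention of common image
analysis tools: connected components (8-connectivity) filtered by pixel
area and by circularity 4*pi*area/perimeter^2, clipped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from skimage import measure

logger = logging.getLogger(__name__)


@dataclass
class LaminarScene:
    """Layer boundaries, soma points and an optional dendrite mask (pixels)."""

    mcl_boundary: np.ndarray  # (n, 2) polyline, px
    gl_boundary: np.ndarray  # (m, 2) polyline, px
    somata: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    dendrite_mask: np.ndarray | None = None  # binary raster (rows=y, cols=x)
    scale_um_per_px: float = 1.0

    def __post_init__(self):
        self.mcl_boundary = np.asarray(self.mcl_boundary, dtype=float)
        self.gl_boundary = np.asarray(self.gl_boundary, dtype=float)
        self.somata = np.asarray(self.somata, dtype=float).reshape(-1, 2)
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")
        for name, b in (("mcl", self.mcl_boundary), ("gl", self.gl_boundary)):
            if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 2:
                raise ValueError(f"{name} boundary must be an (n>=2, 2) polyline")
            if not LineString(b).is_simple:
                raise ValueError(f"{name} boundary is self-intersecting")

    @property
    def mcl_line(self) -> LineString:
        return LineString(self.mcl_boundary)

    @property
    def gl_line(self) -> LineString:
        return LineString(self.gl_boundary)


def _is_closed(polyline: np.ndarray, tol: float = 1e-6) -> bool:
    return bool(np.allclose(polyline[0], polyline[-1], atol=tol))


def _project(line: LineString, pts: np.ndarray):
    """Nearest points on ``line`` for each row of ``pts`` plus arc positions."""
    geoms = shapely.points(pts)
    s = shapely.line_locate_point(line, geoms)
    proj = shapely.get_coordinates(shapely.line_interpolate_point(line, s))
    return proj, np.asarray(s, dtype=float)


def normalize_epl_depth(points, scene: LaminarScene, return_valid: bool = False):
    """Normalized EPL depth for one point or an (n, 2) array of points.

    Depth is d_MCL/(d_MCL + d_GL) between the boundaries, negative below the
    MCL and above 1 beyond the GL (computed against the local EPL thickness).
    Points whose projection falls on a boundary endpoint are outside the
    annotated region: they come back NaN (and False in the validity mask
    when ``return_valid``).
    """
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    pts = points.reshape(-1, 2)

    mcl, gl = scene.mcl_line, scene.gl_line
    geoms = shapely.points(pts)
    d_m = shapely.distance(geoms, mcl)
    d_g = shapely.distance(geoms, gl)

    proj_m, s_m = _project(mcl, pts)
    proj_g, s_g = _project(gl, pts)
    eps = 1e-9
    valid = np.ones(pts.shape[0], dtype=bool)
    # projections hitting a free endpoint are outside the annotated extent;
    # closed boundaries (ring-shaped layers) have no free endpoints
    if not _is_closed(scene.mcl_boundary):
        valid &= (s_m > eps) & (s_m < mcl.length - eps)
    if not _is_closed(scene.gl_boundary):
        valid &= (s_g > eps) & (s_g < gl.length - eps)

    # side tests: below the MCL when the point sits opposite the GL across it
    to_gl_from_m = shapely.get_coordinates(
        shapely.line_interpolate_point(gl, shapely.line_locate_point(gl, shapely.points(proj_m)))
    ) - proj_m
    below_mcl = np.einsum("ij,ij->i", pts - proj_m, to_gl_from_m) < 0
    to_mcl_from_g = shapely.get_coordinates(
        shapely.line_interpolate_point(mcl, shapely.line_locate_point(mcl, shapely.points(proj_g)))
    ) - proj_g
    beyond_gl = np.einsum("ij,ij->i", pts - proj_g, to_mcl_from_g) < 0

    depth = np.full(pts.shape[0], np.nan)
    on_mcl = d_m < eps
    inside = ~below_mcl & ~beyond_gl
    with np.errstate(divide="ignore", invalid="ignore"):
        depth[inside] = d_m[inside] / (d_m[inside] + d_g[inside])
        depth[below_mcl] = -d_m[below_mcl] / (d_g[below_mcl] - d_m[below_mcl])
        depth[beyond_gl] = d_m[beyond_gl] / (d_m[beyond_gl] - d_g[beyond_gl])
    depth[on_mcl] = 0.0
    depth[~valid] = np.nan

    if single:
        return (float(depth[0]), bool(valid[0])) if return_valid else float(depth[0])
    return (depth, valid) if return_valid else depth


def depth_density_profile(scene: LaminarScene, source: str = "mask",
                          n_bins: int = 20) -> pd.DataFrame:
    """Signal density along the normalized EPL depth axis.

    ``source='mask'`` bins the dendrite mask: per depth bin, the fraction of
    in-bin pixels that are above threshold (True), i.e. the average of the
    binary signal along the axis parallel to the layers.  ``source='points'``
    bins soma points: per-bin counts normalized by the total point count.
    Densities lie in [0, 1]; bins tile [0, 1].
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if source == "mask":
        if scene.dendrite_mask is None:
            raise ValueError("scene has no dendrite mask")
        mask = np.asarray(scene.dendrite_mask, dtype=bool)
        rows, cols = np.indices(mask.shape)
        pix = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)  # (x, y)
        depth, valid = normalize_epl_depth(pix, scene, return_valid=True)
        sig = mask.ravel()
        keep = valid & (depth >= 0) & (depth <= 1)
        if not sig[keep].any():
            logger.warning("empty mask: zero density profile")
            return pd.DataFrame({"depth": centers, "density": np.zeros(n_bins)})
        idx = np.clip(np.digitize(depth[keep], edges) - 1, 0, n_bins - 1)
        total = np.bincount(idx, minlength=n_bins)
        hits = np.bincount(idx, weights=sig[keep].astype(float), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            dens = np.where(total > 0, hits / np.maximum(total, 1), 0.0)
    elif source == "points":
        depth, valid = normalize_epl_depth(scene.somata, scene, return_valid=True)
        keep = valid & (depth >= 0) & (depth <= 1)
        if keep.sum() == 0:
            logger.warning("no points in the EPL: zero profile")
            return pd.DataFrame({"depth": centers, "density": np.zeros(n_bins)})
        idx = np.clip(np.digitize(depth[keep], edges) - 1, 0, n_bins - 1)
        dens = np.bincount(idx, minlength=n_bins) / keep.sum()
    else:
        raise ValueError("source must be 'mask' or 'points'")
    return pd.DataFrame({"depth": centers, "density": dens})


def dendritic_preference_index(profile: pd.DataFrame) -> float:
    """(upper - lower) / (upper + lower) EPL signal density contrast.

    Upper EPL is depth in (0.5, 1]; lower is [0, 0.5].  Returns NaN when the
    total signal is zero (undefined).
    """
    upper = profile.loc[profile["depth"] > 0.5, "density"].mean()
    lower = profile.loc[profile["depth"] <= 0.5, "density"].mean()
    total = upper + lower
    if not np.isfinite(total) or total == 0:
        return float("nan")
    return float((upper - lower) / total)


def mcl_fraction(depths, cutoff: float = 0.3) -> float:
    """Fraction of somata within ``cutoff`` of the MCL (depth <= cutoff).

    Somata below the MCL (negative depth) count as MCL cells — displaced
    mitral cells are deliberately included.
    """
    depths = np.asarray(depths, dtype=float)
    depths = depths[np.isfinite(depths)]
    if depths.size == 0:
        raise ValueError("no somata")
    return float((depths <= cutoff).mean())


def detect_particles(mask, area_range=(70, 600), circularity_range=(0.1, 1.0),
                     connectivity: int = 2) -> pd.DataFrame:
    """Round-object detection on a binary mask.

    Connected components (8-connectivity by default) are kept when their
    pixel area falls in ``area_range`` and their circularity
    4*pi*area/perimeter^2 (clipped at 1) falls in ``circularity_range``.
    The perimeter is the Crofton estimate of the outline length, which like
    the outline-polygon convention penalizes thin elongated shapes instead
    of collapsing their boundary to a single traversal.
    Returns centroids (row, col), areas and circularities of kept particles.
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=connectivity)
    rows = []
    for rp in measure.regionprops(labels):
        area = rp.area
        perim = rp.perimeter_crofton
        circ = 1.0 if perim == 0 else min(4.0 * np.pi * area / perim**2, 1.0)
        if area_range[0] <= area <= area_range[1] and \
                circularity_range[0] <= circ <= circularity_range[1]:
            rows.append({"row": rp.centroid[0], "col": rp.centroid[1],
                         "area_px": int(area), "circularity": circ})
    return pd.DataFrame(rows, columns=["row", "col", "area_px", "circularity"])


# ---------------------------------------------------------------------------
# standardized polar coordinates on the MCL


@dataclass
class PolarMap:
    center: np.ndarray  # (2,)
    angles: np.ndarray  # per soma, [0, 2*pi)
    arc_positions_mm: np.ndarray  # per soma, along the MCL
    mcl_length_mm: float


def standardize_polar(scene: LaminarScene, n_interp: int = 512) -> PolarMap:
    """Project somata onto the MCL and standardize angles to [0, 2*pi).

    The bulb center is the centroid of the MCL polyline interpolated at
    uniform arc length; each soma's angle is measured at its nearest MCL
    point, counter-clockwise from the +x axis.
    """
    line = scene.mcl_line
    # for a closed ring, s=0 and s=length are the same point: drop the duplicate
    s = np.linspace(0.0, line.length, n_interp,
                    endpoint=not _is_closed(scene.mcl_boundary))
    interp = shapely.get_coordinates(shapely.line_interpolate_point(line, s))
    center = interp.mean(axis=0)
    spread = interp - center
    # collinear MCL: the centroid lies on the line, angles are degenerate
    if np.linalg.matrix_rank(spread - spread.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) MCL polyline")

    proj, arc = _project(line, scene.somata)
    v = proj - center
    angles = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2.0 * np.pi)
    angles[angles > 2.0 * np.pi - 1e-9] = 0.0  # snap the seam to angle 0
    arc_mm = arc * scene.scale_um_per_px / 1000.0
    return PolarMap(center=center, angles=angles, arc_positions_mm=arc_mm,
                    mcl_length_mm=line.length * scene.scale_um_per_px / 1000.0)


def linear_density(scene: LaminarScene, n_interp: int = 2048) -> pd.DataFrame:
    """Labeled cells per mm of MCL, per angular quadrant and overall."""
    pm = standardize_polar(scene)
    if pm.mcl_length_mm <= 0:
        raise ValueError("zero MCL arc length")
    line = scene.mcl_line
    s = np.linspace(0.0, line.length, n_interp)
    pts = shapely.get_coordinates(shapely.line_interpolate_point(line, s))
    mids = 0.5 * (pts[1:] + pts[:-1]) - pm.center
    seg_len_mm = np.hypot(*np.diff(pts, axis=0).T) * scene.scale_um_per_px / 1000.0
    seg_ang = np.mod(np.arctan2(mids[:, 1], mids[:, 0]), 2 * np.pi)

    rows = []
    for q in range(4):
        lo, hi = q * np.pi / 2, (q + 1) * np.pi / 2
        arc = seg_len_mm[(seg_ang >= lo) & (seg_ang < hi)].sum()
        count = int(((pm.angles >= lo) & (pm.angles < hi)).sum())
        rows.append({"quadrant": q, "count": count, "arc_mm": arc,
                     "density_per_mm": count / arc if arc > 0 else np.nan})
    rows.append({"quadrant": "all", "count": int(pm.angles.size),
                 "arc_mm": pm.mcl_length_mm,
                 "density_per_mm": pm.angles.size / pm.mcl_length_mm})
    return pd.DataFrame(rows)


def region_density(centroids, regions, scale_um_per_px: float) -> pd.DataFrame:
    """Cells per mm^2 for each region polygon (vertices in px).

    A point exactly on a polygon edge counts as inside (``covers`` semantics).
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    pts = shapely.points(centroids) if centroids.size else np.empty(0, dtype=object)
    rows = []
    for i, poly in enumerate(regions):
        poly = Polygon(poly) if not isinstance(poly, Polygon) else poly
        if not poly.is_valid:
            raise ValueError(f"region {i} is not a simple polygon")
        area_mm2 = poly.area * (scale_um_per_px / 1000.0) ** 2
        if area_mm2 == 0:
            raise ValueError(f"region {i} has zero area")
        count = int(shapely.covers(poly, pts).sum()) if centroids.size else 0
        rows.append({"region": i, "count": count, "area_mm2": area_mm2,
                     "density_per_mm2": count / area_mm2})
    return pd.DataFrame(rows)
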