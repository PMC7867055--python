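"""Per-slice segmentation of the LV cavity, RV cavity, external layer and trabeculae.

The pipeline per slice is:

1. bright maximally stable extremal regions (MSERs) inside a centered ROI
   (:func:`detect_msers`, built on the image max-tree);
2. LV blood-pool selection by circularity and centrality (:func:`select_lv_cavity`);
3. convex hull of the pool — the smoothed endocardial outline that spans the
   trabecular recesses (:func:`convex_hull_region`);
4. epicardial (external-layer) contour by casting radial rays from the LV
   centroid outward through the compact wall (:func:`cast_external_layer`);
5. RV blood-pool detection anywhere around the external contour (:func:`detect_rv`);
6. Otsu separation of dark trabeculae inside the hull and of compact
   myocardium between hull and external contour (:func:`detect_trabeculae`).

All operations are deterministic; ray casting is a pure function of the ray
index, so parallel evaluation over rays or slices reproduces the serial
result bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton
from skimage.morphology import max_tree, remove_small_objects

from .studyio import SliceImage, window_normalize


class SegmentationError(RuntimeError):
    """A slice could not be segmented (detection failure or geometry violation)."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class MSERConfig:
    """Stability parameters on the 0-255 windowed gray scale."""

    delta: int = 5
    min_area_fraction: float = 0.001
    max_area_fraction: float = 0.20
    max_variation: float = 0.25
    smooth_sigma: float = 1.0  # px, pre-detection Gaussian
    # keep only regions whose level-set threshold is above the slice Otsu
    # level, i.e. genuine blood-bright pools rather than anything brighter
    # than the air background (which would merge pool, wall and RV into one
    # stable component)
    bright_only: bool = True


@dataclass(frozen=True)
class RayCastConfig:
    """External-layer search parameters.

    ``d_expand`` is the reach multiplier on the LV equivalent radius (the
    "e-expand" tunable): each radial line extends to length ``r * d_expand``
    from the centroid.  ``r`` is the hull's equivalent-disk radius, floored by
    the coarse estimate ``n / r_estimate_divisor`` with ``n`` the total pixel
    count of the slice.  The outer myocardial edge on a ray is where intensity
    falls below ``edge_drop_fraction`` of the local myocardium level for two
    consecutive samples.
    """

    n_rays: int = 360
    d_expand: float = 1.60
    r_estimate_divisor: float = 3000.0
    edge_drop_fraction: float = 0.5
    step_px: float = 0.5
    max_failed_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.n_rays < 90:
            raise ValueError("n_rays: must be >= 90")
        if self.d_expand <= 1.0:
            raise ValueError("d_expand: must be > 1.0")
        if not 0 < self.edge_drop_fraction < 1:
            raise ValueError("edge_drop_fraction: must be in (0, 1)")


@dataclass(frozen=True)
class SegmentationConfig:
    roi_fraction: float = 0.5
    mser: MSERConfig = field(default_factory=MSERConfig)
    raycast: RayCastConfig = field(default_factory=RayCastConfig)
    rv_min_area_fraction: float = 0.25  # of LV cavity area
    rv_adjacency_px: float = 3.0
    min_trabecula_px: int = 4
    lv_centrality_weight: float = 0.5


# ---------------------------------------------------------------------------
# Regions


@dataclass
class Region:
    """A connected pixel region with shape descriptors.

    ``pixels`` is an (N, 2) array of (row, col) indices; ``centroid_mm`` is in
    physical units, ``centroid_px`` in pixel units.  ``circularity`` is the
    isoperimetric ratio 4*pi*A/P^2 clipped to [0, 1] (1 for a disk), with P
    the perimeter of the region's convex hull: a trabeculated blood pool is
    full of narrow recesses that inflate its raw boundary length, and taking
    the hull perimeter keeps the measure about overall roundness rather than
    boundary tortuosity.
    """

    pixels: np.ndarray
    shape: tuple[int, int]
    pixel_spacing: tuple[float, float]
    centroid_px: tuple[float, float] = field(init=False)
    centroid_mm: tuple[float, float] = field(init=False)
    area_px: int = field(init=False)
    circularity: float = field(init=False)

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2 or pix.shape[1] != 2 or len(pix) == 0:
            raise ValueError("pixels: expected a non-empty (N, 2) index array")
        self.pixels = pix
        self.area_px = int(len(pix))
        cr, cc = pix.mean(axis=0)
        self.centroid_px = (float(cr), float(cc))
        self.centroid_mm = (
            float(cr * self.pixel_spacing[0]),
            float(cc * self.pixel_spacing[1]),
        )
        per = self._hull_perimeter()
        self.circularity = (
            min(1.0, 4.0 * math.pi * self.area_px / per**2) if per > 0 else 1.0
        )

    def _hull_perimeter(self) -> float:
        try:
            # +1 px per axis: hull of pixel centers under-measures a rasterized
            # shape by half a pixel on each side
            hull = ConvexHull(self.pixels.astype(float))
            verts = self.pixels[hull.vertices].astype(float)
            d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
            return float(np.hypot(d[:, 0], d[:, 1]).sum()) + math.pi
        except QhullError:
            return float(perimeter_crofton(self.mask(), directions=4))

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, pixel_spacing: tuple[float, float]
    ) -> "Region":
        rows, cols = np.nonzero(mask)
        return cls(
            pixels=np.column_stack([rows, cols]),
            shape=mask.shape,
            pixel_spacing=pixel_spacing,
        )

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class SegmentationResult:
    """Per-slice geometry: cavity, hull, external layer, RV, tissue masks.

    Invariants (checked by :meth:`validate`): the LV cavity lies inside the
    hull, the hull inside the external polygon; trabecular and compact masks
    are disjoint, the former confined to the hull interior, the latter to the
    shell between hull and external contour with RV pixels excluded.
    """

    lv_cavity: Region
    lv_hull: np.ndarray  # (M, 2) closed polygon, (row, col)
    external_polygon: np.ndarray  # (K, 2)
    trabecular_mask: np.ndarray
    compact_mask: np.ndarray
    rv_cavity: Optional[Region] = None

    def validate(self) -> None:
        shape = self.trabecular_mask.shape
        hull_m = polygon_interior_mask(self.lv_hull, shape)
        ext_m = polygon_mask(self.external_polygon, shape)
        cav = self.lv_cavity.mask()
        if not _mostly_subset(cav, hull_m):
            raise SegmentationError("lv_cavity not contained in lv_hull")
        if not _mostly_subset(hull_m, ext_m):
            raise SegmentationError("lv_hull not contained in external_polygon")
        if np.any(self.trabecular_mask & self.compact_mask):
            raise SegmentationError("trabecular and compact masks overlap")
        if not _mostly_subset(self.trabecular_mask, hull_m):
            raise SegmentationError("trabecular_mask leaks outside the hull")
        shell = ext_m & ~hull_m
        if not _mostly_subset(self.compact_mask, shell):
            raise SegmentationError("compact_mask leaks outside the hull/external shell")
        if self.rv_cavity is not None and np.any(
            self.compact_mask & self.rv_cavity.mask()
        ):
            raise SegmentationError("compact_mask overlaps the RV cavity")


def _mostly_subset(a: np.ndarray, b: np.ndarray, tol: float = 0.005) -> bool:
    """a ⊆ b up to a rasterization margin (default 0.5% of |a|)."""
    n = np.count_nonzero(a)
    if n == 0:
        return True
    return np.count_nonzero(a & ~b) <= max(2, tol * n)


def polygon_mask(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled interior (boundary inclusive) of a (row, col) polygon."""
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    rr, cc = polygon_perimeter(poly[:, 0], poly[:, 1], shape=shape)
    m[rr, cc] = True
    return m


def polygon_interior_mask(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie inside the polygon (boundary not drawn).

    Used for the endocardial hull: together with the half-pixel outward pad
    applied by :func:`refine_hull`, membership reduces to "pixel center inside
    the pixel-coverage outline", which keeps wall pixels out of the hull.
    """
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def dilate_polygon(poly: np.ndarray, pad_px: float) -> np.ndarray:
    """Offset a convex (row, col) polygon outward by ``pad_px``."""
    grown = Polygon(poly[:, ::-1]).buffer(pad_px, join_style=2)
    xy = np.asarray(grown.exterior.coords[:-1])
    return xy[:, ::-1]


# ---------------------------------------------------------------------------
# MSER detection


def _windowed_u8(image: SliceImage, sigma: float) -> np.ndarray:
    win = window_normalize(image.pixels)
    if sigma > 0:
        win = gaussian(win, sigma=sigma, preserve_range=True)
    return np.rint(np.clip(win, 0, 1) * 255).astype(np.uint8)


def detect_msers(
    image: SliceImage, roi_fraction: float, config: MSERConfig = MSERConfig()
) -> list[Region]:
    """Bright maximally stable extremal regions intersecting the centered ROI.

    Works on the max-tree of the windowed 8-bit image: a node (connected
    component of a >= threshold level set) is returned when its relative area
    growth over a ``delta`` gray-level descent is below ``max_variation`` and
    is a local minimum along its root path.  Nested near-duplicates keep the
    most stable member.  An empty list is a valid outcome.
    """
    if not 0 < roi_fraction <= 1:
        raise ValueError("roi_fraction: must be in (0, 1]")
    img8 = _windowed_u8(image, config.smooth_sigma)
    if img8.max() == img8.min():
        return []
    h, w = img8.shape
    n_px = img8.size
    parent, traverser = max_tree(img8, connectivity=2)
    parent = parent.ravel()
    flat = img8.ravel().astype(np.int32)

    area = np.ones(n_px, dtype=np.int64)
    for p in traverser[::-1]:
        q = parent[p]
        if q != p:
            area[q] += area[p]

    root = traverser[0]
    is_canonical = (flat != flat[parent]) | (np.arange(n_px) == root)

    # canonical parent of a canonical node (skip the same-level alias pixels)
    def canon_parent(p: int) -> int:
        q = parent[p]
        while not is_canonical[q]:
            q = parent[q]
        return q

    canon = traverser[is_canonical[traverser]]
    variation = np.full(n_px, np.inf)
    cpar = {}
    for p in canon:
        q = canon_parent(p)
        cpar[p] = q
        anc = p
        while flat[anc] > flat[p] - config.delta and anc != root:
            anc = cpar.get(anc) if anc in cpar else canon_parent(anc)
        if flat[anc] <= flat[p] - config.delta:
            variation[p] = (area[anc] - area[p]) / area[p]

    children: dict[int, list[int]] = {}
    for p in canon:
        if p != root:
            children.setdefault(cpar[p], []).append(p)

    min_a = max(4, config.min_area_fraction * n_px)
    max_a = config.max_area_fraction * n_px
    bright_floor = threshold_otsu(img8) if config.bright_only else -1
    selected = []
    for p in canon:
        v = variation[p]
        if not np.isfinite(v) or v > config.max_variation:
            continue
        if not min_a <= area[p] <= max_a:
            continue
        if flat[p] < bright_floor:
            continue
        if p != root and variation[cpar[p]] < v:
            continue
        if any(variation[c] < v for c in children.get(p, ())):
            continue
        selected.append(p)

    # collapse nested candidates: along any ancestor chain keep only the most
    # stable member (ties go to the larger region), so a blood pool nest of
    # level sets yields one region instead of a russian doll of them
    keep = set(selected)
    changed = True
    while changed:
        changed = False
        for p in sorted(keep):
            q = p
            while q != root and p in keep:
                q = cpar.get(q) if q in cpar else canon_parent(q)
                if q in keep and q != p:
                    if variation[p] > variation[q] or (
                        variation[p] == variation[q] and area[p] < area[q]
                    ):
                        keep.discard(p)
                    else:
                        keep.discard(q)
                    changed = True
    # ROI box, centered, side = roi_fraction * min(h, w)
    half = roi_fraction * min(h, w) / 2.0
    r0, r1 = (h - 1) / 2.0 - half, (h - 1) / 2.0 + half
    c0, c1 = (w - 1) / 2.0 - half, (w - 1) / 2.0 + half

    regions = []
    for p in sorted(keep):
        comp = cc_label(img8 >= flat[p], connectivity=2)
        comp_mask = comp == comp.ravel()[p]
        rows, cols = np.nonzero(comp_mask)
        in_roi = (rows >= r0) & (rows <= r1) & (cols >= c0) & (cols <= c1)
        if not np.any(in_roi):
            continue
        regions.append(
            Region(
                pixels=np.column_stack([rows, cols]),
                shape=img8.shape,
                pixel_spacing=image.pixel_spacing,
            )
        )
    regions.sort(key=lambda r: (-r.area_px, r.centroid_px))
    return regions


# ---------------------------------------------------------------------------
# LV selection and hull


def select_lv_cavity(
    regions: list[Region],
    image: SliceImage,
    centrality_weight: float = 0.5,
) -> Region:
    """Pick the region scoring highest on circularity minus a centrality penalty.

    score = circularity - weight * (centroid distance to image center) /
    (image half-diagonal).  Ties break to the larger area, then the smaller
    centroid row, then column — fully deterministic.
    """
    if not regions:
        raise SegmentationError("no candidate regions for LV cavity selection")
    h, w = image.pixels.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    half_diag = math.hypot(h, w) / 2.0

    def key(r: Region):
        d = math.hypot(r.centroid_px[0] - center[0], r.centroid_px[1] - center[1])
        score = r.circularity - centrality_weight * d / half_diag
        return (-score, -r.area_px, r.centroid_px[0], r.centroid_px[1])

    return min(regions, key=key)


def convex_hull_region(region: Region) -> np.ndarray:
    """Convex hull polygon of the region's pixel set, vertices counter-clockwise.

    Counter-clockwise is in the right-handed (x=col, y=row) frame; the hull is
    taken over pixel centers.  Collinear pixel sets raise a detection failure.
    """
    pts = region.pixels[:, ::-1].astype(float)  # (x=col, y=row)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise SegmentationError(f"degenerate region for convex hull: {exc}") from exc
    verts = pts[hull.vertices]  # scipy returns them counter-clockwise in 2-D
    return verts[:, ::-1]  # back to (row, col)


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area (px^2) of a (row, col) polygon."""
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_coverage_area(poly: np.ndarray) -> float:
    """Pixel-coverage area of a convex hull taken over pixel centers.

    A hull over centers misses the half-pixel rim of the rasterized shape;
    the Minkowski sum with a half-pixel disk adds P/2 + pi/4.
    """
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    perimeter = float(np.hypot(d[:, 0], d[:, 1]).sum())
    return polygon_area(poly) + perimeter / 2.0 + math.pi / 4.0


# ---------------------------------------------------------------------------
# External layer by radial ray casting


def _hull_boundary_radii(hull_poly: Polygon, centroid: tuple[float, float],
                         angles: np.ndarray, reach: float) -> np.ndarray:
    """Distance from the centroid to the hull boundary along each angle."""
    cy, cx = centroid
    radii = np.empty(len(angles))
    boundary = hull_poly.exterior
    for i, a in enumerate(angles):
        dy, dx = math.sin(a), math.cos(a)
        ray = LineString([(cx, cy), (cx + dx * reach, cy + dy * reach)])
        inter = ray.intersection(boundary)
        if inter.is_empty:
            radii[i] = 0.0
            continue
        pts = (
            [inter] if isinstance(inter, Point) else list(getattr(inter, "geoms", []))
        )
        dist = max(
            (math.hypot(g.x - cx, g.y - cy) for g in pts if isinstance(g, Point)),
            default=0.0,
        )
        radii[i] = dist
    return radii


def cast_external_layer(
    image: SliceImage, hull: np.ndarray, config: RayCastConfig = RayCastConfig()
) -> np.ndarray:
    """Locate the epicardial contour by walking rays outward from the hull.

    For each of ``n_rays`` equally spaced angles, intensity is sampled
    (bilinear) from the hull boundary out to the reach ``l = r * d_expand``
    from the hull centroid.  The external point is the last sample before the
    intensity drops below ``edge_drop_fraction`` of the ray's local myocardium
    level for two consecutive samples.  Rays that run into bright RV blood are
    bridged by angular interpolation from their neighbors; if more than
    ``max_failed_fraction`` of rays find no edge within reach, the search
    aborts with a hint to raise ``d_expand``.

    Returns the (n_rays, 2) polygon of external points in (row, col).
    """
    win = window_normalize(image.pixels)
    h, w = win.shape
    hull_xy = Polygon(hull[:, ::-1])  # (x=col, y=row)
    cx, cy = hull_xy.centroid.x, hull_xy.centroid.y
    r_eq = math.sqrt(hull_xy.area / math.pi)
    r = max(r_eq, image.pixels.size / config.r_estimate_divisor)
    reach = r * config.d_expand

    angles = np.linspace(0.0, 2.0 * math.pi, config.n_rays, endpoint=False)
    start = _hull_boundary_radii(hull_xy, (cy, cx), angles, reach + 4.0)
    step = config.step_px
    n_steps = int(math.ceil(reach / step)) + 1
    offsets = np.arange(n_steps) * step
    # sample grid: radius_{ij} = start_i + offset_j, clipped to the image
    rad = start[:, None] + offsets[None, :]
    rows = cy + np.sin(angles)[:, None] * rad
    cols = cx + np.cos(angles)[:, None] * rad
    rows = np.clip(rows, 0, h - 1)
    cols = np.clip(cols, 0, w - 1)
    samples = map_coordinates(win, [rows.ravel(), cols.ravel()], order=1).reshape(
        rad.shape
    )

    # local myocardium level: first few samples just beyond the hull boundary
    k0 = max(1, int(round(1.0 / step)))
    myo = np.median(samples[:, k0 : k0 + max(4, k0 * 4)], axis=1)
    # blood level for RV-crossing detection: bright pool inside the hull
    inner = polygon_mask(hull, win.shape)
    inner_vals = win[inner]
    blood = float(np.percentile(inner_vals, 90)) if inner_vals.size else 1.0

    radii = np.full(config.n_rays, np.nan)
    crossed_rv = np.zeros(config.n_rays, dtype=bool)
    for i in range(config.n_rays):
        drop_level = config.edge_drop_fraction * myo[i]
        # anything clearly above the myocardium band means the ray entered
        # blood again (RV); a low blend factor also catches rays grazing the
        # partial-volume penumbra at the RV's angular edges
        bright_level = myo[i] + 0.3 * max(blood - myo[i], 0.0)
        below = samples[i] < drop_level
        bright = samples[i] > bright_level
        # beyond the first wall sample, two consecutive bright samples = RV
        for j in range(k0 + 1, n_steps - 1):
            if bright[j] and bright[j + 1]:
                crossed_rv[i] = True
                break
            if below[j] and below[j + 1]:
                radii[i] = rad[i, j - 1]
                break
        # reaching the reach limit with no edge leaves radii[i] = nan

    no_edge = np.isnan(radii) & ~crossed_rv
    if np.count_nonzero(no_edge) > config.max_failed_fraction * config.n_rays:
        raise SegmentationError(
            f"{np.count_nonzero(no_edge)}/{config.n_rays} rays found no external "
            f"edge within reach l={reach:.1f}px; consider a larger d_expand "
            f"(currently {config.d_expand})"
        )
    radii = _bridge_missing(radii, angles)
    radii = _reject_radial_outliers(radii, angles)
    out_rows = cy + np.sin(angles) * radii
    out_cols = cx + np.cos(angles) * radii
    return np.column_stack([out_rows, out_cols])


def _reject_radial_outliers(
    radii: np.ndarray, angles: np.ndarray, window: int = 9, tol_px: float = 3.0
) -> np.ndarray:
    """Re-bridge rays deviating more than ``tol_px`` from the circular rolling median.

    The epicardial contour varies slowly with angle, so an isolated ray that
    latched onto a remote edge (e.g. the far side of the RV pool) stands out
    against its angular neighborhood and is replaced by interpolation.
    """
    n = len(radii)
    if n < 3 * window:
        return radii
    half = window // 2
    padded = np.concatenate([radii[-half:], radii, radii[:half]])
    med = np.array(
        [np.median(padded[i : i + window]) for i in range(n)]
    )
    out = np.abs(radii - med) > tol_px
    if not np.any(out) or np.all(out):
        return radii
    cleaned = radii.copy()
    cleaned[out] = np.nan
    return _bridge_missing(cleaned, angles)


def _bridge_missing(radii: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Fill nan radii by circular linear interpolation over angle."""
    bad = np.isnan(radii)
    if not np.any(bad):
        return radii
    if np.all(bad):
        raise SegmentationError("no ray found an external edge")
    good = ~bad
    # unwrap by tiling one period on each side
    ang = np.concatenate([angles[good] - 2 * math.pi, angles[good],
                          angles[good] + 2 * math.pi])
    val = np.tile(radii[good], 3)
    radii = radii.copy()
    radii[bad] = np.interp(angles[bad], ang, val)
    return radii


# ---------------------------------------------------------------------------
# RV detection


def detect_rv(
    image: SliceImage,
    lv: Region,
    external: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
) -> Optional[Region]:
    """Largest bright region adjacent to the external contour, other than the LV.

    A candidate must be at least ``rv_min_area_fraction`` of the LV cavity
    area and come within ``rv_adjacency_px`` of the external polygon.  The
    search is position independent — no assumption about which side the RV
    lies on.  Returns None when nothing qualifies.
    """
    win = window_normalize(image.pixels)
    thr = threshold_otsu(win)
    bright = win > thr
    labels = cc_label(bright, connectivity=2)
    lv_labels = np.unique(labels[lv.mask() & bright])
    lv_labels = set(int(v) for v in lv_labels if v != 0)

    border = np.zeros(win.shape, dtype=bool)
    rr, cc = polygon_perimeter(external[:, 0], external[:, 1], shape=win.shape)
    border[rr, cc] = True
    dist_to_border = distance_transform_edt(~border)

    best: Optional[Region] = None
    for lbl in range(1, labels.max() + 1):
        if lbl in lv_labels:
            continue
        mask = labels == lbl
        area = np.count_nonzero(mask)
        if area < config.rv_min_area_fraction * lv.area_px:
            continue
        if dist_to_border[mask].min() > config.rv_adjacency_px:
            continue
        if best is None or area > best.area_px:
            best = Region.from_mask(mask, image.pixel_spacing)
    return best


# ---------------------------------------------------------------------------
# Trabecular / compact separation

# minimum contrast (windowed units) between the Otsu classes for the dark
# class to count as real tissue rather than the lower half of the noise
_MIN_CLASS_SEPARATION = 0.25


def _drop_boundary_rim(
    trabecular: np.ndarray, hull_m: np.ndarray, min_depth_px: float = 2.0
) -> np.ndarray:
    """Remove dark components that never leave the hull's partial-volume rim.

    The hull polygon lands on the endocardial edge to within a pixel or so;
    dark pixels hugging it are wall partial volume, not trabeculae.  A real
    trabecula projects into the cavity, i.e. some of its pixels lie deeper
    than ``min_depth_px`` inside the hull.
    """
    if not trabecular.any():
        return trabecular
    depth = distance_transform_edt(hull_m)
    labels = cc_label(trabecular, connectivity=2)
    keep = np.zeros_like(trabecular)
    for lbl in range(1, labels.max() + 1):
        comp = labels == lbl
        if depth[comp].max() > min_depth_px:
            keep |= comp
    return keep


def _otsu_separation(vals: np.ndarray, thr: float) -> float:
    dark = vals[vals < thr]
    bright = vals[vals >= thr]
    if dark.size == 0 or bright.size == 0:
        return 0.0
    return float(bright.mean() - dark.mean())


def detect_trabeculae(
    image: SliceImage,
    hull: np.ndarray,
    external: np.ndarray,
    rv: Optional[Region] = None,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[np.ndarray, np.ndarray, Region]:
    """Split hull interior into trabeculae and blood, and the shell into myocardium.

    The threshold is Otsu over windowed intensities inside the hull.  Dark
    components inside the hull of at least ``min_trabecula_px`` pixels form the
    trabecular mask; bright pixels form the cavity (largest component returned
    as a Region).  Dark pixels between hull and external contour, minus RV
    pixels, form the compact mask.
    """
    win = window_normalize(image.pixels)
    hull_m = polygon_interior_mask(hull, win.shape)
    ext_m = polygon_mask(external, win.shape)
    if not _mostly_subset(hull_m, ext_m):
        raise SegmentationError(
            "geometry error: hull is not strictly inside the external polygon"
        )
    vals = win[hull_m]
    if vals.size == 0 or vals.max() <= vals.min():
        raise SegmentationError("empty or flat hull interior")
    thr = threshold_otsu(vals)
    if _otsu_separation(vals, thr) < _MIN_CLASS_SEPARATION:
        # no genuine dark class inside the hull (untrabeculated cavity):
        # Otsu would split pure noise, so the trabecular mask stays empty
        trabecular = np.zeros_like(hull_m)
        cavity_px = hull_m
    else:
        trabecular = hull_m & (win < thr)
        trabecular = remove_small_objects(
            trabecular, max_size=config.min_trabecula_px - 1
        )
        trabecular = _drop_boundary_rim(trabecular, hull_m)
        cavity_px = hull_m & (win >= thr)
    labels = cc_label(cavity_px, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no blood pool found inside the hull")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    cavity_region = Region.from_mask(labels == largest, image.pixel_spacing)

    shell = ext_m & ~hull_m
    compact = shell & (win < thr)
    # rasterizing the external polygon sweeps in a sub-pixel rim of dark
    # background beyond the epicardial edge; a second Otsu over the sub-blood
    # shell pixels separates myocardium from background when both are present
    sub = win[compact]
    if sub.size and sub.max() > sub.min():
        thr_bg = threshold_otsu(sub)
        if _otsu_separation(sub, thr_bg) >= _MIN_CLASS_SEPARATION:
            compact &= win >= thr_bg
    if rv is not None:
        compact &= ~rv.mask()
    return trabecular, compact, cavity_region


# ---------------------------------------------------------------------------
# Whole-slice driver


def refine_hull(image: SliceImage, hull: np.ndarray) -> np.ndarray:
    """Second refinement of the endocardial hull.

    The MSER pool is extracted at its stability level on a smoothed image and
    so overshoots the endocardial edge by a pixel or two.  Re-thresholding the
    unsmoothed windowed intensities inside the seed hull (Otsu) recovers the
    blood pool at the blood/myocardium midpoint, and its convex hull lands on
    the true endocardial outline.
    """
    win = window_normalize(image.pixels)
    hull_m = polygon_mask(hull, win.shape)
    vals = win[hull_m]
    if vals.size == 0 or vals.max() <= vals.min():
        return hull
    thr = threshold_otsu(vals)
    if _otsu_separation(vals, thr) < _MIN_CLASS_SEPARATION:
        return hull  # untrabeculated pool: the seed hull is already the pool
    pool = hull_m & (win >= thr)
    labels = cc_label(pool, connectivity=2)
    if labels.max() == 0:
        return hull
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    refined = convex_hull_region(
        Region.from_mask(labels == largest, image.pixel_spacing)
    )
    # a hull over pixel centers sits half a pixel inside the rasterized pool;
    # pad to pixel coverage (interior-mask membership then matches rendering)
    return dilate_polygon(refined, 0.5)


def segment_slice(
    image: SliceImage, config: SegmentationConfig = SegmentationConfig()
) -> SegmentationResult:
    """Run the full per-slice chain and return a validated SegmentationResult."""
    regions = detect_msers(image, config.roi_fraction, config.mser)
    lv_seed = select_lv_cavity(regions, image, config.lv_centrality_weight)
    hull = refine_hull(image, convex_hull_region(lv_seed))
    external = cast_external_layer(image, hull, config.raycast)
    rv = detect_rv(image, lv_seed, external, config)
    trabecular, compact, cavity = detect_trabeculae(
        image, hull, external, rv=rv, config=config
    )
    result = SegmentationResult(
        lv_cavity=cavity,
        lv_hull=hull,
        external_polygon=external,
        trabecular_mask=trabecular,
        compact_mask=compact,
        rv_cavity=rv,
    )
    result.validate()
    return result
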