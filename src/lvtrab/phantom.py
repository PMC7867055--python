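"""Synthetic short-axis cardiac phantom with analytically known geometry.

Each slice renders, on a dark background, a bright circular LV blood pool,
a dark compact myocardial annulus around it, dark radial trabecular strands
attached to the endocardial wall inside the pool, and optionally a bright RV
blood pool beyond the annulus at an arbitrary angle.  The cross-section
shrinks concentrically toward the apex so that slice-order detection has a
real signal to work with.

All areas (compact annulus, trabecular strands) have closed-form values, so
the downstream segmentation and quantification stages can be tested against
exact ground truth without any imaging data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .studyio import SliceImage, StudyStack

APICAL_SCALE = 0.7  # cross-section scale at the apex relative to the base
RV_EXTENT_MM = 14.0  # radial extent of the RV crescent beyond the annulus
RV_HALFSPAN_DEG = 50.0  # angular half-width of the RV crescent
STRAND_ANGLE_OFFSET = 0.2399  # rad; see _render_slice
GRAY_MAX = 4095  # 12-bit acquisition scale


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and photometric description of one synthetic study.

    Lengths are mm, intensities are gray levels on a 12-bit scale, angles are
    degrees measured counter-clockwise from the +column axis.  Defaults follow
    a 1.5 T short-axis protocol: 8 mm slices with a 2 mm gap on a 224 x 224
    matrix at 1 mm/px, with a moderately trabeculated ventricle.
    """

    image_size: int = 224
    cavity_radius: float = 26.0
    wall_thickness: float = 7.0
    n_trabeculae: int = 8
    trabecula_depth: float = 16.0
    trabecula_width: float = 6.0
    rv_present: bool = True
    rv_angle: float = 200.0
    n_slices: int = 9
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    pixel_spacing: float = 1.0
    intensity_blood: float = 800.0
    intensity_myocardium: float = 300.0
    intensity_background: float = 60.0
    noise_sd: float = 12.0
    seed: int = 0
    order: str = "apical_to_basal"

    def validate(self) -> None:
        if self.image_size < 64:
            raise PhantomSpecError("image_size: must be >= 64")
        if self.wall_thickness <= 0:
            raise PhantomSpecError("wall_thickness: must be > 0")
        if self.trabecula_depth < 0:
            raise PhantomSpecError("trabecula_depth: must be >= 0")
        if self.cavity_radius <= self.trabecula_depth:
            raise PhantomSpecError(
                "cavity_radius: must exceed trabecula_depth "
                f"({self.cavity_radius} <= {self.trabecula_depth})"
            )
        if not (
            self.intensity_blood > self.intensity_myocardium > self.intensity_background
        ):
            raise PhantomSpecError(
                "intensity_blood: bright-blood contrast requires "
                "blood > myocardium > background"
            )
        if self.n_trabeculae < 0:
            raise PhantomSpecError("n_trabeculae: must be >= 0")
        if self.n_trabeculae > 0:
            if self.trabecula_width <= 0:
                raise PhantomSpecError("trabecula_width: must be > 0")
            if self.trabecula_width / 2.0 >= self.cavity_radius:
                raise PhantomSpecError(
                    "trabecula_width: strand half-width must be below the "
                    "cavity radius"
                )
            if self.n_trabeculae >= 2:
                if self.strand_half_angle >= math.pi / self.n_trabeculae:
                    raise PhantomSpecError(
                        "n_trabeculae: strands overlap (angular width too large "
                        "for the strand count)"
                    )
        if self.n_slices < 1:
            raise PhantomSpecError("n_slices: must be >= 1")
        if self.slice_thickness <= 0:
            raise PhantomSpecError("slice_thickness: must be > 0")
        if self.slice_gap < 0:
            raise PhantomSpecError("slice_gap: must be >= 0")
        if self.pixel_spacing <= 0:
            raise PhantomSpecError("pixel_spacing: must be > 0")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd: must be >= 0")
        if self.order not in ("apical_to_basal", "basal_to_apical"):
            raise PhantomSpecError(
                "order: expected 'apical_to_basal' or 'basal_to_apical'"
            )
        outer = self.cavity_radius + self.wall_thickness
        if self.rv_present:
            outer += RV_EXTENT_MM
        if outer / self.pixel_spacing > self.image_size / 2.0 - 2:
            raise PhantomSpecError(
                "image_size: rendered geometry does not fit in the image"
            )

    @property
    def strand_half_angle(self) -> float:
        """Angular half-width (rad) of a strand, set at the endocardial wall."""
        return math.asin(
            min(1.0, self.trabecula_width / (2.0 * self.cavity_radius))
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        spec = cls(**json.loads(Path(path).read_text()))
        spec.validate()
        return spec


@dataclass
class PhantomTruth:
    """Per-slice ground truth masks and closed-form areas (mm^2).

    Lists follow the stored slice order of the companion stack.  The three
    tissue masks are pairwise disjoint by construction; ``external_polygon``
    is the epicardial circle as an (N, 2) array of (row, col) pixel
    coordinates.
    """

    cavity_mask: list[np.ndarray]
    trabecular_mask: list[np.ndarray]
    compact_mask: list[np.ndarray]
    rv_mask: list[np.ndarray]
    external_polygon: list[np.ndarray]
    analytic_compact_area: list[float]
    analytic_trabecular_area: list[float]

    @property
    def analytic_trabecular_fraction(self) -> float:
        """Stack-level At / (At + Ac); constant per slice by concentric scaling."""
        at = sum(self.analytic_trabecular_area)
        ac = sum(self.analytic_compact_area)
        return at / (at + ac) if at + ac > 0 else 0.0


def strand_area(cavity_radius: float, depth: float, width: float) -> float:
    """Exact area of one trabecular strand (mm^2).

    A strand is a radial wedge: tangential width ``width`` at its endocardial
    attachment (radius ``cavity_radius``), tapering linearly in arc toward the
    tip at radius ``cavity_radius - depth``.  Wedges keep the blood channels
    between strands open at every radius, which is what keeps the blood pool
    connected even at heavy trabeculation; their area is the annular sector
    beta * (R^2 - (R - depth)^2) with beta the half-angle asin(width / 2R).
    """
    if depth <= 0 or width <= 0:
        return 0.0
    beta = math.asin(min(1.0, width / (2.0 * cavity_radius)))
    inner = cavity_radius - depth
    return beta * (cavity_radius**2 - inner**2)


def annulus_area(cavity_radius: float, wall_thickness: float) -> float:
    """Closed-form compact annulus area pi*((R+t)^2 - R^2), mm^2."""
    outer = cavity_radius + wall_thickness
    return math.pi * (outer**2 - cavity_radius**2)


def _slice_scales(spec: PhantomSpec) -> np.ndarray:
    """Per-slice concentric scale factor, in stored order."""
    n = spec.n_slices
    if n == 1:
        basal_to_apical = np.array([1.0])
    else:
        basal_to_apical = np.linspace(1.0, APICAL_SCALE, n)
    if spec.order == "basal_to_apical":
        return basal_to_apical
    return basal_to_apical[::-1]


def _render_slice(
    spec: PhantomSpec, scale: float, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    size = spec.image_size
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    x = (cols - c) * spec.pixel_spacing
    y = -(rows - c) * spec.pixel_spacing  # angles counter-clockwise on screen
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    cav_r = spec.cavity_radius * scale
    wall = spec.wall_thickness * scale
    depth = spec.trabecula_depth * scale
    width = spec.trabecula_width * scale
    outer_r = cav_r + wall

    pool = r < cav_r
    strands = np.zeros_like(pool)
    beta = spec.strand_half_angle  # scale-invariant under concentric shrink
    for k in range(spec.n_trabeculae):
        # fixed angular offset keeps strand axes away from the pixel-grid
        # diagonals, where a thin wedge's rasterized area is biased low
        th_k = 2.0 * math.pi * k / spec.n_trabeculae + STRAND_ANGLE_OFFSET
        d_th = np.angle(np.exp(1j * (theta - th_k)))
        strands |= pool & (r >= cav_r - depth) & (np.abs(d_th) <= beta)
    cavity = pool & ~strands
    compact = (r >= cav_r) & (r < outer_r)

    rv = np.zeros_like(pool)
    if spec.rv_present:
        rv_ext = RV_EXTENT_MM * scale
        d_th = np.angle(np.exp(1j * (theta - math.radians(spec.rv_angle))))
        rv = (
            (r >= outer_r)
            & (r < outer_r + rv_ext)
            & (np.abs(d_th) <= math.radians(RV_HALFSPAN_DEG))
        )

    img = np.full((size, size), spec.intensity_background, dtype=np.float64)
    img[pool] = spec.intensity_blood
    img[strands] = spec.intensity_myocardium
    img[compact] = spec.intensity_myocardium
    img[rv] = spec.intensity_blood
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    # quantize to the integer acquisition scale so a write/read round trip
    # through 16-bit DICOM or PNG is bit-exact
    img = np.clip(np.rint(img), 0, GRAY_MAX)

    ang = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    poly = np.column_stack(
        [
            c - np.sin(ang) * outer_r / spec.pixel_spacing,
            c + np.cos(ang) * outer_r / spec.pixel_spacing,
        ]
    )
    truth = {
        "cavity_mask": cavity,
        "trabecular_mask": strands,
        "compact_mask": compact,
        "rv_mask": rv,
        "external_polygon": poly,
        "analytic_compact_area": annulus_area(cav_r, wall),
        "analytic_trabecular_area": spec.n_trabeculae
        * strand_area(cav_r, depth, width),
    }
    return img, truth


def generate_phantom(spec: PhantomSpec) -> tuple[StudyStack, PhantomTruth]:
    """Render the study described by ``spec`` and its exact ground truth.

    Deterministic: identical spec (including seed) gives bit-identical output.
    Slice locations increase in the stored order; instance numbers are 1-based.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scales = _slice_scales(spec)
    slices = []
    truth_fields: dict[str, list] = {
        "cavity_mask": [],
        "trabecular_mask": [],
        "compact_mask": [],
        "rv_mask": [],
        "external_polygon": [],
        "analytic_compact_area": [],
        "analytic_trabecular_area": [],
    }
    for i, scale in enumerate(scales):
        img, truth = _render_slice(spec, float(scale), rng)
        slices.append(
            SliceImage(
                pixels=img,
                pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
                instance_index=i + 1,
                slice_location=i * (spec.slice_thickness + spec.slice_gap),
            )
        )
        for key, value in truth.items():
            truth_fields[key].append(value)
    stack = StudyStack(
        slices=slices,
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
        source_order=spec.order,
    )
    return stack, PhantomTruth(**truth_fields)


_N_STRANDS_MAX = 40
GAP_MIN_MM = 3.0  # narrowest blood channel (arc) allowed between strand tips
_TIP_RADIUS_MIN = 1.0  # mm; strands never reach the exact center
DEPTH_MIN_MM = 4.0  # shallowest strand the sweep will generate: anything
# shallower is indistinguishable from partial-volume rim at ~1 mm/px


def _u_min(n: int, beta: float) -> float:
    """Smallest tip radius keeping the inter-strand channel >= GAP_MIN_MM."""
    gap_angle = 2.0 * math.pi / n - 2.0 * beta
    if gap_angle <= 0:
        return math.inf
    return max(GAP_MIN_MM / gap_angle, _TIP_RADIUS_MIN)


def _beta_max(n: int, r_cav: float) -> float:
    """Widest half-angle leaving a GAP_MIN_MM channel at a tip radius < R."""
    return math.pi / n - GAP_MIN_MM / (2.0 * (r_cav - _TIP_RADIUS_MIN))


def _solve_strands(
    r_cav: float, target_at: float, n: int, beta_base: float
) -> Optional[tuple[float, float]]:
    """Solve (depth, width) for ``n`` wedges totalling ``target_at`` mm^2.

    Strands deepen first at the base width; once depth is exhausted they
    widen at the gap-limited tip radius.  Returns None when ``n`` strands
    cannot carry the target area.
    """
    # the target must support at least DEPTH_MIN_MM-deep strands: fewer
    # strands carry more area each, so a too-small target means n is too high
    u_cap = r_cav - DEPTH_MIN_MM
    if n * beta_base * (r_cav**2 - u_cap**2) > target_at:
        return None
    # phase 1: fixed width, solve tip radius u from target = n*beta*(R^2-u^2)
    u_lo = _u_min(n, beta_base)
    if u_lo < r_cav and n * beta_base * (r_cav**2 - u_lo**2) >= target_at:
        u = math.sqrt(r_cav**2 - target_at / (n * beta_base))
        u = max(u, u_lo)
        return (r_cav - u, 2.0 * r_cav * math.sin(beta_base))
    # phase 2: gap-limited tip radius, solve half-angle on the rising branch
    # of the (unimodal) area-vs-width curve
    b_hi = _beta_max(n, r_cav)
    if b_hi <= beta_base:
        return None

    def gap(beta: float) -> float:
        u = _u_min(n, beta)
        return n * beta * (r_cav**2 - u**2) - target_at

    grid = np.linspace(beta_base, b_hi, 400)
    vals = np.array([gap(b) for b in grid])
    crossing = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if crossing.size == 0:
        return None
    i = int(crossing[0])
    beta = brentq(gap, grid[i], grid[i + 1], xtol=1e-12)
    u = _u_min(n, beta)
    return (r_cav - u, 2.0 * r_cav * math.sin(beta))


def attainable_fraction_range(spec: PhantomSpec) -> tuple[float, float]:
    """Trabecular fractions reachable by varying strand depth, width and count.

    The upper end is limited by packing: wedges must leave a blood channel of
    at least GAP_MIN_MM between neighboring tips at every radius.
    """
    r_cav = spec.cavity_radius
    ac = annulus_area(r_cav, spec.wall_thickness)
    at_best = 0.0
    for n in range(1, _N_STRANDS_MAX + 1):
        b_hi = _beta_max(n, r_cav)
        if b_hi <= 0:
            continue
        # area trades width against gap-limited depth; scan the width range
        for b in np.linspace(b_hi / 200.0, b_hi, 200):
            u = _u_min(n, b)
            if u < r_cav:
                at_best = max(at_best, n * b * (r_cav**2 - u**2))
    return (0.0, at_best / (at_best + ac)) if at_best > 0 else (0.0, 0.0)


def trabeculation_sweep(
    base_spec: PhantomSpec, fractions: list[float]
) -> list[tuple[StudyStack, PhantomTruth]]:
    """Generate stacks whose analytic trabecular fraction hits each target.

    ``fractions`` must be strictly increasing, each in [0, 0.6).  For each
    target the strand geometry (depth, then width, then count) is solved
    numerically so the achieved analytic fraction matches the request exactly,
    well within the contracted 0.02.
    """
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise PhantomSpecError("fractions: must be strictly increasing")
    if any(f < 0 or f >= 0.6 for f in fractions):
        raise PhantomSpecError("fractions: each must lie in [0, 0.6)")
    lo, hi = attainable_fraction_range(base_spec)
    r_cav = base_spec.cavity_radius
    ac = annulus_area(r_cav, base_spec.wall_thickness)
    beta_base = base_spec.strand_half_angle if base_spec.trabecula_width > 0 else 0.1
    out = []
    for f in fractions:
        if f == 0.0:
            spec = replace(base_spec, n_trabeculae=0)
        else:
            if f > hi:
                raise PhantomSpecError(
                    f"fractions: {f} outside attainable range [{lo:.3f}, {hi:.3f}] "
                    "for this geometry"
                )
            target_at = f / (1.0 - f) * ac
            base_n = max(base_spec.n_trabeculae, 1)
            # prefer the base strand count, then fewer (deeper strands for
            # small targets), then more (to carry large targets)
            order = [base_n, *range(base_n - 1, 0, -1),
                     *range(base_n + 1, _N_STRANDS_MAX + 1)]
            solved = None
            for n in order:
                solved = _solve_strands(r_cav, target_at, n, beta_base)
                if solved is not None:
                    break
            if solved is None:
                raise PhantomSpecError(
                    f"fractions: {f} outside attainable range [{lo:.3f}, {hi:.3f}] "
                    "for this geometry"
                )
            depth, width = solved
            spec = replace(
                base_spec,
                n_trabeculae=n,
                trabecula_depth=float(depth),
                trabecula_width=float(width),
            )
        out.append(generate_phantom(spec))
    return out
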