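"""Synthetic delay-phase CT phantoms with exact ground-truth geometry.

A phantom emulates the contrast pattern the pipeline relies on: a kidney
ellipsoid of mid-intensity parenchyma, an embedded lower-intensity tumor
sphere, and a contrast-bright tubular urinary tract (CT value above 420, so
any threshold in the clinically used range r in [350, 420] captures it),
over a zero background, with optional Gaussian noise. Because every shape is
analytic, the exact tumor-to-tract surface gap is known in closed form and
every pipeline stage can be validated without patient data.

All stochastic steps (noise, annotation sampling) derive from the single
``rng_seed`` in the spec, so a given spec reproduces bit-identical volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import Contour, ContourStack, ScribbleSet, SeedSet
from .volume_io import CTVolume, LabelMask

logger = logging.getLogger(__name__)

# minimum threshold-to-tract contrast: any r in [350, 420] must segment the tract
TRACT_MIN_CT = 420.0


@dataclass
class PhantomSpec:
    """Analytic geometry and imaging parameters of one phantom.

    All geometry is in world mm; the grid origin is at the center of voxel
    (0,0,0) = (0,0,0) mm. Intensity defaults: background 0, parenchyma 150,
    tumor 60 (hypodense lesion), tract 500 (contrast-filled collecting
    system, above the 420 upper end of the clinical threshold range).
    """

    shape: tuple = (140, 96, 84)
    spacing: tuple = (0.8, 0.8, 0.8)
    kidney_center: tuple = (55.0, 38.0, 33.0)
    kidney_semi_axes: tuple = (50.0, 30.0, 25.0)
    tumor_center: tuple = (75.0, 38.0, 33.0)
    tumor_radius: float = 12.0
    tract_polyline: tuple = ()   # sequence of 3D mm points; default built below
    tract_radius: float = 2.0
    background_value: float = 0.0
    parenchyma_value: float = 150.0
    tumor_value: float = 60.0
    tract_value: float = 500.0
    noise_sd: float = 15.0
    rng_seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if not self.tract_polyline:
            self.tract_polyline = _default_tract_polyline(
                np.asarray(self.kidney_center),
                np.asarray(self.tumor_center),
                self.tumor_radius,
                self.tract_radius,
                gap_mm=2.5,
            )
        self.tract_polyline = tuple(tuple(float(x) for x in p) for p in self.tract_polyline)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        c = np.asarray(self.kidney_center)
        a = np.asarray(self.kidney_semi_axes)
        t = np.asarray(self.tumor_center)
        if _ellipsoid_scaled_norm(t, c, a) >= 1.0 + self.tumor_radius / a.min():
            raise ValueError("tumor sphere does not intersect the kidney ellipsoid")
        pts = _densify_polyline(np.asarray(self.tract_polyline), step=1.0)
        margin = self.tract_radius / a.min()
        worst = (_ellipsoid_scaled_norm(pts, c, a) + margin).max()
        if worst > 1.0:
            raise ValueError(
                f"tract tube leaves the kidney ellipsoid (scaled excess {worst - 1:.3f})"
            )
        if self.tract_value <= TRACT_MIN_CT:
            raise ValueError(
                f"tract CT value must exceed {TRACT_MIN_CT} so every clinical "
                f"threshold segments it, got {self.tract_value}"
            )
        if abs(self.tumor_value - self.parenchyma_value) < 3 * self.noise_sd:
            raise ValueError(
                "tumor/parenchyma contrast must be at least 3x the noise sd"
            )
        if len(self.tract_polyline) < 2:
            raise ValueError("tract centerline needs at least one segment")

    def analytic_min_distance(self) -> float:
        """Exact closest surface-to-surface distance, tumor sphere to tract tube.

        The closest point of a capsule (tube) to an external point lies along
        the point-to-centerline segment, so the surface gap is
        min_over_segments dist(tumor_center, segment) - r_tumor - r_tube.
        """
        t = np.asarray(self.tumor_center)
        poly = np.asarray(self.tract_polyline)
        d = min(
            _point_segment_distance(t, poly[i], poly[i + 1])
            for i in range(len(poly) - 1)
        )
        return float(d - self.tumor_radius - self.tract_radius)


def _ellipsoid_scaled_norm(points, center, semi_axes) -> np.ndarray:
    p = (np.atleast_2d(points) - center) / semi_axes
    return np.sqrt((p * p).sum(axis=-1))


def _point_segment_distance(p, a, b) -> float:
    ab = np.asarray(b, float) - np.asarray(a, float)
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def _densify_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    out = []
    for a, b in zip(poly[:-1], poly[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / step)) + 1)
        out.append(np.linspace(a, b, n))
    return np.concatenate(out)


def _default_tract_polyline(kidney_center, tumor_center, r_tumor, r_tube, gap_mm):
    """3-segment centerline whose middle segment realizes the surface gap exactly.

    The middle segment runs parallel to y at axis distance
    r_tumor + r_tube + gap from the tumor center (perpendicular foot interior
    to the segment), and the two end segments bend away toward the renal
    pelvis, strictly farther from the tumor.
    """
    t = np.asarray(tumor_center, float)
    c = np.asarray(kidney_center, float)
    axis_dist = r_tumor + r_tube + gap_mm
    x_mid = t[0] - axis_dist
    mid_a = np.array([x_mid, t[1] - 8.0, t[2]])
    mid_b = np.array([x_mid, t[1] + 8.0, t[2]])
    end_a = np.array([max(c[0] - 28.0, x_mid - 10.0), t[1] - 16.0, t[2] - 4.0])
    end_b = np.array([max(c[0] - 28.0, x_mid - 10.0), t[1] + 16.0, t[2] + 4.0])
    return (tuple(end_a), tuple(mid_a), tuple(mid_b), tuple(end_b))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _tube_mask(shape, spacing, polyline, radius) -> np.ndarray:
    X, Y, Z = _voxel_centers(shape, spacing)
    pts = np.stack([X, Y, Z], axis=-1)
    poly = np.asarray(polyline, float)
    dist = np.full(shape, np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = max(float(ab @ ab), 1e-300)
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(pts - closest, axis=-1)
        dist = np.minimum(dist, d)
    return dist <= radius


def generate_phantom(spec: PhantomSpec):
    """Voxelize the phantom: CT volume, ground-truth masks, analytic gap.

    A voxel belongs to a mask iff its center lies inside the analytic shape.
    Returns ``(volume, masks, analytic_min_distance)`` where ``masks`` is a
    dict with keys ``kidney``, ``tumor``, ``tract``. Intensity precedence is
    tract > tumor > parenchyma > background (the contrast-filled tract is
    brightest even where shapes overlap).
    """
    spec.validate()
    shape, spacing = spec.shape, np.asarray(spec.spacing)
    X, Y, Z = _voxel_centers(shape, spacing)
    pts = np.stack([X, Y, Z], axis=-1)

    kidney = _ellipsoid_scaled_norm(
        pts.reshape(-1, 3), np.asarray(spec.kidney_center),
        np.asarray(spec.kidney_semi_axes),
    ).reshape(shape) <= 1.0
    tumor = (
        np.linalg.norm(pts - np.asarray(spec.tumor_center), axis=-1)
        <= spec.tumor_radius
    )
    tract = _tube_mask(shape, spacing, spec.tract_polyline, spec.tract_radius)

    data = np.full(shape, spec.background_value, dtype=np.float64)
    data[kidney] = spec.parenchyma_value
    data[tumor] = spec.tumor_value
    data[tract] = spec.tract_value
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)

    volume = CTVolume(data.astype(np.float32), spacing, np.zeros(3))
    masks = {
        "kidney": LabelMask(kidney, spacing, np.zeros(3)),
        "tumor": LabelMask(tumor, spacing, np.zeros(3)),
        "tract": LabelMask(tract, spacing, np.zeros(3)),
    }
    return volume, masks, spec.analytic_min_distance()


def generate_annotations(
    spec: PhantomSpec,
    masks: dict,
    n_scribbles: int = 20,
    n_seeds: int = 4,
    n_contours: int = 5,
    contour_vertices: int = 24,
    threshold_r: float = 350.0,
    clearance_mm: float = 2.0,
):
    """Simulated user interactions for the three segmentation methods.

    Scribbles are drawn from the kidney parenchyma interior / exterior with
    at least ``clearance_mm`` from the kidney boundary; tract seeds sit on
    the centerline; tumor contours are exact circles of the sphere on
    equally spaced axial planes. Sampling uses the spec's rng_seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 7]))
    spacing = np.asarray(spec.spacing)
    kidney = masks["kidney"].data
    tumor = masks["tumor"].data
    tract = masks["tract"].data

    depth_in = ndimage.distance_transform_edt(kidney, sampling=spacing)
    depth_out = ndimage.distance_transform_edt(~kidney, sampling=spacing)
    fg_pool = np.argwhere((depth_in >= clearance_mm) & ~tumor & ~tract)
    bg_pool = np.argwhere(depth_out >= clearance_mm)
    if len(fg_pool) < n_scribbles or len(bg_pool) < n_scribbles:
        raise ValueError("phantom too thin to place scribbles with the clearance")
    fg = fg_pool[rng.choice(len(fg_pool), n_scribbles, replace=False)]
    bg = bg_pool[rng.choice(len(bg_pool), n_scribbles, replace=False)]
    scribbles = ScribbleSet(fg, bg)

    # tract seeds: voxels nearest to points along the centerline
    center_pts = _densify_polyline(np.asarray(spec.tract_polyline), step=2.0)
    take = np.linspace(0, len(center_pts) - 1, n_seeds).astype(int)
    seed_idx = np.rint(center_pts[take] / spacing).astype(int)
    seed_idx = np.clip(seed_idx, 0, np.asarray(spec.shape) - 1)
    seed_idx = seed_idx[tract[tuple(seed_idx.T)]]
    if len(seed_idx) == 0:
        raise ValueError("no centerline voxel landed inside the tract mask")
    seeds = SeedSet(seed_idx, threshold_r)

    # tumor contours: analytic circles on axial planes through the sphere
    tc = np.asarray(spec.tumor_center)
    r = spec.tumor_radius
    z_off = np.linspace(-0.7 * r, 0.7 * r, n_contours)
    contours = []
    for dz in z_off:
        k = int(round((tc[2] + dz) / spacing[2]))
        z_mm = k * spacing[2]
        rho2 = r * r - (z_mm - tc[2]) ** 2
        if rho2 <= (2 * spacing[0]) ** 2:
            continue
        rho = np.sqrt(rho2)
        th = np.linspace(0, 2 * np.pi, contour_vertices, endpoint=False)
        u = (tc[0] + rho * np.cos(th)) / spacing[0]
        v = (tc[1] + rho * np.sin(th)) / spacing[1]
        contours.append(Contour(2, k, np.stack([u, v], axis=1)))
    stack = ContourStack(contours)
    return scribbles, seeds, stack


# ---------------------------------------------------------------------------
# Variants used by studies and tests
# ---------------------------------------------------------------------------

def simple_ellipsoid_phantom(
    shape=(40, 40, 40),
    spacing=(1.0, 1.0, 1.0),
    semi_axes=(12.0, 9.0, 7.0),
    inside_value: float = 100.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
):
    """Minimal two-intensity phantom (ellipsoid on zero background).

    Returns ``(volume, mask)``; used to exercise binary segmentation where
    the full kidney/tumor/tract anatomy would only add confounds.
    """
    spacing = np.asarray(spacing, float)
    center = (np.asarray(shape) - 1) * spacing / 2.0
    X, Y, Z = _voxel_centers(shape, spacing)
    pts = np.stack([X, Y, Z], axis=-1)
    inside = _ellipsoid_scaled_norm(
        pts.reshape(-1, 3), center, np.asarray(semi_axes)
    ).reshape(shape) <= 1.0
    data = np.where(inside, inside_value, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        data = data + rng.normal(0.0, noise_sd, size=shape)
    return (
        CTVolume(data.astype(np.float32), spacing, np.zeros(3)),
        LabelMask(inside, spacing, np.zeros(3)),
    )


def random_phantom_spec(
    rng_seed: int,
    gap_mm: float | None = None,
    shape=(128, 128, 128),
    spacing=(0.8, 0.8, 0.8),
    noise_sd: float = 15.0,
    max_tries: int = 200,
) -> PhantomSpec:
    """Randomized phantom with an exactly known tumor-to-tract surface gap.

    Tumor position and radius and the tract tube's approach direction are
    randomized; the tube is a straight segment placed at a surface gap of
    ``gap_mm`` (drawn uniformly from [0.5, 7.0] mm when not given), so the
    expected minimum opening margin is known in closed form.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 11]))
    spacing = np.asarray(spacing, float)
    extent = (np.asarray(shape) - 1) * spacing
    kidney_center = extent / 2.0
    semi_axes = np.array([45.0, 34.0, 28.0])
    if gap_mm is None:
        gap_mm = float(rng.uniform(0.5, 7.0))
    r_tube = 2.0
    for _ in range(max_tries):
        r_tumor = float(rng.uniform(8.0, 13.0))
        # tumor center inside the kidney, not too close to its boundary
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        tc = kidney_center + u * rng.uniform(0.0, 0.4) * semi_axes
        # approach direction of the tube, biased toward the kidney center
        v = -u + 0.3 * rng.normal(size=3)
        v /= np.linalg.norm(v)
        axis_dist = r_tumor + r_tube + gap_mm
        foot = tc + v * axis_dist
        d = rng.normal(size=3)
        d -= (d @ v) * v  # tube direction perpendicular to the approach
        d /= np.linalg.norm(d)
        half = 8.0
        poly = (tuple(foot - half * d), tuple(foot + half * d))
        try:
            spec = PhantomSpec(
                shape=tuple(shape),
                spacing=tuple(spacing),
                kidney_center=tuple(kidney_center),
                kidney_semi_axes=tuple(semi_axes),
                tumor_center=tuple(tc),
                tumor_radius=r_tumor,
                tract_polyline=poly,
                tract_radius=r_tube,
                noise_sd=noise_sd,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        except ValueError:
            continue
        if abs(spec.analytic_min_distance() - gap_mm) > 1e-9:
            continue
        return spec
    raise RuntimeError(f"could not place a valid random phantom after {max_tries} tries")
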