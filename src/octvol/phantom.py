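"""Synthetic phantoms: 3-D shapes with closed-form volumes, rendered as
annotation stacks, plus simulated noisy observers.

Shapes (all dimensions in mm; the axial axis is z, the raster advances in y):

``ellipsoid``
    params ``a`` (lateral), ``b`` (across-scan), ``c`` (axial) semi-axes;
    volume 4/3*pi*a*b*c.
``slab_cylinder``
    a uniform tissue slab of thickness ``t`` whose measured entity is the
    cylinder over a circle of radius ``r`` centred on the fovea; rendered
    contours are the full slab (width 2*``half_width``, default ``4r``) so
    that the circular-ROI pipeline performs the chord clipping, exactly as
    on-screen.  Analytic volume pi*r^2*t refers to the cylinder.
``paraboloid_pit``
    pit of rim radius ``a`` and depth ``h`` between the paraboloid
    z = h*rho^2/a^2 and the plane z = h; volume pi*a^2*h/2.
``lens``
    two equal spherical caps base-to-base (sphere radius ``R``, cap height
    ``h``); volume 2*pi*h^2*(3R - h)/3.

Rendered contours are polygons inscribed in the exact cross-section
boundary, so the polygon area converges to the analytic section area as
the vertex count grows (error ~ 1/m^2), and the slab-summed volume
converges to the analytic volume as the scan spacing shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate

from .annotation_io import AnnotationStack, Contour, FoveaCenter, PairedMeasurements, ScanAnnotation
from .geometry import CircularROI
from .volumetry import entity_volume, foveal_volume

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "StudyResult",
    "analytic_volume",
    "analytic_cross_section",
    "render_stack",
    "simulate_observers",
]

SHAPES = ("ellipsoid", "slab_cylinder", "paraboloid_pit", "lens")
_REQUIRED_PARAMS = {
    "ellipsoid": ("a", "b", "c"),
    "slab_cylinder": ("r", "t"),
    "paraboloid_pit": ("a", "h"),
    "lens": ("R", "h"),
}
# Default raster: 49-line horizontal macular raster at 0.12 mm spacing
# (a plausible dense-macular preset; both are assumptions, not device facts).
DEFAULT_N_SCANS = 49
DEFAULT_SCAN_SPACING_MM = 0.12


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric 3-D shape + raster + polygonization description."""

    shape: str
    params: dict[str, float] = field(default_factory=dict)
    center: tuple[float, float] | None = None  # (x, y) mm; None -> raster middle
    center_z: float = 0.0
    scan_spacing: float = DEFAULT_SCAN_SPACING_MM
    n_scans: int = DEFAULT_N_SCANS
    grid_phase: float = 0.0
    vertices_per_contour: int = 128
    label: str = "entity"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        missing = [k for k in _REQUIRED_PARAMS[self.shape] if k not in self.params]
        if missing:
            raise ValueError(f"shape {self.shape!r} requires params {missing}")
        for key in _REQUIRED_PARAMS[self.shape]:
            if not self.params[key] > 0:
                raise ValueError(f"param {key!r} must be > 0, got {self.params[key]}")
        if self.shape == "lens" and self.params["h"] > self.params["R"]:
            raise ValueError("lens cap height h must be <= sphere radius R")
        if not self.scan_spacing > 0:
            raise ValueError("scan_spacing must be > 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.vertices_per_contour < 4:
            raise ValueError("vertices_per_contour must be >= 4")
        # Raster must straddle the shape's across-scan footprint.
        cy = self.center_y
        half = self.scan_spacing / 2.0
        span_lo, span_hi = -half, (self.n_scans - 1) * self.scan_spacing + half
        ext = self.footprint_halfwidth
        if cy - ext < span_lo - 1e-12 or cy + ext > span_hi + 1e-12:
            raise ValueError(
                f"shape footprint [{cy - ext:.4f}, {cy + ext:.4f}] mm exceeds the "
                f"raster span [{span_lo:.4f}, {span_hi:.4f}] mm"
            )

    @property
    def center_x(self) -> float:
        return 0.0 if self.center is None else self.center[0]

    @property
    def center_y(self) -> float:
        if self.center is not None:
            return self.center[1]
        return (self.n_scans - 1) / 2.0 * self.scan_spacing + self.grid_phase

    @property
    def footprint_halfwidth(self) -> float:
        """Across-scan (y) half-extent of the measured entity."""
        p = self.params
        if self.shape == "ellipsoid":
            return p["b"]
        if self.shape == "slab_cylinder":
            return p["r"]
        if self.shape == "paraboloid_pit":
            return p["a"]
        return math.sqrt(p["h"] * (2.0 * p["R"] - p["h"]))  # lens rim radius

    def scan_offsets(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.scan_spacing

    def roi(self) -> CircularROI:
        """The foveal circle matching a ``slab_cylinder`` phantom."""
        if self.shape != "slab_cylinder":
            raise ValueError("roi() is defined for slab_cylinder phantoms only")
        return CircularROI(self.center_x, self.center_y, self.params["r"])

    def scaled(self, factor: float) -> "PhantomSpec":
        """Spec with every linear shape dimension multiplied by ``factor``
        (the raster, i.e. the instrument, is unchanged)."""
        if not factor > 0:
            raise ValueError(f"scale factor must be > 0, got {factor}")
        return replace(self, params={k: v * factor for k, v in self.params.items()})


@dataclass(frozen=True)
class ObserverModel:
    """Multiplicative per-scan area error: observed = true * (1 + bias + noise)."""

    area_bias: float = 0.0
    area_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_noise_sd < 0:
            raise ValueError("area_noise_sd must be >= 0")


def analytic_volume(spec: PhantomSpec) -> float:
    """Closed-form volume (mm^3) of the phantom's measured entity."""
    p = spec.params
    if spec.shape == "ellipsoid":
        return 4.0 / 3.0 * math.pi * p["a"] * p["b"] * p["c"]
    if spec.shape == "slab_cylinder":
        return math.pi * p["r"] ** 2 * p["t"]
    if spec.shape == "paraboloid_pit":
        return math.pi * p["a"] ** 2 * p["h"] / 2.0
    cap = math.pi * p["h"] ** 2 * (3.0 * p["R"] - p["h"]) / 3.0
    return 2.0 * cap


def analytic_cross_section(spec: PhantomSpec, scan_offset_y: float) -> float:
    """Exact area (mm^2) of the measured entity on the plane y = scan_offset_y.

    For ``slab_cylinder`` this is the chord-clipped slab rectangle (the
    cylinder's section), not the unbounded slab.
    """
    p = spec.params
    d = abs(scan_offset_y - spec.center_y)
    if spec.shape == "ellipsoid":
        if d >= p["b"]:
            return 0.0
        return math.pi * p["a"] * p["c"] * (1.0 - (d / p["b"]) ** 2)
    if spec.shape == "slab_cylinder":
        if d >= p["r"]:
            return 0.0
        return 2.0 * p["t"] * math.sqrt(p["r"] ** 2 - d**2)
    if spec.shape == "paraboloid_pit":
        if d >= p["a"]:
            return 0.0
        return 4.0 * p["h"] * (p["a"] ** 2 - d**2) ** 1.5 / (3.0 * p["a"] ** 2)
    # lens: region |z| <= sqrt(R^2 - d^2 - x^2) - (R - h)
    rho_sq = p["h"] * (2.0 * p["R"] - p["h"])
    if d * d >= rho_sq:
        return 0.0
    w = math.sqrt(rho_sq - d * d)
    rd_sq = p["R"] ** 2 - d * d
    rd = math.sqrt(rd_sq)
    return 2.0 * rd_sq * math.asin(w / rd) - 2.0 * (p["R"] - p["h"]) * w


def quadrature_volume(spec: PhantomSpec) -> float:
    """Cross-section integral over y by adaptive quadrature (self-check oracle)."""
    ext = spec.footprint_halfwidth
    value, _ = integrate.quad(
        lambda y: analytic_cross_section(spec, y),
        spec.center_y - ext,
        spec.center_y + ext,
        limit=400,
    )
    return value


def _section_boundary(spec: PhantomSpec, d: float) -> np.ndarray | None:
    """Vertices (m, 2) inscribed in the exact section boundary at offset d."""
    p = spec.params
    m = spec.vertices_per_contour
    cx, cz = spec.center_x, spec.center_z
    if spec.shape == "ellipsoid":
        if d >= p["b"]:
            return None
        shrink = math.sqrt(1.0 - (d / p["b"]) ** 2)
        theta = 2.0 * math.pi * np.arange(m) / m
        return np.column_stack(
            [cx + p["a"] * shrink * np.cos(theta), cz + p["c"] * shrink * np.sin(theta)]
        )
    if spec.shape == "slab_cylinder":
        # Full slab rectangle; the ROI pipeline performs the chord clipping.
        if d >= p["r"]:
            return None
        half_w = p.get("half_width", 2.0 * p["r"])
        half_t = p["t"] / 2.0
        corners = np.array(
            [
                [cx - half_w, cz - half_t],
                [cx + half_w, cz - half_t],
                [cx + half_w, cz + half_t],
                [cx - half_w, cz + half_t],
            ]
        )
        per_edge = max(m // 4, 1)
        pieces = []
        for i in range(4):
            a, b = corners[i], corners[(i + 1) % 4]
            frac = np.arange(per_edge)[:, None] / per_edge
            pieces.append(a + (b - a) * frac)
        return np.vstack(pieces)
    if spec.shape == "paraboloid_pit":
        if d >= p["a"]:
            return None
        w = math.sqrt(p["a"] ** 2 - d * d)
        k = max(m - m // 4, 3)  # parabola points; rest pads the flat top
        x = np.linspace(-w, w, k)
        parab = np.column_stack([cx + x, cz + p["h"] * (x * x + d * d) / p["a"] ** 2])
        n_top = max(m - k, 1)
        x_top = np.linspace(w, -w, n_top + 2)[1:-1]
        top = np.column_stack([cx + x_top, np.full(n_top, cz + p["h"])])
        return np.vstack([parab, top])
    # lens
    rho_sq = p["h"] * (2.0 * p["R"] - p["h"])
    if d * d >= rho_sq:
        return None
    w = math.sqrt(rho_sq - d * d)
    rd_sq = p["R"] ** 2 - d * d
    k = m // 2 + 1
    x = np.linspace(-w, w, k)
    zeta = np.sqrt(np.maximum(rd_sq - x * x, 0.0)) - (p["R"] - p["h"])
    zeta = np.maximum(zeta, 0.0)
    upper = np.column_stack([cx + x, cz + zeta])
    lower = np.column_stack([cx + x[-2:0:-1], cz - zeta[-2:0:-1]])
    return np.vstack([upper, lower])


def render_stack(spec: PhantomSpec) -> AnnotationStack:
    """Render the phantom as an annotation stack.

    Every raster line appears as a scan; lines the shape misses carry no
    contour.  The fovea centre is recorded on the scan nearest the shape
    centre so the circular-ROI pipeline can run without extra input.
    """
    offsets = spec.scan_offsets()
    scans = []
    for i, y in enumerate(offsets):
        d = abs(y - spec.center_y)
        verts = _section_boundary(spec, d)
        contours = []
        if verts is not None:
            contours.append(
                Contour(scan_index=i, vertices=verts, label=spec.label, validated=True)
            )
        scans.append(ScanAnnotation(scan_index=i, lateral_offset_y=float(y), contours=contours))
    fovea_scan = int(np.argmin(np.abs(offsets - spec.center_y)))
    return AnnotationStack(
        scan_spacing=spec.scan_spacing,
        scans=scans,
        fovea_center=FoveaCenter(scan_index=fovea_scan, x_mm=spec.center_x),
        meta={"phantom_shape": spec.shape, "phantom_params": dict(spec.params)},
    )


def _true_scan_areas(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Noise-free measured per-scan areas and total volume, via the pipeline
    the shape calls for (chord-clipped for slab_cylinder, free otherwise)."""
    stack = render_stack(spec)
    if spec.label not in stack.labels():
        return np.zeros(0), 0.0
    if spec.shape == "slab_cylinder":
        vr = foveal_volume(stack, spec.label, roi=spec.roi())
    else:
        vr = entity_volume(stack, spec.label)
    areas = np.array([area for _, area in vr.per_scan], dtype=float)
    return areas, vr.total_volume


@dataclass
class StudyResult:
    """Everything a simulated two-observer repeatability study produces."""

    comparisons: dict[str, PairedMeasurements]
    true_volumes: np.ndarray
    size_factors: np.ndarray
    seed: int


def simulate_observers(
    spec: PhantomSpec,
    obs1: ObserverModel,
    obs2: ObserverModel,
    n_subjects: int,
    sessions: int = 2,
    subject_size_jitter: float = 0.0,
    seed: int = 0,
) -> StudyResult:
    """Simulate a two-observer, multi-session agreement study on phantoms.

    Each subject is the phantom with its linear dimensions scaled by
    ``1 + Normal(0, subject_size_jitter)``.  Each observer x session
    re-measures every scan with multiplicative area error
    ``1 + area_bias + Normal(0, area_noise_sd)`` (truncated at zero) and
    volumes follow the slab sum.  Output pairings: observer 1 vs observer 2
    (session 1), each observer's session 1 vs session 2, and truth vs each
    observer (truth playing the automated-reference role, difference
    truth - observer).  Identical seeds give bit-identical results.
    """
    if n_subjects < 3:
        raise ValueError(f"n_subjects must be >= 3, got {n_subjects}")
    if sessions < 1:
        raise ValueError(f"sessions must be >= 1, got {sessions}")
    if subject_size_jitter < 0:
        raise ValueError("subject_size_jitter must be >= 0")

    jitter_rng = np.random.default_rng([seed, 0x5EED])
    if subject_size_jitter > 0:
        factors = 1.0 + jitter_rng.normal(0.0, subject_size_jitter, n_subjects)
        factors = np.maximum(factors, 0.05)
    else:
        factors = np.ones(n_subjects)

    base_areas: tuple[np.ndarray, float] | None = None
    true_areas: list[np.ndarray] = []
    true_volumes = np.zeros(n_subjects)
    for s, f in enumerate(factors):
        if f == 1.0:
            if base_areas is None:
                base_areas = _true_scan_areas(spec)
            areas, volume = base_areas
        else:
            areas, volume = _true_scan_areas(spec.scaled(float(f)))
        true_areas.append(areas)
        true_volumes[s] = volume

    observers = (obs1, obs2)
    volumes = np.zeros((2, sessions, n_subjects))
    for o, obs in enumerate(observers):
        for t in range(sessions):
            rng = np.random.default_rng([seed, obs.seed, o + 1, t + 1])
            for s in range(n_subjects):
                a = true_areas[s]
                if a.size == 0:
                    continue
                factor = 1.0 + obs.area_bias + rng.normal(0.0, obs.area_noise_sd, a.size)
                observed = np.maximum(a * factor, 0.0)
                volumes[o, t, s] = observed.sum() * spec.scan_spacing

    def _pairs(label_a, label_b, va, vb):
        return PairedMeasurements(
            label_a, label_b, [(f"subj{s:03d}", float(va[s]), float(vb[s])) for s in range(n_subjects)]
        )

    comparisons = {"obs1-obs2": _pairs("obs1", "obs2", volumes[0, 0], volumes[1, 0])}
    if sessions >= 2:
        for o in range(2):
            comparisons[f"obs{o + 1}_s1-obs{o + 1}_s2"] = _pairs(
                f"obs{o + 1}_s1", f"obs{o + 1}_s2", volumes[o, 0], volumes[o, 1]
            )
    for o in range(2):
        comparisons[f"truth-obs{o + 1}"] = _pairs("truth", f"obs{o + 1}", true_volumes, volumes[o, 0])
    return StudyResult(
        comparisons=comparisons,
        true_volumes=true_volumes,
        size_factors=factors,
        seed=seed,
    )
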