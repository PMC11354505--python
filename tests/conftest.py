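"""Shared fixtures and independent oracles for the octvol test suite."""

from __future__ import annotations

import json

import numpy as np
import pytest

from octvol.annotation_io import Contour

PX_MM = 0.001  # 1 micron per pixel, the rasterization-oracle resolution


def raster_area_mm2(vertices: np.ndarray, px: float = PX_MM) -> float:
    """Pixel-count area of the filled polygon at ``px`` mm/pixel.

    Independent oracle for the shoelace formula: rasterize with
    scikit-image and count pixels.  Agreement is expected within
    2 * perimeter * px.
    """
    from skimage.draw import polygon as sk_polygon

    v = np.asarray(vertices, dtype=float) / px
    rr, cc = sk_polygon(v[:, 1] - v[:, 1].min() + 2.0, v[:, 0] - v[:, 0].min() + 2.0)
    return len(rr) * px * px


def star_polygon(rng: np.random.Generator, n_min: int = 5, n_max: int = 40) -> np.ndarray:
    """Random simple polygon: jittered angles around the origin, random radii.

    Strictly increasing angles make the polygon star-shaped with respect to
    the origin, hence simple, and keep it connected under any vertical-strip
    clip whose strip contains the origin.
    """
    m = int(rng.integers(n_min, n_max))
    base = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    ang = base + rng.uniform(-0.35, 0.35, m) * 2.0 * np.pi / m
    rad = rng.uniform(0.1, 0.7, m)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def regular_polygon(radius: float, n: int, center=(0.0, 0.0)) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)])


@pytest.fixture
def unit_square() -> Contour:
    return Contour(scan_index=0, vertices=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240807)


@pytest.fixture
def minimal_stack_doc() -> dict:
    """Smallest legal annotation JSON document: one scan, one triangle."""
    return {
        "scan_spacing_mm": 0.12,
        "x_scale_mm_per_px": None,
        "z_scale_mm_per_px": None,
        "fovea_center": None,
        "meta": {"eye": "OD"},
        "scans": [
            {
                "scan_index": 0,
                "contours": [
                    {"label": "FS", "vertices_mm": [[0.0, 0.0], [1.0, 0.0], [0.5, 0.5]]}
                ],
            }
        ],
    }


@pytest.fixture
def stack_file(tmp_path, minimal_stack_doc):
    path = tmp_path / "stack.json"
    path.write_text(json.dumps(minimal_stack_doc))
    return path
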