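"""Annotation, paired-measurement and result I/O.

The interchange format for contour annotations is a JSON document, one per
eye/session, holding the raster geometry (inter-scan spacing, optional pixel
scales), an optional fovea center, and one polygon per traced entity per
B-scan.  All geometry downstream of this module works in millimetres;
pixel-space vertices are converted on read using the per-axis scales and a
file that mixes pixel vertices with missing scales is rejected outright.

Schema::

    {
      "scan_spacing_mm": float,
      "x_scale_mm_per_px": float | null,
      "z_scale_mm_per_px": float | null,
      "fovea_center": {"scan_index": int, "x_mm": float} | null,
      "meta": {...},
      "scans": [
        {"scan_index": int,
         "lateral_offset_y_mm": float,          # optional
         "contours": [
            {"label": str,
             "vertices_mm" | "vertices_px": [[x, z], ...]}
         ]}
      ]
    }
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np

from .errors import FormatError, SchemaError, UnitError

logger = logging.getLogger("octvol")

__all__ = [
    "Point2D",
    "Contour",
    "ScanAnnotation",
    "FoveaCenter",
    "AnnotationStack",
    "PairedMeasurements",
    "read_annotation_stack",
    "write_annotation_stack",
    "read_paired_csv",
    "write_paired_csv",
    "write_results",
    "read_results",
]

# Relative tolerance (fraction of scan spacing) for checking that an explicit
# lateral offset agrees with scan_index * scan_spacing.
_OFFSET_RTOL = 0.01


@dataclass(frozen=True)
class Point2D:
    """A vertex on one B-scan: lateral position ``x`` and axial position ``z``, mm."""

    x: float
    z: float


@dataclass
class Contour:
    """A closed, implicitly-cyclic planar polygon traced on one B-scan.

    ``vertices`` is an ``(n, 2)`` float array of ``(x, z)`` positions in mm.
    The last vertex connects back to the first; a duplicated closing vertex
    is stripped on construction.  Simplicity (absence of self-intersection)
    is checked lazily by the geometry module and cached in ``validated``.
    """

    scan_index: int
    vertices: np.ndarray
    label: str = "entity"
    validated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise SchemaError(
                f"contour vertices must be an (n, 2) array, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise SchemaError("contour vertices must be finite")
        if len(v) > 1 and np.array_equal(v[0], v[-1]):
            v = v[:-1]
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def points(self) -> list[Point2D]:
        return [Point2D(float(x), float(z)) for x, z in self.vertices]

    def closed_vertices(self) -> np.ndarray:
        """Vertices with the first repeated at the end (explicit ring)."""
        return np.vstack([self.vertices, self.vertices[:1]])


@dataclass
class ScanAnnotation:
    """All contours drawn on one B-scan, plus its lateral raster offset (mm)."""

    scan_index: int
    lateral_offset_y: float
    contours: list[Contour] = field(default_factory=list)


@dataclass(frozen=True)
class FoveaCenter:
    """Location of the foveal centre: the B-scan it falls on and its lateral x (mm)."""

    scan_index: int
    x_mm: float


@dataclass
class AnnotationStack:
    """An ordered raster of annotated B-scans — the unit of volumetric measurement."""

    scan_spacing: float
    scans: list[ScanAnnotation]
    x_scale: float | None = None
    z_scale: float | None = None
    fovea_center: FoveaCenter | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.scan_spacing > 0):
            raise UnitError(f"scan_spacing must be > 0 mm, got {self.scan_spacing}")
        indices = [s.scan_index for s in self.scans]
        if any(i < 0 for i in indices):
            raise SchemaError("scan_index must be >= 0")
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise SchemaError("scan_index must be strictly increasing")
        tol = _OFFSET_RTOL * self.scan_spacing
        for s in self.scans:
            expected = s.scan_index * self.scan_spacing
            if abs(s.lateral_offset_y - expected) > tol:
                raise SchemaError(
                    f"scan {s.scan_index}: lateral_offset_y {s.lateral_offset_y} "
                    f"inconsistent with scan_index * scan_spacing = {expected}"
                )

    def iter_contours(self, label: str | None = None) -> Iterator[tuple[ScanAnnotation, Contour]]:
        for scan in self.scans:
            for contour in scan.contours:
                if label is None or contour.label == label:
                    yield scan, contour

    def labels(self) -> set[str]:
        return {c.label for _, c in self.iter_contours()}

    def fovea_offset_y(self) -> float | None:
        """Lateral raster offset (mm) of the B-scan carrying the foveal centre."""
        if self.fovea_center is None:
            return None
        return self.fovea_center.scan_index * self.scan_spacing


@dataclass
class PairedMeasurements:
    """Paired volumes (mm^3) from two methods/observers, one pair per subject."""

    method_a_label: str
    method_b_label: str
    pairs: list[tuple[str, float, float]]

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def values_a(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)

    @property
    def values_b(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)


# ---------------------------------------------------------------------------
# Annotation JSON
# ---------------------------------------------------------------------------


def _require(obj: dict, key: str, where: str) -> Any:
    if key not in obj:
        raise SchemaError(f"missing key '{key}' in {where}")
    return obj[key]


def read_annotation_stack(path: str | Path, units: str | None = None) -> AnnotationStack:
    """Read an annotation stack from JSON, returning all vertices in mm.

    Parameters
    ----------
    path:
        Path to the annotation JSON file.
    units:
        ``"mm"``, ``"px"`` or ``None`` (infer per contour from whether the
        file uses ``vertices_mm`` or ``vertices_px``).  When given, every
        contour in the file must use the stated unit.

    Pixel vertices are converted using ``x_scale_mm_per_px`` /
    ``z_scale_mm_per_px``; pixel vertices without both scales raise
    :class:`~octvol.errors.UnitError`.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if units not in (None, "mm", "px"):
        raise UnitError(f"units must be 'mm' or 'px', got {units!r}")

    spacing = _require(doc, "scan_spacing_mm", "document root")
    if not isinstance(spacing, (int, float)) or not spacing > 0:
        raise UnitError(f"scan_spacing_mm must be a positive number, got {spacing!r}")
    x_scale = doc.get("x_scale_mm_per_px")
    z_scale = doc.get("z_scale_mm_per_px")

    fovea = None
    if doc.get("fovea_center") is not None:
        fc = doc["fovea_center"]
        fovea = FoveaCenter(
            scan_index=int(_require(fc, "scan_index", "fovea_center")),
            x_mm=float(_require(fc, "x_mm", "fovea_center")),
        )

    scans: list[ScanAnnotation] = []
    for rec in _require(doc, "scans", "document root"):
        idx = int(_require(rec, "scan_index", "scan record"))
        offset = rec.get("lateral_offset_y_mm")
        if offset is None:
            offset = idx * spacing
        contours = []
        for c in rec.get("contours", []):
            label = str(_require(c, "label", f"contour on scan {idx}"))
            has_mm = "vertices_mm" in c
            has_px = "vertices_px" in c
            if has_mm == has_px:
                raise SchemaError(
                    f"contour '{label}' on scan {idx} must have exactly one of "
                    "'vertices_mm' or 'vertices_px'"
                )
            if units == "mm" and has_px:
                raise UnitError(
                    f"units='mm' requested but contour '{label}' on scan {idx} "
                    "has 'vertices_px'"
                )
            if units == "px" and has_mm:
                raise UnitError(
                    f"units='px' requested but contour '{label}' on scan {idx} "
                    "has 'vertices_mm'"
                )
            verts = np.asarray(c["vertices_mm" if has_mm else "vertices_px"], dtype=float)
            if has_px:
                if x_scale is None or z_scale is None:
                    raise UnitError(
                        f"contour '{label}' on scan {idx} has pixel vertices but "
                        "x_scale_mm_per_px/z_scale_mm_per_px are not set"
                    )
                verts = verts * np.array([x_scale, z_scale], dtype=float)
            if len(verts) < 3:
                raise SchemaError(
                    f"contour '{label}' on scan {idx} has {len(verts)} vertices; >= 3 required"
                )
            contours.append(Contour(scan_index=idx, vertices=verts, label=label))
        scans.append(ScanAnnotation(scan_index=idx, lateral_offset_y=float(offset), contours=contours))

    return AnnotationStack(
        scan_spacing=float(spacing),
        scans=scans,
        x_scale=x_scale,
        z_scale=z_scale,
        fovea_center=fovea,
        meta=dict(doc.get("meta", {})),
    )


def write_annotation_stack(stack: AnnotationStack, path: str | Path) -> None:
    """Write an annotation stack to JSON (always in mm)."""
    doc = {
        "scan_spacing_mm": stack.scan_spacing,
        "x_scale_mm_per_px": stack.x_scale,
        "z_scale_mm_per_px": stack.z_scale,
        "fovea_center": (
            None
            if stack.fovea_center is None
            else {"scan_index": stack.fovea_center.scan_index, "x_mm": stack.fovea_center.x_mm}
        ),
        "meta": stack.meta,
        "scans": [
            {
                "scan_index": s.scan_index,
                "lateral_offset_y_mm": s.lateral_offset_y,
                "contours": [
                    {"label": c.label, "vertices_mm": c.vertices.tolist()} for c in s.contours
                ],
            }
            for s in stack.scans
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Paired CSV
# ---------------------------------------------------------------------------


def read_paired_csv(
    path: str | Path,
    method_a_label: str = "value_a",
    method_b_label: str = "value_b",
) -> PairedMeasurements:
    """Read a ``subject,value_a,value_b`` CSV of paired measurements.

    Rows with a missing value in either column are dropped with a logged
    warning (standard Bland-Altman practice: incomplete pairs are excluded,
    never imputed).  A non-numeric, non-empty value is a parse error that
    names the row.
    """
    path = Path(path)
    pairs: list[tuple[str, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: no pairs (empty file)") from None
        expected = ["subject", "value_a", "value_b"]
        if [h.strip().lower() for h in header[:3]] != expected:
            raise SchemaError(f"{path}: expected header subject,value_a,value_b, got {header}")
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise SchemaError(f"{path}: row {row_no}: expected 3 columns, got {len(row)}")
            subject, a_raw, b_raw = row[0].strip(), row[1].strip(), row[2].strip()
            if not a_raw or not b_raw:
                logger.warning(
                    "%s: row %d (subject %r): incomplete pair dropped", path, row_no, subject
                )
                continue
            try:
                a, b = float(a_raw), float(b_raw)
            except ValueError:
                raise SchemaError(
                    f"{path}: row {row_no}: non-numeric value in ({a_raw!r}, {b_raw!r})"
                ) from None
            pairs.append((subject, a, b))
    if not pairs:
        raise SchemaError(f"{path}: no pairs")
    return PairedMeasurements(method_a_label, method_b_label, pairs)


def write_paired_csv(pairs: PairedMeasurements, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "value_a", "value_b"])
        for subject, a, b in pairs.pairs:
            writer.writerow([subject, repr(a), repr(b)])


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def _to_jsonable(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return list(value)
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, dict):
        return {k: _to_jsonable(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_to_jsonable(v) for v in value]
    return value


def write_results(result: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a result dataclass to JSON or CSV, round-trip safe.

    JSON keeps full float precision (Python's ``json`` uses ``repr``).  CSV
    is supported for per-scan volume tables (one row per scan plus a total
    row) and as flat key/value for scalar results.
    """
    from .volumetry import VolumeResult  # local import to avoid a cycle

    path = Path(path)
    if format == "json":
        payload = {"_type": type(result).__name__}
        payload.update(_to_jsonable(result))
        path.write_text(json.dumps(payload, indent=1))
    elif format == "csv":
        if isinstance(result, VolumeResult):
            with open(path, "w", newline="") as fh:
                fh.write(f"# _type=VolumeResult\n")
                fh.write(f"# scan_spacing_mm={result.scan_spacing!r}\n")
                fh.write(f"# protocol={result.protocol}\n")
                writer = csv.writer(fh)
                writer.writerow(["scan_index", "area_mm2"])
                for idx, area in result.per_scan:
                    writer.writerow([idx, repr(area)])
                writer.writerow(["total_volume_mm3", repr(result.total_volume)])
        else:
            flat = _to_jsonable(result)
            if not isinstance(flat, dict):
                raise FormatError(f"cannot write {type(result).__name__} as CSV")
            with open(path, "w", newline="") as fh:
                fh.write(f"# _type={type(result).__name__}\n")
                writer = csv.writer(fh)
                writer.writerow(["field", "value"])
                for key, value in flat.items():
                    writer.writerow([key, json.dumps(value)])
    else:
        raise FormatError(f"unknown format {format!r}; expected 'csv' or 'json'")


def read_results(path: str | Path, format: str = "json") -> Any:
    """Read back a result written by :func:`write_results`.

    JSON results are re-hydrated into their dataclass when the type is one
    of octvol's result types, otherwise returned as a dict.  CSV volume
    tables are re-hydrated into :class:`~octvol.volumetry.VolumeResult`.
    """
    from .agreement import AgreementResult
    from .volumetry import VolumeResult

    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        kind = doc.pop("_type", None)
        if kind == "VolumeResult":
            doc["per_scan"] = [(int(i), float(a)) for i, a in doc["per_scan"]]
            return VolumeResult(**doc)
        if kind == "AgreementResult":
            for key in ("bias_ci", "loa_ci_lower", "loa_ci_upper"):
                doc[key] = tuple(doc[key])
            for key in ("means", "diffs"):
                doc[key] = np.asarray(doc[key], dtype=float)
            return AgreementResult(**doc)
        return doc
    if format == "csv":
        meta: dict[str, str] = {}
        rows: list[list[str]] = []
        with open(path, newline="") as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key] = value
                else:
                    rows.extend(csv.reader([line]))
        if meta.get("_type") == "VolumeResult":
            per_scan = []
            total = None
            for row in rows[1:]:
                if not row:
                    continue
                if row[0] == "total_volume_mm3":
                    total = float(row[1])
                else:
                    per_scan.append((int(row[0]), float(row[1])))
            return VolumeResult(
                per_scan=per_scan,
                scan_spacing=float(meta["scan_spacing_mm"]),
                total_volume=float(total),
                protocol=meta["protocol"],
            )
        return {row[0]: row[1] for row in rows[1:] if row}
    raise FormatError(f"unknown format {format!r}; expected 'csv' or 'json'")
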