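"""Cell contour ingestion and normalization.

Segmentation polygons (Labelme JSON or plain coordinate tables) are turned
into centered, principal-axis aligned, equidistantly resampled closed
contours — the raw shape representation every downstream stage consumes.
Each contour also yields its intra-cell pairwise distance matrix, the
rigid-transform-invariant object compared by the Gromov–Wasserstein metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

__all__ = [
    "RawCell",
    "Contour",
    "IntraDistanceMatrix",
    "load_annotations",
    "resample_contour",
    "align_contour",
    "intra_distance_matrix",
    "process_cells",
    "contours_to_frame",
]


class DegenerateGeometryError(ValueError):
    """Polygon has zero perimeter or too few vertices to resample."""


@dataclass
class RawCell:
    """One segmented cell: an ordered boundary polygon plus its time stamp."""

    cell_id: str
    time_label: float
    polygon: np.ndarray  # (n, 2), open representation (first != last)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (n, 2) array")
        # store open: drop a duplicated closing vertex
        if len(self.polygon) > 1 and np.allclose(self.polygon[0], self.polygon[-1]):
            self.polygon = self.polygon[:-1]
        if not np.isfinite(self.time_label):
            raise ValueError("time_label must be finite")


@dataclass
class Contour:
    """Resampled closed contour: K points equidistant in arc length."""

    cell_id: str
    time_label: float
    points: np.ndarray  # (K, 2)
    aligned: bool = False
    isotropic: bool = False  # alignment skipped (no preferred axis)

    @property
    def K(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclass
class IntraDistanceMatrix:
    """Pairwise Euclidean distances between a contour's sample points."""

    cell_id: str
    D: np.ndarray  # (K, K) symmetric, zero diagonal


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _area_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * cross.sum()
    if abs(A) < 1e-12:
        return pts.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * A)
    cy = np.sum((y + yn) * cross) / (6.0 * A)
    return np.array([cx, cy])


def _parse_labelme(path: Path) -> tuple[list[RawCell], int]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed Labelme JSON in {path}: {exc}") from exc
    time_label = _extract_time(doc, path)
    cells: list[RawCell] = []
    dropped = 0
    for i, shape in enumerate(doc.get("shapes", [])):
        pts = np.asarray(shape.get("points", []), dtype=float)
        if len(pts) < 3 or abs(_polygon_area(pts)) == 0.0:
            dropped += 1
            continue
        label = shape.get("label", "cell")
        cells.append(RawCell(f"{path.stem}:{label}:{i}", time_label, pts))
    return cells, dropped


def _extract_time(doc: dict, path: Path) -> float:
    # accept explicit keys, or a dayN / dN token in the file name
    for key in ("time", "day", "time_label"):
        if key in doc:
            return float(doc[key])
        flags = doc.get("flags") or {}
        if key in flags:
            return float(flags[key])
    import re

    m = re.search(r"(?:day|d|t)[\-_]?(\d+(?:\.\d+)?)", path.stem, re.IGNORECASE)
    if m:
        return float(m.group(1))
    raise ValueError(f"no time label found for {path} (need 'time'/'day' key or dayN in name)")


def load_annotations(path, format: str = "labelme_json") -> list[RawCell]:
    """Read segmentation polygons from disk.

    Parameters
    ----------
    path
        A file or directory. Directories are scanned for ``*.json`` (labelme)
        or ``*.csv`` files.
    format
        ``"labelme_json"`` — Labelme export, one polygon per ``shapes`` entry,
        image-level time label from a ``time``/``day`` key or a ``dayN`` token
        in the file name. ``"csv_table"`` — long table with columns
        ``cell_id, x, y`` and a ``time`` (or ``day``) column.

    Degenerate polygons (fewer than 3 vertices, zero area) are dropped; the
    count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files: list[Path]
    if path.is_dir():
        pattern = "*.json" if format == "labelme_json" else "*.csv"
        files = sorted(path.glob(pattern))
    else:
        files = [path]

    cells: list[RawCell] = []
    dropped = 0
    if format == "labelme_json":
        for f in files:
            c, d = _parse_labelme(f)
            cells.extend(c)
            dropped += d
    elif format == "csv_table":
        for f in files:
            df = pd.read_csv(f)
            tcol = next((c for c in ("time", "day", "time_label") if c in df.columns), None)
            if tcol is None:
                raise ValueError(f"{f}: csv table needs a 'time' or 'day' column")
            for cid, grp in df.groupby("cell_id", sort=True):
                pts = grp[["x", "y"]].to_numpy(dtype=float)
                tvals = grp[tcol].unique()
                if len(tvals) != 1 or not np.isfinite(tvals[0]):
                    logger.warning("cell %s rejected: ambiguous/missing time label", cid)
                    dropped += 1
                    continue
                if len(pts) >= 3 and np.allclose(pts[0], pts[-1]):
                    pts = pts[:-1]
                if len(pts) < 3 or abs(_polygon_area(pts)) == 0.0:
                    dropped += 1
                    continue
                cells.append(RawCell(str(cid), float(tvals[0]), pts))
    else:
        raise ValueError(f"unknown format {format!r}")
    if dropped:
        logger.info("load_annotations: dropped %d degenerate/invalid records", dropped)
    load_annotations.last_dropped = dropped  # type: ignore[attr-defined]
    return cells


def resample_contour(cell: RawCell, K: int = 150) -> Contour:
    """Resample a closed polygon to ``K`` points equidistant in arc length.

    Orientation is normalized to counter-clockwise and the parameterization
    starts at the boundary point farthest from the centroid, removing the
    start-vertex ambiguity of the raw annotation.
    """
    pts = np.asarray(cell.polygon, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{cell.cell_id}: polygon needs >= 3 vertices")
    if _polygon_area(pts) < 0:  # force CCW
        pts = pts[::-1]

    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    P = float(seg.sum())
    if P <= 0:
        raise DegenerateGeometryError(f"{cell.cell_id}: zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seg)])  # arc length at each vertex

    # canonical start: the vertex farthest from the polygon's area centroid
    # (the area centroid is invariant to boundary re-parameterization, so
    # resampling at the same K is idempotent)
    centroid = _area_centroid(pts)
    start_idx = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
    s0 = cum[start_idx]

    s = (s0 + P * np.arange(K) / K) % P
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return Contour(cell.cell_id, cell.time_label, np.column_stack([x, y]))


def align_contour(contour: Contour, normalize_scale: bool = False) -> Contour:
    """Center at the origin and rotate the principal axis onto axis 1.

    Sign conventions: the third moment of the first coordinate is made
    nonnegative (fixes the 180-degree rotation), then the third moment of the
    second coordinate is made nonnegative (fixes the reflection). Point sets
    with equal covariance eigenvalues (relative gap < 1e-9) carry no preferred
    axis; they are centered only and flagged ``isotropic``.
    """
    pts = contour.points - contour.points.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    isotropic = (evals[1] - evals[0]) <= 1e-9 * max(evals[1], 1e-300)
    if not isotropic:
        major, minor = evecs[:, 1], evecs[:, 0]
        R = np.column_stack([major, minor])  # maps aligned frame -> data frame
        pts = pts @ R  # coordinates in the principal frame
        if np.sum(pts[:, 0] ** 3) < 0:
            pts[:, 0] = -pts[:, 0]
        if np.sum(pts[:, 1] ** 3) < 0:
            pts[:, 1] = -pts[:, 1]
    if normalize_scale:
        rms = np.sqrt(np.mean(np.sum(pts**2, axis=1)))
        if rms > 0:
            pts = pts / rms
    return replace(contour, points=pts, aligned=True, isotropic=bool(isotropic))


def intra_distance_matrix(contour: Contour) -> IntraDistanceMatrix:
    """Pairwise Euclidean distance matrix of the contour's sample points."""
    D = squareform(pdist(contour.points))
    return IntraDistanceMatrix(contour.cell_id, D)


def process_cells(
    cells: Iterable[RawCell], K: int = 150, normalize_scale: bool = False
) -> list[Contour]:
    """resample + align every cell; the standard preprocessing chain."""
    return [align_contour(resample_contour(c, K=K), normalize_scale=normalize_scale) for c in cells]


def contours_to_frame(contours: Sequence[Contour]) -> pd.DataFrame:
    """Long-format table (cell_id, time, point_index, x, y) for CSV export."""
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.cell_id, c.time_label, i, x, y))
    return pd.DataFrame(rows, columns=["cell_id", "time", "point_index", "x", "y"])
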