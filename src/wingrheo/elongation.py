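"""Cell-elongation tensor, regional means, peak alignment, shear decomposition.

The elongation of a cell with polygonal outline is the traceless symmetric
tensor with components

    eps_xx = (1/Ac) * integral over the cell of cos(2*phi) dA
    eps_xy = (1/Ac) * integral over the cell of sin(2*phi) dA

where phi is the polar angle of the area element about the cell centroid and
Ac the cell area.  Magnitude is sqrt(eps_xx^2 + eps_xy^2), orientation
0.5*atan2(eps_xy, eps_xx).  The x axis is the proximal-distal (PD) tissue
axis and eps_xx is plotted as Q, the PD component of cell elongation.

Both integrals are evaluated exactly: each edge of the centroid fan is a
triangle with one vertex at the origin, where r(phi) = d / cos(phi - phi0)
for the line carrying the opposite edge, and

    int cos(2 phi) r^2/2 dphi = (d^2/2) [cos(2 phi0)(2 psi - tan psi)
                                         + 2 sin(2 phi0) ln cos psi]
    int sin(2 phi) r^2/2 dphi = (d^2/2) [sin(2 phi0)(2 psi - tan psi)
                                         - 2 cos(2 phi0) ln cos psi]

with psi = phi - phi0 in (-pi/2, pi/2).  Signed triangles make this valid
for any simple polygon, convex or not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "CellPolygon",
    "ElongationTensor",
    "CellMesh",
    "MeshTimeSeries",
    "PeakAlignment",
    "elongation_tensor",
    "mean_Q",
    "align_to_peak",
    "coarse_shear_decomposition",
    "polygon_second_moments",
]


@dataclass(frozen=True)
class ElongationTensor:
    """Traceless symmetric elongation tensor ((eps_xx, eps_xy), (eps_xy, -eps_xx))."""

    eps_xx: float
    eps_xy: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.eps_xx, self.eps_xy))

    @property
    def angle(self) -> float:
        """Orientation of the elongation axis, radians in (-pi/2, pi/2]."""
        return 0.5 * float(np.arctan2(self.eps_xy, self.eps_xx))


@dataclass
class CellPolygon:
    """Simple polygon cell outline (um), counter-clockwise, positive area."""

    vertices: np.ndarray
    cell_id: int = 0
    region: str = "blade"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("vertices must be an (n>=3, 2) array")
        poly = _ShapelyPolygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"cell {self.cell_id}: degenerate or self-intersecting polygon")
        if _signed_area(v) < 0:
            v = v[::-1]
        self.vertices = v

    @property
    def area(self) -> float:
        return _signed_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return _centroid(self.vertices)


@dataclass
class CellMesh:
    """A snapshot of segmented cells, each with a persistent id and region label."""

    cells: list[CellPolygon]

    def region_cells(self, region: str | None = None) -> list[CellPolygon]:
        if region is None:
            return list(self.cells)
        return [c for c in self.cells if c.region == region]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"cell_id": c.cell_id, "region": c.region, "vertices": c.vertices.tolist()}
                for c in self.cells
            ]
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "CellMesh":
        return cls(
            cells=[
                CellPolygon(
                    vertices=np.asarray(d["vertices"]),
                    cell_id=d["cell_id"],
                    region=d.get("region", "blade"),
                )
                for d in json.loads(text)
            ]
        )

    @classmethod
    def load(cls, path: str | Path) -> "CellMesh":
        return cls.from_json(Path(path).read_text())

    def elongation_table(self) -> pd.DataFrame:
        """Per-cell elongation components as a tidy table."""
        rows = []
        for c in self.cells:
            t = elongation_tensor(c)
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "region": c.region,
                    "eps_xx": t.eps_xx,
                    "eps_xy": t.eps_xy,
                    "magnitude": t.magnitude,
                    "angle": t.angle,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class MeshTimeSeries:
    """Time-ordered mesh snapshots (times in hAPF or any consistent hours)."""

    times: np.ndarray
    meshes: list[CellMesh]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.meshes):
            raise ValueError("times and meshes must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# geometry helpers (exact polygon integrals)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def _centroid(v: np.ndarray) -> np.ndarray:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    c = x * yn - xn * y
    a = 0.5 * np.sum(c)
    cx = np.sum((x + xn) * c) / (6 * a)
    cy = np.sum((y + yn) * c) / (6 * a)
    return np.array([cx, cy])


def polygon_second_moments(v: np.ndarray, about: np.ndarray | None = None):
    """Area and central second moments (Ixx=<x^2>A, Ixy, Iyy) of a polygon.

    ``about`` defaults to the centroid.  Uses the exact shoelace-type
    formulas for integrals of x^2, xy, y^2 over the polygon interior.
    """
    v = np.asarray(v, dtype=float)
    if about is None:
        about = _centroid(v)
    v = v - about
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    c = x * yn - xn * y
    area = 0.5 * float(np.sum(c))
    ixx = float(np.sum((x * x + x * xn + xn * xn) * c)) / 12.0
    iyy = float(np.sum((y * y + y * yn + yn * yn) * c)) / 12.0
    ixy = float(np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * c)) / 24.0
    return area, ixx, ixy, iyy


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _fan_harmonic_integrals(v: np.ndarray) -> tuple[float, float]:
    """Exact (int cos 2phi dA, int sin 2phi dA) about the origin for the
    polygon ``v`` (must enclose the origin via its signed centroid fan)."""
    ic = is_ = 0.0
    n = len(v)
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        cross = a[0] * b[1] - a[1] * b[0]
        if cross == 0.0:
            continue  # edge collinear with origin: zero area contribution
        e = b - a
        # foot of the perpendicular from the origin to the line through a, b
        t = -(a @ e) / (e @ e)
        f = a + t * e
        d2 = f @ f
        if d2 == 0.0:
            continue
        phi0 = np.arctan2(f[1], f[0])
        psi_a = _wrap_angle(np.arctan2(a[1], a[0]) - phi0)
        psi_b = _wrap_angle(np.arctan2(b[1], b[0]) - phi0)
        c2, s2 = np.cos(2 * phi0), np.sin(2 * phi0)

        def _F(psi):
            g = 2 * psi - np.tan(psi)
            h = np.log(np.cos(psi))
            return c2 * g + 2 * s2 * h, s2 * g - 2 * c2 * h

        fc_b, fs_b = _F(psi_b)
        fc_a, fs_a = _F(psi_a)
        ic += 0.5 * d2 * (fc_b - fc_a)
        is_ += 0.5 * d2 * (fs_b - fs_a)
    return ic, is_


def elongation_tensor(cell: CellPolygon) -> ElongationTensor:
    """Area-normalized elongation tensor of one cell, exactly integrated.

    phi is measured about the cell centroid, which makes the tensor invariant
    to translation and uniform scaling; a regular n-gon (n >= 3, n != 1, 2)
    has zero elongation because the 2*phi harmonic averages out.
    """
    v = cell.vertices - cell.centroid
    area = _signed_area(cell.vertices)
    ic, is_ = _fan_harmonic_integrals(v)
    return ElongationTensor(eps_xx=ic / area, eps_xy=is_ / area)


# ---------------------------------------------------------------------------
# regional statistics


def mean_Q(mesh: CellMesh, region: str | None = "blade", *, weight: str = "cell") -> float:
    """Regional mean of the PD elongation component eps_xx (plotted as Q).

    ``weight='cell'`` (default) averages per cell; ``weight='area'`` weights
    each cell by its area (which regional average the original tooling used
    is not documented, so both are provided).
    """
    cells = mesh.region_cells(region)
    if not cells:
        raise ValueError(f"region {region!r} is empty")
    q = np.array([elongation_tensor(c).eps_xx for c in cells])
    if weight == "cell":
        return float(q.mean())
    if weight == "area":
        w = np.array([c.area for c in cells])
        return float(np.sum(w * q) / np.sum(w))
    raise ValueError("weight must be 'cell' or 'area'")


# ---------------------------------------------------------------------------
# peak alignment (hRPCE origin)


@dataclass
class PeakAlignment:
    """Result of quadratic peak refinement of a blade-mean elongation series."""

    peak_time: float
    aligned_times: np.ndarray
    window: tuple[int, int]
    flags: list[str] = field(default_factory=list)


def align_to_peak(
    times: Sequence[float], values: Sequence[float], *, half_window: int = 40
) -> PeakAlignment:
    """Refine the elongation maximum with a local quadratic fit.

    A parabola is least-squares fitted to the ``half_window`` frames on each
    side of the absolute maximum (window truncated at the series boundaries,
    flagged if so); the vertex time becomes the 0 hRPCE origin and all times
    are re-expressed relative to it.  An upward-opening fit has no maximum
    and is an error; a vertex falling outside the window is flagged and the
    argmax time is used instead.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 3:
        raise ValueError("need >= 3 (time, value) pairs")
    flags: list[str] = []
    imax = int(np.argmax(y))
    if np.sum(y == y[imax]) > 1:
        flags.append("tied_maximum")
    lo, hi = max(0, imax - half_window), min(len(t), imax + half_window + 1)
    if lo == 0 or hi == len(t):
        flags.append("window_truncated")
    tw, yw = t[lo:hi], y[lo:hi]
    coef = np.polyfit(tw - tw.mean(), yw, 2)
    if coef[0] >= 0:
        raise ValueError("quadratic opens upward: no elongation maximum in window")
    vertex = tw.mean() - coef[1] / (2 * coef[0])
    if not (tw[0] <= vertex <= tw[-1]):
        flags.append("vertex_outside_window")
        vertex = float(t[imax])
    return PeakAlignment(
        peak_time=float(vertex), aligned_times=t - vertex, window=(lo, hi), flags=flags
    )


# ---------------------------------------------------------------------------
# coarse shear decomposition


def _region_axis_log_ratio(mesh: CellMesh, region: str | None) -> float:
    """0.5*ln(lambda_PD/lambda_AP) of the region's area-normalized
    second-moment ellipse (lambda = principal axis lengths, PD = the
    eigenvector closer to the x axis)."""
    cells = mesh.region_cells(region)
    if not cells:
        raise ValueError(f"region {region!r} is empty")
    # accumulate cell moments about the common region centroid
    areas = np.array([c.area for c in cells])
    cents = np.array([c.centroid for c in cells])
    total_area = float(areas.sum())
    if total_area <= 0:
        raise ValueError("region has zero area")
    rc = (areas[:, None] * cents).sum(axis=0) / total_area
    ixx = ixy = iyy = 0.0
    for c in cells:
        _, a_xx, a_xy, a_yy = polygon_second_moments(c.vertices, about=rc)
        ixx += a_xx
        ixy += a_xy
        iyy += a_yy
    m = np.array([[ixx, ixy], [ixy, iyy]]) / total_area
    evals, evecs = np.linalg.eigh(m)
    # eigenvector more aligned with x carries the PD axis
    align_x = np.abs(evecs[0, :])
    i_pd = int(np.argmax(align_x))
    i_ap = 1 - i_pd
    lam_pd, lam_ap = np.sqrt(evals[i_pd]), np.sqrt(evals[i_ap])
    return 0.5 * float(np.log(lam_pd / lam_ap))


def coarse_shear_decomposition(
    series: MeshTimeSeries, region: str | None = "blade", *, weight: str = "cell"
) -> pd.DataFrame:
    """Two-way decomposition of PD tissue shear per time interval.

    total_xx is the change of the region's shape anisotropy
    0.5*ln(lambda_PD/lambda_AP); cell_shape_xx is the change of the regional
    mean elongation Q; rearrangement_xx = total_xx - cell_shape_xx is the
    residual, which absorbs neighbour exchanges, divisions, extrusions and
    correlation terms.  The closure total = shape + rearrangement therefore
    holds exactly at every interval.  Columns *_cum are cumulative sums.
    """
    if len(series.meshes) < 2:
        raise ValueError("need >= 2 snapshots")
    logratio = np.array([_region_axis_log_ratio(m, region) for m in series.meshes])
    q = np.array([mean_Q(m, region, weight=weight) for m in series.meshes])
    total = np.diff(logratio)
    shape = np.diff(q)
    rearr = total - shape
    df = pd.DataFrame(
        {
            "t_start": series.times[:-1],
            "t_end": series.times[1:],
            "total_xx": total,
            "cell_shape_xx": shape,
            "rearrangement_xx": rearr,
        }
    )
    df["total_xx_cum"] = np.cumsum(total)
    df["cell_shape_xx_cum"] = np.cumsum(shape)
    df["rearrangement_xx_cum"] = np.cumsum(rearr)
    return df
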