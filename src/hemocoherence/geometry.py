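"""2D microvessel flow domains and structured quadrilateral meshes.

A vessel is a single unbranched segment described by a centerline polyline with
a per-point lumen width (both in micrometres). The flow domain is bounded by
the two wall curves obtained by offsetting the centerline by half the local
width along the centerline normals; the inlet and outlet are the end
cross-sections. Meshing is transfinite (structured, body-fitted) between the
wall curves, which yields the quadrilateral cells the finite-volume solver
expects. All mesh coordinates are SI metres; micrometres are used at the I/O
boundary only.

Segments can also be recovered from 8-bit binary masks via morphological
skeletonization plus the Euclidean distance transform (a documented stand-in
for whatever image pipeline produced the mask); bifurcating or multi-component
masks are rejected explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UM = 1e-6  # micrometre in metres

#: Cell-data bitmask values marking boundary-adjacent cells in VTK exports.
BOUNDARY_TAGS = {"inlet": 1, "outlet": 2, "wall_lower": 4, "wall_upper": 8}


class GeometryError(ValueError):
    """Invalid or unsupported vessel geometry."""


class MeshingError(GeometryError):
    """Mesh generation produced inverted or degenerate cells."""


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


@dataclass
class VesselSegment:
    """A single 2D microvessel: centerline + width profile, micrometres."""

    vessel_id: str
    centerline: np.ndarray        # (N, 2) um
    width_profile: np.ndarray     # (N,) um
    inlet_velocity: float         # um/s

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.width_profile = np.asarray(self.width_profile, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise GeometryError("centerline needs at least 2 points")
        if self.width_profile.shape != (self.centerline.shape[0],):
            raise GeometryError("one width per centerline point required")
        if not np.all(self.width_profile > 0):
            raise GeometryError("widths must be strictly positive")

    @property
    def nominal_length(self) -> float:
        """Arc length of the centerline, um."""
        return _polyline_length(self.centerline)

    @property
    def nominal_diameter(self) -> float:
        """Arc-length-weighted mean lumen width, um."""
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        w_mid = 0.5 * (self.width_profile[:-1] + self.width_profile[1:])
        return float(np.sum(w_mid * seg) / np.sum(seg))

    @classmethod
    def straight(
        cls,
        diameter: float,
        length: float,
        inlet_velocity: float,
        vessel_id: str = "straight",
        n_points: int = 25,
    ) -> "VesselSegment":
        """Axis-aligned straight channel of constant width."""
        x = np.linspace(0.0, length, n_points)
        centerline = np.column_stack([x, np.zeros_like(x)])
        return cls(vessel_id, centerline, np.full(n_points, float(diameter)),
                   float(inlet_velocity))

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x": self.centerline[:, 0],
                "y": self.centerline[:, 1],
                "width": self.width_profile,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, vessel_id: str | None = None,
                 inlet_velocity: float = 0.0) -> "VesselSegment":
        df = pd.read_csv(path)
        return cls(
            vessel_id or Path(path).stem,
            df[["x", "y"]].to_numpy(float),
            df["width"].to_numpy(float),
            inlet_velocity,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "vessel_id": self.vessel_id,
                    "centerline": self.centerline.tolist(),
                    "width_profile": self.width_profile.tolist(),
                    "inlet_velocity": self.inlet_velocity,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "VesselSegment":
        d = json.loads(Path(path).read_text())
        return cls(
            d["vessel_id"],
            np.asarray(d["centerline"]),
            np.asarray(d["width_profile"]),
            d["inlet_velocity"],
        )


def _tangents_normals(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.gradient(centerline, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise GeometryError("repeated centerline points")
    t = t / norms
    n = np.column_stack([-t[:, 1], t[:, 0]])  # left normal
    return t, n


def build_channel_domain(segment: VesselSegment) -> tuple[np.ndarray, np.ndarray]:
    """Offset the centerline by +/- width/2 along its normals.

    Returns ``(lower, upper)`` wall polylines in SI metres, with the origin at
    the inlet centroid and x along the mean flow direction. Raises
    :class:`GeometryError` when the half-width exceeds the local radius of
    curvature (the offset would self-intersect).
    """
    c = segment.centerline * UM
    w = segment.width_profile * UM
    t, n = _tangents_normals(c)

    # curvature via finite differences of the unit tangent
    dt = np.gradient(t, axis=0)
    ds = np.linalg.norm(np.gradient(c, axis=0), axis=1)
    kappa = np.linalg.norm(dt, axis=1) / ds
    if np.any(0.5 * w * kappa >= 0.95):
        raise GeometryError(
            "half-width exceeds the local radius of curvature; the offset "
            "walls would self-intersect"
        )

    upper = c + 0.5 * w[:, None] * n
    lower = c - 0.5 * w[:, None] * n

    # local frame: origin at inlet centroid, x along mean flow direction
    origin = c[0]
    mean_dir = c[-1] - c[0]
    mean_dir = mean_dir / np.linalg.norm(mean_dir)
    rot = np.array([[mean_dir[0], mean_dir[1]], [-mean_dir[1], mean_dir[0]]])
    upper = (upper - origin) @ rot.T
    lower = (lower - origin) @ rot.T
    return lower, upper


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])]
    )


@dataclass
class Mesh2D:
    """Structured body-fitted quadrilateral mesh; nodes in SI metres.

    ``nodes[i, j]`` is the node at axial index i (0..n_axial) and transverse
    index j (0..n_transverse). Boundary faces are implied by the structure:
    i=0 inlet, i=n_axial outlet, j=0 lower wall, j=n_transverse upper wall.
    """

    nodes: np.ndarray  # (ni+1, nj+1, 2)
    vessel_id: str = ""

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        areas = self.cell_areas_signed()
        if np.any(areas <= 0):
            bad = np.argwhere(areas <= 0)[:5]
            raise MeshingError(
                f"inverted/degenerate cells at (i, j) indices {bad.tolist()}"
            )

    @property
    def n_axial(self) -> int:
        return self.nodes.shape[0] - 1

    @property
    def n_transverse(self) -> int:
        return self.nodes.shape[1] - 1

    @property
    def n_cells(self) -> int:
        return self.n_axial * self.n_transverse

    def cell_areas_signed(self) -> np.ndarray:
        X = self.nodes
        p00, p10 = X[:-1, :-1], X[1:, :-1]
        p11, p01 = X[1:, 1:], X[:-1, 1:]
        d1 = p11 - p00
        d2 = p01 - p10
        return 0.5 * (d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0])

    @property
    def cell_areas(self) -> np.ndarray:
        return np.abs(self.cell_areas_signed())

    @property
    def total_area(self) -> float:
        return float(np.sum(self.cell_areas))

    def cell_centroids(self) -> np.ndarray:
        X = self.nodes
        return 0.25 * (X[:-1, :-1] + X[1:, :-1] + X[1:, 1:] + X[:-1, 1:])

    def refine(self) -> "Mesh2D":
        """One uniform refinement (2x in each direction) by midpoint insertion."""
        X = self.nodes
        ni, nj = self.n_axial, self.n_transverse
        out = np.empty((2 * ni + 1, 2 * nj + 1, 2))
        out[::2, ::2] = X
        out[1::2, ::2] = 0.5 * (X[:-1, :] + X[1:, :])
        out[::2, 1::2] = 0.5 * (X[:, :-1] + X[:, 1:])
        out[1::2, 1::2] = 0.25 * (X[:-1, :-1] + X[1:, :-1] + X[:-1, 1:] + X[1:, 1:])
        return Mesh2D(out, vessel_id=self.vessel_id)

    def boundary_cell_tags(self) -> np.ndarray:
        """Bitmask of BOUNDARY_TAGS for cells adjacent to each boundary."""
        tags = np.zeros((self.n_axial, self.n_transverse), dtype=int)
        tags[0, :] |= BOUNDARY_TAGS["inlet"]
        tags[-1, :] |= BOUNDARY_TAGS["outlet"]
        tags[:, 0] |= BOUNDARY_TAGS["wall_lower"]
        tags[:, -1] |= BOUNDARY_TAGS["wall_upper"]
        return tags

    def to_vtk(self, path, cell_data: dict | None = None) -> None:
        """Write the mesh (and optional cell-centered fields) as legacy
        ASCII VTK with quad cells; boundary tags go out as cell data."""
        ni, nj = self.n_axial, self.n_transverse
        pts = self.nodes.reshape(-1, 2)  # node (i, j) -> row i*(nj+1)+j
        idx = lambda i, j: i * (nj + 1) + j
        lines = [
            "# vtk DataFile Version 3.0",
            f"hemocoherence mesh {self.vessel_id}",
            "ASCII",
            "DATASET UNSTRUCTURED_GRID",
            f"POINTS {len(pts)} double",
        ]
        lines += [f"{x:.9e} {y:.9e} 0.0" for x, y in pts]
        ncell = self.n_cells
        lines.append(f"CELLS {ncell} {5 * ncell}")
        for i in range(ni):
            for j in range(nj):
                lines.append(
                    f"4 {idx(i, j)} {idx(i + 1, j)} {idx(i + 1, j + 1)} {idx(i, j + 1)}"
                )
        lines.append(f"CELL_TYPES {ncell}")
        lines += ["9"] * ncell  # VTK_QUAD
        data = {"boundary_tag": self.boundary_cell_tags().astype(float)}
        if cell_data:
            data.update(cell_data)
        lines.append(f"CELL_DATA {ncell}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9e}" for v in arr.reshape(-1)]
        Path(path).write_text("\n".join(lines) + "\n")


def mesh_domain(
    lower: np.ndarray,
    upper: np.ndarray,
    n_axial: int = 250,
    n_transverse: int = 20,
    vessel_id: str = "",
) -> Mesh2D:
    """Transfinite interpolation between the two wall curves.

    Walls are resampled to ``n_axial + 1`` points by arc length and blended
    linearly across the width. Defaults give 5000 cells with 20 across the
    width. Raises :class:`MeshingError` on inverted cells.
    """
    if n_axial < 1 or n_transverse < 1:
        raise MeshingError("need at least one cell in each direction")
    lo = _resample_polyline(np.asarray(lower, float), n_axial + 1)
    up = _resample_polyline(np.asarray(upper, float), n_axial + 1)
    t = np.linspace(0.0, 1.0, n_transverse + 1)
    nodes = lo[:, None, :] * (1.0 - t)[None, :, None] + up[:, None, :] * t[None, :, None]
    return Mesh2D(nodes, vessel_id=vessel_id)


def mesh_vessel(
    segment: VesselSegment, n_axial: int = 250, n_transverse: int = 20
) -> Mesh2D:
    lower, upper = build_channel_domain(segment)
    return mesh_domain(lower, upper, n_axial, n_transverse, vessel_id=segment.vessel_id)


# ---------------------------------------------------------------------------
# Mask pathway: skeletonization + distance transform.
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def segment_from_mask(
    mask: np.ndarray,
    pixel_size: float,
    threshold: float = 127,
    inlet_velocity: float = 0.0,
    vessel_id: str = "mask",
) -> VesselSegment:
    """Recover a :class:`VesselSegment` from an 8-bit grayscale mask.

    The centerline is the morphological skeleton ordered from one endpoint to
    the other; the local width is twice the Euclidean distance transform at
    the skeleton pixels; both ends are trimmed by one local width because
    distance-transform widths are biased at vessel caps. ``pixel_size`` is in
    um/pixel. Masks with multiple components, loops, or branches raise
    :class:`GeometryError` (declared limitation: single unbranched segments).
    """
    from scipy import ndimage
    from skimage.morphology import skeletonize

    fg = np.asarray(mask) > threshold
    if not fg.any():
        raise GeometryError("mask contains no foreground")
    _, n_comp = ndimage.label(fg, structure=np.ones((3, 3)))
    if n_comp != 1:
        raise GeometryError(f"expected one connected component, found {n_comp}")

    skel = skeletonize(fg)
    coords = {tuple(rc) for rc in np.argwhere(skel)}
    if len(coords) < 3:
        raise GeometryError("skeleton too short to define a centerline")
    nbr_count = {
        rc: sum(((rc[0] + dr, rc[1] + dc) in coords) for dr, dc in _NEIGHBORS)
        for rc in coords
    }
    endpoints = [rc for rc, n in nbr_count.items() if n == 1]
    if any(n > 2 for n in nbr_count.values()) or len(endpoints) != 2:
        raise GeometryError(
            "unsupported topology: skeleton has branches or loops; only "
            "single unbranched segments are handled"
        )

    # walk the skeleton from one endpoint
    path = [endpoints[0]]
    visited = {endpoints[0]}
    while True:
        r, c = path[-1]
        nxt = [
            (r + dr, c + dc)
            for dr, dc in _NEIGHBORS
            if (r + dr, c + dc) in coords and (r + dr, c + dc) not in visited
        ]
        if not nxt:
            break
        # prefer 4-connected steps to avoid diagonal shortcuts
        nxt.sort(key=lambda rc: abs(rc[0] - r) + abs(rc[1] - c))
        path.append(nxt[0])
        visited.add(nxt[0])

    edt = ndimage.distance_transform_edt(fg)
    pts = np.array(path, dtype=float)
    widths = 2.0 * np.array([edt[int(r), int(c)] for r, c in path])

    # trim one local width from each end (cap bias)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    keep = (s >= widths[0]) & (s <= s[-1] - widths[-1])
    if keep.sum() < 2:
        raise GeometryError("segment too short after end trimming")
    pts, widths = pts[keep], widths[keep]

    centerline = np.column_stack([pts[:, 1], pts[:, 0]]) * pixel_size  # (x, y) um
    return VesselSegment(vessel_id, centerline, widths * pixel_size, inlet_velocity)
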