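"""Axisymmetric structured meshes for cylindrical-punch indentation.

The mesh is a structured grid of rectangular elements in the (r, z) plane,
with biquadratic (9-node) displacement elements overlaid by bilinear
(4-node) pressure elements sharing corner nodes -- the Taylor-Hood pair for
the mixed displacement/pressure problem.  Element edges are graded toward
the indenter rim (r = a, z = h) where the contact-pressure gradient is
steepest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import MeshError

__all__ = ["SampleGeometry", "Mesh", "build_mesh"]


@dataclass(frozen=True)
class SampleGeometry:
    """Specimen and indenter geometry (mm).

    thickness : cartilage thickness h
    radius    : specimen (disc) radius R
    indenter_radius : plane-ended indenter radius a, with 0 < a < R
    """

    thickness: float = 2.0
    radius: float = 2.0
    indenter_radius: float = 0.35

    def __post_init__(self):
        if self.thickness <= 0:
            raise MeshError("thickness must be positive")
        if not 0 < self.indenter_radius < self.radius:
            raise MeshError(
                f"need 0 < a < R, got a={self.indenter_radius}, R={self.radius}"
            )

    @property
    def aspect(self) -> float:
        """Indentation aspect ratio a/h."""
        return self.indenter_radius / self.thickness

    @property
    def contact_area(self) -> float:
        """Nominal contact area pi a^2 (mm^2)."""
        return np.pi * self.indenter_radius**2


def _graded(x0, x1, n, ratio):
    """n+1 points on [x0, x1]; |ratio| is last/first interval size, sizes
    geometric.  ratio > 0 refines toward x0, ratio < 0 toward x1."""
    if n < 1:
        raise MeshError("need at least one element per segment")
    q = abs(ratio) ** (1.0 / max(n - 1, 1))
    sizes = q ** np.arange(n)
    if ratio < 0:
        sizes = sizes[::-1]
    sizes = sizes / sizes.sum() * (x1 - x0)
    return np.concatenate([[x0], x0 + np.cumsum(sizes)])


@dataclass
class Mesh:
    """Structured Taylor-Hood mesh; see :func:`build_mesh`."""

    geometry: SampleGeometry
    r9: np.ndarray  # displacement-node radii, shape (n9,)
    z9: np.ndarray
    r4: np.ndarray  # pressure-node radii, shape (n4,)
    z4: np.ndarray
    conn9: np.ndarray  # (nelem, 9) displacement connectivity
    conn4: np.ndarray  # (nelem, 4) pressure connectivity
    shape: tuple  # (nr, nz) element counts
    node_sets: dict = field(default_factory=dict)  # displacement-node masks
    pnode_sets: dict = field(default_factory=dict)  # pressure-node masks

    @property
    def n_elements(self) -> int:
        return self.conn9.shape[0]

    @property
    def n_disp_nodes(self) -> int:
        return self.r9.size

    @property
    def n_pressure_nodes(self) -> int:
        return self.r4.size

    @property
    def contact_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_sets["contact"])

    def element_sizes(self) -> tuple:
        """(dr, dz) per element, from the corner nodes."""
        c = self.conn9
        dr = self.r9[c[:, 1]] - self.r9[c[:, 0]]
        dz = self.z9[c[:, 3]] - self.z9[c[:, 0]]
        return dr, dz


def build_mesh(
    geometry: SampleGeometry,
    resolution: float = 1.0,
    grading: float = 3.0,
    counts: tuple = None,
) -> Mesh:
    """Build a graded axisymmetric Taylor-Hood mesh.

    Parameters
    ----------
    geometry : SampleGeometry
    resolution : float
        Scales element counts; 1.0 gives the coarse reference mesh
        (2 elements under the indenter, 4 outside, 4 through the depth),
        2.0 doubles every count.
    grading : float
        Geometric size ratio of the largest to smallest element edge within
        each graded segment; refinement is toward the indenter rim.
    counts : (nr_in, nr_out, nz), optional
        Explicit element counts (under the indenter, outside it, through the
        depth), overriding ``resolution``.

    Raises
    ------
    MeshError
        If the resolution leaves fewer than 2 displacement nodes under the
        indenter, or the geometry is invalid.
    """
    g = geometry
    if counts is not None:
        nr_in, nr_out, nz = counts
    else:
        nr_in = max(1, round(2 * resolution))
        nr_out = max(2, round(4 * resolution))
        nz = max(2, round(4 * resolution))

    r_lines = np.concatenate(
        [
            _graded(0.0, g.indenter_radius, nr_in, -grading)[:-1],
            _graded(g.indenter_radius, g.radius, nr_out, grading),
        ]
    )
    # refine toward the articular surface z = h
    z_lines = g.thickness - _graded(0.0, g.thickness, nz, grading)[::-1]
    nr = r_lines.size - 1
    nz = z_lines.size - 1

    # displacement grid ((2nr+1) x (2nz+1)) with midpoints
    def midline(v):
        out = np.empty(2 * (v.size - 1) + 1)
        out[0::2] = v
        out[1::2] = 0.5 * (v[:-1] + v[1:])
        return out

    rl9, zl9 = midline(r_lines), midline(z_lines)
    R9, Z9 = np.meshgrid(rl9, zl9, indexing="ij")
    R4, Z4 = np.meshgrid(r_lines, z_lines, indexing="ij")

    def idx9(i, j):
        return i * zl9.size + j

    def idx4(i, j):
        return i * z_lines.size + j

    conn9 = np.empty((nr * nz, 9), dtype=np.int64)
    conn4 = np.empty((nr * nz, 4), dtype=np.int64)
    e = 0
    for i in range(nr):
        for j in range(nz):
            I, Jj = 2 * i, 2 * j
            # corners counter-clockwise, then edge midpoints, then center
            conn9[e] = [
                idx9(I, Jj),
                idx9(I + 2, Jj),
                idx9(I + 2, Jj + 2),
                idx9(I, Jj + 2),
                idx9(I + 1, Jj),
                idx9(I + 2, Jj + 1),
                idx9(I + 1, Jj + 2),
                idx9(I, Jj + 1),
                idx9(I + 1, Jj + 1),
            ]
            conn4[e] = [idx4(i, j), idx4(i + 1, j), idx4(i + 1, j + 1), idx4(i, j + 1)]
            e += 1

    r9, z9 = R9.ravel(), Z9.ravel()
    r4, z4 = R4.ravel(), Z4.ravel()
    tol = 1e-9 * g.radius
    a = g.indenter_radius
    node_sets = {
        "bottom": z9 < tol,
        "top": z9 > g.thickness - tol,
        "axis": r9 < tol,
        "outer": r9 > g.radius - tol,
    }
    node_sets["contact"] = node_sets["top"] & (r9 <= a + tol)
    pnode_sets = {
        "bottom": z4 < tol,
        "top": z4 > g.thickness - tol,
        "outer": r4 > g.radius - tol,
    }
    pnode_sets["top_outside"] = pnode_sets["top"] & (r4 > a + tol)
    pnode_sets["top_contact"] = pnode_sets["top"] & (r4 <= a + tol)

    if node_sets["contact"].sum() < 2:
        raise MeshError("resolution too coarse: fewer than 2 nodes under the indenter")

    return Mesh(
        geometry=g,
        r9=r9,
        z9=z9,
        r4=r4,
        z4=z4,
        conn9=conn9,
        conn4=conn4,
        shape=(nr, nz),
        node_sets=node_sets,
        pnode_sets=pnode_sets,
    )
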