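"""Isodose-surface extraction and triangulated-mesh geometry.

An *isodose volume* is the superlevel set ``{dose >= level}``.  Its boundary
is extracted directly from the dose grid by marching cubes with linear
interpolation along grid edges, which yields a watertight, consistently
oriented (outward-normal) triangulation — including all disconnected
components of the level set.

Surface area is the sum of half cross-product magnitudes over triangles;
enclosed volume is the signed tetrahedron sum (divergence theorem).  Both
are exact for the given triangulation.

Mask morphology (uniform expansion, body cropping) uses the exact Euclidean
distance transform with anisotropic voxel spacing; voxels are classified by
their centre position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph
from skimage import measure

from .exceptions import (
    EmptyIsodoseError,
    EmptyStructureError,
    OpenMeshError,
    OpenSurfaceError,
)
from .grid import BinaryMask, DoseGrid

__all__ = [
    "TriangleMesh",
    "mesh_surface_area",
    "mesh_volume",
    "extract_isosurface",
    "mask_surface",
    "signed_distance",
    "uniform_expand",
    "crop_body",
]


@dataclass(eq=False)
class TriangleMesh:
    """A triangulated surface in physical (mm) coordinates.

    ``vertices`` is ``(n, 3)`` float, ``faces`` is ``(m, 3)`` integer with
    consistent winding (outward normals for meshes produced by this module).
    A mesh may contain several disjoint closed components, e.g. disconnected
    isodose regions.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def surface_area(self) -> float:
        return mesh_surface_area(self)

    @property
    def volume(self) -> float:
        return mesh_volume(self)

    def open_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces (0 if closed)."""
        edges = np.sort(
            np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def n_components(self) -> int:
        """Number of connected surface components."""
        used = np.unique(self.faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        f = remap[self.faces]
        i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        adj = sparse.coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(len(used), len(used))
        )
        n, _ = csgraph.connected_components(adj, directed=False)
        return int(n)

    def flipped(self) -> "TriangleMesh":
        """Same surface with reversed winding (normals inverted)."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())

    def as_trimesh(self):
        """Convert to a :class:`trimesh.Trimesh` (no processing applied)."""
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def export(self, path) -> None:
        """Write the mesh to STL/PLY/etc. for visual debugging."""
        self.as_trimesh().export(path)


def mesh_surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area in mm^2 (degenerate triangles contribute 0)."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in mm^3 via the signed tetrahedron sum.

    Positive for outward-oriented meshes; sums over disjoint components.
    Raises :class:`OpenMeshError` for non-closed meshes.
    """
    n_open = mesh.open_edge_count()
    if n_open:
        raise OpenMeshError(f"mesh is not closed: {n_open} open edges")
    tri = mesh.vertices[mesh.faces]
    return float(
        np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    )


def _march(values, level, spacing, origin) -> TriangleMesh:
    """Marching cubes on a scalar array, padded so the surface closes.

    ``gradient_direction='ascent'`` orients normals outward for superlevel
    sets (verified by the positive signed volume of a spherical level set).
    """
    fill = min(float(values.min()), level) - 1.0
    padded = np.pad(values, 1, constant_values=fill)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=level, spacing=tuple(spacing), gradient_direction="ascent"
    )
    verts = verts + (np.asarray(origin) - np.asarray(spacing))
    return TriangleMesh(verts, faces)


def _touches_domain_boundary(region: np.ndarray, domain: np.ndarray | None) -> bool:
    """True if the superlevel region reaches the grid edge or the domain rim."""
    border = np.zeros(region.shape, dtype=bool)
    for a in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[a] = end
            border[tuple(sl)] = True
    if np.any(region & border):
        return True
    if domain is not None:
        rim = domain & ~ndimage.binary_erosion(domain)
        if np.any(region & rim):
            return True
    return False


def extract_isosurface(
    grid: DoseGrid, level: float, domain: BinaryMask | None = None
) -> TriangleMesh:
    """Extract the closed isodose surface ``{dose >= level}``.

    Parameters
    ----------
    grid
        The dose field.
    level
        Isodose level in Gy, strictly between the grid minimum and maximum
        (within ``domain`` when given).
    domain
        Optional evaluation domain (typically the cropped body).  Levels
        whose surface touches the domain boundary are rejected with
        :class:`OpenSurfaceError` — capping a clipped surface would corrupt
        its area.
    """
    values = grid.values
    if domain is not None:
        grid.require_same_geometry(domain)
        if not domain.values.any():
            raise EmptyStructureError("evaluation domain is empty")
        inside = values[domain.values]
    else:
        inside = values
    vmin, vmax = float(inside.min()), float(inside.max())
    if not vmin < level < vmax:
        raise EmptyIsodoseError(
            f"no isodose surface at {level:g} Gy: dose range in domain is "
            f"[{vmin:g}, {vmax:g}] Gy"
        )
    region = values >= level
    if domain is not None:
        region = region & domain.values
        if not region.any():
            raise EmptyIsodoseError(
                f"isodose region at {level:g} Gy is empty inside the domain"
            )
    if _touches_domain_boundary(region, None if domain is None else domain.values):
        raise OpenSurfaceError(
            f"isodose surface at {level:g} Gy intersects the evaluation-domain "
            "boundary"
        )
    if domain is not None:
        work = np.where(domain.values, values, vmin - 1.0)
    else:
        work = values
    return _march(work, level, grid.spacing, grid.origin)


def signed_distance(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance field of a mask (mm, positive inside).

    Centre-to-centre exact EDT with anisotropic spacing; the zero crossing
    sits midway between the innermost outside and outermost inside voxel
    centres, i.e. on the half-voxel interface.
    """
    inner = ndimage.distance_transform_edt(mask.values, sampling=mask.spacing)
    outer = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return inner - outer


def mask_surface(mask: BinaryMask, sigma_vox: float = 0.7) -> TriangleMesh:
    """Triangulate the boundary of a binary mask with sub-voxel placement.

    Marching cubes on the raw 0/1 values (or on the unsmoothed distance
    field) produces faceted surfaces whose area overestimates a smooth
    boundary by ~8-9%.  Three standard steps remove that bias:

    1. the signed Euclidean distance field replaces the binary values,
    2. a small Gaussian (``sigma_vox`` voxels) suppresses the facets, with
       the smoothing-induced inward drift cancelled by the Laplacian
       curvature correction ``F = d_s - (sigma^2/2) lap(d_s)`` (exact for a
       radial distance field),
    3. the extraction level is calibrated by bisection so the mesh volume
       reproduces the mask's voxel-count volume (conservation of the
       mask's canonical volume).
    """
    if not mask.values.any():
        raise EmptyStructureError("cannot triangulate an empty mask")
    if _touches_domain_boundary(mask.values, None):
        raise OpenSurfaceError("mask touches the grid boundary; surface would be open")
    ds = ndimage.gaussian_filter(signed_distance(mask), sigma_vox)
    lap = sum(
        np.gradient(np.gradient(ds, mask.spacing[a], axis=a), mask.spacing[a], axis=a)
        for a in range(3)
    )
    sig2 = sum((sigma_vox * s) ** 2 for s in mask.spacing) / 3.0
    field = ds - 0.5 * sig2 * lap
    target = mask.volume_mm3
    h = max(mask.spacing)
    lo, hi = -h, h  # mesh volume decreases as the level rises
    mesh = None
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        mesh = _march(field, mid, mask.spacing, mask.origin)
        vol = mesh_volume(mesh)
        if abs(vol - target) <= 1e-4 * target:
            break
        if vol > target:
            lo = mid
        else:
            hi = mid
    return mesh


def uniform_expand(mask: BinaryMask, distance: float) -> BinaryMask:
    """Uniform (isotropic in mm) expansion of a mask.

    The result contains every voxel whose centre lies within ``distance`` of
    the input region; always a superset of the input.  Erosion is not
    supported here (use :func:`crop_body`).
    """
    if distance < 0:
        raise ValueError(f"expansion distance must be >= 0, got {distance}")
    if distance == 0:
        return BinaryMask(mask.values.copy(), mask.spacing, mask.origin)
    if not mask.values.any():
        raise EmptyStructureError("cannot expand an empty mask")
    dist_out = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return BinaryMask(dist_out <= distance, mask.spacing, mask.origin)


def crop_body(body: BinaryMask, margin: float = 3.0) -> BinaryMask:
    """Erode the body mask by ``margin`` mm (skin crop).

    The cropped body is the evaluation domain for all isodose extraction:
    build-up and surface-dose artefacts live in the outer few millimetres.
    """
    if margin < 0:
        raise ValueError(f"crop margin must be >= 0, got {margin}")
    if not body.values.any():
        raise EmptyStructureError("body mask is empty")
    if margin == 0:
        return BinaryMask(body.values.copy(), body.spacing, body.origin)
    dist_in = ndimage.distance_transform_edt(body.values, sampling=body.spacing)
    cropped = dist_in > margin
    if not cropped.any():
        raise EmptyStructureError(
            f"cropping the body by {margin:g} mm leaves an empty domain"
        )
    return BinaryMask(cropped, body.spacing, body.origin)
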