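"""Parametric cortical model: two corrugated ribbon hemispheres.

Each hemisphere is a rectangular sheet corrugated sinusoidally along x.
The white surface is the graph ``z = h(x)`` and the pial surface is the
vertical offset ``z = h(x) + t(x)``, so the white->pial correspondence
segment has length exactly ``t`` (the stored thickness) at every vertex.

Curvature sign convention (used package-wide): **positive = concave
(sulcal fundus), negative = convex (gyral crown)**.  Thickness co-varies
with folding: crowns are thick, fundi thin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["CorticalModel", "make_cortical_model"]

#: distance (mm) of simulated white-matter slab below the white surface
WM_DEPTH_MM = 5.0
#: height (mm) of the CSF layer above the pial surface
CSF_HEIGHT_MM = 3.0
#: margin (mm) of background padding around the ribbon bounding box
MARGIN_MM = 2.0
#: gap (mm) between the two hemisphere sheets
HEMI_GAP_MM = 4.0

THICKNESS_MID_MM = 2.75
THICKNESS_AMP_MM = 1.25  # gives the 1.5..4 mm physiological range
N_FOLDS = 3.0


@dataclass
class HemisphereGeometry:
    """Analytic description of one corrugated sheet (for voxel labelling)."""

    x0: float  # sheet origin in world x (mm)
    extent_x: float
    y0: float
    extent_y: float
    amplitude: float
    wavenumber: float  # k, rad/mm; h(x) = amplitude * sin(k*(x-x0) + phase)
    phase: float
    t_mid: float
    t_amp: float

    def height(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(self.wavenumber * (x - self.x0) + self.phase)

    def thickness(self, x: np.ndarray) -> np.ndarray:
        return self.t_mid + self.t_amp * np.sin(
            self.wavenumber * (x - self.x0) + self.phase
        )

    def slope(self, x: np.ndarray) -> np.ndarray:
        return (
            self.amplitude
            * self.wavenumber
            * np.cos(self.wavenumber * (x - self.x0) + self.phase)
        )

    def curvature(self, x: np.ndarray) -> np.ndarray:
        # profile curvature of z=h(x); positive in sulcal fundi (h'' > 0)
        u = self.wavenumber * (x - self.x0) + self.phase
        h2 = -self.amplitude * self.wavenumber**2 * np.sin(u)
        h1 = self.amplitude * self.wavenumber * np.cos(u)
        return h2 / (1.0 + h1**2) ** 1.5

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0)
            & (x <= self.x0 + self.extent_x)
            & (y >= self.y0)
            & (y <= self.y0 + self.extent_y)
        )

    def region_of(self, x: np.ndarray, n_regions: int) -> np.ndarray:
        frac = np.clip((x - self.x0) / max(self.extent_x, 1e-12), 0.0, 1.0)
        return np.minimum((frac * n_regions).astype(np.int64), n_regions - 1)


@dataclass
class CorticalModel:
    """Two-hemisphere cortical ribbon with per-vertex attributes.

    Arrays are indexed by a single global vertex index; ``hemi`` separates
    hemispheres (0 = left, 1 = right).
    """

    white: np.ndarray  # (V, 3) mm
    pial: np.ndarray  # (V, 3) mm
    normals: np.ndarray  # (V, 3) outward unit normals of the white surface
    thickness: np.ndarray  # (V,) mm
    curvature: np.ndarray  # (V,) mm^-1, positive = concave/sulcal
    roi: np.ndarray  # (V,) int region label, same label set per hemisphere
    hemi: np.ndarray  # (V,) int, 0 left / 1 right
    triangles: np.ndarray  # (T, 3) int
    adjacency: sp.csr_matrix  # (V, V) symmetric 0/1 mesh adjacency
    n_regions: int
    voxel_size: float
    vol_shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4) voxel -> world (mm)
    geometry: dict = field(default_factory=dict)  # hemi index -> HemisphereGeometry
    grid_shape: tuple[int, int] = (0, 0)  # per-hemisphere (nx, ny) vertex grid
    seed: int | None = None

    @property
    def n_vertices(self) -> int:
        return self.white.shape[0]

    def hemisphere_mask(self, h: int) -> np.ndarray:
        return self.hemi == h

    def neighbors(self, v: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[v] : self.adjacency.indptr[v + 1]
        ]


def _grid_triangles(nx: int, ny: int, offset: int) -> np.ndarray:
    """Two triangles per quad of an nx-by-ny vertex grid."""
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel() + offset
    v01 = v00 + 1
    v10 = v00 + ny
    v11 = v10 + 1
    tri = np.concatenate(
        [np.stack([v00, v10, v01], axis=1), np.stack([v10, v11, v01], axis=1)]
    )
    return tri.astype(np.int64)


def _adjacency_from_triangles(tri: np.ndarray, n_vertices: int) -> sp.csr_matrix:
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    a = sp.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)),
        shape=(n_vertices, n_vertices),
    ).tocsr()
    a.data[:] = 1
    a.sum_duplicates()
    a.data[:] = 1
    return a


def make_cortical_model(
    n_vertices_per_hemisphere: int,
    folding_amplitude: float,
    voxel_size: float,
    n_regions: int,
    seed: int,
    vertex_spacing: float = 1.0,
) -> CorticalModel:
    """Build the two-hemisphere corrugated ribbon model.

    Parameters
    ----------
    n_vertices_per_hemisphere:
        Minimum vertex count per hemisphere (rounded up to a full grid).
    folding_amplitude:
        Corrugation amplitude in mm.  ``0`` yields a flat slab with zero
        curvature and constant thickness.
    voxel_size:
        Isotropic voxel edge (mm) of the enclosing simulation grid.
    n_regions:
        Number of contiguous region labels per hemisphere.
    seed:
        Controls the (per-hemisphere) corrugation phase.
    """
    if n_vertices_per_hemisphere < 100:
        raise ValueError("n_vertices_per_hemisphere must be >= 100")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if folding_amplitude < 0:
        raise ValueError("folding_amplitude must be >= 0")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")

    nx = int(np.ceil(np.sqrt(n_vertices_per_hemisphere)))
    ny = int(np.ceil(n_vertices_per_hemisphere / nx))
    extent_x = (nx - 1) * vertex_spacing
    extent_y = (ny - 1) * vertex_spacing

    wavelength = extent_x / N_FOLDS
    k = 2.0 * np.pi / wavelength
    # vertical-offset construction degenerates when the sheet folds too
    # steeply relative to its own thickness; reject early with a diagnostic
    if folding_amplitude * k > 2.0:
        raise ValueError(
            "degenerate geometry: folding slope "
            f"{folding_amplitude * k:.2f} > 2 would self-intersect the sampled "
            "ribbon; reduce folding_amplitude or increase the sheet extent"
        )

    t_amp = THICKNESS_AMP_MM if folding_amplitude > 0 else 0.0
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)

    hemi_geoms: dict[int, HemisphereGeometry] = {}
    blocks = []
    v_per_hemi = nx * ny
    for h, x0 in enumerate([-(extent_x + HEMI_GAP_MM), HEMI_GAP_MM]):
        geom = HemisphereGeometry(
            x0=x0,
            extent_x=extent_x,
            y0=0.0,
            extent_y=extent_y,
            amplitude=folding_amplitude,
            wavenumber=k,
            phase=float(phases[h]),
            t_mid=THICKNESS_MID_MM,
            t_amp=t_amp,
        )
        hemi_geoms[h] = geom
        xs = x0 + np.arange(nx) * vertex_spacing
        ys = np.arange(ny) * vertex_spacing
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        gx = gx.ravel()
        gy = gy.ravel()
        hz = geom.height(gx)
        th = geom.thickness(gx)
        white = np.stack([gx, gy, hz], axis=1)
        pial = white + np.stack([np.zeros_like(th), np.zeros_like(th), th], axis=1)
        hp = geom.slope(gx)
        nrm = np.stack([-hp, np.zeros_like(hp), np.ones_like(hp)], axis=1)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        blocks.append(
            dict(
                white=white,
                pial=pial,
                normals=nrm,
                thickness=th,
                curvature=geom.curvature(gx),
                roi=geom.region_of(gx, n_regions),
                hemi=np.full(v_per_hemi, h, dtype=np.int64),
            )
        )

    white = np.concatenate([b["white"] for b in blocks])
    pial = np.concatenate([b["pial"] for b in blocks])
    tri = np.concatenate(
        [_grid_triangles(nx, ny, 0), _grid_triangles(nx, ny, v_per_hemi)]
    )
    n_vertices = white.shape[0]

    # enclosing voxel grid
    lo = np.array(
        [
            white[:, 0].min() - MARGIN_MM,
            white[:, 1].min() - MARGIN_MM,
            white[:, 2].min() - WM_DEPTH_MM - MARGIN_MM,
        ]
    )
    hi = np.array(
        [
            white[:, 0].max() + MARGIN_MM,
            white[:, 1].max() + MARGIN_MM,
            pial[:, 2].max() + CSF_HEIGHT_MM + MARGIN_MM,
        ]
    )
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_size)) + 1 for i in range(3))
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = lo

    model = CorticalModel(
        white=white,
        pial=pial,
        normals=np.concatenate([b["normals"] for b in blocks]),
        thickness=np.concatenate([b["thickness"] for b in blocks]),
        curvature=np.concatenate([b["curvature"] for b in blocks]),
        roi=np.concatenate([b["roi"] for b in blocks]),
        hemi=np.concatenate([b["hemi"] for b in blocks]),
        triangles=tri,
        adjacency=_adjacency_from_triangles(tri, n_vertices),
        n_regions=n_regions,
        voxel_size=voxel_size,
        vol_shape=shape,
        affine=affine,
        geometry=hemi_geoms,
        grid_shape=(nx, ny),
        seed=seed,
    )
    _validate_model(model)
    return model


def _validate_model(model: CorticalModel) -> None:
    d = np.linalg.norm(model.pial - model.white, axis=1)
    if not np.allclose(d, model.thickness, rtol=0, atol=1e-9):
        raise ValueError("degenerate geometry: pial-white distance != thickness")
    if np.any(model.thickness <= 0):
        raise ValueError("degenerate geometry: non-positive thickness")
    if (model.adjacency != model.adjacency.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
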