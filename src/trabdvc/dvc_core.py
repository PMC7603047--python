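"""Global grid-based digital volume correlation (DVC).

A regular grid of nodes with spacing NS voxels is overlaid on a pair of
volumes of the same specimen in two mechanical states. The nodal
displacements u minimize a sum-of-squared-differences image term with
Laplacian smoothing over the node graph:

    E(u) = sum_{x in mask} [ fixed(x) - moving(x + u(x)) ]^2
         + lambda * sum_nodes || (L u)_node ||^2

where u(x) interpolates the nodal displacements trilinearly inside each
grid cell and L is the discrete (graph) vector Laplacian of the node grid.
E is minimized by damped Gauss-Newton with a coarse-grid warm start
(spacing 2 NS on blurred images), which covers the sub-cell to few-voxel
displacement magnitudes of stepwise in situ loading.

The nodal spacing sets the precision / spatial-resolution trade-off: large
NS averages image information over more voxels (lower strain uncertainty),
small NS resolves finer displacement gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .volume import BinaryMask, ImageVolume

__all__ = [
    "NodeGrid",
    "DisplacementField",
    "build_grid",
    "register",
    "node_mask_coverage",
    "save_displacement",
    "load_displacement",
]

#: Default dimensionless smoothing weight (see docs/methods.md for how the
#: default was chosen on zero-strain synthetic pairs).
DEFAULT_SMOOTHING = 0.1


@dataclass
class NodeGrid:
    """Regular DVC node grid over a volume."""

    ns: int  # nodal spacing, voxels
    voxel_size: float  # µm
    dims: tuple[int, int, int]  # voxels of the underlying image
    node_coords: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        coords = tuple(np.arange(0, n, self.ns) for n in self.dims)
        if any(len(c) < 2 for c in coords):
            raise ValueError(
                f"volume {self.dims} smaller than one grid cell at NS={self.ns}"
            )
        self.node_coords = coords  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Node counts per axis."""
        return tuple(len(c) for c in self.node_coords)  # type: ignore[return-value]

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def nodal_spacing_um(self) -> float:
        return self.ns * self.voxel_size

    @property
    def extent(self) -> tuple[int, int, int]:
        """Last node coordinate per axis (grid coverage in voxels)."""
        return tuple(int(c[-1]) for c in self.node_coords)  # type: ignore[return-value]

    def node_positions(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of node voxel coordinates."""
        X, Y, Z = np.meshgrid(*self.node_coords, indexing="ij")
        return np.stack([X, Y, Z], axis=-1).astype(np.float64)


@dataclass
class DisplacementField:
    """Per-node displacement vectors from one registration."""

    grid: NodeGrid
    u: np.ndarray  # (nx, ny, nz, 3), µm
    converged: bool
    residual: float  # final SSD data term
    smoothing_weight: float
    n_iterations: int = 0
    low_confidence: np.ndarray | None = None  # nodes with scant mask support

    @property
    def u_voxels(self) -> np.ndarray:
        return self.u / self.grid.voxel_size


def build_grid(dims: tuple[int, int, int], voxel_size: float, ns: int) -> NodeGrid:
    """Place nodes at voxel coordinates {0, NS, 2NS, ...} on each axis.

    Spacing bookkeeping is exact: NS voxels at ``voxel_size`` µm gives a
    nodal spacing of ``NS * voxel_size`` µm.
    """
    if ns < 2:
        raise ValueError(f"NS must be >= 2 voxels, got {ns}")
    return NodeGrid(ns=ns, voxel_size=voxel_size, dims=tuple(int(d) for d in dims))


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------

def _graph_laplacian(shape: tuple[int, int, int]) -> sparse.csr_matrix:
    """Discrete Laplacian of the node grid (6-neighborhood, scalar)."""
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    deg = np.zeros(n)
    for axis in range(3):
        for sign in (-1, 1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign == 1:
                src[axis] = slice(0, -1)
                dst[axis] = slice(1, None)
            else:
                src[axis] = slice(1, None)
                dst[axis] = slice(0, -1)
            a = idx[tuple(src)].ravel()
            b = idx[tuple(dst)].ravel()
            rows.append(a)
            cols.append(b)
            vals.append(np.ones(len(a)))
            np.add.at(deg, a, 1.0)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(-deg)
    L = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return L


def _interp_nodal(u: np.ndarray, pts_over_ns: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a nodal field at points given in cell units."""
    out = np.empty((pts_over_ns.shape[1], u.shape[-1]))
    for c in range(u.shape[-1]):
        out[:, c] = ndimage.map_coordinates(
            u[..., c], pts_over_ns, order=1, mode="nearest"
        )
    return out


class _Level:
    """One resolution level: images, grid, masked-voxel bookkeeping."""

    def __init__(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        grid: NodeGrid,
        mask: np.ndarray,
        blur_sigma: float,
        fill: float,
    ) -> None:
        self.grid = grid
        self.fill = fill
        if blur_sigma > 0:
            fixed = ndimage.gaussian_filter(fixed, blur_sigma)
            moving = ndimage.gaussian_filter(moving, blur_sigma)
        self.fixed = fixed
        # pad with one voxel of background so trilinear sampling blends
        # smoothly into the fill value at the volume border instead of
        # switching discontinuously to it
        self.moving = np.pad(moving, 1, constant_values=fill)
        self.grad = np.gradient(self.moving)
        ex, ey, ez = grid.extent
        box = (slice(0, ex + 1), slice(0, ey + 1), slice(0, ez + 1))
        self.mask_box = mask[box]
        gx, gy, gz = np.meshgrid(
            np.arange(ex + 1), np.arange(ey + 1), np.arange(ez + 1), indexing="ij"
        )
        self.coords = np.stack(
            [gx.ravel(), gy.ravel(), gz.ravel()]
        ).astype(np.float64)  # (3, N) voxel coords within coverage
        self.msk = self.mask_box.ravel()
        if not self.msk.any():
            raise ValueError("empty masked overlap between images and grid")
        self.fvals = self.fixed[box].ravel()
        self.box_shape = self.mask_box.shape
        self.ns = grid.ns
        self._build_cells()

    def _build_cells(self) -> None:
        """Per-cell voxel index ranges and trilinear weights."""
        ns = self.ns
        nxn, nyn, nzn = self.grid.shape
        self.cells = []
        sx, sy, sz = self.box_shape
        for i in range(nxn - 1):
            x0, x1 = i * ns, min((i + 1) * ns, sx - 1)
            xs = np.arange(x0, x1 + 1) if i == nxn - 2 else np.arange(x0, x1)
            for j in range(nyn - 1):
                y0, y1 = j * ns, min((j + 1) * ns, sy - 1)
                ys = np.arange(y0, y1 + 1) if j == nyn - 2 else np.arange(y0, y1)
                for k in range(nzn - 1):
                    z0, z1 = k * ns, min((k + 1) * ns, sz - 1)
                    zs = np.arange(z0, z1 + 1) if k == nzn - 2 else np.arange(z0, z1)
                    self.cells.append(((i, j, k), xs, ys, zs))

    def sample_moving(self, warped: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            self.moving, warped + 1.0, order=1, mode="constant", cval=self.fill
        )

    def objective(self, u: np.ndarray, lam: float, LTL: sparse.csr_matrix) -> float:
        warped = self.coords + _interp_nodal(u, self.coords / self.ns).T
        m = self.sample_moving(warped)
        r = np.where(self.msk, self.fvals - m, 0.0)
        reg = sum(
            float(u[..., c].ravel() @ (LTL @ u[..., c].ravel())) for c in range(3)
        )
        return float(r @ r) + lam * reg

    def data_residual(self, u: np.ndarray) -> float:
        warped = self.coords + _interp_nodal(u, self.coords / self.ns).T
        m = self.sample_moving(warped)
        r = np.where(self.msk, self.fvals - m, 0.0)
        return float(r @ r)


def _assemble(level: _Level, u: np.ndarray):
    """Gauss-Newton normal matrix and gradient of the data term."""
    grid = level.grid
    n_nodes = grid.n_nodes
    ndof = 3 * n_nodes
    JTJ = np.zeros((ndof, ndof))
    JTr = np.zeros(ndof)

    warped = level.coords + _interp_nodal(u, level.coords / level.ns).T
    m = level.sample_moving(warped)
    g = np.stack(
        [
            ndimage.map_coordinates(
                gc, warped + 1.0, order=1, mode="constant", cval=0.0
            )
            for gc in level.grad
        ],
        axis=1,
    )  # (N, 3)
    r_all = level.fvals - m

    shape3 = level.box_shape
    r3 = r_all.reshape(shape3)
    g3 = g.reshape(shape3 + (3,))
    m3 = level.mask_box

    node_shape = grid.shape
    node_index = np.arange(n_nodes).reshape(node_shape)
    ns = float(level.ns)

    for (ci, cj, ck), xs, ys, zs in level.cells:
        sub_mask = m3[np.ix_(xs, ys, zs)]
        if not sub_mask.any():
            continue
        r_c = r3[np.ix_(xs, ys, zs)][sub_mask]
        g_c = g3[np.ix_(xs, ys, zs)][sub_mask]  # (nv, 3)
        # local coordinates in [0,1]
        lx = (xs - ci * ns) / ns
        ly = (ys - cj * ns) / ns
        lz = (zs - ck * ns) / ns
        LX, LY, LZ = np.meshgrid(lx, ly, lz, indexing="ij")
        LX, LY, LZ = LX[sub_mask], LY[sub_mask], LZ[sub_mask]
        w = np.empty((LX.size, 8))
        nodes = np.empty(8, dtype=int)
        c = 0
        for di in (0, 1):
            wx = LX if di else 1.0 - LX
            for dj in (0, 1):
                wy = LY if dj else 1.0 - LY
                for dk in (0, 1):
                    wz = LZ if dk else 1.0 - LZ
                    w[:, c] = wx * wy * wz
                    nodes[c] = node_index[ci + di, cj + dj, ck + dk]
                    c += 1
        # B[v, 3*n + comp] = dm/du = g_c[v, comp] * w[v, n]
        B = (w[:, :, None] * g_c[:, None, :]).reshape(LX.size, 24)
        dofs = (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()
        JTJ[np.ix_(dofs, dofs)] += B.T @ B
        JTr[dofs] += B.T @ r_c

    return JTJ, JTr


def _solve_level(
    level: _Level,
    u0: np.ndarray,
    smoothing_weight: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool, float, int]:
    grid = level.grid
    L = _graph_laplacian(grid.shape)
    LTL = (L.T @ L).tocsr()
    LTL3 = sparse.kron(LTL, sparse.eye(3), format="csr")

    u = u0.copy()
    lam_abs = None
    obj_prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        JTJ, JTr = _assemble(level, u)
        if lam_abs is None:
            scale = np.trace(JTJ) / JTJ.shape[0]
            lam_abs = smoothing_weight * scale if scale > 0 else smoothing_weight
        u_flat = u.reshape(-1)
        A = sparse.csr_matrix(JTJ) + lam_abs * LTL3
        b = JTr - lam_abs * (LTL3 @ u_flat)
        du = spsolve(A.tocsc(), b)
        if obj_prev is None:
            obj_prev = level.objective(u, lam_abs, LTL)
        # backtracking line search on the full objective
        step = 1.0
        obj_new = None
        for _ in range(8):
            u_try = (u_flat + step * du).reshape(u.shape)
            obj_try = level.objective(u_try, lam_abs, LTL)
            if obj_try <= obj_prev:
                u = u_try
                obj_new = obj_try
                break
            step *= 0.5
        if obj_new is None:
            converged = True  # no descent possible: at a (numerical) optimum
            break
        rel = abs(obj_prev - obj_new) / max(obj_prev, 1e-300)
        obj_prev = obj_new
        if rel < tol:
            converged = True
            break
    residual = level.data_residual(u)
    return u, converged, residual, it


def _prolong(u_coarse: np.ndarray, grid_c: NodeGrid, grid_f: NodeGrid) -> np.ndarray:
    """Interpolate a coarse-grid nodal field onto a finer grid."""
    pos = grid_f.node_positions()  # (..., 3) voxel coords
    pts = pos.reshape(-1, 3).T / grid_c.ns
    u_f = _interp_nodal(u_coarse, pts)
    return u_f.reshape(grid_f.shape + (3,))


def node_mask_coverage(grid: NodeGrid, mask: np.ndarray) -> np.ndarray:
    """Fraction of masked voxels in each node's +/- NS/2 support cube."""
    ns = grid.ns
    cs = np.zeros(tuple(s + 1 for s in mask.shape))
    cs[1:, 1:, 1:] = mask.astype(np.float64).cumsum(0).cumsum(1).cumsum(2)

    def box_sum(lo, hi):
        x0, y0, z0 = lo
        x1, y1, z1 = hi
        return (
            cs[x1, y1, z1] - cs[x0, y1, z1] - cs[x1, y0, z1] - cs[x1, y1, z0]
            + cs[x0, y0, z1] + cs[x0, y1, z0] + cs[x1, y0, z0] - cs[x0, y0, z0]
        )

    half = ns // 2
    shape = grid.shape
    cov = np.zeros(shape)
    for i, x in enumerate(grid.node_coords[0]):
        for j, y in enumerate(grid.node_coords[1]):
            for k, z in enumerate(grid.node_coords[2]):
                lo = (max(x - half, 0), max(y - half, 0), max(z - half, 0))
                hi = (
                    min(x + half + 1, mask.shape[0]),
                    min(y + half + 1, mask.shape[1]),
                    min(z + half + 1, mask.shape[2]),
                )
                vol = (hi[0] - lo[0]) * (hi[1] - lo[1]) * (hi[2] - lo[2])
                cov[i, j, k] = box_sum(lo, hi) / vol
    return cov


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    grid: NodeGrid,
    mask: BinaryMask | None = None,
    smoothing_weight: float = DEFAULT_SMOOTHING,
    tol: float = 1e-5,
    max_iter: int = 30,
    warm_start: bool = True,
    fine_blur: float = 0.0,
) -> DisplacementField:
    """Find nodal displacements mapping ``fixed`` onto ``moving``.

    Parameters
    ----------
    fixed, moving:
        Same-dimension volumes of the specimen in two states. Voxels where
        ``mask`` is false contribute nothing to the image term — pass the
        external-contour mask of the bone to suppress noise outside the
        specimen border.
    smoothing_weight:
        Dimensionless Laplacian regularization weight; the absolute weight
        is scaled by the mean Gauss-Newton diagonal so behaviour is
        invariant to grey-level units and voxel counts.
    tol, max_iter:
        Stop when the relative objective decrease falls below ``tol``.
    warm_start:
        Solve first on a grid with doubled spacing and blurred images
        (sigma 2 voxels), then refine; extends the capture range to several
        voxels of displacement.
    fine_blur:
        Optional Gaussian blur (voxels) of both images at the fine level.

    Returns
    -------
    DisplacementField
        Nodal displacements in µm with convergence flag (non-convergence is
        reported, never silent), final data residual, and per-node
        low-confidence flags where the support cube holds < 5% masked voxels.
    """
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if abs(fixed.voxel_size - moving.voxel_size) > 1e-9:
        raise ValueError("voxel size mismatch between fixed and moving")
    mask_arr = (
        np.ones(fixed.shape, dtype=bool) if mask is None else mask.data
    )
    if mask is not None and mask.shape != fixed.shape:
        raise ValueError("mask shape mismatch")
    if not mask_arr.any():
        raise ValueError("mask is empty")

    f = fixed.data.astype(np.float64) / 255.0
    m = moving.data.astype(np.float64) / 255.0
    fill = float(m[~mask_arr].mean()) if (~mask_arr).any() else float(np.median(m))

    u = np.zeros(grid.shape + (3,))
    total_it = 0
    if warm_start:
        ns2 = grid.ns * 2
        if all(d > ns2 for d in grid.dims):
            grid_c = build_grid(grid.dims, grid.voxel_size, ns2)
            level_c = _Level(f, m, grid_c, mask_arr, blur_sigma=2.0, fill=fill)
            u_c = np.zeros(grid_c.shape + (3,))
            u_c, _, _, it_c = _solve_level(
                level_c, u_c, smoothing_weight, tol * 10, max_iter
            )
            u = _prolong(u_c, grid_c, grid)
            total_it += it_c

    level = _Level(f, m, grid, mask_arr, blur_sigma=fine_blur, fill=fill)
    u, converged, residual, it = _solve_level(
        level, u, smoothing_weight, tol, max_iter
    )
    total_it += it

    coverage = node_mask_coverage(grid, mask_arr)
    low_conf = coverage < 0.05
    return DisplacementField(
        grid=grid,
        u=u * grid.voxel_size,
        converged=converged,
        residual=residual,
        smoothing_weight=smoothing_weight,
        n_iterations=total_it,
        low_confidence=low_conf,
    )


def save_displacement(field: DisplacementField, path) -> None:
    """Store a displacement field with its grid metadata as HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("u_um", data=field.u)
        if field.low_confidence is not None:
            f.create_dataset("low_confidence", data=field.low_confidence)
        f.attrs["ns"] = field.grid.ns
        f.attrs["voxel_size_um"] = field.grid.voxel_size
        f.attrs["dims"] = field.grid.dims
        f.attrs["converged"] = field.converged
        f.attrs["residual"] = field.residual
        f.attrs["smoothing_weight"] = field.smoothing_weight
        f.attrs["n_iterations"] = field.n_iterations


def load_displacement(path) -> DisplacementField:
    """Load a displacement field written by :func:`save_displacement`."""
    import h5py

    with h5py.File(path, "r") as f:
        grid = build_grid(
            tuple(int(d) for d in f.attrs["dims"]),
            float(f.attrs["voxel_size_um"]),
            int(f.attrs["ns"]),
        )
        return DisplacementField(
            grid=grid,
            u=f["u_um"][...],
            converged=bool(f.attrs["converged"]),
            residual=float(f.attrs["residual"]),
            smoothing_weight=float(f.attrs["smoothing_weight"]),
            n_iterations=int(f.attrs["n_iterations"]),
            low_confidence=(
                f["low_confidence"][...] if "low_confidence" in f else None
            ),
        )
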