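"""Strain tensors from nodal displacement fields.

Nodal displacements are differentiated on the hexahedral cells of the DVC
grid: the displacement gradient of each cell is evaluated from the
trilinear shape-function derivatives at the cell center, the small-strain
tensor is eps = 1/2 (grad u + grad u^T), and nodal tensors are the
volume-weighted average of the adjacent cell tensors. Principal strains
(eigenvalues sorted descending, eps_p3 the most compressive) and the von
Mises equivalent strain follow per node. Strains are reported in
microstrain (µε; 10,000 µε = 1% strain).

Shear convention: the stored off-diagonal components are TENSOR shears
(eps_ij = gamma_ij / 2). Engineering shears are available on request; the
distinction matters when comparing against software that reports gamma.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dvc_core import DisplacementField, NodeGrid, node_mask_coverage
from .volume import BinaryMask

__all__ = [
    "StrainField",
    "COMPONENTS",
    "differentiate",
    "principal_strains",
    "von_mises",
    "mask_nodes",
]

#: Component order of the strain arrays (tensor shear convention).
COMPONENTS = ("exx", "eyy", "ezz", "exy", "eyz", "exz")


@dataclass
class StrainField:
    """Per-node strain state on a DVC grid (all strains in µε)."""

    grid: NodeGrid
    eps: np.ndarray  # (nx, ny, nz, 6) in COMPONENTS order, tensor shear
    principal: np.ndarray  # (nx, ny, nz, 3), descending
    eqv: np.ndarray  # (nx, ny, nz) von Mises equivalent
    included: np.ndarray  # bool, False = removed from downstream statistics
    boundary: np.ndarray  # bool, node averages fewer than 8 cells

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def tensors(self) -> np.ndarray:
        """(nx, ny, nz, 3, 3) symmetric tensor form of ``eps``."""
        e = self.eps
        t = np.empty(e.shape[:-1] + (3, 3))
        t[..., 0, 0] = e[..., 0]
        t[..., 1, 1] = e[..., 1]
        t[..., 2, 2] = e[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = e[..., 3]
        t[..., 1, 2] = t[..., 2, 1] = e[..., 4]
        t[..., 0, 2] = t[..., 2, 0] = e[..., 5]
        return t

    def engineering_shears(self) -> np.ndarray:
        """(..., 3) engineering shears gamma_xy, gamma_yz, gamma_xz (µε)."""
        return 2.0 * self.eps[..., 3:]

    def component(self, name: str) -> np.ndarray:
        """Values of one component over included nodes (flat array, µε)."""
        if name in COMPONENTS:
            vals = self.eps[..., COMPONENTS.index(name)]
        elif name == "ep1":
            vals = self.principal[..., 0]
        elif name == "ep2":
            vals = self.principal[..., 1]
        elif name == "ep3":
            vals = self.principal[..., 2]
        elif name == "eqv":
            vals = self.eqv
        else:
            raise KeyError(f"unknown strain component {name!r}")
        return vals[self.included]

    def to_csv(self, path: str | Path) -> None:
        """Per-node export: index, position (µm), 6 components, ep1, ep3, eqv, flag."""
        pos = self.grid.node_positions() * self.grid.voxel_size
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["i", "j", "k", "x_um", "y_um", "z_um", *COMPONENTS,
                 "ep1", "ep3", "eqv", "included"]
            )
            nx, ny, nz = self.grid.shape
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        w.writerow(
                            [i, j, k, *pos[i, j, k],
                             *self.eps[i, j, k],
                             self.principal[i, j, k, 0],
                             self.principal[i, j, k, 2],
                             self.eqv[i, j, k],
                             int(self.included[i, j, k])]
                        )


def _cell_gradients(u_vox: np.ndarray, ns: float) -> np.ndarray:
    """Displacement gradient per cell from trilinear shape functions.

    At the cell center the trilinear gradient along an axis is the mean of
    the four edge differences along that axis divided by the spacing.
    Returns (ncx, ncy, ncz, 3, 3) with G[..., i, j] = du_i/dx_j.
    """
    d0 = np.diff(u_vox, axis=0)
    gx = 0.25 * (
        d0[:, :-1, :-1] + d0[:, 1:, :-1] + d0[:, :-1, 1:] + d0[:, 1:, 1:]
    ) / ns
    d1 = np.diff(u_vox, axis=1)
    gy = 0.25 * (
        d1[:-1, :, :-1] + d1[1:, :, :-1] + d1[:-1, :, 1:] + d1[1:, :, 1:]
    ) / ns
    d2 = np.diff(u_vox, axis=2)
    gz = 0.25 * (
        d2[:-1, :-1] + d2[1:, :-1] + d2[:-1, 1:] + d2[1:, 1:]
    ) / ns
    return np.stack([gx, gy, gz], axis=-1)  # (..., comp_i, axis_j)


def differentiate(dfield: DisplacementField) -> StrainField:
    """Differentiate nodal displacements into the small-strain tensor field.

    Cell tensors are averaged onto nodes (each interior node averages its
    8 adjacent cells; boundary nodes average fewer and are flagged).
    """
    grid = dfield.grid
    if min(grid.shape) < 2:
        raise ValueError("degenerate grid: need >= 2 nodes per axis")
    u_vox = dfield.u_voxels
    G = _cell_gradients(u_vox, float(grid.ns))
    eps_cell = 0.5 * (G + np.swapaxes(G, -1, -2)) * 1e6  # µε

    node_shape = grid.shape
    acc = np.zeros(node_shape + (3, 3))
    cnt = np.zeros(node_shape)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                sl = (
                    slice(di, node_shape[0] - 1 + di),
                    slice(dj, node_shape[1] - 1 + dj),
                    slice(dk, node_shape[2] - 1 + dk),
                )
                acc[sl] += eps_cell
                cnt[sl] += 1.0
    tensors = acc / cnt[..., None, None]
    boundary = cnt < 8

    eps = np.stack(
        [
            tensors[..., 0, 0], tensors[..., 1, 1], tensors[..., 2, 2],
            tensors[..., 0, 1], tensors[..., 1, 2], tensors[..., 0, 2],
        ],
        axis=-1,
    )
    principal = principal_strains(tensors)
    eqv = von_mises(tensors)
    included = np.ones(node_shape, dtype=bool)
    return StrainField(
        grid=grid,
        eps=eps,
        principal=principal,
        eqv=eqv,
        included=included,
        boundary=boundary,
    )


def principal_strains(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric strain tensor(s), sorted descending.

    Accepts a single 3x3 tensor or an array of them (..., 3, 3); the last
    eigenvalue (eps_p3) is the most compressive principal strain.
    """
    t = np.asarray(tensor, dtype=np.float64)
    if not np.isfinite(t).all():
        raise ValueError("non-finite strain tensor")
    vals = np.linalg.eigvalsh(t)  # ascending
    return vals[..., ::-1]


def von_mises(tensor: np.ndarray) -> np.ndarray:
    """Von Mises equivalent strain (deviatoric definition).

    eqv = (2/3) sqrt{ [(e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2] / 2 }

    equivalently sqrt(2/3 e_dev : e_dev); zero for hydrostatic states and
    invariant under rotation of the tensor.
    """
    p = principal_strains(tensor)
    e1, e2, e3 = p[..., 0], p[..., 1], p[..., 2]
    return (2.0 / 3.0) * np.sqrt(
        ((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2) / 2.0
    )


def mask_nodes(
    strain: StrainField, mask: BinaryMask, coverage_cutoff: float = 0.05
) -> StrainField:
    """Exclude nodes whose NS-cube neighborhood lies (mostly) outside a mask.

    A node centered in a cyst or outside the specimen contour has little or
    no masked-voxel coverage and is removed from all downstream statistics.
    Returns a new field; the input is not modified.
    """
    if mask.shape != strain.grid.dims:
        raise ValueError("mask grid does not match the image grid")
    cov = node_mask_coverage(strain.grid, mask.data)
    included = strain.included & (cov >= coverage_cutoff)
    if not included.any():
        raise ValueError("node masking removed every node")
    return StrainField(
        grid=strain.grid,
        eps=strain.eps,
        principal=strain.principal,
        eqv=strain.eqv,
        included=included,
        boundary=strain.boundary,
    )


def save_strain(strain: StrainField, path) -> None:
    """Store a strain field as HDF5, keyed by component name."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, name in enumerate(COMPONENTS):
            f.create_dataset(name, data=strain.eps[..., i])
        f.create_dataset("ep1", data=strain.principal[..., 0])
        f.create_dataset("ep2", data=strain.principal[..., 1])
        f.create_dataset("ep3", data=strain.principal[..., 2])
        f.create_dataset("eqv", data=strain.eqv)
        f.create_dataset("included", data=strain.included)
        f.create_dataset("boundary", data=strain.boundary)
        f.attrs["ns"] = strain.grid.ns
        f.attrs["voxel_size_um"] = strain.grid.voxel_size
        f.attrs["dims"] = strain.grid.dims
        f.attrs["shear_convention"] = "tensor"


def load_strain(path) -> StrainField:
    """Load a strain field written by :func:`save_strain`."""
    import h5py
    from .dvc_core import build_grid

    with h5py.File(path, "r") as f:
        grid = build_grid(
            tuple(int(d) for d in f.attrs["dims"]),
            float(f.attrs["voxel_size_um"]),
            int(f.attrs["ns"]),
        )
        eps = np.stack([f[name][...] for name in COMPONENTS], axis=-1)
        principal = np.stack([f["ep1"][...], f["ep2"][...], f["ep3"][...]], axis=-1)
        return StrainField(
            grid=grid,
            eps=eps,
            principal=principal,
            eqv=f["eqv"][...],
            included=f["included"][...].astype(bool),
            boundary=f["boundary"][...].astype(bool),
        )
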