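"""Image stack I/O and preprocessing for trabecular bone microCT volumes.

Implements the standard chain applied to reconstructed scans before
registration and morphometry: 8-bit conversion, Gaussian denoising with a
global grey-value threshold, despeckling, half-resolution resampling, and
construction of the solid external-contour mask of the bone used to confine
the registration. Also fits the best-fit sphere used to delimit the
trabecular analysis region of a femoral head.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .volume import BinaryMask, ImageVolume

__all__ = [
    "SphereFit",
    "read_stack",
    "write_stack",
    "to_8bit",
    "segment_bone",
    "resample_half",
    "bone_contour_mask",
    "best_fit_sphere",
]

#: Default segmentation parameters: Gaussian kernel truncation radius
#: (voxels), Gaussian sigma (voxels), global grey-value threshold.
DEFAULT_SUPPORT = 1
DEFAULT_SIGMA = 0.5
DEFAULT_THRESHOLD = 110


@dataclass
class SphereFit:
    """Least-squares sphere fitted to the boundary of a binary mask."""

    center: tuple[float, float, float]  # voxel coordinates
    radius: float  # µm
    rms_residual: float  # µm


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (pages along z) or MHD/RAW.

    TIFF output is accompanied by a JSON sidecar recording the voxel size
    and axis order, so that a round trip preserves all metadata.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        # internal order is (x, y, z); TIFF pages are (z, y, x)
        tifffile.imwrite(path, np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        _sidecar_path(path).write_text(
            json.dumps({"voxel_size_um": vol.voxel_size, "axis_order": "xyz"})
        )
    elif suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing((vol.voxel_size, vol.voxel_size, vol.voxel_size))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r}")


def read_stack(path: str | Path) -> ImageVolume:
    """Read a multi-page TIFF (with JSON sidecar) or MHD/RAW volume.

    Raises
    ------
    ValueError
        If the voxel size cannot be determined from sidecar or header;
        no silent default is applied.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {data.shape}")
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no voxel size available for {path}: sidecar {sidecar.name} missing"
            )
        meta = json.loads(sidecar.read_text())
        if "voxel_size_um" not in meta:
            raise ValueError(f"sidecar {sidecar.name} lacks 'voxel_size_um'")
        return ImageVolume(data.transpose(2, 1, 0), float(meta["voxel_size_um"]))
    if suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        sp = img.GetSpacing()
        if abs(sp[0] - sp[1]) > 1e-9 or abs(sp[0] - sp[2]) > 1e-9:
            raise ValueError(f"anisotropic spacing {sp} not supported")
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        return ImageVolume(data.transpose(2, 1, 0), float(sp[0]))
    raise ValueError(f"unsupported stack format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def to_8bit(vol: ImageVolume, window: tuple[float, float]) -> ImageVolume:
    """Linearly map the grey window ``[lo, hi]`` onto [0, 255].

    Values are clipped to the window and rounded half-up, so ``lo`` maps to
    0, ``hi`` to 255 and the window midpoint to 128.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"degenerate window: ({lo}, {hi})")
    scaled = (np.asarray(vol.data, dtype=np.float64) - lo) * (255.0 / (hi - lo))
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)  # round half-up
    return ImageVolume(np.clip(out, 0, 255).astype(np.uint8), vol.voxel_size)


def segment_bone(
    vol: ImageVolume,
    sigma: float = DEFAULT_SIGMA,
    support: int = DEFAULT_SUPPORT,
    threshold: int = DEFAULT_THRESHOLD,
) -> BinaryMask:
    """Segment bone: Gaussian filter, global threshold, despeckle.

    The Gaussian kernel is truncated at ``support`` voxels from the center;
    voxels whose filtered grey value is >= ``threshold`` are foreground.
    Despeckling keeps only the largest 26-connected component ("remove any
    unconnected regions").
    """
    if not vol.is_8bit:
        raise ValueError("segment_bone expects an 8-bit volume")
    if sigma > 0:
        blurred = ndimage.gaussian_filter(
            vol.data.astype(np.float64), sigma=sigma, truncate=support / sigma
        )
    else:
        blurred = vol.data.astype(np.float64)
    fg = blurred >= threshold
    if not fg.any():
        raise ValueError(f"empty segmentation at threshold {threshold} GSV")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    return BinaryMask(fg, vol.voxel_size)


def resample_half(vol: ImageVolume, xy_only: bool = False) -> ImageVolume:
    """Downsample by a factor 0.5 per axis; voxel size doubles.

    The default dialect is an isotropic 2x2x2 block mean, which equals
    trilinear interpolation sampled at half-sample offsets and is exactly
    reproducible. ``xy_only=True`` restricts the block mean to within-slice
    2x2 blocks (slice-wise bilinear dialect) followed by pairwise slice
    averaging along z.
    """
    if min(vol.shape) < 2:
        raise ValueError("need at least 2 voxels per axis to halve")
    data = vol.data.astype(np.float64)
    nx, ny, nz = (s // 2 for s in vol.shape)
    data = data[: 2 * nx, : 2 * ny, : 2 * nz]
    if xy_only:
        out = data.reshape(nx, 2, ny, 2, 2 * nz).mean(axis=(1, 3))
        out = out.reshape(nx, ny, nz, 2).mean(axis=3)
    else:
        out = data.reshape(nx, 2, ny, 2, nz, 2).mean(axis=(1, 3, 5))
    if vol.is_8bit:
        out = np.floor(out + 0.5).astype(np.uint8)
    return ImageVolume(out, vol.voxel_size * 2)


def bone_contour_mask(bone: BinaryMask, closing_radius: float) -> BinaryMask:
    """Solid external-contour mask of the bone via morphological closing.

    A Euclidean closing with a ball of ``closing_radius`` voxels bridges
    inter-trabecular gaps; fully enclosed cavities (marrow space, cysts) are
    then filled, producing the solid mask used to confine registration to
    the specimen and to exclude image noise outside its border.
    """
    if closing_radius < 0:
        raise ValueError("closing_radius must be >= 0")
    m = bone.data
    if closing_radius == 0:
        closed = m.copy()
    else:
        r = float(closing_radius)
        # Euclidean closing via distance transforms (exact ball element)
        dilated = ndimage.distance_transform_edt(~m) <= r
        closed = ndimage.distance_transform_edt(dilated) > r
        closed |= m  # guarantee extensivity at the discrete boundary
    filled = ndimage.binary_fill_holes(closed)
    faces = [
        filled[0].any(), filled[-1].any(),
        filled[:, 0].any(), filled[:, -1].any(),
        filled[:, :, 0].any(), filled[:, :, -1].any(),
    ]
    if all(faces):
        warnings.warn(
            "mask touches the volume border on all faces; closing may be "
            "truncated there",
            stacklevel=2,
        )
    return BinaryMask(filled, bone.voxel_size)


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=1)
    return np.argwhere(mask & ~eroded)


def best_fit_sphere(mask: BinaryMask) -> SphereFit:
    """Least-squares sphere through the boundary voxels of a mask.

    An algebraic fit (linear least squares on ``|x|^2 = 2 c.x + d``) seeds a
    geometric refinement minimizing radial residuals. Used to delimit the
    trabecular analysis region of a femoral head: the slice containing the
    fitted center is taken as the lowest slice of that region.
    """
    if not mask.data.any():
        raise ValueError("mask is empty")
    pts = _boundary_voxels(mask.data).astype(np.float64)
    if len(pts) < 10:
        raise ValueError(f"only {len(pts)} boundary voxels; need >= 10")
    # algebraic fit
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(sol[3] + c0 @ c0))

    def residuals_for(points):
        def residuals(p: np.ndarray) -> np.ndarray:
            return np.linalg.norm(points - p[:3], axis=1) - p[3]

        return residuals

    # robust refinement: a femoral-head mask boundary includes the flat
    # neck-cut plane, which must not drag the fit off the spherical part
    p = np.append(c0, r0)
    subset = pts
    for _ in range(3):
        res = optimize.least_squares(
            residuals_for(subset), p, loss="soft_l1", f_scale=1.0
        )
        p = res.x
        r_all = residuals_for(pts)(p)
        scale = 1.4826 * np.median(np.abs(r_all - np.median(r_all)))
        keep = np.abs(r_all) <= max(3.0 * scale, 1.0)
        if keep.sum() < 10:
            break
        subset = pts[keep]
    cx, cy, cz, r = p
    rms = float(np.sqrt(np.mean(residuals_for(subset)(p) ** 2)))
    return SphereFit(
        center=(float(cx), float(cy), float(cz)),
        radius=float(r * mask.voxel_size),
        rms_residual=rms * mask.voxel_size,
    )
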