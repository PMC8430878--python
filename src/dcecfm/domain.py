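"""Construction of the labeled isotropic simulation domain.

A tumor ROI mask plus its Ktrans map are resliced to 1 mm isotropic voxels,
the tumor is dilated by a spherical margin (default 10 voxels = 10 mm) to
include surrounding normal tissue, and the result is labeled
outside / normal / tumor.  The pressure PDE is solved on normal+tumor with a
no-flux boundary on the dilation surface.  The ROI surface can also be
exported as an STL mesh for provenance and interchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "LABEL_OUTSIDE", "LABEL_NORMAL", "LABEL_TUMOR",
    "DomainGrid", "SurfaceMesh",
    "build_domain", "compute_tumor_volume", "export_stl", "voxelize_surface",
]

log = logging.getLogger(__name__)

LABEL_OUTSIDE, LABEL_NORMAL, LABEL_TUMOR = 0, 1, 2


@dataclass
class DomainGrid:
    """Labeled isotropic voxel lattice carrying the tumor Ktrans field.

    ``labels`` holds 0/1/2 for outside/normal/tumor; ``ktrans`` (min^-1) is
    defined (finite) on tumor voxels only and NaN elsewhere; ``ktrans_mean``
    is its arithmetic mean over the tumor label.  ``spacing_mm`` is the
    isotropic voxel edge.
    """

    labels: np.ndarray
    spacing_mm: float
    ktrans: np.ndarray
    ktrans_mean: float
    lp_sv: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.labels.shape != self.ktrans.shape:
            raise ValueError("labels and ktrans shapes differ")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == LABEL_TUMOR

    @property
    def normal_mask(self) -> np.ndarray:
        return self.labels == LABEL_NORMAL

    @property
    def domain_mask(self) -> np.ndarray:
        return self.labels != LABEL_OUTSIDE


@dataclass
class SurfaceMesh:
    """Triangulated ROI surface with provenance."""

    mesh: "object"  # trimesh.Trimesh
    iso_level: float
    degenerate: bool = False

    @property
    def volume_mm3(self) -> float:
        return float(abs(self.mesh.volume))

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)


def _reslice(mask: np.ndarray, ktrans: np.ndarray,
             spacing: np.ndarray, target: float) -> tuple[np.ndarray, np.ndarray]:
    """Reslice mask (nearest-neighbor) and Ktrans (mask-weighted trilinear)."""
    factors = spacing / target
    if np.allclose(factors, 1.0):
        return mask.copy(), ktrans.copy()
    out_shape = tuple(int(round(n * f)) for n, f in zip(mask.shape, factors))
    mask_iso = ndi.zoom(mask.astype(np.uint8), factors, order=0,
                        output=None, grid_mode=True, mode="grid-constant").astype(bool)
    mask_iso = _fix_shape(mask_iso, out_shape)
    # interpolate Ktrans weighted by the mask so out-of-tumor zeros do not
    # bleed into the tumor rim
    w = ndi.zoom(mask.astype(float), factors, order=1, grid_mode=True,
                 mode="grid-constant")
    kw = ndi.zoom(np.where(mask, np.nan_to_num(ktrans), 0.0), factors, order=1,
                  grid_mode=True, mode="grid-constant")
    w = _fix_shape(w, out_shape)
    kw = _fix_shape(kw, out_shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        kt_iso = np.where(w > 1e-6, kw / np.maximum(w, 1e-6), 0.0)
    return mask_iso, kt_iso


def _fix_shape(a: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Crop/pad ndi.zoom output to the analytically expected shape."""
    pad = [(0, max(0, s - n)) for n, s in zip(a.shape, shape)]
    if any(p[1] for p in pad):
        a = np.pad(a, pad)
    return a[tuple(slice(0, s) for s in shape)]


def build_domain(mask: np.ndarray, spacing_mm, ktrans_map: np.ndarray,
                 dilation_voxels: int = 10, target_spacing_mm: float = 1.0) -> DomainGrid:
    """Build the labeled isotropic simulation domain from a tumor ROI.

    The mask and Ktrans map are resliced to ``target_spacing_mm`` isotropic
    voxels (nearest-neighbor for the labels, mask-weighted trilinear for
    Ktrans), the grid is padded so the margin fits, and the tumor is dilated
    with a spherical structuring element of radius ``dilation_voxels``; the
    dilated-minus-tumor shell is labeled normal tissue.

    Parameters
    ----------
    mask : 3-D boolean array, tumor ROI in native voxels.
    spacing_mm : native voxel spacing, length-3.
    ktrans_map : Ktrans in min^-1 aligned with ``mask`` (values outside the
        mask are ignored).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("tumor mask is empty")
    ktrans_map = np.asarray(ktrans_map, dtype=float)
    if ktrans_map.shape != mask.shape:
        raise ValueError("Ktrans map is not aligned with the mask")
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three positive numbers")

    mask_iso, kt_iso = _reslice(mask, ktrans_map, spacing, target_spacing_mm)
    if not mask_iso.any():
        raise ValueError("tumor mask vanished during reslicing")

    pad = dilation_voxels + 1
    mask_iso = np.pad(mask_iso, pad)
    kt_iso = np.pad(kt_iso, pad)
    log.debug("padded grid by %d voxels to fit the dilation margin", pad)

    # spherical dilation via the Euclidean distance transform: a voxel is in
    # the dilated region iff its distance to the tumor is <= radius
    dist = ndi.distance_transform_edt(~mask_iso)
    dilated = dist <= dilation_voxels

    labels = np.zeros(mask_iso.shape, dtype=np.uint8)
    labels[dilated] = LABEL_NORMAL
    labels[mask_iso] = LABEL_TUMOR

    ktrans = np.where(mask_iso, kt_iso, np.nan)
    ktrans_mean = float(np.nanmean(ktrans[mask_iso]))
    affine = np.diag([target_spacing_mm] * 3 + [1.0])
    affine[:3, 3] = -pad * target_spacing_mm
    return DomainGrid(labels=labels, spacing_mm=float(target_spacing_mm),
                      ktrans=ktrans, ktrans_mean=ktrans_mean, affine=affine)


def compute_tumor_volume(mask: np.ndarray, spacing_mm) -> float:
    """Tumor volume in cm^3: voxel count times voxel volume."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.array_equal(np.unique(mask), np.unique(mask).astype(bool).astype(mask.dtype)):
        raise ValueError("mask must be binary")
    voxel_mm3 = float(np.prod(np.asarray(spacing_mm, dtype=float)))
    return float(mask.astype(bool).sum()) * voxel_mm3 / 1000.0


def export_stl(mask: np.ndarray, spacing_mm, path: str | Path | None = None,
               iso_level: float = 0.5) -> SurfaceMesh:
    """Triangulate the ROI surface (marching cubes) and optionally write STL.

    The mask is zero-padded by one voxel so the surface closes; vertex
    coordinates are in mm.  A single-voxel mask cannot support a marching-
    cubes surface and is emitted as a flagged voxel-sized box.
    """
    import trimesh
    from skimage import measure

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    spacing = tuple(float(s) for s in np.atleast_1d(spacing_mm).repeat(
        3 if np.ndim(spacing_mm) == 0 else 1)[:3])

    if mask.sum() == 1:
        idx = np.argwhere(mask)[0]
        center = (idx + 0.5) * np.asarray(spacing)
        box = trimesh.creation.box(extents=spacing, transform=trimesh.transformations.translation_matrix(center))
        log.warning("single-voxel mask: emitting a voxel-sized box surface")
        surf = SurfaceMesh(mesh=box, iso_level=iso_level, degenerate=True)
    else:
        padded = np.pad(mask.astype(float), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=iso_level,
                                                    spacing=spacing)
        verts = verts - np.asarray(spacing) * 0.5  # undo pad, voxel-center origin
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        if mesh.volume < 0:
            mesh.invert()
        surf = SurfaceMesh(mesh=mesh, iso_level=iso_level)
    if path is not None:
        surf.mesh.export(Path(path), file_type="stl")
    return surf


def voxelize_surface(surf: SurfaceMesh, shape: tuple[int, int, int], spacing_mm,
                     oversample: int = 2) -> np.ndarray:
    """Rasterize a surface mesh back onto a voxel grid (round-trip check).

    The watertight mesh is voxelized and flood-filled at ``oversample`` times
    the grid resolution, then sampled at the voxel centers of the target
    grid.  Coordinates follow the same voxel-center convention as
    :func:`export_stl`.
    """
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    if np.ptp(spacing) > 1e-9:
        raise ValueError("voxelize_surface expects isotropic spacing")
    pitch = float(spacing[0]) / oversample
    vg = surf.mesh.voxelized(pitch=pitch).fill()
    centers = (np.argwhere(np.ones(shape, dtype=bool)) + 0.5) * spacing
    return vg.is_filled(centers).reshape(shape)
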