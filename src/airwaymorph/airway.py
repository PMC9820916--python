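"""Airway metrics from a binary voxel grid: volume, CSAmin and its extents.

The airway is analysed between two horizontal planes in the reoriented
frame: the superior plane at the palatal level (through PNS and ANS,
parallel to Frankfort horizontal) and the inferior plane at the most
anterior point of the third cervical vertebral body.  Within that band the
volume is the air-voxel count times the voxel volume, and CSAmin is the
axial slice of minimal nonzero area; its anteroposterior (Ap) and lateral
(Lat) dimensions are the bounding-box extents of air in that slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .landmarks import RAW, LandmarkSet


@dataclass
class VoxelGrid:
    """Binary occupancy grid (air = 1) with isotropic spacing.

    ``data`` is indexed ``[ix, iy, iz]``; world coordinate of voxel
    ``(i, j, k)`` center is ``origin_mm + (i, j, k) * voxel_mm`` in the
    same axis order as the landmark frame (x anterior, y left, z superior).
    """

    data: np.ndarray
    voxel_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = RAW

    def __post_init__(self):
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("voxel grid must be 3D")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    def z_centers(self) -> np.ndarray:
        return self.origin_mm[2] + np.arange(self.data.shape[2]) * self.voxel_mm

    # ------------------------------------------------------------- NIfTI
    def to_nifti(self, path) -> None:
        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.data.astype(np.uint8), affine)
        img.header.set_zooms((self.voxel_mm,) * 3)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, frame: str = RAW) -> "VoxelGrid":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-4):
            raise ValueError(f"anisotropic voxels not supported: {zooms}")
        affine = img.affine
        if not np.allclose(affine[:3, :3], np.diag([zooms[0]] * 3), atol=1e-6):
            raise ValueError("only axis-aligned NIfTI grids are supported")
        data = (np.asanyarray(img.dataobj) > 0).astype(np.uint8)
        return cls(data=data, voxel_mm=float(zooms[0]),
                   origin_mm=affine[:3, 3].copy(), frame=frame)


@dataclass(frozen=True)
class AirwayMetrics:
    """Vol (mm³), CSAmin (mm²), the z of the minimal slice, and its extents."""

    volume_mm3: float
    csa_min_mm2: float
    slice_z_mm: float
    ap_mm: float
    lat_mm: float

    def as_dict(self) -> dict[str, float]:
        return {"Vol": self.volume_mm3, "CSAmin": self.csa_min_mm2,
                "Ap": self.ap_mm, "Lat": self.lat_mm}


def bounding_planes(landmarks: LandmarkSet) -> tuple[float, float]:
    """(z_sup, z_inf) of the airway band, from reoriented landmarks.

    z_sup is the mean z of PNS and ANS (the palatal plane parallel to FH;
    a warning is emitted when the two points disagree by more than 3 mm),
    z_inf is the z of the C3 landmark.
    """
    landmarks.require(("PNS", "ANS", "C3"))
    z_pns, z_ans = landmarks["PNS"][2], landmarks["ANS"][2]
    if abs(z_pns - z_ans) > 3.0:
        warnings.warn(
            f"PNS and ANS differ by {abs(z_pns - z_ans):.1f} mm in height; "
            "palatal plane poorly defined", stacklevel=2)
    z_sup = 0.5 * (z_pns + z_ans)
    z_inf = float(landmarks["C3"][2])
    if z_sup <= z_inf:
        raise ValueError(f"superior plane ({z_sup:.1f}) not above inferior ({z_inf:.1f})")
    return float(z_sup), z_inf


def crop_between_planes(grid: VoxelGrid, z_sup: float, z_inf: float) -> VoxelGrid:
    """Zero out voxels whose center z lies outside [z_inf, z_sup] (both inclusive)."""
    if z_sup <= z_inf:
        raise ValueError("z_sup must exceed z_inf")
    z = grid.z_centers()
    keep = (z >= z_inf) & (z <= z_sup)
    if not keep.any():
        raise ValueError("cropping planes do not intersect the grid")
    data = grid.data.copy()
    data[:, :, ~keep] = 0
    return VoxelGrid(data=data, voxel_mm=grid.voxel_mm,
                     origin_mm=grid.origin_mm, frame=grid.frame)


def airway_volume(grid: VoxelGrid) -> float:
    """Air volume in mm³: occupied-voxel count × voxel³."""
    return float(np.count_nonzero(grid.data)) * grid.voxel_mm ** 3


def largest_component(grid: VoxelGrid) -> VoxelGrid:
    """Keep the largest 26-connected air component (drops stray voxels)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(grid.data > 0, structure=structure)
    if n <= 1:
        return grid
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    data = (labels == counts.argmax()).astype(np.uint8)
    return VoxelGrid(data=data, voxel_mm=grid.voxel_mm,
                     origin_mm=grid.origin_mm, frame=grid.frame)


def csa_min(grid: VoxelGrid, clean: bool = True) -> AirwayMetrics:
    """Minimal axial cross-section of the airway and its linear extents.

    Area per slice is the air-voxel count × voxel²; CSAmin is the minimum
    over slices with nonzero area, ties broken toward the most inferior
    slice.  Ap/Lat are the x/y bounding-box extents of air in that slice
    (inclusive voxel span × voxel size).  With ``clean`` a single 3D
    largest-connected-component filter is applied first, emulating the
    segmentation of one airway object.
    """
    if clean:
        grid = largest_component(grid)
    counts = np.count_nonzero(grid.data, axis=(0, 1))
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        raise ValueError("grid contains no air voxels")
    v = grid.voxel_mm
    areas = counts[nz] * v * v
    k = int(nz[np.argmin(areas)])  # argmin returns the first = most inferior tie
    sl = grid.data[:, :, k]
    xs, ys = np.nonzero(sl)
    ap = (xs.max() - xs.min() + 1) * v
    lat = (ys.max() - ys.min() + 1) * v
    return AirwayMetrics(
        volume_mm3=airway_volume(grid),
        csa_min_mm2=float(areas.min()),
        slice_z_mm=float(grid.origin_mm[2] + k * v),
        ap_mm=float(ap), lat_mm=float(lat),
    )


def analyze_airway(grid: VoxelGrid, landmarks: LandmarkSet,
                   clean: bool = True) -> AirwayMetrics:
    """Crop the grid between the anatomical planes and measure it."""
    z_sup, z_inf = bounding_planes(landmarks)
    return csa_min(crop_between_planes(grid, z_sup, z_inf), clean=clean)
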