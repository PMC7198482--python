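"""BBB-opening quantification on contrast-enhanced T1-weighted volumes.

A voxel inside the sonicated-side elliptical ROI (FUS+) is classified as
containing an opened blood-brain barrier when its post-contrast intensity
exceeds ``mean + 3 * SD`` of the contralateral (FUS-) ROI intensities.  The
opening volume is the open-voxel count per slice summed and multiplied by the
voxel volume, and the targeting offset is the open-mask centroid minus the
planned transducer focus, reported per world axis
(X = left-right, Y = head-foot, Z = anterior-posterior; Z is the slice axis).

Conventions: voxel indices are 0-based; world coordinates are in mm at voxel
centers (``world = origin + index * spacing``); contralateral statistics are
pooled over all slices of the contralateral ROI; the sample (n-1) standard
deviation is used; the threshold inequality is strict; the centroid is the
unweighted mean of open-voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import AnalysisError, InputError

__all__ = [
    "ImageVolume",
    "EllipticalROI",
    "OpeningResult",
    "rasterize_roi",
    "opening_threshold",
    "classify_open_voxels",
    "targeting_offset",
]


@dataclass
class ImageVolume:
    """3D intensity grid with world geometry.

    ``voxel_mm`` is the spacing per axis; ``origin_mm`` the world position of
    the voxel (0,0,0) center.  Axis order is (X, Y, Z) with Z the slice axis.
    """

    voxels: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ("X-LR", "Y-HF", "Z-AP")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InputError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("intensities must be finite")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if any(v <= 0 for v in self.voxel_mm):
            raise InputError("voxel spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.voxel_mm[axis]

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(idx, dtype=float) * np.asarray(
            self.voxel_mm
        )

    def save(self, path) -> None:
        affine = np.diag([*self.voxel_mm, 1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return cls(
            voxels=np.asarray(img.get_fdata(), dtype=float),
            voxel_mm=spacing,
            origin_mm=origin,
        )


@dataclass
class EllipticalROI:
    """In-plane elliptical ROI replicated over an inclusive slice range.

    ``center_mm`` is the (x, y) world center; ``major_mm``/``minor_mm`` the
    full axis lengths (defaults 19 and 8 mm); ``orientation_deg`` rotates the
    major axis in-plane; ``exclusion_mask`` removes voxels (e.g. ventricles).
    """

    slice_range: tuple[int, int]
    center_mm: tuple[float, float]
    major_mm: float = 19.0
    minor_mm: float = 8.0
    orientation_deg: float = 0.0
    exclusion_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.major_mm >= self.minor_mm > 0):
            raise InputError("need major_mm >= minor_mm > 0")
        lo, hi = self.slice_range
        if lo > hi:
            raise InputError("slice_range must be (lo, hi) with lo <= hi")

    def to_dict(self) -> dict:
        return {
            "slice_range": list(self.slice_range),
            "center_mm": list(self.center_mm),
            "major_mm": self.major_mm,
            "minor_mm": self.minor_mm,
            "orientation_deg": self.orientation_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipticalROI":
        return cls(
            slice_range=tuple(d["slice_range"]),
            center_mm=tuple(d["center_mm"]),
            major_mm=float(d.get("major_mm", 19.0)),
            minor_mm=float(d.get("minor_mm", 8.0)),
            orientation_deg=float(d.get("orientation_deg", 0.0)),
        )


def rasterize_roi(roi: EllipticalROI, vol: ImageVolume) -> np.ndarray:
    """Boolean voxel mask of the ROI: a voxel belongs when its center
    satisfies the in-plane ellipse inequality on a slice in ``slice_range``."""
    lo, hi = roi.slice_range
    nz = vol.shape[2]
    if hi < 0 or lo >= nz:
        raise InputError("ROI slice range entirely outside the volume")
    if lo < 0 or hi >= nz:
        raise InputError("ROI slice range extends outside the volume")
    xs = vol.axis_coords(0) - roi.center_mm[0]
    ys = vol.axis_coords(1) - roi.center_mm[1]
    dx, dy = np.meshgrid(xs, ys, indexing="ij")
    th = np.deg2rad(roi.orientation_deg)
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    inplane = (u / (roi.major_mm / 2.0)) ** 2 + (v / (roi.minor_mm / 2.0)) ** 2 <= 1.0
    mask = np.zeros(vol.shape, dtype=bool)
    mask[:, :, lo : hi + 1] = inplane[:, :, None]
    if roi.exclusion_mask is not None:
        mask &= ~np.asarray(roi.exclusion_mask, dtype=bool)
    if not mask.any():
        raise InputError("ROI contains no voxel centers")
    return mask


def opening_threshold(contra_intensities) -> tuple[float, float, float]:
    """Classification threshold from contralateral intensities.

    Returns (threshold, mean, sd) with ``threshold = mean + 3 * sd`` and the
    sample (n-1) standard deviation.
    """
    vals = np.asarray(contra_intensities, dtype=float).ravel()
    if len(vals) < 2:
        raise AnalysisError("need >= 2 contralateral intensities")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return mean + 3.0 * sd, mean, sd


@dataclass
class OpeningResult:
    """Opening classification output.

    ``voxels_per_slice`` counts open voxels per slice index (full Z length);
    ``total_volume_cm3`` equals the open-voxel count times the voxel volume;
    ``centroid_mm``/``offset_mm`` are None when no voxel is open.
    """

    threshold: float
    contra_mean: float
    contra_sd: float
    open_mask: np.ndarray = field(repr=False)
    voxels_per_slice: np.ndarray
    total_volume_cm3: float
    centroid_mm: np.ndarray | None
    offset_mm: np.ndarray | None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "contra_mean": self.contra_mean,
            "contra_sd": self.contra_sd,
            "open_voxel_count": int(self.open_mask.sum()),
            "voxels_per_slice": self.voxels_per_slice.astype(int).tolist(),
            "total_volume_cm3": self.total_volume_cm3,
            "centroid_mm": None if self.centroid_mm is None else self.centroid_mm.tolist(),
            "offset_mm": None if self.offset_mm is None else self.offset_mm.tolist(),
        }


def classify_open_voxels(
    post: ImageVolume,
    roi_fus: EllipticalROI,
    roi_contra: EllipticalROI,
    planned_focus_mm=None,
) -> OpeningResult:
    """Classify opened voxels in the FUS+ ROI of a post-contrast volume.

    The threshold is ``mean + 3 * SD`` of the contralateral ROI intensities,
    pooled across its slices; a FUS+ voxel is open when strictly above it.
    """
    contra_mask = rasterize_roi(roi_contra, post)
    fus_mask = rasterize_roi(roi_fus, post)
    threshold, mean, sd = opening_threshold(post.voxels[contra_mask])
    open_mask = fus_mask & (post.voxels > threshold)
    voxels_per_slice = open_mask.sum(axis=(0, 1))
    count = int(open_mask.sum())
    total_volume_cm3 = count * post.voxel_volume_mm3 / 1000.0
    centroid = offset = None
    if count > 0:
        idx = np.argwhere(open_mask)
        world = np.asarray(post.origin_mm) + idx * np.asarray(post.voxel_mm)
        centroid = world.mean(axis=0)
        if planned_focus_mm is not None:
            offset = centroid - np.asarray(planned_focus_mm, dtype=float)
    return OpeningResult(
        threshold=threshold,
        contra_mean=mean,
        contra_sd=sd,
        open_mask=open_mask,
        voxels_per_slice=voxels_per_slice,
        total_volume_cm3=total_volume_cm3,
        centroid_mm=centroid,
        offset_mm=offset,
    )


def targeting_offset(result: OpeningResult, planned_focus_mm) -> tuple[float, float, float]:
    """Signed per-axis offset (dx, dy, dz) in mm between the open-mask
    centroid and the planned focus."""
    if result.centroid_mm is None:
        raise AnalysisError("no opening detected: open mask is empty")
    d = result.centroid_mm - np.asarray(planned_focus_mm, dtype=float)
    return float(d[0]), float(d[1]), float(d[2])
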