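"""Spatially referenced image volumes and NIfTI I/O.

An :class:`ImageVolume` is a thin container around a 3D or 4D numpy array
plus a 4x4 voxel-to-world affine (RAS convention, as in NIfTI).  The fourth
array axis, when present, indexes frames (b-values, repetition times, DCE
time points) and is not covered by the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "read_volume",
    "write_volume",
    "volume_to_sitk",
    "sitk_to_volume",
]

# RAS (nibabel) <-> LPS (ITK) flips the sign of the first two world axes.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ImageVolume:
    """A scalar image grid with world-space pose.

    Parameters
    ----------
    data : ndarray
        ``(nx, ny, nz)`` or ``(nx, ny, nz, nframes)`` array.
    affine : ndarray
        4x4 voxel-index-to-world (RAS, mm) transform of the spatial axes.
    frame_times : ndarray, optional
        Acquisition time (s) or acquisition parameter per frame for 4D data.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.data.ndim not in (3, 4):
            raise ValueError("ImageVolume data must be 3D or 4D")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) per spatial axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def frame(self, i: int) -> "ImageVolume":
        """Extract one frame of a 4D volume as a 3D volume."""
        if self.data.ndim != 4:
            raise ValueError("frame() requires a 4D volume")
        return ImageVolume(self.data[..., i], self.affine.copy())

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same pose, new voxel data."""
        return replace(self, data=np.asarray(data))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` voxel indices to world (RAS, mm) coordinates."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.data.copy(),
            self.affine.copy(),
            None if self.frame_times is None else self.frame_times.copy(),
        )


def read_volume(path) -> ImageVolume:
    """Load a NIfTI-1 file as an :class:`ImageVolume`."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError as err:
        raise FileNotFoundError(f"volume not found: {path}") from err
    data = np.asanyarray(img.dataobj)
    vol = ImageVolume(data, img.affine)
    if data.ndim == 4:
        dt = float(img.header["pixdim"][4])
        if dt > 0:
            vol.frame_times = np.arange(data.shape[3]) * dt
    return vol


def write_volume(vol: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` to NIfTI-1, preserving dtype exactly."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_data_dtype(vol.data.dtype)
    # store scl as identity so integer / float data round-trips bit-exactly
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    if vol.data.ndim == 4 and vol.frame_times is not None and len(vol.frame_times) > 1:
        dt = float(vol.frame_times[1] - vol.frame_times[0])
        img.header["pixdim"][4] = dt
    nib.save(img, str(path))


def volume_to_sitk(vol: ImageVolume) -> sitk.Image:
    """Convert a 3D :class:`ImageVolume` (RAS affine) to a SimpleITK image (LPS)."""
    if vol.data.ndim != 3:
        raise ValueError("only 3D volumes convert to SimpleITK")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T.astype(np.float64)))
    lps = _RAS2LPS @ vol.affine
    m = lps[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    img.SetSpacing(tuple(spacing))
    img.SetDirection(tuple(direction.ravel()))
    img.SetOrigin(tuple(lps[:3, 3]))
    return img


def sitk_to_volume(img: sitk.Image) -> ImageVolume:
    """Convert a SimpleITK image back to an :class:`ImageVolume` (RAS affine)."""
    data = sitk.GetArrayFromImage(img).T
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing())
    lps = np.eye(4)
    lps[:3, :3] = direction * spacing
    lps[:3, 3] = img.GetOrigin()
    return ImageVolume(data, _RAS2LPS @ lps)
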