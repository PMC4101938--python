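"""3D volume container and TIFF stack I/O.

All of svftrace uses a single coordinate convention: arrays are indexed
``(z, y, x)``, 0-based, with voxel centers at integer coordinates.  Multi-page
TIFFs map page -> z.  Anisotropic voxel spacing is carried as metadata only;
the filter and snake mathematics assume isotropic voxels, so anisotropic
stacks should be resampled by the caller first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError

__all__ = ["Volume3D", "read_stack", "write_stack", "normalize"]


@dataclass
class Volume3D:
    """A scalar intensity grid over a 3D voxel lattice.

    Parameters
    ----------
    data : ndarray, shape (Dz, Dy, Dx)
        Intensities, indexed ``(z, y, x)``.
    spacing : tuple of float
        Physical size of one voxel along ``(z, y, x)``; arbitrary units.
    intensity_range : tuple of float or None
        Original (min, max) recorded by :func:`normalize`; ``None`` if the
        volume has not been normalized.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_range: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume data must be 3-dimensional (z, y, x); got ndim={self.data.ndim}"
            )
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"voxel spacing must be positive; got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def contains(self, point) -> bool:
        """True if a continuous ``(z, y, x)`` point lies inside the voxel lattice."""
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= np.asarray(self.shape) - 1))


def read_stack(path) -> Volume3D:
    """Read a single- or multi-page grayscale TIFF as a :class:`Volume3D`.

    Raises
    ------
    FormatError
        If the file is not grayscale, pages disagree in size, or the file
        cannot be interpreted as a 2D/3D stack.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if any(len(s) != 2 for s in shapes):
                raise FormatError(
                    f"{path}: pages are not single-channel grayscale (page shapes {sorted(shapes)})"
                )
            if len(shapes) > 1:
                raise FormatError(
                    f"{path}: inconsistent page dimensions {sorted(shapes)}"
                )
            arr = tif.asarray()
    except FormatError:
        raise
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc

    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale 2D/3D stack, got array of shape {arr.shape}"
        )
    return Volume3D(arr.astype(np.float64))


def write_stack(path, volume: Volume3D) -> None:
    """Write a volume as a multi-page 32-bit float TIFF (page = z-slice)."""
    tifffile.imwrite(path, volume.data.astype(np.float32))


def normalize(volume: Volume3D) -> Volume3D:
    """Linearly rescale intensities so min -> 0 and max -> 1.

    Constant volumes map to all zeros.  The original (min, max) is recorded in
    ``intensity_range``.  Idempotent and monotone.
    """
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi > lo:
        data = (volume.data - lo) / (hi - lo)
    else:
        data = np.zeros_like(volume.data, dtype=np.float64)
    return Volume3D(data.astype(np.float64), spacing=volume.spacing, intensity_range=(lo, hi))
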