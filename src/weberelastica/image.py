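"""Image-field container and raster I/O.

The multiplicative-noise model f = g·η and its variational restorers divide
by g and take log g, so every field fed to a solver must be strictly
positive.  Raster files are therefore loaded onto a shifted intensity scale
[floor, floor + 255] with floor > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

__all__ = ["ImageField", "load_image", "save_image"]

#: Default grid spacing Δx = Δy used throughout the solvers.
DEFAULT_SPACING = 10.0

# ITU-R 601 luma weights for collapsing colour input to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageField:
    """A 2-D grid of intensities with uniform spacing Δx = Δy.

    Parameters
    ----------
    values
        2-D float array, shape (M, N), M ≥ 3 and N ≥ 3, all finite.
    spacing
        Grid step Δx = Δy in (dimensionless) length units.
    """

    values: np.ndarray
    spacing: float = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D field, got ndim={self.values.ndim}")
        if self.values.shape[0] < 3 or self.values.shape[1] < 3:
            raise ValueError(
                f"field must be at least 3x3 (stencils need one interior ring), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_positive(self) -> bool:
        return bool(np.all(self.values > 0))

    def require_positive(self, what: str = "field") -> None:
        """Raise if any intensity is non-positive (solver-input invariant)."""
        if not self.is_positive():
            raise ValueError(f"{what} must be strictly positive everywhere")

    def with_values(self, values: np.ndarray) -> "ImageField":
        return replace(self, values=values)

    def copy(self) -> "ImageField":
        return ImageField(self.values.copy(), self.spacing)


def load_image(path, floor: float = 1.0, spacing: float = DEFAULT_SPACING) -> ImageField:
    """Load a grayscale/colour raster and map it onto [floor, floor + 255].

    Colour input is converted to luminance (ITU-R 601 weights).  8-bit input
    keeps its native codes; 16-bit input is rescaled to the 255-wide range.
    ``floor`` must be positive so the result is admissible as a solver input.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"unsupported raster layout with shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image too small for the stencils: {arr.shape}")
    if arr.max() > 255.0:  # 16-bit container
        arr = arr * (255.0 / 65535.0)
    return ImageField(arr + floor, spacing=spacing)


def save_image(
    field: ImageField, path, bitdepth: int = 8, rescale: bool = False, floor: float = 1.0
) -> None:
    """Write a field as an 8- or 16-bit grayscale raster.

    With ``rescale=False`` (default) the stored codes are ``v - floor``
    clipped to the container range, so ``load_image(save_image(x))`` with the
    same floor returns the original values up to quantization whenever they
    lie in [floor, floor + 255].  With ``rescale=True`` values are linearly
    stretched to the full container range (ordering-preserving only); a
    constant field maps to mid-gray.
    """
    if bitdepth not in (8, 16):
        raise ValueError("bitdepth must be 8 or 16")
    v = field.values
    top = 255 if bitdepth == 8 else 65535
    if rescale:
        lo, hi = float(v.min()), float(v.max())
        if hi > lo:
            scaled = (v - lo) / (hi - lo) * top
        else:
            scaled = np.full_like(v, top / 2.0)
    else:
        scaled = np.clip(v - floor, 0.0, 255.0)
        if bitdepth == 16:
            scaled = scaled * (65535.0 / 255.0)
    dtype = np.uint8 if bitdepth == 8 else np.uint16
    iio.imwrite(path, np.round(scaled).astype(dtype))
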