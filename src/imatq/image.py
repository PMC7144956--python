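"""Raster containers for 2-D MR cross-sections.

Everything downstream (phantom channels, bias fields, fat-fraction maps)
is an :class:`Image2D`: a single-channel float raster plus an isotropic
physical pixel spacing in millimetres.  Compartment assignments travel as
an integer :class:`LabelMask` of identical geometry.  Pixel indices are
0-based and row-major; areas derived from these rasters are reported in
cm² (pixel count × spacing² / 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D", "LabelMask"]


@dataclass
class Image2D:
    """Single-channel float raster with physical pixel spacing.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Pixel intensities in arbitrary units (or unitless for fields and
        fat-fraction maps).
    spacing : float
        Isotropic pixel edge length in mm.
    """

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got shape {self.data.shape}")
        if not self.spacing > 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_geometry(self, other: "Image2D | LabelMask") -> bool:
        return self.shape == other.shape and np.isclose(self.spacing, other.spacing)

    def copy(self) -> "Image2D":
        return Image2D(self.data.copy(), self.spacing)


@dataclass
class LabelMask:
    """Integer raster assigning each pixel to one anatomical compartment."""

    data: np.ndarray
    spacing: float = 1.0
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("label mask must hold integer compartment ids")
            self.data = self.data.astype(np.int32)
        if self.data.ndim != 2:
            raise ValueError(f"LabelMask requires a 2-D array, got shape {self.data.shape}")
        if not self.spacing > 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of the pixels carrying ``label``."""
        return self.data == label

    def copy(self) -> "LabelMask":
        return LabelMask(self.data.copy(), self.spacing, dict(self.names))
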