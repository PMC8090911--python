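"""Shared raster containers.

Every raster carries its pixel size in micrometres so that physical
calibrations (ring widths, areas in um^2) are derived from the image and
never hard-coded downstream. Coordinates are 0-based ``(row, col)`` with the
origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default pixel size of the screening microscope configuration, in um/px
#: (40x widefield; a 25 px expansion corresponds to 4.0625 um).
DEFAULT_PIXEL_SIZE_UM = 0.1625


@dataclass
class FieldImage:
    """One acquired field: named 2-D intensity channels plus calibration."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    well: str | None = None
    field: int | None = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMask:
    """Integer-labelled segmentation raster; 0 is background.

    Labels are positive and each labelled region is a connected component
    (8-connectivity throughout the package).
    """

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = np.ascontiguousarray(self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of label ids present (background excluded)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)


@dataclass
class BinaryMask:
    """Boolean foreground raster with calibration."""

    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2
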