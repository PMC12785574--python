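"""The in-memory container for a single hyperspectral secondary-ion image."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


@dataclass
class SpectralImage:
    """Pixel grid of ion counts on a common m/z axis.

    Parameters
    ----------
    mz_axis
        Strictly increasing channel centres in Thomson, shape ``(C,)``.
    counts
        Non-negative ion counts, shape ``(H, W, C)`` (row-major pixel grid).
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    polarity
        ``"negative"`` or ``"positive"``.
    metadata
        Free-form key/value pairs (instrument, primary-ion dose, flags).
    """

    mz_axis: np.ndarray
    counts: np.ndarray
    pixel_size_um: float
    polarity: str = "negative"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.mz_axis.ndim != 1:
            raise ValueError("mz_axis must be one-dimensional")
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (height, width, channels)")
        if self.counts.shape[2] != self.mz_axis.size:
            raise ValueError(
                f"counts has {self.counts.shape[2]} channels but mz_axis has "
                f"{self.mz_axis.size}"
            )
        if self.mz_axis.size > 1 and not np.all(np.diff(self.mz_axis) > 0):
            raise ValueError("mz_axis must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def height_px(self) -> int:
        return self.counts.shape[0]

    @property
    def width_px(self) -> int:
        return self.counts.shape[1]

    @property
    def n_channels(self) -> int:
        return self.mz_axis.size

    @property
    def field_of_view_um(self) -> float:
        """Physical width of the image in micrometres."""
        return self.width_px * self.pixel_size_um

    def with_axis(self, mz_axis: np.ndarray) -> "SpectralImage":
        """Copy of the image with a replaced (e.g. recalibrated) m/z axis."""
        return replace(self, mz_axis=np.asarray(mz_axis, dtype=float),
                       metadata=dict(self.metadata))

    def mean_spectrum(self) -> np.ndarray:
        """Pixel-averaged spectrum, shape ``(C,)``."""
        return self.counts.mean(axis=(0, 1))

    def total_ion_count(self) -> float:
        """Summed counts over all pixels and channels."""
        return float(self.counts.sum())
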