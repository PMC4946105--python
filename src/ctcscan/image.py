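"""Calibrated image containers shared by all pipeline stages.

Lengths are micrometres, areas square micrometres, exposures milliseconds.
Pixel coordinates are 0-based ``(row, col)``; physical coordinates are
``(x, y)`` in micrometres with ``x = col * pixel_size`` and
``y = row * pixel_size``.  Crops are half-open slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Channel roles used across the package.
DAPI = "dapi"
EPITHELIAL = "epithelial"  # green / AF488
MESENCHYMAL = "mesenchymal"  # red / AF546
CD45 = "cd45"  # dark red / APC
FISH_RED = "red"
FISH_GREEN = "green"
FISH_AQUA = "aqua"
BRIGHTFIELD = "brightfield"

FLUO_ROLES = (DAPI, EPITHELIAL, MESENCHYMAL, CD45)
FISH_ROLES = (FISH_RED, FISH_GREEN, FISH_AQUA)


class MissingPixelSizeError(ValueError):
    """Raised when a physical measurement is requested without a pixel size."""


@dataclass
class ChannelImage:
    """A single 2-D fluorescence (or brightfield) plane with calibration.

    Parameters
    ----------
    data:
        2-D intensity array (typically ``uint8``, detector range 0-255).
    pixel_size_um:
        Lateral pixel size in micrometres.  ``None`` is tolerated for
        uncalibrated images but any operation needing physical units
        raises :class:`MissingPixelSizeError`.
    role:
        Channel role, one of the module-level constants.
    exposure_ms:
        Exposure used for acquisition, if known.
    """

    data: np.ndarray
    pixel_size_um: float | None
    role: str = DAPI
    exposure_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ChannelImage requires a 2-D array, got ndim={self.data.ndim}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def require_pixel_size(self) -> float:
        if self.pixel_size_um is None:
            raise MissingPixelSizeError(
                f"channel {self.role!r} has no pixel size; physical units are undefined"
            )
        return float(self.pixel_size_um)

    def pixel_area_um2(self) -> float:
        ps = self.require_pixel_size()
        return ps * ps


@dataclass
class ZStackSeries:
    """A z-stack of optical sections for one channel.

    ``data`` is ``(n_planes, ny, nx)``.  Plane ``j`` sits at axial position
    ``z_center_um + (j - (n - 1) / 2) * step_um`` so the comb is centred on
    the (per-frame refocused) DAPI focus.
    """

    data: np.ndarray
    pixel_size_um: float | None
    step_um: float
    role: str = FISH_RED
    z_center_um: float = 0.0
    exposure_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ZStackSeries requires a 3-D array, got ndim={self.data.ndim}")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def span_um(self) -> float:
        """Total comb span ``(n_planes - 1) * step_um``."""
        return (self.n_planes - 1) * self.step_um

    def plane_z_um(self, j: int | np.ndarray) -> float | np.ndarray:
        return self.z_center_um + (np.asarray(j) - (self.n_planes - 1) / 2.0) * self.step_um

    def require_pixel_size(self) -> float:
        if self.pixel_size_um is None:
            raise MissingPixelSizeError(f"z-stack {self.role!r} has no pixel size")
        return float(self.pixel_size_um)
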