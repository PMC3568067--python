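"""Cell geometry and rate-unit conversions.

All fluxes in the package are expressed per liter of cell volume
(mmol·min⁻¹·(l cell)⁻¹).  Experimental rates measured per cell are converted
through the volume of a single cardiomyocyte, modelled as a cylinder:
V = π/4 · d² · l.  With the default dimensions d = 14 μm, l = 140 μm this
gives 2.16e-11 l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: default cardiomyocyte dimensions, μm
DEFAULT_DIAMETER_UM = 14.0
DEFAULT_LENGTH_UM = 140.0

_M3_TO_L = 1000.0


def cardiomyocyte_volume(d_um: float = DEFAULT_DIAMETER_UM,
                         l_um: float = DEFAULT_LENGTH_UM) -> float:
    """Cylinder volume π/4·d²·l in liters, dimensions in μm."""
    if d_um <= 0 or l_um <= 0:
        raise ValueError("cell dimensions must be positive")
    return math.pi / 4.0 * (d_um * 1e-6) ** 2 * (l_um * 1e-6) * _M3_TO_L


@dataclass(frozen=True)
class CellGeometry:
    """Cylindrical cell geometry; volume derived from diameter and length."""

    diameter_um: float = DEFAULT_DIAMETER_UM
    length_um: float = DEFAULT_LENGTH_UM

    @property
    def volume_l(self) -> float:
        return cardiomyocyte_volume(self.diameter_um, self.length_um)


def per_cell_to_per_liter(rate_per_cell: float, volume_l: float) -> float:
    """Convert a per-cell rate to a per-liter-of-cell rate."""
    if volume_l <= 0:
        raise ValueError("cell volume must be positive")
    return rate_per_cell / volume_l


def per_liter_to_per_cell(rate_per_liter: float, volume_l: float) -> float:
    """Inverse of :func:`per_cell_to_per_liter`."""
    if volume_l <= 0:
        raise ValueError("cell volume must be positive")
    return rate_per_liter * volume_l
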