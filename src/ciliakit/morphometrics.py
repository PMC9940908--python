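"""Cell-level cilia morphometrics: area density and inter-cilia spacing.

Multiciliated cells carry tens of cilia on a small apical surface; two
derived numbers summarize how tightly the bundle is packed.  The area
density is simply cilia count over apical area.  The spacing is defined as
the diameter of the circle whose area is one cilium's share of the apical
surface, 2 sqrt(area / (pi n)) - a lattice-free definition, between the
square-lattice and hexagonal-lattice nearest-neighbour spacings.  The two
obey spacing^2 x density = 4 / pi identically.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CellMeasurements", "cilia_area_density", "intercilia_spacing"]

import math


@dataclass(frozen=True)
class CellMeasurements:
    """Per-cell measurements (all positive)."""

    n_cilia: float
    apical_area: float  # um^2
    cilium_length: float | None = None  # um

    def __post_init__(self) -> None:
        if self.n_cilia <= 0 or self.apical_area <= 0:
            raise ValueError("cilia count and apical area must be positive")
        if self.cilium_length is not None and self.cilium_length <= 0:
            raise ValueError("cilium length must be positive")

    @property
    def density(self) -> float:
        return cilia_area_density(self.n_cilia, self.apical_area)

    @property
    def spacing(self) -> float:
        return intercilia_spacing(self.n_cilia, self.apical_area)


def cilia_area_density(n_cilia: float, apical_area: float) -> float:
    """Cilia per um^2 of apical surface."""
    if apical_area <= 0:
        raise ValueError("apical area must be positive")
    if n_cilia <= 0:
        raise ValueError("cilia count must be positive")
    return n_cilia / apical_area

def intercilia_spacing(n_cilia: float, apical_area: float) -> float:
    """Circle-equivalent distance between cilia in um: 2 sqrt(A / (pi n))."""
    if apical_area <= 0 or n_cilia <= 0:
        raise ValueError("inputs must be positive")
    return 2.0 * math.sqrt(apical_area / (math.pi * n_cilia))
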