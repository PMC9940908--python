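"""Admissible traveling waves on the triangular cilia lattice.

A 16x16 unit cell with periodic boundary conditions admits exactly 256
traveling plane waves of cilia phase.  Each wave is a point
k = 2 pi/lambda (-sin theta, cos theta) in the first Brillouin zone;
theta = 0 is the symplectic wave along the effective stroke, the in-phase
state is k = (0, 0).
"""

import numpy as np

from ciliakit import (
    LatticeSpec,
    angle_to_wavevector,
    build_lattice,
    lattice_density,
    noisy_phase_field,
)
from ciliakit.lattice import wave_table

spec = LatticeSpec(n1=16, n2=16, spacing=18.0)
print(f"lattice: {spec.n1}x{spec.n2}, spacing {spec.spacing} um, "
      f"density {lattice_density(spec.spacing):.4f} cilia/um^2")

table = wave_table(spec)
finite = table[np.isfinite(table.wavelength_um)]
print(f"admissible waves: {len(table)} (incl. in-phase k=0)")
print(f"wavelengths span {finite.wavelength_um.min():.1f} to "
      f"{finite.wavelength_um.max():.1f} um")
print(table.head(5).round(4).to_string(index=False))

# a noisy symplectic wave as initial condition for carpet simulations
positions = build_lattice(spec)
k = angle_to_wavevector(0.0, 96.0)
field = noisy_phase_field(k, positions, sigma=0.2, seed=0)
print(f"\nnoisy symplectic wave (lambda 96 um, sigma 0.2 rad): "
      f"{field.phases.size} site phases, e.g. {np.round(field.phases[:4], 3)}")
# The wave count equals n1*n2 and the longest finite wavelength is the
# unit-cell period along the stroke axis.
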