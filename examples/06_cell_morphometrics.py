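"""Cilia packing statistics of a multiciliated cell.

From a cilia count and an apical surface area, derive the area density and
the circle-equivalent distance between neighbouring cilia.  The example
values (47.7 cilia on 17.4 um^2) are typical of small, densely ciliated
epithelial cells.
"""

from ciliakit import CellMeasurements

cell = CellMeasurements(n_cilia=47.7, apical_area=17.4, cilium_length=8.8)
print(f"cilia per cell:     {cell.n_cilia}")
print(f"apical area:        {cell.apical_area} um^2")
print(f"area density:       {cell.density:.2g} cilia/um^2")
print(f"inter-cilia spacing: {cell.spacing:.2g} um")
# Density ~2.7 cilia/um^2 at ~0.68 um spacing: cilia sit much closer than
# one cilium length apart, so neighbouring cilia interact strongly.
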