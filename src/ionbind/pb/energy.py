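"""Grid energies: E = 1/2 * sum_nodes q_node * phi_node (kT).

Grid energies contain the lattice self-energy of the spread charges; this is
why physically meaningful numbers are always *differences* between runs that
share the identical lattice, where the self-term cancels.
"""

from __future__ import annotations

import numpy as np

from .grids import DielectricGrid
from .solver import PotentialGrid


def grid_energy(potential: PotentialGrid, grid: DielectricGrid) -> float:
    """Total grid energy in kT."""
    if potential.geometry != grid.geometry:
        raise ValueError(
            "potential and charge grids are not congruent: "
            f"{potential.geometry} vs {grid.geometry}"
        )
    return 0.5 * float(np.sum(grid.charge * potential.values))
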