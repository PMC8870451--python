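"""Physical constants in the reduced unit system used throughout.

Lengths are in angstrom, charges in units of the elementary charge e, and
energies in kT.  Potentials produced by the PB solver are therefore in kT/e.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

DEFAULT_TEMPERATURE = 298.15  # K

#: Avogadro constant scaled to molecules per Å^3 per (mol/L)
_MOLAR_TO_PER_A3 = _sc.Avogadro / 1e27


def coulomb_kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Coulomb constant ``e^2 / (4 pi eps0)`` expressed in kT*Å/e^2.

    At 298 K this is approximately 561, so two unit charges 1 Å apart in
    vacuum interact with ~561 kT.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    e2_over_4pieps0 = _sc.e**2 / (4.0 * math.pi * _sc.epsilon_0)  # J*m
    kt = _sc.Boltzmann * temperature  # J
    return e2_over_4pieps0 / kt / 1e-10  # -> kT*Å


def modified_kappa2(
    ionic_strength: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Dielectric-independent screening factor ``eps * kappa^2`` in 1/Å^2.

    The linearized PB operator carries the term ``eps_out * kappa^2 * phi``
    with ``kappa`` the inverse Debye length of the bulk solvent; this helper
    returns ``eps_out * kappa^2`` directly, which does not depend on the
    dielectric (``kappa^2`` itself scales as 1/eps).

    For 0.15 M at 298 K the implied Debye length in water (eps 80) is
    ~7.9 Å.
    """
    if ionic_strength < 0:
        raise ValueError(f"ionic strength must be >= 0, got {ionic_strength}")
    # eps*kappa^2 = 8 pi C I with I in molecules/Å^3 (both ion species).
    return 8.0 * math.pi * coulomb_kt(temperature) * ionic_strength * _MOLAR_TO_PER_A3


def debye_length(
    ionic_strength: float,
    eps: float = 80.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Debye screening length in Å for the given ionic strength and dielectric."""
    mk2 = modified_kappa2(ionic_strength, temperature)
    if mk2 == 0:
        return math.inf
    return math.sqrt(eps / mk2)
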