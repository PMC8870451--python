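"""Stationary synthetic energy series for boost parameterization tests."""

from __future__ import annotations

import numpy as np

from ..amd import EnergySeries


def gen_energy_series(
    mean: float,
    sd: float,
    n: int,
    dt: float = 0.01,
    seed: int = 0,
    dihedral_mean: float | None = None,
    dihedral_sd: float | None = None,
) -> EnergySeries:
    """i.i.d. Gaussian series around ``mean`` (potential) sampled every ``dt`` ns.

    The dihedral column defaults to the same distribution; deterministic for a
    given seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    dm = mean if dihedral_mean is None else dihedral_mean
    ds = sd if dihedral_sd is None else dihedral_sd
    if ds < 0:
        raise ValueError(f"dihedral_sd must be >= 0, got {ds}")
    rng = np.random.default_rng(seed)
    times = dt * np.arange(n, dtype=float)
    dihedral = dm + (ds * rng.standard_normal(n) if ds > 0 else np.zeros(n))
    potential = mean + (sd * rng.standard_normal(n) if sd > 0 else np.zeros(n))
    return EnergySeries(times=times, dihedral=dihedral, potential=potential)
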