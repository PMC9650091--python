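"""Core FRET arithmetic shared by every analysis stage.

Apparent FRET efficiency is the ratiometric proxy

    E = I_A / (I_A + I_D)

computed from background-corrected donor and acceptor intensities with no
gamma-factor, spectral-leakage or direct-excitation correction.  Efficiency
and mean dye separation are interconverted through the Foerster relation

    E = R0**6 / (R0**6 + R**6),

where R0 is the Foerster radius of the dye pair (5.3 nm for DiI-DiD).
Intensities entering this module are assumed to be background-corrected
already; background handling lives with the modules that own raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import DomainError

__all__ = [
    "FretParams",
    "IntensityPair",
    "fret_efficiency",
    "efficiency_to_distance",
    "distance_to_efficiency",
]

#: Correction hook signature: (donor, acceptor) -> (donor, acceptor).
CorrectionHook = Callable[[float, float], tuple[float, float]]


def _identity_correction(donor: float, acceptor: float) -> tuple[float, float]:
    return donor, acceptor


@dataclass(frozen=True)
class FretParams:
    """Parameters of the FRET pair.

    Parameters
    ----------
    forster_radius_nm
        Donor-acceptor separation at which transfer efficiency is 50%.
        Default 5.3 nm (DiI-DiD).
    """

    forster_radius_nm: float = 5.3

    def __post_init__(self):
        if not self.forster_radius_nm > 0:
            raise DomainError(
                f"Foerster radius must be positive, got {self.forster_radius_nm}"
            )


@dataclass(frozen=True)
class IntensityPair:
    """Background-corrected donor and acceptor intensities (same arbitrary units)."""

    donor: float
    acceptor: float

    def __post_init__(self):
        if self.donor < 0 or self.acceptor < 0:
            raise DomainError(
                f"intensities must be nonnegative, got ({self.donor}, {self.acceptor})"
            )


def fret_efficiency(
    pair: IntensityPair, correction: CorrectionHook = _identity_correction
) -> float:
    """Apparent FRET efficiency E = I_A / (I_A + I_D).

    ``correction`` is an optional hook applied to (donor, acceptor) before the
    ratio is formed; the default is the identity (apparent efficiency).

    Raises
    ------
    DomainError
        If both intensities are zero (ratio undefined) or either is negative.
    """
    donor, acceptor = correction(pair.donor, pair.acceptor)
    if donor < 0 or acceptor < 0:
        raise DomainError("corrected intensities must be nonnegative")
    total = donor + acceptor
    if total <= 0:
        raise DomainError("donor + acceptor must be positive to form an efficiency")
    return acceptor / total


def efficiency_to_distance(E: float, params: FretParams = FretParams()) -> float:
    """Mean dye separation R (nm) from efficiency: R = R0 * ((1-E)/E)**(1/6).

    Strictly decreasing in E.  E must lie strictly inside (0, 1); the distance
    diverges as E -> 0 and collapses to zero as E -> 1.
    """
    E = float(E)
    if not 0.0 < E < 1.0:
        raise DomainError(f"efficiency must lie strictly in (0, 1), got {E}")
    return params.forster_radius_nm * ((1.0 - E) / E) ** (1.0 / 6.0)


def distance_to_efficiency(R: float, params: FretParams = FretParams()) -> float:
    """Efficiency from separation: E = R0**6 / (R0**6 + R**6).

    Exact inverse of :func:`efficiency_to_distance` for R > 0.
    """
    R = float(R)
    if not R > 0:
        raise DomainError(f"separation must be positive, got {R}")
    # Work with the sixth-power ratio to stay stable for extreme R/R0.
    ratio6 = (R / params.forster_radius_nm) ** 6
    return 1.0 / (1.0 + ratio6)


def efficiencies_to_distances(
    E: "np.ndarray", params: FretParams = FretParams()
) -> "np.ndarray":
    """Vectorised :func:`efficiency_to_distance` for arrays of efficiencies."""
    E = np.asarray(E, dtype=float)
    if np.any((E <= 0) | (E >= 1)):
        raise DomainError("all efficiencies must lie strictly in (0, 1)")
    return params.forster_radius_nm * ((1.0 - E) / E) ** (1.0 / 6.0)
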