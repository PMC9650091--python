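"""Dynamic light scattering: correlogram fitting and vesicle sizing.

The backscatter intensity autocorrelation of monodisperse Brownian
diffusers follows

    G(tau) = A * [1 + B * exp(-2 * D * q**2 * tau)]

with scattering vector q = 4*pi*n/lambda0 * sin(theta/2).  The fitted
diffusion coefficient D converts to a hydrodynamic diameter through the
Stokes-Einstein relation d_H = k_B * T / (3 * pi * eta * D).

Default instrument geometry matches a 633 nm backscatter correlator
(theta = 178 deg, n = 1.33); the environment defaults to water at 25 C
(T = 298.15 K, eta = 8.9e-4 Pa s).  Both are configuration, not constants.

``size_distribution_stats`` additionally summarises externally measured
diameter tables (e.g. electron-microscopy sizing) with a fixed-bin-width
histogram and a log-normal maximum-likelihood fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.constants import Boltzmann

from .errors import ConfigurationError, DegenerateFitError, DomainError

__all__ = [
    "Instrument",
    "Environment",
    "Correlogram",
    "DlsFit",
    "scattering_vector",
    "fit_correlogram",
    "stokes_einstein_diameter",
    "diameter_to_diffusion",
    "size_distribution_stats",
    "lognormal_from_mode_fwhm",
]


@dataclass(frozen=True)
class Instrument:
    """Correlator optical geometry."""

    wavelength_nm: float = 633.0
    angle_deg: float = 178.0
    refractive_index: float = 1.33


@dataclass(frozen=True)
class Environment:
    """Solvent conditions for Stokes-Einstein conversion."""

    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4


@dataclass
class Correlogram:
    """Lag-time versus intensity-autocorrelation curve."""

    lag_s: np.ndarray
    g2: np.ndarray
    instrument: Instrument = field(default_factory=Instrument)
    environment: Environment = field(default_factory=Environment)

    def __post_init__(self):
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lag_s.shape != self.g2.shape:
            raise ConfigurationError("lag and g2 arrays differ in length")
        if np.any(np.diff(self.lag_s) <= 0) or np.any(self.lag_s <= 0):
            raise ConfigurationError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g2)):
            raise DomainError("g2 contains non-finite values")


@dataclass
class DlsFit:
    """Fitted single-exponential correlogram parameters and derived size."""

    A: float
    B: float
    D_m2_s: float
    d_H_nm: float
    residual_rms: float


def scattering_vector(
    refractive_index: float, wavelength_nm: float, angle_deg: float
) -> float:
    """Scattering vector magnitude q = 4*pi*n/lambda0 * sin(theta/2), in 1/m."""
    if wavelength_nm <= 0:
        raise DomainError("wavelength must be positive")
    if not 0 <= angle_deg <= 180:
        raise DomainError("scattering angle must lie in [0, 180] degrees")
    wavelength_m = wavelength_nm * 1e-9
    return 4 * math.pi * refractive_index / wavelength_m * math.sin(
        math.radians(angle_deg) / 2
    )


def stokes_einstein_diameter(
    D_m2_s: float, temperature_K: float = 298.15, viscosity_Pa_s: float = 8.9e-4
) -> float:
    """Hydrodynamic diameter d_H = k_B T / (3 pi eta D), returned in nm."""
    if D_m2_s <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise DomainError("D, T and eta must all be positive")
    d_m = Boltzmann * temperature_K / (3 * math.pi * viscosity_Pa_s * D_m2_s)
    return d_m * 1e9


def diameter_to_diffusion(
    d_H_nm: float, temperature_K: float = 298.15, viscosity_Pa_s: float = 8.9e-4
) -> float:
    """Inverse Stokes-Einstein map: diffusion coefficient (m^2/s) from d_H (nm)."""
    if d_H_nm <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise DomainError("d_H, T and eta must all be positive")
    return Boltzmann * temperature_K / (3 * math.pi * viscosity_Pa_s * d_H_nm * 1e-9)


def fit_correlogram(corr: Correlogram) -> DlsFit:
    """Nonlinear least-squares fit of G(tau) = A[1 + B exp(-2 D q^2 tau)].

    Initialisation: A from the tail mean, B from the intercept, D from a
    log-linear fit of the early decay.  All three parameters are constrained
    positive.  A flat curve (no decay information) raises
    :class:`DegenerateFitError`.
    """
    tau = corr.lag_s
    g2 = corr.g2
    if tau.size < 10:
        raise ConfigurationError("need at least 10 lag points spanning the decay")
    q = scattering_vector(
        corr.instrument.refractive_index,
        corr.instrument.wavelength_nm,
        corr.instrument.angle_deg,
    )

    n_tail = max(3, tau.size // 10)
    A0 = float(np.mean(g2[-n_tail:]))
    if A0 <= 0:
        A0 = max(float(g2.min()), 1e-12)
    B0 = max(float(g2[0] / A0 - 1.0), 1e-3)
    span = float(g2.max() - g2.min())
    if span < 1e-6 * max(abs(float(g2.mean())), 1e-30):
        raise DegenerateFitError("correlogram is flat: no decay to fit")

    # Log-linear slope of the normalised early decay for the D estimate.
    norm = (g2 - A0) / (A0 * B0)
    early = norm > 0.1
    if early.sum() >= 2:
        slope = np.polyfit(tau[early], np.log(np.clip(norm[early], 1e-12, None)), 1)[0]
        D0 = max(-slope / (2 * q * q), 1e-18)
    else:
        D0 = 1.0 / (2 * q * q * tau[tau.size // 2])

    # Fit in a dimensionless rate (decay rate x reference lag) so the three
    # parameters share a common scale; D in m^2/s differs from A by ~12
    # orders of magnitude and would otherwise stall the optimiser.
    tau_ref = float(np.median(tau))

    def model(tau, A, B, r):
        return A * (1.0 + B * np.exp(-r * tau / tau_ref))

    r0 = 2.0 * D0 * q * q * tau_ref
    popt, _ = curve_fit(
        model, tau, g2, p0=[A0, B0, r0],
        bounds=([0, 0, 0], [np.inf, 1.2, np.inf]), maxfev=20000,
    )
    A, B = float(popt[0]), float(popt[1])
    D = float(popt[2]) / (2.0 * q * q * tau_ref)
    if D <= 0:
        raise DegenerateFitError(f"fitted diffusion coefficient not positive: {D}")
    resid = g2 - model(tau, *popt)
    d_H = stokes_einstein_diameter(
        D, corr.environment.temperature_K, corr.environment.viscosity_Pa_s
    )
    return DlsFit(A=A, B=B, D_m2_s=D, d_H_nm=d_H,
                  residual_rms=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# Size-distribution summaries for diameter tables.

def lognormal_from_mode_fwhm(mode: float, fwhm: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given density mode and FWHM.

    Solved numerically: for fixed sigma the mode pins mu = ln(mode) + sigma^2,
    and the FWHM of the density scales linearly with the mode, so a 1-D root
    find in sigma suffices.
    """
    if mode <= 0 or fwhm <= 0:
        raise DomainError("mode and FWHM must be positive")

    def fwhm_of(sigma):
        mu = math.log(mode) + sigma * sigma
        lo, hi = _lognormal_fwhm_points(mu, sigma)
        return hi - lo

    sigma = brentq(lambda s: fwhm_of(s) - fwhm, 1e-4, 3.0)
    return math.log(mode) + sigma * sigma, sigma


def _lognormal_pdf(x, mu, sigma):
    return np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma**2)) / (
        x * sigma * math.sqrt(2 * math.pi)
    )


def _lognormal_fwhm_points(mu: float, sigma: float) -> tuple[float, float]:
    mode = math.exp(mu - sigma * sigma)
    half = _lognormal_pdf(mode, mu, sigma) / 2

    def f(x):
        return _lognormal_pdf(x, mu, sigma) - half

    lo = brentq(f, mode * 1e-6, mode)
    hi = brentq(f, mode, mode * 1e6)
    return lo, hi


def size_distribution_stats(
    diameters_nm, bin_width_nm: float = 25.0
) -> dict:
    """Histogram plus log-normal fit of a diameter sample.

    Returns a dict with ``histogram`` (DataFrame of bin_lo/bin_hi/count),
    ``peak_nm`` (fitted density mode), ``fwhm_nm``, ``mu`` and ``sigma``
    (log-normal parameters by maximum likelihood).  A degenerate sample
    (all diameters equal) returns that value as the peak with zero FWHM.
    """
    d = np.asarray(diameters_nm, dtype=float)
    if d.size < 10:
        raise ConfigurationError("need at least 10 diameters")
    if bin_width_nm <= 0:
        raise DomainError("bin width must be positive")
    if np.any(d <= 0):
        raise DomainError("diameters must be positive")

    edges = np.arange(0.0, d.max() + bin_width_nm, bin_width_nm)
    counts, edges = np.histogram(d, bins=edges)
    hist = pd.DataFrame(
        {"bin_lo_nm": edges[:-1], "bin_hi_nm": edges[1:], "count": counts}
    )

    logs = np.log(d)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma < 1e-12:
        return {"histogram": hist, "peak_nm": float(d[0]), "fwhm_nm": 0.0,
                "mu": mu, "sigma": sigma}
    mode = math.exp(mu - sigma * sigma)
    lo, hi = _lognormal_fwhm_points(mu, sigma)
    return {"histogram": hist, "peak_nm": mode, "fwhm_nm": hi - lo,
            "mu": mu, "sigma": sigma}


# ---------------------------------------------------------------------------
# CSV interface: (lag_s, g2) with instrument/environment fields in comment
# headers, e.g. "# wavelength_nm=633".

_HEADER_FIELDS = {
    "wavelength_nm": ("instrument", float),
    "angle_deg": ("instrument", float),
    "refractive_index": ("instrument", float),
    "temperature_K": ("environment", float),
    "viscosity_Pa_s": ("environment", float),
}


def read_correlogram_csv(path: str | Path) -> Correlogram:
    path = Path(path)
    inst: dict = {}
    env: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").strip().partition("=")
            if key in _HEADER_FIELDS:
                group, cast = _HEADER_FIELDS[key]
                (inst if group == "instrument" else env)[key] = cast(value)
    df = pd.read_csv(path, comment="#")
    return Correlogram(
        df["lag_s"].to_numpy(), df["g2"].to_numpy(),
        instrument=Instrument(**inst), environment=Environment(**env),
    )


def write_correlogram_csv(corr: Correlogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wavelength_nm={corr.instrument.wavelength_nm}\n")
        fh.write(f"# angle_deg={corr.instrument.angle_deg}\n")
        fh.write(f"# refractive_index={corr.instrument.refractive_index}\n")
        fh.write(f"# temperature_K={corr.environment.temperature_K}\n")
        fh.write(f"# viscosity_Pa_s={corr.environment.viscosity_Pa_s}\n")
        pd.DataFrame({"lag_s": corr.lag_s, "g2": corr.g2}).to_csv(fh, index=False)
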