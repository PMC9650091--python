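"""Bulk emission-spectrum analysis for crowder titrations.

A titration series is a set of donor/acceptor emission spectra recorded at
increasing crowder concentration.  Each spectrum is background-corrected,
integrated over a donor band and an acceptor band, and converted to an
apparent FRET efficiency and a mean dye separation.  The concentration trend
is summarised with the heuristic quadratic fit used for titration curves.

Default integration bands are 545-610 nm (DiI donor) and 650-750 nm (DiD
acceptor), consistent with a 640 nm long-pass dichroic; both are
configuration parameters, not fixed constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, InsufficientDataError
from .photophysics import FretParams, IntensityPair, efficiency_to_distance, fret_efficiency

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "DEFAULT_DONOR_BAND",
    "DEFAULT_ACCEPTOR_BAND",
    "integrate_bands",
    "series_to_efret",
    "fit_titration_quadratic",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

DEFAULT_DONOR_BAND = (545.0, 610.0)
DEFAULT_ACCEPTOR_BAND = (650.0, 750.0)
#: Wavelength window used for the default constant-baseline estimate.
BASELINE_WINDOW = (750.0, 780.0)


@dataclass
class EmissionSpectrum:
    """A single fluorescence emission spectrum on its native wavelength grid."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float = 532.0

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ConfigurationError("wavelength and intensity grids differ in length")
        if self.wavelength_nm.size < 2:
            raise ConfigurationError("spectrum needs at least two samples")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")


@dataclass
class TitrationSeries:
    """Spectra recorded across an ordered crowder titration.

    ``concentration`` may repeat (replicates); within the series it must be
    sorted ascending.  ``replicate_id`` labels the series as a whole.
    """

    concentration: Sequence[float]
    spectra: Sequence[EmissionSpectrum]
    replicate_id: str = ""

    def __post_init__(self):
        conc = np.asarray(self.concentration, dtype=float)
        if conc.size != len(self.spectra):
            raise ConfigurationError("one spectrum required per concentration")
        if conc.size < 2:
            raise ConfigurationError("titration needs at least two points")
        if np.any(np.diff(conc) < 0):
            raise ConfigurationError("concentrations must be sorted ascending")


def _default_baseline(spectrum: EmissionSpectrum) -> float:
    """Median intensity over the red-edge window, 0 if the window is absent."""
    lo, hi = BASELINE_WINDOW
    mask = (spectrum.wavelength_nm >= lo) & (spectrum.wavelength_nm <= hi)
    if not mask.any():
        return 0.0
    return float(np.median(spectrum.intensity[mask]))


def _band_integral(wl: np.ndarray, signal: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise DomainError(f"band {band} falls outside the wavelength grid")
    return float(np.trapezoid(signal[mask], wl[mask]))


def integrate_bands(
    spectrum: EmissionSpectrum,
    donor_band: tuple[float, float] = DEFAULT_DONOR_BAND,
    acceptor_band: tuple[float, float] = DEFAULT_ACCEPTOR_BAND,
    baseline: EmissionSpectrum | float | None = None,
) -> IntensityPair:
    """Integrated, background-corrected donor and acceptor band intensities.

    The baseline is either a measured blank spectrum (on the same grid), a
    constant, or None, in which case the median intensity over 750-780 nm is
    used.  Trapezoidal quadrature on the native grid; each band integral is
    clipped at zero.
    """
    if donor_band[0] >= donor_band[1] or acceptor_band[0] >= acceptor_band[1]:
        raise ConfigurationError("band limits must be (low, high) with low < high")
    if max(donor_band[0], acceptor_band[0]) < min(donor_band[1], acceptor_band[1]):
        raise ConfigurationError(
            f"donor band {donor_band} and acceptor band {acceptor_band} overlap"
        )
    wl = spectrum.wavelength_nm
    if donor_band[0] < wl[0] or acceptor_band[1] > wl[-1]:
        raise DomainError("integration bands extend beyond the wavelength grid")

    if baseline is None:
        corrected = spectrum.intensity - _default_baseline(spectrum)
    elif isinstance(baseline, EmissionSpectrum):
        if baseline.wavelength_nm.shape != wl.shape or not np.allclose(
            baseline.wavelength_nm, wl
        ):
            raise ConfigurationError("blank spectrum must share the sample grid")
        corrected = spectrum.intensity - baseline.intensity
    else:
        corrected = spectrum.intensity - float(baseline)

    donor = max(0.0, _band_integral(wl, corrected, donor_band))
    acceptor = max(0.0, _band_integral(wl, corrected, acceptor_band))
    return IntensityPair(donor=donor, acceptor=acceptor)


def series_to_efret(
    series: TitrationSeries,
    params: FretParams = FretParams(),
    donor_band: tuple[float, float] = DEFAULT_DONOR_BAND,
    acceptor_band: tuple[float, float] = DEFAULT_ACCEPTOR_BAND,
    baseline: EmissionSpectrum | float | None = None,
) -> pd.DataFrame:
    """Per-concentration E_FRET and mean separation table.

    Returns a tidy frame with columns ``concentration, e_fret, e_sd, r_nm,
    r_sd, n_replicates, flagged``.  Spectra whose total band signal is zero
    are flagged and excluded from the aggregate rather than propagating NaN.
    Replicated concentrations are averaged (mean +/- sd).
    """
    rows = []
    for conc, spectrum in zip(series.concentration, series.spectra):
        pair = integrate_bands(spectrum, donor_band, acceptor_band, baseline)
        if pair.donor + pair.acceptor <= 0:
            rows.append({"concentration": conc, "e_fret": np.nan, "flagged": True})
            continue
        E = fret_efficiency(pair)
        rows.append({"concentration": conc, "e_fret": E, "flagged": False})
    raw = pd.DataFrame(rows)

    out = []
    for conc, grp in raw.groupby("concentration", sort=True):
        ok = grp.loc[~grp["flagged"], "e_fret"]
        if ok.empty:
            out.append(
                dict(concentration=conc, e_fret=np.nan, e_sd=np.nan,
                     r_nm=np.nan, r_sd=np.nan, n_replicates=0, flagged=True)
            )
            continue
        e_mean = float(ok.mean())
        e_sd = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
        r_vals = [efficiency_to_distance(e, params) for e in ok if 0 < e < 1]
        r_mean = float(np.mean(r_vals)) if r_vals else np.nan
        r_sd = float(np.std(r_vals, ddof=1)) if len(r_vals) > 1 else 0.0
        out.append(
            dict(concentration=conc, e_fret=e_mean, e_sd=e_sd,
                 r_nm=r_mean, r_sd=r_sd, n_replicates=len(ok), flagged=False)
        )
    return pd.DataFrame(out)


def fit_titration_quadratic(
    concentration: Sequence[float], response: Sequence[float]
) -> tuple[float, float, float, np.ndarray]:
    """Heuristic degree-2 least-squares trend fit of response vs concentration.

    Returns ``(c0, c1, c2, residuals)`` for y = c0 + c1*x + c2*x**2.
    NaN responses (flagged titration points) are dropped before fitting.
    """
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(
            f"quadratic trend fit needs >= 3 points, got {x.size}"
        )
    c2, c1, c0 = np.polyfit(x, y, 2)
    residuals = y - (c0 + c1 * x + c2 * x * x)
    return float(c0), float(c1), float(c2), residuals


# ---------------------------------------------------------------------------
# CSV interface: one (wavelength_nm, intensity) file per condition plus a
# manifest (file, concentration, replicate).

def read_spectrum_csv(path: str | Path, excitation_nm: float = 532.0) -> EmissionSpectrum:
    df = pd.read_csv(path)
    if not {"wavelength_nm", "intensity"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns wavelength_nm, intensity")
    return EmissionSpectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        excitation_nm=excitation_nm,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV with columns ``file, concentration`` (optional ``replicate``)."""
    df = pd.read_csv(path)
    if not {"file", "concentration"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns file, concentration")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df.sort_values(["concentration", "replicate"]).reset_index(drop=True)


def analyze_manifest(
    manifest_path: str | Path,
    params: FretParams = FretParams(),
    donor_band: tuple[float, float] = DEFAULT_DONOR_BAND,
    acceptor_band: tuple[float, float] = DEFAULT_ACCEPTOR_BAND,
    baseline: float | None = None,
) -> pd.DataFrame:
    """Run the full titration analysis from a manifest of spectrum CSVs."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    spectra = [
        read_spectrum_csv(manifest_path.parent / f) for f in manifest["file"]
    ]
    series = TitrationSeries(
        concentration=manifest["concentration"].tolist(), spectra=spectra
    )
    return series_to_efret(series, params, donor_band, acceptor_band, baseline)
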