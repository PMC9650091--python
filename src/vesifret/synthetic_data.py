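"""Synthetic instrument data with known ground truth.

Every analysis stage in this package consumes a distinct data modality:
emission spectra, TCSPC decay histograms, DLS correlograms and dual-view
TIRF movies.  The generators here emulate each modality under the study
conditions the analyses assume — biexponential photon decays convolved with
an instrument response at 1e4 peak counts, single-exponential field
correlograms for ~100-1000 nm diffusers, and 500-frame dual-channel movies
of immobile, diffraction-limited vesicles with log-normal brightness — so
that every pipeline stage can be exercised against exact ground truth.

All generators are deterministic given a seed (bit-identical re-runs) and
return the generated dataset together with a :class:`GroundTruth` record
that can be serialised as a JSON sidecar next to the data files.

What the simulations deliberately omit: photobleaching, blinking and FRET
dynamics within a trace, vesicle diffusion (tethered vesicles are
immobile), and detailed dye photophysics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .dls import (
    Correlogram,
    Environment,
    Instrument,
    diameter_to_diffusion,
    scattering_vector,
)
from .ensemble_spectra import EmissionSpectrum
from .errors import DomainError, PackingError
from .single_vesicle_imaging import VesicleMovie
from .tcspc import DecayHistogram, Irf, convolve_irf

__all__ = [
    "GroundTruth",
    "generate_spectrum",
    "generate_decay",
    "generate_correlogram",
    "generate_movie",
]


@dataclass
class GroundTruth:
    """True parameters behind a generated dataset, keyed by modality."""

    modality: str
    params: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not JSON-serialisable: {type(obj)}")

        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_default))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Emission spectra

#: Skew-normal emission templates (skewness, location nm, scale nm) chosen so
#: that each line shape is essentially fully contained in its integration
#: band (donor 545-610 nm, acceptor 650-750 nm).
DONOR_SHAPE = (4.0, 558.0, 12.0)
ACCEPTOR_SHAPE = (4.0, 663.0, 12.0)


def _line_shape(wavelength: np.ndarray, shape: tuple[float, float, float]) -> np.ndarray:
    a, loc, scale = shape
    return stats.skewnorm.pdf(wavelength, a, loc=loc, scale=scale)


def generate_spectrum(
    E_true: float,
    total_area: float = 1e5,
    donor_shape: tuple[float, float, float] = DONOR_SHAPE,
    acceptor_shape: tuple[float, float, float] = ACCEPTOR_SHAPE,
    baseline: float = 5.0,
    noise_sd: float = 0.0,
    wavelength_nm: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[EmissionSpectrum, GroundTruth]:
    """Two-band emission spectrum with donor:acceptor areas (1-E):E.

    The donor line peaks near 565 nm and the acceptor near 670 nm (skewed
    Gaussians with red tails, as emission bands have).  A constant baseline
    and optional additive Gaussian noise emulate detector background.
    """
    if not 0.0 < E_true < 1.0:
        raise DomainError("E_true must lie strictly in (0, 1)")
    if wavelength_nm is None:
        wavelength_nm = np.arange(540.0, 781.0, 1.0)
    rng = np.random.default_rng(seed)
    donor = _line_shape(wavelength_nm, donor_shape)
    acceptor = _line_shape(wavelength_nm, acceptor_shape)
    intensity = total_area * ((1.0 - E_true) * donor + E_true * acceptor) + baseline
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=wavelength_nm.size)
    spectrum = EmissionSpectrum(wavelength_nm=wavelength_nm, intensity=intensity)
    truth = GroundTruth(
        modality="spectrum",
        params={"E_true": E_true, "total_area": total_area, "baseline": baseline,
                "noise_sd": noise_sd, "donor_shape": list(donor_shape),
                "acceptor_shape": list(acceptor_shape)},
        seed=seed,
    )
    return spectrum, truth


# ---------------------------------------------------------------------------
# TCSPC decays

def generate_decay(
    components=((0.6, 0.5), (0.4, 2.0)),
    irf_fwhm_ns: float = 0.2,
    irf_t0_ns: float = 1.5,
    rep_period_ns: float = 12.5,
    n_bins: int = 250,
    peak_counts: float = 1e4,
    offset_counts: float = 2.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[DecayHistogram, Irf, GroundTruth]:
    """Poisson photon decay histogram plus its Gaussian instrument response.

    The noiseless model (multi-exponential wrapped over the repetition
    period, convolved with the IRF) is scaled so its maximum equals
    ``peak_counts`` — the usual acquisition stopping criterion — before an
    independent Poisson draw per bin.
    """
    if peak_counts < 100:
        raise DomainError("peak_counts must be >= 100")
    rng = np.random.default_rng(seed)
    dt = rep_period_ns / n_bins
    t = (np.arange(n_bins) + 0.5) * dt
    sigma = irf_fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf_counts = np.exp(-((t - irf_t0_ns) ** 2) / (2 * sigma**2))
    irf = Irf(time_ns=t, counts=irf_counts)

    model = convolve_irf(list(components), irf, rep_period_ns)
    scale = (peak_counts - offset_counts) / model.max()
    expected = model * scale + offset_counts
    counts = rng.poisson(expected).astype(float) if noise else expected
    decay = DecayHistogram(time_ns=t, counts=counts, rep_period_ns=rep_period_ns)
    truth = GroundTruth(
        modality="decay",
        params={"components": [list(c) for c in components],
                "irf_fwhm_ns": irf_fwhm_ns, "irf_t0_ns": irf_t0_ns,
                "rep_period_ns": rep_period_ns, "n_bins": n_bins,
                "peak_counts": peak_counts, "offset_counts": offset_counts,
                "noise": noise},
        seed=seed,
    )
    return decay, irf, truth


# ---------------------------------------------------------------------------
# DLS correlograms

def generate_correlogram(
    d_H_true_nm: float = 227.0,
    A: float = 1.0,
    B: float = 0.9,
    instrument: Instrument = Instrument(),
    environment: Environment = Environment(),
    n_lags: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Correlogram, GroundTruth]:
    """Single-exponential intensity correlogram for a monodisperse diffuser.

    Lags are log-spaced from 0.01/(D q^2) to 10/(D q^2), spanning the decay;
    g2 = A[1 + B exp(-2 D q^2 tau)] plus optional additive Gaussian noise.
    """
    if d_H_true_nm <= 0:
        raise DomainError("d_H_true_nm must be positive")
    rng = np.random.default_rng(seed)
    D = diameter_to_diffusion(
        d_H_true_nm, environment.temperature_K, environment.viscosity_Pa_s
    )
    q = scattering_vector(
        instrument.refractive_index, instrument.wavelength_nm, instrument.angle_deg
    )
    rate = D * q * q
    lags = np.geomspace(0.01 / rate, 10.0 / rate, n_lags)
    g2 = A * (1.0 + B * np.exp(-2.0 * rate * lags))
    if noise_sd > 0:
        g2 = g2 + rng.normal(0.0, noise_sd, size=n_lags)
    corr = Correlogram(lag_s=lags, g2=g2, instrument=instrument,
                       environment=environment)
    truth = GroundTruth(
        modality="correlogram",
        params={"d_H_true_nm": d_H_true_nm, "A": A, "B": B,
                "D_m2_s": D, "q_per_m": q, "noise_sd": noise_sd,
                "n_lags": n_lags},
        seed=seed,
    )
    return corr, truth


# ---------------------------------------------------------------------------
# Dual-view TIRF movies

def _sample_positions(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    margin: float,
    min_separation_px: float,
    max_attempts_factor: int = 200,
) -> np.ndarray:
    """Uniform positions with minimum-separation rejection sampling."""
    positions: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max_attempts_factor * max(n, 1)
    min_sep2 = min_separation_px**2
    while len(positions) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} spots with separation "
                f">= {min_separation_px}px in {height}x{width}px"
            )
        attempts += 1
        y = rng.uniform(margin, height - margin)
        x = rng.uniform(margin, width - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep2 for py, px in positions):
            positions.append((y, x))
    return np.array(positions)


def _render_spots(
    image: np.ndarray,
    positions: np.ndarray,
    brightness: np.ndarray,
    psf_sigma_px: float,
) -> None:
    """Add Gaussian PSFs (total integrated intensity = brightness) in place."""
    w = int(np.ceil(4 * psf_sigma_px)) + 1
    height, width = image.shape
    for (y, x), b in zip(positions, brightness):
        r0, r1 = int(np.floor(y)) - w, int(np.floor(y)) + w + 1
        c0, c1 = int(np.floor(x)) - w, int(np.floor(x)) + w + 1
        r0, r1 = max(r0, 0), min(r1, height)
        c0, c1 = max(c0, 0), min(c1, width)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        psf = np.exp(
            -((rr - y) ** 2 + (cc - x) ** 2) / (2 * psf_sigma_px**2)
        ) / (2 * np.pi * psf_sigma_px**2)
        image[r0:r1, c0:c1] += b * psf


def generate_movie(
    n_frames: int = 500,
    field_um: tuple[float, float] = (25.0, 50.0),
    density_per_um2: float = 195.0 / (25.0 * 50.0),
    E_spec=0.5,
    brightness_lognormal: tuple[float, float] = (np.log(1500.0), 0.4),
    psf_sigma_px: float = 1.0,
    pixel_size_um: float = 0.11,
    exposure_s: float = 0.05,
    channel_shift_px: tuple[float, float] = (1.3, -0.6),
    min_separation_px: float = 8.0,
    camera_offset: float = 100.0,
    read_noise_sd: float = 2.0,
    gain: float = 1.0,
    seed: int = 0,
) -> tuple[VesicleMovie, GroundTruth]:
    """Dual-view movie of immobile surface-tethered vesicles.

    The vesicle count is Poisson with mean density*area (default ~195 per
    25 x 50 um, the surface coverage the analysis is designed for);
    positions are uniform with minimum-separation rejection.  Each vesicle
    has a log-normal total brightness (photons per frame) split
    (1-E):E between the donor and acceptor channels.  The acceptor half is
    rendered with a fixed true inter-channel shift (``channel_shift_px``,
    (dy, dx) applied to acceptor positions).  Per-pixel shot noise is
    Poisson; the camera adds an offset and Gaussian read noise.

    ``E_spec`` may be a scalar (one efficiency for every vesicle) or a
    tuple ``("normal", mean, sd)`` for per-vesicle variability.

    Geometry and brightness are drawn from a random stream independent of
    the one used for the efficiency spec and the pixel noise, so the same
    seed produces the same vesicle field at any ``E_spec`` — per-vesicle
    total intensity is independent of E by construction.
    """
    if psf_sigma_px <= 0 or density_per_um2 <= 0:
        raise DomainError("psf_sigma_px and density must be positive")
    ss = np.random.SeedSequence([seed, 0x7E51])
    rng_geom, rng_e, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    height = int(round(field_um[0] / pixel_size_um))
    width = int(round(field_um[1] / pixel_size_um))
    area = field_um[0] * field_um[1]
    n_vesicles = int(rng_geom.poisson(density_per_um2 * area))
    margin = 4 * psf_sigma_px + max(abs(channel_shift_px[0]),
                                    abs(channel_shift_px[1])) + 8
    positions = _sample_positions(rng_geom, n_vesicles, height, width,
                                  margin, min_separation_px)
    mu, sig = brightness_lognormal
    brightness = rng_geom.lognormal(mu, sig, size=n_vesicles)

    if np.isscalar(E_spec):
        efficiencies = np.full(n_vesicles, float(E_spec))
    else:
        kind, *args = E_spec
        if kind != "normal":
            raise DomainError(f"unknown E_spec kind: {kind}")
        mean, sd = args
        efficiencies = np.clip(
            rng_e.normal(mean, sd, size=n_vesicles), 0.01, 0.99
        )

    donor_expected = np.zeros((height, width))
    acceptor_expected = np.zeros((height, width))
    _render_spots(donor_expected, positions, brightness * (1 - efficiencies),
                  psf_sigma_px)
    acceptor_positions = positions + np.asarray(channel_shift_px)
    _render_spots(acceptor_expected, acceptor_positions,
                  brightness * efficiencies, psf_sigma_px)
    expected = np.concatenate([donor_expected, acceptor_expected], axis=1)

    frames = np.empty((n_frames, height, 2 * width), dtype=np.uint16)
    for f in range(n_frames):
        photons = rng_noise.poisson(expected)
        signal = (photons * gain + camera_offset
                  + rng_noise.normal(0.0, read_noise_sd, size=expected.shape))
        frames[f] = np.clip(np.round(signal), 0, 65535).astype(np.uint16)

    movie = VesicleMovie(frames=frames, exposure_s=exposure_s,
                         pixel_size_um=pixel_size_um, dualview_axis="col")
    truth = GroundTruth(
        modality="movie",
        params={
            "n_vesicles": n_vesicles,
            "positions_yx": positions,
            "brightness": brightness,
            "efficiencies": efficiencies,
            "total_intensity": brightness,  # donor+acceptor photons per frame
            "channel_shift_px": list(channel_shift_px),
            "field_um": list(field_um),
            "density_per_um2": density_per_um2,
            "pixel_size_um": pixel_size_um,
            "psf_sigma_px": psf_sigma_px,
            "camera_offset": camera_offset,
            "read_noise_sd": read_noise_sd,
            "gain": gain,
            "n_frames": n_frames,
        },
        seed=seed,
    )
    return movie, truth
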