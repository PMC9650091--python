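"""Single-vesicle FRET analysis of dual-view TIRF movies.

A dual-view emission splitter projects the donor and acceptor channels side
by side on one camera, so each recorded frame holds two half-images of the
same field.  The pipeline here:

1. split the movie into donor and acceptor stacks and register the acceptor
   onto the donor grid (translation estimated by sub-pixel phase
   cross-correlation of the time-averaged channels);
2. detect diffraction-limited vesicle spots on the summed, time-averaged
   image (difference-of-Gaussians band-pass, local maxima above a robust
   median + k*MAD threshold, minimum-separation enforcement);
3. extract background-corrected intensity traces per vesicle: integrated
   counts in a circular aperture minus the local background estimated as
   the annulus median times the aperture area;
4. compute one apparent FRET efficiency per vesicle from the trace means,
   histogram the population in fixed 0.01-wide bins over [0, 1], fit a
   single Gaussian to the binned counts and convert the fitted mean to a
   mean dye separation;
5. compare before/after/wash conditions to classify a perturbation as
   reversible, irreversible, or no effect, with a total-intensity
   invariance check for vesicle intactness.

Vesicles are surface-tethered and treated as immobile; registration is
translation-only, which matches a dual-view splitter at the camera scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians
from skimage.registration import phase_cross_correlation

from .errors import ConfigurationError, DomainError, RegistrationError
from .photophysics import FretParams, efficiency_to_distance

__all__ = [
    "VesicleMovie",
    "SpotTable",
    "TraceSet",
    "EfretHistogram",
    "split_and_register",
    "detect_spots",
    "extract_traces",
    "trace_efret",
    "traces_to_efret_table",
    "build_histogram",
    "compare_conditions",
    "analyze_movie",
]

#: Fixed histogram bin width for per-vesicle efficiency populations.
EFRET_BIN_WIDTH = 0.01


@dataclass
class VesicleMovie:
    """Dual-view image stack: (frame, row, col) of nonnegative pixel values."""

    frames: np.ndarray
    exposure_s: float = 0.05
    pixel_size_um: float = 0.11
    dualview_axis: str = "col"  # which axis the splitter divides: "col" or "row"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ConfigurationError("movie must be a (frame, row, col) stack")
        if self.dualview_axis not in ("row", "col"):
            raise ConfigurationError("dualview_axis must be 'row' or 'col'")
        axis = 2 if self.dualview_axis == "col" else 1
        if self.frames.shape[axis] % 2:
            raise ConfigurationError(
                f"dual-view axis has odd length {self.frames.shape[axis]}; "
                "cannot split into equal halves"
            )

    @classmethod
    def from_tiff(cls, path: str | Path, **kwargs) -> "VesicleMovie":
        return cls(frames=tifffile.imread(str(path)), **kwargs)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.frames)


@dataclass
class SpotTable:
    """Detected vesicle positions in donor-channel pixel coordinates."""

    table: pd.DataFrame  # columns: id, x (col), y (row), quality

    def __post_init__(self):
        required = {"id", "x", "y", "quality"}
        if not required <= set(self.table.columns):
            raise ConfigurationError(f"spot table needs columns {sorted(required)}")
        if self.table["id"].duplicated().any():
            raise ConfigurationError("spot ids must be unique")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TraceSet:
    """Background-corrected per-spot, per-frame donor/acceptor intensities."""

    traces: pd.DataFrame  # long format: spot, frame, donor, acceptor
    transform: tuple[float, float]  # (dy, dx) applied to the acceptor channel
    dropped_spots: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return int(self.traces["frame"].max()) + 1 if len(self.traces) else 0

    @property
    def spot_ids(self) -> np.ndarray:
        return self.traces["spot"].unique()


@dataclass
class EfretHistogram:
    """Population histogram of per-vesicle efficiencies with a Gaussian peak fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_vesicles: int
    mean: float | None = None
    sigma: float | None = None
    amplitude: float | None = None
    mean_separation_nm: float | None = None
    mean_total_intensity: float | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def fitted(self) -> bool:
        return self.mean is not None


# ---------------------------------------------------------------------------
# 1. Channel splitting and registration

def split_movie(movie: VesicleMovie) -> tuple[np.ndarray, np.ndarray]:
    """Split the dual view into (donor, acceptor) stacks; donor is the first half."""
    axis = 2 if movie.dualview_axis == "col" else 1
    half = movie.frames.shape[axis] // 2
    if axis == 2:
        return movie.frames[:, :, :half], movie.frames[:, :, half:]
    return movie.frames[:, :half, :], movie.frames[:, half:, :]


def split_and_register(
    movie: VesicleMovie,
    upsample_factor: int = 20,
    min_correlation: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Split the dual view and register the acceptor onto the donor grid.

    The translation is estimated at sub-pixel precision by phase
    cross-correlation of the time-averaged channel images; the acceptor
    stack is resampled (linear interpolation) onto the donor grid.

    Returns ``(donor_stack, acceptor_registered, (dy, dx))`` where (dy, dx)
    is the shift applied to the acceptor.

    Raises
    ------
    RegistrationError
        If the channels carry no common structure (normalised correlation
        at the located peak below ``min_correlation``); the error object
        carries the identity transform.
    """
    donor, acceptor = split_movie(movie)
    donor_avg = donor.mean(axis=0).astype(float)
    acceptor_avg = acceptor.mean(axis=0).astype(float)

    d0 = donor_avg - donor_avg.mean()
    a0 = acceptor_avg - acceptor_avg.mean()
    denom = np.linalg.norm(d0) * np.linalg.norm(a0)
    if denom == 0:
        raise RegistrationError("featureless channel(s): cannot register",
                                transform=(0.0, 0.0))

    shift, _, _ = phase_cross_correlation(
        donor_avg, acceptor_avg, upsample_factor=upsample_factor,
        normalization=None,
    )
    dy, dx = float(shift[0]), float(shift[1])

    shifted_avg = ndimage.shift(acceptor_avg, (dy, dx), order=1, mode="nearest")
    s0 = shifted_avg - shifted_avg.mean()
    corr = float((d0 * s0).sum() / (np.linalg.norm(d0) * np.linalg.norm(s0)))
    if corr < min_correlation:
        raise RegistrationError(
            f"registration correlation {corr:.3f} below {min_correlation}",
            transform=(0.0, 0.0),
        )

    if dy == 0.0 and dx == 0.0:
        registered = acceptor.astype(float)
    else:
        registered = ndimage.shift(
            acceptor.astype(float), (0.0, dy, dx), order=1, mode="nearest"
        )
    return donor.astype(float), registered, (dy, dx)


# ---------------------------------------------------------------------------
# 2. Spot detection

def detect_spots(
    stack: np.ndarray,
    threshold_k: float = 5.0,
    min_separation_px: int = 4,
    psf_sigma_px: float = 1.0,
) -> SpotTable:
    """Detect diffraction-limited spots on the time-averaged image.

    Band-pass filter (difference of Gaussians at the PSF scale), local
    maxima above median + k * MAD, minimum-separation enforcement, sub-pixel
    centroids by centre of mass in a small window.  An empty table is a
    valid result.
    """
    if stack.ndim == 2:
        avg = np.asarray(stack, dtype=float)
    else:
        avg = np.asarray(stack, dtype=float).mean(axis=0)

    bandpassed = difference_of_gaussians(avg, psf_sigma_px, 3 * psf_sigma_px)
    med = np.median(bandpassed)
    mad = np.median(np.abs(bandpassed - med))
    threshold = med + threshold_k * 1.4826 * mad

    peaks = peak_local_max(
        bandpassed, min_distance=min_separation_px,
        threshold_abs=threshold, exclude_border=2,
    )

    rows = []
    w = max(2, int(round(2 * psf_sigma_px)))
    for sid, (r, c) in enumerate(peaks):
        r0, r1 = max(r - w, 0), min(r + w + 1, avg.shape[0])
        c0, c1 = max(c - w, 0), min(c + w + 1, avg.shape[1])
        window = avg[r0:r1, c0:c1] - avg[r0:r1, c0:c1].min()
        total = window.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            y = float((rr * window).sum() / total)
            x = float((cc * window).sum() / total)
        else:
            y, x = float(r), float(c)
        rows.append({"id": sid, "x": x, "y": y,
                     "quality": float(bandpassed[r, c] - med)})
    table = pd.DataFrame(rows, columns=["id", "x", "y", "quality"])
    return SpotTable(table=table)


# ---------------------------------------------------------------------------
# 3. Trace extraction

def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    mask = dy * dy + dx * dx <= radius * radius
    return dy[mask], dx[mask]


def _annulus_offsets(r_in: float, r_out: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(r_out))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy * dy + dx * dx
    mask = (d2 >= r_in * r_in) & (d2 <= r_out * r_out)
    return dy[mask], dx[mask]


def extract_traces(
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    spots: SpotTable,
    aperture_radius_px: float = 3.0,
    annulus_radii_px: tuple[float, float] = (5.0, 7.0),
    transform: tuple[float, float] = (0.0, 0.0),
) -> TraceSet:
    """Integrated, locally background-corrected traces for every spot.

    Per frame and channel: sum of pixel values inside a circular aperture
    minus the annulus median multiplied by the aperture pixel count.  Spots
    whose annulus would leave the image are dropped and recorded in
    ``dropped_spots``.
    """
    if annulus_radii_px[0] <= aperture_radius_px:
        raise ConfigurationError("annulus must lie outside the aperture")
    donor_stack = np.asarray(donor_stack, dtype=float)
    acceptor_stack = np.asarray(acceptor_stack, dtype=float)
    if donor_stack.shape != acceptor_stack.shape:
        raise ConfigurationError("donor and acceptor stacks must match in shape")
    n_frames, height, width = donor_stack.shape

    ap_dy, ap_dx = _disk_offsets(aperture_radius_px)
    an_dy, an_dx = _annulus_offsets(*annulus_radii_px)
    ap_area = ap_dy.size
    margin = int(np.ceil(annulus_radii_px[1]))

    frames_idx = np.arange(n_frames)
    records = []
    dropped = []
    for _, spot in spots.table.iterrows():
        sid = int(spot["id"])
        r, c = int(round(spot["y"])), int(round(spot["x"]))
        if not (margin <= r < height - margin and margin <= c < width - margin):
            dropped.append(sid)
            continue
        ap_r, ap_c = r + ap_dy, c + ap_dx
        an_r, an_c = r + an_dy, c + an_dx
        for stack, channel in ((donor_stack, "donor"), (acceptor_stack, "acceptor")):
            signal = stack[:, ap_r, ap_c].sum(axis=1)
            background = np.median(stack[:, an_r, an_c], axis=1) * ap_area
            records.append(
                pd.DataFrame({
                    "spot": sid, "frame": frames_idx, "channel": channel,
                    "intensity": signal - background,
                })
            )
    if records:
        long = pd.concat(records, ignore_index=True)
        traces = long.pivot_table(
            index=["spot", "frame"], columns="channel", values="intensity"
        ).reset_index()[["spot", "frame", "donor", "acceptor"]]
        traces.columns.name = None
    else:
        traces = pd.DataFrame(columns=["spot", "frame", "donor", "acceptor"])
    return TraceSet(traces=traces, transform=transform, dropped_spots=dropped)


# ---------------------------------------------------------------------------
# 4. Per-vesicle efficiency and histogramming

def trace_efret(
    donor: np.ndarray, acceptor: np.ndarray,
    frame_range: tuple[int, int] | None = None,
) -> float:
    """Per-vesicle apparent efficiency from trace means over a frame range.

    E = mean(I_A) / (mean(I_A) + mean(I_D)).  Raises DomainError when the
    mean total intensity is not positive (the vesicle should be flagged and
    excluded by the caller).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if frame_range is not None:
        sl = slice(*frame_range)
        donor, acceptor = donor[sl], acceptor[sl]
    if donor.size == 0:
        raise DomainError("empty frame range")
    mean_d, mean_a = donor.mean(), acceptor.mean()
    if mean_d + mean_a <= 0:
        raise DomainError("mean total intensity not positive")
    return float(mean_a / (mean_a + mean_d))


def traces_to_efret_table(
    traces: TraceSet, frame_range: tuple[int, int] | None = None
) -> pd.DataFrame:
    """One row per vesicle: efficiency, mean total intensity, flag status."""
    rows = []
    for sid, grp in traces.traces.groupby("spot"):
        donor = grp["donor"].to_numpy()
        acceptor = grp["acceptor"].to_numpy()
        total = float(np.mean(donor + acceptor))
        try:
            e = trace_efret(donor, acceptor, frame_range)
            flagged = not (0.0 <= e <= 1.0)
        except DomainError:
            e, flagged = np.nan, True
        rows.append({"spot": sid, "e_fret": e, "total_intensity": total,
                     "flagged": flagged})
    return pd.DataFrame(rows, columns=["spot", "e_fret", "total_intensity", "flagged"])


def _gaussian(x, amplitude, mean, sigma):
    return amplitude * np.exp(-((x - mean) ** 2) / (2 * sigma**2))


def build_histogram(
    efficiencies,
    params: FretParams = FretParams(),
    total_intensities=None,
    max_fit_relative_error: float = 0.6,
) -> EfretHistogram:
    """Fixed 0.01-bin efficiency histogram with a single-Gaussian peak fit.

    Out-of-range efficiencies are clipped into [0, 1] before binning so
    every non-flagged vesicle is counted.  The Gaussian is fitted to the
    binned counts (initialised at the argmax bin, sigma 0.05); if the
    relative fit error exceeds ``max_fit_relative_error``, or fewer than 10
    vesicles are supplied, the histogram is returned without a fit.  The
    fitted mean is converted to a mean dye separation through the Foerster
    relation.
    """
    e = np.asarray(efficiencies, dtype=float)
    e = e[np.isfinite(e)]
    edges = np.round(np.arange(0.0, 1.0 + EFRET_BIN_WIDTH, EFRET_BIN_WIDTH), 10)
    counts, _ = np.histogram(np.clip(e, 0.0, 1.0 - 1e-9), bins=edges)
    mean_total = (
        float(np.mean(total_intensities)) if total_intensities is not None else None
    )
    hist = EfretHistogram(
        bin_edges=edges, counts=counts, n_vesicles=int(e.size),
        mean_total_intensity=mean_total,
    )
    if e.size < 10:
        return hist

    centers = hist.bin_centers
    peak_center = centers[int(np.argmax(counts))]
    sigma0 = float(np.clip(np.std(np.clip(e, 0, 1)), EFRET_BIN_WIDTH / 2, 0.2))
    popt = None
    for sigma_init in (0.05, sigma0, 0.01):
        try:
            popt, _ = curve_fit(
                _gaussian, centers, counts,
                p0=[counts.max(), peak_center, sigma_init],
                bounds=([0, 0, 1e-4], [np.inf, 1, 1]), maxfev=5000,
            )
            break
        except RuntimeError:
            continue
    if popt is None:
        return hist
    fitted = _gaussian(centers, *popt)
    rel_err = np.linalg.norm(counts - fitted) / max(np.linalg.norm(counts), 1e-12)
    if rel_err > max_fit_relative_error:
        return hist
    hist.amplitude, hist.mean, hist.sigma = (float(v) for v in popt)
    if 0.0 < hist.mean < 1.0:
        hist.mean_separation_nm = efficiency_to_distance(hist.mean, params)
    return hist


# ---------------------------------------------------------------------------
# 5. Condition comparison (reversibility logic)

def compare_conditions(
    hist_before: EfretHistogram,
    hist_after: EfretHistogram,
    hist_wash: EfretHistogram,
    shift_threshold: float = 0.03,
    intensity_change_threshold: float = 0.20,
) -> dict:
    """Classify a perturbation from before/after/wash efficiency histograms.

    Verdicts on the fitted peak positions:

    - ``"irreversible"``: the peak moved on perturbation and stayed moved
      after washing (both shifts exceed ``shift_threshold``);
    - ``"reversible"``: the peak moved on perturbation but returned after
      washing;
    - ``"no effect"``: the peak never moved beyond threshold.

    When mean total vesicle intensities are available, any condition whose
    mean deviates from the before-condition by more than
    ``intensity_change_threshold`` (fractional) is flagged: a large change
    suggests vesicle loss or disruption rather than a pure conformational
    response.
    """
    for name, h in (("before", hist_before), ("after", hist_after),
                    ("wash", hist_wash)):
        if not h.fitted:
            raise ConfigurationError(f"histogram '{name}' has no Gaussian fit")

    d_after = hist_after.mean - hist_before.mean
    d_wash = hist_wash.mean - hist_before.mean
    if abs(d_after) > shift_threshold and abs(d_wash) > shift_threshold:
        verdict = "irreversible"
    elif abs(d_after) > shift_threshold:
        verdict = "reversible"
    else:
        verdict = "no effect"

    totals = {
        "before": hist_before.mean_total_intensity,
        "after": hist_after.mean_total_intensity,
        "wash": hist_wash.mean_total_intensity,
    }
    intensity_flags = {}
    if all(v is not None and v > 0 for v in totals.values()):
        ref = totals["before"]
        for name, v in totals.items():
            intensity_flags[name] = abs(v - ref) / ref > intensity_change_threshold

    return {
        "delta_after": float(d_after),
        "delta_wash": float(d_wash),
        "verdict": verdict,
        "peak_before": float(hist_before.mean),
        "peak_after": float(hist_after.mean),
        "peak_wash": float(hist_wash.mean),
        "mean_total_intensity": totals,
        "intensity_flags": intensity_flags,
        "vesicles_intact": not any(intensity_flags.values()) if intensity_flags else None,
    }


# ---------------------------------------------------------------------------
# End-to-end convenience

def analyze_movie(
    movie: VesicleMovie,
    params: FretParams = FretParams(),
    threshold_k: float = 5.0,
    min_separation_px: int = 4,
    psf_sigma_px: float = 1.0,
    aperture_radius_px: float = 3.0,
    annulus_radii_px: tuple[float, float] = (5.0, 7.0),
    frame_range: tuple[int, int] | None = None,
) -> dict:
    """Full movie pipeline: register, detect, extract, histogram.

    Returns a dict with ``spots`` (SpotTable), ``traces`` (TraceSet),
    ``efret_table`` (per-vesicle DataFrame), ``histogram``
    (EfretHistogram) and ``transform``.
    """
    donor, acceptor, transform = split_and_register(movie)
    combined = donor.mean(axis=0) + acceptor.mean(axis=0)
    spots = detect_spots(combined, threshold_k, min_separation_px, psf_sigma_px)
    traces = extract_traces(donor, acceptor, spots, aperture_radius_px,
                            annulus_radii_px, transform)
    table = traces_to_efret_table(traces, frame_range)
    ok = table.loc[~table["flagged"]]
    hist = build_histogram(
        ok["e_fret"].to_numpy(), params,
        total_intensities=ok["total_intensity"].to_numpy() if len(ok) else None,
    )
    return {"spots": spots, "traces": traces, "efret_table": table,
            "histogram": hist, "transform": transform}
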