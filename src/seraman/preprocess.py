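"""Spectral preprocessing chain.

Order of operations, applied per sample:

1. **Cosmic-ray removal** — replicate-consensus robust-z detection across
   the point spectra of a sample (cosmic spikes are not reproducible
   between acquisitions), repaired by linear interpolation.
2. **Savitzky-Golay smoothing** — local least-squares polynomial filter,
   default 5th order over a 17-channel frame.
3. **Modified-polyfit baseline subtraction** — iterative fit-and-clip
   polynomial (default degree 9) that converges onto the broad
   fluorescence background beneath the narrow Raman bands.
4. **SNV normalisation** — per-spectrum standardisation to zero mean and
   unit variance, removing multiplicative and additive intensity effects
   (laser power, focus, film thickness).

The full chain is therefore invariant under positive affine transforms
of the raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from seraman.exceptions import DegenerateDataError, ParameterError
from seraman.io import PointSpectrum, SampleSpectra

_MAD_TO_SD = 1.4826  # consistency factor: MAD -> sd for a normal law


@dataclass
class PreprocessParams:
    """Tunable parameters of the preprocessing chain.

    sg_order / sg_window
        Savitzky-Golay polynomial order and odd frame width (channels).
    baseline_degree
        Degree of the modified-polyfit baseline polynomial.
    baseline_tol
        Stop when the sup-norm change of the fitted baseline between
        iterations falls below this fraction of the signal's
        peak-to-peak range.
    baseline_max_iter
        Iteration cap; non-convergence is recorded in QC, not raised.
    cosmic_threshold
        Robust z-score above which a channel is called a spike.
    cosmic_max_width
        Maximum spike run length (channels) eligible for repair.
    """

    sg_order: int = 5
    sg_window: int = 17
    baseline_degree: int = 9
    baseline_tol: float = 1e-6
    baseline_max_iter: int = 100
    cosmic_threshold: float = 8.0
    cosmic_max_width: int = 3

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ParameterError(
                f"sg_window must be odd and > sg_order "
                f"(got window={self.sg_window}, order={self.sg_order})"
            )
        if self.baseline_degree < 1:
            raise ParameterError("baseline_degree must be >= 1")
        if min(self.baseline_tol, self.cosmic_threshold) <= 0:
            raise ParameterError("tolerances and thresholds must be > 0")
        if self.cosmic_max_width < 1:
            raise ParameterError("cosmic_max_width must be >= 1")


@dataclass
class ProcessedSpectrum:
    """A fully preprocessed point spectrum (SNV units) plus QC record.

    ``snv_offset`` is the mean the SNV step removed, expressed in SNV
    units (mean/sd of the baseline-corrected spectrum).  Ratiometric
    quantification adds it back so a peak ratio estimates the band
    amplitude ratio rather than a mean-shifted transform of it; the SNV
    scale cancels in the ratio either way.
    """

    sample_id: str
    point_index: int
    wavenumbers: np.ndarray
    intensities: np.ndarray  # dimensionless, mean 0 / sd 1
    baseline: np.ndarray  # estimated fluorescence curve, pre-SNV units
    snv_offset: float = 0.0
    qc: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cosmic rays


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as half-open (start, stop)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _repair(values: np.ndarray, mask: np.ndarray, max_width: int) -> int:
    """Replace flagged runs (width <= max_width) by linear interpolation
    from the nearest unflagged flanking channels.  Returns the number of
    repaired channels."""
    repaired = 0
    n = values.size
    for start, stop in _runs(mask):
        if stop - start > max_width:
            continue
        lo, hi = start - 1, stop
        if lo < 0 and hi >= n:
            continue
        if lo < 0:
            values[start:stop] = values[hi]
        elif hi >= n:
            values[start:stop] = values[lo]
        else:
            values[start:stop] = np.interp(
                np.arange(start, stop), [lo, hi], [values[lo], values[hi]]
            )
        repaired += stop - start
    return repaired


def remove_cosmic_rays(
    sample: SampleSpectra, params: PreprocessParams | None = None
) -> SampleSpectra:
    """Detect and repair cosmic-ray spikes.

    With >= 3 replicate points on a common axis, a channel of one point is
    flagged when its deviation from the per-channel median across points,
    scaled by a pooled MAD over all channels, exceeds ``cosmic_threshold``; flagged runs no wider
    than ``cosmic_max_width`` channels are linearly interpolated from the
    flanking channels.  With fewer replicates a single-spectrum detector
    (residual against a 5-channel median filter) is used instead.

    QC (``qc['spikes_removed']`` per point) is attached to the returned
    points' ``.qc`` entries via :func:`preprocess_sample`; here the count
    is returned on the SampleSpectra as ``last_cosmic_counts``.
    """
    params = params or PreprocessParams()
    if sample.n_points < 1:
        raise DegenerateDataError(f"{sample.sample_id}: no point spectra")
    axis0 = sample.points[0].wavenumbers
    counts: list[int] = []
    new_points: list[PointSpectrum] = []
    if sample.n_points >= 3 and all(
        np.array_equal(p.wavenumbers, axis0) for p in sample.points
    ):
        stack = np.stack([p.intensities for p in sample.points])
        med = np.median(stack, axis=0)
        # pooled robust scale: per-channel MAD is far too variable with a
        # handful of replicates, so the noise scale is estimated from the
        # deviations of ALL channels jointly (spikes are too sparse to
        # contaminate a median over ~10^4 values)
        mad = np.median(np.abs(stack - med))
        ptp = float(np.ptp(stack))
        denom = _MAD_TO_SD * mad + 1e-12 * (ptp if ptp > 0 else 1.0)
        z = (stack - med) / denom
        for i, p in enumerate(sample.points):
            vals = p.intensities.copy()
            n = _repair(vals, z[i] > params.cosmic_threshold, params.cosmic_max_width)
            counts.append(n)
            new_points.append(
                PointSpectrum(p.sample_id, p.point_index, p.wavenumbers.copy(), vals)
            )
    else:
        for p in sample.points:
            smooth = median_filter(p.intensities, size=5, mode="nearest")
            resid = p.intensities - smooth
            mad = np.median(np.abs(resid - np.median(resid)))
            ptp = float(np.ptp(p.intensities))
            denom = _MAD_TO_SD * mad + 1e-12 * (ptp if ptp > 0 else 1.0)
            z = (resid - np.median(resid)) / denom
            vals = p.intensities.copy()
            n = _repair(vals, z > params.cosmic_threshold, params.cosmic_max_width)
            counts.append(n)
            new_points.append(
                PointSpectrum(p.sample_id, p.point_index, p.wavenumbers.copy(), vals)
            )
    out = SampleSpectra(sample.sample_id, new_points, common_axis=sample.common_axis)
    out.last_cosmic_counts = counts  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# smoothing


def savgol_smooth(
    spectrum: PointSpectrum, params: PreprocessParams | None = None
) -> PointSpectrum:
    """Savitzky-Golay smoothing (default 5th order, 17-channel frame).

    Requires a uniform wavenumber grid.  Edges are handled by fitting the
    full boundary window and evaluating the fit at the edge positions —
    no data is fabricated outside the measured range.
    """
    params = params or PreprocessParams()
    if spectrum.wavenumbers.size < params.sg_window:
        raise ParameterError(
            f"spectrum shorter ({spectrum.wavenumbers.size}) than the "
            f"SG window ({params.sg_window})"
        )
    steps = np.diff(spectrum.wavenumbers)
    if np.ptp(steps) > 1e-6 * steps.mean():
        raise ParameterError("Savitzky-Golay smoothing needs a uniform grid")
    smoothed = savgol_filter(
        spectrum.intensities,
        window_length=params.sg_window,
        polyorder=params.sg_order,
        mode="interp",
    )
    return PointSpectrum(
        spectrum.sample_id, spectrum.point_index, spectrum.wavenumbers.copy(), smoothed
    )


# ---------------------------------------------------------------------------
# baseline


def modpoly_baseline(
    spectrum: PointSpectrum, params: PreprocessParams | None = None
) -> tuple[PointSpectrum, PointSpectrum, dict]:
    """Modified-polyfit fluorescence baseline estimation.

    The fit-and-clip iteration: least-squares fit a polynomial of
    ``baseline_degree`` to the working signal, clip the working signal to
    the fit wherever it exceeds it, repeat.  Peaks, which sit above the
    background, are progressively flattened out of the working signal
    while the smooth fluorescence curve survives.  Stops when the
    sup-norm change of the fit drops below ``baseline_tol`` times the
    input's peak-to-peak range (a shift-invariant yardstick, so the whole
    procedure is exactly equivariant under positive affine intensity
    maps), or at ``baseline_max_iter`` with a QC warning.

    The channel axis is rescaled to [-1, 1] before fitting: degree-9
    polynomials on raw wavenumbers are numerically hostile.

    Returns ``(baseline, corrected, qc)``.
    """
    params = params or PreprocessParams()
    y = spectrum.intensities
    n = y.size
    if n <= params.baseline_degree + 1:
        raise ParameterError(
            f"spectrum length {n} too short for degree {params.baseline_degree}"
        )
    t = np.linspace(-1.0, 1.0, n)
    # Fixed Vandermonde + pseudo-inverse: the design never changes, only y.
    V = np.polynomial.polynomial.polyvander(t, params.baseline_degree)
    pinv = np.linalg.pinv(V)
    scale = float(np.ptp(y))
    if scale == 0.0:
        zeros = np.zeros_like(y)
        qc = {"baseline_iterations": 0, "baseline_converged": True}
        return (
            PointSpectrum(spectrum.sample_id, spectrum.point_index,
                          spectrum.wavenumbers.copy(), zeros),
            PointSpectrum(spectrum.sample_id, spectrum.point_index,
                          spectrum.wavenumbers.copy(), zeros.copy()),
            qc,
        )
    work = y.astype(float).copy()
    prev_fit = None
    converged = False
    iterations = 0
    for iterations in range(1, params.baseline_max_iter + 1):
        fit = V @ (pinv @ work)
        if prev_fit is not None and np.max(np.abs(fit - prev_fit)) < (
            params.baseline_tol * scale
        ):
            converged = True
            break
        work = np.minimum(work, fit)
        prev_fit = fit
    baseline = PointSpectrum(
        spectrum.sample_id, spectrum.point_index, spectrum.wavenumbers.copy(), fit
    )
    corrected = PointSpectrum(
        spectrum.sample_id,
        spectrum.point_index,
        spectrum.wavenumbers.copy(),
        y - fit,
    )
    qc = {"baseline_iterations": iterations, "baseline_converged": converged}
    return baseline, corrected, qc


# ---------------------------------------------------------------------------
# normalisation


def snv_normalize(spectrum: PointSpectrum) -> PointSpectrum:
    """Standard-normal-variate normalisation: (x - mean) / sd (ddof=1)."""
    x = spectrum.intensities
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError(
            f"{spectrum.sample_id}/{spectrum.point_index}: constant spectrum, "
            "SNV undefined"
        )
    return PointSpectrum(
        spectrum.sample_id,
        spectrum.point_index,
        spectrum.wavenumbers.copy(),
        (x - np.mean(x)) / sd,
    )


# ---------------------------------------------------------------------------
# full chain


def preprocess_sample(
    sample: SampleSpectra, params: PreprocessParams | None = None
) -> list[ProcessedSpectrum]:
    """Run the full chain on every point spectrum of a sample.

    Cosmic-ray removal uses all replicate points jointly; smoothing,
    baseline estimation and SNV are applied per point spectrum, in that
    order.  Per-point QC records spike repairs and baseline convergence.
    """
    params = params or PreprocessParams()
    if sample.n_points < 1:
        raise DegenerateDataError(f"{sample.sample_id}: no point spectra")
    despiked = remove_cosmic_rays(sample, params)
    counts = despiked.last_cosmic_counts  # type: ignore[attr-defined]
    out: list[ProcessedSpectrum] = []
    for p, n_spikes in zip(despiked.points, counts):
        smoothed = savgol_smooth(p, params)
        baseline, corrected, qc = modpoly_baseline(smoothed, params)
        normalized = snv_normalize(corrected)
        c_mean = float(np.mean(corrected.intensities))
        c_sd = float(np.std(corrected.intensities, ddof=1))
        qc = dict(qc, spikes_removed=n_spikes)
        out.append(
            ProcessedSpectrum(
                sample_id=p.sample_id,
                point_index=p.point_index,
                wavenumbers=normalized.wavenumbers,
                intensities=normalized.intensities,
                baseline=baseline.intensities,
                snv_offset=c_mean / c_sd,
                qc=qc,
            )
        )
    return out


def scale_processed(spectrum: ProcessedSpectrum, factor: float) -> ProcessedSpectrum:
    """Rescale a processed spectrum (intensities and SNV offset together),
    as a positive rescaling of the underlying corrected spectrum would."""
    if factor <= 0:
        raise ParameterError("scale factor must be > 0")
    return ProcessedSpectrum(
        sample_id=spectrum.sample_id,
        point_index=spectrum.point_index,
        wavenumbers=spectrum.wavenumbers.copy(),
        intensities=spectrum.intensities * factor,
        baseline=spectrum.baseline.copy(),
        snv_offset=spectrum.snv_offset * factor,
        qc=dict(spectrum.qc),
    )
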