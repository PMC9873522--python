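"""BOLD conditioning: volume dropping, nuisance regression, filtering, smoothing.

The canonical order is drop -> (detrend + nuisance regression in one OLS) ->
bandpass.  Linear detrending is expressed as intercept + trend columns inside
the nuisance design so a single least-squares pass guarantees exact
orthogonality between residuals and every regressor.  The temporal filter is
frequency-domain masking of the real FFT: a bin is retained iff its frequency
lies in [low, high]; the 0 Hz bin is always outside the band, so filtered
series are mean-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import ndimage

from .volumes import BoldSeries, Grid, MaskMap, ScalarMap

__all__ = [
    "MotionTrace",
    "NuisanceSet",
    "drop_initial_volumes",
    "friston24",
    "mean_timecourse",
    "regress_nuisance",
    "bandpass",
    "smooth_gaussian",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionTrace:
    """Six rigid-body parameters per timepoint: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be a (T, 6) matrix")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    def drop_initial(self, n_drop: int) -> "MotionTrace":
        if n_drop >= self.n_timepoints:
            raise ValueError("cannot drop all motion rows")
        return MotionTrace(self.params[n_drop:])

    def max_displacement(self):
        """Max absolute translation (mm) and rotation (radians), per-parameter.

        Interpretive choice: the screening rule is applied to the absolute
        per-parameter maximum rather than a framewise composite.
        """
        trans = float(np.abs(self.params[:, :3]).max())
        rot = float(np.abs(self.params[:, 3:]).max())
        return trans, rot

    def passes_screening(self, max_trans_mm: float = 2.0, max_rot_deg: float = 2.0) -> bool:
        trans, rot = self.max_displacement()
        return trans <= max_trans_mm and rot <= np.deg2rad(max_rot_deg)

    @classmethod
    def from_file(cls, path) -> "MotionTrace":
        return cls(np.loadtxt(path))

    def to_file(self, path) -> None:
        np.savetxt(path, self.params, fmt="%.17g")


@dataclass
class NuisanceSet:
    """Named nuisance time courses, one column per regressor."""

    regressors: np.ndarray
    labels: list

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("one label per regressor column required")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("nuisance regressors must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]

    def hstack(self, other: "NuisanceSet") -> "NuisanceSet":
        if other.n_timepoints != self.n_timepoints:
            raise ValueError("row counts differ")
        return NuisanceSet(
            np.hstack([self.regressors, other.regressors]),
            list(self.labels) + list(other.labels),
        )


def drop_initial_volumes(series: BoldSeries, n_drop: int = 10) -> BoldSeries:
    """Remove the first ``n_drop`` timepoints (scanner signal stabilization)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= series.n_timepoints:
        raise ValueError(
            f"n_drop={n_drop} would leave no volumes of {series.n_timepoints}"
        )
    return BoldSeries(series.grid, series.values[..., n_drop:], series.tr_seconds)


def friston24(motion: MotionTrace) -> NuisanceSet:
    """Friston 24-parameter motion expansion.

    Columns: the 6 parameters, their one-timepoint lags (first row backfilled
    with 0), and the squares of both sets.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for the lagged expansion")
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    block = np.hstack([p, lag, p**2, lag**2])
    names = [f"mot{i+1}" for i in range(6)]
    labels = (
        names
        + [f"{n}_lag" for n in names]
        + [f"{n}_sq" for n in names]
        + [f"{n}_lag_sq" for n in names]
    )
    return NuisanceSet(block, labels)


def mean_timecourse(series: BoldSeries, mask: MaskMap, label: str = "mean") -> NuisanceSet:
    """In-mask mean signal per timepoint (WM / CSF / global regressors)."""
    series.grid.check_matches(mask.grid, "mask")
    tc = series.values[mask.inside].mean(axis=0)
    return NuisanceSet(tc[:, None], [label])


def _prune_design(design: np.ndarray, labels):
    """Drop exact-duplicate columns, then verify full rank."""
    keep, seen = [], []
    for j in range(design.shape[1]):
        col = design[:, j]
        if any(np.array_equal(col, design[:, k]) for k in seen):
            continue
        seen.append(j)
        keep.append(j)
    X = design[:, keep]
    kept_labels = [labels[j] for j in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns implicated via pivoted QR
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        offending = sorted(kept_labels[j] for j in piv[rank:])
        raise ValueError(
            f"nuisance design is rank deficient; offending columns: {offending}"
        )
    return X, kept_labels


def regress_nuisance(
    series: BoldSeries,
    nuisance: NuisanceSet,
    mask: MaskMap,
    include_trend: bool = True,
) -> BoldSeries:
    """Replace in-mask voxel series by OLS residuals on [intercept | trend | nuisance].

    Out-of-mask voxels are passed through untouched.  Raises if the design is
    rank deficient after dropping exact duplicate columns, naming the columns.
    """
    series.grid.check_matches(mask.grid, "mask")
    T = series.n_timepoints
    if nuisance.n_timepoints != T:
        raise ValueError(
            f"nuisance rows ({nuisance.n_timepoints}) != timepoints ({T})"
        )
    cols = [np.ones(T)]
    labels = ["intercept"]
    if include_trend:
        cols.append(np.linspace(-1.0, 1.0, T))
        labels.append("linear_trend")
    design = np.column_stack(cols + [nuisance.regressors])
    labels = labels + list(nuisance.labels)
    X, _ = _prune_design(design, labels)

    Y = series.values[mask.inside].T  # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = series.values.copy()
    out[mask.inside] = resid.T
    return BoldSeries(series.grid, out, series.tr_seconds)


def bandpass(series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldSeries:
    """Retain only frequency content in [low_hz, high_hz] (real-FFT bin mask)."""
    nyq = series.nyquist_hz
    if not (0 <= low_hz < high_hz <= nyq + 1e-12):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] outside valid range [0, {nyq}] Hz"
        )
    T = series.n_timepoints
    freqs = np.fft.rfftfreq(T, d=series.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(series.values, axis=-1)
    spec[..., ~keep] = 0.0
    return BoldSeries(series.grid, np.fft.irfft(spec, n=T, axis=-1), series.tr_seconds)


def band_fraction(n_timepoints: int, tr_seconds: float, low_hz: float = 0.01,
                  high_hz: float = 0.1):
    """(in-band bin count, positive bin count) of the length-T real FFT."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    in_band = int(np.sum((freqs >= low_hz) & (freqs <= high_hz)))
    positive = int(np.sum(freqs > 0))
    return in_band, positive


def smooth_gaussian(scalar_map: ScalarMap, fwhm_mm: float, mask: MaskMap = None) -> ScalarMap:
    """Gaussian smoothing (FWHM in mm) restricted to a mask.

    The kernel is renormalized by the smoothed mask so in-mask constants are
    preserved and values never bleed across the mask edge; missing voxels
    carry zero weight.  Out-of-mask / missing voxels stay missing.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    grid = scalar_map.grid
    if mask is not None:
        grid.check_matches(mask.grid, "mask")
        region = mask.inside & scalar_map.present
    else:
        region = scalar_map.present
    if fwhm_mm == 0:
        out = np.full(grid.shape, np.nan)
        out[region] = scalar_map.values[region]
        return ScalarMap(grid, out)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size
    vals = np.where(region, scalar_map.values, 0.0)
    weights = region.astype(float)
    num = ndimage.gaussian_filter(vals, sigma=sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(weights, sigma=sigma_vox, mode="constant")
    out = np.full(grid.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[region] = num[region] / den[region]
    return ScalarMap(grid, out)
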