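"""Per-subject activity maps: degree centrality, fALFF, and z-standardization.

Degree centrality counts (or sums) the positive supra-threshold Pearson
correlations between each gray-matter voxel's BOLD series and every other
in-mask voxel.  The correlation pass runs on temporally standardized series
via blocked inner products; the block size is a memory knob with no effect on
the result.  Negative correlations are discarded outright: after global
signal regression their interpretation is ambiguous, so only r >= threshold
edges count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import BoldSeries, MaskMap, ScalarMap

__all__ = ["DcParams", "FalffParams", "degree_centrality", "falff", "zscore_map"]

_CANONICAL_THRESHOLDS = (0.15, 0.2, 0.25)


@dataclass(frozen=True)
class DcParams:
    """Degree-centrality settings.

    r_threshold: minimum positive Pearson r for an edge (0.2 default; 0.15 and
    0.25 are the standard robustness settings).  mode: 'binary_count' counts
    edges, 'weighted_sum' sums their r.  normalize: divide by M-1 so a binary
    DC is the fraction of possible edges, in [0, 1].
    """

    r_threshold: float = 0.2
    mode: str = "binary_count"
    normalize: bool = True

    def __post_init__(self):
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.mode not in ("binary_count", "weighted_sum"):
            raise ValueError(f"unknown DC mode {self.mode!r}")


@dataclass(frozen=True)
class FalffParams:
    low_hz: float = 0.01
    high_hz: float = 0.1

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


def _standardized_series(series: BoldSeries, mask: MaskMap) -> np.ndarray:
    """In-mask series as unit-norm, zero-mean rows (M x T); errors on constants."""
    X = series.values[mask.inside]
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        idx = np.argwhere(mask.inside)[bad]
        raise ValueError(
            "constant time series (undefined correlation) at in-mask voxels "
            f"{[tuple(int(x) for x in v) for v in idx[:10]]}"
            + ("..." if bad.size > 10 else "")
        )
    return X / norms[:, None]


def degree_centrality(
    series: BoldSeries,
    mask: MaskMap,
    params: DcParams = DcParams(),
    block_size: int = 512,
) -> ScalarMap:
    """Voxel-wise degree centrality over the in-mask voxel graph.

    For each in-mask voxel, Pearson r with every other in-mask voxel is
    computed; edges with r >= r_threshold contribute 1 (binary_count) or r
    (weighted_sum).  The self-edge is excluded.  With normalize, values are
    divided by M - 1.  Out-of-mask voxels are missing in the output.
    """
    series.grid.check_matches(mask.grid, "mask")
    Xn = _standardized_series(series, mask)
    M = Xn.shape[0]
    if M < 2:
        raise ValueError("degree centrality needs at least 2 in-mask voxels")
    thr = params.r_threshold
    out_vals = np.empty(M)
    for start in range(0, M, max(1, int(block_size))):
        stop = min(start + block_size, M)
        R = Xn[start:stop] @ Xn.T  # rows x M correlation block
        rows = np.arange(start, stop)
        R[np.arange(stop - start), rows] = -np.inf  # exclude self-edge
        hits = R >= thr
        if params.mode == "binary_count":
            out_vals[start:stop] = hits.sum(axis=1)
        else:
            out_vals[start:stop] = np.where(hits, R, 0.0).sum(axis=1)
    if params.normalize:
        out_vals = out_vals / (M - 1)
    out = np.full(series.grid.shape, np.nan)
    out[mask.inside] = out_vals
    return ScalarMap(series.grid, out)


def falff(
    series: BoldSeries, mask: MaskMap, params: FalffParams = FalffParams()
) -> ScalarMap:
    """Fractional amplitude of low-frequency fluctuations.

    Per in-mask voxel: sum of real-FFT amplitudes over bins with frequency in
    [low, high], divided by the amplitude summed over all positive-frequency
    bins.  The standard amplitude-ratio definition; values lie in [0, 1].
    """
    series.grid.check_matches(mask.grid, "mask")
    if params.high_hz > series.nyquist_hz + 1e-12:
        raise ValueError("fALFF band extends beyond the Nyquist frequency")
    X = series.values[mask.inside]
    freqs = np.fft.rfftfreq(series.n_timepoints, d=series.tr_seconds)
    amp = np.abs(np.fft.rfft(X, axis=1))
    pos = freqs > 0
    in_band = pos & (freqs >= params.low_hz) & (freqs <= params.high_hz)
    total = amp[:, pos].sum(axis=1)
    if np.any(total == 0):
        bad = np.argwhere(mask.inside)[np.where(total == 0)[0]]
        raise ValueError(
            f"zero spectral amplitude (constant series) at voxels "
            f"{[tuple(v) for v in bad[:10]]}"
        )
    vals = amp[:, in_band].sum(axis=1) / total
    out = np.full(series.grid.shape, np.nan)
    out[mask.inside] = vals
    return ScalarMap(series.grid, out)


def zscore_map(scalar_map: ScalarMap, mask: MaskMap) -> ScalarMap:
    """Standardize to zero mean, unit SD over non-missing in-mask voxels.

    Sample SD (N-1 denominator).  Missing and out-of-mask voxels stay missing.
    """
    scalar_map.grid.check_matches(mask.grid, "mask")
    region = mask.inside & scalar_map.present
    vals = scalar_map.values[region]
    if vals.size < 2:
        raise ValueError("z-scoring needs at least 2 usable in-mask voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("z-scoring undefined: zero in-mask variance")
    out = np.full(scalar_map.grid.shape, np.nan)
    out[region] = (vals - vals.mean()) / sd
    return ScalarMap(scalar_map.grid, out)
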