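"""Neurovascular-coupling statistics.

Two complementary indices: (1) a subject's *global* coupling — the Pearson
correlation between CBF and an activity metric (DC or fALFF) across all
gray-matter voxels; (2) the *regional* CBF/metric ratio map, computed from
original (un-z-scored, unsmoothed) values and only afterwards standardized
and smoothed.  Voxels whose metric falls below a small positive floor are
excluded from the ratio rather than epsilon-padded: near-zero denominators
would otherwise manufacture arbitrarily extreme ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as gstats
from .volumes import MaskMap, ScalarMap

__all__ = [
    "CouplingRecord",
    "RatioParams",
    "global_coupling",
    "ratio_map",
    "compare_global_coupling",
]


@dataclass
class CouplingRecord:
    """One subject's across-voxel CBF-metric correlation."""

    subject_id: str
    metric_name: str
    r: float
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels < 3:
            raise ValueError("coupling needs >= 3 voxels")
        if not np.isfinite(self.r):
            raise ValueError("coupling r must be finite")


@dataclass(frozen=True)
class RatioParams:
    """min_metric: positive floor below which a voxel is excluded from the ratio."""

    min_metric: float = 1e-6

    def __post_init__(self):
        if not self.min_metric > 0:
            raise ValueError("min_metric must be positive")


def global_coupling(
    cbf_map: ScalarMap,
    metric_map: ScalarMap,
    gm_mask: MaskMap,
    subject_id: str = "",
    metric_name: str = "DC",
) -> CouplingRecord:
    """Across-voxel Pearson correlation between CBF and the activity metric.

    Uses the voxels that are in-mask and non-missing in both maps; the voxel
    count is recorded so mask shrinkage is never silent.
    """
    cbf_map.grid.check_matches(metric_map.grid, "metric map")
    cbf_map.grid.check_matches(gm_mask.grid, "GM mask")
    use = gm_mask.inside & cbf_map.present & metric_map.present
    n = int(use.sum())
    if n < 3:
        raise ValueError(f"only {n} usable voxels for coupling (need >= 3)")
    x = cbf_map.values[use]
    y = metric_map.values[use]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance over the coupling voxels")
    r = float(np.corrcoef(x, y)[0, 1])
    return CouplingRecord(subject_id, metric_name, r, n)


def ratio_map(
    cbf_map: ScalarMap,
    metric_map: ScalarMap,
    gm_mask: MaskMap,
    params: RatioParams = RatioParams(),
) -> ScalarMap:
    """Voxel-wise CBF / metric ratio from original values.

    In-mask voxels with metric >= min_metric get cbf/metric; voxels below the
    floor (or missing in either input) are missing in the output and hence
    excluded from any subsequent z-scoring.
    """
    cbf_map.grid.check_matches(metric_map.grid, "metric map")
    cbf_map.grid.check_matches(gm_mask.grid, "GM mask")
    usable = (
        gm_mask.inside
        & cbf_map.present
        & metric_map.present
        & (np.nan_to_num(metric_map.values, nan=-np.inf) >= params.min_metric)
    )
    out = np.full(cbf_map.grid.shape, np.nan)
    out[usable] = cbf_map.values[usable] / metric_map.values[usable]
    return ScalarMap(cbf_map.grid, out)


def compare_global_coupling(records_a, records_b, alpha: float = 0.05) -> dict:
    """Group comparison of per-subject coupling correlations.

    Each group's r values are checked for normality (Lilliefors-corrected KS);
    if both groups pass at ``alpha`` the pooled-variance two-sample t-test is
    used, otherwise the Mann-Whitney U-test.  Groups too small for the
    normality test (n < 4) fall through to Mann-Whitney.
    """

    def _values(records):
        return np.asarray(
            [rec.r if isinstance(rec, CouplingRecord) else float(rec) for rec in records]
        )

    a, b = _values(records_a), _values(records_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 coupling records")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise ValueError("degenerate groups: all coupling values identical")

    normal = True
    normality = {}
    for name, sample in (("a", a), ("b", b)):
        if sample.size >= 4 and sample.std() > 0:
            ks = gstats.ks_normality(sample, alpha=alpha)
            normality[name] = ks
            normal = normal and ks["pass"]
        else:
            normality[name] = None
            normal = False

    if normal:
        res = gstats.two_sample_t(a, b)
        test, stat = "t", res["t"]
    else:
        res = gstats.mann_whitney(a, b)
        test, stat = "mann-whitney", res["U"]
    return {
        "test": test,
        "statistic": float(stat),
        "p": float(res["p"]),
        "normality": normality,
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "n_a": int(a.size),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "n_b": int(b.size),
        "significant": bool(res["p"] < alpha),
    }
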