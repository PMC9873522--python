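"""Voxel-wise group GLM.

The group comparison is an ordinary least-squares fit per voxel of
value ~ intercept + group + covariates, with the t statistic of the group
coefficient as the map of interest — the standard "two-sample t-test
adjusting for covariates".  With no covariates this reduces exactly to the
pooled-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import Grid, MaskMap, ScalarMap

__all__ = ["GroupDesign", "VoxelGLM", "VoxelGLMResults", "glm_voxelwise", "cluster_means"]


@dataclass
class GroupDesign:
    """Subject-level design: 0/1 group indicator plus covariate columns."""

    group_indicator: np.ndarray
    covariates: np.ndarray = None
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        g = np.asarray(self.group_indicator, dtype=float)
        if not np.all(np.isin(g, (0.0, 1.0))):
            raise ValueError("group_indicator must be 0/1")
        if g.sum() == 0 or g.sum() == g.size:
            raise ValueError("both groups must be non-empty")
        self.group_indicator = g
        if self.covariates is None:
            self.covariates = np.empty((g.size, 0))
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != g.size:
            raise ValueError("covariate rows must match subjects")
        if not self.covariate_names:
            self.covariate_names = [f"cov{i+1}" for i in range(self.covariates.shape[1])]
        X = self.matrix
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix [intercept | group | covariates] is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.group_indicator.size

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack(
            [np.ones(self.n_subjects), self.group_indicator, self.covariates]
        )

    @property
    def column_names(self) -> list:
        return ["intercept", "group"] + list(self.covariate_names)


@dataclass
class VoxelGLMResults:
    """Group-contrast t map with degrees of freedom and residuals.

    ``residuals`` is (n_subjects x n_analyzed_voxels) over ``analyzed`` voxels
    (needed downstream for smoothness estimation).
    """

    t_map: ScalarMap
    beta_map: ScalarMap
    df: int
    contrast: str
    analyzed: np.ndarray
    residuals: np.ndarray

    @property
    def grid(self) -> Grid:
        return self.t_map.grid


class VoxelGLM:
    """Mass-univariate OLS of subject maps on a group design.

    Analyzed voxels are those in-mask and non-missing in every subject.
    Voxels with zero residual variance are reported and set missing.
    """

    def __init__(self, maps_per_subject, design: GroupDesign, mask: MaskMap):
        maps = list(maps_per_subject)
        if len(maps) != design.n_subjects:
            raise ValueError("one map per design row required")
        grid = maps[0].grid
        for m in maps[1:]:
            grid.check_matches(m.grid, "subject map")
        grid.check_matches(mask.grid, "mask")
        self.design = design
        self.mask = mask
        self.grid = grid
        analyzed = mask.inside.copy()
        for m in maps:
            analyzed &= m.present
        self.analyzed = analyzed
        self.Y = np.stack([m.values[analyzed] for m in maps])  # n x V

    def fit(self) -> VoxelGLMResults:
        X = self.design.matrix
        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        df = n - rank
        if df <= 0:
            raise ValueError("no residual degrees of freedom")
        pinv = np.linalg.pinv(X)
        beta = pinv @ self.Y  # p x V
        resid = self.Y - X @ beta
        ssr = np.einsum("nv,nv->v", resid, resid)
        yss = np.einsum("nv,nv->v", self.Y, self.Y)
        # residual variance indistinguishable from zero at the data's scale
        zero_var = ssr <= 1e-20 * np.maximum(yss, 1e-30)
        xtx_inv_gg = np.linalg.inv(X.T @ X)[1, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma2 = ssr / df
            se = np.sqrt(sigma2 * xtx_inv_gg)
            t = beta[1] / se
        # zero residual variance: t undefined unless the group effect itself
        # is zero too (identical maps), which is reported as t = 0
        scale = np.sqrt(np.maximum(yss, 1e-30))
        t_vals = np.where(
            ~zero_var & (se > 0),
            t,
            np.where(np.abs(beta[1]) <= 1e-10 * scale, 0.0, np.nan),
        )
        t_map = np.full(self.grid.shape, np.nan)
        b_map = np.full(self.grid.shape, np.nan)
        t_map[self.analyzed] = t_vals
        b_map[self.analyzed] = beta[1]
        return VoxelGLMResults(
            t_map=ScalarMap(self.grid, t_map),
            beta_map=ScalarMap(self.grid, b_map),
            df=int(df),
            contrast="group (1 vs 0), adjusted for " + ", ".join(self.design.covariate_names or ["nothing"]),
            analyzed=self.analyzed,
            residuals=resid,
        )


def glm_voxelwise(maps_per_subject, design: GroupDesign, mask: MaskMap) -> VoxelGLMResults:
    """Functional wrapper over :class:`VoxelGLM`."""
    return VoxelGLM(maps_per_subject, design, mask).fit()


def cluster_means(maps_per_subject, cluster_rows) -> np.ndarray:
    """Per-subject mean of each cluster's voxels: (subjects x clusters)."""
    maps = list(maps_per_subject)
    if not cluster_rows:
        return np.empty((len(maps), 0))
    grid = maps[0].grid
    out = np.empty((len(maps), len(cluster_rows)))
    for j, row in enumerate(cluster_rows):
        vox = row.voxels
        if vox is None or len(vox) == 0:
            raise ValueError("cluster has no voxels")
        idx = tuple(np.asarray(vox).T)
        for i, m in enumerate(maps):
            grid.check_matches(m.grid, "subject map")
            out[i, j] = np.nanmean(m.values[idx])
    return out
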