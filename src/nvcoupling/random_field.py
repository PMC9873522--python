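"""Gaussian-random-field cluster-level inference.

Smoothness of the statistic image is estimated from the spatial
autocorrelation of normalized GLM residuals, expressed as the FWHM of the
Gaussian kernel that would produce the observed roughness when applied to
white noise.  Cluster-level p-values follow classical random-field theory for
3-D Gaussian fields: with resel count R and (Gaussianized) cluster-forming
threshold u, the expected number of clusters is

    E[m] = R (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) exp(-u^2 / 2),

the expected suprathreshold volume is E[N] = S Phi(-u) voxels, and cluster
extents are modelled as P(n >= k) = exp(-beta k^{2/3}) with
beta = (Gamma(5/2) E[m] / E[N])^{2/3}.  The familywise cluster p-value is
1 - exp(-E[m] P(n >= k)).  Two-tailed maps are handled by splitting both the
voxel-forming p and the cluster p evenly across the positive and negative
excursion sets, so the overall familywise rate matches the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma as gamma_fn

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .volumes import Grid, MaskMap, ScalarMap, voxel_to_mm

__all__ = [
    "SmoothnessEstimate",
    "ClusterRow",
    "estimate_smoothness",
    "grf_cluster_correct",
    "lattice_resel_counts",
]

_LN4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Per-axis field smoothness (FWHM, mm) and the implied resel count."""

    fwhm_mm: tuple
    resel_count: float
    n_voxels: int

    def __post_init__(self):
        if len(self.fwhm_mm) != 3 or any(f <= 0 for f in self.fwhm_mm):
            raise ValueError("fwhm_mm must be 3 positive reals")
        if not self.resel_count > 0:
            raise ValueError("resel_count must be positive")

    @classmethod
    def from_fwhm(cls, fwhm_mm, mask: MaskMap) -> "SmoothnessEstimate":
        """Build from known per-axis smoothness (mm) and a mask."""
        fwhm_mm = tuple(float(f) for f in np.broadcast_to(fwhm_mm, 3))
        fwhm_vox = np.asarray(fwhm_mm) / mask.grid.voxel_size
        n = mask.n_inside
        return cls(fwhm_mm, float(n / np.prod(fwhm_vox)), n)


@dataclass
class ClusterRow:
    """One supra-threshold cluster of the statistic map."""

    n_voxels: int
    peak_t: float
    peak_ijk: tuple
    peak_mm: tuple
    cluster_p: float
    sign: str
    voxels: np.ndarray = None  # (k, 3) voxel indices

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("a cluster has at least one voxel")
        if not 0 < self.cluster_p <= 1:
            raise ValueError("cluster_p must lie in (0, 1]")


def estimate_smoothness(residual_maps, mask: MaskMap) -> SmoothnessEstimate:
    """Estimate field smoothness from normalized residual spatial derivatives.

    Residuals are normalized voxel-wise to unit sum of squares across maps;
    for each axis the mean squared forward difference of the normalized
    residual vectors estimates 2(1 - rho(1)), giving a per-axis FWHM of
    sqrt(4 ln 2 / lambda) voxels, floored at half a voxel.
    """
    if isinstance(residual_maps, np.ndarray) and residual_maps.ndim == 2:
        raise ValueError(
            "pass residuals as an (n, x, y, z) array or a list of ScalarMaps"
        )
    if isinstance(residual_maps, (list, tuple)):
        arrs = [
            m.values if isinstance(m, ScalarMap) else np.asarray(m, float)
            for m in residual_maps
        ]
        R = np.stack(arrs)
    else:
        R = np.asarray(residual_maps, dtype=float)
    if R.ndim != 4 or R.shape[0] < 2:
        raise ValueError("need at least 2 residual maps on the grid")
    if R.shape[1:] != mask.grid.shape:
        raise ValueError("residual maps do not match the mask grid")

    inside = mask.inside & np.all(np.isfinite(R), axis=0)
    ss = np.einsum("nxyz,nxyz->xyz", R, R)
    ok = inside & (ss > 0)
    if not ok.any():
        raise ValueError("no usable voxels for smoothness estimation")
    U = np.where(ok, R / np.sqrt(np.where(ok, ss, 1.0)), 0.0)

    fwhm_vox = []
    voxel_size = mask.grid.voxel_size
    for axis in range(3):

        def shift(a):
            return np.roll(a, -1, axis=axis)

        pair = ok & shift(ok)
        # drop wrap-around pairs at the far edge
        edge = [slice(None)] * 3
        edge[axis] = slice(-1, None)
        pair[tuple(edge)] = False
        if pair.sum() < 2:
            fwhm_vox.append(0.5)
            continue
        diff2 = np.zeros(mask.grid.shape)
        for n in range(R.shape[0]):
            d = shift(U[n]) - U[n]
            diff2 += d * d
        lam = diff2[pair].mean()
        if lam <= 0:
            fwhm_vox.append(float(max(mask.grid.shape)))
            continue
        fwhm_vox.append(float(max(np.sqrt(_LN4 / lam), 0.5)))

    fwhm_mm = tuple(float(f * v) for f, v in zip(fwhm_vox, voxel_size))
    n = mask.n_inside
    return SmoothnessEstimate(fwhm_mm, float(n / np.prod(fwhm_vox)), n)


def lattice_resel_counts(inside: np.ndarray, fwhm_vox) -> tuple:
    """Resel counts (R0..R3) of a voxel mask for per-axis FWHM in voxels.

    Uses the lattice intrinsic-volume counts: voxels P, in-mask edge pairs
    E_x/E_y/E_z, fully in-mask 2x2 faces F_xy/F_xz/F_yz and 2x2x2 cubes C.
    The boundary (lower-dimensional) terms matter for small masks and enter
    the expected Euler characteristic of the excursion set.
    """
    m = np.asarray(inside, bool)
    fx, fy, fz = (float(f) for f in fwhm_vox)

    def _and(*arrs):
        out = arrs[0]
        for a in arrs[1:]:
            out = out & a
        return out

    sx = m[1:, :, :] & m[:-1, :, :]
    sy = m[:, 1:, :] & m[:, :-1, :]
    sz = m[:, :, 1:] & m[:, :, :-1]
    P = int(m.sum())
    Ex, Ey, Ez = int(sx.sum()), int(sy.sum()), int(sz.sum())
    Fxy = int(_and(m[1:, 1:, :], m[:-1, 1:, :], m[1:, :-1, :], m[:-1, :-1, :]).sum())
    Fxz = int(_and(m[1:, :, 1:], m[:-1, :, 1:], m[1:, :, :-1], m[:-1, :, :-1]).sum())
    Fyz = int(_and(m[:, 1:, 1:], m[:, :-1, 1:], m[:, 1:, :-1], m[:, :-1, :-1]).sum())
    C = int(
        _and(
            m[1:, 1:, 1:], m[:-1, 1:, 1:], m[1:, :-1, 1:], m[1:, 1:, :-1],
            m[:-1, :-1, 1:], m[:-1, 1:, :-1], m[1:, :-1, :-1], m[:-1, :-1, :-1],
        ).sum()
    )
    r0 = P - Ex - Ey - Ez + Fxy + Fxz + Fyz - C
    r1 = (Ex - Fxy - Fxz + C) / fx + (Ey - Fxy - Fyz + C) / fy + (Ez - Fxz - Fyz + C) / fz
    r2 = (Fxy - C) / (fx * fy) + (Fxz - C) / (fx * fz) + (Fyz - C) / (fy * fz)
    r3 = C / (fx * fy * fz)
    return (float(r0), float(r1), float(r2), float(r3))


def _ec_densities(u: float) -> tuple:
    """Gaussian-field EC densities (rho_0..rho_3) at threshold u."""
    e = np.exp(-(u**2) / 2.0)
    rho0 = sps.norm.sf(u)
    rho1 = _LN4**0.5 / (2 * np.pi) * e
    rho2 = _LN4 / (2 * np.pi) ** 1.5 * u * e
    rho3 = _LN4**1.5 / (2 * np.pi) ** 2 * (u**2 - 1.0) * e
    return (rho0, rho1, rho2, rho3)


def _expected_clusters(u_z: float, resels: tuple) -> float:
    """E[cluster count] above u_z: expected EC with the full resel vector."""
    return float(max(sum(r * d for r, d in zip(resels, _ec_densities(u_z))), 0.0))


def _cluster_p(k_voxels: int, u_z: float, resels: tuple, n_voxels: int) -> float:
    """Familywise p-value for a cluster of k voxels (one excursion set)."""
    em = _expected_clusters(u_z, resels)
    en = n_voxels * sps.norm.sf(u_z)
    if em <= 0 or en <= 0:
        return 1.0
    nbar = en / em
    beta = (gamma_fn(2.5) / nbar) ** (2.0 / 3.0)
    p_size = np.exp(-beta * k_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_size))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    levels = {6: 1, 18: 2, 26: 3}
    if connectivity not in levels:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, levels[connectivity])


def grf_cluster_correct(
    t_map: ScalarMap,
    df: float,
    smoothness: SmoothnessEstimate,
    mask: MaskMap,
    voxel_p: float = 0.005,
    cluster_p: float = 0.05,
    connectivity: int = 26,
    two_tailed: bool = True,
    keep_voxels: bool = True,
) -> list:
    """Threshold a t map and keep clusters surviving GRF cluster correction.

    The voxel-forming threshold is the two-tailed ``voxel_p`` quantile of
    t(df) (or of the standard normal for df=inf).  Positive and negative
    excursion sets are labelled separately (``connectivity``-neighbour
    components) and each cluster's familywise p is computed from random-field
    theory with the Gaussianized threshold; with ``two_tailed`` the retention
    level is cluster_p/2 per sign.  Rows are sorted by |peak t| descending.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
    if smoothness is None:
        raise ValueError("a smoothness estimate is required")
    t_map.grid.check_matches(mask.grid, "mask")

    tail_p = voxel_p / 2.0 if two_tailed else voxel_p
    retain_p = cluster_p / 2.0 if two_tailed else cluster_p
    if np.isinf(df):
        u_t = sps.norm.isf(tail_p)
        u_z = u_t
    else:
        u_t = sps.t.isf(tail_p, df)
        u_z = sps.norm.isf(sps.t.sf(u_t, df))

    vals = np.where(mask.inside & t_map.present, t_map.values, 0.0)
    structure = _connectivity_structure(connectivity)
    n_mask = mask.n_inside
    fwhm_vox = np.asarray(smoothness.fwhm_mm) / mask.grid.voxel_size
    resels = lattice_resel_counts(mask.inside, fwhm_vox)
    rows = []
    signs = (("positive", vals >= u_t), ("negative", -vals >= u_t))
    if not two_tailed:
        signs = (signs[0],)
    for sign, excursion in signs:
        labels, n_lab = ndimage.label(excursion, structure=structure)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            k = vox.shape[0]
            p = _cluster_p(k, u_z, resels, n_mask)
            if p > retain_p:
                continue
            t_here = t_map.values[tuple(vox.T)]
            peak_local = np.argmax(t_here) if sign == "positive" else np.argmin(t_here)
            peak_ijk = tuple(int(i) for i in vox[peak_local])
            rows.append(
                ClusterRow(
                    n_voxels=int(k),
                    peak_t=float(t_here[peak_local]),
                    peak_ijk=peak_ijk,
                    peak_mm=tuple(float(x) for x in voxel_to_mm(t_map.grid, peak_ijk)),
                    cluster_p=float(p),
                    sign=sign,
                    voxels=vox if keep_voxels else None,
                )
            )
    rows.sort(key=lambda r: abs(r.peak_t), reverse=True)
    return rows
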