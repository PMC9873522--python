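"""Seed-deterministic synthetic cohorts with known neurovascular structure.

The generator emulates the data a coupling study consumes: per subject a 4-D
BOLD series, a CBF perfusion map, a rigid-motion trace and a demographic
record, plus shared brain/GM/WM/CSF masks — all on a common grid, already "in
register".

Generative model
----------------
* K smooth spatial network maps (Gaussian blobs, shared across subjects) and
  per-subject band-limited (0.01-0.1 Hz) network time courses.  A voxel's
  BOLD series is the loading-weighted sum of network signals plus white
  noise, so voxels inside a network correlate strongly (high degree
  centrality) and background voxels do not.
* In patients, network loadings inside a focal "decoupling" region are
  attenuated by a per-subject factor, lowering their DC there while the CBF
  map does not follow — the injected regional ratio elevation.
* CBF = baseline + b_g * z(expected-DC field) + smooth noise.  The group
  gain b_g is calibrated analytically from the noise SD so the across-voxel
  CBF-DC correlation hits the group target (weaker in patients).  The
  expected-DC field is computed in closed form from the population
  correlation structure, passing population r through the sampling
  distribution of the empirical correlation so thresholding is smoothed the
  way measured DC smooths it.
* Patient performance IQ is drawn to correlate (target -0.4 by default) with
  the subject's latent regional CBF/DC ratio; the latent variable is stored
  in the ground truth so recovery can be verified.

All randomness flows from a single seed through a hierarchical generator, so
cohorts are bit-reproducible and subjects independently so.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import special as sp_special

from .preprocess import FWHM_TO_SIGMA, MotionTrace, band_fraction
from .volumes import BoldSeries, Grid, MaskMap, ScalarMap, write_volume

__all__ = [
    "CohortParams",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class CohortParams:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the emulated study: 26 patients vs 35 controls, 210
    volumes at TR 2 s (10 dropped downstream), 3-mm 24^3 grid, group
    across-voxel coupling targets 0.35 (controls) vs 0.25 (patients), focal
    attenuation 0.5 of network loadings in the decoupling region, and a
    -0.4 latent correlation between patient PIQ and the regional ratio.
    """

    n_patients: int = 26
    n_controls: int = 35
    shape: tuple = (24, 24, 24)
    voxel_mm: float = 3.0
    n_timepoints: int = 210
    tr_seconds: float = 2.0
    n_drop: int = 10  # volumes the analysis will drop; used for calibration only
    n_networks: int = 4
    network_fwhm_mm: float = 9.0
    bold_amplitude: float = 1.0
    noise_sd: float = 0.5
    loading_sd: float = 0.1
    coupling_hc: float = 0.35
    coupling_patient: float = 0.25
    cbf_mean: float = 50.0
    cbf_noise_sd: float = 5.0
    cbf_noise_fwhm_mm: float = 6.0
    attenuation: float = 0.5
    attenuation_sd: float = 0.15
    roi_center: tuple = (15, 15, 10)
    roi_radius_vox: float = 2.5
    dc_r_threshold: float = 0.2
    analysis_fwhm_mm: float = 6.0  # smoothing the analysis will apply; used by calibration
    iq_ratio_corr: float = -0.4
    piq_mean: float = 84.0
    piq_sd: float = 16.76
    age_mean: float = 11.8
    age_sd: float = 2.7
    age_range: tuple = (6.0, 16.0)

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("group sizes must be >= 2")
        for c in (self.coupling_hc, self.coupling_patient):
            if not -1 < c < 1:
                raise ValueError("coupling targets must lie in (-1, 1)")
        if not -1 < self.iq_ratio_corr < 1:
            raise ValueError("iq_ratio_corr must lie in (-1, 1)")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")


@dataclass
class SubjectData:
    subject_id: str
    group: str  # 'patient' | 'control'
    sex: int
    age: float
    education: float
    viq: float
    piq: float
    fiq: float
    bold: BoldSeries
    cbf: ScalarMap
    motion: MotionTrace


@dataclass
class GroundTruth:
    """Everything needed to verify recovery by the downstream analysis."""

    params: CohortParams
    roi_voxels: np.ndarray  # (k, 3)
    control_roi_voxels: np.ndarray
    network_centers: np.ndarray
    loadings: dict  # subject_id -> (K,) loadings
    attenuations: dict  # subject_id -> ROI attenuation factor (1.0 controls)
    latent_roi_ratio: dict  # patient_id -> latent regional ratio proxy
    coupling_gain: dict  # group -> b_g
    expected_dc_field: np.ndarray  # GM-shaped, NaN outside GM


@dataclass
class Cohort:
    subjects: list
    masks: dict  # 'brain' | 'gm' | 'wm' | 'csf' -> MaskMap
    truth: GroundTruth
    grid: Grid

    def participants(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "age": s.age,
                "education": s.education,
                "VIQ": s.viq,
                "PIQ": s.piq,
                "FIQ": s.fiq,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixed anatomy of the phantom

_BRAIN_RADIUS_VOX = 8.0
_WM_RADIUS_VOX = 2.5
_CSF_RADIUS_VOX = 1.8
_CSF_OFFSET_VOX = (0.0, 0.0, -5.0)
_NETWORK_CENTERS = ((7, 8, 11), (15, 15, 10), (8, 15, 14), (15, 8, 15))
_CONTROL_ROI_CENTER = (7, 8, 11)


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@dataclass
class CohortStructure:
    """Deterministic, parameter-only scaffolding shared by all subjects.

    Holds the grid, masks, network maps, the population edge-probability
    machinery and the expected-DC field.  Building it is the expensive part
    of generation, so it is computed once per parameter set and reused (also
    by the fast clinical-only sampling path).
    """

    params: CohortParams
    grid: Grid
    masks: dict
    network_maps: np.ndarray  # (K, x, y, z), peak-normalized, zero off-brain
    gm_idx: np.ndarray  # (M, 3)
    A_gm: np.ndarray  # (M, K) signal amplitudes at GM voxels
    roi_rows: np.ndarray  # row indices of ROI voxels within GM
    roi_voxels: np.ndarray
    control_roi_voxels: np.ndarray
    sigma2_eff: float
    t_eff: float
    expected_dc_gm: np.ndarray  # (M,)
    expected_dc_field: np.ndarray
    z_dc_gm: np.ndarray = None  # standardized expected-DC over GM
    calibration: dict = None  # post-smoothing variances/covariances (pilot-based)

    def gain_for_target(self, target_r: float, cbf_noise_sd: float) -> float:
        """CBF gain b so the *measured* across-voxel coupling hits target_r.

        The measured coupling correlates the smoothed CBF map (b*z + noise)
        with the smoothed empirical DC map.  With az = cov(S z, S DC),
        v_z = var(S z), v_D = var(S DC) and v_eta the smoothed-noise variance
        (all measured by the deterministic pilot), solving
        target = b az / sqrt((b^2 v_z + v_eta) v_D) for b gives the gain.
        Raises when the target exceeds the noise-free ceiling az/sqrt(v_z v_D).
        """
        c = self.calibration
        v_eta = cbf_noise_sd**2 * c["v_eta_unit"]
        disc = c["az"] ** 2 - target_r**2 * c["v_z"] * c["v_d"]
        if disc <= 0:
            ceiling = c["az"] / np.sqrt(c["v_z"] * c["v_d"])
            raise ValueError(
                f"infeasible coupling target {target_r:.3f}: the generator can "
                f"reach at most r = {ceiling:.3f} with the current noise settings"
            )
        return float(abs(target_r) * np.sqrt(v_eta * c["v_d"] / disc)
                     * np.sign(target_r))


def _edge_prob(r_pop: np.ndarray, threshold: float, t_eff: float) -> np.ndarray:
    """P(empirical r >= threshold | population r), Fisher-z normal approx."""
    z = np.arctanh(np.clip(r_pop, -0.999999, 0.999999))
    z0 = np.arctanh(threshold)
    return sp_special.ndtr((z - z0) * np.sqrt(max(t_eff - 3.0, 1.0)))


def build_structure(params: CohortParams) -> CohortStructure:
    shape = tuple(params.shape)
    grid = Grid.isotropic(shape, params.voxel_mm)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _sphere(shape, center, _BRAIN_RADIUS_VOX)
    wm = _sphere(shape, center, _WM_RADIUS_VOX) & brain
    csf_center = tuple(c + o for c, o in zip(center, _CSF_OFFSET_VOX))
    csf = _sphere(shape, csf_center, _CSF_RADIUS_VOX) & brain & ~wm
    gm = brain & ~wm & ~csf
    masks = {
        "brain": MaskMap(grid, brain),
        "gm": MaskMap(grid, gm),
        "wm": MaskMap(grid, wm),
        "csf": MaskMap(grid, csf),
    }

    sigma_net = params.network_fwhm_mm * FWHM_TO_SIGMA / params.voxel_mm
    K = params.n_networks
    centers = np.asarray(_NETWORK_CENTERS[:K] if K <= 4 else _NETWORK_CENTERS)
    if K > 4:
        raise ValueError("at most 4 network centers are defined for this phantom")
    maps = np.zeros((K,) + shape)
    for k, c in enumerate(centers):
        impulse = np.zeros(shape)
        impulse[tuple(int(x) for x in c)] = 1.0
        blob = ndimage.gaussian_filter(impulse, sigma=sigma_net)
        blob /= blob.max()
        blob *= brain
        maps[k] = blob

    gm_idx = np.argwhere(gm)
    A_gm = params.bold_amplitude * np.stack([maps[k][gm] for k in range(K)], axis=1)

    roi = _sphere(shape, params.roi_center, params.roi_radius_vox)
    if not np.all(gm[roi]):
        raise ValueError("decoupling ROI must lie inside the GM mask")
    gm_flat = np.zeros(shape, dtype=int)
    gm_flat[gm] = np.arange(gm_idx.shape[0])
    roi_rows = gm_flat[roi]
    roi_voxels = np.argwhere(roi)
    ctl_roi = _sphere(shape, _CONTROL_ROI_CENTER, params.roi_radius_vox) & gm
    control_roi_voxels = np.argwhere(ctl_roi)

    # effective noise variance after the analysis bandpass, and effective
    # sample size of band-limited series
    t_post = params.n_timepoints - params.n_drop
    n_band, _ = band_fraction(t_post, params.tr_seconds)
    sigma2_eff = params.noise_sd**2 * (2.0 * n_band / t_post)
    t_eff = 2.0 * n_band

    # population correlations and the expected (measured) DC field
    power = np.einsum("mk,nk->mn", A_gm, A_gm)
    var = np.diag(power) + sigma2_eff
    denom = np.sqrt(np.outer(var, var))
    r_pop = power / denom
    p_edge = _edge_prob(r_pop, params.dc_r_threshold, t_eff)
    np.fill_diagonal(p_edge, 0.0)
    M = A_gm.shape[0]
    expected_dc = p_edge.sum(axis=1) / (M - 1)
    field = np.full(shape, np.nan)
    field[gm] = expected_dc
    struct = CohortStructure(
        params=params,
        grid=grid,
        masks=masks,
        network_maps=maps,
        gm_idx=gm_idx,
        A_gm=A_gm,
        roi_rows=roi_rows,
        roi_voxels=roi_voxels,
        control_roi_voxels=control_roi_voxels,
        sigma2_eff=sigma2_eff,
        t_eff=t_eff,
        expected_dc_gm=expected_dc,
        expected_dc_field=field,
    )
    z = expected_dc.copy()
    struct.z_dc_gm = (z - z.mean()) / z.std(ddof=0)
    struct.calibration = _pilot_calibration(struct)
    return struct


def _pilot_calibration(struct: CohortStructure, n_pilot: int = 3,
                       n_noise: int = 4) -> dict:
    """Measure post-smoothing variances/covariances with a deterministic pilot.

    A few reference subjects (fixed internal seed, unit loadings, no
    attenuation) are simulated through the DC path (bandpass + thresholded
    correlation count) to measure, after the analysis smoothing kernel,
    var(S z), var(S DC), cov(S z, S DC) and the variance retained by a
    unit-SD smooth CBF noise field.  These feed :meth:`gain_for_target`.
    """
    from .preprocess import smooth_gaussian

    p = struct.params
    grid, gm = struct.grid, struct.masks["gm"]
    inside = gm.inside
    fwhm = p.analysis_fwhm_mm

    def _smooth_gm(vals_gm):
        full = np.full(grid.shape, np.nan)
        full[inside] = vals_gm
        return smooth_gaussian(ScalarMap(grid, full), fwhm, gm).values[inside]

    s_z = _smooth_gm(struct.z_dc_gm)
    v_z = float(s_z.var())

    rng = np.random.default_rng(np.random.SeedSequence(202405))
    t_post = p.n_timepoints - p.n_drop
    freqs = np.fft.rfftfreq(t_post, d=p.tr_seconds)
    keep = (freqs >= 0.01) & (freqs <= 0.1)
    A = struct.A_gm
    M = A.shape[0]
    az_vals, vd_vals = [], []
    for _ in range(n_pilot):
        tcs = _bandlimited_timecourses(rng, p.n_networks, t_post, p.tr_seconds)
        series = A @ tcs + p.noise_sd * rng.standard_normal((M, t_post))
        spec = np.fft.rfft(series, axis=1)
        spec[:, ~keep] = 0.0
        series = np.fft.irfft(spec, n=t_post, axis=1)
        # global-signal regression, as the DC analysis branch applies
        g = series.mean(axis=0)
        g = g - g.mean()
        series -= np.outer(series @ g / (g @ g), g)
        series -= series.mean(axis=1, keepdims=True)
        series /= np.linalg.norm(series, axis=1, keepdims=True)
        corr = series @ series.T
        np.fill_diagonal(corr, -np.inf)
        dc = (corr >= p.dc_r_threshold).sum(axis=1) / (M - 1)
        s_d = _smooth_gm(dc.astype(float))
        az_vals.append(float(np.cov(s_z, s_d)[0, 1]))
        vd_vals.append(float(s_d.var()))

    v_eta_vals = []
    for _ in range(n_noise):
        eta = _smooth_noise(rng, grid, p.cbf_noise_fwhm_mm, inside)
        v_eta_vals.append(float(_smooth_gm(eta[inside]).var()))

    return {
        "v_z": v_z,
        "az": float(np.mean(az_vals)),
        "v_d": float(np.mean(vd_vals)),
        "v_eta_unit": float(np.mean(v_eta_vals)),
    }


_STRUCTURE_CACHE = {}


def get_structure(params: CohortParams) -> CohortStructure:
    key = json.dumps(asdict(params), sort_keys=True, default=str)
    if key not in _STRUCTURE_CACHE:
        _STRUCTURE_CACHE[key] = build_structure(params)
    return _STRUCTURE_CACHE[key]


def _bandlimited_timecourses(rng, k, n_t, tr) -> np.ndarray:
    """K unit-variance time courses with support in 0.01-0.1 Hz."""
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= 0.01) & (freqs <= 0.1)
    spec = np.fft.rfft(rng.standard_normal((k, n_t)), axis=1)
    spec[:, ~keep] = 0.0
    tc = np.fft.irfft(spec, n=n_t, axis=1)
    tc -= tc.mean(axis=1, keepdims=True)
    tc /= tc.std(axis=1, keepdims=True)
    return tc


def _roi_expected_dc(struct: CohortStructure, attenuation: float) -> float:
    """Mean expected DC over ROI voxels when ROI loadings are attenuated."""
    p = struct.params
    A = struct.A_gm.copy()
    A[struct.roi_rows] *= attenuation
    A_roi = A[struct.roi_rows]
    power = A_roi @ A.T
    var_all = np.einsum("mk,mk->m", A, A) + struct.sigma2_eff
    var_roi = var_all[struct.roi_rows]
    r_pop = power / np.sqrt(np.outer(var_roi, var_all))
    p_edge = _edge_prob(r_pop, p.dc_r_threshold, struct.t_eff)
    M = A.shape[0]
    self_p = p_edge[np.arange(len(struct.roi_rows)), struct.roi_rows]
    dc = (p_edge.sum(axis=1) - self_p) / (M - 1)
    return float(dc.mean())


def sample_patient_clinical(params: CohortParams, rng: np.random.Generator,
                            struct: CohortStructure = None):
    """Draw per-patient attenuations, latent ROI-ratio proxies and IQ scores.

    This is the exact code path :func:`generate_cohort` uses for the patient
    group, exposed separately so clinical-recovery properties can be checked
    over many resimulated groups without generating images.

    Returns a DataFrame with columns attenuation, latent_roi_ratio (the
    standardized latent the PIQ draw is correlated against), VIQ, PIQ, FIQ.
    """
    if struct is None:
        struct = get_structure(params)
    n = params.n_patients
    att = np.clip(
        rng.normal(params.attenuation, params.attenuation_sd, size=n), 0.15, 0.95
    )
    roi_dc = np.array([_roi_expected_dc(struct, a) for a in att])
    latent = params.cbf_mean / roi_dc  # expected regional CBF/DC ratio
    c = params.iq_ratio_corr
    noise = rng.standard_normal(n)
    noise = (noise - noise.mean()) / noise.std(ddof=0)
    if latent.std(ddof=0) > 0:
        z_latent = (latent - latent.mean()) / latent.std(ddof=0)
        # orthogonalize so the realized latent-PIQ correlation equals the target
        noise = noise - (noise @ z_latent) / (z_latent @ z_latent) * z_latent
        noise /= noise.std(ddof=0)
        z_piq = c * z_latent + np.sqrt(1 - c**2) * noise
    else:  # degenerate case: identical attenuation for every patient
        z_piq = noise
    piq = params.piq_mean + params.piq_sd * z_piq
    shared = 0.7
    z_v = shared * z_piq + np.sqrt(1 - shared**2) * rng.standard_normal(n)
    viq = 90.07 + 20.08 * z_v
    fiq = 86.53 + 18.26 * (0.5 * (z_piq + z_v)) / np.std(0.5 * (z_piq + z_v))
    return pd.DataFrame(
        {
            "attenuation": att,
            "latent_roi_ratio": latent,
            "VIQ": viq,
            "PIQ": piq,
            "FIQ": fiq,
        }
    )


def _smooth_noise(rng, grid: Grid, fwhm_mm: float, region: np.ndarray) -> np.ndarray:
    sigma = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size
    field = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma)
    sd = field[region].std()
    return field / sd


def _motion_trace(rng, n_t: int) -> MotionTrace:
    steps = np.hstack(
        [
            rng.normal(0.0, 0.02, size=(n_t, 3)),  # mm
            rng.normal(0.0, 0.0004, size=(n_t, 3)),  # rad
        ]
    )
    walk = np.cumsum(steps, axis=0)
    walk[:, :3] = np.clip(walk[:, :3], -1.5, 1.5)
    walk[:, 3:] = np.clip(walk[:, 3:], -0.02, 0.02)
    return MotionTrace(walk)


def generate_cohort(params: CohortParams = CohortParams(), seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort (images, motion, demographics, truth)."""
    struct = get_structure(params)
    p = params
    grid, masks = struct.grid, struct.masks
    brain = masks["brain"].inside
    gm = masks["gm"].inside

    ss = np.random.SeedSequence(seed)
    ss_cohort, ss_subjects = ss.spawn(2)
    rng_cohort = np.random.default_rng(ss_cohort)

    # CBF gains per group, calibrated so the *measured* post-pipeline
    # coupling hits the group targets
    z_dc = struct.z_dc_gm
    gains = {
        "control": struct.gain_for_target(p.coupling_hc, p.cbf_noise_sd),
        "patient": struct.gain_for_target(p.coupling_patient, p.cbf_noise_sd),
    }

    clinical = sample_patient_clinical(p, rng_cohort, struct)

    n_total = p.n_patients + p.n_controls
    subject_seeds = ss_subjects.spawn(n_total)
    subjects = []
    loadings, attenuations, latent_ratio = {}, {}, {}
    K = p.n_networks
    A_brain = p.bold_amplitude * np.stack(
        [struct.network_maps[k][brain] for k in range(K)], axis=1
    )
    roi_mask_brain = np.zeros(grid.shape, bool)
    roi_mask_brain[tuple(struct.roi_voxels.T)] = True
    roi_rows_brain = roi_mask_brain[brain]

    for i in range(n_total):
        is_patient = i < p.n_patients
        group = "patient" if is_patient else "control"
        sid = f"sub-{i + 1:02d}"
        rng = np.random.default_rng(subject_seeds[i])

        load = rng.normal(1.0, p.loading_sd, size=K)
        att = float(clinical["attenuation"].iloc[i]) if is_patient else 1.0
        tcs = _bandlimited_timecourses(rng, K, p.n_timepoints, p.tr_seconds)

        A_subj = A_brain * load[None, :]
        if att != 1.0:
            A_subj = A_subj.copy()
            A_subj[roi_rows_brain] *= att
        series_brain = A_subj @ tcs + p.noise_sd * rng.standard_normal(
            (A_brain.shape[0], p.n_timepoints)
        )
        bold = np.zeros(grid.shape + (p.n_timepoints,))
        bold[brain] = series_brain

        # CBF: vascular field follows the shared (unattenuated) expected-DC
        # structure; the focal neural attenuation is NOT mirrored -> decoupling
        eta = _smooth_noise(rng, grid, p.cbf_noise_fwhm_mm, gm) * p.cbf_noise_sd
        cbf = np.full(grid.shape, np.nan)
        cbf[brain] = p.cbf_mean + eta[brain]
        cbf[gm] += gains[group] * z_dc

        motion = _motion_trace(rng, p.n_timepoints)

        age = float(np.clip(rng.normal(p.age_mean, p.age_sd), *p.age_range))
        sex = int(rng.integers(0, 2))
        education = float(max(age - 5.0 + rng.normal(0, 0.7), 0.0))
        if is_patient:
            row = clinical.iloc[i]
            viq, piq, fiq = float(row["VIQ"]), float(row["PIQ"]), float(row["FIQ"])
            latent_ratio[sid] = float(row["latent_roi_ratio"])
        else:
            viq = piq = fiq = float("nan")

        subjects.append(
            SubjectData(
                subject_id=sid,
                group=group,
                sex=sex,
                age=age,
                education=education,
                viq=viq,
                piq=piq,
                fiq=fiq,
                bold=BoldSeries(grid, bold, p.tr_seconds),
                cbf=ScalarMap(grid, cbf),
                motion=motion,
            )
        )
        loadings[sid] = load
        attenuations[sid] = att

    truth = GroundTruth(
        params=p,
        roi_voxels=struct.roi_voxels,
        control_roi_voxels=struct.control_roi_voxels,
        network_centers=np.asarray(_NETWORK_CENTERS[:K]),
        loadings=loadings,
        attenuations=attenuations,
        latent_roi_ratio=latent_ratio,
        coupling_gain=gains,
        expected_dc_field=struct.expected_dc_field,
    )
    return Cohort(subjects=subjects, masks=masks, truth=truth, grid=grid)


# ---------------------------------------------------------------------------
# disk layout


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: Cohort, out_dir) -> str:
    """Write a cohort in a BIDS-flavoured layout; returns the manifest path.

    sub-XX/func/ holds the BOLD series and motion trace, sub-XX/perf/ the CBF
    map; masks/, participants.csv and ground_truth.json sit at the top level.
    The manifest lists every file with a sha256 checksum.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    files = []

    for s in cohort.subjects:
        func = os.path.join(out_dir, s.subject_id, "func")
        perf = os.path.join(out_dir, s.subject_id, "perf")
        os.makedirs(func, exist_ok=True)
        os.makedirs(perf, exist_ok=True)
        bold_path = os.path.join(func, f"{s.subject_id}_bold.nii.gz")
        write_volume(s.bold, bold_path)
        motion_path = os.path.join(func, f"{s.subject_id}_motion.txt")
        s.motion.to_file(motion_path)
        cbf_path = os.path.join(perf, f"{s.subject_id}_cbf.nii.gz")
        write_volume(s.cbf, cbf_path)
        files += [bold_path, motion_path, cbf_path]

    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(mask_dir, exist_ok=True)
    for name, mask in cohort.masks.items():
        path = os.path.join(mask_dir, f"{name}_mask.nii.gz")
        write_volume(mask, path)
        files.append(path)

    part_path = os.path.join(out_dir, "participants.csv")
    cohort.participants().to_csv(part_path, index=False)
    files.append(part_path)

    t = cohort.truth
    truth_payload = {
        "params": asdict(t.params),
        "roi_voxels": t.roi_voxels.tolist(),
        "control_roi_voxels": t.control_roi_voxels.tolist(),
        "network_centers": t.network_centers.tolist(),
        "loadings": {k: list(map(float, v)) for k, v in t.loadings.items()},
        "attenuations": {k: float(v) for k, v in t.attenuations.items()},
        "latent_roi_ratio": {k: float(v) for k, v in t.latent_roi_ratio.items()},
        "coupling_gain": {k: float(v) for k, v in t.coupling_gain.items()},
    }
    truth_path = os.path.join(out_dir, "ground_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    files.append(truth_path)

    manifest = {
        "n_subjects": len(cohort.subjects),
        "files": {os.path.relpath(f, out_dir): _sha256(f) for f in sorted(files)},
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def load_cohort(cohort_dir) -> "Cohort":
    """Read a written cohort back (images, motion, demographics; truth if present)."""
    from .volumes import read_mask, read_series, read_volume

    cohort_dir = str(cohort_dir)
    participants = pd.read_csv(os.path.join(cohort_dir, "participants.csv"))
    masks = {}
    for name in ("brain", "gm", "wm", "csf"):
        path = os.path.join(cohort_dir, "masks", f"{name}_mask.nii.gz")
        if os.path.exists(path):
            masks[name] = read_mask(path)
    grid = next(iter(masks.values())).grid

    truth = None
    truth_path = os.path.join(cohort_dir, "ground_truth.json")
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            payload = json.load(fh)
        params = CohortParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload["params"].items()
        })
        truth = GroundTruth(
            params=params,
            roi_voxels=np.asarray(payload["roi_voxels"]),
            control_roi_voxels=np.asarray(payload["control_roi_voxels"]),
            network_centers=np.asarray(payload["network_centers"]),
            loadings={k: np.asarray(v) for k, v in payload["loadings"].items()},
            attenuations=payload["attenuations"],
            latent_roi_ratio=payload["latent_roi_ratio"],
            coupling_gain=payload["coupling_gain"],
            expected_dc_field=None,
        )

    subjects = []
    for _, row in participants.iterrows():
        sid = row["subject_id"]
        func = os.path.join(cohort_dir, sid, "func")
        perf = os.path.join(cohort_dir, sid, "perf")
        bold = read_series(os.path.join(func, f"{sid}_bold.nii.gz"))
        cbf = read_volume(os.path.join(perf, f"{sid}_cbf.nii.gz"))
        motion = MotionTrace.from_file(os.path.join(func, f"{sid}_motion.txt"))
        subjects.append(
            SubjectData(
                subject_id=sid,
                group=row["group"],
                sex=int(row["sex"]),
                age=float(row["age"]),
                education=float(row["education"]),
                viq=float(row["VIQ"]),
                piq=float(row["PIQ"]),
                fiq=float(row["FIQ"]),
                bold=bold,
                cbf=cbf,
                motion=motion,
            )
        )
    return Cohort(subjects=subjects, masks=masks, truth=truth, grid=grid)
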