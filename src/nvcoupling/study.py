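"""Study-level model objects: cohort in, fitted coupling results out.

:class:`NVCStudy` binds a cohort (subject images + demographics + shared
masks) to an analysis configuration; :meth:`NVCStudy.fit` runs the
subject-level pipeline (preprocessing -> DC / fALFF -> z-scoring ->
smoothing -> coupling and ratio maps) and the group stage (demographic
tests, coupling comparison, covariate-adjusted voxel-wise GLMs with GRF
cluster correction, clinical correlations) and returns a
:class:`NVCStudyResults` carrying the estimates, tables and a ``summary()``.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import stats as gstats
from .coupling import (
    CouplingRecord,
    RatioParams,
    compare_global_coupling,
    global_coupling,
    ratio_map,
)
from .glm import GroupDesign, VoxelGLMResults, cluster_means, glm_voxelwise
from .metrics import DcParams, FalffParams, degree_centrality, falff, zscore_map
from .preprocess import (
    MotionTrace,
    bandpass,
    drop_initial_volumes,
    friston24,
    mean_timecourse,
    regress_nuisance,
    smooth_gaussian,
)
from .random_field import estimate_smoothness, grf_cluster_correct
from .volumes import MaskMap, ScalarMap, write_volume

__all__ = ["RunConfig", "NVCStudy", "NVCStudyResults", "run_subject", "dice"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; defaults are the study-standard values.

    10 dropped volumes, 0.01-0.1 Hz band, 6-mm smoothing, DC threshold 0.2
    with global-signal regression on the DC branch only, covariates
    age/sex/education, GRF voxel p 0.005 (two-tailed) with cluster p 0.05 at
    26-connectivity.
    """

    n_drop: int = 10
    band: tuple = (0.01, 0.1)
    fwhm_mm: float = 6.0
    global_signal_dc: bool = True
    global_signal_falff: bool = False
    dc: DcParams = field(default_factory=DcParams)
    falff: FalffParams = field(default_factory=FalffParams)
    ratio: RatioParams = field(default_factory=RatioParams)
    covariates: tuple = ("age", "sex", "education")
    voxel_p: float = 0.005
    cluster_p: float = 0.05
    connectivity: int = 26
    compute_falff: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectProducts:
    """Per-subject standardized maps and coupling records."""

    subject_id: str
    zdc: ScalarMap
    zcbf: ScalarMap
    zratio: ScalarMap
    coupling_dc: CouplingRecord
    zfalff: ScalarMap = None
    zratio_falff: ScalarMap = None
    coupling_falff: CouplingRecord = None


def run_subject(subject, masks: dict, config: RunConfig = RunConfig()) -> SubjectProducts:
    """Run the full subject-level pipeline.

    BOLD: drop initial volumes -> one OLS removing intercept, linear trend,
    WM/CSF means and the Friston-24 motion expansion (plus the global signal
    on the DC branch) -> bandpass (DC branch only) -> DC / fALFF -> z-score
    over GM -> 6-mm smoothing.  CBF: z-score over the whole-brain mask ->
    smoothing.  Ratio: original CBF / original DC over GM, then z-score and
    smooth.  Coupling: Pearson r between the standardized smoothed CBF and
    metric maps over GM.
    """
    gm, brain = masks["gm"], masks["brain"]
    bold = drop_initial_volumes(subject.bold, config.n_drop)
    motion = subject.motion.drop_initial(config.n_drop)

    nuis = mean_timecourse(bold, masks["wm"], "wm")
    nuis = nuis.hstack(mean_timecourse(bold, masks["csf"], "csf"))
    nuis = nuis.hstack(friston24(motion))
    global_sig = mean_timecourse(bold, brain, "global")

    def _zsmooth(m, mask):
        return smooth_gaussian(zscore_map(m, mask), config.fwhm_mm, mask)

    # DC branch
    nuis_dc = nuis.hstack(global_sig) if config.global_signal_dc else nuis
    resid_dc = regress_nuisance(bold, nuis_dc, brain)
    filtered = bandpass(resid_dc, *config.band)
    dc_map = degree_centrality(filtered, gm, config.dc)
    zdc = _zsmooth(dc_map, gm)

    # CBF (z over whole brain, per convention for perfusion maps)
    zcbf = _zsmooth(subject.cbf, brain)

    # regional ratio from original values
    ratio = ratio_map(subject.cbf, dc_map, gm, config.ratio)
    zratio = _zsmooth(ratio, gm)

    coupling_dc = global_coupling(zcbf, zdc, gm, subject.subject_id, "DC")

    zfalff = zratio_falff = coupling_falff = None
    if config.compute_falff:
        nuis_fa = nuis.hstack(global_sig) if config.global_signal_falff else nuis
        resid_fa = regress_nuisance(bold, nuis_fa, brain)
        falff_map = falff(resid_fa, gm, config.falff)
        zfalff = _zsmooth(falff_map, gm)
        ratio_fa = ratio_map(subject.cbf, falff_map, gm, config.ratio)
        zratio_falff = _zsmooth(ratio_fa, gm)
        coupling_falff = global_coupling(zcbf, zfalff, gm, subject.subject_id, "fALFF")

    return SubjectProducts(
        subject_id=subject.subject_id,
        zdc=zdc,
        zcbf=zcbf,
        zratio=zratio,
        coupling_dc=coupling_dc,
        zfalff=zfalff,
        zratio_falff=zratio_falff,
        coupling_falff=coupling_falff,
    )


def _cluster_table(rows, family: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": family,
                "n_voxels": r.n_voxels,
                "peak_t": r.peak_t,
                "peak_x_mm": r.peak_mm[0],
                "peak_y_mm": r.peak_mm[1],
                "peak_z_mm": r.peak_mm[2],
                "sign": r.sign,
                "cluster_p": r.cluster_p,
            }
            for r in rows
        ],
        columns=[
            "family", "n_voxels", "peak_t",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "sign", "cluster_p",
        ],
    )


def dice(voxels_a, voxels_b) -> float:
    """Dice overlap of two voxel-index sets."""
    a = {tuple(v) for v in np.atleast_2d(np.asarray(voxels_a))} if len(voxels_a) else set()
    b = {tuple(v) for v in np.atleast_2d(np.asarray(voxels_b))} if len(voxels_b) else set()
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


class NVCStudy:
    """A neurovascular-coupling study: cohort data bound to a configuration."""

    def __init__(self, subjects, masks: dict, participants: pd.DataFrame = None,
                 config: RunConfig = RunConfig(), truth=None):
        self.subjects = list(subjects)
        if len(self.subjects) < 4:
            raise ValueError("a group study needs at least 2 subjects per group")
        self.masks = masks
        self.config = config
        self.truth = truth
        if participants is None:
            participants = pd.DataFrame(
                [
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
            )
        self.participants = participants.reset_index(drop=True)
        groups = self.participants["group"]
        if (groups == "patient").sum() < 2 or (groups != "patient").sum() < 2:
            raise ValueError("each group needs at least 2 subjects")

    @classmethod
    def from_cohort(cls, cohort, config: RunConfig = RunConfig()) -> "NVCStudy":
        return cls(cohort.subjects, cohort.masks, cohort.participants(),
                   config=config, truth=cohort.truth)

    @classmethod
    def from_cohort_dir(cls, cohort_dir, config: RunConfig = RunConfig()) -> "NVCStudy":
        from .simulate import load_cohort

        return cls.from_cohort(load_cohort(cohort_dir), config=config)

    @classmethod
    def from_simulation(cls, params=None, seed: int = 0,
                        config: RunConfig = RunConfig()) -> "NVCStudy":
        from .simulate import CohortParams, generate_cohort

        return cls.from_cohort(generate_cohort(params or CohortParams(), seed),
                               config=config)

    # ------------------------------------------------------------------
    def _design(self) -> GroupDesign:
        part = self.participants
        group = (part["group"] == "patient").to_numpy(float)
        cov_cols = [c for c in self.config.covariates if c in part]
        cov = part[cov_cols].to_numpy(float) if cov_cols else None
        return GroupDesign(group, cov, list(cov_cols))

    def _family_inference(self, maps, mask: MaskMap):
        res = glm_voxelwise(maps, self._design(), mask)
        resid_maps = np.full((res.residuals.shape[0],) + res.grid.shape, np.nan)
        resid_maps[:, res.analyzed] = res.residuals
        analyzed_mask = MaskMap(res.grid, res.analyzed)
        smooth_est = estimate_smoothness(resid_maps, analyzed_mask)
        clusters = grf_cluster_correct(
            res.t_map, res.df, smooth_est, analyzed_mask,
            voxel_p=self.config.voxel_p, cluster_p=self.config.cluster_p,
            connectivity=self.config.connectivity,
        )
        return res, smooth_est, clusters

    def fit(self, cache_dir=None, verbose: bool = False) -> "NVCStudyResults":
        products = {}
        for s in self.subjects:
            prod = self._cached_subject(s, cache_dir) if cache_dir else None
            if prod is None:
                prod = run_subject(s, self.masks, self.config)
                if cache_dir:
                    self._cache_subject(prod, cache_dir)
            products[s.subject_id] = prod
            if verbose:
                print(f"[subject] {s.subject_id} coupling r={prod.coupling_dc.r:.3f} "
                      f"n={prod.coupling_dc.n_voxels}")

        part = self.participants
        ids = part["subject_id"].tolist()
        is_patient = (part["group"] == "patient").to_numpy(bool)

        coupling_rows = []
        for sid, patient in zip(ids, is_patient):
            rec = products[sid].coupling_dc
            coupling_rows.append(
                {"subject_id": sid, "group": "patient" if patient else "control",
                 "metric": "DC", "r": rec.r, "n_voxels": rec.n_voxels}
            )
            if products[sid].coupling_falff is not None:
                fa = products[sid].coupling_falff
                coupling_rows.append(
                    {"subject_id": sid, "group": "patient" if patient else "control",
                     "metric": "fALFF", "r": fa.r, "n_voxels": fa.n_voxels}
                )
        coupling_table = pd.DataFrame(coupling_rows)

        dc_r = coupling_table[coupling_table["metric"] == "DC"]
        coupling_test = compare_global_coupling(
            dc_r[dc_r["group"] == "patient"]["r"].to_numpy(),
            dc_r[dc_r["group"] == "control"]["r"].to_numpy(),
        )
        coupling_test_falff = None
        if self.config.compute_falff:
            fa_r = coupling_table[coupling_table["metric"] == "fALFF"]
            coupling_test_falff = compare_global_coupling(
                fa_r[fa_r["group"] == "patient"]["r"].to_numpy(),
                fa_r[fa_r["group"] == "control"]["r"].to_numpy(),
            )

        demographics = gstats.demographics_table(part)

        gm = self.masks["gm"]
        families = {
            "cbf": [products[sid].zcbf for sid in ids],
            "dc": [products[sid].zdc for sid in ids],
            "ratio": [products[sid].zratio for sid in ids],
        }
        inference, cluster_tables = {}, []
        for fam, maps in families.items():
            res, smooth_est, clusters = self._family_inference(maps, gm)
            inference[fam] = {"glm": res, "smoothness": smooth_est, "clusters": clusters}
            cluster_tables.append(_cluster_table(clusters, fam))
            if verbose:
                print(f"[group] {fam}: {len(clusters)} clusters, "
                      f"fwhm={np.round(smooth_est.fwhm_mm, 1)} mm")
        non_empty = [t for t in cluster_tables if len(t)]
        cluster_table = (
            pd.concat(non_empty, ignore_index=True) if non_empty else cluster_tables[0]
        )

        # clinical correlations: mean of each significant cluster in the
        # patients' maps against the patients' IQ scores
        clinical_rows = []
        patient_ids = [sid for sid, p in zip(ids, is_patient) if p]
        pat_part = part[is_patient]
        for fam, maps_key in (("ratio", "zratio"), ("cbf", "zcbf"), ("dc", "zdc")):
            clusters = inference[fam]["clusters"]
            if not clusters:
                continue
            pat_maps = [getattr(products[sid], maps_key) for sid in patient_ids]
            means = cluster_means(pat_maps, clusters)
            for j, row in enumerate(clusters):
                for score in ("PIQ", "VIQ", "FIQ"):
                    y = pat_part[score].to_numpy(float)
                    ok = np.isfinite(y) & np.isfinite(means[:, j])
                    if ok.sum() < 4 or means[ok, j].std() == 0 or y[ok].std() == 0:
                        continue
                    cc = gstats.clinical_correlation(means[ok, j], y[ok])
                    clinical_rows.append(
                        {"family": fam, "cluster": j, "sign": row.sign,
                         "n_voxels": row.n_voxels, "score": score,
                         "r": cc["r"], "p": cc["p"], "n": cc["n"]}
                    )
        clinical = pd.DataFrame(
            clinical_rows,
            columns=["family", "cluster", "sign", "n_voxels", "score", "r", "p", "n"],
        )

        return NVCStudyResults(
            study=self,
            products=products,
            coupling_table=coupling_table,
            coupling_test=coupling_test,
            coupling_test_falff=coupling_test_falff,
            demographics=demographics,
            inference=inference,
            cluster_table=cluster_table,
            clinical=clinical,
            config=self.config,
        )

    # ------------------------------------------------------------------
    def _cache_path(self, subject_id, cache_dir):
        return os.path.join(str(cache_dir), f"{subject_id}_{self.config.config_hash}.npz")

    def _cache_subject(self, prod: SubjectProducts, cache_dir):
        os.makedirs(str(cache_dir), exist_ok=True)
        arrays = {"zdc": prod.zdc.values, "zcbf": prod.zcbf.values,
                  "zratio": prod.zratio.values,
                  "coupling_dc": np.array([prod.coupling_dc.r, prod.coupling_dc.n_voxels])}
        if prod.zfalff is not None:
            arrays["zfalff"] = prod.zfalff.values
            arrays["zratio_falff"] = prod.zratio_falff.values
            arrays["coupling_falff"] = np.array(
                [prod.coupling_falff.r, prod.coupling_falff.n_voxels])
        np.savez_compressed(self._cache_path(prod.subject_id, cache_dir), **arrays)

    def _cached_subject(self, subject, cache_dir):
        path = self._cache_path(subject.subject_id, cache_dir)
        if not os.path.exists(path):
            return None
        grid = self.masks["gm"].grid
        with np.load(path) as z:
            def _map(key):
                return ScalarMap(grid, z[key]) if key in z else None

            cdc = z["coupling_dc"]
            cfa = z["coupling_falff"] if "coupling_falff" in z else None
            return SubjectProducts(
                subject_id=subject.subject_id,
                zdc=_map("zdc"), zcbf=_map("zcbf"), zratio=_map("zratio"),
                coupling_dc=CouplingRecord(subject.subject_id, "DC",
                                           float(cdc[0]), int(cdc[1])),
                zfalff=_map("zfalff"), zratio_falff=_map("zratio_falff"),
                coupling_falff=None if cfa is None else CouplingRecord(
                    subject.subject_id, "fALFF", float(cfa[0]), int(cfa[1])),
            )

    # ------------------------------------------------------------------
    def validate(self, results: "NVCStudyResults",
                 thresholds=(0.15, 0.25), include_falff: bool = True) -> pd.DataFrame:
        """Robustness re-analysis: alternate DC thresholds and the fALFF metric.

        Re-runs the ratio-map group inference per variant and reports the Dice
        overlap between each variant's significant ratio-cluster voxels and
        the main run's, plus the coupling-comparison p-value per variant.
        """
        main_vox = np.concatenate(
            [r.voxels for r in results.inference["ratio"]["clusters"]]
        ) if results.inference["ratio"]["clusters"] else np.empty((0, 3), int)

        rows = [{
            "variant": f"dc_r{self.config.dc.r_threshold:g}", "kind": "main",
            "n_clusters": len(results.inference["ratio"]["clusters"]),
            "dice_with_main": 1.0 if len(main_vox) else float("nan"),
            "coupling_p": results.coupling_test["p"],
        }]

        gm = self.masks["gm"]
        ids = self.participants["subject_id"].tolist()
        for thr in thresholds:
            cfg = RunConfig(**{**self.config.to_dict(),
                               "dc": DcParams(r_threshold=thr,
                                              mode=self.config.dc.mode,
                                              normalize=self.config.dc.normalize),
                               "falff": self.config.falff,
                               "ratio": self.config.ratio,
                               "compute_falff": False})
            prods = {s.subject_id: run_subject(s, self.masks, cfg)
                     for s in self.subjects}
            res, sm, clusters = self._family_inference(
                [prods[sid].zratio for sid in ids], gm)
            vox = np.concatenate([r.voxels for r in clusters]) if clusters else np.empty((0, 3), int)
            part = self.participants
            ct = compare_global_coupling(
                [prods[sid].coupling_dc.r for sid, g in zip(ids, part["group"]) if g == "patient"],
                [prods[sid].coupling_dc.r for sid, g in zip(ids, part["group"]) if g != "patient"],
            )
            rows.append({
                "variant": f"dc_r{thr:g}", "kind": "dc_threshold",
                "n_clusters": len(clusters),
                "dice_with_main": dice(main_vox, vox),
                "coupling_p": ct["p"],
            })

        if include_falff and self.config.compute_falff:
            maps = [results.products[sid].zratio_falff for sid in ids]
            res, sm, clusters = self._family_inference(maps, gm)
            vox = np.concatenate([r.voxels for r in clusters]) if clusters else np.empty((0, 3), int)
            rows.append({
                "variant": "falff", "kind": "metric",
                "n_clusters": len(clusters),
                "dice_with_main": dice(main_vox, vox),
                "coupling_p": results.coupling_test_falff["p"],
            })
        return pd.DataFrame(rows)


@dataclass
class NVCStudyResults:
    """Fitted study: coupling, demographics, voxel-wise inference, clinical links."""

    study: NVCStudy
    products: dict
    coupling_table: pd.DataFrame
    coupling_test: dict
    coupling_test_falff: dict
    demographics: pd.DataFrame
    inference: dict
    cluster_table: pd.DataFrame
    clinical: pd.DataFrame
    config: RunConfig

    def group_mean_coupling(self) -> dict:
        dc = self.coupling_table[self.coupling_table["metric"] == "DC"]
        return {
            "patient": float(dc[dc["group"] == "patient"]["r"].mean()),
            "control": float(dc[dc["group"] == "control"]["r"].mean()),
        }

    def summary(self) -> str:
        means = self.group_mean_coupling()
        ct = self.coupling_test
        lines = [
            "Neurovascular coupling study summary",
            "====================================",
            f"subjects: {len(self.products)} "
            f"({(self.study.participants['group'] == 'patient').sum()} patients, "
            f"{(self.study.participants['group'] != 'patient').sum()} controls)",
            "",
            "Demographics:",
            self.demographics.to_string(index=False),
            "",
            f"Global CBF-DC coupling: patients {means['patient']:.3f}, "
            f"controls {means['control']:.3f}",
            f"  group test: {ct['test']}, statistic={ct['statistic']:.3f}, "
            f"p={ct['p']:.4f}",
            "",
            "Significant clusters (GRF-corrected):",
            self.cluster_table.to_string(index=False)
            if len(self.cluster_table) else "  none",
        ]
        if len(self.clinical):
            lines += ["", "Cluster-mean x clinical correlations (patients):",
                      self.clinical.to_string(index=False)]
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write the report bundle (CSV tables, t maps, run log); returns paths."""
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {}

        def _csv(name, df):
            path = os.path.join(out_dir, name)
            df.to_csv(path, index=False, float_format="%.6g")
            paths[name] = path

        _csv("demographics.csv", self.demographics)
        _csv("coupling.csv", self.coupling_table)
        _csv("clusters.csv", self.cluster_table)
        _csv("clinical_correlations.csv", self.clinical)
        coupling_test = {"dc": self.coupling_test}
        if self.coupling_test_falff is not None:
            coupling_test["falff"] = self.coupling_test_falff
        test_path = os.path.join(out_dir, "coupling_test.json")
        with open(test_path, "w") as fh:
            json.dump(coupling_test, fh, indent=1, sort_keys=True, default=str)
        paths["coupling_test.json"] = test_path
        for fam, inf in self.inference.items():
            p = os.path.join(out_dir, f"tmap_{fam}.nii.gz")
            write_volume(inf["glm"].t_map, p)
            paths[f"tmap_{fam}.nii.gz"] = p
        log = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash,
            "n_subjects": len(self.products),
            "smoothness_mm": {
                fam: list(inf["smoothness"].fwhm_mm)
                for fam, inf in self.inference.items()
            },
        }
        log_path = os.path.join(out_dir, "run_log.json")
        with open(log_path, "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True, default=str)
        paths["run_log.json"] = log_path
        return paths

    def plot_coupling(self, ax=None):
        """Strip/box plot of per-subject coupling r by group (DC metric)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        dc = self.coupling_table[self.coupling_table["metric"] == "DC"]
        data = [dc[dc["group"] == g]["r"].to_numpy() for g in ("control", "patient")]
        ax.boxplot(data, tick_labels=["control", "patient"], widths=0.5)
        for i, vals in enumerate(data, start=1):
            x = np.random.default_rng(0).normal(i, 0.04, size=vals.size)
            ax.plot(x, vals, "o", alpha=0.5, ms=4)
        ax.set_ylabel("across-voxel CBF-DC correlation (r)")
        ax.set_title(f"global coupling (p={self.coupling_test['p']:.3g})")
        return ax
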