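import json

import numpy as np
import pytest

from nvcoupling.coupling import global_coupling
from nvcoupling.simulate import (
    CohortParams,
    generate_cohort,
    get_structure,
    load_cohort,
    sample_patient_clinical,
    write_cohort,
)
from nvcoupling.stats import clinical_correlation

SMALL = CohortParams(n_patients=3, n_controls=3)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(SMALL, seed=5)
        b = generate_cohort(SMALL, seed=5)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.bold.values, sb.bold.values)
            assert np.array_equal(sa.cbf.values, sb.cbf.values,
                                  equal_nan=True)
            assert np.array_equal(sa.motion.params, sb.motion.params)
            assert (sa.age, sa.sex) == (sb.age, sb.sex)
            assert np.array_equal([sa.piq], [sb.piq], equal_nan=True)

    def test_different_seeds_differ(self):
        a = generate_cohort(SMALL, seed=5)
        b = generate_cohort(SMALL, seed=6)
        assert not np.array_equal(a.subjects[0].bold.values,
                                  b.subjects[0].bold.values)

    def test_checksums_stable_across_writes(self, tmp_path):
        cohort = generate_cohort(SMALL, seed=5)
        m1 = write_cohort(cohort, tmp_path / "a")
        m2 = write_cohort(cohort, tmp_path / "b")
        with open(m1) as fh:
            h1 = json.load(fh)["files"]
        with open(m2) as fh:
            h2 = json.load(fh)["files"]
        assert h1 == h2


class TestCohortStructure:
    def test_masks_are_disjoint_partitions_of_brain(self):
        c = generate_cohort(SMALL, seed=0)
        brain = c.masks["brain"].inside
        gm, wm, csf = (c.masks[k].inside for k in ("gm", "wm", "csf"))
        assert not (gm & wm).any() and not (gm & csf).any() and not (wm & csf).any()
        assert np.array_equal(gm | wm | csf, brain)

    def test_roi_inside_gm(self):
        c = generate_cohort(SMALL, seed=0)
        gm = c.masks["gm"].inside
        assert all(gm[tuple(v)] for v in c.truth.roi_voxels)

    def test_roi_outside_gm_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            get_structure(CohortParams(n_patients=3, n_controls=3,
                                       roi_center=(2, 2, 2)))

    def test_infeasible_coupling_target_rejected(self):
        params = CohortParams(n_patients=3, n_controls=3, coupling_hc=0.999)
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(params, seed=0)

    def test_motion_within_screening_bounds(self):
        c = generate_cohort(SMALL, seed=3)
        assert all(s.motion.passes_screening() for s in c.subjects)

    def test_patient_attenuation_recorded(self):
        c = generate_cohort(SMALL, seed=3)
        for s in c.subjects:
            att = c.truth.attenuations[s.subject_id]
            if s.group == "control":
                assert att == 1.0
            else:
                assert 0 < att < 1


class TestWriteLoadRoundTrip:
    def test_manifest_bookkeeping(self, tmp_path):
        cohort = generate_cohort(SMALL, seed=1)
        manifest = write_cohort(cohort, tmp_path / "cohort")
        with open(manifest) as fh:
            files = json.load(fh)["files"]
        n = len(cohort.subjects)
        # per subject: bold + motion + cbf; plus 4 masks and 2 tables
        assert len(files) == n * 3 + 4 + 2

    def test_roundtrip_values(self, tmp_path):
        cohort = generate_cohort(SMALL, seed=1)
        write_cohort(cohort, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort")
        assert len(back.subjects) == len(cohort.subjects)
        for sa, sb in zip(cohort.subjects, back.subjects):
            assert np.allclose(sa.bold.values, sb.bold.values)
            assert sb.bold.tr_seconds == pytest.approx(sa.bold.tr_seconds)
            assert np.allclose(sa.cbf.values, sb.cbf.values, equal_nan=True)
            assert np.allclose(sa.motion.params, sb.motion.params, atol=1e-8)
            assert sb.group == sa.group
        assert back.truth.params == cohort.truth.params
        assert np.array_equal(back.truth.roi_voxels, cohort.truth.roi_voxels)


class TestInjectedStructure:
    def test_network_voxels_correlate_strongly(self):
        c = generate_cohort(SMALL, seed=2)
        # use a control subject and a network far from the attenuated ROI
        s = next(x for x in c.subjects if x.group == "control")
        k0 = (7, 8, 11)
        bg = None
        gm = c.masks["gm"].inside
        # pick a background GM voxel far from all network centres
        for idx in np.argwhere(gm):
            if all(np.linalg.norm(idx - np.array(cn)) > 5
                   for cn in ((7, 8, 11), (15, 15, 10), (8, 15, 14), (15, 8, 15))):
                bg = tuple(idx)
                break
        center_series = s.bold.values[k0]
        neighbor = (k0[0] + 1, k0[1], k0[2])
        r_net = np.corrcoef(center_series, s.bold.values[neighbor])[0, 1]
        r_bg = np.corrcoef(center_series, s.bold.values[bg])[0, 1]
        assert r_net > 0.5
        assert abs(r_bg) < 0.3

    def test_cbf_coupling_gain_ordering(self):
        c = generate_cohort(SMALL, seed=2)
        assert c.truth.coupling_gain["control"] > c.truth.coupling_gain["patient"] > 0

    def test_expected_dc_field_drives_cbf(self):
        # a control subject's CBF should correlate positively with the
        # expected-DC field over GM
        c = generate_cohort(SMALL, seed=4)
        gm = c.masks["gm"]
        field = c.truth.expected_dc_field
        from nvcoupling.volumes import ScalarMap

        ctrl = next(s for s in c.subjects if s.group == "control")
        rec = global_coupling(ctrl.cbf, ScalarMap(c.grid, field), gm)
        assert rec.r > 0.1


class TestClinicalSampling:
    def test_injected_piq_latent_correlation_exact_per_group(self):
        params = CohortParams()
        rng = np.random.default_rng(9)
        df = sample_patient_clinical(params, rng)
        cc = clinical_correlation(df["latent_roi_ratio"], df["PIQ"])
        assert cc["r"] == pytest.approx(params.iq_ratio_corr, abs=1e-8)

    def test_latent_ratio_decreases_with_attenuation(self):
        params = CohortParams()
        rng = np.random.default_rng(10)
        df = sample_patient_clinical(params, rng)
        cc = clinical_correlation(df["attenuation"], df["latent_roi_ratio"])
        assert cc["r"] < -0.9  # stronger attenuation (smaller factor) -> higher ratio


def test_coupling_difference_monotone_in_patient_target():
    """Narrowing the coupling-target gap shrinks the measured group difference."""
    from nvcoupling.study import RunConfig, run_subject

    cfg = RunConfig(compute_falff=False)
    diffs = []
    for target in (0.15, 0.25, 0.35):
        gaps = []
        for seed in (0, 1, 2, 3):
            params = CohortParams(n_patients=5, n_controls=5,
                                  coupling_patient=target)
            c = generate_cohort(params, seed=seed)
            rs = {"patient": [], "control": []}
            for s in c.subjects:
                rs[s.group].append(run_subject(s, c.masks, cfg).coupling_dc.r)
            gaps.append(np.mean(rs["control"]) - np.mean(rs["patient"]))
        diffs.append(np.mean(gaps))
    assert diffs[0] > diffs[1] > diffs[2]
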