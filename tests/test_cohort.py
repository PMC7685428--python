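"""Synthetic two-site cohort generator: determinism, calibration, invariants."""

import numpy as np
import pandas as pd
import pytest

from voxelsvm.cohort import (
    CohortSpec,
    EffectRegion,
    SiteSpec,
    default_two_site_spec,
    generate_cohort,
    generate_template,
    load_cohort,
    region_profile,
    write_cohort,
)


def small_single_site_spec(seed, n=20, effect_d=1.2, **overrides):
    spec = CohortSpec(
        grid_shape=(16, 16, 16),
        voxel_size_mm=4.0,
        sites=[SiteSpec(name="s", n_patients=n, n_controls=n, age_mean=35.0, age_sd=6.0)],
        effect_regions=[
            EffectRegion(center_mm=(28.0, 30.0, 34.0), radii_mm=(16.0,) * 3, effect_d=effect_d)
        ],
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


class TestTemplate:
    def test_deterministic_under_fixed_seed(self, desk_spec):
        a = generate_template(desk_spec)
        b = generate_template(desk_spec)
        assert np.array_equal(a.values, b.values)
        other = default_two_site_spec(seed=desk_spec.seed + 1, grid_shape=desk_spec.grid_shape)
        assert not np.array_equal(a.values, generate_template(other).values)

    def test_zero_background_keeps_boundary_below_mask_threshold(self):
        spec = default_two_site_spec(seed=3, background=0.0)
        tpl = generate_template(spec).values
        faces = np.concatenate(
            [tpl[0].ravel(), tpl[-1].ravel(), tpl[:, 0].ravel(), tpl[:, -1].ravel(),
             tpl[:, :, 0].ravel(), tpl[:, :, -1].ravel()]
        )
        assert np.all(faces < 0.2)

    def test_interior_values_within_configured_range(self, desk_spec):
        # brute-force scan of the lattice: every voxel well inside the
        # ellipsoidal support must lie in the configured interior range
        tpl = generate_template(desk_spec).values
        shape = np.asarray(desk_spec.grid_shape, float)
        center = (shape - 1) / 2
        semi = shape * 0.42
        lo, hi = desk_spec.interior_range
        count = 0
        for idx in np.ndindex(tpl.shape):
            r = np.sqrt((((np.asarray(idx) - center) / semi) ** 2).sum())
            if r < 0.75:
                assert lo <= tpl[idx] <= hi
                count += 1
        assert count > 50

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_shape"):
            generate_template(default_two_site_spec(seed=0, grid_shape=(4, 16, 16)))


class TestCohortStructure:
    def test_table_one_design_row_counts(self, desk_cohort, tmp_path):
        counts = desk_cohort.participants.groupby("site").size()
        assert counts["site1"] == 101 and counts["site2"] == 97
        by_group = desk_cohort.participants.groupby(["site", "diagnosis"]).size()
        assert by_group["site1", "patient"] == 50 and by_group["site1", "control"] == 51
        assert by_group["site2", "patient"] == 49 and by_group["site2", "control"] == 48
        write_cohort(desk_cohort, tmp_path)
        tsv = pd.read_csv(tmp_path / "participants.tsv", sep="\t")
        assert (tsv.groupby("site").size() == counts).all()

    def test_bitwise_deterministic(self, desk_spec, desk_cohort):
        again = generate_cohort(desk_spec)
        assert again.participants.equals(desk_cohort.participants)
        for sid in desk_cohort.volumes:
            assert np.array_equal(again.volumes[sid].values, desk_cohort.volumes[sid].values)

    def test_roundtrip_through_disk(self, desk_cohort, tmp_path):
        write_cohort(desk_cohort, tmp_path)
        loaded = load_cohort(tmp_path)
        assert loaded.subject_ids == desk_cohort.subject_ids
        sid = desk_cohort.subject_ids[0]
        np.testing.assert_allclose(
            loaded.volumes[sid].values, desk_cohort.volumes[sid].values, atol=1e-6
        )
        assert loaded.spec.seed == desk_cohort.spec.seed

    def test_clinical_record_invariants(self, desk_cohort):
        part = desk_cohort.participants
        patients = part[part["diagnosis"] == "patient"]
        controls = part[part["diagnosis"] == "control"]
        assert (patients["PANSS_total"] >= patients["PANSS_positive"]).all()
        assert (patients["PANSS_total"] >= patients["PANSS_negative"]).all()
        np.testing.assert_allclose(
            patients["duration"], patients["age"] - patients["onset_age"], atol=0.2
        )
        for col in ("PANSS_total", "onset_age", "duration", "CPZ_mg"):
            assert controls[col].isna().all(), f"{col} should be missing for controls"
        assert controls["JART"].notna().all()

    def test_truth_mask_marks_effect_regions(self, desk_spec, desk_cohort):
        truth = desk_cohort.truth_mask.values > 0
        assert truth.any()
        expected = np.zeros(desk_spec.grid_shape, dtype=bool)
        for reg in desk_spec.effect_regions:
            expected |= region_profile(desk_spec, reg) > 0.5
        assert np.array_equal(truth, expected)


class TestEffectCalibration:
    def test_null_effect_gives_nonsignificant_core(self):
        # with effect_d = 0 the patient/control difference at the region
        # core should be null-distributed: few seeds reach p < 0.05
        from scipy.stats import ttest_ind

        n_sig = 0
        for seed in range(10):
            spec = small_single_site_spec(seed, effect_d=0.0)
            coh = generate_cohort(spec)
            core = region_profile(spec, spec.effect_regions[0]) > 0.9
            p = coh.participants
            pat = [coh.volumes[s].values[core].mean() for s in p[p.diagnosis == "patient"].subject_id]
            con = [coh.volumes[s].values[core].mean() for s in p[p.diagnosis == "control"].subject_id]
            if ttest_ind(pat, con).pvalue < 0.05:
                n_sig += 1
        assert n_sig <= 3

    def test_cohens_d_matches_target(self):
        # direct group-mean / pooled-SD computation on generated samples,
        # averaged over seeds to separate calibration error from sampling noise
        ds = []
        for seed in range(6):
            spec = default_two_site_spec(seed=seed, grid_shape=(16, 16, 16))
            coh = generate_cohort(spec)
            core = region_profile(spec, spec.effect_regions[0]) > 0.9
            p = coh.participants
            for site in ("site1", "site2"):
                sel = p["site"] == site
                pat = np.array([
                    coh.volumes[s].values[core].mean()
                    for s in p[sel & (p.diagnosis == "patient")].subject_id
                ])
                con = np.array([
                    coh.volumes[s].values[core].mean()
                    for s in p[sel & (p.diagnosis == "control")].subject_id
                ])
                pooled = np.sqrt(
                    ((len(pat) - 1) * pat.var(ddof=1) + (len(con) - 1) * con.var(ddof=1))
                    / (len(pat) + len(con) - 2)
                )
                ds.append((con.mean() - pat.mean()) / pooled)
        assert abs(np.mean(ds) - 1.2) <= 0.25

    def test_effect_monotone_in_d(self):
        # expected patient-vs-control core difference strictly increases
        # with effect_d (3 d values x 20 seeds)
        mean_diff = {}
        for d in (0.0, 0.6, 1.2):
            diffs = []
            for seed in range(20):
                spec = small_single_site_spec(seed, n=12, effect_d=d)
                coh = generate_cohort(spec)
                core = region_profile(spec, spec.effect_regions[0]) > 0.9
                p = coh.participants
                pat = np.mean([
                    coh.volumes[s].values[core].mean()
                    for s in p[p.diagnosis == "patient"].subject_id
                ])
                con = np.mean([
                    coh.volumes[s].values[core].mean()
                    for s in p[p.diagnosis == "control"].subject_id
                ])
                diffs.append(con - pat)
            mean_diff[d] = np.mean(diffs)
        assert mean_diff[0.0] < mean_diff[0.6] < mean_diff[1.2]

    def test_site_intensity_shift_visible_in_interior_mean(self):
        from voxelsvm.cohort import _support_profile

        spec = default_two_site_spec(seed=11, grid_shape=(16, 16, 16))
        spec.sites[0].site_intensity_shift = 0.02
        spec.sites[1].site_intensity_shift = -0.01
        coh = generate_cohort(spec)
        interior = _support_profile(spec) >= 1.0
        p = coh.participants
        means = {
            site: np.array([
                coh.volumes[s].values[interior].mean() for s in p[p.site == site].subject_id
            ])
            for site in ("site1", "site2")
        }
        diff = means["site1"].mean() - means["site2"].mean()
        se = np.sqrt(means["site1"].var(ddof=1) / len(means["site1"])
                     + means["site2"].var(ddof=1) / len(means["site2"]))
        assert abs(diff - 0.03) <= 3 * se

    def test_clipping_fraction_below_one_percent(self):
        spec = default_two_site_spec(seed=2)
        coh = generate_cohort(spec)
        frac = np.mean([
            np.mean((v.values == 0.0) | (v.values == 1.0)) for v in coh.volumes.values()
        ])
        assert frac < 0.01


class TestClinicalLink:
    def test_linked_variable_tracks_regional_gm(self, desk_spec, desk_cohort):
        from voxelsvm.clinical import spearman

        reg = desk_spec.effect_regions[1]
        var, rho_target = reg.clinical_link
        mask = region_profile(desk_spec, reg) > 0.5
        p = desk_cohort.participants
        sel = (p.site == "site1") & (p.diagnosis == "patient")
        gm = [desk_cohort.volumes[s].values[mask].mean() for s in p[sel].subject_id]
        rho, _ = spearman(gm, p[sel][var])
        assert rho < 0
        assert abs(rho - rho_target) <= 0.3

    def test_invalid_target_rho_rejected(self):
        reg = EffectRegion(center_mm=(0, 0, 0), radii_mm=(5, 5, 5),
                           effect_d=0.5, clinical_link=("CPZ_mg", 1.0))
        with pytest.raises(ValueError, match="rho"):
            reg.validate()

    def test_unattainable_link_reported_not_clamped(self):
        # region entirely outside the lattice -> regional GM has no variance
        spec = small_single_site_spec(0)
        spec.effect_regions = [
            EffectRegion(center_mm=(500.0, 500.0, 500.0), radii_mm=(8.0,) * 3,
                         effect_d=0.5, clinical_link=("CPZ_mg", -0.5))
        ]
        with pytest.raises(RuntimeError, match="unattainable"):
            generate_cohort(spec)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "mutation, message",
        [
            ({"voxel_size_mm": 0.0}, "voxel_size_mm"),
            ({"subject_noise_sd": -0.1}, "subject_noise_sd"),
            ({"grid_shape": (8, 8, 7)}, "grid_shape"),
        ],
    )
    def test_bad_fields_rejected(self, mutation, message):
        spec = small_single_site_spec(0, **mutation)
        with pytest.raises(ValueError, match=message):
            spec.validate()

    def test_negative_cohort_size_rejected(self):
        spec = small_single_site_spec(0)
        spec.sites[0].n_patients = -1
        with pytest.raises(ValueError, match="cohort sizes"):
            spec.validate()
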