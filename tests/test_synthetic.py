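import numpy as np
import pytest
from scipy import stats as sps

from braineff import (
    CohortDesign,
    generate_atlas,
    generate_cohort,
    generate_covariates_and_cognition,
    generate_timeseries,
)
from braineff.synthetic import SUBNETWORKS


class TestAtlas:
    def test_default_atlas_has_160_nodes_in_six_subnetworks(self):
        atlas = generate_atlas(160)
        assert atlas.node_count == 160
        labels = set(atlas.subnetwork_of.values())
        assert labels == set(SUBNETWORKS)
        # contiguous blocks: subnetwork codes are non-decreasing
        codes = atlas.subnetwork_index()
        assert (np.diff(codes) >= 0).all()

    def test_singleton_subnetworks(self):
        atlas = generate_atlas(6, [1, 1, 1, 1, 1, 1])
        assert atlas.node_count == 6
        for lab in SUBNETWORKS:
            assert len(atlas.indices_of(lab)) == 1

    @pytest.mark.parametrize(
        "node_count,sizes",
        [(20, [10, 10]), (160, [10] * 6), (12, [2, 2, 2, 2, 2, 1])],
    )
    def test_invalid_sizes_rejected(self, node_count, sizes):
        with pytest.raises(ValueError):
            generate_atlas(node_count, sizes)


class TestTimeseries:
    def test_zero_coupling_gives_uncorrelated_series(self, atlas12):
        design = CohortDesign(
            group_sizes={"HC": 2, "WMH-NC": 2, "WMH-CIND": 2},
            timepoints=5000,
            coupling_within=0.0,
            coupling_global=0.0,
            deficit_delta=0.0,
            seed=11,
        )
        ts = generate_timeseries(design, atlas12, 0)
        r = np.corrcoef(ts.data, rowvar=False)
        np.fill_diagonal(r, 0.0)
        assert np.abs(r).max() < 0.1

    def test_global_factor_dominates_when_rho_g_high(self, atlas12):
        design = CohortDesign(
            group_sizes={"HC": 2, "WMH-NC": 2, "WMH-CIND": 2},
            timepoints=5000,
            coupling_within=0.0,
            coupling_global=0.99,
            deficit_delta=0.0,
            seed=3,
        )
        ts = generate_timeseries(design, atlas12, 1)
        r = np.corrcoef(ts.data, rowvar=False)
        off = r[np.triu_indices(12, 1)]
        assert np.abs(off - 0.99).max() < 0.05

    def test_same_seed_reproduces_identical_matrices(self, atlas12, small_design):
        a = generate_timeseries(small_design, atlas12, 4)
        b = generate_timeseries(small_design, atlas12, 4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_within_subnetwork_correlation_matches_closed_form(self, atlas12):
        # population correlation of same-subnetwork pairs is rho_g + rho_w
        design = CohortDesign(
            group_sizes={"HC": 2, "WMH-NC": 2, "WMH-CIND": 2},
            timepoints=8000,
            coupling_within=0.3,
            coupling_global=0.1,
            deficit_delta=0.0,
            n_mediator_nodes=0,
            seed=5,
        )
        ts = generate_timeseries(design, atlas12, 0)
        r = np.corrcoef(ts.data, rowvar=False)
        codes = atlas12.subnetwork_index()
        same = codes[:, None] == codes[None, :]
        mask = same & ~np.eye(12, dtype=bool)
        assert abs(r[mask].mean() - 0.4) < 0.03
        assert abs(r[~same].mean() - 0.1) < 0.03

    def test_invalid_inputs_rejected(self, atlas12):
        with pytest.raises(ValueError):
            CohortDesign(timepoints=1)
        with pytest.raises(ValueError):
            CohortDesign(coupling_within=0.7, coupling_global=0.4)
        with pytest.raises(ValueError):
            CohortDesign(deficit_delta=0.5, coupling_within=0.3)
        design = CohortDesign(group_sizes={"HC": 2, "WMH-NC": 2, "WMH-CIND": 2})
        with pytest.raises(ValueError):
            generate_timeseries(design, atlas12, 99)


class TestCovariatesAndCognition:
    def test_direct_effect_recovered_when_no_mediation(self):
        design = CohortDesign(
            group_sizes={"HC": 667, "WMH-NC": 666, "WMH-CIND": 667},
            mediation_params={
                "a": 0.0, "b": 0.0, "c_prime": 0.3,
                "noise_sd_M": 1.0, "noise_sd_Y": 1.0,
                "beta_age": 0.0, "beta_edu": 0.0,
            },
            seed=21,
        )
        cohort, info = generate_covariates_and_cognition(design)
        slope = np.polyfit(info["x_std"], cohort.cognition_y, 1)[0]
        assert abs(slope - 0.3) < 0.05

    def test_noiseless_limit_is_exact(self):
        design = CohortDesign(
            group_sizes={"HC": 30, "WMH-NC": 30, "WMH-CIND": 30},
            mediation_params={
                "a": -0.5, "b": 0.4, "c_prime": -0.2,
                "noise_sd_M": 0.0, "noise_sd_Y": 0.0,
                "beta_age": 0.0, "beta_edu": 0.0,
            },
            seed=2,
        )
        cohort, info = generate_covariates_and_cognition(design)
        expected = -0.2 * info["x_std"] + 0.4 * info["M"]
        np.testing.assert_allclose(cohort.cognition_y, expected, atol=1e-12)

    def test_volume_construction_constraints(self, small_design):
        cohort, _ = generate_covariates_and_cognition(small_design)
        assert (cohort.total_brain_mm3 > 0).all()
        assert (cohort.wmh_mm3 > 0).all()
        assert (cohort.pwmh_mm3 + cohort.dwmh_mm3 <= cohort.wmh_mm3 * (1 + 1e-9)).all()

    def test_cohort_generation_is_deterministic(self, atlas12, small_design):
        a = generate_cohort(small_design, atlas12)
        b = generate_cohort(small_design, atlas12)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(a.ground_truth.coupling, b.ground_truth.coupling)
        for ta, tb in zip(a.timeseries, b.timeseries):
            np.testing.assert_array_equal(ta.data, tb.data)


class TestPlantedDeficit:
    def test_cind_within_fpn_correlation_is_lower(self):
        # scaled-down version of the detectability property: with a 0.15
        # coupling deficit, the CIND group's mean within-FPN correlation
        # sits below HC's in every tried seed (one-sided t, p < 0.01)
        atlas = generate_atlas(24)
        fpn = atlas.indices_of("FPN")
        hits = 0
        for seed in range(5):
            design = CohortDesign(
                group_sizes={"HC": 30, "WMH-NC": 4, "WMH-CIND": 30},
                timepoints=200,
                deficit_delta=0.15,
                n_mediator_nodes=0,
                seed=seed,
            )
            cohort = generate_cohort(design, atlas)
            vals = {"HC": [], "WMH-CIND": []}
            for g, ts in zip(cohort.ground_truth.groups, cohort.timeseries):
                if g in vals:
                    r = np.corrcoef(ts.data[:, fpn], rowvar=False)
                    vals[g].append(r[np.triu_indices(len(fpn), 1)].mean())
            p = sps.ttest_ind(vals["WMH-CIND"], vals["HC"], alternative="less").pvalue
            hits += p < 0.01
        assert hits == 5
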