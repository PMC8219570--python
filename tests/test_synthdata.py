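import numpy as np
import pytest
from scipy.linalg import subspace_angles

import bodycal as bc


class TestSampleComposition:
    def test_empty(self):
        assert bc.sample_composition("female", 0, seed=1) == []

    def test_records_satisfy_invariants(self):
        for rec in bc.sample_composition("male", 200, seed=2):
            assert rec.fatm >= 2.0 and rec.smm >= 15.0
            assert rec.fatm + rec.smm < rec.weight
            assert rec.bmi == pytest.approx(
                rec.weight / (rec.height / 100.0) ** 2, rel=1e-9
            )

    @pytest.mark.parametrize(
        "sex,fat_mean,muscle_mean,corr",
        [("male", 14.53, 39.55, 0.45), ("female", 17.65, 26.34, 0.38)],
    )
    def test_large_sample_calibration(self, sex, fat_mean, muscle_mean, corr):
        """Realized descriptives and fat-muscle correlation match targets."""
        recs = bc.sample_composition(sex, 50_000, seed=11)
        fat = np.array([r.fatm for r in recs])
        mus = np.array([r.smm for r in recs])
        assert fat.mean() == pytest.approx(fat_mean, abs=0.1)
        assert mus.mean() == pytest.approx(muscle_mean, abs=0.1)
        assert np.corrcoef(fat, mus)[0, 1] == pytest.approx(corr, abs=0.01)

    def test_infeasible_floor_rejected(self):
        params = bc.CompositionParams(
            fat_mean=5.0, fat_sd=1.0, muscle_mean=30.0, muscle_sd=3.0, corr=0.4,
            height_mean=170.0, height_sd=6.0, residual_mean=20.0,
            residual_per_cm=0.25, residual_sd=2.0, fat_floor=15.0,
        )
        with pytest.raises(ValueError, match="infeasible"):
            bc.sample_composition("female", 10, params=params)

    def test_bad_correlation_rejected(self):
        params = bc.CompositionParams(
            fat_mean=15.0, fat_sd=7.0, muscle_mean=30.0, muscle_sd=3.0, corr=1.0,
            height_mean=170.0, height_sd=6.0, residual_mean=20.0,
            residual_per_cm=0.25, residual_sd=2.0,
        )
        with pytest.raises(ValueError):
            bc.sample_composition("female", 10, params=params)


class TestGenerateCohort:
    def test_seed_determinism(self):
        cfg = bc.SynthConfig(sex="female", n=5, seed=42)
        m1, r1, _ = bc.generate_cohort(cfg)
        m2, r2, _ = bc.generate_cohort(cfg)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.vertices, b.vertices)
        assert [r.fatm for r in r1] == [r.fatm for r in r2]

    def test_equal_composition_gives_identical_meshes(self):
        """Without noise and jitter, geometry is a function of composition."""
        cfg = bc.SynthConfig(
            sex="male", n=2, noise_sd=0.0, jitter_rotation=0.0,
            jitter_translation=0.0, seed=1,
        )
        meshes, records, truth = bc.generate_cohort(cfg)
        comp = [records[0].fatm, records[0].smm]
        rebuilt = (
            truth.base.vertices
            + comp[0] * truth.d_fat
            + comp[1] * truth.d_muscle
        )
        np.testing.assert_allclose(meshes[0].vertices, rebuilt, atol=1e-12)
        # same composition -> same mesh
        twin = (
            truth.base.vertices
            + records[1].fatm * truth.d_fat
            + records[1].smm * truth.d_muscle
        )
        np.testing.assert_allclose(meshes[1].vertices, twin, atol=1e-12)

    def test_preset_region_counts(self):
        meshes, _, _ = bc.generate_cohort(bc.SynthConfig(n=2, seed=3))
        counts = bc.preset_counts("small")
        labels = meshes[0].region_labels
        assert meshes[0].n_vertices == counts["total"]
        assert int(np.sum(labels == "torso")) == counts["torso"]
        assert int(np.sum(labels != "excluded")) == counts["retained"]

    def test_ground_truth_subspace_recovered(self, noiseless_cohort):
        """PCA of a noiseless cohort spans the (d_fat, d_muscle) plane."""
        meshes, records, truth = noiseless_cohort
        _, aligned, _ = bc.build_consensus(meshes)
        shapes = bc.flatten_cohort(aligned)
        model = bc.fit_shape_model(shapes, records)
        assert model.n_components == 2  # two generating directions only
        idx = shapes.topology.index_map
        fields = np.column_stack(
            [truth.d_fat[idx].reshape(-1), truth.d_muscle[idx].reshape(-1)]
        )
        angles = subspace_angles(model.basis, fields)
        assert np.max(angles) < 1e-3


class TestScenarios:
    def test_zero_residual_exact_recovery(self):
        x, y, spec = bc.scenario_data(
            bc.ScenarioSpec(name="ideal", residual_sd=0.0, n=50, seed=4)
        )
        fit = bc.fit_mvlm(x, y)
        np.testing.assert_allclose(fit.B_hat.T, spec.resolved_coefficients(), atol=1e-10)

    @pytest.mark.parametrize("name", ["self_estimate", "ideal"])
    def test_large_n_parameter_recovery(self, name):
        x, y, spec = bc.scenario_data(bc.ScenarioSpec(name=name, n=20_000, seed=5))
        fit = bc.fit_mvlm(x, y)
        np.testing.assert_allclose(
            fit.B_hat.T, spec.resolved_coefficients(), atol=0.05
        )

    def test_estimator_rmse_shrinks_with_n(self):
        """Coefficient RMSE across replicates decreases as n grows."""
        truth = bc.ScenarioSpec(name="self_estimate").resolved_coefficients()
        rmses = []
        for n in (500, 2_000, 8_000):
            errs = []
            for rep in range(8):
                x, y, _ = bc.scenario_data(
                    bc.ScenarioSpec(name="self_estimate", n=n, seed=1000 * n + rep)
                )
                fit = bc.fit_mvlm(x, y)
                errs.append(np.mean((fit.B_hat.T - truth) ** 2))
            rmses.append(np.sqrt(np.mean(errs)))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError):
            bc.scenario_data(
                bc.ScenarioSpec(name="ideal", fat_muscle_cov=1.2, n=100, seed=1)
            )
        with pytest.raises(ValueError):
            bc.scenario_data(bc.ScenarioSpec(name="ideal", n=5, seed=1))


@pytest.fixture(scope="module")
def table():
    return bc.simpson_cohort(bc.SimpsonConfig(seed=6))


class TestSimpson:
    def test_stratified_counts(self, table):
        assert len(table) == 500
        assert table.groupby("band").size().tolist() == [100] * 5

    def test_bmi_within_bands(self, table):
        edges = bc.SimpsonConfig().band_edges
        for band, grp in table.groupby("band"):
            lo, hi = edges[band], edges[band + 1]
            assert np.all((grp["bmi"] >= lo) & (grp["bmi"] < hi))

    def test_paradox_sign_pattern(self, table):
        """Positive marginal association, negative within every BMI band."""
        overall, bands = bc.simpson_slopes(table)
        assert overall > 0
        assert len(bands) == 5 and all(b < 0 for b in bands)
        fat, mus = table["fat"].to_numpy(), table["muscle"].to_numpy()
        assert np.corrcoef(fat, mus)[0, 1] > 0

    def test_single_band_equals_overall(self, table):
        one = table.copy()
        one["band"] = 0
        overall, bands = bc.simpson_slopes(one)
        assert bands == [overall]

    def test_slopes_match_polyfit_oracle(self, table):
        overall, bands = bc.simpson_slopes(table)
        ref = np.polyfit(table["fat"], table["muscle"], 1)[0]
        assert overall == pytest.approx(ref, abs=1e-12)
        for band, grp in table.groupby("band"):
            ref_b = np.polyfit(grp["fat"], grp["muscle"], 1)[0]
            assert bands[band] == pytest.approx(ref_b, abs=1e-12)

    def test_determinism_and_validation(self):
        t1 = bc.simpson_cohort(bc.SimpsonConfig(seed=7))
        t2 = bc.simpson_cohort(bc.SimpsonConfig(seed=7))
        np.testing.assert_array_equal(t1.to_numpy(), t2.to_numpy())
        with pytest.raises(ValueError):
            bc.SimpsonConfig(band_edges=(20.0, 15.0)).validate()
        with pytest.raises(ValueError):
            bc.SimpsonConfig(n_per_band=1).validate()
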