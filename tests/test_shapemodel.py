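import numpy as np
import pytest

import bodycal as bc
from bodycal.shapemodel import CollinearityError, RangeError, predict_scores


def _fit(cohort, predictors=("fatm", "smm")):
    meshes, records, _ = cohort
    _, aligned, _ = bc.build_consensus(meshes)
    shapes = bc.flatten_cohort(aligned)
    return bc.fit_shape_model(shapes, records, predictors=predictors), shapes, records


def test_subspace_dimension_is_at_most_c_minus_1(fitted_model):
    model, shapes, _, _ = fitted_model
    assert model.n_components <= shapes.n_identities - 1
    # basis orthonormality
    np.testing.assert_allclose(
        model.basis.T @ model.basis, np.eye(model.n_components), atol=1e-8
    )


def test_variance_conservation(fitted_model):
    """Total PC variance equals total coordinate variance of the centred data."""
    model, shapes, _, _ = fitted_model
    centred = shapes.data - shapes.data.mean(axis=0)
    total = centred.var(axis=0, ddof=1).sum()
    assert model.pc_variances.sum() == pytest.approx(total, rel=1e-6)


def test_pca_matches_bruteforce_eigendecomposition():
    """Scores/loadings agree with explicit eigendecomposition of the covariance."""
    rng = np.random.default_rng(2)
    data = rng.normal(size=(7, 12))
    meshes = [
        bc.BodyMesh(f"i{k}", row.reshape(-1, 3)) for k, row in enumerate(data)
    ]
    shapes = bc.flatten_cohort(meshes, regions=("torso",))
    records = [
        bc.CompositionRecord(f"i{k}", "female", fatm=float(10 + k), smm=float(25 + (k % 3)))
        for k in range(7)
    ]
    model = bc.fit_shape_model(shapes, records)
    cov = np.cov(data, rowvar=False, ddof=1)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(model.pc_variances, evals[: model.n_components], atol=1e-9)
    # loadings span: each basis vector is an eigenvector of the covariance
    for j in range(model.n_components):
        v = model.basis[:, j]
        np.testing.assert_allclose(cov @ v, model.pc_variances[j] * v, atol=1e-8)


def test_noiseless_cohort_recovered_exactly(noiseless_cohort):
    """With linear ground truth and no noise, predictions match true shapes."""
    meshes, records, _ = noiseless_cohort
    _, aligned, _ = bc.build_consensus(meshes)
    shapes = bc.flatten_cohort(aligned)
    model = bc.fit_shape_model(shapes, records)
    for i, rec in enumerate(records):
        vec = bc.predict_vector(model, [rec.fatm, rec.smm], clamp="allow")
        rms = np.sqrt(np.mean((vec - shapes.data[i]) ** 2))
        assert rms < 1e-6


def test_training_identity_reconstructed_from_own_scores(fitted_model):
    """PCA completeness: full scores reproduce a training shape."""
    model, shapes, _, _ = fitted_model
    row = shapes.data[3]
    scores = model.basis.T @ (row - model.mean_vector)
    recon = model.mean_vector + model.basis @ scores
    assert np.sqrt(np.mean((recon - row) ** 2)) < 1e-6


def test_prediction_at_predictor_means_is_mean_shape(fitted_model):
    model, shapes, records, _ = fitted_model
    by_id = {r.identity_id: r for r in records}
    vals = np.mean(
        [[by_id[i].fatm, by_id[i].smm] for i in shapes.identity_ids], axis=0
    )
    vec = bc.predict_vector(model, vals)
    scale = np.abs(model.mean_vector).max()
    np.testing.assert_allclose(vec, model.mean_vector, atol=1e-9 * scale)


def test_clamp_policies(fitted_model, caplog):
    model, _, _, _ = fitted_model
    beyond = model.training_ranges[:, 1] + np.array([10.0, 10.0])
    at_max = model.training_ranges[:, 1]
    with caplog.at_level("WARNING", logger="bodycal"):
        clamped = bc.predict_vector(model, beyond)  # default clamp_warn
    assert any("clamping" in r.message for r in caplog.records)
    np.testing.assert_array_equal(clamped, bc.predict_vector(model, at_max))
    with pytest.raises(RangeError):
        bc.predict_vector(model, beyond, clamp="refuse")
    # allow extrapolates linearly, so it differs from the clamped result
    assert not np.allclose(bc.predict_vector(model, beyond, clamp="allow"), clamped)


def test_prediction_linearity(fitted_model):
    """predict(alpha a + (1-alpha) b) = alpha predict(a) + (1-alpha) predict(b)."""
    model, _, _, _ = fitted_model
    lo, hi = model.training_ranges[:, 0], model.training_ranges[:, 1]
    a = lo + 0.25 * (hi - lo)
    b = lo + 0.75 * (hi - lo)
    for alpha in (0.0, 0.3, 1.0):
        mix = bc.predict_vector(model, alpha * a + (1 - alpha) * b, clamp="allow")
        combo = alpha * bc.predict_vector(model, a, clamp="allow") + (
            1 - alpha
        ) * bc.predict_vector(model, b, clamp="allow")
        np.testing.assert_allclose(mix, combo, atol=1e-9 * np.abs(combo).max())


def test_morph_identity_and_reversibility(fitted_model):
    model, _, records, aligned = fitted_model
    person = aligned[2]
    rec = records[2]
    cur = [rec.fatm, rec.smm]
    same = bc.morph_individual(model, person, cur, cur)
    np.testing.assert_array_equal(same.vertices, person.vertices)
    target = [rec.fatm * 0.5, rec.smm]
    there = bc.morph_individual(model, person, cur, target, clamp="allow")
    back = bc.morph_individual(model, there, target, cur, clamp="allow")
    np.testing.assert_allclose(back.vertices, person.vertices, atol=1e-9)


def test_morph_of_mean_equals_prediction(fitted_model):
    """Morphing the mean shape from predictor means lands on predict_shape."""
    model, shapes, records, _ = fitted_model
    by_id = {r.identity_id: r for r in records}
    means = np.mean(
        [[by_id[i].fatm, by_id[i].smm] for i in shapes.identity_ids], axis=0
    )
    mean_mesh = bc.unflatten(model.mean_vector, model.topology, "mean")
    target = model.training_ranges[:, 0]
    morphed = bc.morph_individual(model, mean_mesh, means, target)
    predicted = bc.predict_shape(model, target)
    idx = model.topology.index_map
    np.testing.assert_allclose(
        morphed.vertices[idx], predicted.vertices[idx], atol=1e-8
    )


def test_bmi_only_model_is_same_code_path(small_cohort):
    model, shapes, _ = _fit(small_cohort, predictors=("bmi",))
    assert model.predictor_names == ["bmi"]
    assert model.coefficients.shape == (model.n_components, 2)
    vec = bc.predict_vector(model, [23.8])
    assert vec.shape == (shapes.data.shape[1],)


def test_insufficient_data_and_collinearity(small_cohort):
    meshes, records, _ = small_cohort
    shapes = bc.flatten_cohort(meshes[:3])
    with pytest.raises(ValueError, match="at least"):
        bc.fit_shape_model(shapes, records[:3], predictors=("fatm", "smm"))
    shapes_full = bc.flatten_cohort(meshes)
    const = [
        bc.CompositionRecord(r.identity_id, r.sex, fatm=5.0, smm=r.smm)
        for r in records
    ]
    with pytest.raises(CollinearityError):
        bc.fit_shape_model(shapes_full, const, predictors=("fatm", "smm"))


def test_held_out_error_approaches_noise_floor():
    """RMS held-out point error tends to the sigma*sqrt(3) noise floor."""
    sigma = 0.3
    cfg = bc.SynthConfig(
        sex="female", n=40, noise_sd=sigma, jitter_rotation=0.0,
        jitter_translation=0.0, seed=21,
    )
    meshes, records, _ = bc.generate_cohort(cfg)
    _, aligned, _ = bc.build_consensus(meshes[:-1])
    shapes = bc.flatten_cohort(aligned)
    model = bc.fit_shape_model(shapes, records[:-1])
    held = bc.align_to_reference(meshes[-1], bc.unflatten(model.mean_vector, model.topology)).aligned
    vec = bc.predict_vector(model, [records[-1].fatm, records[-1].smm], clamp="allow")
    diff = vec - bc.flatten_mesh(held, model.topology)
    rms_point = np.sqrt(np.mean(np.sum(diff.reshape(-1, 3) ** 2, axis=1)))
    assert rms_point == pytest.approx(sigma * np.sqrt(3), rel=0.15)


def test_model_save_load_round_trip(tmp_path, fitted_model):
    model, _, _, _ = fitted_model
    path = model.save(tmp_path / "model.npz")
    back = bc.ShapeModel.load(path)
    np.testing.assert_array_equal(back.basis, model.basis)
    np.testing.assert_array_equal(back.coefficients, model.coefficients)
    assert back.predictor_names == model.predictor_names
    assert back.c == model.c
    np.testing.assert_array_equal(
        bc.predict_vector(back, [18.0, 26.0]), bc.predict_vector(model, [18.0, 26.0])
    )


def test_predict_scores_validates_input(fitted_model):
    model, _, _, _ = fitted_model
    with pytest.raises(ValueError):
        predict_scores(model, [1.0])  # wrong arity
    with pytest.raises(ValueError):
        predict_scores(model, [np.nan, 1.0])
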