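import numpy as np
import pytest

import bodycal as bc


@pytest.fixture
def tetrahedron():
    return bc.BodyMesh(
        "tet",
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        faces=np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default noisy synthetic cohort with rigid jitter (12 women)."""
    cfg = bc.SynthConfig(sex="female", n=12, seed=7)
    return bc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise- and jitter-free cohort: composition -> shape is exactly linear."""
    cfg = bc.SynthConfig(
        sex="male", n=10, noise_sd=0.0, jitter_rotation=0.0, jitter_translation=0.0, seed=5
    )
    return bc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_model(small_cohort):
    meshes, records, _ = small_cohort
    _, aligned, _ = bc.build_consensus(meshes)
    shapes = bc.flatten_cohort(aligned)
    model = bc.fit_shape_model(shapes, records)
    return model, shapes, records, aligned
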