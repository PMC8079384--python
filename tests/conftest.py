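import numpy as np
import pytest

from helixforce import group_residues
from helixforce import helix_model as hm
from helixforce import synthetic_helix as sh


def model_from_spec(spec: sh.IdealHelixSpec) -> hm.HelixModel:
    atoms, annotation = sh.generate_ideal_helix(spec)
    return hm.build_helix_model(group_residues(atoms, annotation), spec.helix_id)


@pytest.fixture
def ideal_spec() -> sh.IdealHelixSpec:
    return sh.IdealHelixSpec(n_residues=30, atoms_per_sidechain=3, jitter_sd=0.0, seed=11)


@pytest.fixture
def ideal_model(ideal_spec) -> hm.HelixModel:
    return model_from_spec(ideal_spec)


@pytest.fixture
def random_rotation():
    """Seeded random proper rotation matrix factory."""

    def make(seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )

    return make
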