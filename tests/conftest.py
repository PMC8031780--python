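import logging

import numpy as np
import pytest

from secgeom.config import default_config
from secgeom.docking import GateDefinition
from secgeom.synthetic import BundleBlueprint, HelixBlueprint, make_bundle

logging.getLogger("secgeom").setLevel(logging.ERROR)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def channel_blueprint(radius: float = 9.0, n_residues: int = 22) -> BundleBlueprint:
    """Four pore-lining helices on a circle, residue-numbered like the channel."""
    helices = []
    for i, (name, first) in enumerate([("TM2", 83), ("TM5", 181), ("TM7", 292), ("TM10", 447)]):
        th = i * np.pi / 2
        helices.append(
            HelixBlueprint(name, "A", first, n_residues, (0, 0, 1),
                           (radius * np.cos(th), radius * np.sin(th), 0.0))
        )
    return BundleBlueprint(helices=tuple(helices))


@pytest.fixture(scope="session")
def channel_bundle():
    """(model, enumeration ground truth) of the four-helix channel stand-in."""
    return make_bundle(channel_blueprint())


@pytest.fixture(scope="session")
def gate(channel_bundle):
    cfg = default_config()
    return GateDefinition(cfg.regions["gate_cTM2"], cfg.regions["gate_nTM7"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
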