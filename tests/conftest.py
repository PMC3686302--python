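import numpy as np
import pytest

import metathread as mt


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20130619)


@pytest.fixture
def zinc_target():
    """A 60-residue helical target with a zinc ion 3 A off residue 30."""
    target = mt.make_toy_structure(60, "helix", seed=3, struct_id="tgt")
    site = target.ca_coords[30] + np.array([3.0, 0.0, 0.0])
    target.het_groups.append(
        mt.BoundPartner(
            aspect=mt.BindingAspect.METAL, atoms=site[None, :], element="Zn", name="ZN"
        )
    )
    return target
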