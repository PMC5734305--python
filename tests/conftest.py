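import numpy as np
import pytest

from coilforge import build_assembly, place_sidechains
from coilforge.builder import basic_spec

CANONICAL_SEQ = "EIAALKQ" * 4       # g a b c d e f: Ile@a, Leu@d
CANONICAL_REG = "gabcdef" * 4


@pytest.fixture(scope="session")
def canonical_dimer_spec():
    return basic_spec(2, 4.9, -180.0, 26.0, CANONICAL_SEQ, CANONICAL_REG)


@pytest.fixture(scope="session")
def dimer_backbone(canonical_dimer_spec):
    model, report = build_assembly(canonical_dimer_spec)
    assert not report.warnings
    return model


@pytest.fixture(scope="session")
def dimer_allatom(dimer_backbone):
    return place_sidechains(dimer_backbone)


@pytest.fixture()
def rotation_matrix():
    """A fixed, arbitrary proper rotation."""
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("xyz", [31.0, -47.0, 112.0],
                               degrees=True).as_matrix()


def rmsd(model_a, model_b):
    xa = np.vstack([list(r.atoms.values())
                    for c in model_a.chains for r in c.residues])
    xb = np.vstack([list(r.atoms.values())
                    for c in model_b.chains for r in c.residues])
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
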