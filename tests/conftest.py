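import numpy as np
import pytest

from macroioncg.system import (SP_COUNTERION, SP_SOLVENT, Configuration)


def free_config(positions, charges=None, box=60.0, velocities=None,
                masses=72.0):
    """Configuration of free (non-rigid) particles for small test systems."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    q = np.zeros(n) if charges is None else np.asarray(charges, float)
    v = np.zeros((n, 3)) if velocities is None else np.asarray(velocities, float)
    species = np.where(q != 0, SP_COUNTERION, SP_SOLVENT).astype(np.int8)
    return Configuration(box=float(box), positions=pos, velocities=v,
                         charges=q, species=species,
                         mol=np.full(n, -1, np.int32),
                         masses=np.full(n, float(masses)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
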