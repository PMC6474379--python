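import numpy as np
import pytest

from satspline import AtomicMeasure, KnotAtom, SplineModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def identity_scaling():
    def make(D: int) -> np.ndarray:
        return np.column_stack((np.zeros(D), np.ones(D)))

    return make


@pytest.fixture
def simple_model(identity_scaling):
    """Tent on [0.25, 0.75] rising to 0.25 then flat at 0.5: saturating."""
    measure = AtomicMeasure(
        [KnotAtom(0, 0.25, 1.0), KnotAtom(0, 0.75, -1.0)], D=1
    )
    return SplineModel(measure=measure, intercept=0.0, scaling=identity_scaling(1))


def random_saturating_measure(rng, D, atoms_per_coord=4):
    """Feasible random measure: per-coordinate weights exactly cancel in pairs."""
    atoms = []
    for d in range(D):
        ts = rng.uniform(0.02, 0.98, size=atoms_per_coord)
        mags = rng.uniform(0.2, 2.0, size=atoms_per_coord // 2)
        ws = np.empty(atoms_per_coord)
        ws[0::2] = mags
        ws[1::2] = -mags
        atoms.extend(KnotAtom(d, float(t), float(w)) for t, w in zip(ts, ws))
    return AtomicMeasure(atoms, D)
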