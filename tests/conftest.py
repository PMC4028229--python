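import numpy as np
import pytest

from epioct import (NoiseModel, PhantomSpec, ScanGeometry, SessionSpec,
                    render_bscan, trace_boundaries)
from epioct.phantom import CorneaModel


@pytest.fixture(scope="session")
def reduced_geometry():
    return ScanGeometry().scaled(4)


@pytest.fixture(scope="session")
def noiseless_spec(reduced_geometry):
    return PhantomSpec(geometry=reduced_geometry, noise=NoiseModel().silent())


@pytest.fixture(scope="session")
def noisy_spec(reduced_geometry):
    return PhantomSpec(geometry=reduced_geometry)


@pytest.fixture(scope="session")
def flat_spec(reduced_geometry):
    """Uniform 52-µm layer below a flat front surface."""
    cornea = CorneaModel(anterior_radius_mm=np.inf,
                         coeff_temporal=0.0, coeff_nasal=0.0,
                         coeff_superior=0.0, coeff_inferior=0.0)
    return PhantomSpec(geometry=reduced_geometry, cornea=cornea,
                       noise=NoiseModel().silent())


@pytest.fixture(scope="session")
def noiseless_bscan(noiseless_spec):
    return render_bscan(noiseless_spec, SessionSpec(), seed=0)


@pytest.fixture(scope="session")
def noiseless_traces(noiseless_bscan):
    return trace_boundaries(noiseless_bscan)


@pytest.fixture(scope="session")
def noisy_bscan(noisy_spec):
    return render_bscan(noisy_spec, SessionSpec(), seed=42)


@pytest.fixture(scope="session")
def vertical_bscan(noisy_spec):
    return render_bscan(noisy_spec, SessionSpec(meridian="vertical"), seed=43)
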