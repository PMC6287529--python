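import numpy as np
import pytest

from hookdetect.curve import AmplificationCurve
from hookdetect.synth import write_rdml_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def simple_curves():
    """Two small deterministic curves on a shared 45-cycle grid."""
    x = np.arange(1, 46, dtype=float)
    sig = 0.1 + 1.0 / (1.0 + np.exp(-(x - 22) / 2.0))
    return [
        AmplificationCurve("A01", x, sig, sample_name="s1", detector="FAM"),
        AmplificationCurve("A02", x, 0.1 + 0.001 * x, sample_name="s2", detector="FAM"),
    ]


@pytest.fixture
def rdml_file(tmp_path, simple_curves):
    """Minimal zipped RDML with two reacts, written at test time."""
    path = tmp_path / "plate.rdml"
    write_rdml_fixture(simple_curves, path, zipped=True)
    return path
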