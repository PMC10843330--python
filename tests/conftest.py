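import numpy as np
import pytest

from wingrheo.rheology import MechanicalParams, RelaxationParams
from wingrheo.synthetic import GenotypeScenario


@pytest.fixture
def midband_params() -> RelaxationParams:
    """Recoil parameters at the midpoints of the measured bands."""
    return RelaxationParams(X_f=2.2, X_s=7.0, tau_f=0.65, tau_s=20.0)


@pytest.fixture
def scenario() -> GenotypeScenario:
    return GenotypeScenario.default()


def random_mechanics(rng: np.random.Generator) -> MechanicalParams:
    """Log-uniform draw of a valid mechanical parameter set."""
    u = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return MechanicalParams(
        sigma=u(1, 50),
        k=u(0.1, 10),
        kf=u(1, 50),
        ks=u(0.1, 5),
        eta_f=u(0.5, 20),
        eta_s=u(5, 200),
    )


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0), phase: float = 0.0):
    ang = 2 * np.pi * np.arange(n) / n + phase
    return np.c_[radius * np.cos(ang), radius * np.sin(ang)] + np.asarray(center)


def ellipse_polygon(a: float, b: float, n: int = 720, center=(0.0, 0.0), theta: float = 0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.c_[a * np.cos(t), b * np.sin(t)]
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + np.asarray(center)
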