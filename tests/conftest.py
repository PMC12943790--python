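import numpy as np
import pytest

from saltscreen import CrystallinePhase, Role, load_case
from saltscreen.constants import R


@pytest.fixture(scope="session")
def case1():
    return load_case("case1_4ClMA_CHEA")


@pytest.fixture(scope="session")
def case2():
    return load_case("case2_2ClMA_CHEA")


@pytest.fixture(scope="session")
def case3():
    return load_case("case3_2ClMA_pregabalin")


def make_phase(name="P", role=Role.OTHER_SALT, coords=(0.5, 0.0, 0.5),
               t_fus=400.0, dh_fus=25000.0, **kw):
    return CrystallinePhase(name, role, coords, t_fus, dh_fus, **kw)


# ---------------------------------------------------------------------------
# Independent brute-force oracles.  These re-derive eutectics by direct
# temperature scans of the liquidus equations, written from the closed forms
# alone, with no use of the package's solvers.

def svl_x(T, t_fus, dh_fus):
    return np.exp(dh_fus / R * (1.0 / t_fus - 1.0 / T))


def scan_simple_eutectic(phase_a, phase_b, dT=0.001):
    """Grid-scan temperature minimizing |x_A + x_B - 1| on a dT grid."""
    hi = min(phase_a.t_fus, phase_b.t_fus) - 1e-6
    T = np.arange(1.0, hi, dT)
    resid = (
        svl_x(T, phase_a.t_fus, phase_a.dh_fus)
        + svl_x(T, phase_b.t_fus, phase_b.dh_fus)
        - 1.0
    )
    i = int(np.argmin(np.abs(resid)))
    return T[i], svl_x(T[i], phase_a.t_fus, phase_a.dh_fus)


def scan_side_eutectic(side, compound, dT=0.001):
    """Highest-T grid point where the side SVL branch meets the compound's
    Prigogine-Defay branch (residual sign change scanned from the top)."""
    hi = min(side.t_fus, compound.t_fus) - 1e-6
    T = np.arange(hi, 1.0, -dT)
    x = svl_x(T, side.t_fus, side.dh_fus)
    ok = x < 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(
            ok,
            np.log(4.0 * x * (1.0 - x))
            - compound.dh_fus / R * (1.0 / compound.t_fus - 1.0 / T),
            -np.inf,
        )
    finite = np.isfinite(g)
    sign_change = np.where(finite[:-1] & finite[1:] & (g[:-1] * g[1:] <= 0))[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    return T[i], x[i]


def scan_ternary_eutectic(phases, dT=0.001):
    hi = min(p.t_fus for p in phases) - 1e-6
    T = np.arange(1.0, hi, dT)
    resid = sum(svl_x(T, p.t_fus, p.dh_fus) for p in phases) - 1.0
    i = int(np.argmin(np.abs(resid)))
    return T[i]
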