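import numpy as np
import pytest

from leafgx import EnvironmentState, PhotoConstants
from leafgx.constants import gamma_star, michaelis_k
from leafgx.photosynthesis import net_assimilation, supply_rate


@pytest.fixture(scope="session")
def constants():
    return PhotoConstants()


@pytest.fixture(scope="session")
def ref_env():
    """Reference temperate growth environment used by the bundled scenarios."""
    return EnvironmentState(temp_c=25.0, vpd=1000.0, ca_ppm=400.0,
                            ppfd=800.0, patm=101325.0)


def bisect_ci_oracle(gs_co2, env, vcmax, j, constants, iters=80):
    """Independent vectorised bisection solver for the supply-demand c_i.

    Deliberately avoids the package's Brent-based ``solve_ci`` code path:
    plain interval bisection on the (monotone) residual, vectorised over
    an array of conductances.
    """
    gs_co2 = np.atleast_1d(np.asarray(gs_co2, dtype=float))
    gstar = gamma_star(env.temp_c, env.patm, constants)
    lo = np.full_like(gs_co2, gstar + 1e-9)
    hi = np.full_like(gs_co2, env.ca_pa)

    def residual(ci):
        a = np.array([net_assimilation(c, vcmax, j, constants, env.temp_c,
                                       env.patm).a_net for c in ci])
        return a - gs_co2 * (env.ca_pa - ci) / env.patm * 1e6

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        lo = np.where(r < 0, mid, lo)
        hi = np.where(r < 0, hi, mid)
    return 0.5 * (lo + hi)
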