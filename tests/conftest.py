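import numpy as np
import pytest

from combopd import DesignSpec, Regimen
from combopd import reference as ref


@pytest.fixture(scope="session")
def jimt1_pd():
    return ref.PD_PARAMS["JIMT-1"]


@pytest.fixture(scope="session")
def mda_pd():
    return ref.PD_PARAMS["MDA-MB-468"]


@pytest.fixture(scope="session")
def deg():
    return ref.DEGRADATION


@pytest.fixture(scope="session")
def noise_free_static_design():
    return DesignSpec(times=(72.0,), n_replicates=1, noise_cv=0.0)


@pytest.fixture(scope="session")
def small_regimen():
    """One 3-week cycle: keeps population/scenario tests fast."""
    return Regimen.q3w(n_cycles=1)


def rk4_oracle(params, deg, c0_dox, c0_dex, t_end, dt=0.01):
    """Independent fixed-step RK4 integration of the full PD system,
    including viability as an explicit state (the package solves the kill
    integral instead), for golden-trajectory comparisons."""
    psi = params.psi if (c0_dox > 0 and c0_dex > 0) else 1.0
    sc50_dox = params.dox.sc50 * psi
    sc50_dex = params.dex.sc50 * (psi if params.psi_on == "both" else 1.0)

    def f(t, y):
        k1d, k2d, k3d, k1x, k2x, k3x, r = y
        cd = c0_dox * np.exp(-deg.kdeg_dox * t)
        cx = c0_dex * np.exp(-deg.kdeg_dex * t)
        kd = params.dox.smax * cd / (sc50_dox + cd)
        kx = params.dex.smax * cx / (sc50_dex + cx)
        itd, itx = 1.0 / params.dox.tau, 1.0 / params.dex.tau
        return np.array([
            itd * (kd - k1d), itd * (k1d - k2d), itd * (k2d - k3d),
            itx * (kx - k1x), itx * (k1x - k2x), itx * (k2x - k3x),
            params.kg * r - (k3d + k3x) * r,
        ])

    n = int(round(t_end / dt))
    y = np.array([0, 0, 0, 0, 0, 0, params.r0], dtype=float)
    ts = [0.0]
    rs = [params.r0]
    t = 0.0
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        ts.append(t)
        rs.append(y[6])
    return np.array(ts), np.array(rs)
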