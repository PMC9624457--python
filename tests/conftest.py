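import numpy as np
import pytest

from poppkgx import (
    ErrorModel,
    PKDataset,
    PopPKModel,
    RandomEffectsSpec,
    StructuralParams,
)
from poppkgx.synth import (
    SimulationDesign,
    default_truth_model,
    simulate_pk,
    simulate_subjects,
)


@pytest.fixture(scope="session")
def toy_params() -> StructuralParams:
    return StructuralParams(CL=0.732, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, F=1.0, NN=4)


@pytest.fixture(scope="session")
def truth_model() -> PopPKModel:
    return default_truth_model()


@pytest.fixture(scope="session")
def bsv_only_truth() -> PopPKModel:
    m = default_truth_model()
    m.re.bov = {}
    return m


@pytest.fixture(scope="session")
def small_intensive_data(bsv_only_truth) -> PKDataset:
    """12 intensively sampled subjects simulated from the truth model."""
    design = SimulationDesign(n_intensive=12, n_sparse=0, fraction_ungenotyped=0.0)
    subjects = simulate_subjects(12, seed=101)
    return simulate_pk(design, bsv_only_truth, subjects, None, seed=102)


def ode_profile(params: StructuralParams, doses, times) -> np.ndarray:
    """Brute-force stiff-ODE integration of the full transit-chain system.

    Independent oracle for the closed-form solution: integrates the
    NN + 3 compartment amounts piecewise between dose events with LSODA
    at tight tolerance.
    """
    from scipy.integrate import solve_ivp

    p = params
    NN = p.NN
    k10, k12, k21 = p.CL / p.Vc, p.Q / p.Vc, p.Q / p.Vp
    ktr = (NN + 1) / p.MTT

    def rhs(t, x):
        dx = np.zeros(NN + 3)
        dx[0] = -ktr * x[0]
        for i in range(1, NN):
            dx[i] = ktr * (x[i - 1] - x[i])
        dx[NN] = ktr * x[NN - 1] - p.ka * x[NN]
        dx[NN + 1] = p.ka * x[NN] - (k10 + k12) * x[NN + 1] + k21 * x[NN + 2]
        dx[NN + 2] = k12 * x[NN + 1] - k21 * x[NN + 2]
        return dx

    times = np.asarray(times, float)
    events = sorted(doses, key=lambda d: d.time)
    bounds = sorted({d.time for d in events})
    tend = float(max(times.max(), bounds[-1]))
    out = np.zeros(times.size)
    x = np.zeros(NN + 3)
    cur = 0.0
    for i, t0 in enumerate(times):
        if t0 < bounds[0]:
            out[i] = 0.0
    for b in bounds + [tend + 1.0]:
        if b > cur:
            t_eval = sorted({t for t in times if cur <= t < b} | {min(b, tend + 1.0)})
            sol = solve_ivp(rhs, (cur, min(b, tend + 1.0)), x, method="LSODA",
                            rtol=1e-11, atol=1e-13, t_eval=t_eval)
            for tt, col in zip(sol.t, sol.y.T):
                hit = np.isclose(times, tt, rtol=0, atol=1e-12)
                out[hit] = col[NN + 1] / p.Vc
            x = sol.y[:, -1]
            cur = sol.t[-1]
        for d in events:
            if abs(d.time - cur) < 1e-12:
                x[0] += p.F * d.amount
        if cur > tend:
            break
    return out
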