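import numpy as np
import pytest

from protdyn import (
    ErrorModel,
    KineticParameters,
    MrnaTrajectory,
    ProteinTrajectory,
    SimulationConfig,
    TimeGrid,
    simulate_gene,
)


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def err() -> ErrorModel:
    return ErrorModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


def random_mrna(rng, grid, gene_id="g") -> MrnaTrajectory:
    """A random but realistic positive mRNA trajectory."""
    u = rng.uniform(1.0, 100.0, size=len(grid))
    return MrnaTrajectory(gene_id, u, grid)


@pytest.fixture()
def production_gene(grid, sim_config):
    """One noise-free synthetic production gene with its ground truth."""
    gen = np.random.default_rng(7)
    u, y, record = simulate_gene("production", sim_config, gen)
    mrna = MrnaTrajectory("prod0", u, grid)
    protein = ProteinTrajectory("prod0", y, grid)
    return mrna, protein, record


def ode_oracle(params: KineticParameters, mrna: MrnaTrajectory, eval_times):
    """Adaptive Runge-Kutta integration of the kinetic ODE, used as an oracle.

    Integrates segment by segment between the kinks of the piecewise-linear
    input (and the translation-onset time), so the integrator never steps
    over a derivative discontinuity.
    """
    from scipy.integrate import solve_ivp

    t = np.asarray(mrna.grid.times)
    brk = set(t)
    if 0.0 < params.tau < t[-1] and params.variant == "delayed_production":
        brk.add(params.tau)
    brk = sorted(brk)
    eval_times = np.asarray(eval_times, dtype=float)

    def rhs(tt, yy):
        active = params.variant != "delayed_production" or tt >= params.tau
        u = np.interp(tt, t, mrna.values)
        return params.alpha * (1.0 if active else 0.0) * u - params.lambda_ * yy

    out = {t[0]: params.y0}
    y = params.y0
    for a, b in zip(brk[:-1], brk[1:]):
        te = sorted({x for x in eval_times if a < x <= b} | {b})
        sol = solve_ivp(rhs, (a, b), [y], t_eval=te, rtol=1e-10, atol=1e-14)
        out.update(zip(sol.t, sol.y[0]))
        y = sol.y[0][-1]
    return np.array([out[tt] for tt in eval_times])


def random_params(rng, variant: str) -> KineticParameters:
    """Log-uniform parameter draw inside the fitting boxes."""
    kw = {"y0": 10 ** rng.uniform(-1, np.log10(5e3))}
    if variant != "stationary":
        kw["lambda_"] = 10 ** rng.uniform(np.log10(np.log(2) / 1e3), np.log10(np.log(2) / 1e-1))
    if variant in ("production", "delayed_production"):
        kw["alpha"] = 10 ** rng.uniform(-5, -1)
    if variant == "delayed_production":
        kw["tau"] = 10 ** rng.uniform(-5, 1)
    return KineticParameters(variant=variant, **kw)
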