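"""Synthetic batch-fermentation generator.

Produces time courses with the kinetic structure the downstream analysis
assumes, so the whole pipeline is testable without wet-lab data.  The model
is the minimal textbook structure for an anaerobic yeast batch culture:

* Monod growth, optionally damped by Andrews/Haldane substrate inhibition
  and by a product-toxicity factor::

      mu(S, P) = f_stress * mu_max * S/(Ks + S)
                 * [1 / (1 + S/Ki)]            (if Ki given)
                 * [max(0, 1 - P/P_crit)^n]    (if P_crit given)

* Luedeking–Piret product formation ``dP/dt = (alpha*mu + beta*f_stress)*X``
  (growth-associated plus non-growth-associated terms),

* substrate balance ``dS/dt = -dX/dt / Yxs - dP/dt / Yps - m_s*X`` with S
  clamped at zero; once S = 0 every rate is forced to zero.

Environmental stress (pH, salinity) enters as a single multiplier
``f_stress`` in [0, 1]: the product of a cardinal-pH term (zero at the pH
limits, one at the optimum) and a salinity term that declines exponentially
away from the salinity optimum on the molar-NaCl axis.

Measurement noise is multiplicative log-normal with mean 1 and a stated
coefficient of variation, applied after integration so noise-free dynamics
remain available for exact checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .timecourse import Condition, TimeCourse, salinity_molar

__all__ = [
    "SimParams",
    "StressParams",
    "SimulationError",
    "ze75_preset",
    "stress_factor",
    "simulate_batch",
    "add_noise",
    "generate_study",
]

# Integrator tolerances: tight enough that mass-balance residuals on
# noise-free runs stay below 1e-6 * s0.
_RTOL = 1e-8
_ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails for a parameter set."""


@dataclass(frozen=True)
class SimParams:
    """Generative kinetic parameters for one batch simulation.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate, 1/h.
    ks : float
        Monod half-saturation constant for growth, g/L.
    alpha : float
        Growth-associated product coefficient, g ethanol / g biomass.
    beta : float
        Non-growth-associated product coefficient, g ethanol/(g biomass h).
    y_xs : float
        Biomass-on-substrate yield, g/g, in (0, 1].
    y_ps : float
        Product-on-substrate yield, g/g, in (0, 1].
    m_s : float
        Maintenance coefficient, g substrate/(g biomass h).
    ki : float or None
        Andrews/Haldane substrate-inhibition constant, g/L; ``None`` disables
        substrate inhibition.
    p_crit : float or None
        Ethanol concentration at which growth ceases, g/L; ``None`` disables
        product inhibition.
    n_tox : float
        Product-inhibition exponent (used only when ``p_crit`` is set).
    x0, s0 : float
        Inoculum biomass and initial substrate, g/L.
    t_end, dt_out : float
        Simulation horizon and output sampling interval, h.
    noise_cv : float
        Coefficient of variation of the multiplicative measurement noise;
        0 means noise-free output.
    seed : int
        Random seed for the noise draws.
    """

    mu_max: float
    ks: float
    alpha: float = 0.0
    beta: float = 0.0
    y_xs: float = 0.5
    y_ps: float = 0.51
    m_s: float = 0.0
    ki: float | None = None
    p_crit: float | None = None
    n_tox: float = 1.0
    x0: float = 0.5
    s0: float = 150.0
    t_end: float = 72.0
    dt_out: float = 2.0
    noise_cv: float = 0.0
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if not self.mu_max > 0:
            out.append("mu_max must be > 0")
        if not self.ks > 0:
            out.append("ks must be > 0")
        if not 0 < self.y_xs <= 1:
            out.append("y_xs must lie in (0, 1]")
        if not 0 < self.y_ps <= 1:
            out.append("y_ps must lie in (0, 1]")
        if not self.x0 > 0:
            out.append("x0 must be > 0")
        if not self.s0 > 0:
            out.append("s0 must be > 0")
        if self.noise_cv < 0:
            out.append("noise_cv must be >= 0")
        if self.alpha < 0 or self.beta < 0 or self.m_s < 0:
            out.append("alpha, beta and m_s must be >= 0")
        if self.ki is not None and not self.ki > 0:
            out.append("ki must be > 0 when present")
        if self.p_crit is not None:
            if not self.p_crit > 0:
                out.append("p_crit must be > 0 when present")
            if not self.n_tox > 0:
                out.append("n_tox must be > 0 when p_crit is present")
        if not self.t_end > 0 or not 0 < self.dt_out <= self.t_end:
            out.append("need t_end > 0 and 0 < dt_out <= t_end")
        return out


@dataclass(frozen=True)
class StressParams:
    """Cardinal-pH and salinity stress model.

    The pH term is the three-parameter cardinal model
    ``(ph-ph_min)(ph-ph_max) / [(ph-ph_min)(ph-ph_max) - (ph-ph_opt)^2]``,
    zero outside [ph_min, ph_max] and one at the optimum.  The salinity term
    is ``exp(-sal_decay * max(0, m - sal_opt))`` above the optimum and
    ``exp(-sal_decay_hypo * max(0, sal_opt - m))`` below it, on the molar
    NaCl axis (labels mapped via the time-course module).  A marine isolate
    grows best at seawater strength, so sub-seawater media carry a mild
    penalty and hypersaline media a steep one.
    """

    ph_min: float = 2.5
    ph_opt: float = 4.5
    ph_max: float = 8.0
    sal_opt: float = 0.6
    sal_decay: float = 0.5
    sal_decay_hypo: float = 0.22

    def violations(self) -> list[str]:
        out = []
        if not self.ph_min < self.ph_opt < self.ph_max:
            out.append("need ph_min < ph_opt < ph_max")
        if self.sal_decay < 0 or self.sal_decay_hypo < 0:
            out.append("salinity decay rates must be >= 0")
        return out


def ze75_preset(substrate_inhibition: bool = False, **overrides) -> SimParams:
    """Default parameter set emulating a strongly fermentative marine yeast.

    The growth law uses ``mu_max = 0.141 /h`` and ``Ks = 24.40 g/L``; the
    remaining constants are calibrated so that a 150 g/L glucose batch over
    72 h lands near peak ethanol ~90 g/L, peak biomass ~9 g/L, volumetric
    productivity ~1.25 g/(L h) and substrate uptake ~2 g/(L h).  Growth is
    halted by product toxicity well before substrate exhaustion, after which
    the non-growth-associated term carries production to ~72 h.

    With ``substrate_inhibition=True`` a Haldane constant is added so that
    the ethanol optimum across initial glucose 50-250 g/L is interior
    (production declines again above ~175 g/L).
    """
    params = SimParams(
        mu_max=0.141,
        ks=24.40,
        alpha=3.93,
        beta=0.125,
        y_xs=0.72,
        y_ps=0.66,
        m_s=0.0,
        ki=650.0 if substrate_inhibition else None,
        p_crit=80.5,
        n_tox=2.0,
        x0=0.5,
        s0=150.0,
        t_end=72.0,
        dt_out=2.0,
        noise_cv=0.02,
        seed=0,
    )
    return replace(params, **overrides) if overrides else params


def stress_factor(
    ph: float | None, salinity: float | str, stress: StressParams
) -> float:
    """Combined pH x salinity growth-capacity multiplier in [0, 1].

    ``ph=None`` is treated as the optimum (condition with pH not recorded).
    """
    bad = stress.violations()
    if bad:
        raise ValueError("; ".join(bad))
    if ph is None:
        f_ph = 1.0
    elif ph <= stress.ph_min or ph >= stress.ph_max:
        f_ph = 0.0
    else:
        num = (ph - stress.ph_min) * (ph - stress.ph_max)
        den = num - (ph - stress.ph_opt) ** 2
        f_ph = 0.0 if den == 0.0 else min(1.0, max(0.0, num / den))
    m = salinity_molar(salinity)
    if m >= stress.sal_opt:
        f_sal = math.exp(-stress.sal_decay * (m - stress.sal_opt))
    else:
        f_sal = math.exp(-stress.sal_decay_hypo * (stress.sal_opt - m))
    return f_ph * f_sal


def _simulate_states(params: SimParams, f_stress: float):
    """Integrate the batch ODE system; return (times, X, P, S) noise-free."""
    p = params
    n_out = int(round(p.t_end / p.dt_out))
    t_eval = np.linspace(0.0, n_out * p.dt_out, n_out + 1)
    t_eval = t_eval[t_eval <= p.t_end + 1e-12]

    def mu_of(S: float, P: float) -> float:
        if S <= 0:
            return 0.0
        mu = f_stress * p.mu_max * S / (p.ks + S)
        if p.ki is not None:
            mu /= 1.0 + S / p.ki
        if p.p_crit is not None:
            mu *= max(0.0, 1.0 - P / p.p_crit) ** p.n_tox
        return mu

    def rhs(t, y):
        X, P, S = y
        if S <= 0 or X <= 0:
            return (0.0, 0.0, 0.0)
        mu = mu_of(S, P)
        dX = mu * X
        dP = (p.alpha * mu + p.beta * f_stress) * X
        dS = -dX / p.y_xs - dP / p.y_ps - p.m_s * X
        return (dX, dP, dS)

    def substrate_exhausted(t, y):
        return y[2]

    substrate_exhausted.terminal = True
    substrate_exhausted.direction = -1.0

    sol = solve_ivp(
        rhs,
        (0.0, p.t_end),
        (p.x0, 0.0, p.s0),
        method="LSODA",
        t_eval=t_eval,
        events=substrate_exhausted,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success and sol.status != 1:
        raise SimulationError(
            f"integration failed for params {params}: {sol.message}"
        )
    times = sol.t
    X, P, S = sol.y
    if sol.status == 1:  # substrate ran out: freeze the state afterwards
        y_end = sol.y_events[0][0]
        rest = t_eval[len(times):]
        times = np.concatenate([times, rest])
        X = np.concatenate([X, np.full(rest.shape, y_end[0])])
        P = np.concatenate([P, np.full(rest.shape, y_end[1])])
        S = np.concatenate([S, np.zeros(rest.shape)])
    S = np.clip(S, 0.0, None)
    return times, X, P, S


def simulate_batch(
    params: SimParams,
    condition: Condition,
    stress: StressParams = StressParams(),
) -> TimeCourse:
    """Simulate one batch fermentation under ``condition``.

    The condition supplies the stress inputs (pH, salinity) and the initial
    substrate (``condition.s_g0`` overrides ``params.s0``).  Noise with CV
    ``params.noise_cv`` is applied after integration using ``params.seed``;
    set ``noise_cv=0`` for the exact trajectory.
    """
    bad = params.violations() + stress.violations()
    if bad:
        raise ValueError("; ".join(bad))
    p = replace(params, s0=condition.s_g0)
    f = stress_factor(condition.ph, condition.salinity, stress)
    times, X, P, S = _simulate_states(p, f)
    tc = TimeCourse(condition=condition, times=times, biomass=X, ethanol=P,
                    substrate=S)
    if p.noise_cv > 0:
        tc = add_noise(tc, p.noise_cv, p.seed)
    return tc


def add_noise(tc: TimeCourse, noise_cv: float, seed: int) -> TimeCourse:
    """Multiply every concentration by independent log-normal noise.

    The noise distribution has mean 1 and coefficient of variation
    ``noise_cv`` (``sigma^2 = ln(1 + cv^2)``, ``mu = -sigma^2/2``), so
    expected concentrations are unchanged and values stay positive.  The
    same ``(tc, noise_cv, seed)`` always yields the same output;
    ``noise_cv=0`` returns the input unchanged.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv == 0:
        return tc
    sigma = math.sqrt(math.log1p(noise_cv**2))
    mu = -0.5 * sigma**2
    rng = np.random.default_rng(seed)

    def jitter(values: np.ndarray) -> np.ndarray:
        return values * rng.lognormal(mean=mu, sigma=sigma, size=values.shape)

    return replace(
        tc,
        biomass=jitter(tc.biomass),
        ethanol=jitter(tc.ethanol),
        substrate=None if tc.substrate is None else jitter(tc.substrate),
    )


def _cell_seed(seed: int, cell_index: int, rep: int) -> int:
    """Deterministic per-replicate seed from (study seed, cell, replicate)."""
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(int(cell_index), int(rep)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_study(
    base: SimParams,
    stress: StressParams,
    s0_grid: list[float],
    ph_grid: list[float],
    salinity_grid: list[float | str],
    replicates: int,
    seed: int,
) -> list[TimeCourse]:
    """Simulate a full factorial design s0 x pH x salinity with replicates.

    One :class:`TimeCourse` per grid cell per replicate; each replicate gets
    its own counter-derived seed so the whole collection is reproducible
    element-wise from ``seed`` alone.  Condition labels encode the cell.
    """
    if not (s0_grid and ph_grid and salinity_grid):
        raise ValueError("design grids must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    records: list[TimeCourse] = []
    cells = list(itertools.product(s0_grid, ph_grid, salinity_grid))
    for cell_index, (s0, ph, sal) in enumerate(cells):
        sal_label = sal if isinstance(sal, str) else f"{float(sal):g}M"
        cid = f"s0={s0:g}_ph={ph:g}_sal={sal_label}"
        for rep in range(1, replicates + 1):
            condition = Condition(
                condition_id=cid,
                carbon_source="glucose",
                s_g0=float(s0),
                salinity=sal,
                ph=float(ph),
                replicate=rep,
            )
            params = replace(base, s0=float(s0),
                             seed=_cell_seed(seed, cell_index, rep))
            records.append(simulate_batch(params, condition, stress))
    return records
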