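"""Monod saturation-model fitting of specific rates vs initial substrate.

The Monod law ``rate(S) = rate_max * S / (Ks + S)`` relates a microbial
specific rate (growth ``mu`` in 1/h, or ethanol production ``v`` in
g/(g h)) to substrate concentration; here the independent variable is the
*initial* substrate concentration of each batch, the classical shake-flask
design.  Fitting is non-linear least squares with positivity enforced by
optimising log-parameters; starting values come from the Hanes–Woolf
linearisation (regress S/rate on S), which is exact on noise-free Monod
data.  A parameter-recovery harness quantifies estimator bias and precision
under multiplicative rate noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .descriptors import InsufficientDataError, descriptor_table
from .timecourse import TimeCourse

__all__ = [
    "MonodFit",
    "monod",
    "initial_guess",
    "fit_monod",
    "rate_vs_substrate",
    "recovery_experiment",
]

_FTOL = 1e-10
_XTOL = 1e-10
_MAX_ITER = 500


@dataclass(frozen=True)
class MonodFit:
    """Result of a non-linear Monod fit.

    ``r2`` is 1 - SSE/SST about the mean rate (it can be negative for a fit
    worse than the mean, and is NaN when SST is zero).  ``se_rate_max`` and
    ``se_ks`` are asymptotic standard errors from the Jacobian at the
    optimum.  A non-converged fit is returned with ``converged=False`` rather
    than raised, so batch studies can proceed.
    """

    rate_max: float
    ks: float
    r2: float
    sse: float
    n: int
    converged: bool
    se_rate_max: float
    se_ks: float
    init_rate_max: float
    init_ks: float


def monod(s, rate_max: float, ks: float):
    """Monod rate law ``rate_max * s / (ks + s)`` (vectorised over ``s``)."""
    s = np.asarray(s, dtype=float)
    out = rate_max * s / (ks + s)
    return float(out) if out.ndim == 0 else out


def initial_guess(points) -> tuple[float, float]:
    """Starting values via the Hanes–Woolf linearisation.

    Regressing ``s/rate`` on ``s`` gives slope ``1/rate_max`` and intercept
    ``ks/rate_max``.  Exact on noise-free Monod data.  Falls back to
    ``(1.2 * max rate, median s)`` whenever the linearisation yields a
    non-positive estimate (e.g. perfectly flat saturated data).
    """
    pts = np.asarray(points, dtype=float)
    usable = pts[(pts[:, 0] > 0) & (pts[:, 1] > 0)]
    if len(usable) < 2 or len(np.unique(usable[:, 0])) < 2:
        raise InsufficientDataError(
            "need at least 2 points with distinct s > 0 and rate > 0"
        )
    s, rate = usable[:, 0], usable[:, 1]
    slope, intercept = np.polyfit(s, s / rate, 1)
    if slope > 0 and intercept > 0:
        return 1.0 / slope, intercept / slope
    return 1.2 * float(rate.max()), float(np.median(s))


def _r2(rate: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    sse = float(((rate - fitted) ** 2).sum())
    sst = float(((rate - rate.mean()) ** 2).sum())
    return (math.nan if sst == 0.0 else 1.0 - sse / sst), sse


def fit_monod(points, init: tuple[float, float] | None = None) -> MonodFit:
    """Least-squares Monod fit of ``(s, rate)`` points.

    Minimises ``sum (rate_i - monod(s_i))^2`` over positive ``(rate_max,
    ks)`` by optimising their logarithms (trust-region reflective, ftol =
    xtol = 1e-10, at most 500 iterations).  ``init`` defaults to
    :func:`initial_guess`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InsufficientDataError("need at least 3 (s, rate) points")
    if (pts < 0).any():
        raise ValueError("s and rate must be non-negative")
    s, rate = pts[:, 0], pts[:, 1]
    if init is None:
        init = initial_guess(pts)
    init_rate_max, init_ks = float(init[0]), float(init[1])

    def residuals(logp):
        rm, ks = np.exp(logp)
        return monod(s, rm, ks) - rate

    sol = least_squares(
        residuals,
        x0=np.log([init_rate_max, init_ks]),
        method="trf",
        ftol=_FTOL,
        xtol=_XTOL,
        gtol=None,
        max_nfev=_MAX_ITER,
    )
    rate_max, ks = (float(v) for v in np.exp(sol.x))
    fitted = monod(s, rate_max, ks)
    r2, sse = _r2(rate, fitted)
    # asymptotic SEs on the natural scale from the analytic Jacobian
    j1 = s / (ks + s)
    j2 = -rate_max * s / (ks + s) ** 2
    jac = np.column_stack([j1, j2])
    dof = len(s) - 2
    se1 = se2 = math.nan
    if dof > 0:
        try:
            cov = sse / dof * np.linalg.inv(jac.T @ jac)
            se1, se2 = (math.sqrt(max(c, 0.0)) for c in np.diag(cov))
        except np.linalg.LinAlgError:
            pass
    return MonodFit(
        rate_max=rate_max,
        ks=ks,
        r2=r2,
        sse=sse,
        n=len(s),
        converged=bool(sol.success),
        se_rate_max=se1,
        se_ks=se2,
        init_rate_max=init_rate_max,
        init_ks=init_ks,
    )


def rate_vs_substrate(
    records: list[TimeCourse],
    which: str = "growth",
    exclude_above_peak: bool = False,
) -> np.ndarray:
    """Replicate-averaged (s_g0, rate) points from a time-course collection.

    ``which="growth"`` uses the log-linear specific growth rate mu;
    ``which="production"`` uses the specific ethanol production summary v_g.
    Rates are averaged over replicates within each condition, then paired
    with the condition's initial substrate.  With ``exclude_above_peak`` the
    points beyond the rate-maximising s_g0 are dropped, so a Haldane-type
    decline does not distort the saturation fit; the default keeps all
    points.
    """
    if which not in ("growth", "production"):
        raise ValueError("which must be 'growth' or 'production'")
    table = descriptor_table(records)
    means = table[table["stat"] == "mean"]
    col = "mu" if which == "growth" else "v_g"
    pts = (
        means.groupby("s_g0", sort=True)[col].mean().reset_index().to_numpy()
    )
    if len(np.unique(pts[:, 0])) < 3:
        raise InsufficientDataError("need at least 3 distinct s_g0 levels")
    if exclude_above_peak:
        k = int(np.argmax(pts[:, 1]))
        pts = pts[: k + 1]
    return pts


def recovery_experiment(
    true_rate_max: float,
    true_ks: float,
    s_grid,
    noise_cv: float,
    n_rep: int,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo parameter-recovery study for the Monod fit.

    For each replicate, rates are the true Monod values perturbed by
    multiplicative log-normal noise (mean 1, CV ``noise_cv``; replicate
    seeds derived deterministically from ``seed``), then refitted.  Returns
    the per-replicate table and a summary with per-parameter median bias
    (relative), RMSE and median r2.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    s = np.asarray(s_grid, dtype=float)
    truth = monod(s, true_rate_max, true_ks)
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    mu = -0.5 * sigma**2
    rows = []
    for rep in range(n_rep):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(rep,))
        rng = np.random.default_rng(ss)
        rates = truth if noise_cv == 0 else truth * rng.lognormal(mu, sigma, truth.shape)
        fit = fit_monod(np.column_stack([s, rates]))
        rows.append(
            {"replicate": rep + 1, "rate_max": fit.rate_max, "ks": fit.ks,
             "r2": fit.r2, "converged": fit.converged}
        )
    df = pd.DataFrame(rows)
    summary = {
        "median_bias_rate_max": float(
            np.median(df["rate_max"] / true_rate_max - 1.0)
        ),
        "median_bias_ks": float(np.median(df["ks"] / true_ks - 1.0)),
        "rmse_rate_max": float(
            np.sqrt(np.mean((df["rate_max"] - true_rate_max) ** 2))
        ),
        "rmse_ks": float(np.sqrt(np.mean((df["ks"] - true_ks) ** 2))),
        "median_r2": float(df["r2"].median()),
        "n_rep": n_rep,
    }
    return df, summary
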