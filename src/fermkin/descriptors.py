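"""Per-condition kinetic summary descriptors for batch fermentations.

For a time course with biomass X(t), ethanol P(t) and optional substrate
S(t), the summary quantities are:

==========  =====================================================  =========
symbol      definition                                             units
==========  =====================================================  =========
E_p         max P(t) (peak ethanol)                                g/L
t_peak      earliest time attaining E_p                            h
X_m         max X(t) (peak dry biomass)                            g/L
Y_P/S       E_p / S_G0 (yield on *initial* substrate)              g/g
Y_X/S       X_m / S_G0                                             g/g
Q_p         E_p / t_peak (volumetric ethanol productivity)         g/(L h)
Q_s         (S(0) - S(t_peak)) / t_peak (average substrate uptake) g/(L h)
v_g         Q_p / X_m (specific ethanol production, summary)       g/(g h)
v_peak      max over t of (dP/dt)/X (pointwise specific rate)      g/(g h)
mu          slope of ln X vs t over the best exponential window    1/h
==========  =====================================================  =========

Yields are deliberately based on the substrate *supplied*, not consumed, and
``v_g = Q_p / X_m`` is the summary form of the specific production rate; the
pointwise Eq.-style maximum is exposed separately as ``v_peak``.  The
specific growth rate is the classical log-linear estimate: the least-squares
slope of ln X against t over the contiguous window (>= 4 points, positive
slope) that maximises the coefficient of determination — an automated stand-in
for reading the exponential phase off a logarithmic plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .timecourse import TimeCourse, validate_timecourse

__all__ = [
    "KineticDescriptors",
    "DescriptorError",
    "UndefinedRateError",
    "InsufficientDataError",
    "yields",
    "volumetric_productivity",
    "substrate_uptake",
    "specific_production_series",
    "specific_production_summary",
    "specific_growth_rate",
    "compute_descriptors",
    "descriptor_table",
]


class DescriptorError(ValueError):
    """Base class for descriptor computation failures."""


class UndefinedRateError(DescriptorError):
    """A rate whose defining window collapses (e.g. peak at t = 0)."""


class InsufficientDataError(DescriptorError):
    """Too few usable points for the requested estimate."""


@dataclass(frozen=True)
class KineticDescriptors:
    """One condition's kinetic summary row."""

    condition_id: str
    replicate: int
    s_g0: float
    e_p: float
    t_peak: float
    x_m: float
    y_ps: float
    y_xs: float
    q_p: float
    q_s: float | None
    v_g: float
    v_peak: float
    mu: float
    mu_window: tuple[float, float] | None


def _check(tc: TimeCourse) -> None:
    problems = validate_timecourse(tc)
    if problems:
        raise DescriptorError(
            f"invalid time course ({tc.condition.condition_id!r}): "
            + "; ".join(problems)
        )


def yields(tc: TimeCourse) -> tuple[float, float]:
    """Ethanol and biomass coefficient yields on initial substrate:
    ``(Y_P/S, Y_X/S) = (max P / S_G0, max X / S_G0)`` in g/g."""
    _check(tc)
    s_g0 = tc.condition.s_g0
    if not s_g0 > 0:
        raise DescriptorError("initial substrate s_g0 must be > 0")
    return float(tc.ethanol.max() / s_g0), float(tc.biomass.max() / s_g0)


def _peak(tc: TimeCourse) -> tuple[float, float]:
    """(E_p, t_peak) with the earliest time attaining the maximum."""
    i = int(np.argmax(tc.ethanol))  # argmax returns the first maximum
    return float(tc.ethanol[i]), float(tc.times[i])


def volumetric_productivity(tc: TimeCourse) -> float:
    """Peak ethanol divided by the time it is first reached, g/(L h)."""
    _check(tc)
    e_p, t_peak = _peak(tc)
    if t_peak == 0.0:
        raise UndefinedRateError(
            "ethanol maximum attained only at t = 0; productivity undefined"
        )
    return e_p / t_peak


def substrate_uptake(tc: TimeCourse) -> float | None:
    """Average substrate consumption over [0, t_peak], g/(L h); ``None``
    when the record carries no substrate series."""
    _check(tc)
    if tc.substrate is None:
        return None
    e_p, t_peak = _peak(tc)
    if t_peak == 0.0:
        raise UndefinedRateError(
            "ethanol maximum attained only at t = 0; uptake window undefined"
        )
    i = int(np.argmax(tc.ethanol))
    return float((tc.substrate[0] - tc.substrate[i]) / t_peak)


def specific_production_series(tc: TimeCourse) -> np.ndarray:
    """Pointwise specific production rate v(t) = (dP/dt)/X, g/(g h).

    dP/dt uses central differences at interior points and one-sided
    differences at the ends (``numpy.gradient``); negative values are floored
    at zero.  Returns an array of (t, v) rows.
    """
    _check(tc)
    interior_zero = np.where(tc.biomass[1:-1] <= 0)[0]
    if interior_zero.size:
        t_bad = tc.times[1 + interior_zero[0]]
        raise DescriptorError(
            f"biomass is zero at interior time {t_bad} h; v(t) undefined"
        )
    dpdt = np.gradient(tc.ethanol, tc.times)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(tc.biomass > 0, dpdt / np.where(tc.biomass > 0, tc.biomass, 1.0), 0.0)
    v = np.clip(v, 0.0, None)
    return np.column_stack([tc.times, v])


def specific_production_summary(tc: TimeCourse) -> float:
    """Summary specific production rate ``v_g = Q_p / X_m``, g/(g h)."""
    _check(tc)
    x_m = float(tc.biomass.max())
    if x_m == 0.0:
        raise DescriptorError("maximum biomass is zero; v_g undefined")
    e_p, t_peak = _peak(tc)
    if e_p == 0.0:
        return 0.0
    return volumetric_productivity(tc) / x_m


def _window_regressions(logx: np.ndarray, t: np.ndarray, min_len: int = 4):
    """Yield (i, j, slope, r2) for every contiguous window of >= min_len."""
    n = len(t)
    for i in range(0, n - min_len + 1):
        for j in range(i + min_len, n + 1):
            tw = t[i:j]
            yw = logx[i:j]
            tbar = tw.mean()
            ybar = yw.mean()
            sxx = float(((tw - tbar) ** 2).sum())
            sxy = float(((tw - tbar) * (yw - ybar)).sum())
            syy = float(((yw - ybar) ** 2).sum())
            if sxx == 0.0 or syy == 0.0:
                continue
            slope = sxy / sxx
            r2 = (sxy * sxy) / (sxx * syy)
            yield i, j, slope, r2


def specific_growth_rate(
    tc: TimeCourse, min_points: int = 4
) -> tuple[float, tuple[float, float] | None]:
    """Log-linear specific growth rate and the window that produced it.

    Considers every contiguous run of at least ``min_points`` samples with
    X > 0, fits ln X ~ t by least squares, and keeps the positive-slope
    window with the highest R² (ties broken toward longer, then earlier,
    windows, so exactly exponential data report the full range).  Returns
    ``(0.0, None)`` when no positive-slope window exists.
    """
    _check(tc)
    positive = tc.biomass > 0
    if int(positive.sum()) < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} points with positive biomass "
            f"(got {int(positive.sum())})"
        )
    best: tuple[float, int, int, float] | None = None  # (r2, length, -start, slope)
    # scan each maximal contiguous run of positive biomass
    idx = np.where(positive)[0]
    runs = np.split(idx, np.where(np.diff(idx) != 1)[0] + 1)
    for run in runs:
        if len(run) < min_points:
            continue
        t = tc.times[run]
        logx = np.log(tc.biomass[run])
        for i, j, slope, r2 in _window_regressions(logx, t, min_points):
            if slope <= 0:
                continue
            key = (round(r2 / 1e-9) * 1e-9, j - i, -i)
            if best is None or key > (best[0], best[1], best[2]):
                best = (key[0], key[1], key[2], slope, t[i], t[j - 1])
    if best is None:
        return 0.0, None
    return float(best[3]), (float(best[4]), float(best[5]))


def compute_descriptors(tc: TimeCourse) -> KineticDescriptors:
    """All kinetic descriptors for one time course."""
    y_ps, y_xs = yields(tc)
    e_p, t_peak = _peak(tc)
    x_m = float(tc.biomass.max())
    q_p = volumetric_productivity(tc) if t_peak > 0 else 0.0
    q_s = substrate_uptake(tc)
    v_g = specific_production_summary(tc)
    v_series = specific_production_series(tc)
    v_peak = float(v_series[:, 1].max())
    try:
        mu, mu_window = specific_growth_rate(tc)
    except InsufficientDataError:
        mu, mu_window = 0.0, None
    return KineticDescriptors(
        condition_id=tc.condition.condition_id,
        replicate=tc.condition.replicate,
        s_g0=tc.condition.s_g0,
        e_p=e_p,
        t_peak=t_peak,
        x_m=x_m,
        y_ps=y_ps,
        y_xs=y_xs,
        q_p=q_p,
        q_s=q_s,
        v_g=v_g,
        v_peak=v_peak,
        mu=mu,
        mu_window=mu_window,
    )


_NUMERIC = ["e_p", "t_peak", "x_m", "y_ps", "y_xs", "q_p", "q_s", "v_g",
            "v_peak", "mu"]


def descriptor_table(records: list[TimeCourse]) -> pd.DataFrame:
    """Descriptor rows for every record plus per-condition mean/sd summaries.

    The returned frame has a ``stat`` column: ``"replicate"`` rows carry one
    record each; ``"mean"`` and ``"sd"`` rows summarise the replicates of each
    condition (sd is the ddof=1 sample standard deviation; 0 for n=1).
    Errors raised by component descriptors are annotated with the condition.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for tc in records:
        try:
            d = compute_descriptors(tc)
        except DescriptorError as exc:
            raise type(exc)(
                f"condition {tc.condition.condition_id!r} "
                f"replicate {tc.condition.replicate}: {exc}"
            ) from exc
        row = asdict(d)
        row.pop("mu_window")
        row["stat"] = "replicate"
        rows.append(row)
    df = pd.DataFrame(rows)
    summaries = []
    for cid, g in df.groupby("condition_id", sort=False):
        for stat in ("mean", "sd"):
            row = {"condition_id": cid, "replicate": len(g), "stat": stat,
                   "s_g0": g["s_g0"].iloc[0]}
            for col in _NUMERIC:
                vals = g[col].dropna()
                if vals.empty:
                    row[col] = np.nan
                elif stat == "mean":
                    row[col] = float(vals.mean())
                else:
                    row[col] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            summaries.append(row)
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
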