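"""Time-course data model and delimited-text I/O.

A batch fermentation experiment is recorded as a :class:`TimeCourse`: sampled
concentrations of biomass ``X(t)``, ethanol ``P(t)`` and (optionally) residual
substrate ``S(t)`` in g/L against time in hours, annotated with the culture
condition (carbon source, initial substrate, salinity, pH, replicate index).

The on-disk format is a single long ("tidy") CSV with one row per
(condition, replicate, timepoint) and the condition metadata repeated on each
row.  Salinity is a tagged value: either a molar NaCl concentration or one of
the water labels ``seawater``, ``half_seawater``, ``distilled``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "TimeCourse",
    "TimeCourseFormatError",
    "TimeCourseValidationError",
    "SALINITY_LABELS",
    "salinity_molar",
    "read_timecourses",
    "write_timecourses",
    "validate_timecourse",
]

#: Molar NaCl equivalents for the categorical water labels.  Natural seawater
#: holds roughly 35 g/L salt, i.e. about 0.6 M NaCl.
SALINITY_LABELS: dict[str, float] = {
    "seawater": 0.6,
    "half_seawater": 0.3,
    "distilled": 0.0,
}

#: Required CSV header columns, in canonical order.  ``glucose_g_per_L`` is
#: optional: descriptors that need a substrate series are reported absent
#: when it is missing.
REQUIRED_COLUMNS = (
    "condition_id",
    "carbon_source",
    "s_g0_g_per_L",
    "salinity",
    "ph",
    "replicate",
    "time_h",
    "biomass_g_per_L",
    "ethanol_g_per_L",
)
SUBSTRATE_COLUMN = "glucose_g_per_L"


class TimeCourseFormatError(ValueError):
    """Raised when a file does not conform to the expected layout."""


class TimeCourseValidationError(ValueError):
    """Raised when the data violate a time-course invariant."""


def salinity_molar(salinity: float | str) -> float:
    """Molar NaCl equivalent of a tagged salinity value.

    Numeric salinities pass through unchanged; the water labels map via
    :data:`SALINITY_LABELS`.
    """
    if isinstance(salinity, str):
        try:
            return SALINITY_LABELS[salinity]
        except KeyError:
            raise TimeCourseFormatError(
                f"unknown salinity label {salinity!r}; expected a molar "
                f"concentration or one of {sorted(SALINITY_LABELS)}"
            ) from None
    return float(salinity)


@dataclass(frozen=True)
class Condition:
    """Culture condition metadata for one fermentation.

    Parameters
    ----------
    condition_id
        Free-text label identifying the condition (e.g. an isolate name or a
        grid-cell label such as ``"ph4.5"``).
    s_g0
        Initial substrate concentration :math:`S_{G0}` in g/L; must be > 0.
    carbon_source
        Carbon source name (glucose, fructose, sucrose, maltose, lactose, ...).
    salinity
        Molar NaCl concentration (float, ≥ 0) or one of the labels in
        :data:`SALINITY_LABELS`.
    ph
        Initial medium pH; ``None`` when not recorded.
    replicate
        Positive replicate index.
    """

    condition_id: str
    s_g0: float
    carbon_source: str = "glucose"
    salinity: float | str = "distilled"
    ph: float | None = None
    replicate: int = 1

    def violations(self) -> list[str]:
        out: list[str] = []
        if not (self.s_g0 > 0):
            out.append(f"s_g0 must be > 0 (got {self.s_g0})")
        if self.ph is not None and not (0.0 <= self.ph <= 14.0):
            out.append(f"ph must lie in [0, 14] (got {self.ph})")
        if isinstance(self.salinity, str):
            if self.salinity not in SALINITY_LABELS:
                out.append(
                    f"salinity label {self.salinity!r} not one of "
                    f"{sorted(SALINITY_LABELS)}"
                )
        elif not (float(self.salinity) >= 0.0):
            out.append(f"molar salinity must be >= 0 (got {self.salinity})")
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            out.append(f"replicate must be a positive integer (got {self.replicate})")
        return out


@dataclass(frozen=True)
class TimeCourse:
    """One condition's sampled trajectory of biomass, ethanol and substrate.

    ``times`` must be strictly increasing, start at 0 and contain at least
    three points; all concentrations must be finite and non-negative; every
    series has the same length as ``times``.  ``substrate`` may be ``None``
    (residual sugar not assayed).
    """

    condition: Condition
    times: np.ndarray
    biomass: np.ndarray
    ethanol: np.ndarray
    substrate: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("times", "biomass", "ethanol"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.substrate is not None:
            object.__setattr__(self, "substrate", np.asarray(self.substrate, dtype=float))

    def __len__(self) -> int:
        return len(self.times)


def validate_timecourse(tc: TimeCourse) -> list[str]:
    """Return human-readable descriptions of every violated invariant.

    An empty list means the record conforms.  Violations name the offending
    field and, where applicable, the index of the first offending sample.
    """
    out = list(tc.condition.violations())
    t = tc.times
    if len(t) < 3:
        out.append(f"times must contain at least 3 points (got {len(t)})")
    if len(t) and t[0] != 0.0:
        out.append(f"times must start at 0 (got {t[0]})")
    if len(t) > 1:
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            i = int(bad[0])
            out.append(
                f"times must be strictly increasing (violation at index {i + 1}: "
                f"{t[i]} -> {t[i + 1]})"
            )
    series = {"biomass": tc.biomass, "ethanol": tc.ethanol}
    if tc.substrate is not None:
        series["substrate"] = tc.substrate
    for name, values in series.items():
        if len(values) != len(t):
            out.append(
                f"{name} length {len(values)} does not match times length {len(t)}"
            )
            continue
        finite = np.isfinite(values)
        if not finite.all():
            out.append(f"{name} contains a non-finite value at index "
                       f"{int(np.argmin(finite))}")
        neg = np.where(values < 0)[0]
        if neg.size:
            out.append(f"{name} contains a negative value at index {int(neg[0])}")
    return out


def _render_salinity(salinity: float | str) -> str:
    return salinity if isinstance(salinity, str) else repr(float(salinity))


def _parse_salinity(token: str) -> float | str:
    token = str(token).strip()
    if token in SALINITY_LABELS:
        return token
    try:
        return float(token)
    except ValueError:
        raise TimeCourseFormatError(
            f"salinity value {token!r} is neither numeric nor one of "
            f"{sorted(SALINITY_LABELS)}"
        ) from None


def write_timecourses(records: Iterable[TimeCourse], path: str | Path) -> None:
    """Write records to ``path`` in the long CSV layout.

    Floats are rendered with ``repr`` (shortest round-tripping decimal), so a
    write/read cycle reproduces every value bit-for-bit.  An empty collection
    yields a header-only file.
    """
    rows: list[dict] = []
    for tc in records:
        problems = validate_timecourse(tc)
        if problems:
            raise TimeCourseValidationError(
                f"record {tc.condition.condition_id!r} rep {tc.condition.replicate}: "
                + "; ".join(problems)
            )
        c = tc.condition
        for i, t in enumerate(tc.times):
            row = {
                "condition_id": c.condition_id,
                "carbon_source": c.carbon_source,
                "s_g0_g_per_L": repr(float(c.s_g0)),
                "salinity": _render_salinity(c.salinity),
                "ph": "" if c.ph is None else repr(float(c.ph)),
                "replicate": int(c.replicate),
                "time_h": repr(float(t)),
                "biomass_g_per_L": repr(float(tc.biomass[i])),
                "ethanol_g_per_L": repr(float(tc.ethanol[i])),
            }
            if tc.substrate is not None:
                row[SUBSTRATE_COLUMN] = repr(float(tc.substrate[i]))
            rows.append(row)
    any_substrate = any(SUBSTRATE_COLUMN in r for r in rows)
    columns = list(REQUIRED_COLUMNS) + ([SUBSTRATE_COLUMN] if any_substrate else [])
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Read a long CSV file into one :class:`TimeCourse` per
    (condition_id, replicate) group.

    Rows within a group are sorted by time before validation, so file row
    order is immaterial; a time that repeats or decreases after sorting is a
    validation error naming the group.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-course file not found: {path}")
    df = pd.read_csv(path, dtype={"condition_id": str, "carbon_source": str,
                                  "salinity": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TimeCourseFormatError(
            f"missing required column(s): {', '.join(missing)}"
        )
    has_substrate = SUBSTRATE_COLUMN in df.columns
    records: list[TimeCourse] = []
    for (cid, rep), g in df.groupby(["condition_id", "replicate"], sort=True):
        g = g.sort_values("time_h", kind="mergesort")
        ph_val = g["ph"].iloc[0]
        condition = Condition(
            condition_id=str(cid),
            carbon_source=str(g["carbon_source"].iloc[0]),
            s_g0=float(g["s_g0_g_per_L"].iloc[0]),
            salinity=_parse_salinity(g["salinity"].iloc[0]),
            ph=None if pd.isna(ph_val) else float(ph_val),
            replicate=int(rep),
        )
        substrate = None
        if has_substrate and not g[SUBSTRATE_COLUMN].isna().all():
            substrate = g[SUBSTRATE_COLUMN].to_numpy(dtype=float)
        tc = TimeCourse(
            condition=condition,
            times=g["time_h"].to_numpy(dtype=float),
            biomass=g["biomass_g_per_L"].to_numpy(dtype=float),
            ethanol=g["ethanol_g_per_L"].to_numpy(dtype=float),
            substrate=substrate,
        )
        problems = validate_timecourse(tc)
        if problems:
            raise TimeCourseValidationError(
                f"group ({cid!r}, replicate {rep}): " + "; ".join(problems)
            )
        records.append(tc)
    return records
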