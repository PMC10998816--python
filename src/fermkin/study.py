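"""End-to-end study driver: generation -> descriptors -> fits -> comparison.

``run_study`` reproduces the experimental sequence of a batch-fermentation
optimisation study as one deterministic pipeline:

1. simulate three one-factor-at-a-time designs (initial-glucose gradient,
   pH gradient, salinity gradient) with replicates,
2. compute descriptor tables per design axis,
3. fit the Monod model to specific growth and production rates over the
   glucose gradient,
4. compare conditions on the pH and salinity axes (Tukey letters) and
   identify the optima,
5. write a run manifest (config hash, seed, version, artifact list).

Everything is a pure function of (config, seed): per-stage seeds are derived
from the study seed, and identical configs produce byte-identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import find_optimum, letter_table
from .descriptors import descriptor_table
from .monod import fit_monod, rate_vs_substrate
from .simulate import SimParams, StressParams, generate_study, ze75_preset
from .timecourse import write_timecourses

log = logging.getLogger("fermkin")

__all__ = ["StudyConfig", "StudyReport", "run_study"]

_DEFAULT_S0_GRID = [50.0, 100.0, 150.0, 200.0, 250.0]
_DEFAULT_PH_GRID = [3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0]
_DEFAULT_SALINITY_GRID = [
    "distilled", "half_seawater", "seawater", 1.0, 2.0, 3.0, 4.0,
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run.

    ``sim`` are the batch kinetics (default: the ze75-like preset, with
    Haldane substrate inhibition switched on for the glucose-gradient axis);
    ``stress`` the pH/salinity response; the three grids define the
    one-factor designs.  ``s0_for_ph`` / ``s0_for_salinity`` pin the initial
    glucose used on the stress axes; ``alpha`` is the Tukey family-wise
    level.  A seed is mandatory — there is no silent nondeterminism.
    """

    seed: int
    sim: SimParams = field(default_factory=ze75_preset)
    stress: StressParams = field(default_factory=StressParams)
    s0_grid: tuple[float, ...] = tuple(_DEFAULT_S0_GRID)
    ph_grid: tuple[float, ...] = tuple(_DEFAULT_PH_GRID)
    salinity_grid: tuple = tuple(_DEFAULT_SALINITY_GRID)
    replicates: int = 3
    alpha: float = 0.05
    s0_for_ph: float = 175.0
    s0_for_salinity: float = 150.0
    substrate_inhibition_ki: float | None = 650.0
    fit_which: tuple[str, ...] = ("growth", "production")

    def violations(self) -> list[str]:
        out = []
        if self.seed is None:
            out.append("seed is required")
        if not (self.s0_grid and self.ph_grid and self.salinity_grid):
            out.append("design grids must be non-empty")
        if self.replicates < 1:
            out.append("replicates must be >= 1")
        if not 0 < self.alpha <= 0.5:
            out.append("alpha must lie in (0, 0.5]")
        return out + self.sim.violations() + self.stress.violations()

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a config from YAML or JSON.

        Top-level keys mirror the dataclass fields; ``sim`` and ``stress``
        are nested mappings overriding the preset defaults.
        """
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "seed" not in raw:
            raise ValueError("config must be a mapping with a 'seed' key")
        sim = ze75_preset(**raw.pop("sim", {}))
        stress = StressParams(**raw.pop("stress", {}))
        for key in ("s0_grid", "ph_grid", "salinity_grid", "fit_which"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, stress=stress, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    """In-memory bundle of a completed run (files are also written)."""

    manifest: dict
    timecourses: dict[str, list]
    descriptor_tables: dict[str, pd.DataFrame]
    monod_fits: dict[str, object]
    comparisons: dict[str, object]
    optima: dict[str, dict]


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_study(config: StudyConfig, outdir: str | Path) -> StudyReport:
    """Run the full pipeline and write all artifacts under ``outdir``."""
    problems = config.violations()
    if problems:
        raise ValueError("invalid study config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "artifacts": [],
        "stages": [],
    }
    report = StudyReport(
        manifest=manifest, timecourses={}, descriptor_tables={},
        monod_fits={}, comparisons={}, optima={},
    )

    def _write_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))

    stage = "generate"
    try:
        axes = {
            "glucose_gradient": dict(
                s0_grid=list(config.s0_grid),
                ph_grid=[config.stress.ph_opt],
                salinity_grid=["seawater"],
                sim=replace(config.sim, ki=config.substrate_inhibition_ki),
            ),
            "ph": dict(
                s0_grid=[config.s0_for_ph],
                ph_grid=list(config.ph_grid),
                salinity_grid=["seawater"],
                sim=config.sim,
            ),
            "salinity": dict(
                s0_grid=[config.s0_for_salinity],
                ph_grid=[config.stress.ph_opt],
                salinity_grid=list(config.salinity_grid),
                sim=config.sim,
            ),
        }
        for axis, spec in axes.items():
            log.info("stage=%s axis=%s", stage, axis)
            records = generate_study(
                base=spec["sim"],
                stress=config.stress,
                s0_grid=spec["s0_grid"],
                ph_grid=spec["ph_grid"],
                salinity_grid=spec["salinity_grid"],
                replicates=config.replicates,
                seed=_stage_seed(config.seed, f"generate:{axis}"),
            )
            report.timecourses[axis] = records
            path = outdir / f"timecourses_{axis}.csv"
            write_timecourses(records, path)
            manifest["artifacts"].append(path.name)
        manifest["stages"].append(stage)

        stage = "descriptors"
        for axis, records in report.timecourses.items():
            log.info("stage=%s axis=%s", stage, axis)
            table = descriptor_table(records)
            report.descriptor_tables[axis] = table
            path = outdir / f"descriptors_{axis}.csv"
            table.to_csv(path, index=False)
            manifest["artifacts"].append(path.name)
        manifest["stages"].append(stage)

        stage = "monod_fit"
        fit_rows = []
        for which in config.fit_which:
            log.info("stage=%s which=%s", stage, which)
            pts = rate_vs_substrate(report.timecourses["glucose_gradient"],
                                    which=which)
            fit = fit_monod(pts)
            report.monod_fits[which] = fit
            fit_rows.append({"which": which, **dataclasses.asdict(fit)})
        path = outdir / "monod_fits.csv"
        pd.DataFrame(fit_rows).to_csv(path, index=False)
        manifest["artifacts"].append(path.name)
        manifest["stages"].append(stage)

        stage = "compare"
        if config.replicates < 2:
            log.warning(
                "stage=%s skipped: replicates=%d gives no within-group "
                "variance", stage, config.replicates,
            )
            manifest["stages"].append(f"{stage} (skipped)")
        else:
            letter_rows = []
            for axis, metric in (("ph", "e_p"), ("salinity", "y_ps"),
                                 ("glucose_gradient", "e_p")):
                log.info("stage=%s axis=%s metric=%s", stage, axis, metric)
                table = report.descriptor_tables[axis]
                reps = table[table["stat"] == "replicate"]
                groups = {
                    str(cid): g[metric].tolist()
                    for cid, g in reps.groupby("condition_id", sort=False)
                }
                lt = letter_table(groups, alpha=config.alpha)
                report.comparisons[(axis, metric)] = lt
                for s in lt.summaries:
                    letter_rows.append({
                        "axis": axis, "metric": metric, "condition_id": s.group,
                        "n": s.n, "mean": s.mean, "sd": s.sd,
                        "letters": lt.letters[s.group],
                        "f_stat": lt.f_stat, "p_value": lt.p_value,
                    })
                best, mean, letters, co = find_optimum(table, metric,
                                                       alpha=config.alpha)
                report.optima[axis] = {
                    "metric": metric, "best": best, "mean": mean,
                    "letters": letters, "co_optimal": co,
                }
            path = outdir / "comparisons.csv"
            pd.DataFrame(letter_rows).to_csv(path, index=False)
            manifest["artifacts"].append(path.name)
            path = outdir / "optima.json"
            path.write_text(json.dumps(report.optima, indent=2, default=str))
            manifest["artifacts"].append(path.name)
            manifest["stages"].append(stage)
    except Exception:
        log.exception("stage=%s failed", stage)
        manifest["failed_stage"] = stage
        _write_manifest()
        raise
    _write_manifest()
    manifest["artifacts"].append("manifest.json")
    _write_manifest()
    return report
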