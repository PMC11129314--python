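"""Config-driven computational experiments: simulate, fit, tabulate.

A :class:`ScenarioConfig` describes a sweep over molecular concentrations
and trap settings for one dimensionality, with the photophysics, time
grid, configuration count, optional instrument response and fit models.
:func:`run_scenario` executes the sweep and writes kinetics CSVs, fit
results, a tidy summary table and a resolved copy of the config, so every
bundle can be reproduced exactly from its own output directory.

Two paired experiments mirror the standard model comparisons:
:func:`compare_trap_models` (statistical clusters vs a random model matched
to the measured mean trap fraction) and :func:`compare_orientation`
(identical geometries with and without the kappa^2 orientation factor).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fitting import fit_decay
from .kinetics import DecayKinetics, convolve_irf
from .rates import PhotophysicalParams
from .simulate import simulate_decay

__all__ = [
    "ScenarioConfig",
    "run_scenario",
    "compare_trap_models",
    "compare_orientation",
    "packaged_config",
    "packaged_config_names",
]

log = logging.getLogger("fretquench")


class PhotophysicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    quantum_yield: float = Field(0.33, gt=0, le=1)
    tau_total_ns: float = Field(5.0, gt=0)
    forster_radius_nm: float = Field(5.0, gt=0)
    include_orientation: bool = False


class TrapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: Literal["none", "random", "statistical"] = "none"
    fractions: list[float] | None = None  # random model: sweep of trap fractions
    r_trap_nm: float | None = Field(None, gt=0)  # statistical model threshold

    @model_validator(mode="after")
    def _check(self):
        if self.model == "random" and not self.fractions:
            raise ValueError("random trap model needs a list of trap fractions")
        if self.model == "statistical" and self.r_trap_nm is None:
            raise ValueError("statistical trap model needs r_trap_nm")
        return self


class IRFConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fwhm_ns: float = Field(..., gt=0)
    center_ns: float = 0.0


class TimeGridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_max_ns: float = Field(25.0, gt=0)
    n_points: int = Field(501, ge=2)

    def build(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max_ns, self.n_points)


class ScenarioConfig(BaseModel):
    """Validated description of one computational experiment."""

    model_config = ConfigDict(extra="forbid")

    name: str = "scenario"
    dimension: Literal[2, 3]
    box_lengths_nm: float | list[float]
    concentrations: list[float] = Field(..., min_length=1)  # nm^-2 or nm^-3
    diameter_nm: float = Field(1.0, gt=0)
    hard_core: bool = True
    traps: TrapConfig = TrapConfig()
    photophysics: PhotophysicsConfig = PhotophysicsConfig()
    n_configs: int = Field(100, ge=1)
    time_grid: TimeGridConfig = TimeGridConfig()
    fit_models: list[Literal["stretched", "lifetime_stretched", "fixed_b"]] = []
    irf: IRFConfig | None = None
    master_seed: int = 0

    def photo_params(self, include_orientation: bool | None = None) -> PhotophysicalParams:
        p = self.photophysics
        return PhotophysicalParams(
            quantum_yield=p.quantum_yield,
            tau_total=p.tau_total_ns,
            forster_radius=p.forster_radius_nm,
            include_orientation=(
                p.include_orientation if include_orientation is None else include_orientation
            ),
            dimension=self.dimension,
        )

    def fixed_b_default(self) -> float:
        """Exponent of the ideal single-donor law: d/6."""
        return self.dimension / 6.0


def _trap_settings(cfg: ScenarioConfig):
    """Yield (label, trap_model, fraction, r_trap) for the sweep."""
    if cfg.traps.model == "random":
        for f in cfg.traps.fractions:
            yield f"random_f{f:g}", "random", f, None
    elif cfg.traps.model == "statistical":
        yield f"statistical_R{cfg.traps.r_trap_nm:g}", "statistical", 0.0, cfg.traps.r_trap_nm
    else:
        yield "no_traps", "none", 0.0, None


def _run_one(cfg: ScenarioConfig, concentration, trap_model, fraction, r_trap,
             seed, include_orientation=None) -> DecayKinetics:
    return simulate_decay(
        dimension=cfg.dimension,
        box_lengths=cfg.box_lengths_nm,
        concentration=concentration,
        params=cfg.photo_params(include_orientation),
        trap_model=trap_model,
        trap_fraction_value=fraction,
        r_trap=r_trap,
        diameter=cfg.diameter_nm,
        hard_core=cfg.hard_core,
        n_configs=cfg.n_configs,
        time_grid=cfg.time_grid.build(),
        master_seed=seed,
    )


def _sweep_seed(master_seed: int, index: int) -> int:
    """Stable per-sweep-point seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def run_scenario(cfg: ScenarioConfig, out_dir) -> pd.DataFrame:
    """Execute the sweep; write kinetics CSVs, fit JSONs, a summary table.

    Returns the tidy summary DataFrame (one row per concentration x trap
    setting x fit model, plus a row without a fit model for the kinetics
    bookkeeping).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(cfg.model_dump_json(indent=2))
    rows = []
    idx = 0
    for label, trap_model, fraction, r_trap in _trap_settings(cfg):
        for conc in cfg.concentrations:
            seed = _sweep_seed(cfg.master_seed, idx)
            idx += 1
            kin = _run_one(cfg, conc, trap_model, fraction, r_trap, seed)
            if cfg.irf is not None:
                kin = convolve_irf(kin, cfg.irf.fwhm_ns, cfg.irf.center_ns)
            stem = f"{cfg.name}_{label}_n{conc:g}"
            kin.to_csv(out / f"{stem}.csv")
            (out / f"{stem}.meta.json").write_text(json.dumps(kin.meta, indent=2, default=str))
            base = {
                "scenario": cfg.name,
                "dimension": cfg.dimension,
                "concentration": conc,
                "trap_setting": label,
                "mean_trap_fraction": kin.meta.get("mean_trap_fraction"),
                "n_configs": kin.n_configs,
                "seed": seed,
            }
            log.info("ran %s (mean trap fraction %.4f)", stem, base["mean_trap_fraction"] or 0.0)
            if cfg.irf is None and cfg.fit_models:
                for model in cfg.fit_models:
                    fit = fit_decay(
                        kin,
                        model=model,
                        fixed_lifetime=(
                            cfg.photophysics.tau_total_ns if model != "stretched" else None
                        ),
                        fixed_b=cfg.fixed_b_default() if model == "fixed_b" else None,
                    )
                    fit.to_json(out / f"{stem}_{model}.json")
                    rows.append({**base, "fit_model": model, "tau_ns": fit.tau, "b": fit.b,
                                 "msd": fit.msd, "converged": fit.converged})
            else:
                rows.append({**base, "fit_model": None, "tau_ns": None, "b": None,
                             "msd": None, "converged": None})
    table = pd.DataFrame(rows)
    table.to_csv(out / f"{cfg.name}_summary.csv", index=False)
    return table


def compare_trap_models(cfg: ScenarioConfig, out_dir=None) -> list[dict]:
    """Statistical-trap kinetics vs a random model matched on trap fraction.

    For each concentration: run the statistical model, measure the mean
    realized trap fraction, then run the random model at that fraction on
    fresh geometries.  Returns one record per concentration with both
    curves and the matching fraction.
    """
    if cfg.traps.model != "statistical":
        raise ValueError("compare_trap_models needs a statistical trap config")
    records = []
    for i, conc in enumerate(cfg.concentrations):
        seed = _sweep_seed(cfg.master_seed, i)
        stat = _run_one(cfg, conc, "statistical", 0.0, cfg.traps.r_trap_nm, seed)
        frac = stat.meta["mean_trap_fraction"]
        rand = _run_one(cfg, conc, "random", frac, None, seed + 1)
        records.append(
            {"concentration": conc, "matched_trap_fraction": frac,
             "statistical": stat, "random": rand}
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            stat.to_csv(out / f"{cfg.name}_stat_n{conc:g}.csv")
            rand.to_csv(out / f"{cfg.name}_rand_n{conc:g}.csv")
    return records


def compare_orientation(cfg: ScenarioConfig, out_dir=None) -> list[dict]:
    """Kinetics with vs without the orientation factor, identical geometries.

    The same master seed drives both runs, so molecular positions,
    orientations and trap draws coincide; only the rate expression differs.
    """
    records = []
    idx = 0
    for label, trap_model, fraction, r_trap in _trap_settings(cfg):
        for conc in cfg.concentrations:
            seed = _sweep_seed(cfg.master_seed, idx)
            idx += 1
            on = _run_one(cfg, conc, trap_model, fraction, r_trap, seed, include_orientation=True)
            off = _run_one(cfg, conc, trap_model, fraction, r_trap, seed, include_orientation=False)
            records.append({"concentration": conc, "trap_setting": label,
                            "orientation_on": on, "orientation_off": off})
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                on.to_csv(out / f"{cfg.name}_{label}_n{conc:g}_orient_on.csv")
                off.to_csv(out / f"{cfg.name}_{label}_n{conc:g}_orient_off.csv")
    return records


# ---------------------------------------------------------------------------
# packaged scenarios

def packaged_config_names() -> list[str]:
    files = resources.files("fretquench") / "configs"
    return sorted(p.name.removesuffix(".json") for p in files.iterdir() if p.name.endswith(".json"))


def packaged_config(name: str, **overrides) -> ScenarioConfig:
    """Load a shipped scenario config by name, optionally overriding fields."""
    path = resources.files("fretquench") / "configs" / f"{name}.json"
    if not path.is_file():
        raise FileNotFoundError(
            f"no packaged config {name!r}; available: {packaged_config_names()}"
        )
    data = json.loads(path.read_text())
    data.update(overrides)
    return ScenarioConfig.model_validate(data)
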