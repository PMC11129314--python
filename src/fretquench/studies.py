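"""Canonical study conditions for the headline numerical experiments.

These are the frozen parameter sets behind the package's summary numbers;
tests, scripts and examples all call the same functions so the conditions
are defined once.

* **Exponent-limit study** — random traps at fraction 0.5 with a low
  molecular concentration (0.005 nm^-2 in the 100 nm 2D box, N = 50;
  0.005 nm^-3 in the 20 nm 3D box, N = 40).  In this regime migration
  between donors is weak and every excitation sees its own static trap
  field, so the lifetime-stretched exponent b should approach the
  single-donor values d/6: 1/3 in 2D and 1/2 in 3D, ratio 3/2.
* **Analytic-convergence study** — a three-point path through the
  (concentration, trap-fraction) plane along which the trap concentration
  rises while the molecular concentration falls, so the fitted fixed-b
  stretched time should converge to the exact tau_theor.
"""

from __future__ import annotations

import numpy as np

from .analytic import tau_theoretical, transfer_microparameter
from .fitting import FitResult, fit_decay
from .rates import PhotophysicalParams
from .simulate import simulate_decay

__all__ = [
    "EXPONENT_LIMIT_CONDITIONS",
    "CONVERGENCE_GRID",
    "exponent_limit_fit",
    "stretched_exponent_ratio",
    "analytic_convergence_deviations",
]

#: dimension -> (box length nm, molecular concentration, trap fraction)
EXPONENT_LIMIT_CONDITIONS = {
    2: {"box": 100.0, "concentration": 0.005, "trap_fraction": 0.5},
    3: {"box": 20.0, "concentration": 0.005, "trap_fraction": 0.5},
}

#: dimension -> [(molecular concentration, trap fraction), ...] with the trap
#: concentration increasing along the path and the molecular one decreasing
CONVERGENCE_GRID = {
    2: [(0.04, 0.05), (0.025, 0.2), (0.015, 0.5)],
    3: [(0.1, 0.05), (0.04, 0.2), (0.02, 0.5)],
}


def exponent_limit_fit(
    dimension: int, n_configs: int = 100, master_seed: int = 0
) -> FitResult:
    """Lifetime-stretched fit of the low-concentration high-trap decay."""
    cond = EXPONENT_LIMIT_CONDITIONS[dimension]
    params = PhotophysicalParams(dimension=dimension)
    kin = simulate_decay(
        dimension,
        cond["box"],
        cond["concentration"],
        params,
        trap_model="random",
        trap_fraction_value=cond["trap_fraction"],
        n_configs=n_configs,
        master_seed=master_seed,
    )
    return fit_decay(kin, "lifetime_stretched", fixed_lifetime=params.tau_total)


def stretched_exponent_ratio(n_configs: int = 100, master_seed: int = 0) -> dict:
    """b_3D / b_2D in the single-donor limit regime (expected near 3/2)."""
    f2 = exponent_limit_fit(2, n_configs, master_seed)
    f3 = exponent_limit_fit(3, n_configs, master_seed)
    return {"b_2d": f2.b, "b_3d": f3.b, "ratio": f3.b / f2.b}


def analytic_convergence_deviations(
    dimension: int, n_configs: int = 30, master_seed: int = 11
) -> list[dict]:
    """Relative deviation of fitted fixed-b tau from tau_theor along the grid."""
    params = PhotophysicalParams(dimension=dimension)
    c_da = transfer_microparameter(params)
    cond = EXPONENT_LIMIT_CONDITIONS[dimension]
    out = []
    for conc, frac in CONVERGENCE_GRID[dimension]:
        kin = simulate_decay(
            dimension,
            cond["box"],
            conc,
            params,
            trap_model="random",
            trap_fraction_value=frac,
            n_configs=n_configs,
            master_seed=master_seed,
        )
        fit = fit_decay(
            kin, "fixed_b", fixed_lifetime=params.tau_total, fixed_b=dimension / 6.0
        )
        tau_exact = tau_theoretical(dimension, conc * frac, c_da)
        out.append(
            {
                "concentration": conc,
                "trap_fraction": frac,
                "tau_fit": fit.tau,
                "tau_theor": tau_exact,
                "rel_deviation": abs(fit.tau - tau_exact) / tau_exact,
            }
        )
    return out
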