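"""Closed-form decay of one donor among infinitely deep acceptors.

For a single excited donor with lifetime tau_d surrounded by a Poisson
field of static acceptors at number density n, direct Förster transfer
w(r) = C_DA / r^6 gives the exact ensemble-averaged survival probability

    3D:  P(t) = exp(-t/tau_d - Gamma(1/2) (4 pi / 3) n_3D (C_DA t)^(1/2))
    2D:  P(t) = exp(-t/tau_d - Gamma(2/3) pi       n_2D (C_DA t)^(1/3))

i.e. a lifetime exponential times a stretched term with exponent d/6.
The transfer microparameter is C_DA = R_F^6 / tau_fluor, so that
w(R_F) = 1/tau_fluor by definition of the Förster radius.

Matching the fixed-exponent fitting form
exp(-t/tau_d - (t/tau)^(d/6)) to these laws term-by-term defines the
theoretical stretched time

    tau_theor = (Gamma(1 - d/6) V_d n)^(-6/d) / C_DA,

with V_d = pi (2D) or 4 pi/3 (3D) — scaling as n^-3/C_DA in 2D and
n^-2/C_DA in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro
from scipy.special import gamma as gamma_fn

from .rates import PhotophysicalParams

__all__ = [
    "AnalyticDecayParams",
    "transfer_microparameter",
    "single_donor_decay",
    "tau_theoretical",
    "concentration_mM_to_nm3",
]


def _shell_coeff(dimension: int) -> float:
    """V_d: unit-ball measure coefficient (area pi r^2, volume 4/3 pi r^3)."""
    if dimension == 2:
        return np.pi
    if dimension == 3:
        return 4.0 * np.pi / 3.0
    raise ValueError(f"dimension must be 2 or 3, got {dimension}")


@dataclass(frozen=True)
class AnalyticDecayParams:
    """Inputs of the single-donor decay law (nm, ns units)."""

    dimension: int
    acceptor_concentration: float  # nm^-2 (2D) or nm^-3 (3D)
    c_da: float  # transfer microparameter, nm^6/ns
    donor_lifetime: float  # ns

    def __post_init__(self) -> None:
        _shell_coeff(self.dimension)
        if self.acceptor_concentration < 0:
            raise ValueError("acceptor concentration must be non-negative")
        if self.c_da <= 0:
            raise ValueError("C_DA must be positive")
        if self.donor_lifetime <= 0:
            raise ValueError("donor lifetime must be positive")


def transfer_microparameter(params: PhotophysicalParams) -> float:
    """C_DA = R_F^6 / tau_fluor in nm^6/ns."""
    return params.forster_radius**6 / params.tau_fluor


def single_donor_decay(t, params: AnalyticDecayParams):
    """Survival probability of the donor at times t (ns).

    Vectorized over t; P(0) = 1 and P is monotone in both t and the
    acceptor concentration.
    """
    t = np.asarray(t, float)
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    d = params.dimension
    quench = (
        gamma_fn(1.0 - d / 6.0)
        * _shell_coeff(d)
        * params.acceptor_concentration
        * (params.c_da * t) ** (d / 6.0)
    )
    out = np.exp(-t / params.donor_lifetime - quench)
    return out if out.ndim else float(out)


def tau_theoretical(dimension: int, trap_concentration: float, c_da: float) -> float:
    """Stretched time tau (ns) of the fixed-exponent form matching the exact law.

    Equates (t/tau)^(d/6) with the quenching term of the analytic decay:
    tau = (Gamma(1 - d/6) V_d n)^(-6/d) / C_DA.
    """
    if trap_concentration <= 0:
        raise ValueError("trap concentration must be positive (tau diverges at zero)")
    if c_da <= 0:
        raise ValueError("C_DA must be positive")
    d = dimension
    pref = gamma_fn(1.0 - d / 6.0) * _shell_coeff(d) * trap_concentration
    return float(pref ** (-6.0 / d) / c_da)


def concentration_mM_to_nm3(c_mM: float) -> float:
    """Convert a molar concentration in mM to a number density in nm^-3.

    c [mM] * 1e-3 mol/L * N_A / (1e24 nm^3/L); 1 mM ~ 6.022e-4 nm^-3.
    """
    if c_mM < 0:
        raise ValueError("concentration must be non-negative")
    return c_mM * 1e-3 * Avogadro * 1e-24
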