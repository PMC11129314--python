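"""Förster transfer rates and the master-equation generator.

The pairwise excitation-transfer rate between identical molecules at
distance r (nm) follows the dipole–dipole Förster expression

    K(r) = (1 / tau_fluor) * (R_F / r)**6            (orientation-free)
    K(r) = (1 / tau_fluor) * (R_F / r)**6 * kappa**2 / <kappa**2>

where tau_fluor = tau_total / QY is the fluorescence (radiative) lifetime,
R_F the Förster radius, and kappa the signed orientation factor

    kappa = d_i . d_j - 3 (d_i . r_hat)(d_j . r_hat).

<kappa**2> is the isotropic average of kappa**2: 2/3 for dipoles free in 3D
and 5/4 for dipoles confined to the plane containing the pair vector (2D).
Dividing by <kappa**2> keeps the orientation-resolved rates centred on the
orientation-free ones, because R_F is defined through the orientationally
averaged coupling.

The full generator K of dP/dt = K P holds rate K[i, j] for j -> i transfer
on the off-diagonal; the diagonal of a fluorescent column j is
-1/tau_total - sum_i K[i, j], so each fluorescent column sums to
-1/tau_total exactly.  Traps are infinitely deep: their columns (diagonal
included) are identically zero, which makes them absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularEnsemble

__all__ = [
    "PhotophysicalParams",
    "TransferRateMatrix",
    "orientation_factor",
    "kappa_sq_mean",
    "pair_transfer_rate",
    "build_rate_matrix",
]

KAPPA_SQ_MEAN_2D = 5.0 / 4.0
KAPPA_SQ_MEAN_3D = 2.0 / 3.0


def kappa_sq_mean(dimension: int) -> float:
    """Isotropic average of the squared orientation factor: 5/4 (2D), 2/3 (3D)."""
    if dimension == 2:
        return KAPPA_SQ_MEAN_2D
    if dimension == 3:
        return KAPPA_SQ_MEAN_3D
    raise ValueError(f"dimension must be 2 or 3, got {dimension}")


@dataclass(frozen=True)
class PhotophysicalParams:
    """Photophysics of the fluorophore, in ns and nm.

    Parameters
    ----------
    quantum_yield : float
        Fluorescence quantum yield, in (0, 1].
    tau_total : float
        Total excited-state lifetime of an isolated molecule (ns).
    forster_radius : float
        R_F (nm): distance at which the transfer rate equals 1/tau_fluor.
    include_orientation : bool
        Whether pairwise rates carry the kappa^2/<kappa^2> factor.
    dimension : int
        2 or 3; sets <kappa^2> when orientation is enabled.
    """

    quantum_yield: float = 0.33
    tau_total: float = 5.0
    forster_radius: float = 5.0
    include_orientation: bool = False
    dimension: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError(f"quantum yield must be in (0, 1], got {self.quantum_yield}")
        if self.tau_total <= 0:
            raise ValueError(f"tau_total must be positive, got {self.tau_total}")
        if self.forster_radius <= 0:
            raise ValueError(f"forster_radius must be positive, got {self.forster_radius}")
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")

    @property
    def tau_fluor(self) -> float:
        """Fluorescence lifetime tau_total / QY (ns); >= tau_total."""
        return self.tau_total / self.quantum_yield

    @property
    def kappa_sq_mean(self) -> float:
        return kappa_sq_mean(self.dimension)


@dataclass(frozen=True)
class TransferRateMatrix:
    """Dense generator of the master equation, entries in ns^-1."""

    rates: np.ndarray
    trap_mask: np.ndarray
    tau_total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, float))
        object.__setattr__(self, "trap_mask", np.asarray(self.trap_mask, bool))
        n = self.rates.shape[0]
        if self.rates.shape != (n, n) or self.trap_mask.shape != (n,):
            raise ValueError("rates must be square and trap_mask length-matched")
        if not np.isfinite(self.rates).all():
            raise ValueError("rate matrix contains non-finite entries")

    @property
    def size(self) -> int:
        return self.rates.shape[0]

    @property
    def trap_indices(self) -> np.ndarray:
        return np.flatnonzero(self.trap_mask)

    def column_sums(self) -> np.ndarray:
        return self.rates.sum(axis=0)


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit vector (norm {np.linalg.norm(v):.6g})")
    return v


def orientation_factor(d_i, d_j, r_hat) -> float:
    """Signed orientation factor kappa for a donor/acceptor dipole pair.

    kappa = d_i.d_j - 3 (d_i.r_hat)(d_j.r_hat), bounded by [-2, 2].
    """
    d_i = _check_unit(d_i, "d_i")
    d_j = _check_unit(d_j, "d_j")
    r_hat = _check_unit(r_hat, "r_hat")
    return float(d_i @ d_j - 3.0 * (d_i @ r_hat) * (d_j @ r_hat))


def pair_transfer_rate(
    params: PhotophysicalParams, r_ij: float, kappa_sq_ij: float | None = None
) -> float:
    """Förster rate (ns^-1) between two molecules at distance r_ij (nm).

    With ``kappa_sq_ij`` given the rate carries the factor
    kappa^2/<kappa^2>; otherwise the orientation-free expression is used.
    """
    if r_ij <= 0:
        raise ValueError(f"intermolecular distance must be positive, got {r_ij}")
    rate = (params.forster_radius / r_ij) ** 6 / params.tau_fluor
    if kappa_sq_ij is not None:
        rate *= kappa_sq_ij / params.kappa_sq_mean
    return rate


def build_rate_matrix(
    ensemble: MolecularEnsemble, params: PhotophysicalParams
) -> TransferRateMatrix:
    """Assemble the dense master-equation generator for an ensemble.

    Transfer into traps uses the same Förster expression as transfer between
    fluorescent molecules; transfer *out of* a trap never happens (the whole
    trap column is zero).  No distance cutoff is applied: every pair
    contributes, however far apart.
    """
    if ensemble.n_fluorescent < 1:
        raise ValueError("ensemble must contain at least one fluorescent molecule")
    if params.include_orientation and params.dimension != ensemble.dimension:
        raise ValueError(
            f"params.dimension={params.dimension} does not match "
            f"ensemble.dimension={ensemble.dimension}"
        )
    n = ensemble.n_molecules
    dist = ensemble.pairwise_distances()
    off = ~np.eye(n, dtype=bool)
    if n > 1:
        dmin = dist[off].min()
        if dmin <= 0.0:
            masked = np.where(off, dist, np.inf)
            i, j = np.unravel_index(np.argmin(masked), dist.shape)
            raise ValueError(f"coincident molecules {i} and {j} (distance 0)")

    rates = np.zeros((n, n))
    if n > 1:
        with np.errstate(divide="ignore"):
            rates = np.where(off, (params.forster_radius / np.where(off, dist, 1.0)) ** 6, 0.0)
        rates /= params.tau_fluor
        if params.include_orientation:
            d = ensemble.orientations
            diff = ensemble.positions[:, None, :] - ensemble.positions[None, :, :]
            r_hat = diff / np.where(off, dist, 1.0)[:, :, None]
            dd = d @ d.T
            proj = np.einsum("ik,ijk->ij", d, r_hat)  # d_i . r_hat(i<-j)
            # proj.T[i,j] = d_j . r_hat(j<-i) = -d_j . r_hat(i<-j), hence the +
            kappa = dd + 3.0 * proj * proj.T
            rates *= np.where(off, kappa**2, 0.0) / params.kappa_sq_mean

    # diagonal: decay + total outflow; then zero the trap columns entirely
    np.fill_diagonal(rates, 0.0)
    rates[np.diag_indices(n)] = -1.0 / params.tau_total - rates.sum(axis=0)
    rates[:, ensemble.trap_mask] = 0.0
    return TransferRateMatrix(rates=rates, trap_mask=ensemble.trap_mask.copy(),
                              tau_total=params.tau_total)
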