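"""Random molecular ensembles in bounded 2D/3D regions with trap assignment.

Molecules are placed uniformly inside a rectangular box (units: nm), each
carrying a transition-dipole orientation (a unit vector, in-plane for 2D,
isotropic on the sphere for 3D) and a boolean trap flag.  Two trap models are
supported:

* **random traps** — a prescribed fraction of molecules, drawn uniformly
  without replacement, become infinitely deep traps;
* **statistical traps** — every molecule belonging to a cluster of two or
  more molecules with pairwise centre distance below a threshold ``r_trap``
  becomes a trap (pairs *and* larger aggregates quench).

Distances are plain Euclidean within the finite box; there is no periodic
wrapping, so edge effects are part of the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MolecularEnsemble",
    "PackingError",
    "place_molecules",
    "assign_random_traps",
    "assign_statistical_traps",
    "trap_fraction",
    "save_ensemble",
    "load_ensemble",
]

_HARD_CORE_MAX_TRIES = 10_000


class PackingError(RuntimeError):
    """Raised when hard-core placement cannot fit the requested density."""


@dataclass(frozen=True)
class MolecularEnsemble:
    """Positions, dipole orientations and trap flags of N molecules.

    Attributes
    ----------
    dimension : int
        2 or 3.
    box_lengths : ndarray, shape (dimension,)
        Box edge lengths in nm.
    positions : ndarray, shape (N, dimension)
        Molecular centre coordinates in nm, each in ``[0, box_length)``.
    orientations : ndarray, shape (N, dimension)
        Unit transition-dipole vectors.
    trap_mask : ndarray of bool, shape (N,)
        True for infinitely deep traps.
    diameter : float
        Molecular diameter in nm (hard-core exclusion distance).
    seed : int or None
        Seed the placement was generated from, for provenance.
    """

    dimension: int
    box_lengths: np.ndarray
    positions: np.ndarray
    orientations: np.ndarray
    trap_mask: np.ndarray
    diameter: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        object.__setattr__(self, "box_lengths", np.asarray(self.box_lengths, float))
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "orientations", np.asarray(self.orientations, float))
        object.__setattr__(self, "trap_mask", np.asarray(self.trap_mask, bool))
        if self.positions.shape != (self.n_molecules, self.dimension):
            raise ValueError("positions must have shape (N, dimension)")
        if self.orientations.shape != self.positions.shape:
            raise ValueError("orientations must match positions in shape")
        norms = np.linalg.norm(self.orientations, axis=1)
        if self.n_molecules and not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("orientations must be unit vectors")
        inside = (self.positions >= 0) & (self.positions < self.box_lengths)
        if not inside.all():
            raise ValueError("all positions must lie inside the box")

    @property
    def n_molecules(self) -> int:
        return len(self.trap_mask)

    @property
    def n_traps(self) -> int:
        return int(self.trap_mask.sum())

    @property
    def n_fluorescent(self) -> int:
        return self.n_molecules - self.n_traps

    def pairwise_distances(self) -> np.ndarray:
        """Dense N x N Euclidean distance matrix in nm."""
        return squareform(pdist(self.positions))


def _sample_orientations(dimension: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if dimension == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([np.cos(theta), np.sin(theta)])
    # isotropic on the unit sphere via normalized Gaussian deviates
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def place_molecules(
    dimension: int,
    box_lengths,
    concentration: float,
    diameter: float = 1.0,
    hard_core: bool = True,
    rng: np.random.Generator | int | None = None,
) -> MolecularEnsemble:
    """Scatter molecules uniformly in a box at the given number density.

    Parameters
    ----------
    dimension : int
        2 or 3.
    box_lengths : float or sequence
        Edge lengths in nm; a scalar means a square/cubic box.
    concentration : float
        Number density in nm^-2 (2D) or nm^-3 (3D).  The molecule count is
        ``N = round(concentration * area_or_volume)`` (ties to even).
    diameter : float
        Molecular diameter in nm; with ``hard_core`` enabled no two centres
        come closer than this.
    hard_core : bool
        Reject overlapping placements.  Disable for the literal
        ideal-gas uniform distribution.
    rng : numpy Generator, int seed, or None

    Returns
    -------
    MolecularEnsemble with all molecules fluorescent (no traps).
    """
    if dimension not in (2, 3):
        raise ValueError(f"dimension must be 2 or 3, got {dimension}")
    box = np.broadcast_to(np.asarray(box_lengths, float), (dimension,)).copy()
    if not (box > 0).all():
        raise ValueError(f"box lengths must be positive, got {box}")
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    measure = float(np.prod(box))
    n = int(np.rint(concentration * measure))
    if n < 1:
        raise ValueError(
            f"concentration {concentration} in box of measure {measure} nm^{dimension} "
            f"yields N={n} molecules; need at least 1"
        )
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    if not hard_core:
        positions = gen.uniform(0.0, 1.0, size=(n, dimension)) * box
    else:
        positions = np.empty((n, dimension))
        placed = 0
        tries = 0
        d2 = diameter * diameter
        while placed < n:
            cand = gen.uniform(0.0, 1.0, size=dimension) * box
            if placed == 0 or (
                np.einsum("ij,ij->i", positions[:placed] - cand, positions[:placed] - cand).min()
                >= d2
            ):
                positions[placed] = cand
                placed += 1
                tries = 0
            else:
                tries += 1
                if tries > _HARD_CORE_MAX_TRIES:
                    raise PackingError(
                        f"hard-core placement stalled after {placed}/{n} molecules "
                        f"(diameter {diameter} nm, density {concentration} nm^-{dimension}); "
                        "reduce the density or disable hard_core"
                    )
    orientations = _sample_orientations(dimension, n, gen)
    return MolecularEnsemble(
        dimension=dimension,
        box_lengths=box,
        positions=positions,
        orientations=orientations,
        trap_mask=np.zeros(n, bool),
        diameter=diameter,
        seed=int(seed) if seed is not None else None,
        meta={"concentration": concentration, "hard_core": hard_core},
    )


def assign_random_traps(
    ensemble: MolecularEnsemble,
    trap_fraction: float,
    rng: np.random.Generator | int | None = None,
) -> MolecularEnsemble:
    """Flag ``round(trap_fraction * N)`` molecules (ties to even) as traps.

    Trap identities are drawn uniformly without replacement; the input
    ensemble is not modified.
    """
    if not 0.0 <= trap_fraction < 1.0:
        raise ValueError(f"trap_fraction must lie in [0, 1), got {trap_fraction}")
    n = ensemble.n_molecules
    n_traps = int(np.rint(trap_fraction * n))
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mask = np.zeros(n, bool)
    if n_traps:
        mask[gen.choice(n, size=n_traps, replace=False)] = True
    return replace(ensemble, trap_mask=mask)


def assign_statistical_traps(ensemble: MolecularEnsemble, r_trap: float) -> MolecularEnsemble:
    """Flag every molecule in a proximity cluster of size >= 2 as a trap.

    Builds the graph with an edge for each pair closer than ``r_trap`` and
    marks all members of non-singleton connected components, so dimers and
    larger aggregates both quench.  Deterministic given the geometry.
    """
    if r_trap <= 0:
        raise ValueError(f"r_trap must be positive, got {r_trap}")
    n = ensemble.n_molecules
    mask = np.zeros(n, bool)
    if n > 1:
        close = pdist(ensemble.positions) < r_trap
        adj = squareform(close).astype(np.int8)
        _, labels = connected_components(csr_matrix(adj), directed=False)
        counts = np.bincount(labels)
        mask = counts[labels] >= 2
    return replace(ensemble, trap_mask=mask)


def trap_fraction(ensemble: MolecularEnsemble) -> float:
    """Fraction of molecules flagged as traps, count(traps)/N."""
    if ensemble.n_molecules == 0:
        raise ValueError("empty ensemble has no trap fraction")
    return ensemble.n_traps / ensemble.n_molecules


# ---------------------------------------------------------------------------
# serialization: CSV table of per-molecule columns + JSON metadata sidecar

def save_ensemble(ensemble: MolecularEnsemble, csv_path) -> None:
    """Write positions/orientations/trap flags as CSV plus a JSON sidecar."""
    csv_path = Path(csv_path)
    axes = "xyz"[: ensemble.dimension]
    cols = {a: ensemble.positions[:, i] for i, a in enumerate(axes)}
    cols.update({f"u{a}": ensemble.orientations[:, i] for i, a in enumerate(axes)})
    cols["is_trap"] = ensemble.trap_mask.astype(int)
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    meta = {
        "dimension": ensemble.dimension,
        "box_lengths_nm": ensemble.box_lengths.tolist(),
        "diameter_nm": ensemble.diameter,
        "seed": ensemble.seed,
        "n_molecules": ensemble.n_molecules,
        "n_traps": ensemble.n_traps,
        "units": {"length": "nm"},
        **{k: v for k, v in ensemble.meta.items()},
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_ensemble(csv_path) -> MolecularEnsemble:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    dim = meta["dimension"]
    axes = "xyz"[:dim]
    return MolecularEnsemble(
        dimension=dim,
        box_lengths=np.asarray(meta["box_lengths_nm"], float),
        positions=df[list(axes)].to_numpy(),
        orientations=df[[f"u{a}" for a in axes]].to_numpy(),
        trap_mask=df["is_trap"].to_numpy().astype(bool),
        diameter=meta["diameter_nm"],
        seed=meta.get("seed"),
    )
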