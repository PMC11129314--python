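# Methods

## Physical model

The package simulates incoherent excitation transport in an ensemble of
`N` identical point-dipole fluorophores placed in a rectangular 2D area or
3D box.  A single excitation (created by an infinitely short pulse,
uniformly over the fluorescent molecules) hops between molecules with
Förster rates and is lost either by the intrinsic decay of whichever
molecule carries it or by arrival at a trap.  The state is the vector of
site-occupation probabilities `P(t)`, governed by `dP/dt = K P`.

Rates use the dipole–dipole `r⁻⁶` form at *all* separations — no
short-range excitonic or exchange corrections and no long-range cutoff
(truncating distant pairs is known to distort migration kinetics, so the
full dense matrix is always built).  All material constants are absorbed
into three parameters: the quantum yield `QY`, the total lifetime
`τ_total` (so `τ_fluor = τ_total/QY`), and the Förster radius `R_F`.
Orientations can be resolved per pair through `κ²/⟨κ²⟩`, with
`⟨κ²⟩ = 5/4` for dipoles confined to the plane (2D) and `2/3` for free
dipoles (3D); the normalization makes the isotropic average of the
orientation-resolved rate equal the orientation-free rate at every
distance.

Traps are infinitely deep: a trap's column of `K` is identically zero, so
it absorbs and never re-emits or decays further.  Transfer *into* traps
uses the same Förster expression as donor–donor transfer.  Finite trap
depth and back-transfer are deliberately out of scope; so are
multi-excitation effects (annihilation) and kinetic-Monte-Carlo
trajectory sampling — the master equation is solved exactly instead.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `QY` | 0.33 | fluorescence quantum yield (0.4 in the phthalocyanine scenario) |
| `τ_total` | 5 ns | excited-state lifetime of an isolated molecule |
| `R_F` | 5 nm | Förster radius (4 and 7 nm in the phthalocyanine scenario) |
| box | 100×100 nm (2D), 20³ nm³ (3D), 50³ nm³ (phthalocyanine) | simulation region |
| diameter | 1 nm (2D/3D), 1.5 nm (phthalocyanine) | hard-core exclusion distance |
| `R_trap` | 3 nm (2D), 1 nm (3D), 4.5 nm (phthalocyanine) | statistical-trap threshold |
| `n_configs` | 100 | configurations averaged |
| time grid | 0–25 ns, 501 points | linear; 25 ns = 5 τ_total |

The time grid is a package choice (the sources of these parameter sets do
not state one); fitted `τ` and `b` are insensitive to it, but the absolute
mean-squared deviation (MSD) of a fit is grid-dependent, so the grid is
recorded in every `FitResult` and MSD values should only be compared at
order-of-magnitude resolution.

## Ensemble generation

Positions are sampled uniformly; by default a hard-core rejection step
enforces centre distances ≥ the molecular diameter (a physical diameter
implies excluded volume), with `hard_core=False` available for the
literal ideal-gas reading.  **Exception:** 3D statistical-trap scenarios
run with `hard_core=False`, because the canonical 3D threshold
`R_trap = 1 nm` equals the diameter — with excluded volume no pair could
ever be closer than `R_trap` and no statistical trap could form.
Orientations are uniform on the circle (2D) or sphere (3D, normalized
Gaussian deviates).  Boundaries are hard walls, not periodic: distances
are plain Euclidean inside the finite box, and edge effects are part of
the model (donors near a wall see roughly half the acceptor field; see
"Analytic limit" below).

Random traps: exactly `round(f·N)` molecules (ties to even), drawn
uniformly without replacement.  Statistical traps: connected components
of the graph with edges at distance `< R_trap`; every member of a
component of size ≥ 2 becomes a trap, so aggregates beyond dimers quench
too.  One master seed expands via `SeedSequence.spawn` into
per-configuration seeds, making configuration `k` reproducible regardless
of how many configurations are requested.

## Solver

Because trap columns are zero, the fluorescent sub-block `K_ff` decouples,
and — donor–donor rates being reciprocal (`κ²` and `r` are symmetric, the
molecules identical) — it is symmetric.  The propagator is therefore
evaluated exactly by eigendecomposition, `P_f(t) = V e^{Λt} Vᵀ P_f(0)`,
and the trap inflow by the closed-form quadrature
`∫₀ᵗ e^{Λs} ds = (e^{Λt}−1)/Λ` (all eigenvalues are ≤ −1/τ_total, so the
division is safe).  This is exact for arbitrarily stiff rate spreads —
important because nearest-neighbour rates reach ~10³ ns⁻¹ while decay is
0.2 ns⁻¹.  Generators without this structure fall back to
`scipy.sparse.linalg.expm_multiply`; an independent `solve_ivp`
integration cross-checks the eigensolver in the test suite.  Per-molecule
probabilities are clipped at 0 to remove −1e-17-scale eigensolver noise.

`P_sum(t)` sums the fluorescent molecules and is normalized to 1 at
`t = 0` *before* configuration averaging, so realizations with different
trap counts contribute comparable curves (normalize-then-average).

IRF convolution uses a discretely unit-normalized Gaussian kernel on the
curve's uniform grid, with the output reported on a right-padded grid so
no mass is truncated.  The only discretization error is `O(Δt)` and is
pinned to the image of the signal's `t = 0` step; elsewhere the discrete
convolution matches the exponential⊗Gaussian closed form to ~1e-11.

## Analytic models and fitting

The exact single-donor law
`P(t) = exp(−t/τ_d − Γ(1−d/6) V_d n (C_DA t)^{d/6})` (`V₂ = π`,
`V₃ = 4π/3`) is implemented directly and validated in the tests against a
direct Monte-Carlo average over Poisson acceptor placements, which guards
the Gamma-function prefactors independently of any fitting machinery.
Two conventions are kept deliberately distinct: the lifetime in the
exponential factor is `τ_total`, while `C_DA = R_F⁶/τ_fluor` carries the
fluorescence lifetime.  Matching the fixed-b fit form term-by-term gives
`τ_theor = (Γ(1−d/6) V_d n)^{−6/d}/C_DA`.

Fits minimize unweighted least squares on the linear-scale curve over the
full grid (curves are O(1) and noise is configuration noise, not photon
noise).  The stretched-exponential objective has shallow valleys, so each
fit is multistarted on `b ∈ {0.25, 0.5, 0.75, 1}` × `τ ∈ {0.1, 1, 10}` ns
within bounds `τ ∈ (1e-4, 1e4)` ns, `b ∈ (0.05, 1.5)`; ties go to the
smaller `b`, making results deterministic.

## Frozen study conditions

Two headline experiments are defined once in `fretquench.studies`:

* **Exponent limit** — random traps at fraction 0.5, `n = 0.005` nm⁻²
  (2D, N = 50) and 0.005 nm⁻³ (3D, N = 40).  Donors are then dilute on
  the `R_F` scale, so migration is weak and each excitation decays in its
  own static trap field: the lifetime-stretched exponent approaches the
  single-donor values `b = d/6`.  Measured: `b₂D ≈ 0.35`, `b₃D ≈ 0.50`,
  ratio ≈ 1.38 (ideal 1.5; the 2D exponent carries a small upward bias
  from residual migration and wall effects).  The molecule counts keep a
  full 100-configuration run under a second; `scripts/acceptance.py`
  averages 800 configurations per dimension to pin down the ratio of two
  fitted exponents, which is noisier than either exponent alone.
* **Analytic-limit convergence** — a three-point path, 2D
  `(n, f) = (0.04, 0.05) → (0.025, 0.2) → (0.015, 0.5)` and 3D
  `(0.1, 0.05) → (0.04, 0.2) → (0.02, 0.5)`, along which trap
  concentration rises while molecular concentration falls.  The relative
  deviation of the fitted fixed-b `τ` from `τ_theor` shrinks
  monotonically along it.  The path deliberately *increases* the trap
  concentration: at very weak total quenching the finite box's edge bias
  inflates the fitted `τ` and would otherwise mask the convergence.

The packaged scenario concentration lists (`fig3_2d_random`,
`fig8_3d_random`, comparison configs) span the experimentally motivated
ranges 0.005–0.04 nm⁻² and 0.01–0.1 nm⁻³; they are representative sweeps,
not a reproduction of any specific published axis.  The phthalocyanine
configs use the nine number densities 0.00031–0.0124 nm⁻³ verbatim.  The
`mM → nm⁻³` helper uses the CODATA Avogadro constant
(1 mM = 6.022×10⁻⁴ nm⁻³); note the nominal mM labels attached to those
nine densities correspond to a rounded factor 6.2×10⁻⁴.

## What the synthetic data does and does not emulate

Simulated curves are noiseless solutions of the model averaged over
configuration disorder; they emulate the *shape* of time-resolved
fluorescence (including, optionally, IRF broadening) but not photon-counting
(Poisson) noise, background, pile-up, reabsorption/inner-filter effects, or
spectral heterogeneity.  Passing tests therefore validate the transport
model and its fitted parametrizations, not an end-to-end instrument model;
fitting real TCSPC data at high signal-to-noise would additionally need a
noise model and possibly finite trap depth with back-transfer.

## Known limitations

* Infinitely deep traps; no back-transfer or internal trapping rate.
* Hard-wall finite boxes; observables carry edge effects that vanish only
  when quenching is strong and local.
* Single-excitation regime; no annihilation.
* The dipole–dipole rate is used down to contact distance, where Förster
  theory is not quantitative.
* MSD values are meaningful only relative to the recorded fit grid.
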