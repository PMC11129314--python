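# fretquench

Numerical simulation of **fluorescence concentration quenching** — the loss
of fluorescence quantum yield that sets in when fluorophores (chlorophylls,
phthalocyanines, dye films…) are packed densely enough for excitation energy
to migrate between molecules and drain into non-fluorescent traps.

`fretquench` builds random 2D/3D molecular ensembles, assembles the Förster
transfer-rate matrix, solves the master equation for the excited-state
populations, and characterizes the resulting decay curves with
stretched-exponential fits and exact single-donor decay laws.  It is a
library first (importable API plus `examples/` scripts), with a thin
`fretquench` CLI for config-driven runs.

## Model

For `N` identical molecules the excitation probabilities obey the master
equation `dP/dt = K P`.  Off-diagonal elements are Förster rates in the
dipole–dipole approximation, used at all distances:

```
K_ij = (1/τ_fluor) (R_F / r_ij)^6                     (orientations averaged)
K_ij = (1/τ_fluor) (R_F / r_ij)^6 κ²_ij / ⟨κ²⟩        (orientations resolved)
κ_ij = d_i·d_j − 3 (d_i·r̂)(d_j·r̂),   ⟨κ²⟩ = 5/4 (2D), 2/3 (3D)
```

with `τ_fluor = τ_total/QY` and the Förster radius `R_F` defined by
`K(R_F) = 1/τ_fluor`.  The diagonal of a fluorescent column is
`−1/τ_total − Σ_i K_ij`, so each column sums to the decay rate exactly.
Traps are **infinitely deep**: their columns are zero (absorbing states).
Two trap models are supported — *random* (a prescribed fraction of
molecules) and *statistical* (every cluster of molecules closer than
`R_trap`, dimers and larger aggregates alike).

The observable is the total fluorescent population `P_sum(t)`, averaged
over molecular configurations, and optionally convolved with a Gaussian
instrument response.  Decays are fitted with

```
exp(−(t/τ)^b)                      stretched (KWW)
exp(−t/τ_total − (t/τ)^b)          lifetime-stretched
exp(−t/τ_total − (t/τ)^(d/6))      fixed-b  (the ideal single-donor form)
```

and compared with the exact one-donor-among-acceptors law
`P(t) = exp(−t/τ_d − Γ(1−d/6) V_d n (C_DA t)^(d/6))`, `C_DA = R_F⁶/τ_fluor`.

## Worked example

```python
from fretquench import PhotophysicalParams, fit_decay, simulate_decay

params = PhotophysicalParams(dimension=2)   # QY=0.33, τ_total=5 ns, R_F=5 nm
kin = simulate_decay(2, 100.0, 0.04, params,            # 400 molecules
                     trap_model="random", trap_fraction_value=0.3,
                     n_configs=25, master_seed=1)
fit = fit_decay(kin, "lifetime_stretched", fixed_lifetime=params.tau_total)
print(f"tau = {fit.tau:.3f} ns, b = {fit.b:.3f}, msd = {fit.msd:.2e}")
```

prints

```
tau = 3.586 ns, b = 0.415, msd = 1.59e-08
```

i.e. at 0.04 nm⁻² with 30 % traps the quenching term decays with a
stretched time of ~3.6 ns and exponent b ≈ 0.42 — strongly nonexponential,
and well above the ideal 2D single-donor exponent 1/3 because energy
migration between donors accelerates trapping.  The `examples/` scripts
walk through each capability (pair kinetics vs closed form, trap-model and
orientation comparisons, the analytic limit, and a phthalocyanine-solution
scenario with IRF convolution); packaged scenario configs are listed by
`fretquench.packaged_config_names()` and runnable via

```bash
fretquench simulate -c fig3_2d_random --n-configs 10 -o out/
```

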