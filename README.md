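# permeakin

Multi-scale modelling of K⁺ permeation through KcsA-like potassium
channels, for computational biophysicists who want to connect channel
structure to single-channel electrophysiology without running molecular
dynamics.

The package implements three coupled layers:

1. **Steric Poisson–Boltzmann equilibrium** (`permeakin.geometry`,
   `permeakin.solver`).  A parametric KcsA-like pore — a selectivity
   filter (SF) about 12 Å long and 3 Å wide spanning z ∈ [−4.15, 11.12] Å,
   flanked by vestibules and lined by rings of carbonyl-like partial
   charges — is rasterised onto a 3D grid, and the Bikerman–PB equation
   is solved by finite volumes:

       ∇·(ε(x)∇φ) + z_p e p + z_n e n + q = 0

   with steric (lattice-gas) ion distributions that cap each species at
   its reciprocal ion volume, p ≤ 1/a³ (≈79 M for a_K = 2.76 Å), and a
   Born solvation penalty ΔW = z²e²/(8πε₀r)·(1/ε_r(x) − 1/ε_bulk) for
   entering the low-dielectric filter (ε_SF = 1.5 → ΔW ≈ 132 k_BT for
   K⁺).  The solve yields the line density λ(z) of K⁺ along the pore and
   per-site occupancies: the equilibrium filter holds ions at sites
   S0/S2/S3/S5 and leaves S1/S4 empty, with Cl⁻ excluded.

2. **Rate theory** (`permeakin.profiles`, `permeakin.rates`).  1D free-
   energy profiles U(x) are converted to rate constants by mean
   first-passage time quadrature, k = [τ_f + τ_b·Z_f/Z_b]⁻¹ with
   τ = (1/D)∫dy e^{+βU(y)}∫dz e^{−βU(z)}, checked against the
   high-friction Kramers closed form; diffusion-limited association
   constants come from Smoluchowski theory through a hemispherical shell
   (k_a = 2πD[∫ e^{βU}/r² dr]⁻¹) or a cylindrical vestibule
   (k_a = πDr_v²[∫ e^{βU} dr]⁻¹).  Membrane voltage tilts profiles by a
   linear potential drop.

3. **4-state kinetic scheme** (`permeakin.kinetics`).  Permeation is an
   association/dissociation cycle over four filter configurations
   (3-ion outer, 4-ion, 3-ion inner, 2-ion) with eight binding/unbinding
   constants and a voltage-dependent single-file interconversion
   k_f(V), k_b(V).  Steady states, microscopic-reversibility
   diagnostics/repair (cycle products, log-space projection), single-
   channel currents, IV curves, conductance–concentration curves and
   reversal potentials all derive from the published rate table
   (`TABLE_RAW_MD`, `TABLE_ADJUSTED`, values × 10⁸).

## Worked example

```python
import numpy as np
from permeakin import (TABLE_ADJUSTED, TABLE_RAW_MD, DriveConditions,
                       cycle_balance, enforce_reversibility, iv_curve,
                       reversal_potential, debye_length)

# Screening length inside the filter (single-species form, eps_r = 1.5,
# 100 mM, 300 K) - printed as 1.89 A:
print(debye_length(1.5, 0.1, 300.0))        # 1.8864114264654717

# The raw simulation-derived rate constants violate microscopic
# reversibility; the adjusted table closes all three cycles exactly:
print(cycle_balance(TABLE_RAW_MD))          # (3.573, 0.678, 5.272)
print(cycle_balance(TABLE_ADJUSTED))        # (1.0, 1.0, 1.0)
bal = enforce_reversibility(TABLE_RAW_MD)   # log-space projection
print(np.max(np.abs(bal.as_array() / TABLE_RAW_MD.as_array() - 1)))  # 0.301

# IV curve at symmetric 100 mM: zero current at equilibrium, outward
# rectification, sublinear saturation toward both extremes:
iv = iv_curve(TABLE_ADJUSTED, DriveConditions(0.0, 0.1, 0.1),
              [-200, -100, 0, 100, 200])
for v, i in zip(iv["V_mV"], iv["I_pA"]):
    print(f"{v:6.0f} mV  {i:8.3f} pA")
#  -200 mV    -4.889 pA
#  -100 mV    -4.679 pA
#     0 mV     0.000 pA
#   100 mV     6.020 pA
#   200 mV     6.372 pA

# A 10-fold outward K+ gradient reverses at the Nernst potential:
print(reversal_potential(TABLE_ADJUSTED, 0.1, 1.0))  # 59.526 mV = 25.85*ln(10)
```

The equilibrium continuum layer runs in a few seconds on the reduced
0.5 Å grid:

```python
from permeakin import (default_kcsa_spec, make_geometry, reduced_grid,
                       default_params, solve_equilibrium, line_density)

geo = make_geometry(default_kcsa_spec(), reduced_grid(0.5), eps_sf=1.5)
state = solve_equilibrium(geo, default_params())
print(line_density(state, geo).occupancy)
# {'S0': 0.196, 'S1': 0.000, 'S2': 0.169, 'S3': 0.173, 'S4': 0.000, 'S5': 0.365}
```

Occupied S0/S2/S3/S5 and empty S1/S4 — the alternating filter loading
that motivates the kinetic scheme.  The command-line interface mirrors
these operations (`permeakin solve-bpb`, `scan-eps`, `rates`, `iv`,
`gc`, `check-reversibility`, `run --config run.toml`).

## Layout

    src/permeakin/
      geometry.py    synthetic channel geometry, charge rings, PQR import
      bikerman.py    steric ion distributions, Born solvation, Debye lengths
      solver.py      3D finite-volume Bikerman-PB solve, line densities, scans
      profiles.py    1D free-energy profiles (synthetic or tabulated)
      rates.py       MFPT / Kramers / Smoluchowski rates, voltage tilting
      kinetics.py    4-state scheme, reversibility, IV and G(c) curves
      io.py          OpenDX, PQR, CSV, TOML
      pipeline.py    configured end-to-end runs with checksummed manifests
      cli.py         the `permeakin` command
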