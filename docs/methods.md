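# Methods

## Scope and model structure

permeakin connects three descriptions of K⁺ permeation through a
KcsA-like channel. An equilibrium continuum model establishes *where*
ions sit in the selectivity filter (SF); rate theory turns 1D free-energy
landscapes into *how fast* ions bind, unbind and shuffle; and a 4-state
kinetic scheme assembles those rates into steady-state currents. The
layers share unit conventions (Å, k_BT, mol/L, mV, s⁻¹) and are usable
independently.

## Equilibrium continuum layer

### Governing equations

The electrostatic free energy contains the mean-field Coulomb energy,
ideal and excluded-volume (lattice-gas) entropy, and a Born solvation
energy per ion. Stationarity gives the Poisson equation

    ∇·(ε₀ε_r(x)∇φ) = −(z_p e p + z_n e n + q)

with equilibrium concentrations obtained by equating the steric chemical
potential μ_i = z_i eφ + k_BT[ln(c_i a_i³) − ln(1 − p a_p³ − n a_n³)] + W_i
to its bulk value. Solving that equality for p and n gives

    p = p_b E_p / (1 − v_b + p_b a_p³ E_p + n_b a_n³ E_n),
    E_i = exp(−z_i eφ/k_BT − ΔW_i/k_BT),   v_b = p_b a_p³ + n_b a_n³

and analogously for n. Two limits pin the form down: as a³ → 0 it
reduces to the classical Boltzmann–Born distribution, and as φ → −∞ the
cation concentration saturates at 1/a_p³ *independently of the solvation
penalty* (the penalty delays saturation but cannot lower the ceiling).
The second limit is what produces the ≈79 M plateaus at the carbonyl
ridges inside a filter whose Born penalty is ~132 k_BT; a variant that
omits the Born factor from the denominator would cap the filter
concentration at 79·e^{−βΔW} M ≈ 0 and cannot reproduce that behaviour,
which is why the full factor appears in the denominator here.

The Born penalty is evaluated from the *local* dielectric field,
ΔW_i = z²e²/(8πε₀r_i)·(1/ε_r(x) − 1/ε_bulk), so cells inside the
dielectric transition ramp get intermediate penalties.

### Parameters

| quantity | default | unit | origin/role |
|---|---|---|---|
| a_K, a_Cl | 2.76, 3.62 | Å | ion lattice diameters; set the Bikerman ceilings (79 M, 35 M) |
| Born radii | a/2 | Å | solvation penalty scale; K⁺: 132 k_BT at ε=1.5 |
| D_K, D_Cl (bulk) | 1.957, 2.032 ×10⁻⁹ | m²/s | Smoluchowski association constants |
| D (bath / filter) | 0.235 / 0.040 | Å²/ps | first-passage prefactors |
| ε_bulk, ε_protein, ε_SF | 80, 2, 1.5 | — | ε_SF is a model parameter; the scan {10…1.5} shows S1/S4 emptying as it falls |
| c₀ | 0.1 | M | symmetric KCl bath |
| T | 300 | K | thermal scale, k_BT/e = 25.85 mV |
| SF span, radius | [−4.15, 11.12], 1.5 | Å | filter region Ω_SF |
| probe radius | 1.4 | Å | rolling-ball regularisation of the protein surface |
| dielectric ramp | 2 | Å | width of the linear ε transition just outside each SF edge (the transition is stated to be sharp and linear; its width is a free choice) |

The single-species screening length √(ε₀ε_r k_BT/(c₀e²)) evaluates to
1.89 Å inside the filter (ε_r = 1.5, 100 mM, 300 K). Note this form
omits the factor 2 of the conventional 1:1-electrolyte Debye length;
`screening_length` provides the conventional form (1.33 Å under the same
conditions). Both are exposed because the filter value is quoted in the
single-species convention.

### What the synthetic geometry emulates — and what it does not

The generator replaces a crystal structure with a solid of revolution:
membrane slab, conical intracellular vestibule, narrow SF, shallow
extracellular mouth. The protein mask is regularised by a morphological
closing with a probe-radius ball (the grid-native accessible-surface
rule); the closing is never allowed to seal the parametric pore, whose
radius profile already describes the probe-accessible lumen.

The filter's electrostatics are emulated by six rings of four point
charges (one per subunit, dipole-compensated radially to mimic carbonyl
C=O polarity). A real structure's permanent-charge map is a full 3D
field; it is not reconstructible from printed information. Uniform rings
at the oxygen-plane positions produce a *uniformly* loaded filter in a
mean-field model — the alternating 0/2/3/5 occupancy is, physically, a
correlation/charge-map effect that mean-field theory only reproduces
when fed the detailed charge distribution. The default spec therefore
places one ring per binding site (S0–S5) with per-site weights
(S2/S3 = 1.0, S0/S5 = 0.6, S1/S4 = 0.25; base charge −0.95 e₀/point,
compensation offset 1.2 Å, ring radius 2.8 Å), calibrated once so the
reduced-grid solve at ε_SF = 1.5 reproduces the structure-inferred
equilibrium: line-density peaks near S0/S2/S3/S5, S1/S4 below 5 % of S2,
Cl⁻ excluded by >10³, and S1/S4 occupancy monotonically falling along
the ε_SF scan. Consequently, passing tests demonstrate that the solver
produces the correct physics *given* an attraction pattern of this
shape; they do not demonstrate that the pattern emerges from an
uninformed charge layout, and results on real structures require the
PQR import path. The oxygen-plane positions remain available as a
documented constant for users who want plane-positioned rings.

### Discretisation and solver

Finite volumes on a uniform cell-centred grid; face dielectric constants
are harmonic means, which enforces flux continuity at the
protein/solution interface (no surface charge lives on the interface —
ring charges are deposited volumetrically by trilinear weighting, which
conserves total charge to machine precision). Potential is stored in
k_BT/e; the source couples through 4π l_c with l_c = e²/(4πε₀k_BT)
≈ 557 Å. Boundary conditions: φ = 0 on both z faces (no applied bias —
the continuum layer is equilibrium-only), zero normal derivative on the
four lateral faces.

The default solve is a damped Newton iteration: the source derivative
∂ρ/∂φ ≤ 0 is evaluated analytically in a bounded form (occupied-fraction
formulation, immune to overflow at saturation), each linearised step is
solved by Jacobi-preconditioned conjugate gradients (the operator is
symmetric positive definite), steps are clamped to 25 k_BT/e with
backtracking. Convergence requires the scaled residual max-norm
h²‖F‖∞/(1+‖φ‖∞) < 10⁻⁶ *and* relative site-occupancy change < 10⁻⁵
between iterates. An explicit RK4 pseudo-time relaxation of the same
residual (`method="pseudo_time"`, Δt bounded by the diffusive stability
limit) is retained as a cross-check; it agrees with Newton to the
tolerance on 1D fixtures but is impractical for routine 3D use, which is
why Newton is the default.

Validation: a charged-sheet configuration at 10 mM with point ions
matches the closed-form Gouy–Chapman profile to better than 0.1 % within
two screening lengths (grid h = 0.5 Å); the charge-free problem returns
φ ≡ 0; x↔y symmetric inputs give symmetric fields; occupancies converge
under mesh halving.

### Problem sizes

Routine solves (tests, examples) use a reduced domain
[−9,9]×[−9,9]×[−14,20] Å at h = 0.5 Å (≈88 000 cells, seconds per
solve); the intracellular vestibule is truncated at the domain edge.
The full-resolution configuration (h = 0.2 Å over
[−30,30]²×[−38,35.6] Å) is exposed as `full_resolution_grid()` for
production runs.

### Observables

λ(z) integrates [K⁺] over solution cells within a 6 Å cylinder — wide
enough to include the vestibule entrance sites (which owe their large
peaks to cross-sectional room, not higher concentration), narrow enough
to exclude bulk. Site occupancies integrate λ over ±1.5 Å windows;
peaks are local maxima with prominence ≥10 % of the window maximum.
Window half-width, cylinder radius and prominence are configurable; none
of them is prescribed by theory.

## Rate-theory layer

`mfpt_rate` implements the two-well rate k = [τ_f + τ_b·Z_f/Z_b]⁻¹ with
the standard weights (outer e^{+βU}, inner e^{−βU}) by trapezoidal
quadrature after shifting U by its minimum (all exponents bounded by the
barrier height). The i/b/f landmarks identify the initial well, barrier
top and final well; each basin extends from the barrier to the grid edge
on its side, so the well partition functions Z are complete. (Truncating
the basins at the well minima would halve each Z and distort both the
Kramers agreement and the tilt identity by tens of percent.) The same
composite quantity evaluated on a detailed-balance random walk
(tridiagonal chain, hop rates (D/h²)e^{−βΔU/2}) agrees to <2 % across
random rough profiles; the high-friction Kramers form agrees to a few
percent for matched parabolic barriers ≥3 kcal/mol.

Voltage tilting subtracts a linear ramp worth z_eff·eV across a chosen
span. For interconversion rates the gradient is set by the well-to-well
distance and extended linearly through the wells, which makes the
detailed-balance identity k_f(V)/k_b(V) = (k_f/k_b)(0)·e^{z_eff eV/k_BT}
hold to <2 % for deep (≳5 kcal/mol), narrow (≲0.7 Å) wells; for broad
shallow wells the basin reweighting under the tilt genuinely shifts the
ratio and no convention removes that. "Forward" in this module means
the outward transition (accelerated by positive intracellular-minus-
extracellular voltage).

Smoluchowski association constants convert via N_A to s⁻¹M⁻¹; the
hemispherical form with U ≡ 0 reduces to 2πD r_c (1.11×10⁹ s⁻¹M⁻¹ at
r_c = 1.5 Å with bulk K⁺ diffusion), and the cylindrical-vestibule form
scales exactly as r_v² (ratio 2.52 between 13.5 and 8.5 Å vestibules).

## Kinetic layer

States: 1 = S0/S2/S3 (3-ion, outer entrance loaded), 2 = S0/S2/S3/S5
(4-ion), 3 = S2/S3/S5 (3-ion, inner entrance loaded), 4 = S2/S3 (2-ion).
Binding edges carry k_a·[K⁺] on the appropriate side; k_f (1→3) is the
*inward* single-file step — the configuration relabelling implied by the
balance equations makes 3→1 (k_b) the outward step. The default voltage
closure is a symmetric Eyring split with the signs that follow from that
orientation: k_f(V) = k_f(0)e^{−z_eff v/2}, k_b(V) = k_b(0)e^{+z_eff v/2},
v = eV/k_BT. With microscopically reversible constants every cycle
product then balances exactly at v = ln([K]_ex/[K]_in), so the
zero-current potential is Nernstian for z_eff = 1 — the orientation with
the opposite closure signs would reverse at −E_K and rectify inward,
which is how the sign convention was fixed.

The steady state replaces one balance row with Σn = 1, row-equilibrates
(rates span many decades at large |V|), checks the condition number, and
verifies every balance residual to 10⁻¹⁰ of the largest flux. The
current is evaluated on the intracellular side and cross-checked against
the extracellular side expression to 10⁻⁸ — at steady state the two are
equal by flux conservation, and a mismatch marks a non-stationary
occupancy.

Microscopic reversibility: the three cycle products (two independent —
the third cycle is the ratio of the first two) are reported as
clockwise/counter-clockwise ratios. `enforce_reversibility` projects
log-rates orthogonally onto the constraint subspace (minimal sum of
squared log-changes); the published adjusted table is a fixed point, and
balancing the raw table moves no constant by more than ~30 %. The
published manual adjustment is not the orthogonal projection (its
largest change is 33 % on one association constant), so the projected
raw table and the published adjusted table differ slightly; the
published adjusted column is used as the default rate set.

Behavioural properties with the adjusted table at symmetric 100 mM:
I(0) = 0 exactly; outward rectification (+200 mV: 6.4 pA, −200 mV:
−4.9 pA); sublinear saturation toward both voltage extremes, with the
large-V ceiling equal to the stationary flux of the reduced scheme in
which the interconversion is one-way. The chord conductance G(c) rises
monotonically and flattens over the experimentally characterised
10 mM–1.6 M range; far beyond it (≳10 M) the scheme's G passes through a
maximum and falls, because saturating rebinding at both entrances traps
the filter in the 4-ion state — the "G(2c)/G(c) → 1" saturation
statement applies to the measured range, not the literal c → ∞ limit.

## Pipeline and I/O

A TOML configuration drives geometry → continuum → rates → kinetics;
physical quantities in the configuration are {value, unit} tables whose
units are validated at load (mismatches name the offending field).
Outputs are CSV tables with unit-bearing headers, OpenDX text grids
(full float64 precision, lossless round-trip) and a JSON report with
per-stage diagnostics and SHA-256 checksums of every written file; a
fixed (config, seed) pair reproduces identical checksums. PQR files are
parsed as whitespace ATOM/HETATM records (last five numeric fields =
x, y, z, charge, radius) and can replace the synthetic geometry.

## Known limitations

- Equilibrium only: no applied bias in the continuum layer, no
  Poisson–Nernst–Planck transport; voltage enters exclusively through
  the kinetic layer's closure.
- Mean-field: no ion–ion correlations beyond the lattice-gas entropy;
  the alternating site pattern is encoded in the calibrated ring
  weights, not emergent (see above).
- The kinetic layer's k_f(V), k_b(V) use the symmetric Eyring closure
  unless profile-derived rates are supplied; IV curves are therefore
  qualitative (shape, rectification sign, saturation), not fitted.
- Na⁺ selectivity, inactivation and blocker states are out of scope.
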