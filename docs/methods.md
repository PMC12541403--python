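# Model and methods

## Scope

`redoxfilm` models a thin redox hydrogel film on a rotating-disc electrode:
viologen moieties (total concentration `v_total`) shuttle electrons by
self-exchange hopping, treated as apparent diffusion of the oxidized and
reduced forms with a common coefficient `d_e`; an immobilized [FeFe]
hydrogenase interconverts H₂ and protons using the viologen couple as its
redox partner; H₂ and O₂ enter the film from the solution side.  The film is
one-dimensional in the normalized coordinate ξ = x/L, with the electrode at
ξ = 0 and the film/solution interface at ξ = 1.

## Governing equations

Species: oxidized fraction u = [V_ox]/v_total (so [V_red] = v_total(1−u) and
mediator conservation is built in), dissolved H₂ and O₂, and the enzyme
split into active, reversibly inactive, and irreversibly dead pools (per
node; the enzyme does not move).

Chemistry:

    H2 + 2 V_ox  <->  2 H+ + 2 V_red        (enzyme, net rate r)
    O2 + s_o2 V_red -> products + s_o2 V_ox  (mediator autoxidation, rate q)

with q = k_o2_v·[O₂]·[V_red] and s_o2 = 1 by default (viologen radical →
superoxide; configurable to 2 or 4 for peroxide/water stoichiometries, which
the available data do not distinguish).

The enzyme rate law is a reversible two-substrate form,

    r = e_active · k_cat_ox · (a_ox − C·a_red) / (1 + a_ox + a_red)
    a_ox = (v_ox/K_vox)²·(h2/K_h2),   a_red = (v_red/K_vred)²

quadratic in the mediator because two one-electron mediator events are
needed per H₂.  The constant C is not free: detailed balance fixes it so
that r = 0 exactly when the local mediator Nernst potential equals the
H⁺/H₂ equilibrium potential at the local H₂ activity,

    C = exp(2F(E_eq − E⁰)/RT) · c_sat · K_vred² / (K_vox²·K_h2),

where c_sat (`h2_solubility`) is the dissolved-H₂ concentration at 1 bar.
This is the property the tests pin down (zero net rate at equilibrium,
correct forward/reverse limits, linearity in active enzyme); the saturation
denominators are a conventional choice.

Oxidative inactivation is driven by the *local* Nernst potential
E_V = E⁰ + (RT/F)·ln(u/(1−u)):

    k_i = k_x·exp(+α(E_V − E_inact)/2),  k_a = k_x·exp(−α(E_V − E_inact)/2)

equal at E_inact by construction, with the steady inactive fraction a
logistic function of α(E_V − E_inact).  O₂ adds a parallel
active → inactive channel at rate `k_inact_o2`·[O₂], of which a fraction
`phi_irr` (default 0) is diverted to the dead pool — the knob that turns
the fully recoverable film into one that loses a constant fraction of
activity per air exposure.

Rate ceiling: the exponential pair saturates at a shared ceiling `k_cap`
(both rates scaled down together wherever max(k_i, k_a) would exceed it).
The ratio — hence every equilibrium — is untouched; only the transition
*speed* is bounded, reflecting that the protective cysteine-gate motion is a
slow conformational change.  Default 0.5 s⁻¹.  Without a ceiling,
reactivation at low potential would be so fast that no O₂-inactivation
front could ever form, which contradicts the observed front propagation.

Boundary conditions: the mediator is confined (zero flux at ξ = 1) and in
Nernstian equilibrium with the electrode at ξ = 0 (u(0) set by
exp(F(E−E⁰)/RT); no interfacial resistance).  H₂ and O₂ are zero-flux at the
electrode and take partition-scaled bulk values at ξ = 1; no external
diffusion layer is modelled, consistent with rotation-rate-independent
currents.  Protons/buffer are not modelled; pH enters only through E_eq and
the detailed-balance constant (buffered electrolyte).

The current density is the electron flux at the electrode,
j = F·d_e·∂[V_red]/∂x |₀ (second-order one-sided difference), positive for
H₂ oxidation.  At anaerobic steady state it equals 2F·∫r dx; with O₂
present, part of the enzymatic turnover is sacrificial (it reduces incoming
O₂ rather than the electrode).

## Numerics

Uniform grid (default 200 nodes, minimum 50), second-order central
differences, ghost-node closure of the zero-flux boundaries.  Steady states:
damped Newton on the interleaved (u, ĥ, ŵ) system with a banded
finite-difference Jacobian (bandwidth 3, 7-coloring), the enzyme pools
eliminated algebraically (exact at steady state), and a pseudo-transient
fallback; convergence at inf-norm residual ≤ 1e-8 in normalized units (about
1e-10 relative to the dominant rate scale).  Transients: method of lines
with SciPy's BDF, analytic sparsity pattern, rtol 1e-8 / atol 1e-12 in
normalized units (1e-6/1e-9 for voltammetry, where the driving program
changes on the 0.1 s scale); snapshot times are honored exactly via
`t_eval`, and CV/CA programs are integrated sweep-by-sweep so vertices and
steps restart the integrator.  Nernst potentials at numerically fully
oxidized/reduced nodes (fraction beyond 1−1e-14) are flagged NaN rather than
raised.

The one-sided electrode flux and the trapezoid rate integral discretize the
same balance differently; they agree to ~0.4% at 1600 nodes (first-order in
dx because of the thin electrode-equilibration layer), which is the grid the
electron-balance cross-check uses.

## Default parameters (the simulated study conditions)

| parameter | default | why |
|---|---|---|
| L (`thickness`) | 1 µm | drop-cast dendrimer film scale |
| `v_total` | 100 mol m⁻³ | ~0.1 M viologen in hydrogels |
| `d_e` | 1e-12 m² s⁻¹ | typical apparent electron diffusion in viologen films |
| `d_h2`, `d_o2` | 1e-9 m² s⁻¹ | hydrogels are mostly water; near-aqueous gas diffusivities. This keeps H₂ depletion inside the film mild, the regime the film electrodes operate in |
| `part_h2`, `part_o2` | 1 | no partitioning data available |
| `e_total` | 10 mol m⁻³ | 0.16 nmol enzyme in a ~1e-11 m³ film implies order 5–20 mol m⁻³; strong catalysis is required for the outer film to equilibrate with H⁺/H₂ |
| `k_cat_ox` | 1000 s⁻¹ | [FeFe] hydrogenases turn over at 10³–10⁴ s⁻¹ |
| `K_h2` | 0.1 mol m⁻³ | currents are H₂-saturation independent at 1 bar (0.78 mol m⁻³), so K_h2 ≪ c_sat |
| `K_vox` | 1 mol m⁻³ | high affinity for the oxidizing substrate; keeps the film responsive near equilibrium |
| `K_vred` | 100 mol m⁻³ | weak product inhibition |
| `E_inact` | +0.17 V vs RHE (−0.25 V SHE at pH 7) | the inactivation gate is coupled to the H⁺/H₂ scale: pinning it vs RHE reproduces both the pH-7 value and the observation that high-pH operation is harsher for the high-potential mediator while the viologen E⁰ is pH-independent |
| `k_x` | 0.1 s⁻¹ | seconds-scale interconversion at E_inact |
| `alpha` | 79 V⁻¹ (≈ 2F/RT) | the protective window closes within ~50 mV: a mediator E⁰ of −0.3 V vs SHE at pH 7 is the upper edge of usable potentials |
| `k_inact_o2` | 100 m³ mol⁻¹ s⁻¹ | ~1e5 M⁻¹ s⁻¹, typical O₂ attack on reduced [FeFe] sites |
| `k_o2_v` | 1000 m³ mol⁻¹ s⁻¹ | conservative lower bound on viologen-radical autoxidation; Damköhler ≈ 70 keeps O₂ scavenging inside the film and resolvable on the grid |
| `temperature` | 293.15 K | experiments at 20 °C |

`default_parameter_set` exposes these with the mediator/pH combinations of
the two dendrimers (DV1: −0.22 V; DV2: −0.40 V vs SHE) and the polymer
(PV2: −0.431 V).

Potential-scale convention: E_eq uses the rounded 60 mV/pH slope (so
E_eq(pH 7) = −0.420 V vs SHE exactly), matching how such values are quoted;
the physically exact 2.303RT/F slope is available by passing
`slope_mV_per_pH=None`.  All potentials are carried internally vs SHE; RHE
is a pH-dependent view.

## Derived diagnostics

*Reaction layer*: nodes where the enzymatic rate is ≥ 10% of its spatial
maximum **and** the oxidized mediator fraction is ≤ 0.9.  The second clause
excludes the thin electrode-equilibration zone where E_V simply tracks the
applied potential; what remains is the region whose rate-weighted mean E_V
(`layer_potential`) is the potential the working enzyme population
experiences — buffered near the mediator E⁰.

*Inactive-enzyme front*: scanning inward from ξ = 1, the first crossing of
e_inactive + e_dead above e_total/2, linearly interpolated.

*Front-speed estimate*: speed = s_o2·J_O2 / (v_red_eq·(1 + J_e/(s_o2·J_O2)))
with J_O2 = d_o2·[O₂]_s/L and J_e = d_e·v_red_eq/L.  The incoming O₂ flux
must both titrate the standing reduced-mediator pool (v_red_eq, the pool at
H⁺/H₂ equilibrium — smaller for lower mediator E⁰, which is why the front
runs faster for the low-potential mediator) and fight the electron-hopping
resupply across the inactivated zone.  It matches simulated front
displacement within a factor of 2 over a tenfold range of bulk O₂ and
reproduces the mediator ordering.

*Zero-crossing potential*: mean of the forward- and reverse-sweep crossings;
averaging cancels the antisymmetric pseudocapacitive (mediator-charging)
contribution to first order, recovering E_eq within a few mV at 10 mV/s.

*Mediator E⁰ extraction*: Savitzky–Golay smoothing (window 11, order 2,
configurable), interior extrema per sweep direction, ties broken toward the
sweep midpoint, midpoint (E_pa+E_pc)/2.  Exact on ideal surface-confined
waves; 0.5 mV bias on the diffusion-tailed variant (symmetric peak shifts
cancel in the midpoint).

## What the synthetic generators emulate — and what they do not

The generators reproduce the *structure* of the measured traces: symmetric
mediator waves (surface-confined or diffusion-tailed), sigmoidal catalytic
waves crossing zero at E_eq with a plateau and an optional high-potential
fall-off, step-response CAs, and geometric per-exposure activity decay, all
with additive Gaussian noise proportional to the signal scale (default 5%,
motivated by the ±15% spread of replicate film measurements) and
deterministic seeding.  They do not emulate capacitive backgrounds, iR drop,
potentiostat filtering, film-to-film loading variability, or drift, so
recovery tests certify the estimators against the stated noise model only —
accuracy on real traces depends on those unmodelled artifacts being removed
upstream.

## Design choices made where the design was open

- **Enzyme loading and gas diffusivities** are set to place the model in the
  regime the film electrodes demonstrably operate in (mild H₂ depletion,
  outer-film equilibration with H⁺/H₂, strong-catalysis titration
  structure), with magnitudes from the film composition and hydrogel
  physics, rather than at the weak-catalysis end of the plausible range.
- **E_inact pinned vs RHE** (see table): the alternative — fixed vs SHE at
  all pH — cannot reproduce the worsening of anaerobic inactivation with pH
  at fixed mediator E⁰.
- **Per-cycle loss model** is exponential (geometric); the per-exposure
  percentage readout implies a multiplicative process.  The log-linear
  least-squares estimator returns r = 1 − exp(slope) with a delta-method
  standard error.
- **Normalization** by the maximal positive current uses the global maximum
  over the whole trace (the forward-sweep maximum is nearly identical for
  these waves).
- **Thin-film linearity** of the plateau current in enzyme loading holds in
  the kinetically limited regime, i.e. while the film's total enzymatic
  capacity 2F·L·k_cat·e_total stays below the mediator-transport ceiling;
  the linearity check therefore runs at loadings of 0.005–0.02 mol m⁻³
  (R² > 0.999 over that 4× range).  At the default loading the current is
  transport-limited and deliberately insensitive to loading.

## Problem sizes used

Steady profiles: 200 nodes (1600 for the electron-balance cross-check).
Voltammetry: 80 nodes, 240 samples per sweep at 10 mV/s.  O₂-exposure
transients: 120–150 nodes, seconds of simulated time (the front crosses a
1 µm film in ~1 s at 5% O₂).  Dual-solver cross-checks: 60 nodes, 150 s of
simulated time, 10 random parameter draws.

## Known limitations

- 1D, uniform, non-swelling film; no electrostatics, no explicit
  H₂O₂/superoxide follow-up chemistry, no proton transport.
- The near-electrode equilibration layer is much thinner than a grid cell
  under strong bias; E_V(0) is exact by construction, but the electrode
  flux converges only first-order in dx (hence the fine-grid balance
  check).
- With a mediator E⁰ *below* E_eq (the DV2/pH 6 condition, E⁰ − E_eq =
  −40 mV), the catalytic wave foot extends ~100 mV above E_eq, so the
  current at −0.3 V vs SHE is thermodynamically bound to ~89% of its
  +0.2 V value: a flat (<5%) plateau over −0.3…+0.2 V cannot exist there,
  for any kinetics.  The plateau criterion holds at pH 7 and 8.8.
- The mediator-only CV generator and the film model treat the viologen as a
  one-electron couple; the second viologen reduction is outside the
  operating window and is ignored.
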