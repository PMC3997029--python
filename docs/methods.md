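# Methods

`gliawave` simulates intercellular Ca²⁺ waves (ICWs) in three-dimensional
networks of astrocytes coupled by gap-junction channels (GJCs), and asks how
the *organization* of those couplings — who is coupled to whom — controls
how far a wave travels.

## The single-cell model

Each astrocyte is a well-stirred point cell with three state variables:
cytosolic Ca²⁺ `C` (μM), the fraction `h` ∈ [0,1] of IP₃-receptor channels
not yet inactivated by Ca²⁺, and cytosolic IP₃ `I` (μM).  The dynamics are
the ChI model: Li–Rinzel Ca²⁺-induced Ca²⁺ release from the ER combined
with Ca²⁺-dependent IP₃ metabolism,

    dC/dt = J_C + J_L − J_P
    dh/dt = Ω_h (h∞ − h)
    dI/dt = J_δ − J_3K − J_5P + Σ_j J_ij

with

    J_C  = Ω_C m∞³ n∞³ h³ (C_T − (1+ρ_A) C),   m∞ = I/(I+d1),  n∞ = C/(C+d5)
    J_L  = Ω_L (C_T − (1+ρ_A) C)
    J_P  = O_P C² / (C² + K_P²)
    Q₂   = d2 (I+d1)/(I+d3),   h∞ = Q₂/(Q₂+C),   Ω_h = O₂ (Q₂+C)
    J_δ  = O_δ κ_δ/(κ_δ+I) · C²/(C²+K_δ²)
    J_3K = O_3K C⁴/(C⁴+K_D⁴) · I/(I+K_3K)
    J_5P = Ω_5P I

All parameters (units: μM, s) default to the published calibration of this
network model (`ChIParams`); they are strictly positive and validated at
construction.  These are the canonical ChI flux forms, the unique choice
consistent with the parameter names and units of that calibration; but
published variants of the model family differ in details (Hill exponents,
degradation kinetics) that a calibration table alone cannot pin down, so
small discrepancies against the original simulator cannot be excluded.
This uncertainty is quantified below under *Fidelity*.

Two fixed points matter.  The resting state (C ≈ 0.035, h ≈ 0.91,
I ≈ 0.305 μM) is the quiescent baseline and the initial condition of every
simulation.  With the reference parameters there is also a second stable
fixed point — the **Up state** (C ≈ 0.48, I ≈ 1.15 μM) — so the isolated
cell is bistable: a cell pushed above I ≈ 0.53 μM does not relax on its
own; in a network it returns to rest only by draining IP₃ to its
neighbours.  `detect_up_state` flags cells whose final-10% time averages of
C and I both exceed twice the resting values.

Clamping `I` at a constant level yields sustained Ca²⁺ oscillations for
I ≈ 0.55–1.13 μM, with period decreasing from ≈ 28 s to a minimum of
≈ 17.2 s near the upper end (`minimum_oscillation_period`; measured as the
mean inter-peak interval of the second half of a 400-s run on a 0.02-μM
clamp grid).

## Gap-junction IP₃ transport

Couplings carry IP₃ only.  The default nonlinear flux into cell *i* from
neighbour *j* is

    J_ij = −(F/2) (1 + tanh((|ΔI| − I_θ)/ω_I)) · sign(ΔI),   ΔI = I_i − I_j

a threshold-gated, saturating exchange: negligible below the gradient
threshold I_θ = 0.3 μM, saturating at the coupling strength F = 2 μM s⁻¹.
At ΔI = 0 the flux is defined as 0 (odd extension).  A linear (Fickian)
mode `J_ij = −F ΔI` with F in s⁻¹ is available.  Per-edge strengths, when a
network carries them, replace F symmetrically; `heterogeneous_strengths`
draws them from a normal law rejection-sampled into [0, 2F], which
preserves the mean exactly.  The exchange is conservative by construction:
each edge contributes equal and opposite fluxes to its endpoints.

## Stimulation

A wave is triggered by stimulating one cell — by default the cell nearest
the domain centroid — for the whole 200-s run.  The default mode adds an
IP₃ production bias of 2 μM s⁻¹ to that cell.  This choice matters: the
injected IP₃ is then a *finite resource* that the source divides among its
k neighbours, which is the premise of the dilution mechanism that limits
wave range.  The alternative clamp mode (holding the source's IP₃ at 2 μM,
overridden inside every integrator stage) makes the source's output grow
with its degree — up to k·F μM s⁻¹ indefinitely — and qualitatively changes
the propagation regimes: dense networks then conduct waves *better*, not
worse.  Only the additive mode reproduces the published phenomenology
(extent decreasing with mean degree, shortcut damage, the ten-fold
lattice-vs-regular gap), so it is the default; the μM figure quoted for the
bias in the reference calibration is read as μM s⁻¹.

## Numerical integration

Fixed-step classical Runge–Kutta (RK4) with dt = 10 ms over T = 200 s, all
cells starting at rest.  The integrator is a compiled (numba) kernel over
packed parameter and edge arrays; the pure-NumPy right-hand side
(`network_rhs`) is retained as the reference implementation and the two are
tested against each other to ~10⁻¹⁰ relative error.  The stimulus override
is applied inside every RK4 stage, not as a post-step projection, so stage
derivatives never see a spurious relaxation.  A cell is *activated* when
its Ca²⁺ first reaches C_θ = 0.7 μM, sampled at step resolution (dt is two
orders of magnitude below the wave timescales; halving dt leaves activation
counts unchanged on the test fixtures).  The wave extent N_act counts cells
activated at least once, the stimulated cell included.  Non-finite states
abort with a diagnostic.

## Spatial placement

N = n³ cells start on a cubic lattice with spacing a and are jittered
independently per axis.  Defaults: n = 11, a = 70 μm, jitter = uniform on
(−σ/2, σ/2) with σ = 55 μm.  This reproduces the measured
nearest-neighbour distance statistics of hippocampal astrocytes — mean
≈ 50 μm, minimum ≈ 20 μm, coefficient of variation ≈ 0.25 — which is the
calibration criterion (`calibrate_placement` greedily minimises the summed
squared relative error of the three statistics over an (a, σ) grid).  A
Gaussian jitter option exists, but a Gaussian of comparable scale cannot
match all three statistics at once (σ = 55 μm gives mean 44.7 μm, CV 0.43);
the uniform reading is the one consistent with the calibration targets.
Jitter may produce pairs closer than 20 μm; no rejection is applied and the
minimum is reported, not enforced.

## Coupling topologies

Five generators, all emitting simple undirected graphs with provenance:

- **regular degree** — candidate pairs visited by increasing distance, an
  edge added while both endpoints have degree < k.  A strict k-nearest-
  neighbour union is not k-regular; this greedy matching is the closest
  realizable reading of "exactly k couplings each", with the realized mean
  degree (slightly below k) recorded.
- **link radius** — all pairs within Euclidean distance d.
- **shortcut** — axis-aligned lattice couplings at 1…m_latt internode
  steps, built *before* the jitter and left fixed; each edge then rewired
  with probability p_s by replacing one uniformly chosen end with a uniform
  random node, resampled until the graph stays simple (edge count exactly
  preserved).  Open boundaries: the nominal bulk degree 6·m_latt is reached
  only in the interior.
- **spatial scale-free** — growth with preferential attachment weighted by
  k_j · exp(−d_ij/r_c); random insertion order, complete seed on the first
  m_sf nodes, newcomers attach to m_sf distinct nodes (weights rescaled by
  the minimum distance before exponentiation, which is exact for the
  normalised law and avoids underflow at small r_c).
- **Erdős–Rényi** — distance-blind, each pair with probability p.

`voronoi_adjacency` returns the Delaunay-neighbour graph of the positions —
the expected coupling rule for domain-tiling astrocytes; interior cells
(outermost lattice layer excluded) have mean degree ≈ 15.3, dropping to
≈ 12.1 / ≈ 9.2 after uniform removal of 21% / 40% of cells
(`removal_mean_degree`, induced subgraph, averaged over removal draws).

The quantifiers are the mean degree ⟨k⟩ = 2E/N and the mean shortest path
L, averaged over ordered pairs at finite hop distance with the disconnected
pair fraction reported separately (the minimal-degree acceptance rule —
under 2% disconnected pairs at k = 3 — is applied as a filter only when
requested).

## Shell analysis

Shells are breadth-first layers around the stimulated cell: N_r cells at
distance r, W_r intra-shell edges, E_r edges to shell r+1 (every edge of
the source's component is one or the other — the BFS property, asserted in
tests).  With a fraction ρ of shell r activated and Q₀ the IP₃ output per
activated cell, the expected per-recipient supply is

    Ψ_out^r = Q₀ ρ N_r / (N_{r−1} + N_{r+1} + 2ρ(1−ρ) W_r)

so intra-shell couplings strictly dilute the dose reaching the next shell.
Cubic lattices have W_r ≡ 0; regular-degree networks of identical mean
degree do not, and correspondingly carry waves roughly an order of
magnitude less far (measured max ratio ≈ 12 over matched pairs).  ρ is
measured per shell at the moment the first cell of shell r+1 activates
(`measure_shell_activation`); Q₀ is treated as an abstract unit.

## The simplified UAR model

The three-state automaton (Unactivated → Activated → Refractory → U)
replaces the biophysics with one rule: an A cell's *propagation efficiency*
is β = 1/N^u (its IP₃ pool divided among its N^u unactivated neighbours,
zero when it has none), and a U cell fires, with per-step probability
1 − exp(−dt/τ_U), while Σβ over its neighbours exceeds ϑ = a·k + b.  A→R
and R→U relax at rates 1/τ_A and 1/τ_R.  Updates are synchronous at
dt = 0.1 s.  The stimulated source is re-seeded to A and propagates at full
efficiency (β = 1) while stimulated: an externally driven cell's IP₃ is
continuously replenished, and in the ChI model the stimulated source indeed
activates its entire neighbourhood for every degree up to 15, unlike a
pool-limited relay.

Calibration from the ChI model (`calibrate_uar`):

- τ_U = 6.3 s — median shell-to-shell activation delay of a 5³ lattice
  wave.  (The two-cell transmission delay, 0.31 s, is also measurable but
  reflects a directly stimulated donor ~10× stronger than a relay cell.)
- τ_A = 14.3 s — median time a relay cell on that wave keeps its IP₃ above
  I_rest + I_θ, the level able to drive transport into a resting
  neighbour.  The reference is relative to rest because resting IP₃
  (0.305 μM) already exceeds the absolute gradient threshold (0.3 μM); and
  the measurement needs a network context because an isolated activated
  cell sits in the bistable Up state and never relaxes.
- τ_R = T_min − τ_A = 2.9 s, with T_min ≈ 17.2 s the minimum single-cell
  oscillation period.
- (a, b) ≈ (0.040, 0.062) — a least-squares line through per-degree
  activation thresholds ϑ(k), each measured as the minimal efficiency of a
  single just-activated donor (Up state, with u private resting sinks, so
  β = 1/(u+1)) that fires a degree-k hub within the donor's active period.

## Sweeps and reproducibility

`run_sweep` executes one simulation per (parameter point, replicate), 20
replicates by default, on freshly sampled positions and networks.  Per-run
seeds derive from `SeedSequence([base, point, replicate])` (kept below
2³¹), so reruns are bit-identical; completed rows in an existing CSV are
skipped, and individual failures are recorded as flagged rows without
stopping the sweep.  Summaries are mean ± sample SD (ddof = 1).

## Problem sizes used in the test suite

Unit tests run on 2-cell, star, 5³ and 7³ fixtures.  The end-to-end checks
use the full 11³ geometry with 200-s runs but 5 network samples per
condition and coarse parameter grids (3 degrees per family, 2–3 strength
levels), sizes chosen so the whole suite completes in minutes on one CPU
while leaving every qualitative contrast measurable at full spatial scale.

## Fidelity and known limitations

- **What matches.**  Placement statistics (50 μm / 0.25), Voronoi degree
  estimates (15.3 → 12.1 → 9.2 under removal), minimal-degree
  connectivity (<2% disconnected pairs at k = 3), the single-cell minimum
  period (17.2 s vs the reported ≈ 16 s, within the flux-form uncertainty),
  the decrease of wave extent with mean degree in both spatially
  constrained families, the collapse of propagation under rewiring, the
  order-of-magnitude lattice-vs-regular gap, and the coupling-strength
  window (no propagation below ⟨ΣF⟩ ≈ 0.1 μM s⁻¹, regenerative Up-state
  propagation for 0.1–1, strong reduction above 1) — with the regular-k6
  extent (median 137) inside the reported range.
- **What deviates, and why.**  The calibration table constrains the
  model's excitability only up to the flux-form details noted above.  Three consequences are visible: (i) waves at k = 3 are fully
  regenerative but advance at ≈ 8–12 s per hop, reaching ~72% of the
  network by 200 s (~92% by 400 s) instead of ≈ 100%; (ii) the
  spatial-scale-free extent (median 52) runs ~2.5× above the reported
  ≈ 20; (iii) the isolated cell is bistable (the Up state exists at *all*
  coupling strengths, though drainage hides it at strong coupling), which
  lengthens the donor residence time.  The last point propagates into the
  UAR calibration: with τ_A ≫ τ_R, marginal fronts in the automaton
  avalanche (activation concentrates β on survivors faster than donors
  retire), so the UAR saturates on regular-k6 and shortcut networks where
  the ChI engine stalls, and its rank agreement with the ChI engine across
  a mixed topology ensemble is ρ ≈ 0.6.
- The ⟨ΣF⟩ collapse is sharp for low-degree networks but bimodal at the
  window edge for ⟨k⟩ ≈ 10 (individual runs all-or-nothing), consistent
  with the optimal strength range narrowing as degree grows.
- Out of scope by design: extracellular ATP/purinergic signalling,
  intracellular spatial gradients and astrocyte morphology, stochastic
  channel gating, adaptive-step integration (fixed-step RK4 is part of the
  method's identity), periodic boundaries.
- The synthetic geometry emulates cell-centre statistics only; real
  astrocyte territories, process overlap and regional heterogeneity are
  not modelled, so passing tests demonstrate properties of the model class,
  not of any particular tissue.
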