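# Methods

## Model

`innatesim` integrates eight coupled balance laws on a 1-D strip of
homogenized tissue, x ∈ [0, L] (default L = 5 mm), over a few days
following a localized LPS injection.  Writing Δ for the 1-D Laplacian and
∇·(χ u ∇CH) for the chemotactic flux divergence, the full model (Case 5)
is

```
∂LPS/∂t = −μ_LPS·LPS − act − (λ_N|LPS·N + λ_AM|LPS·AM)·LPS + D_LPS·ΔLPS
∂RM/∂t  = −μ_RM·RM − act + source_RM + D_RM·ΔRM − ∇·(χ_RM RM ∇CH)
∂AM/∂t  = −μ_AM·AM + act + D_AM·ΔAM − ∇·(χ_AM AM ∇CH)
∂CH/∂t  = −μ_CH·CH + (β_CH|N·N + β_CH|AM·AM)·LPS·(1 − CH/ch_inf)/(1 + θ_AC·AC) + D_CH·ΔCH
∂N/∂t   = −μ_N·N − λ_LPS|N·LPS·N + source_N + D_N·ΔN − ∇·(χ_N N ∇CH)
∂ND/∂t  = μ_N·N + λ_LPS|N·LPS·N − λ_ND|AM·ND·AM + D_ND·ΔND
∂G/∂t   = −μ_G·G + α_G|N·source_N·(1 − G/g_inf) + D_G·ΔG
∂AC/∂t  = −μ_AC·AC + (β_RM|ND·RM·ND + α_AC|AM·AM)·(1 − AC/ac_inf) + D_AC·ΔAC
```

with macrophage activation `act = φ_RM|LPS·RM·LPS/(1 + θ_AC·AC)` and the
two-compartment extravasation sources

```
source_RM = [Hill(CH; P_RM^max, P_RM^min, keq_ch) + Hill(G; Q_RM^max, Q_RM^min, keq_g)]·(M^max − RM − AM)
source_N  =  Hill(CH; P_N^max,  P_N^min,  keq_ch)·(N^max − N)
Hill(c; hi, lo, keq) = lo + (hi − lo)·c/(c + keq)
```

All boundaries are zero-flux (Neumann).  Model assumptions worth keeping
in mind:

* **Homogenized vasculature.** Every tissue point exchanges cells with an
  overlying vascular pool (constants `M_max`, `N_max`); extravasation is a
  distributed source, not a boundary flux.  The pools do not deplete.
* **Generic cytokines.** CH and AC stand for pro-/anti-inflammatory
  cytokine classes (TNF-α/IL-8 vs IL-10/TGF-β), not specific molecules.
* **Saturating production, divisive inhibition.** Cytokine and granule
  production saturate at carrying capacities (`ch_inf`, `g_inf`,
  `ac_inf`); AC inhibits macrophage activation and CH production through
  the divisor `1 + θ_AC·AC`.

### Units

Time is in days, lengths in mm.  Concentrations carry the label
"10⁴ cells/mm³" but enter the arithmetic as the raw tabulated numbers:
the literature sources for the rate constants nominally quote them per
cells/mm³ while the initial conditions are quoted on the 10⁴ scale, and
the two are used together as printed.  Treating the scale as a label (one
"model unit") is the only reading that keeps every tabulated number
meaningful at once; none of the qualitative structure depends on it.
Mobility coefficients tabulated in μm²/day are converted to mm²/day
(×10⁻⁶), e.g. D_LPS = 2000 μm²/day = 0.002 mm²/day, χ_N = 14400 μm²/day =
0.0144 mm²/day.

### Default parameterization

`scenarios.default_parameters()` ships the standard set (all rates per
day; second-order rates per model-unit·day): decay/apoptosis μ_LPS=0.005,
μ_RM=0.033, μ_AM=0.07, μ_N=3.43, μ_CH=7, μ_G=5, μ_AC=4; activation
φ_RM|LPS=0.1 with θ_AC=1; phagocytosis λ_N|LPS=λ_LPS|N=0.55, λ_AM|LPS=0.8,
efferocytosis λ_ND|AM=2.6; permeability bounds P_RM∈[0.01,0.1],
Q_RM∈[0,0.5], P_N∈[0.0001,11.4] with keq_ch=keq_g=1; vascular pools
M_max=6, N_max=8; production β_CH|N=1, β_CH|AM=0.8, β_RM|ND=1.5,
α_AC|AM=1.5, α_G|N=0.6; capacities ch_inf=ac_inf=3.6, g_inf=3.1.  Two
readings of the source tables are worth flagging: the three mobility rows
that duplicate μ symbols with μm²/day units (3600, 4320, 14400) are the
chemotaxis coefficients χ_RM, χ_AM, χ_N — they are the only unhoused
symbols with matching units — and α_AC|AM, tabulated dimensionless, acts
as the 1.5/day AM production rate of AC.  Provenance strings
(literature / estimated / adjusted) are kept as metadata in
`scenarios.PROVENANCE`.

### Initial condition

LPS = 100 on the half-open interval [0, 1) mm and 0 on [1, L]; RM = 1
everywhere; all other species 0.  On the default dx = 0.1 mm grid the
trapezoid-integrated initial load is 95 conc·mm.  The node at exactly
x = 1 mm takes the outside value; this half-open convention matters for
the space-refinement study (below).

### Scenario ladder

Five nested configurations gate terms and species: Case 1 macrophages
only (monocyte influx at minimum permeability, no CH dynamics); Case 2
adds CH production by AM, its permeability effect and RM/AM chemotaxis;
Case 3 adds N and ND (Eqs. 5–6); Case 4 adds G and the granule
permeability channel; Case 5 adds AC and both inhibition divisors.
Disabled species are pinned at zero, contribute zero to every other
balance, and are not transported; consequently simulating Case k+1 with
the newly added switches off reproduces Case k bit-exactly (tested).

## Discretization

* **Grid.** Vertex-centered: nx nodes at 0, dx, …, L with
  dx = L/(nx−1); default dx = 0.1 mm (51 nodes).
* **Diffusion.** 3-point central stencil with mirror-ghost boundary nodes
  (f[−1] = f[1]), equivalent to the finite-volume form in which boundary
  nodes own half-width cells.
* **Chemotaxis.** Conservative first-order upwinding: the advective flux
  χ·u·∂CH/∂x is evaluated at the nx−1 cell interfaces, with u taken from
  the side the flux leaves (ties at zero velocity carry zero flux);
  domain walls are sealed, and the boundary divergence uses the same
  half-width cells as diffusion.  With this pairing both operators
  conserve the **trapezoid-rule** total mass to rounding error — the same
  quadrature `analysis.spatial_total` reports — which makes discrete
  bookkeeping identities (e.g. d(∫N + ∫ND)/dt = ∫source − ∫efferocytosis)
  exact per step.
* **Time stepping.** Forward Euler, so the scheme is first-order in dt
  and, through the upwinding, first-order in dx.  After each update any
  negative value is clamped to zero (explicit schemes can undershoot; the
  model is physically non-negative); clamp counts are logged per species.
  The production runs reported here trigger no clamps.
* **Stability guard.** `stability_bound(p, dx)` combines, per species,
  the diffusive/advective limit dx²/(2D + 2χ·ch_inf) — the advective
  velocity bounded by the whole cytokine carrying capacity dropping
  across one cell — with 1/R_max, where R_max bounds the fastest linear
  per-capita turnover with LPS-dependent rates evaluated at the bolus
  amplitude (lps_ref = 100, a documented keyword).  For the default
  parameterization at dx = 0.1 mm the bound is 2.76e-3 day, reaction-
  limited by the CH production slope; the production dt = 1e-5 day sits
  ~280× below it.  `euler_step`/`simulate` refuse any dt above the bound,
  naming the binding constraint.
* **Output alignment.** Requested output times snap to the nearest whole
  step (always within dt/2); no interpolation, so refinement studies are
  not contaminated by a second-order resampling artifact.

The inner loop is a numba-compiled kernel operating on the (8, nx) state
array; `numerics.euler_step` is the pure-numpy reference path and a unit
test pins the two to each other at 1e-12 relative tolerance.  A third,
independently coded transcription of the kinetics lives in the test suite
and must agree with `reaction_terms` to 1e-12.

## Studies and reported quantities

Problem sizes: the standard run is Case 5 on 51 nodes for 5 days at
dt = 1e-5 day (5·10⁵ steps, ~1 s compiled), with totals recorded every
0.01 day and full snapshots every 0.5 day.

* **Peak times.** Reported as the argmax (earliest on ties) of the
  trapezoid-integrated CH and AM series at the 0.01-day cadence, i.e.
  resolved to ±7.2 min.  With the default parameterization the CH total
  peaks at 4.32 h and the AM total at 36.48 h.  The CH peak sits on a
  broad plateau — the series is flat to <1.5% between ~3.5 h and ~6 h —
  so eyeballing a plotted curve could place it anywhere in that window;
  the AM peak is sharp by comparison.  Both values are converged with
  respect to dt (to 2e-6) and dx (to 0.025 mm).
* **Time-refinement study.** dt ∈ {4e-6, 8e-6} day against a dt = 1e-6
  reference, all at dx = 0.1 mm, error = per-species spatial L2 norm
  (√(dx·Σ(test−ref)²)) at the final time, aggregated across species by
  root-sum-of-squares; a single ratio is formed between specs differing
  by exactly a factor 2.  A 0.25-day horizon is ample: the ratio is
  horizon-insensitive and sits at the forward-Euler asymptote
  (dt₂−dt_ref)/(dt₁−dt_ref) = 7/3 ≈ 2.333.
* **Space-refinement study.** dx ∈ {0.4, 0.8} mm against a dx = 0.1 mm
  reference at fixed dt = 1e-5 day, errors restricted to coincident
  nodes.  Two design points:
  (1) the study runs on a 4.8 mm strip — 0.4 and 0.8 mm do not tile a
  5 mm vertex-centered domain, whereas on 4.8 mm every coarse node
  coincides with a reference node (strides 4 and 8);
  (2) it runs the full 5-day horizon.  The dominant spatial error is how
  the discontinuous bolus edge at x = 1 mm lands inside a coarse cell —
  an O(dx) contribution whose prefactor oscillates with the edge-to-node
  offset — and at short horizons (sharp front, two nodes per bolus) the
  coarse-grid error ratio is not yet meaningful.  At the 5-day horizon
  the aggregate ratio is 2.32.  The scheme's genuine first-order spatial
  convergence is verified separately with spacings whose nodes all
  contain the bolus edge (dx = 0.1/0.2 mm against a 0.025 mm reference:
  ratio 2.3, tested).
* **Scenario comparison.** All five cases at the standard resolution;
  the checked orderings are: total LPS non-increasing in every case;
  end-time LPS(3) < LPS(2); peak CH(3) > peak CH(2); peak N(5) < N(4);
  peak AM(5) < AM(4); peak G(4) ≥ G(5); end-time RM increasing up the
  ladder.  All pass with the default configuration.

## Known limitations

* 1-D only; the strip abstracts a thin dermal layer.  No microabscess
  geometry, no 2-D/3-D pattern formation.
* Explicit Euler with a conservative global bound; no adaptivity.  Runs
  with pathological parameter sets may clamp frequently — watch the log.
* The vascular pools are constant in space and time; there is no TNF-α
  autocrine feedback, macrophage desensitization, or LPS-driven
  endothelial permeability (deliberately out of scope).
* The clamp makes the scheme non-conservative exactly when a species
  undershoots zero; at the shipped step sizes this never triggers.
* The parameterization is qualitative: rate constants mix literature
  values on inconsistent concentration scales with estimated ones (see
  `scenarios.PROVENANCE`), so outputs should be read as dynamical
  structure (orderings, timescales) rather than calibrated cell counts.
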