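# Methods

## Model

`scgsim` treats each stereocilium (or microvillus) as a cylindrical,
treadmilling actin bundle. Three processes set its height:

1. **Pushing.** Actin polymerizes at the tip with rate `A(h)` and the
   filament lattice flows rearward, dragging the rootlet through the
   cuticular plate. Over developmental time scales the plate remodels and
   behaves as an effectively viscous medium with coefficient `γ_c`, so the
   pushing force is `γ_c · S_c(h) · A(h)`, with `S_c` the rootlet surface
   area.
2. **Restoring.** Myosin connectors (e.g. myosin I/VII) link the actin core
   to the membrane along the whole length; with per-connector force `α` and
   line density `ν` their total restoring force is `α ν h`. Membrane
   bending adds a constant offset `f_md0` (no height dependence is assumed;
   the default is 0).
3. **Friction.** The membrane slides against the surrounding cytoplasm with
   coefficient `μ`, which only affects relaxation rates, never the steady
   states.

Height dynamics:

    dh/dt = [γ_c S_c(h) A(h) − α ν h − f_md0] / (γ_c S_c(h) + μ)

Restoring terms enter with a negative sign — they must oppose growth; the
steady states are the intersections of the pushing and restoring curves,
and a state is stable when the net force has negative slope there.

**Rootlet-area closure.** The rootlet area is not modelled mechanistically;
we close it as

    S_c(h) = c_S · R_tip(h) · (A/β) / (1 + (A/β)²)

where `β` is the effective severing rate at the rootlet (a single scalar;
no axial profile is resolved) and `c_S` a calibration length. This closure
is chosen so that, for height-independent `A` and `f_md0 = 0`, the ODE's
fixed point coincides exactly with the closed-form steady-state height

    h_st = (γ_c / (α ν)) · c_S · R_tip · A · (A/β) / (1 + (A/β)²),

which reduces to the rootlet-drag scaling `h_st ∝ A²/β` in the
severing-dominated regime `β ≫ A`. The closed form is isolated in
`core_model.steady_state_height`, so an alternative closure is a one-line
change.

A useful consequence of this form is the espin-3 fold-change: multiplying
`A` by 1.3 and halving `β` at fixed tip radius multiplies `h_st` by
`1.3² · 2 · (1 + (A/β)²) / (1 + (2.6·A/β)²)` — 3.198 from a `β = 10A`
baseline, approaching 3.38 as `β/A → ∞`, i.e. roughly a threefold
elongation, consistent with the measured ~7-fold elongation being driven
largely by the accompanying radius increase that the worked example holds
fixed.

**Polymerization-rate families.** `A(h)` is one of:

* `constant` — `a0`;
* `promoter_sum` — `a0 + Σ aᵢ (h/hᵢ)^{nᵢ} / (1 + (h/hᵢ)^{nᵢ})`: several
  promoter species carried to the tip, each saturating at its own height;
  this staircase-shaped pushing force is what makes a spatially *uniform*
  cell multi-stable;
* `sigmoid` / `sharp_sigmoid` — `a0 + a1 h^m / (h^m + h_half^m)`: the
  positive feedback of height on polymerization (tip-transported
  Eps8/whirlin via myosin-XV). The two tags share the formula;
  `sharp_sigmoid` is used with large `m`, which produces the tall-first-row
  phenotype. The Hill form itself is a modelling choice; only its
  saturating, monotone shape matters for the phenotypes.

**Tip radius.** The dynamically regulated tip complex is represented by the
parametric steady-state family

    R_st(h, A) = r_ref (1 − h_min/h)^q (A/a_ref)^(−s),   0 for h < h_min

with defaults `q = 1/2`, `s = 1/2`. It reproduces the three qualitative
behaviours of regulated tip complexes — a minimal height `h_min` below
which no stable complex (and no protrusion) exists, a radius that
approaches `r_ref` for tall protrusions, and thinning (s > 0) or thickening
(s < 0) with increasing polymerization rate — without resolving the
underlying reaction network of nucleators, G-actin and cross-linkers.
`h_min = 0` is allowed as the degenerate fixed-radius limit used in
decoupling tests.

## Units

All computation is nondimensional: `α = ν = c_S = 1` fixes the force and
length scales, and rates are expressed relative to the basal polymerization
rate (order 1 in the fixtures, with `β = 10` giving the severing-dominated
regime). No absolute magnitudes are asserted anywhere; configurations may
declare display scale factors (µm, s) for reporting only.

## Numerics

* **Root finding** (`find_force_balance_roots`): uniform scan of the net
  force on `[0, h_max]` (default `n_scan = 2000`) with Brent bisection to
  `1e-10·h_max` in each bracketing cell. Roots closer than the scan spacing
  can in principle be missed; `h_max` defaults to twice an a-priori bound
  on any root (the pushing force is bounded because `x/(1+x²) ≤ ½` and both
  `A` and the radius are bounded) and at least 10× every characteristic
  height, so no root lies outside the scan.
* **Stability**: sign of the central-difference slope of the net force
  (step `1e-6·h_max`); one-sided at the `h = 0` boundary.
* **Joint height–radius problem** (`solve_joint`): damped alternating
  iteration (factor 0.5, ≤ 200 iterations, convergence at relative residual
  `1e-8`) from a 16-point geometric seed ladder, merged with a dense scan
  of the radius-slaved net force over `(h_min, h_max]`. The scan is both
  the documented fallback for oscillating iterations and a completeness
  guarantee that no solution branch is missed. Converged roots are polished
  by local bracketing, deduplicated at `1e-6` relative in `h`, and
  re-validated against both curve equations.
* **Existence threshold**: bisection on the named parameter (`γ_c`, `a0`
  or `β`) to `1e-4` relative, with explicit precondition checks at both
  endpoints.
* **ODE integration** (`integrate_height`): LSODA, `rtol 1e-8`,
  `atol 1e-10`, heights clamped at zero from below.
* **Branch selection in bundles**: the default `developmental` rule
  integrates the height dynamics from a microvillus-scale seed
  (`h0 = 0.1·h_min`). Because the slaved radius vanishes below `h_min`,
  nucleation is outside the model's scope; growth from the seed is enabled
  by a small nucleation radius floor (default `0.02·r_ref`), and the
  settled height is matched to the nearest stable branch in log-height.
  The `tallest` rule (highest stable state) is exposed for sensitivity
  checks. The two rules coincide whenever the solution is unique.
* **Row coupling**: `k = 1` is special-cased to an exact collapse to the
  mean so the full-coupling contract holds to the last bit.

## Fixtures (what the scenarios emulate)

The registered scenarios are deterministic parameter sets chosen to sit
robustly inside the qualitative regimes they name; none is fitted to
morphometric data.

* `vestibular_wt` — constant `A = 1`, `β = 10`, `h_min = 1e-3`, 8 rows
  under a `γ_c` gradient from 0.03 (below the existence threshold
  `γ_c* ≈ 0.066`: the microvilli-free region) to 150. Heights are linear
  in `γ_c` up to an `O(h_min²/h²)` correction, so `h_min` is kept small
  against row heights (~0.85–5.9) and the height steps are equal to better
  than `1e-6` relative; radii agree to ~0.05% except the slightly thinner
  shortest row.
* `cochlear_graded` — sigmoid feedback (`a0 = 0.6`, `a1 = 0.8`,
  `h_half = 8`, `m = 3`) kept in the regime where the steady height is a
  single-valued, convex function of `γ_c` (the inverse map `γ_c(h)` stays
  strictly increasing): accelerating height steps and strictly thinning
  rows.
* `inner_hair_cell` — sharp feedback (`a1 = 0.5`, `h_half = 4`, `m = 12`).
  The low-height solution branch disappears between `γ_c = 300` and 310;
  the row positions place rows 1–7 below that threshold and row 8 above
  it, so only the tallest row jumps to the high branch.
* Mutants transform these templates: `eps8_ko` flattens `A(h)` to its
  basal value on the inner-hair-cell template (feedback removed, basal
  rate kept — the residual shallow staircase comes from the `γ_c`
  gradient); `espin3_oe` applies (×1.3, ÷2) on the vestibular template;
  `espin_oe` adds a 1.5× radius increase; `jerker` thins `r_ref` to 0.3×
  (the magnitude is a choice — only "much thinner" is established);
  `triobp_ko` triples `β` on the cochlear template. Degradation phenotypes
  are represented as loss of steady-state existence, not as kinetics.

The synthetic configurations exercise the model's mechanisms, not real
measurements: passing tests demonstrate that the mechanisms produce the
claimed geometries in their intended regimes, not that any real bundle's
dimensions are predicted.

## Known limitations

* The tip-complex reaction network, membrane-shape mechanics, tip-link
  tension feedback, Ca²⁺/capping effects on the first row and the lateral
  (hexagonal) organization of the bundle are all outside scope.
* `β` is a single effective scalar; no severing profile along the
  protrusion is resolved.
* The developmental branch rule's nucleation floor is a device for basin
  selection, not a model of protrusion nucleation.
* Multi-stable configurations with features narrower than the scan spacing
  require raising `n_scan`; this is documented rather than auto-detected.
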