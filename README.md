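# scgsim

Force-balance simulation of actin-protrusion height and the stereocilia
staircase geometry.

Auditory and vestibular hair cells carry bundles of stereocilia — actin-filled
membrane protrusions arranged in rows of precisely graded heights (the
staircase geometry). `scgsim` is a small mechanistic simulator for the
biophysics behind that arrangement: it computes the steady-state heights and
tip radii of treadmilling actin protrusions, finds all coexisting steady
states with their stability, assembles whole bundles across a spatially
graded apical surface, and expresses classic deafness-associated mutants
(Eps8 KO, espin overexpression, jerker, Triobp loss) as parameter
transformations. It is aimed at modellers and quantitative biologists who
want to explore how gradients, feedback and mutations shape protrusion
geometry without building the machinery from scratch.

## Model

A protrusion of height `h` treadmills: actin polymerizes at the tip with rate
`A(h)`, flows rearward and is severed at the rootlet with effective rate `β`.
The rearward flux drags the rootlet (surface area `S_c`) through the viscous
cuticular plate (viscosity coefficient `γ_c`), pushing the protrusion up;
actin–membrane myosin connectors (force `α` each, line density `ν`) and
membrane bending (`F_md`) pull it back. The height obeys

    dh/dt = [γ_c S_c(h) A(h) − α ν h − F_md] / (γ_c S_c(h) + μ)

with the rootlet-drag closure `S_c = c_S R_tip (A/β) / (1 + (A/β)²)`, so that
for a height-independent `A` the steady state has the closed form

    h_st = (γ_c / (α ν)) · c_S · R_tip · A · (A/β) / (1 + (A/β)²)
         ≈ (γ_c c_S / (α ν)) · R_tip A² / β        (severing-dominated, β ≫ A)

The tip radius is slaved to a steady-state tip-complex family
`R_st(h, A) = r_ref (1 − h_min/h)^q (A/a_ref)^(−s)` (zero below the minimal
height `h_min`). Height-dependent `A(h)` (promoter sums, sigmoidal feedback)
makes the force balance multi-stable; a linear spatial gradient in `γ_c`,
`A` or `β` across the apical surface turns the row of solutions into a
staircase, with a microvilli-free region wherever the two steady-state
curves fail to intersect. All quantities are nondimensional model units
(see `docs/methods.md`).

## Worked example

The espin-3 overexpression scenario compares a wild-type vestibular-like
bundle with its mutant (polymerization ×1.3, severing ÷2):

```sh
$ scgsim scenario --name espin3_oe --out out/espin
median height factor mut/wt: 2.80478
wrote wildtype.csv, mutant.csv, comparison.csv in out/espin
```

The comparison table lists each row of the bundle:

```
row_index,x,status_wt,status_mut,h_wt,h_mut,r_wt,r_mut,h_ratio,r_ratio,...
0,0,absent,protrusion,0,0.0026202,0,0.275871,,,...
1,1,protrusion,protrusion,0.849174,2.38243,0.399764,0.35075,2.80558,0.877391,...
4,4,protrusion,protrusion,3.39463,9.52121,0.399941,0.350805,2.80478,0.877141,...
```

Reading: row 0 of the wild type sits below the protrusion-existence
threshold (microvilli-free, `status=absent`); the mutation drops that
threshold and a microvillus-scale stub appears. Every shared row elongates
by ×2.80 — the closed-form fold-change at fixed tip radius is ×3.20, and
the self-consistent radius response (thinner at higher `A`, factor 0.877)
brings the full-bundle value to 2.80.

Other entry points: `scgsim solve --config cfg.yaml` (all steady states of
one parameter set), `scgsim bundle --config cfg.yaml` (staircase under a
gradient), `scgsim sweep ... --mode threshold` (existence threshold). The
YAML configuration schema is published in `docs/config.schema.json`;
registered scenarios are `vestibular_wt`, `cochlear_graded`,
`inner_hair_cell`, `eps8_ko`, `espin3_oe`, `jerker`, `espin_oe`,
`triobp_ko`.

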