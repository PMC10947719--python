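# microsim

An individual-based simulator of microbial communities.  Cells are
agents — spheres (cocci), sphere-swept rods (bacilli) or torsion-sprung
chains of rods (filaments) — that grow by catalyzing user-defined
reactions against their local solute environment, divide stochastically,
differentiate, and push each other around through force-based mechanics.
Compartments are either well-mixed (batch / chemostat / retentostat
ODEs) or spatially explicit (biofilms on a Cartesian solute grid with a
pseudo-steady-state reaction–diffusion solver).  Models are declared in
hierarchical XML protocol files with unit-carrying parameters, so a new
model is a text file, not code.

It is written for microbial ecologists and systems biologists who want
to ask how individual-level traits — growth kinetics, yield, morphology,
switching rules — shape community-level outcomes such as biofilm
structure and competitive fitness.

## The core models

* **Growth kinetics.** Reaction rates are arbitrary arithmetic
  expressions (e.g. double Monod,
  `mumax*carbon/(Ks+carbon)*oxygen/(Ko+oxygen)*mass`), with
  stoichiometry q_i = N_i·r.  Logic expressions drive differentiation
  switches, output filters and coloring.
* **Well-mixed compartments.**
  dS_s/dt = Σ_in D_i S_{s,in} − Σ_out D_i S_s + q_s, integrated jointly
  with agent masses and reactor volume by an adaptive stiff solver; the
  closed-form chemostat steady state S* = K_s·D/(µ_max−D),
  X* = Y(S_in−S*) is reproduced to ≪0.02%.
* **Spatial compartments.** Solutes obey ∂S/∂t = div(ω∇S) + q; because
  diffusion equilibrates much faster than growth, each step solves the
  pseudo-steady state div(ω∇S) + q(S) = 0 at frozen biomass
  (finite volumes, harmonic-mean face diffusivities, damped
  Newton–Picard, CG linear solves).  Boundaries: solid, fixed-value,
  periodic, connected compartments, in/outflows, retentostat.
* **Mechanics.** Mass-points move at Stokes terminal velocity
  v = ΣF/(6πr_c µ_f) under Hertzian contact F = (4/3)r_eff E_eff ξ^{3/2},
  linear spine/link springs F = kδl and angular springs F = κδθ/L, with
  a periodic-aware quad/octree for neighbor search and Euler/Heun
  relaxation sweeps.  A legacy shoving algorithm (spheres only) is kept
  for comparison.
* **Division.** Daughter mass fraction ~ Normal(0.5·m, CV), truncated at
  ±2σ; mass conserved exactly; placement is morphology-specific and
  filament daughters stay chained.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Run the solver verification suite from the command line:

```bash
$ microsim verify
{
  "scenarios": {
    "chemostat_non_growing":      {"value": 400.00000000152676, "expected": 400.0, ...},
    "chemostat_growing_substrate":{"value": 6.666666666666747, "expected": 6.666666666666666, ...},
    "chemostat_growing_biomass":  {"value": 498.33333333332877, "expected": 498.3333333333333, ...},
    "diffusion_linear":           {"value": 0.995, "expected": 0.995, ...},
    "diffusion_parabolic":        {"value": 0.9999999999999645, "expected": 1.00000625, ...},
    "thin_cell_layer":            {"value": 1.7999999999999527, "expected": 1.8, ...}
  },
  "max_rel_dev_percent": 0.00031328222656844924
}
```

The values are steady states in mg/L: a non-growing population pulls its
chemostat to 400 mg/L, a Monod-growing one to 6.67 mg/L substrate and
498.33 mg/L biomass, and a thin respiring cell layer under a 100 µm
boundary layer sits at 1.8 mg/L surface oxygen — each matching its
closed form, with the worst relative deviation ~3·10⁻⁴ %.

Or run a model from Python:

```python
from microsim import loads
from microsim.scenarios.competition import build_altruism_protocol

xml = build_altruism_protocol(count_per_strategy=3, seed=1,
                              width=48, height=40, resolution=2,
                              t_end=72, oxygen_bulk=0.25e-3)
sim = loads(xml)
sim.run()
print(sim.total_biomass("RS"), sim.total_biomass("YS"))
# 26974.1 24847.9  (fg) — at low founder density the Yield Strategist
# converts the oxygen flux more efficiently and nearly closes the gap
# the faster Rate Strategist opened early in the run
```

Protocols can also be run from files (`microsim run protocol.xml
--outdir out`), snapshots resumed (`microsim resume snapshot.xml`), and
units converted (`microsim convert-units 1 g/L fg/um^3` → `1`).

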