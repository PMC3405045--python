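# billheat

Does a bigger bill shed meaningfully more "dry" heat — heat lost without
spending water?  Coastal song sparrows (*Melospiza melodia atlantica*) of
the mid-Atlantic dunes and salt-marsh edge carry bills with roughly 17%
more surface area than the inland eastern subspecies (*M. m. melodia*),
and the bill's vascularized ramphotheca can act as a radiator.  `billheat`
implements the full analysis chain for testing this idea with
thermal-imaging data from a temperature-controlled chamber:

1. **Morphometrics** — region surface areas from caliper measurements:
   bill as a nearly circular elliptical cone, `A = ((W+D)/4)·L·π`; both
   tarsi as elliptical cylinders; body from the mass allometry
   `A = 8.11·m^0.67` (cm²); body volume from mass and sparrow density
   0.913 g/cm³.
2. **Heat budget** — per-region dry heat loss
   `Q = εσA(T_s⁴ − T_a⁴) + h_c A (T_s − T_a)` with `h_c = Nu·k/D`,
   `Nu = c·Re^n`, `Re = V·D/ν`; (c, n) = (0.174, 0.618) for bill and legs,
   (0.34, 0.6) for the body; characteristic dimension D = half bill depth,
   tarsus length, and volume^(1/3) respectively; V = 0.1 m/s, ε = 0.96.
3. **Model selection** — Gaussian random-intercept (per-individual) linear
   models for each response (T_bill, T_base, T_body, T_legs, Q_bill,
   %Q_bill, RH) over a null-to-saturated candidate set in subspecies (SSP),
   ambient temperature T_a, its square and cube, and SSP×T_a interactions,
   each with a mandatory √activity covariate; fitted by full ML and ranked
   by AICc, with Akaike weights, evidence ratios, and model-averaged
   predictions carrying unconditional standard errors.
4. **Water savings** — a sustained heat-loss difference ΔQ (W) translates
   into spared evaporation ΔQ·3600/λ g/h at λ = 2418 J/g.

Because no chamber recordings are distributed, a seeded synthetic module
reproduces the experiment's design — 18 birds (9 per subspecies), ambient
stepped 15→37 °C in 2 °C increments, five analysed frames per step — with
the reported response structure (bill 9.8→4.7 °C above ambient, body
4.4→2.6 °C, a sigmoidal leg response, a subspecies×T_a interaction at the
bill base, quadratic activity, humidity anticorrelated with T_a).

## Worked example

```
$ python analysis/01_simulate.py --seed 1 --outdir results
Simulated 18 birds, 1080 frames. Mean full-bill area: eastern 129.3 mm2, Atlantic 148.3 mm2 (+14.7%).
$ python analysis/02_heat_budget.py --outdir results
Computed 1080 frame budgets. Mean total heat loss 296 mW; bill share 5.3% (range 1.9-10.8%).
$ python analysis/03_model_selection.py --outdir results
...
         q_bill: top model 'SSP * Ta' (K=7, weight 0.829)
...
$ python analysis/04_water_savings.py --outdir results
Atlantic bill: 16.7 mW vs eastern 13.9 mW (+19.9%). Water-savings equivalent 4.1 mg/h.
```

Reading the numbers: the simulated Atlantic cohort's larger bill, with the
same biophysics applied to both subspecies, sheds ~20% more heat through
the bill (~2.7 mW for this cohort), which would otherwise cost ~4 mg of
evaporated water per hour; the bill accounts for ~5% of whole-body dry
heat loss while making up only ~2% of surface area.  For the bill's heat
loss the interaction model `SSP * Ta` is the AICc-top candidate — larger
bills lose disproportionately more heat at low ambient temperature.

The same stages are available as one command (`billheat all --seed 1
--outdir results`) or individually (`billheat simulate|heat|models|report`),
configurable from a YAML file.

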