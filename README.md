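# flusim

Scenario-based land-use change simulation coupled with habitat-quality
scoring, for landscape ecologists and land-use planners who want to ask:
*if current conversion trends continue — or are bent by a policy — what does
the landscape look like in a few decades, and what does that do to habitat?*

The package chains three classic models over a six-class land system
(cultivated land, woodland, grassland, waters, construction land, unused
land):

1. **Markov demand.** From two observed epochs a row-stochastic transition
   matrix P is cross-tabulated; per-class demand propagates as
   S_{t+1} = S_t·P over the planning horizon. Policy scenarios edit
   individual transfer probabilities multiplicatively (e.g. cultivated →
   construction × 0.6 under cultivated-land protection), with the displaced
   mass absorbed by the diagonal, and carry a binary cost matrix of allowed
   conversions.
2. **FLUS-style cellular automaton.** A single-hidden-layer neural network
   (sigmoid hidden units) learns per-class occurrence probabilities
   sp(p, k) from nine driver layers (terrain, GDP/population density,
   accessibility distances). Each CA iteration scores every cell and class
   by TP(p,k) = sp(p,k) · Ω(p,k) · I_k · cost(c_p → k), where Ω is the
   weighted Moore-neighbourhood share of class k and I_k an adaptive inertia
   coefficient steering totals toward demand; cells draw their next class by
   roulette competition, and classes that reach demand are frozen.
3. **Habitat quality.** Threat sources (cultivated land, construction land,
   roads, railways) stress habitat with linear or exponential distance decay
   up to a maximum stress distance. Degradation aggregates
   D(x) = Σ_r (w_r/Σw) · i_r(x) · β · S(class(x), r) and quality applies the
   half-saturation transform Q = H · (1 − D²/(D² + k²)), graded
   poor/moderate/good/excellent at 0.4/0.6/0.8.

Because the original study rasters are not redistributable, a synthetic
generator produces landscapes with the structure the pipeline assumes —
spatially autocorrelated class maps whose classes follow the drivers, road
networks, and an epoch transition governed by a *known* matrix — so every
stage is testable end to end, including recovery of that matrix.

## Worked example

```python
from flusim import (SyntheticConfig, generate_fixture, estimate_transition,
                    simulate, assess)

fx = generate_fixture(SyntheticConfig(shape=(120, 120), seed=17))
P = estimate_transition(fx.lu_t0, fx.lu_t1)
print(P.to_frame().round(3))

for name in ("natural", "ecological_protection"):
    res = simulate(fx.lu_t0, fx.lu_t1, fx.drivers, name, steps=3, seed=0)
    hq = assess(res.raster, roads=fx.roads)
    print(name, res.converged, res.n_iter,
          hq.summary["mean_quality"][0])
```

prints (abridged)

```
              cultivated  woodland  grassland  waters  construction  unused
cultivated         0.911     0.009      0.037   0.004         0.039   0.000
woodland           0.008     0.973      0.016   0.000         0.002   0.000
...
natural: converged=True in 6 iterations; construction growth 804 cells;
         mean habitat quality 0.4961
ecological_protection: converged=True in 213 iterations; construction growth
         482 cells; mean habitat quality 0.5359
```

The estimated matrix shows the urbanisation signature built into the
generator defaults (cultivated land leaks ~4% per decade into construction
land). Under the unconstrained scenario construction grows by 804 cells over
three 5-year steps and mean habitat quality lands at 0.4961; the ecological
scenario cuts conversion probabilities toward construction and forbids
conversions of ecological land, restraining growth to 482 cells and holding
quality at 0.5359.

A command-line interface mirrors the library: `flusim synth`, `demand`,
`suitability`, `allocate`, `simulate`, `hq`, `changes`, and `flusim run`
(full pipeline from one YAML config, writing every artifact plus a
checksummed manifest).

## Layout

- `src/flusim/grids.py` — raster data model, GeoTIFF/ESRI-ASCII I/O, distance transforms
- `src/flusim/synthetic.py` — synthetic landscape generator
- `src/flusim/markov.py` — transition estimation, scenario edits, demand projection
- `src/flusim/suitability.py` — occurrence-probability network
- `src/flusim/ca.py` — the cellular-automaton allocator and agreement metrics
- `src/flusim/habitat.py` — threat-decay degradation and habitat quality
- `src/flusim/changes.py` — cross-tabulation change accounting
- `src/flusim/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model description, parameter defaults, design notes
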