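# Methods

## The model chain

The package treats land-use change as a demand problem and an allocation
problem, then scores the allocated landscape for habitat.

**Demand (Markov).** Let S_t be the vector of per-class cell counts and P
the row-stochastic transition matrix estimated by cross-tabulating two
observed maps (rows = source class, columns = destination). Demand at the
planning horizon is S_{t+n} = S_t·Pⁿ; totals are conserved exactly by
row-stochasticity, and the projected vector is rounded to integer cell
counts by largest-remainder apportionment so it sums to the valid-cell
count. A class absent at the base epoch receives an identity self-loop row.
The estimated matrix covers one observation period (a decade by default,
recorded as `period_years` metadata); planning steps iterate this matrix
directly rather than taking a matrix root — three steps span three planning
intervals of one period each.

**Scenarios.** A scenario is (a) a set of multiplicative edits to
off-diagonal transfer probabilities and (b) a binary conversion-allowance
(cost) matrix. Three are built in:

- *natural*: no probability edits; conversions follow the unconstrained
  allowance table (construction land never converts away).
- *cultivated protection*: cultivated → construction × 0.6,
  cultivated → woodland × 0.7; cultivated land may not convert to anything.
- *ecological protection*: woodland/grassland → construction × 0.2,
  woodland/grassland → unused × 0, waters → construction × 0.2,
  cultivated → woodland × 1.3, cultivated → construction × 0.7; conversions
  from high-grade to low-grade ecological land are forbidden.

Edited probability mass moves to the row diagonal — restricted land stays
put — and a row is clipped and re-normalised only if an *increase* edit
would drive the diagonal negative.

*Demand/cost consistency.* Projecting demand from the raw estimated matrix
can request flows the same scenario's cost matrix forbids in space (the
allowance tables are deliberately stricter than observed history), leaving
the allocator chasing unattainable targets. Scenario projection therefore
uses the edited matrix with cost-forbidden entries zeroed (mass to the
diagonal), so the quantity side only ever asks for what the spatial side can
deliver. `roulette_allocate` itself accepts any demand vector and reports
non-convergence honestly.

**Suitability (ANN).** A single-hidden-layer perceptron with logistic
hidden units (scikit-learn's MLPClassifier, L-BFGS, seeded) maps the nine
min–max-normalised drivers to per-class membership probabilities. Training
cells are sampled stratified by class — proportional to prevalence with a
floor of 10 per present class — because uniform sampling leaves rare classes
(waters, unused land) unlearnable on skewed landscapes; uniform sampling is
available as an option. Outputs are renormalised per cell to a simplex so
the roulette competition compares classes on one scale. Defaults: 12 hidden
units (≈ drivers + classes), 5000 training cells, seed 42.

**Allocation (CA).** Per iteration and cell p with current class c:

    TP(p, k) = sp(p, k) · Ω(p, k) · I_k · allowed(orig(p) → k)

- Ω(p, k) = (count of class-k cells in the N×N Moore window, centre
  excluded) / (window cells − 1) × w_k, with N = 3 and expansion weights
  w = (0.2, 0.01, 0.3, 0.4, 1.0, 0.5) for cultivated/woodland/grassland/
  waters/construction/unused. Border cells use their truncated window's
  actual neighbour count, keeping the unweighted share in [0, 1]. The centre
  is excluded because including it would let Ω exceed its weight.
- I_k starts at 1 and updates from the last two demand gaps D = demand −
  count: unchanged when |D^{t−1}| ≤ |D^{t−2}|; × D^{t−2}/D^{t−1} for a
  worsening overshoot (D^{t−1} < D^{t−2} < 0); × D^{t−1}/D^{t−2} for a
  worsening shortfall (0 < D^{t−2} < D^{t−1}). The symmetric printed form of
  the shortfall branch (the same ratio as the overshoot branch) would
  *suppress* an under-allocated class, defeating the mechanism's purpose; it
  is available behind `strict_printed=True`. Inertia is clipped to
  [0.1, 10] to prevent divergence on oscillating gaps.
- `allowed` masks conversions against the cell's class in the *base* map,
  so the realised input→output cross-tabulation can never contain a
  forbidden transition even across iterations.

Cells are visited in a freshly shuffled seeded order each iteration and draw
their next class by roulette over TP (an all-zero score vector retains the
current class). A class whose count reaches its demand exactly is frozen:
its cells lock and it leaves every candidate set. Iteration stops when every
class is within tolerance (0.2% of total cells, configurable) of demand, or
after `max_iter` = 300 sweeps. The sequential sweep is compiled with numba.

**Agreement.** Map agreement is cell-by-cell: overall accuracy is the
confusion-matrix trace over n, kappa the standard chance-corrected form with
p_e = Σ_i row_i·col_i / n².

**Habitat quality.** Threats and parameters (maximum stress distance d_max
in km, weight w_r, decay type): cultivated land (3, 0.7, linear),
construction land (10, 1, exponential), national roads, provincial roads and
railways (2, 0.8, linear each). Impact is i = max(0, 1 − d/d_max) for linear
decay and i = exp(−2.99·d/d_max) inside d_max (≈ 0.05 at the edge, the
standard convention) and 0 beyond, with d the Euclidean distance transform
of the source mask; threat intensity is binary presence on source cells.
Degradation weights are normalised over the threats present; the
accessibility term β defaults to 1 everywhere (no accessibility layer is
modelled). Habitat suitability H is 0.6/1/1/0.8/0/0 per class; the
sensitivity matrix S pairs each class with each threat. Quality is
Q = H·(1 − D²/(D² + k²)) with half-saturation k = 0.5 by default, chosen so
D = k gives Q = H/2 exactly; k is configurable. Grades are left-closed bins
[0, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1], so every value maps to exactly
one grade. Summary means average over all valid cells (non-habitat classes
contribute 0).

Note a consequence of the normalised weights: introducing an *additional
threat* rescales every weight share and is not pointwise monotone in Q;
growing an existing threat's source mask is (distances can only shrink).
The tests check the second, which is the property the formula implies.

## The synthetic generator

The generator emulates what the pipeline assumes about real data, not any
particular geography:

- drivers: elevation is a smoothed Gaussian random field (correlation
  length ≈ `smoothness` cells, default 4), slope its gradient magnitude; GDP
  and population densities are distinct log-scale smooth fields sharing one
  urban-core hotspot; accessibility layers are distance transforms of
  generated towns, a meandering river, and random border-to-border
  road/railway polylines.
- land use: each cell takes the argmax of six affine class scores over the
  normalised drivers plus smooth noise (construction rises with GDP/
  population density and proximity to towns, woodland with slope and
  elevation, waters hug the river, cultivated land prefers flat low ground).
  Per-class intercepts are calibrated iteratively toward the target class
  prevalences.
- epoch transition: per source class, destination counts are the expected
  counts under the true matrix row, rounded by largest remainder, so the
  realised transition frequencies match the matrix to O(1/n); *which* cells
  move is chosen by neighbourhood affinity with Gumbel noise, giving changes
  spatial coherence without biasing the marginals.

Defaults are desk-scale study conditions: a 200×200 grid at 100 m cells
(≈ 400 km²), with the true transition matrix and prevalences taken from the
packaged 2000–2020 reference area matrix (row-normalised probabilities and
base-epoch shares), i.e. a decade of change statistically similar to a
rapidly urbanising region: cultivated land leaking ~4%/decade to
construction land, construction growing ~40% over two decades, woodland
nearly inert.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real terrain statistics and hydrology, mixed
pixels and classification error, nodata structure (clouds, boundaries),
exogenous demand shocks, and any geographic resemblance to a particular
region. Conclusions from synthetic runs are about the *method's* contracts
(recovery, attainment, compliance, ordering), not about any real landscape.

## Numerical choices and degenerate inputs

- All rasters in an analysis must share shape and cell size; mixed
  resolutions are rejected, never resampled.
- Cells nodata in any layer are excluded from sampling, allocation and all
  statistics; an all-nodata threat mask is skipped; a distance transform of
  an empty mask is an error.
- Min–max driver normalisation is computed over non-nodata cells; a
  constant layer normalises to 0.
- Demand rounding, destination-count rounding and grade binning all use
  deterministic tie-breaks (largest remainder; left-closed bins); roulette
  ties are resolved by the draw itself.
- Every stochastic step takes an explicit seed; simulation stages derive
  independent sub-streams from one run seed via `SeedSequence`.
- Problem sizes used by the test suite and the acceptance script — 100–120
  grid cells per side for CA contract suites and scenario comparisons,
  200×200 for transition recovery, 20 allocation seeds and 10 simulation
  seeds — are the package's desk-scale defaults for stable statistics at
  interactive runtimes.

## Known limitations

- Demand projection iterates the estimated period matrix; no continuous-time
  embedding or matrix-root sub-stepping is attempted.
- The CA is cell-based: no patch-level growth, planning-zone constraints or
  multi-resolution nesting.
- Habitat threats act independently (no synergy between threat sources) and
  threat intensity is binary; the accessibility sub-model and habitat-rarity
  term are out of scope.
- The reference area matrix ships with the package for change-accounting
  regression; its printed cultivated-land increase margin is one rounding
  unit below its own column sum, and donor shares derived from it differ
  from their commonly quoted two-decimal values by 0.01 for the same reason.
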