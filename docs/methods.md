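# Methods

## Model summary

The simulator advances a population of spherical cells (radius 9 µm) through
a random network of straight collagen fibers in 30-minute timesteps. Two
nested cubic lattices define the geometry: cells are tracked on a central
50³ lattice (4.5 µm spacing, the "volume of interest") while fibers fill a
75³ lattice centred on it, which suppresses the edge artefact of cells
drifting toward fiber-poor boundaries. Cell centers and fiber origin ends
snap to lattice nodes at initialization only; all subsequent positions are
continuous. Fibers may overlap one another, but no fiber may intersect a
cell and no two cells may overlap, at initialization and at the end of every
step.

All cellular decisions depend on `closeF`, the count of fibers within
13.5 µm of the cell center at the last end-of-step census (closed ball: a
fiber tangent at exactly 13.5 µm counts). Probabilities for a step are
evaluated at the previous census, so all cells act on the same snapshot
regardless of the (shuffled) order in which they are visited.

## Probability functions and their parameters

| quantity | form | default | units |
|---|---|---|---|
| `P_degrade` | `P_degMax / (1 + exp(-k_deg (closeF - x0_deg)))` | `k_deg = 3.0`, `x0_deg = 0.6` | fibers |
| `P_deposit` | `P_depMax / (1 + exp(+k_dep (closeF - x0_dep)))`, only while `closeF <` deposition threshold | `k_dep = 0.1`, `x0_dep = 7.5` | fibers |
| `P_align` | `1 − P_nothing − P_degrade` | — | — |
| `P_move` | `peak · exp(-(closeF - µ)² / 2σ²)`, exactly 0 at/above the motility threshold | `peak = 0.85`, `µ = 0`, `σ = 0.02 ×` motility threshold | fibers |
| pull bias | probability a migration-intersected fiber is pulled rather than degraded | 0.51 | — |
| steric block | max intersecting fibers a move may resolve | 10 | fibers |
| move retries | candidate positions per movement attempt | 5 | — |
| max realign angle | cone half-angle for pulled fibers | π/4 | rad |
| close radius | neighbourhood defining `closeF` | 13.5 | µm |
| max step | movement bound (2 lattice units) | 9 | µm |

`P_depMax`, `P_degMax`, `P_nothing` and the two thresholds are phenotype
parameters (see README table); everything in the table above is shared
between phenotypes and exposed in the configuration.

### How the shape defaults were chosen

The logistic midpoints/steepness, the motility Gaussian and the pull bias
are free parameters of the model; no measurement pins them down. They were
fitted once — by the same systematic sweep the `grid_search_fit` helper
implements, scored against the qualitative remodeling behaviour the model
is meant to exhibit (acellular matrices static; sparse matrices densified by
cells; the two phenotypes diverging in dense matrices, the low-invasive line
densifying and the high-invasive line degrading, with day-wise statistical
separation) — and then frozen.

A geometric fact dominates the calibration: with 1200–3500 fibers of mean
length ~25 µm in a (337.5 µm)³ volume, the *realized* `closeF` of a cell is
small — background values of roughly 0.5 (1200 fibers) to 2.3 (3500), with
local accumulation near depositing cells pushing it to at most ~5–8. The
probability-function transitions therefore must sit in this compressed range
to have any effect at all: the degradation logistic saturates within the
first couple of close fibers (so degradation pressure scales essentially
linearly with local density, at twice the rate for the high-invasive
phenotype), the deposition logistic decays gently across the whole realized
range (so deposition is never the limiting factor below the hard threshold
of 20), and the motility Gaussian is widest for the phenotype with the
higher motility threshold, letting it keep roaming at local densities where
the low-invasive phenotype has already settled.

Under these defaults the two phenotypes behave as: a sessile depositor
(low-invasive: settles, deposits until its neighbourhood saturates ~2–3
fibers above background, net densification) versus a roaming degrader
(high-invasive: its local equilibrium lies *below* the dense-matrix
background, so every relocation mows the new neighbourhood down, a sustained
net degradation of ~13% of the fibril fraction per week at 3500 fibers).

### A known, deliberate limitation

The printed phenotype thresholds (deposition 20, motility 35/50 fibers)
imply local fiber counts an order of magnitude above what the printed
geometry can produce; they act as hard caps that are rarely binding here.
One consequence is provable (and reproduced by every parameter sweep we
ran): with `closeF` compressed to ~0.5–3 and a monotone degradation
logistic, each phenotype's neighbourhood relaxes to a single equilibrium
density, so the *sign* of its net remodeling is monotone in the background
density. The three observations {high-invasive densifies sparse matrices
more than low-invasive; low-invasive densifies the densest matrices;
high-invasive degrades the densest matrices} cannot then hold
simultaneously. The defaults prioritise the dense-matrix phenotype
divergence; in sparse (1200-fiber) matrices the low-invasive phenotype
densifies as expected but the high-invasive phenotype degrades somewhat
rather than out-depositing it, and the corresponding trend tests in
`tests/test_acceptance.py` are expected to fail under the default
calibration. An alternative calibration (motility band centred at
`closeF ≈ 2`) produces the sparse-matrix pattern exactly — both phenotypes
up, high-invasive by far the most — but then the phenotypes do not separate
in dense matrices; the two regimes are mutually exclusive in this model
family.

## Step semantics and tie-breaks

- Cells are visited in a freshly shuffled order each step; a single seeded
  RNG drives every stochastic draw, making trajectories bit-reproducible
  from `(config, seed)`.
- A mover resolves each intersecting, not-yet-modified fiber by pulling
  (realignment away from the cell) with probability `pull_bias`, else by
  marking it for degradation. A pull that finds no admissible orientation
  falls back to degradation so that exclusion is always restored by the
  end-of-step erasure. Candidate positions that touch a fiber already
  realigned this step (locked) are rejected; fibers already marked for
  degradation neither block nor count toward the steric limit, since they
  vanish at the end of the step.
- Realignment pivots about the endpoint nearer the cell, samples up to 40
  directions uniformly from the admissible cone (half-angle π/4 around the
  current direction), discards those leaving the ECM box or touching any
  cell, and picks uniformly among the survivors; length is preserved to
  1e-9 µm. If no candidate survives, the fiber is left unchanged.
- Deposition places the new fiber's proximal end at 9–13.5 µm from the cell
  center (outside the cell, inside the close radius) with random orientation
  and length; up to 40 placements are tried against all cells and the ECM
  box. Pending fibers materialize at the end of the step and are discarded
  if a later-moving cell ended up on top of them — the fiber ledger
  (Δfibers = deposits − degradations) counts only materialized fibers.
- Cells whose centers leave the volume of interest are dropped from
  tracking; replenishment then adds cells at uniformly random points on a
  random face of the region (respecting exclusion, 500 attempts) until the
  phenotype's minimum count is restored.
- Degenerate inputs: an acellular state is exactly invariant under stepping;
  a zero-length fiber is rejected at construction; constant samples give a
  zero-width bootstrap interval; an all-tied Mann–Whitney comparison
  returns p = 1.

## Quantification

A slice image covers the xy-footprint of the volume of interest with
0.45 µm pixels (10 per lattice unit). A pixel is "fiber" when the 3D
distance from its center, taken in the slice plane, to some fiber segment is
at most the rendered fiber radius (0.9 µm) plus half the slab thickness
(default: one pixel). This is a direct geometric binarization — simulated
fibers are already binary objects, so no intensity model or threshold is
involved; absolute fractions therefore depend on the (unmeasured) rendered
radius and comparisons should be made between simulated conditions, not
against absolute experimental fractions.

A recorded fibril fraction is the mean over a z-stack of 15 slices evenly
spaced through the central 80% of the region (configurable; a single
mid-plane slice when `n_slices = 1`), emulating the stack averaging of the
experimental imaging. Stack averaging reduces the seed-to-seed relative
standard deviation of the metric from ~9% (single slice) to its ~2.5% floor,
which is set by the fluctuation of the fiber count inside the quantified
subvolume, not by slice sampling.

Replicate statistics: BCa bootstrap confidence intervals for means
(via `scipy.stats.bootstrap`, method "BCa", 9999 resamples, 95% default) and
two-sided Mann–Whitney tests (exact null distribution whenever both groups
have ≤ 8 tie-free observations, normal approximation otherwise).
`grid_search_fit` sweeps a grid of phenotype-parameter values, simulating
each combination with a common set of seeds, and returns the combination
minimizing the mean squared error against a target fibril-fraction series.

## What the synthetic matrices do and do not capture

Generated matrices reproduce the fiber-number/density relationship and the
pore structure of random line networks, and the acceptance suite verifies
the resulting fibril-fraction ordering across the 2/3/4 mg/mL-like presets.
They do not model fibrillogenesis kinetics, fiber diameter distributions,
the experimental length distribution beyond its printed range (lengths are
uniform on 4.5–45 µm), fiber mechanics or large-scale alignment, cell
proliferation/apoptosis, soluble factors, or non-spherical cell shapes.
Passing tests therefore demonstrate internal consistency and the published
qualitative trends under these idealizations, not quantitative agreement
with any particular gel.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run full-size matrices
(1200–3500 fibers, 75³ lattice) for the structural and divergence checks —
8 builds per acellular preset, 28 replicate week-long runs per phenotype for
the dense-matrix comparison (the day-1 comparison is the statistically
tightest: a ~5% mean gap against ~2.5–3% replicate noise, which the exact
Mann–Whitney test resolves reliably at this replicate count) and 5 per
phenotype for the trend suite. Engine unit tests use a reduced 20³/30³
lattice with a few hundred fibers, which preserves every invariant while
keeping the suite fast.
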