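# ecmsim

A 3D lattice Monte Carlo simulator of extracellular-matrix (ECM) remodeling
by cells in collagen fiber networks, with the image-style quantification and
replicate statistics needed to compare simulated matrices to
confocal-reflectance measurements of real gels.

It is aimed at quantitative cell biologists and biophysicists who want a
cell-scale (as opposed to molecular or continuum tissue-scale) model of how
cell phenotype and initial collagen density jointly shape matrix
architecture over days of culture.

## The model

The matrix is a random assortment of straight collagen fibers (line
segments, lengths uniform on 4.5–45 µm) filling a 75×75×75 lattice with
4.5 µm node spacing; cells are 9 µm-radius spheres seeded on the central
50×50×50 "volume of interest" so that tracked cells never see a fiber-free
boundary. Cells and fibers leave the lattice nodes after initialization and
move in continuous space. Fibers may cross each other, but cell–cell and
cell–fiber volume exclusion is strictly enforced.

Every probability a cell uses is a function of a single state variable:
`closeF`, the number of fibers within 13.5 µm (1.5× the cell radius) of its
center at the previous 30-minute timestep. Per timestep each cell:

- moves with probability `P_move(closeF)` — a Gaussian in `closeF` (the
  biphasic adhesion/traction balance) with a hard zero at the phenotype's
  motility threshold — stepping up to 2 lattice units (9 µm, i.e. a maximum
  speed of 18 µm/h). Fibers intersecting the new position are pulled aside
  (probability `pull_bias` > 0.5) or degraded; an excessively hindered
  candidate position is re-drawn. Movers do no further remodeling.
- otherwise draws, for each unmodified close fiber, one of
  *nothing* / *degrade* / *realign* with probabilities `P_nothing`,
  `P_degrade = P_degMax · σ(closeF)` (an increasing logistic) and
  `P_align = 1 − P_nothing − P_degrade`. Realignment pivots the fiber's far
  end within a bounded cone, preserving length and avoiding all cells.
- may deposit at most one new fiber near itself with probability
  `P_deposit = P_depMax · σ̄(closeF)` (a decreasing logistic), only while
  `closeF` is below the deposition threshold.

Degradations are erased, and deposited fibers materialized, at the end of
each step; a fiber can be modified at most once per step. Cells that migrate
out of the volume of interest stop being tracked, and new cells enter at the
region faces whenever the census drops below the phenotype's minimum.

Two phenotype presets encode a lowly and a highly invasive model cancer cell
line:

| parameter                         | `low_invasive` | `high_invasive` |
|-----------------------------------|---------------:|----------------:|
| initial / minimum cells           | 15 / 14        | 15 / 14         |
| P_depMax                          | 0.8            | 0.8             |
| P_degMax                          | 0.1            | 0.2             |
| P_nothing                         | 0.9            | 0.8             |
| deposition threshold (fibers)     | 20             | 20              |
| motility threshold (fibers)       | 35             | 50              |

Matrix presets map collagen concentration to fiber number: `2mgml` → 1200,
`3mgml` → 2000, `4mgml` → 3000, `4.5mgml` → 3500 fibers.

The structural readout is the **fibril fraction**: the fraction of pixels
occupied by fibers in a binarized xy-slice of the matrix (0.45 µm pixels,
0.9 µm rendered fiber radius), recorded as the mean over a z-stack of
slices. Replicate runs are compared with BCa bootstrap confidence intervals
and two-sided Mann–Whitney tests, exactly the statistics used for the
corresponding gel experiments.

## Worked example

Simulate one week (336 half-hour steps) of the low-invasive phenotype in a
sparse 2 mg/mL-like matrix:

```python
import ecmsim

cfg = ecmsim.config_from_dict({"matrix": {"preset": "2mgml"},
                               "phenotype": "low_invasive"})
traj = ecmsim.run(cfg, seed=0)
for r in traj.records:
    print(f"day {r['hours']/24:3.0f}  fibril_fraction {r['fibril_fraction']:.4f}  "
          f"fibers {r['n_fibers']:4d}  cells {r['n_cells']}")
```

```
day   0  fibril_fraction 0.0033  fibers 1200  cells 15
day   1  fibril_fraction 0.0035  fibers 1237  cells 14
day   2  fibril_fraction 0.0036  fibers 1246  cells 14
day   3  fibril_fraction 0.0036  fibers 1250  cells 14
day   4  fibril_fraction 0.0037  fibers 1251  cells 14
day   5  fibril_fraction 0.0036  fibers 1247  cells 14
day   6  fibril_fraction 0.0037  fibers 1255  cells 14
day   7  fibril_fraction 0.0037  fibers 1248  cells 14
```

The cells densify the sparse matrix: deposition outruns degradation until
the local neighbourhoods saturate, raising the fibril fraction about 12%
above its acellular baseline (which, as the tests verify, does not evolve at
all without cells). In dense 3500-fiber matrices the same phenotype raises
the fibril fraction slightly while the high-invasive phenotype degrades it
by ~13%, separating the two lines at every recorded day.

The same run from a shell:

```
ecmsim simulate --preset 2mgml --phenotype low_invasive --seed 0 \
       --steps 336 --record-every 48 --out runs/low_2mgml_s0
ecmsim quantify --state runs/low_2mgml_s0/final_state.json --out slice.png
ecmsim compare --runs-a runs/low --runs-b runs/high --day 7
```

Every run directory contains `timeseries.csv` and a `manifest.json` holding
the fully resolved configuration and seed, from which the trajectory can be
reproduced bit-for-bit.

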