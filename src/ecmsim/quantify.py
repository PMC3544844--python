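"""Structural quantification and replicate statistics.

The model's structural readout is the *fibril fraction*: the fraction of
pixels occupied by fibers in a binarized 2D xy-slice of the matrix, the same
metric confocal-reflectance images of collagen gels are reduced to.  Here the
slice is produced by direct geometric rasterization: a pixel is "fiber"
whenever some fiber's axis passes within the rendered fiber radius (plus half
the slab thickness) of the pixel center.  No intensity model or threshold is
involved because simulated fibers are already binary objects.

Replicate statistics mirror the experimental analysis: bias-corrected and
accelerated (BCa) bootstrap confidence intervals for means, and two-sided
Mann-Whitney tests for between-condition comparisons (exact null distribution
at small sample sizes).  ``grid_search_fit`` is the systematic parameter
sweep used to pick phenotype parameters that best match a target
fibril-fraction time series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .state import SimState

__all__ = [
    "SliceImage",
    "rasterize_slice",
    "fibril_fraction",
    "stack_fibril_fraction",
    "bca_bootstrap_ci",
    "mann_whitney",
    "grid_search_fit",
]


@dataclass
class SliceImage:
    """A binarized xy-slice: ``pixels[iy, ix]`` True where a fiber is rendered."""

    pixels: np.ndarray
    pixel_size: float
    z_center: float
    z_thickness: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def rasterize_slice(
    state: SimState,
    z_center: float | None = None,
    pixel_size: float = 0.45,
    render_radius: float = 0.9,
    z_thickness: float | None = None,
) -> SliceImage:
    """Render the fibers crossing an xy-slab over the cellular region's footprint.

    ``z_center`` defaults to the mid-plane of the cellular region.  A pixel is
    set when the 3D distance from its center (taken at ``z_center``) to some
    fiber segment is at most ``render_radius + z_thickness/2``.  Deterministic
    and translation-equivariant.
    """
    lattice = state.lattice
    if z_center is None:
        z_center = float(lattice.cell_lo[2] + lattice.cell_extent / 2.0)
    if z_thickness is None:
        z_thickness = pixel_size
    x0, y0 = float(lattice.cell_lo[0]), float(lattice.cell_lo[1])
    n_px = int(round(lattice.cell_extent / pixel_size))
    pixels = np.zeros((n_px, n_px), dtype=bool)
    reach = render_radius + z_thickness / 2.0

    fibers = state.fibers
    if len(fibers) == 0:
        return SliceImage(pixels, pixel_size, z_center, z_thickness, origin=(x0, y0))

    p1, p2 = fibers.p1, fibers.p2
    zmin = np.minimum(p1[:, 2], p2[:, 2])
    zmax = np.maximum(p1[:, 2], p2[:, 2])
    near = np.flatnonzero((zmin <= z_center + reach) & (zmax >= z_center - reach))

    for fi in near:
        a, b = p1[fi], p2[fi]
        # clip the segment to the slab (in z) to bound the affected xy patch
        dz = b[2] - a[2]
        if abs(dz) < 1e-12:
            t0, t1 = 0.0, 1.0
        else:
            ta = (z_center - reach - a[2]) / dz
            tb = (z_center + reach - a[2]) / dz
            t0, t1 = max(0.0, min(ta, tb)), min(1.0, max(ta, tb))
            if t0 > t1:
                continue
        qa = a + t0 * (b - a)
        qb = a + t1 * (b - a)
        xlo = min(qa[0], qb[0]) - reach
        xhi = max(qa[0], qb[0]) + reach
        ylo = min(qa[1], qb[1]) - reach
        yhi = max(qa[1], qb[1]) + reach
        ix0 = max(0, int(np.floor((xlo - x0) / pixel_size - 0.5)))
        ix1 = min(n_px - 1, int(np.ceil((xhi - x0) / pixel_size - 0.5)))
        iy0 = max(0, int(np.floor((ylo - y0) / pixel_size - 0.5)))
        iy1 = min(n_px - 1, int(np.ceil((yhi - y0) / pixel_size - 0.5)))
        if ix0 > ix1 or iy0 > iy1:
            continue
        xs = x0 + (np.arange(ix0, ix1 + 1) + 0.5) * pixel_size
        ys = y0 + (np.arange(iy0, iy1 + 1) + 0.5) * pixel_size
        gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
        pts = np.column_stack(
            [gx.ravel(), gy.ravel(), np.full(gx.size, z_center)]
        )
        d = b - a
        denom = float(d @ d)
        t = (pts - a) @ d / denom
        np.clip(t, 0.0, 1.0, out=t)
        closest = a[None, :] + t[:, None] * d[None, :]
        diff = pts - closest
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff)).reshape(gx.shape)
        patch = pixels[iy0 : iy1 + 1, ix0 : ix1 + 1]
        patch |= dist <= reach

    return SliceImage(pixels, pixel_size, z_center, z_thickness, origin=(x0, y0))


def fibril_fraction(image: SliceImage) -> float:
    """Fraction of slice pixels occupied by fibers, in [0, 1]."""
    return float(np.count_nonzero(image.pixels)) / image.pixels.size


def stack_fibril_fraction(
    state: SimState,
    n_slices: int = 9,
    pixel_size: float = 0.45,
    render_radius: float = 0.9,
    z_thickness: float | None = None,
) -> float:
    """Mean fibril fraction over ``n_slices`` xy-slices through the cellular region.

    Slices sit at evenly spaced fractions of the region's z-extent (the
    mid-plane alone when ``n_slices=1``), emulating how experimental image
    stacks average several slices per gel.
    """
    lattice = state.lattice
    z_lo = float(lattice.cell_lo[2])
    if n_slices == 1:
        fracs = np.array([0.5])
    else:
        fracs = np.linspace(0.1, 0.9, n_slices)
    values = [
        fibril_fraction(
            rasterize_slice(
                state,
                z_center=z_lo + f * lattice.cell_extent,
                pixel_size=pixel_size,
                render_radius=render_radius,
                z_thickness=z_thickness,
            )
        )
        for f in fracs
    ]
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

def bca_bootstrap_ci(
    samples,
    level: float = 0.95,
    n_resamples: int = 9999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean of ``samples``."""
    a = np.asarray(samples, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two samples")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if np.ptp(a) == 0.0:
        c = float(a[0])
        return (c, c)
    res = sps.bootstrap(
        (a,),
        np.mean,
        confidence_level=level,
        n_resamples=n_resamples,
        method="BCa",
        rng=rng,
    )
    return (float(res.confidence_interval.low), float(res.confidence_interval.high))


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney p-value; exact null for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

def grid_search_fit(
    param_grid: dict,
    target_series: np.ndarray,
    config,
    seeds,
    full_output: bool = False,
):
    """Systematic sweep over phenotype parameters against a target series.

    ``param_grid`` maps :class:`~ecmsim.params.Phenotype` field names to lists
    of candidate values; every combination is simulated with each seed in
    ``seeds`` and scored by the mean squared error between the mean recorded
    fibril-fraction series and ``target_series`` (aligned with the run's
    record schedule).  Returns the best-scoring phenotype (and the full list
    of ``(params, mse)`` pairs when ``full_output`` is set).
    """
    from .engine import run

    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("param_grid must be a non-empty grid")
    target = np.asarray(target_series, dtype=float)
    names = list(param_grid)
    results = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        overrides = dict(zip(names, combo))
        phenotype = config.phenotype.with_overrides(**overrides)
        cfg = config.with_overrides(phenotype=phenotype)
        series = np.mean(
            [run(cfg, seed=s).fibril_fractions() for s in seeds], axis=0
        )
        if series.shape != target.shape:
            raise ValueError(
                f"target series length {target.shape} does not match the "
                f"run's record schedule {series.shape}"
            )
        mse = float(np.mean((series - target) ** 2))
        results.append((overrides, mse))
    best = min(results, key=lambda r: r[1])
    best_phenotype = config.phenotype.with_overrides(**best[0])
    if full_output:
        return best_phenotype, results
    return best_phenotype
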