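"""Initial matrix generation.

Cells are placed first, on nodes of the cellular lattice with hard-sphere
volume exclusion.  The ECM lattice is then filled with straight fibers: one
end on a random ECM node, random orientation, random length from the
configured range (uniform on 4.5-45 um by default).  Fibers may cross each
other freely but may not intersect any cell; offending fibers are redrawn.
"""

from __future__ import annotations

import numpy as np

from .geometry import endpoint_from, point_to_segments, random_orientation, segment_to_points
from .params import Phenotype, ProbabilityModel
from .state import CellAgent, FiberNetwork, LatticeSpec, SimState

__all__ = ["PlacementError", "sample_fiber_length", "place_cells", "place_fibers",
           "build_matrix"]

CELL_MAX_TRIES = 10_000
FIBER_MAX_TRIES = 1_000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy volume exclusion."""


def sample_fiber_length(
    rng: np.random.Generator, length_range: tuple[float, float] = (4.5, 45.0)
) -> float:
    """Draw a fiber length (um), uniform over the configured range."""
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid fiber length range {length_range}")
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def place_cells(
    n: int,
    lattice: LatticeSpec,
    rng: np.random.Generator,
    phenotype: Phenotype | None = None,
    radius: float = 9.0,
) -> list[CellAgent]:
    """Place ``n`` cells on cellular-lattice nodes with pairwise exclusion."""
    cells: list[CellAgent] = []
    centers: list[np.ndarray] = []
    for i in range(n):
        for _ in range(CELL_MAX_TRIES):
            cand = lattice.random_cell_node(rng).astype(float)
            if centers:
                d = np.linalg.norm(np.array(centers) - cand, axis=1)
                if np.any(d < 2 * radius):
                    continue
            centers.append(cand)
            cells.append(CellAgent(id=i, center=cand, phenotype=phenotype, radius=radius))
            break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} of radius {radius} um after "
                f"{CELL_MAX_TRIES} tries; density too high for volume exclusion"
            )
    return cells


def place_fibers(
    m: int,
    cells: list[CellAgent],
    lattice: LatticeSpec,
    rng: np.random.Generator,
    length_range: tuple[float, float] = (4.5, 45.0),
    orientation_mode: str = "sphere",
) -> FiberNetwork:
    """Fill the ECM lattice with ``m`` fibers avoiding all cell spheres.

    A fiber whose distal end falls outside the ECM box, or which intersects a
    cell, is redrawn from scratch (origin node, orientation and length).
    """
    centers = np.array([c.center for c in cells]) if cells else np.empty((0, 3))
    radii = np.array([c.radius for c in cells]) if cells else np.empty(0)
    network = FiberNetwork()
    for i in range(m):
        for _ in range(FIBER_MAX_TRIES):
            p1 = lattice.random_ecm_node(rng).astype(float)
            o = random_orientation(rng, mode=orientation_mode)
            length = sample_fiber_length(rng, length_range)
            p2 = endpoint_from(p1, o, length)
            if not lattice.in_ecm_box(p2):
                continue
            if len(centers) and np.any(segment_to_points(p1, p2, centers) <= radii):
                continue
            network.add(p1, p2)
            break
        else:
            raise PlacementError(
                f"could not place fiber {i + 1}/{m} after {FIBER_MAX_TRIES} tries"
            )
    return network


def build_matrix(config, seed: int | None = None) -> SimState:
    """Build a fresh :class:`SimState` from a resolved run configuration.

    Deterministic given ``(config, seed)``.  The state's initial close-fiber
    census is computed so the first timestep has valid probabilities.
    """
    from .config import RunConfig  # local import to keep config optional here

    if not isinstance(config, RunConfig):
        raise TypeError("config must be a RunConfig")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lattice = config.lattice
    n_cells = config.resolved_n_cells()
    cells = place_cells(n_cells, lattice, rng, phenotype=config.phenotype)
    fibers = place_fibers(
        config.n_fibers,
        cells,
        lattice,
        rng,
        length_range=(config.fiber_length_min, config.fiber_length_max),
        orientation_mode=config.orientation_mode,
    )
    state = SimState(
        lattice=lattice,
        cells=cells,
        fibers=fibers,
        step_index=0,
        rng=rng,
        fiber_length_range=(config.fiber_length_min, config.fiber_length_max),
        orientation_mode=config.orientation_mode,
    )
    state.next_cell_id = n_cells
    refresh_census(state, config.model)
    return state


def refresh_census(state: SimState, model: ProbabilityModel) -> None:
    """Recompute every cell's close-fiber count (closeF)."""
    for cell in state.cells:
        cell.closeF = count_close_fibers(cell, state.fibers, model.close_radius)


def count_close_fibers(cell: CellAgent, fibers: FiberNetwork, close_radius: float) -> int:
    """Number of fibers within ``close_radius`` of the cell center (closed ball)."""
    if len(fibers) == 0:
        return 0
    d = point_to_segments(cell.center, fibers.p1, fibers.p2)
    return int(np.count_nonzero(d <= close_radius))
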