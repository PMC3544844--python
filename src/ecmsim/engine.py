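"""The per-timestep remodeling engine.

One timestep represents 30 minutes.  Cells are visited in a freshly shuffled
order each step.  Every probability a cell uses during a step is evaluated at
its close-fiber count from the previous end-of-step census (``closeF``).

Per cell: first a movement draw.  A mover picks random candidate positions up
to 9 um away (2 lattice units); a candidate is accepted when it is not
excessively sterically hindered, overlaps no other cell and stays inside the
ECM box.  Fibers intersecting the accepted position are pulled aside
(realigned out of the cell) with probability ``pull_bias``, otherwise marked
for degradation; a mover does no further remodeling.  A non-mover draws one
of {nothing, degrade, realign} for each unmodified close fiber and may then
deposit at most one new fiber if its neighbourhood is sparse enough.

Fiber erasure and the materialisation of deposited fibers are deferred to the
end of the step, after which cells that migrated out of the cellular region
are dropped, the population is replenished at the region faces, the closeF
census is refreshed and the per-step modification locks are cleared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .build import build_matrix, count_close_fibers, refresh_census, sample_fiber_length
from .geometry import (
    endpoint_from,
    point_to_segments,
    random_orientation,
    random_unit_vector,
    sample_in_cone,
    segment_to_points,
)
from .params import Phenotype, ProbabilityModel
from .state import CellAgent, SimState

logger = logging.getLogger(__name__)

__all__ = [
    "StepStats",
    "Trajectory",
    "p_move",
    "p_degrade",
    "p_deposit",
    "action_probabilities",
    "sample_fiber_action",
    "attempt_move",
    "realign_fiber",
    "deposit_fiber",
    "replenish_cells",
    "step",
    "run",
]


# ---------------------------------------------------------------------------
# probability functions
# ---------------------------------------------------------------------------

def p_move(closeF: int, phenotype: Phenotype, model: ProbabilityModel) -> float:
    """Gaussian (biphasic) motility probability with a hard steric cutoff.

    Exactly zero at and above the phenotype's motility threshold.
    """
    if closeF < 0:
        raise ValueError("closeF must be non-negative")
    if closeF >= phenotype.motility_threshold:
        return 0.0
    mu = model.motility_mu(phenotype)
    sigma = model.motility_sigma(phenotype)
    return float(model.move_peak * np.exp(-((closeF - mu) ** 2) / (2.0 * sigma**2)))


def p_degrade(closeF: int, phenotype: Phenotype, model: ProbabilityModel) -> float:
    """Logistic degradation probability, saturating at ``p_deg_max``."""
    if closeF < 0:
        raise ValueError("closeF must be non-negative")
    z = -model.logistic_k_deg * (closeF - model.logistic_x0_deg)
    return float(phenotype.p_deg_max / (1.0 + np.exp(z)))


def p_deposit(closeF: int, phenotype: Phenotype, model: ProbabilityModel) -> float:
    """Logistic deposition probability, decreasing in closeF, max ``p_dep_max``."""
    if closeF < 0:
        raise ValueError("closeF must be non-negative")
    z = model.logistic_k_dep * (closeF - model.logistic_x0_dep)
    return float(phenotype.p_dep_max / (1.0 + np.exp(z)))


def action_probabilities(
    closeF: int, phenotype: Phenotype, model: ProbabilityModel
) -> tuple[float, float, float]:
    """(P_nothing, P_degrade, P_align) for one close fiber; they sum to 1."""
    pd = p_degrade(closeF, phenotype, model)
    pn = phenotype.p_nothing
    pa = 1.0 - pn - pd
    if pa < -1e-12:
        raise ValueError(
            "P_align negative: p_nothing + p_degrade exceeds 1 "
            f"(closeF={closeF}, p_nothing={pn}, p_degrade={pd})"
        )
    return pn, pd, max(pa, 0.0)


def sample_fiber_action(
    closeF: int, phenotype: Phenotype, model: ProbabilityModel, rng: np.random.Generator
) -> str:
    """Draw one of 'nothing' / 'degrade' / 'align' for a close fiber."""
    _, pd, pa = action_probabilities(closeF, phenotype, model)
    u = rng.random()
    if u < pd:
        return "degrade"
    if u < pd + pa:
        return "align"
    return "nothing"


# ---------------------------------------------------------------------------
# per-step bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class StepStats:
    moves: int = 0
    move_attempts: int = 0
    deposits: int = 0
    degradations: int = 0
    realignments: int = 0
    replenished: int = 0
    cells_left: int = 0

    def __iadd__(self, other: "StepStats") -> "StepStats":
        for f in ("moves", "move_attempts", "deposits", "degradations",
                  "realignments", "replenished", "cells_left"):
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self


# ---------------------------------------------------------------------------
# remodeling operations
# ---------------------------------------------------------------------------

def realign_fiber(
    fiber_index: int,
    cell: CellAgent,
    state: SimState,
    model: ProbabilityModel,
    rng: np.random.Generator,
) -> bool:
    """Pull a fiber: pivot its distal end to a new admissible orientation.

    The endpoint nearer the cell center stays fixed; the far end moves to a
    random orientation within ``max_realign_angle`` of the current direction,
    preserving length, such that the fiber intersects no cell and stays in the
    ECM box.  Returns False (fiber unchanged) if no admissible orientation is
    found within the sampling budget.
    """
    fibers = state.fibers
    p1 = fibers.p1[fiber_index]
    p2 = fibers.p2[fiber_index]
    d1 = np.linalg.norm(p1 - cell.center)
    d2 = np.linalg.norm(p2 - cell.center)
    pivot, distal = (p1, p2) if d1 <= d2 else (p2, p1)
    length = float(np.linalg.norm(distal - pivot))
    old_dir = (distal - pivot) / length

    centers = state.cell_centers
    radii = np.array([c.radius for c in state.cells])
    # If the pivot itself sits inside a cell sphere no orientation can help.
    if np.any(np.linalg.norm(centers - pivot, axis=1) <= radii):
        return False

    dirs = sample_in_cone(rng, old_dir, model.max_realign_angle, model.realign_tries)
    new_ends = pivot[None, :] + length * dirs
    ok = np.all((new_ends >= 0.0) & (new_ends <= state.lattice.ecm_extent), axis=1)
    for center, radius in zip(centers, radii):
        if not ok.any():
            break
        idx = np.flatnonzero(ok)
        d = _segments_from_pivot_to_point(pivot, new_ends[idx], center)
        ok[idx[d <= radius]] = False
    candidates = np.flatnonzero(ok)
    if len(candidates) == 0:
        return False
    choice = candidates[rng.integers(len(candidates))]
    fibers.p1[fiber_index] = pivot
    fibers.p2[fiber_index] = new_ends[choice]
    fibers.modified[fiber_index] = True
    return True


def _segments_from_pivot_to_point(
    pivot: np.ndarray, ends: np.ndarray, point: np.ndarray
) -> np.ndarray:
    """Distance from ``point`` to each segment ``pivot -> ends[i]``."""
    d = ends - pivot[None, :]
    denom = np.einsum("ij,ij->i", d, d)
    t = (d @ (point - pivot)) / denom
    np.clip(t, 0.0, 1.0, out=t)
    closest = pivot[None, :] + t[:, None] * d
    diff = closest - point[None, :]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def attempt_move(
    cell: CellAgent,
    state: SimState,
    model: ProbabilityModel,
    rng: np.random.Generator,
    stats: StepStats | None = None,
) -> bool:
    """Try to move a cell whose movement draw already succeeded.

    Up to ``move_retries`` candidate positions are tested.  A candidate fails
    when it leaves the ECM box, overlaps another cell, touches a fiber already
    realigned this step (which cannot be modified again), or would require
    resolving more than ``steric_block_threshold`` fibers.  On acceptance each
    intersecting unmodified fiber is pulled out of the way with probability
    ``pull_bias`` and marked for degradation otherwise (a pull that finds no
    admissible orientation falls back to degradation so that cell-fiber
    exclusion is restored by the end-of-step erasure).
    """
    stats = stats if stats is not None else StepStats()
    fibers = state.fibers
    others = np.array([c.center for c in state.cells if c is not cell])
    other_radii = np.array([c.radius for c in state.cells if c is not cell])
    for _ in range(model.move_retries):
        stats.move_attempts += 1
        direction = random_unit_vector(rng)
        dist = rng.uniform(0.0, model.max_step)
        cand = cell.center + direction * dist
        if not (np.all(cand >= cell.radius)
                and np.all(cand <= state.lattice.ecm_extent - cell.radius)):
            continue
        if len(others) and np.any(
            np.linalg.norm(others - cand, axis=1) < cell.radius + other_radii
        ):
            continue
        d = point_to_segments(cand, fibers.p1, fibers.p2)
        hit = d <= cell.radius
        # realigned-this-step fibers are locked; marked ones will be erased anyway
        if np.any(hit & fibers.modified & ~fibers.marked):
            continue
        resolvable = hit & ~fibers.modified
        if int(resolvable.sum()) > model.steric_block_threshold:
            continue
        cell.center = cand
        cell.moved_this_step = True
        for fi in np.flatnonzero(resolvable):
            if rng.random() < model.pull_bias and realign_fiber(
                fi, cell, state, model, rng
            ):
                stats.realignments += 1
            else:
                fibers.marked[fi] = True
                fibers.modified[fi] = True
                stats.degradations += 1
        stats.moves += 1
        return True
    return False


def deposit_fiber(
    cell: CellAgent,
    state: SimState,
    model: ProbabilityModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Sample a new fiber near the cell; returns its endpoints or None.

    The proximal end lies between the cell surface and the close radius; the
    whole fiber must avoid every cell sphere and stay inside the ECM box.  The
    fiber itself is materialised at the end of the step.
    """
    centers = state.cell_centers
    radii = np.array([c.radius for c in state.cells])
    lo, hi = state.fiber_length_range
    for _ in range(model.deposit_tries):
        direction = random_unit_vector(rng)
        r = rng.uniform(cell.radius, model.close_radius)
        p1 = cell.center + r * direction
        o = random_orientation(rng, mode=state.orientation_mode)
        length = sample_fiber_length(rng, (lo, hi))
        p2 = endpoint_from(p1, o, length)
        if not (state.lattice.in_ecm_box(p1) and state.lattice.in_ecm_box(p2)):
            continue
        if np.any(segment_to_points(p1, p2, centers) <= radii):
            continue
        return p1, p2
    logger.debug("cell %d found no admissible deposition site", cell.id)
    return None


def replenish_cells(
    state: SimState,
    model: ProbabilityModel,
    rng: np.random.Generator,
    stats: StepStats | None = None,
    max_tries: int = 500,
    phenotype: Phenotype | None = None,
) -> None:
    """Top the population back up to ``min_cells`` with cells on region faces.

    New cells appear at uniformly random positions on a random face of the
    cellular region, subject to cell-cell and cell-fiber exclusion.
    """
    stats = stats if stats is not None else StepStats()
    if phenotype is None:
        phenotype = state.cells[0].phenotype if state.cells else None
    if phenotype is None:
        return
    lattice = state.lattice
    while len(state.cells) < phenotype.min_cells:
        placed = False
        for _ in range(max_tries):
            face = int(rng.integers(6))
            axis, side = divmod(face, 2)
            pos = rng.uniform(lattice.cell_lo, lattice.cell_hi)
            pos[axis] = lattice.cell_hi[axis] if side else lattice.cell_lo[axis]
            radius = 9.0
            centers = state.cell_centers
            if len(centers) and np.any(
                np.linalg.norm(centers - pos, axis=1) < 2 * radius
            ):
                continue
            if len(state.fibers) and np.any(
                point_to_segments(pos, state.fibers.p1, state.fibers.p2) <= radius
            ):
                continue
            cell = CellAgent(
                id=state.next_cell_id, center=pos, phenotype=phenotype, radius=radius
            )
            state.next_cell_id += 1
            state.cells.append(cell)
            stats.replenished += 1
            placed = True
            break
        if not placed:
            logger.warning("replenishment failed after %d tries; continuing", max_tries)
            break


# ---------------------------------------------------------------------------
# the timestep
# ---------------------------------------------------------------------------

def step(state: SimState, model: ProbabilityModel,
         rng: np.random.Generator | None = None) -> StepStats:
    """Advance the state by one 30-minute timestep (in place)."""
    rng = rng if rng is not None else state.rng
    if rng is None:
        raise ValueError("state has no RNG; pass one explicitly")
    fibers = state.fibers
    stats = StepStats()
    pending: list[tuple[np.ndarray, np.ndarray]] = []

    order = rng.permutation(len(state.cells))
    for idx in order:
        cell = state.cells[idx]
        cell.moved_this_step = False
        cell.deposited_this_step = False
        closeF = cell.closeF
        phenotype = cell.phenotype

        if rng.random() < p_move(closeF, phenotype, model):
            if attempt_move(cell, state, model, rng, stats):
                continue  # movers modify no further fibers

        # stationary remodeling: one action draw per unmodified close fiber
        if len(fibers):
            d = point_to_segments(cell.center, fibers.p1, fibers.p2)
            close_idx = np.flatnonzero((d <= model.close_radius) & ~fibers.modified)
            for fi in close_idx:
                action = sample_fiber_action(closeF, phenotype, model, rng)
                if action == "degrade":
                    fibers.marked[fi] = True
                    fibers.modified[fi] = True
                    stats.degradations += 1
                elif action == "align":
                    if realign_fiber(fi, cell, state, model, rng):
                        stats.realignments += 1

        # deposition: at most one fiber per cell per step
        if closeF < phenotype.deposit_threshold and rng.random() < p_deposit(
            closeF, phenotype, model
        ):
            seg = deposit_fiber(cell, state, model, rng)
            if seg is not None:
                pending.append(seg)
                cell.deposited_this_step = True
                stats.deposits += 1

    # deferred erasure and addition; a pending fiber is discarded if a cell
    # moved onto its site after the deposition was drawn (volume exclusion)
    erased = fibers.erase_marked()
    assert erased == stats.degradations, "degradation ledger out of sync"
    centers = state.cell_centers
    radii = np.array([c.radius for c in state.cells])
    materialized = 0
    for p1, p2 in pending:
        if len(centers) and np.any(segment_to_points(p1, p2, centers) <= radii):
            continue
        fibers.add(p1, p2)
        materialized += 1
    stats.deposits = materialized

    # drop cells that migrated out of the tracked region, then replenish
    phenotype = state.cells[0].phenotype if state.cells else None
    kept = [c for c in state.cells if state.lattice.in_cell_region(c.center)]
    stats.cells_left = len(state.cells) - len(kept)
    state.cells = kept
    replenish_cells(state, model, rng, stats, phenotype=phenotype)

    refresh_census(state, model)
    fibers.reset_step_flags()
    state.step_index += 1
    return stats


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded time series of a run plus its final state."""

    records: list[dict] = field(default_factory=list)
    final_state: SimState | None = None
    seed: int | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def fibril_fractions(self) -> np.ndarray:
        return np.array([r["fibril_fraction"] for r in self.records])

    def steps(self) -> np.ndarray:
        return np.array([r["step"] for r in self.records])

    def at_step(self, s: int) -> dict:
        for r in self.records:
            if r["step"] == s:
                return r
        raise KeyError(f"no record at step {s}")


def run(
    config,
    seed: int | None = None,
    n_steps: int | None = None,
    record_every: int | None = None,
) -> Trajectory:
    """Build a matrix and advance it, recording summaries on a schedule.

    Deterministic given ``(config, seed)``.  The recorded fibril fraction is
    the mean over ``config.n_slices`` xy-slices spread through the cellular
    region (a single mid-plane slice when ``n_slices=1``).
    """
    from .quantify import stack_fibril_fraction

    if seed is None:
        seed = config.seed
    if n_steps is None:
        n_steps = config.n_steps
    if record_every is None:
        record_every = config.record_every

    state = build_matrix(config, seed)
    model = config.model

    def record(stats_sum: StepStats) -> dict:
        return {
            "step": state.step_index,
            "hours": state.step_index * config.step_hours,
            "fibril_fraction": stack_fibril_fraction(
                state,
                n_slices=config.n_slices,
                pixel_size=config.pixel_size,
                render_radius=config.render_radius,
                z_thickness=config.z_thickness,
            ),
            "n_fibers": len(state.fibers),
            "n_cells": len(state.cells),
            "deposits": stats_sum.deposits,
            "degradations": stats_sum.degradations,
            "realignments": stats_sum.realignments,
            "moves": stats_sum.moves,
        }

    traj = Trajectory(seed=seed)
    acc = StepStats()
    traj.records.append(record(acc))
    for t in range(1, n_steps + 1):
        acc += step(state, model)
        if t % record_every == 0 or t == n_steps:
            traj.records.append(record(acc))
            acc = StepStats()
    traj.final_state = state
    return traj
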