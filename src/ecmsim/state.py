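"""Simulation state containers: lattice geometry, fibers, cells.

The simulated volume is a nested pair of cubic lattices: cells are seeded and
tracked on a central "cellular" lattice (default 50 nodes per side) while
collagen fibers fill a larger "ECM" lattice (default 75 per side) centred on
it, so that tracked cells never see an artificial fiber-free boundary.  Node
spacing converts lattice units to micrometres (default 4.5 um).  Entities are
initialised on lattice nodes but afterwards live in continuous space.

Fibers are stored struct-of-arrays in :class:`FiberNetwork` for vectorised
distance queries; :class:`Fiber` is a per-fiber record view used for
inspection and serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import Phenotype, phenotype_from_dict

__all__ = ["LatticeSpec", "Fiber", "FiberNetwork", "CellAgent", "SimState",
           "save_state", "load_state"]


@dataclass(frozen=True)
class LatticeSpec:
    """Nested cellular/ECM lattice geometry.

    ``cell_lattice_size`` and ``ecm_lattice_size`` are node counts per side;
    ``spacing`` is micrometres per lattice unit.  The bounding box of a
    lattice of ``n`` nodes spans ``n * spacing`` um, with nodes at
    ``i * spacing`` for ``i in 0..n-1``; the cellular region is centred inside
    the ECM region.
    """

    cell_lattice_size: int = 50
    ecm_lattice_size: int = 75
    spacing: float = 4.5

    def __post_init__(self) -> None:
        if self.ecm_lattice_size < self.cell_lattice_size:
            raise ValueError("ECM lattice must be at least as large as cellular lattice")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    # -- unit conversion -------------------------------------------------
    def to_um(self, lattice_units: float) -> float:
        return lattice_units * self.spacing

    def to_units(self, um: float) -> float:
        return um / self.spacing

    # -- extents ---------------------------------------------------------
    @property
    def ecm_extent(self) -> float:
        """Side length of the ECM box in um."""
        return self.ecm_lattice_size * self.spacing

    @property
    def cell_extent(self) -> float:
        """Side length of the cellular region in um."""
        return self.cell_lattice_size * self.spacing

    @property
    def cell_offset(self) -> float:
        """Offset of the cellular region from the ECM box origin, per axis."""
        return (self.ecm_lattice_size - self.cell_lattice_size) / 2.0 * self.spacing

    @property
    def cell_lo(self) -> np.ndarray:
        return np.full(3, self.cell_offset)

    @property
    def cell_hi(self) -> np.ndarray:
        return np.full(3, self.cell_offset + self.cell_extent)

    # -- membership ------------------------------------------------------
    def in_ecm_box(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= 0.0) and np.all(p <= self.ecm_extent))

    def in_cell_region(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.cell_lo) and np.all(p <= self.cell_hi))

    # -- node sampling ---------------------------------------------------
    def random_ecm_node(self, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(0, self.ecm_lattice_size, size=3) * self.spacing

    def random_cell_node(self, rng: np.random.Generator) -> np.ndarray:
        return self.cell_offset + rng.integers(0, self.cell_lattice_size, size=3) * self.spacing

    @property
    def volume_ml(self) -> float:
        """Volume of the ECM box in millilitres (1 um^3 = 1e-12 mL)."""
        return self.ecm_extent**3 * 1e-12

    def to_dict(self) -> dict:
        return {
            "cell_lattice_size": self.cell_lattice_size,
            "ecm_lattice_size": self.ecm_lattice_size,
            "spacing": self.spacing,
        }


@dataclass
class Fiber:
    """Record view of one fiber: a line segment plus per-step bookkeeping flags."""

    id: int
    p1: np.ndarray
    p2: np.ndarray
    marked_for_degradation: bool = False
    modified_this_step: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p2 - self.p1))


class FiberNetwork:
    """All fibers of one state, struct-of-arrays.

    ``p1`` is the proximal/origin end (on an ECM node at creation, and the
    pivot end after realignment), ``p2`` the distal end.  ``marked`` flags a
    fiber for end-of-step erasure; ``modified`` locks a fiber against further
    remodeling within the current timestep.
    """

    def __init__(self) -> None:
        self.p1 = np.empty((0, 3))
        self.p2 = np.empty((0, 3))
        self.ids = np.empty(0, dtype=np.int64)
        self.marked = np.empty(0, dtype=bool)
        self.modified = np.empty(0, dtype=bool)
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> Fiber:
        return Fiber(
            id=int(self.ids[i]),
            p1=self.p1[i].copy(),
            p2=self.p2[i].copy(),
            marked_for_degradation=bool(self.marked[i]),
            modified_this_step=bool(self.modified[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def lengths(self) -> np.ndarray:
        d = self.p2 - self.p1
        return np.sqrt(np.einsum("ij,ij->i", d, d))

    def add(self, p1, p2) -> int:
        """Append one fiber; returns its id.  Zero-length segments are rejected."""
        p1 = np.asarray(p1, dtype=float).reshape(1, 3)
        p2 = np.asarray(p2, dtype=float).reshape(1, 3)
        if not np.linalg.norm(p2 - p1) > 0:
            raise ValueError("fiber segment must have positive length")
        self.p1 = np.concatenate([self.p1, p1])
        self.p2 = np.concatenate([self.p2, p2])
        fid = self._next_id
        self.ids = np.append(self.ids, fid)
        self.marked = np.append(self.marked, False)
        self.modified = np.append(self.modified, False)
        self._next_id += 1
        return fid

    def add_many(self, p1s: np.ndarray, p2s: np.ndarray) -> None:
        p1s = np.asarray(p1s, dtype=float).reshape(-1, 3)
        p2s = np.asarray(p2s, dtype=float).reshape(-1, 3)
        n = len(p1s)
        if n == 0:
            return
        lengths = np.linalg.norm(p2s - p1s, axis=1)
        if not np.all(lengths > 0):
            raise ValueError("fiber segments must have positive length")
        self.p1 = np.concatenate([self.p1, p1s])
        self.p2 = np.concatenate([self.p2, p2s])
        self.ids = np.concatenate(
            [self.ids, np.arange(self._next_id, self._next_id + n, dtype=np.int64)]
        )
        self.marked = np.concatenate([self.marked, np.zeros(n, dtype=bool)])
        self.modified = np.concatenate([self.modified, np.zeros(n, dtype=bool)])
        self._next_id += n

    def erase_marked(self) -> int:
        """Remove fibers marked for degradation; returns how many were erased."""
        n = int(self.marked.sum())
        if n:
            keep = ~self.marked
            self.p1 = self.p1[keep]
            self.p2 = self.p2[keep]
            self.ids = self.ids[keep]
            self.marked = self.marked[keep]
            self.modified = self.modified[keep]
        return n

    def reset_step_flags(self) -> None:
        self.modified[:] = False

    def copy(self) -> "FiberNetwork":
        out = FiberNetwork()
        out.p1 = self.p1.copy()
        out.p2 = self.p2.copy()
        out.ids = self.ids.copy()
        out.marked = self.marked.copy()
        out.modified = self.modified.copy()
        out._next_id = self._next_id
        return out


@dataclass
class CellAgent:
    """A cell: a sphere with a phenotype and the fiber census driving its behaviour.

    ``closeF`` is the number of fibers within the model's close radius at the
    last end-of-step census; all of the cell's probabilities for the current
    step are evaluated at that count.
    """

    id: int
    center: np.ndarray
    phenotype: Phenotype
    radius: float = 9.0
    closeF: int = 0
    moved_this_step: bool = False
    deposited_this_step: bool = False

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")


@dataclass
class SimState:
    """Cells + fibers + timestep index: the object the engine advances."""

    lattice: LatticeSpec
    cells: list[CellAgent]
    fibers: FiberNetwork
    step_index: int = 0
    rng: np.random.Generator | None = None
    fiber_length_range: tuple[float, float] = (4.5, 45.0)
    orientation_mode: str = "sphere"
    next_cell_id: int = 0

    @property
    def cell_centers(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 3))
        return np.array([c.center for c in self.cells])

    def to_dict(self) -> dict:
        phen = self.cells[0].phenotype.to_dict() if self.cells else None
        return {
            "lattice": self.lattice.to_dict(),
            "step_index": self.step_index,
            "fiber_length_range": list(self.fiber_length_range),
            "orientation_mode": self.orientation_mode,
            "phenotype": phen,
            "cells": [
                {"id": c.id, "center": c.center.tolist(), "radius": c.radius,
                 "closeF": c.closeF}
                for c in self.cells
            ],
            "fibers": [
                {"id": int(fid), "p1": p1.tolist(), "p2": p2.tolist()}
                for fid, p1, p2 in zip(self.fibers.ids, self.fibers.p1, self.fibers.p2)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimState":
        lattice = LatticeSpec(**data["lattice"])
        phen = phenotype_from_dict(data["phenotype"]) if data.get("phenotype") else None
        cells = [
            CellAgent(
                id=c["id"],
                center=np.array(c["center"]),
                phenotype=phen,
                radius=c["radius"],
                closeF=c.get("closeF", 0),
            )
            for c in data["cells"]
        ]
        fibers = FiberNetwork()
        for f in data["fibers"]:
            fibers.add(f["p1"], f["p2"])
        state = cls(
            lattice=lattice,
            cells=cells,
            fibers=fibers,
            step_index=data.get("step_index", 0),
            fiber_length_range=tuple(data.get("fiber_length_range", (4.5, 45.0))),
            orientation_mode=data.get("orientation_mode", "sphere"),
        )
        state.next_cell_id = 1 + max((c.id for c in cells), default=-1)
        return state


def save_state(state: SimState, path) -> None:
    Path(path).write_text(json.dumps(state.to_dict()))


def load_state(path) -> SimState:
    return SimState.from_dict(json.loads(Path(path).read_text()))
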