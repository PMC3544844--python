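"""Remodeling engine: probability functions, per-step operations, invariants."""

import numpy as np
import pytest

from ecmsim import (
    HIGH_INVASIVE,
    LOW_INVASIVE,
    Phenotype,
    ProbabilityModel,
    build_matrix,
    attempt_move,
    deposit_fiber,
    p_degrade,
    p_deposit,
    p_move,
    realign_fiber,
    replenish_cells,
    run,
    sample_fiber_action,
    step,
)
from ecmsim.engine import action_probabilities, StepStats
from ecmsim.geometry import point_to_segments, segment_to_points
from ecmsim.state import CellAgent, FiberNetwork, LatticeSpec, SimState
from tests.conftest import small_config

MODEL = ProbabilityModel()


class TestProbabilityFunctions:
    @pytest.mark.parametrize("phenotype", [LOW_INVASIVE, HIGH_INVASIVE])
    def test_move_zero_at_and_above_motility_threshold(self, phenotype):
        thr = phenotype.motility_threshold
        assert p_move(thr, phenotype, MODEL) == 0.0
        assert p_move(thr + 10, phenotype, MODEL) == 0.0
        assert p_move(thr - 1, phenotype, MODEL) >= 0.0

    def test_move_peak_at_mu_and_symmetric(self):
        model = MODEL.with_overrides(move_mu=10.0, move_sigma=4.0, move_peak=0.5)
        ph = LOW_INVASIVE
        assert p_move(10, ph, model) == pytest.approx(0.5)
        for d in (1, 3, 5):
            assert p_move(10 - d, ph, model) == pytest.approx(p_move(10 + d, ph, model))

    @pytest.mark.parametrize(
        "phenotype,asymptote", [(LOW_INVASIVE, 0.1), (HIGH_INVASIVE, 0.2)]
    )
    def test_degrade_saturates_at_p_deg_max(self, phenotype, asymptote):
        assert p_degrade(1000, phenotype, MODEL) == pytest.approx(asymptote, rel=1e-6)

    def test_degrade_midpoint_and_monotone(self):
        model = MODEL.with_overrides(logistic_x0_deg=12.0, logistic_k_deg=0.5)
        assert p_degrade(12, LOW_INVASIVE, model) == pytest.approx(0.05)
        vals = [p_degrade(n, LOW_INVASIVE, model) for n in range(101)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_deposit_midpoint_and_monotone_decreasing(self):
        model = MODEL.with_overrides(logistic_x0_dep=8.0, logistic_k_dep=0.7)
        assert p_deposit(8, LOW_INVASIVE, model) == pytest.approx(0.4)
        vals = [p_deposit(n, LOW_INVASIVE, model) for n in range(LOW_INVASIVE.deposit_threshold + 1)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_action_probabilities_sum_to_one(self):
        for ph in (LOW_INVASIVE, HIGH_INVASIVE):
            for n in range(0, 80, 5):
                pn, pd, pa = action_probabilities(n, ph, MODEL)
                assert pn + pd + pa == pytest.approx(1.0)
                assert min(pn, pd, pa) >= 0.0

    def test_low_invasive_align_vanishes_at_saturation(self):
        # P_align = 1 - 0.9 - 0.1 = 0 once degradation saturates
        _, pd, pa = action_probabilities(1000, LOW_INVASIVE, MODEL)
        assert pa == pytest.approx(0.0, abs=1e-6)

    def test_sampled_action_frequencies(self):
        rng = np.random.default_rng(9)
        model = MODEL.with_overrides(logistic_x0_deg=3.0, logistic_k_deg=0.8)
        ph = HIGH_INVASIVE
        n, draws = 4, 30_000
        counts = {"nothing": 0, "degrade": 0, "align": 0}
        for _ in range(draws):
            counts[sample_fiber_action(n, ph, model, rng)] += 1
        pn, pd, pa = action_probabilities(n, ph, model)
        for key, p in (("nothing", pn), ("degrade", pd), ("align", pa)):
            se = np.sqrt(draws * p * (1 - p))
            assert abs(counts[key] - draws * p) < 3 * se

    def test_invalid_phenotype_rejected(self):
        with pytest.raises(ValueError):
            Phenotype(p_nothing=0.95, p_deg_max=0.1)


def _exclusion_ok(state):
    """No cell-cell overlap and no cell-fiber intersection."""
    centers = state.cell_centers
    if len(centers) > 1:
        radii = np.array([c.radius for c in state.cells])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        pair_min = radii[:, None] + radii[None, :]
        np.fill_diagonal(d, np.inf)
        if np.any(d < pair_min - 1e-9):
            return False
    for c in state.cells:
        dd = point_to_segments(c.center, state.fibers.p1, state.fibers.p2)
        if len(dd) and dd.min() <= c.radius - 1e-9:
            return False
    return True


class TestAttemptMove:
    def test_unobstructed_cell_always_moves_within_bound(self, rng):
        lat = LatticeSpec(cell_lattice_size=20, ecm_lattice_size=30)
        cell = CellAgent(id=0, center=lat.cell_lo + 45.0, phenotype=LOW_INVASIVE)
        state = SimState(lattice=lat, cells=[cell], fibers=FiberNetwork(), rng=rng)
        for _ in range(50):
            start = cell.center.copy()
            assert attempt_move(cell, state, MODEL, rng)
            assert np.linalg.norm(cell.center - start) <= MODEL.max_step + 1e-9

    def test_dense_state_moves_keep_exclusion(self):
        cfg = small_config(matrix={"n_fibers": 500})
        state = build_matrix(cfg, 11)
        rng = state.rng
        moved = 0
        for _ in range(300):
            for cell in state.cells:
                if attempt_move(cell, state, cfg.model, rng):
                    moved += 1
            # resolve end-of-step bookkeeping manually
            state.fibers.erase_marked()
            state.fibers.reset_step_flags()
            state.cells = [c for c in state.cells if state.lattice.in_ecm_box(c.center)]
            assert _exclusion_ok(state)
        assert moved > 50


class TestRealignFiber:
    def test_length_preserved_pivot_fixed_and_no_intersections(self):
        cfg = small_config(matrix={"n_fibers": 500})
        state = build_matrix(cfg, 5)
        rng = state.rng
        model = cfg.model
        realigned = 0
        for _ in range(400):
            cell = state.cells[rng.integers(len(state.cells))]
            d = point_to_segments(cell.center, state.fibers.p1, state.fibers.p2)
            close = np.flatnonzero(d <= model.close_radius)
            if len(close) == 0:
                continue
            fi = int(close[rng.integers(len(close))])
            before_p1 = state.fibers.p1[fi].copy()
            before_p2 = state.fibers.p2[fi].copy()
            length_before = np.linalg.norm(before_p2 - before_p1)
            old_dir_pivot = (
                before_p1
                if np.linalg.norm(before_p1 - cell.center)
                <= np.linalg.norm(before_p2 - cell.center)
                else before_p2
            )
            if realign_fiber(fi, cell, state, model, rng):
                realigned += 1
                new_p1, new_p2 = state.fibers.p1[fi], state.fibers.p2[fi]
                assert np.allclose(new_p1, old_dir_pivot, atol=1e-12)
                assert np.linalg.norm(new_p2 - new_p1) == pytest.approx(
                    length_before, abs=1e-9
                )
                old_dir = (before_p2 - before_p1) / length_before
                if not np.allclose(old_dir_pivot, before_p1):
                    old_dir = -old_dir
                new_dir = (new_p2 - new_p1) / length_before
                angle = np.arccos(np.clip(old_dir @ new_dir, -1, 1))
                assert angle <= model.max_realign_angle + 1e-9
                centers = state.cell_centers
                radii = np.array([c.radius for c in state.cells])
                assert np.all(segment_to_points(new_p1, new_p2, centers) > radii)
                state.fibers.modified[fi] = False  # allow reuse in this test
        assert realigned > 50


class TestDepositFiber:
    def test_placement_contract(self):
        cfg = small_config(matrix={"n_fibers": 100})
        state = build_matrix(cfg, 2)
        rng = state.rng
        model = cfg.model
        for _ in range(100):
            cell = state.cells[0]
            seg = deposit_fiber(cell, state, model, rng)
            assert seg is not None
            p1, p2 = seg
            d_prox = np.linalg.norm(p1 - cell.center)
            assert cell.radius <= d_prox <= model.close_radius
            centers = state.cell_centers
            radii = np.array([c.radius for c in state.cells])
            assert np.all(segment_to_points(p1, p2, centers) > radii)
            lo, hi = state.fiber_length_range
            assert lo <= np.linalg.norm(p2 - p1) <= hi


class TestReplenishCells:
    def test_tops_up_to_minimum_on_boundary(self):
        cfg = small_config()
        state = build_matrix(cfg, 8)
        min_cells = state.cells[0].phenotype.min_cells
        state.cells = state.cells[: min_cells - 1]
        replenish_cells(state, cfg.model, state.rng)
        assert len(state.cells) == min_cells
        new = state.cells[-1]
        lat = state.lattice
        on_face = np.any(
            np.isclose(new.center, lat.cell_lo) | np.isclose(new.center, lat.cell_hi)
        )
        assert on_face
        assert _exclusion_ok(state)

    def test_no_change_when_above_minimum(self):
        cfg = small_config()
        state = build_matrix(cfg, 8)
        n = len(state.cells)
        replenish_cells(state, cfg.model, state.rng)
        assert len(state.cells) == n


class TestStep:
    def test_acellular_step_is_identity_on_fibers(self):
        cfg = small_config(matrix={"n_fibers": 300}, run={"n_cells": 0})
        state = build_matrix(cfg, 4)
        p1 = state.fibers.p1.copy()
        p2 = state.fibers.p2.copy()
        for _ in range(10):
            step(state, cfg.model)
        assert np.array_equal(state.fibers.p1, p1)
        assert np.array_equal(state.fibers.p2, p2)

    def test_ledger_conservation_and_locks(self):
        cfg = small_config(matrix={"n_fibers": 400})
        state = build_matrix(cfg, 6)
        for _ in range(25):
            ids_before = set(state.fibers.ids.tolist())
            lengths_before = dict(zip(state.fibers.ids.tolist(), state.fibers.lengths))
            n_before = len(state.fibers)
            stats = step(state, cfg.model)
            # conservation: fiber count changes exactly by deposits - degradations
            assert len(state.fibers) - n_before == stats.deposits - stats.degradations
            # at most one deposition per cell per step
            assert stats.deposits <= len(state.cells)
            # surviving fibers keep their length (realignment preserves length)
            for fid, length in zip(state.fibers.ids.tolist(), state.fibers.lengths):
                if fid in ids_before:
                    assert length == pytest.approx(lengths_before[fid], abs=1e-9)
            # volume exclusion restored after erasure/addition
            assert _exclusion_ok(state)
            # step flags cleared for the next step
            assert not state.fibers.modified.any()
            assert not state.fibers.marked.any()

    def test_displacement_bound_per_step(self):
        cfg = small_config(matrix={"n_fibers": 300})
        state = build_matrix(cfg, 9)
        for _ in range(25):
            pos_before = {c.id: c.center.copy() for c in state.cells}
            step(state, cfg.model)
            for c in state.cells:
                if c.id in pos_before:
                    d = np.linalg.norm(c.center - pos_before[c.id])
                    assert d <= cfg.model.max_step + 1e-9

    def test_census_matches_exhaustive_scan(self):
        cfg = small_config(matrix={"n_fibers": 400})
        state = build_matrix(cfg, 10)
        step(state, cfg.model)
        for c in state.cells:
            d = point_to_segments(c.center, state.fibers.p1, state.fibers.p2)
            assert c.closeF == int(np.count_nonzero(d <= cfg.model.close_radius))


class TestRun:
    def test_zero_steps_returns_initial_record_only(self):
        cfg = small_config(run={"n_steps": 0})
        traj = run(cfg, seed=0)
        assert len(traj.records) == 1
        assert traj.records[0]["step"] == 0
        assert traj.records[0]["n_cells"] == 4

    def test_deterministic_trajectories(self):
        cfg = small_config()
        a = run(cfg, seed=42)
        b = run(cfg, seed=42)
        assert a.records == b.records
        assert np.array_equal(a.final_state.fibers.p1, b.final_state.fibers.p1)

    def test_record_schedule_and_fields(self):
        cfg = small_config(run={"n_steps": 10, "record_every": 5})
        traj = run(cfg, seed=1)
        assert [r["step"] for r in traj.records] == [0, 5, 10]
        rec = traj.records[-1]
        assert rec["hours"] == pytest.approx(5.0)
        assert 0.0 <= rec["fibril_fraction"] <= 1.0
        for key in ("n_fibers", "n_cells", "deposits", "degradations",
                    "realignments", "moves"):
            assert key in rec
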