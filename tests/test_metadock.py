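"""Meta-docking: randomized starts, jobs, batches, escalation control."""

import numpy as np
import pytest
from scipy.stats import kstest

from incdock import fixtures
from incdock.engine import EnergyBreakdown, GAConfig, ScoredPose
from incdock.metadock import (
    BatchError,
    Protocol,
    default_protocols,
    incremental_dock,
    escalate,
    load_protocol,
    randomize_start,
    run_batch,
)
from incdock.structio import ComplexStructure
from incdock.torsion import Pose, apply_conformation


class StubEngine:
    """Engine stub producing poses at a controlled distance and energy."""

    needs_grids = False

    def __init__(self, energy=-5.0, offset=10.0):
        self.energy = energy
        self.offset = offset

    def dock(self, grids, ligand, tree, fragment, config, seed,
             init_poses=None, fragment_round=0, job_id=0):
        pose = Pose.identity(tree.n_dofs)
        pose.translation = np.array([self.offset, 0.0, 0.0])
        coords = apply_conformation(tree, ligand.coords, pose)
        breakdown = EnergyBreakdown(self.energy, 0.0, 0.0, 0.0, 0.0)
        return [ScoredPose(pose=pose, energy=breakdown, coords=coords,
                           fragment_round=fragment_round, job_id=job_id)]


class PerfectStubEngine(StubEngine):
    """Returns the input conformation unchanged (a perfect reproduction)."""

    def __init__(self):
        super().__init__(energy=-10.0, offset=0.0)


class SeedEnergyEngine(StubEngine):
    """Energy depends on the seed so batch argmin can be checked."""

    def __init__(self, energies):
        super().__init__()
        self.energies = energies

    def dock(self, grids, ligand, tree, fragment, config, seed,
             init_poses=None, fragment_round=0, job_id=0):
        poses = super().dock(grids, ligand, tree, fragment, config, seed,
                             init_poses, fragment_round, job_id)
        poses[0].energy = EnergyBreakdown(
            self.energies[job_id % len(self.energies)], 0, 0, 0, 0
        )
        return poses


@pytest.fixture(scope="module")
def small_instance():
    return fixtures.make_redock_instance("AGA", seed=1, screen=False)


def _fast_protocol():
    ga = GAConfig(n_runs=1, population=25, max_evals=1200,
                  max_generations=10**6)
    return Protocol(ga=ga, grid_spacing=0.6, box_margin=3.0,
                    final_polish_maxfev=300)


class TestRandomizeStart:
    def test_same_seed_identical(self, small_instance):
        inst = small_instance
        lig = inst.reference.ligand
        a = randomize_start(lig, inst.tree, inst.box, seed=5)
        b = randomize_start(lig, inst.tree, inst.box, seed=5)
        np.testing.assert_array_equal(a.translation, b.translation)
        np.testing.assert_array_equal(a.orientation, b.orientation)
        np.testing.assert_array_equal(a.torsions, b.torsions)

    def test_different_seeds_differ_everywhere(self, small_instance):
        inst = small_instance
        lig = inst.reference.ligand
        a = randomize_start(lig, inst.tree, inst.box, seed=5)
        b = randomize_start(lig, inst.tree, inst.box, seed=6)
        assert np.max(np.abs(a.translation - b.translation)) > 1e-6
        assert np.max(np.abs(a.orientation - b.orientation)) > 1e-6
        assert np.max(np.abs(a.torsions - b.torsions)) > 1e-6

    def test_translation_uniform_per_axis(self, small_instance):
        inst = small_instance
        lig = inst.reference.ligand
        ref = lig.coords
        root_idx = sorted(inst.tree.index_of[s] for s in inst.tree.root_group)
        centroid = ref[root_idx].mean(axis=0)
        lo, hi = inst.box.origin, inst.box.upper
        samples = np.array([
            randomize_start(lig, inst.tree, inst.box, seed=s).translation
            + centroid
            for s in range(1000)
        ])
        for axis in range(3):
            scaled = (samples[:, axis] - lo[axis]) / (hi[axis] - lo[axis])
            assert kstest(scaled, "uniform").pvalue > 0.01

    def test_randomized_start_far_from_reference(self, small_instance):
        inst = small_instance
        lig = inst.reference.ligand
        pose = randomize_start(lig, inst.tree, inst.box, seed=11)
        coords = apply_conformation(inst.tree, lig.coords, pose)
        rmsd = float(np.sqrt(np.mean(np.sum((coords - lig.coords) ** 2, axis=1))))
        assert rmsd > 2.0


class TestIncrementalDock:
    def test_stub_engine_counts_rounds(self, small_instance):
        import math

        inst = small_instance
        result = incremental_dock(
            inst.receptor, inst.reference.ligand, _fast_protocol(), seed=0,
            box=inst.box, engine=StubEngine(),
        )
        d = inst.tree.n_dofs
        expected = 1 + max(0, math.ceil(max(0, d - 6) / 3))
        assert result.rounds_executed == expected

    def test_determinism(self, small_instance):
        inst = small_instance
        protocol = _fast_protocol()
        a = incremental_dock(inst.receptor, inst.reference.ligand, protocol, seed=3,
                     box=inst.box)
        b = incremental_dock(inst.receptor, inst.reference.ligand, protocol, seed=3,
                     box=inst.box)
        assert a.best.energy.total == b.best.energy.total
        np.testing.assert_array_equal(a.best.coords, b.best.coords)

    def test_best_is_lowest_energy(self, small_instance):
        inst = small_instance
        result = incremental_dock(inst.receptor, inst.reference.ligand,
                          _fast_protocol(), seed=1, box=inst.box)
        energies = [sp.energy.total for sp in result.all_final]
        assert result.best.energy.total == min(energies)

    def test_best_pose_covers_all_atoms_with_intact_geometry(self, small_instance):
        inst = small_instance
        lig = inst.reference.ligand
        result = incremental_dock(inst.receptor, lig, _fast_protocol(), seed=1,
                          box=inst.box)
        assert result.best.coords.shape == (len(lig.atoms), 3)
        index = {a.serial: i for i, a in enumerate(lig.atoms)}
        for bond in lig.bonds:
            x, y = tuple(bond)
            ref_len = np.linalg.norm(
                lig.coords[index[x]] - lig.coords[index[y]]
            )
            new_len = np.linalg.norm(
                result.best.coords[index[x]] - result.best.coords[index[y]]
            )
            assert new_len == pytest.approx(ref_len, abs=1e-3)


class TestRunBatch:
    def test_single_job_batch(self, small_instance):
        inst = small_instance
        results, best = run_batch(
            inst.receptor, inst.reference.ligand, _fast_protocol(),
            n_jobs=1, base_seed=0, engine=StubEngine(), box=inst.box,
        )
        assert len(results) == 1
        assert best is results[0]

    def test_argmin_selection(self, small_instance):
        inst = small_instance
        engine = SeedEnergyEngine([-5.0, -7.0, -6.0])
        results, best = run_batch(
            inst.receptor, inst.reference.ligand, _fast_protocol(),
            n_jobs=3, base_seed=0, engine=engine, box=inst.box,
        )
        assert best.best.energy.total == -7.0

    def test_job_order_independent(self, small_instance):
        inst = small_instance
        protocol = _fast_protocol()
        results, best = run_batch(
            inst.receptor, inst.reference.ligand, protocol,
            n_jobs=3, base_seed=0, box=inst.box,
        )
        singles = [
            incremental_dock(inst.receptor, inst.reference.ligand, protocol,
                     seed=s, box=inst.box, job_id=s)
            for s in (2, 0, 1)
        ]
        assert sorted(r.best.energy.total for r in results) == sorted(
            r.best.energy.total for r in singles
        )

    def test_serial_matches_parallel(self, small_instance):
        inst = small_instance
        protocol = _fast_protocol()
        serial, best_serial = run_batch(
            inst.receptor, inst.reference.ligand, protocol, n_jobs=2,
            base_seed=0, box=inst.box, parallel=False,
        )
        parallel, best_parallel = run_batch(
            inst.receptor, inst.reference.ligand, protocol, n_jobs=2,
            base_seed=0, box=inst.box, parallel=True,
        )
        assert [r.best.energy.total for r in serial] == [
            r.best.energy.total for r in parallel
        ]
        np.testing.assert_array_equal(
            best_serial.best.coords, best_parallel.best.coords
        )

    def test_invalid_job_count(self, small_instance):
        inst = small_instance
        with pytest.raises(ValueError):
            run_batch(inst.receptor, inst.reference.ligand,
                      _fast_protocol(), n_jobs=0)


class TestEscalate:
    def test_always_failing_engine_exhausts_100_jobs(self, small_instance):
        inst = small_instance
        outcome = escalate(
            inst.receptor, inst.reference.ligand, inst.reference,
            protocols=default_protocols(), n_jobs=20, base_seed=0,
            engine=StubEngine(offset=15.0), box=inst.box,
        )
        assert not outcome.success
        assert outcome.jobs_executed == 100
        assert len(outcome.protocols_tried) == 5

    def test_immediate_success_stops_after_first_batch(self, small_instance):
        inst = small_instance
        outcome = escalate(
            inst.receptor, inst.reference.ligand, inst.reference,
            protocols=default_protocols(), n_jobs=20, base_seed=0,
            engine=PerfectStubEngine(), box=inst.box,
        )
        assert outcome.success
        assert outcome.jobs_executed == 20
        assert outcome.rmsd_vs_reference == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_exactly_two_is_not_success(self, small_instance):
        inst = small_instance
        # a uniform 2.0 A shift gives an all-atom RMSD of exactly 2.0
        outcome = escalate(
            inst.receptor, inst.reference.ligand, inst.reference,
            protocols=default_protocols()[:1], n_jobs=2, base_seed=0,
            engine=StubEngine(offset=2.0), box=inst.box,
        )
        assert outcome.rmsd_vs_reference == pytest.approx(2.0, abs=1e-9)
        assert not outcome.success

    def test_missing_reference_rejected(self, small_instance):
        inst = small_instance
        with pytest.raises(ValueError):
            escalate(inst.receptor, inst.reference.ligand, None)


class TestProtocols:
    def test_default_ladder_has_five(self):
        protocols = default_protocols()
        assert len(protocols) == 5
        assert protocols[1].root_heuristic == "random"
        assert protocols[3].top_k == 20
        assert protocols[4].ga.n_runs == 2 * protocols[0].ga.n_runs

    def test_paper_ga_defaults(self):
        ga = GAConfig()
        assert ga.n_runs == 50
        assert ga.population == 150
        assert ga.max_evals == 250_000
        assert ga.max_generations == 27_000
        assert ga.elitism == 1
        assert ga.mutation_rate == 0.02
        assert ga.crossover_rate == 0.8

    def test_yaml_round_trip(self, tmp_path):
        text = """
name: custom
root_heuristic: random
window_size: 5
advance: 2
top_k: 7
ga:
  n_runs: 3
  population: 40
  max_evals: 5000
"""
        path = tmp_path / "protocol.yaml"
        path.write_text(text)
        protocol = load_protocol(str(path))
        assert protocol.name == "custom"
        assert protocol.window_size == 5
        assert protocol.ga.population == 40

    def test_invalid_top_k_rejected(self):
        with pytest.raises(ValueError):
            Protocol(top_k=0)
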