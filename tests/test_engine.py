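"""Grid construction, scoring oracle checks, and the GA sampler."""

import math

import numpy as np
import pytest

from incdock import fixtures, params
from incdock.engine import (
    BindingBox,
    ConfigError,
    GAConfig,
    LigandScorer,
    ReferenceEngine,
    build_grids,
    load_grids,
    random_pose,
    run_ga,
    save_grids,
    score_pose,
)
from incdock.structio import Atom, TypedMolecule
from incdock.torsion import Pose, apply_conformation, detect_rotatable_bonds


def _probe_receptor():
    """A handful of typed pocket atoms with charges."""
    spec = [
        ("C", params.CARBON_ALIPHATIC, 0.0, (0.0, 0.0, 0.0)),
        ("O", params.OXYGEN_ACCEPTOR, -0.35, (3.0, 0.0, 0.0)),
        ("N", params.NITROGEN_DONOR_H, -0.35, (0.0, 3.0, 0.0)),
        ("C", params.CARBON_ALIPHATIC, 0.0, (0.0, 0.0, 3.0)),
    ]
    atoms = [
        Atom(serial=10_000 + i, name=el, element=el, residue_name="GRV",
             residue_seq=i + 1, chain_id="R", position=np.array(pos),
             partial_charge=q, atom_class=klass)
        for i, (el, klass, q, pos) in enumerate(spec)
    ]
    return TypedMolecule(atoms=atoms, bonds=set(), role="receptor")


def _direct_sum(point, receptor, probe_class, cutoff=params.NB_CUTOFF):
    """Independent pairwise re-derivation of one affinity grid value."""
    vdw = hb = 0.0
    for atom in receptor.atoms:
        r = float(np.linalg.norm(np.asarray(point) - atom.position))
        if r >= cutoff:
            continue
        r = max(r, 0.01)
        r_eq, eps, is_hb = params.effective_pair_params(
            probe_class, atom.atom_class
        )
        r_s = r + min(max(r_eq - r, -params.SMOOTH_HALF), params.SMOOTH_HALF)
        x = r_eq / r_s
        if is_hb:
            e = eps * (5.0 * x**12 - 6.0 * x**10)
        else:
            e = eps * (x**12 - 2.0 * x**6)
        e = min(e, params.ENERGY_CLAMP)
        if is_hb:
            hb += e
        else:
            vdw += e
    return vdw, hb


class TestBuildGrids:
    box = BindingBox(center=(1.0, 1.0, 1.0), dimensions=(8.0, 8.0, 8.0),
                     spacing=0.5)

    def test_affinity_matches_direct_sum_at_grid_points(self):
        receptor = _probe_receptor()
        grids = build_grids(receptor, self.box)
        axes = self.box.axes()
        rng = np.random.default_rng(0)
        for _ in range(25):
            i, j, k = (int(rng.integers(n)) for n in self.box.shape)
            point = (axes[0][i], axes[1][j], axes[2][k])
            for probe in (params.CARBON_ALIPHATIC, params.POLAR_HYDROGEN,
                          params.OXYGEN_ACCEPTOR):
                vdw, hb = _direct_sum(point, receptor, probe)
                assert grids.vdw[probe][i, j, k] == pytest.approx(vdw, abs=1e-9)
                assert grids.hbond[probe][i, j, k] == pytest.approx(hb, abs=1e-9)

    def test_far_probe_is_nearly_zero(self):
        receptor = _probe_receptor()
        box = BindingBox(center=(20.0, 0.0, 0.0), dimensions=(4.0, 4.0, 4.0),
                         spacing=0.5)
        grids = build_grids(receptor, box)
        # every point of this box is at least 9 A from every receptor atom
        assert np.max(np.abs(grids.vdw[params.CARBON_ALIPHATIC])) < 1e-6

    def test_clash_point_strongly_positive(self):
        receptor = _probe_receptor()
        grids = build_grids(receptor, self.box)
        # grid node exactly on the first receptor atom
        i = int(round((0.0 - self.box.origin[0]) / self.box.spacing))
        assert grids.vdw[params.CARBON_ALIPHATIC][i, i, i] > 1000.0

    def test_interpolation_error_shrinks_with_spacing(self):
        receptor = _probe_receptor()
        probe_atoms = [Atom(
            serial=1, name="C", element="C", residue_name="ALA",
            residue_seq=1, chain_id="P", position=np.zeros(3),
            partial_charge=0.0, atom_class=params.CARBON_ALIPHATIC,
        )]
        ligand = TypedMolecule(atoms=probe_atoms, bonds=set())
        rng = np.random.default_rng(3)
        points = rng.uniform(1.5, 2.5, size=(40, 3))
        errors = []
        for spacing in (0.75, 0.5, 0.375):
            box = BindingBox(center=(1.0, 1.0, 1.0),
                             dimensions=(8.0, 8.0, 8.0), spacing=spacing)
            grids = build_grids(receptor, box)
            scorer = LigandScorer(grids, ligand)
            err = 0.0
            for p in points:
                vdw, hb = _direct_sum(p, receptor, params.CARBON_ALIPHATIC)
                err += abs(scorer.energy(p[None, :]).vdw - vdw)
            errors.append(err / len(points))
        assert errors[0] > errors[1] > errors[2]

    def test_untyped_receptor_rejected(self):
        receptor = _probe_receptor()
        for a in receptor.atoms:
            a.atom_class = None
        with pytest.raises(ConfigError):
            build_grids(receptor, self.box)

    def test_grid_round_trip_via_npz(self, tmp_path):
        receptor = _probe_receptor()
        grids = build_grids(
            receptor, self.box, classes=(params.CARBON_ALIPHATIC,)
        )
        path = tmp_path / "maps.npz"
        save_grids(grids, path)
        loaded = load_grids(path)
        np.testing.assert_array_equal(
            loaded.vdw[params.CARBON_ALIPHATIC],
            grids.vdw[params.CARBON_ALIPHATIC],
        )
        assert loaded.box.spacing == grids.box.spacing


class TestScorePose:
    def test_zero_charges_zero_electrostatics(self, toy_instance):
        ligand = toy_instance.reference.ligand.copy()
        for a in ligand.atoms:
            a.partial_charge = 0.0
        receptor = toy_instance.receptor
        box = toy_instance.box
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(receptor, box, classes=classes)
        breakdown = score_pose(grids, ligand, ligand.coords)
        assert breakdown.electrostatic == pytest.approx(0.0, abs=1e-12)

    def test_pair_at_equilibrium_separation(self):
        """Two neutral atoms >3 bonds apart at r_eq score -eps_eff."""
        r_eq, eps, _ = params.effective_pair_params(
            params.CARBON_ALIPHATIC, params.CARBON_ALIPHATIC
        )
        chain = []
        # atoms 1 and 5 are four bonds apart and exactly r_eq apart in
        # space; every other pair is within three bonds (not scored)
        positions = [
            (0.0, 0.0, 0.0), (9.0, 0.0, 0.0), (18.0, 0.0, 0.0),
            (9.0, 9.0, 0.0), (0.0, r_eq, 0.0),
        ]
        for i, pos in enumerate(positions):
            chain.append(Atom(
                serial=i + 1, name="C", element="C", residue_name="ALA",
                residue_seq=1, chain_id="P", position=np.array(pos),
                partial_charge=0.0, atom_class=params.CARBON_ALIPHATIC,
            ))
        mol = TypedMolecule(
            atoms=chain,
            bonds={frozenset({i, i + 1}) for i in range(1, 5)},
        )
        # receptor far outside the cutoff: only the intramolecular path
        # contributes inside the box
        box = BindingBox(center=(60.0, 60.0, 60.0),
                         dimensions=(30.0, 30.0, 30.0), spacing=0.75)
        grids = build_grids(_probe_receptor(), box,
                            classes=(params.CARBON_ALIPHATIC,))
        coords = mol.coords + 55.0
        mol.set_coords(coords)
        breakdown = score_pose(grids, mol, coords)
        # exactly one pair (atom 1, atom 5) is > 3 bonds apart at r_eq;
        # solvation-weighted desolvation is the only other nonzero term
        assert breakdown.vdw == pytest.approx(-eps, abs=1e-6)

    def test_pose_outside_box_heavily_penalized(self, toy_instance):
        ligand = toy_instance.reference.ligand
        receptor = toy_instance.receptor
        box = toy_instance.box
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(receptor, box, classes=classes)
        inside = score_pose(grids, ligand, ligand.coords).total
        outside = score_pose(
            grids, ligand, ligand.coords + np.array([200.0, 0.0, 0.0])
        ).total
        assert outside > inside + 1000.0

    def test_breakdown_total_is_component_sum(self, toy_instance):
        ligand = toy_instance.reference.ligand
        receptor = toy_instance.receptor
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(receptor, toy_instance.box, classes=classes)
        b = score_pose(grids, ligand, ligand.coords, n_active_dofs=4)
        assert b.total == pytest.approx(
            b.vdw + b.hbond + b.electrostatic + b.desolvation
            + b.torsional_penalty, abs=1e-9,
        )
        assert b.torsional_penalty == pytest.approx(4 * params.W_TORSION)

    def test_fast_total_matches_breakdown(self, toy_instance, rng):
        ligand = toy_instance.reference.ligand
        tree = toy_instance.tree
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(toy_instance.receptor, toy_instance.box,
                            classes=classes)
        scorer = LigandScorer(grids, ligand, None, tree.n_dofs)
        ref = ligand.coords
        root_idx = sorted(tree.index_of[s] for s in tree.root_group)
        centroid = ref[root_idx].mean(axis=0)
        for _ in range(20):
            pose = random_pose(rng, toy_instance.box, tree.n_dofs, centroid)
            coords = apply_conformation(tree, ref, pose)
            assert scorer.total(coords) == pytest.approx(
                scorer.energy(coords).total, rel=1e-12, abs=1e-9
            )


class TestGAConfig:
    def test_invalid_population_rejected(self):
        with pytest.raises(ConfigError):
            GAConfig(population=0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            GAConfig(mutation_rate=1.5)

    def test_budget_scaling(self):
        base = GAConfig(n_runs=50, max_evals=250_000)
        reduced = base.scaled(0.1)
        assert reduced.n_runs == 5
        assert reduced.max_evals == 25_000


class TestRunGA:
    def _setup(self, toy_instance):
        ligand = toy_instance.reference.ligand
        tree = toy_instance.tree
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(toy_instance.receptor, toy_instance.box,
                            classes=classes)
        return ligand, tree, grids

    def test_identical_seed_bit_identical_output(self, toy_instance):
        ligand, tree, grids = self._setup(toy_instance)
        config = GAConfig(n_runs=2, population=30, max_evals=2000,
                          max_generations=10**6, seed=7)
        first = run_ga(grids, ligand, tree, config)
        second = run_ga(grids, ligand, tree, config)
        assert [sp.energy.total for sp in first] == [
            sp.energy.total for sp in second
        ]
        np.testing.assert_array_equal(first[0].coords, second[0].coords)

    def test_ranked_by_energy(self, toy_instance):
        ligand, tree, grids = self._setup(toy_instance)
        config = GAConfig(n_runs=2, population=30, max_evals=2000,
                          max_generations=10**6, seed=3)
        poses = run_ga(grids, ligand, tree, config)
        energies = [sp.energy.total for sp in poses]
        assert energies == sorted(energies)

    def test_search_beats_random_sampling(self, toy_instance, rng):
        ligand, tree, grids = self._setup(toy_instance)
        config = GAConfig(n_runs=1, population=40, max_evals=4000,
                          max_generations=10**6, seed=1)
        best = run_ga(grids, ligand, tree, config)[0].energy.total
        scorer = LigandScorer(grids, ligand, None, tree.n_dofs)
        ref = ligand.coords
        root_idx = sorted(tree.index_of[s] for s in tree.root_group)
        centroid = ref[root_idx].mean(axis=0)
        random_best = min(
            scorer.total(apply_conformation(
                tree, ref, random_pose(rng, toy_instance.box, tree.n_dofs,
                                       centroid)
            ))
            for _ in range(400)
        )
        assert best < random_best

    def test_reference_pose_in_funnel(self, toy_instance, rng):
        """The planted pose scores below 95% of random poses."""
        ligand, tree, grids = self._setup(toy_instance)
        scorer = LigandScorer(grids, ligand, None, 0)
        ref = ligand.coords
        planted = scorer.total(ref)
        root_idx = sorted(tree.index_of[s] for s in tree.root_group)
        centroid = ref[root_idx].mean(axis=0)
        randoms = np.array([
            scorer.total(apply_conformation(
                tree, ref, random_pose(rng, toy_instance.box, tree.n_dofs,
                                       centroid)
            ))
            for _ in range(1000)
        ])
        assert planted <= np.percentile(randoms, 5.0)
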