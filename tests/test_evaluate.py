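"""Superposition and the RMSD/LRMSD metric family."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from incdock import fixtures
from incdock.evaluate import (
    AlignmentError,
    BatchSummary,
    EvaluationReport,
    PairingError,
    evaluate_prediction,
    kabsch_superpose,
    lrmsd,
    rmsd_receptor_aligned,
    sequence_identity,
    summarize,
)
from incdock.structio import ComplexStructure


def _random_rigid(rng):
    rot = Rotation.from_rotvec(rng.normal(size=3))
    trans = rng.normal(0, 5, 3)
    return rot, trans


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(8, 3))
        rot, trans, value = kabsch_superpose(pts, pts)
        assert value == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot.as_matrix(), np.eye(3), atol=1e-9)

    def test_rigid_copy_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans = _random_rigid(rng)
        moved = rot.apply(pts) + trans
        _, _, value = kabsch_superpose(pts, moved)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_returned(self, rng):
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rot.as_matrix()) == pytest.approx(1.0)

    def test_matches_rotation_grid_oracle(self, rng):
        """Brute-force search over rotation space agrees within 1e-3 A."""
        mobile = rng.normal(size=(5, 3))
        target = mobile + rng.normal(0, 0.4, size=(5, 3))
        _, _, kabsch_value = kabsch_superpose(mobile, target)

        # independent oracle: dense Euler-angle grid + local refinement
        mc = mobile - mobile.mean(axis=0)
        tc = target - target.mean(axis=0)

        def rmsd_for(angles):
            rot = Rotation.from_euler("zyx", angles)
            return float(np.sqrt(np.mean(np.sum(
                (rot.apply(mc) - tc) ** 2, axis=1
            ))))

        grid = np.deg2rad(np.arange(-180.0, 180.0, 10.0))
        best = min(
            ((a, b, c) for a in grid for b in grid[:len(grid) // 2] for c in grid),
            key=rmsd_for,
        )
        from scipy.optimize import minimize

        refined = minimize(rmsd_for, best, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
        assert kabsch_value == pytest.approx(refined.fun, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(AlignmentError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(AlignmentError):
            kabsch_superpose(line, line)


@pytest.fixture(scope="module")
def complex_pair():
    """Reference complex plus an identical predicted copy to perturb."""
    instance = fixtures.make_redock_instance("AGA", seed=1, screen=False)
    reference = instance.reference
    predicted = ComplexStructure(
        receptor=reference.receptor.copy(),
        ligand=reference.ligand.copy(),
    )
    return predicted, reference


class TestRmsdFamily:
    def test_identical_prediction_scores_zero(self, complex_pair):
        predicted, reference = complex_pair
        report = evaluate_prediction(predicted, reference)
        for value in (report.all_atom_rmsd, report.ca_rmsd,
                      report.all_atom_lrmsd, report.ca_lrmsd):
            assert value == pytest.approx(0.0, abs=1e-6)
        assert report.success

    def test_uniform_shift_gives_exact_distance(self, complex_pair):
        predicted, reference = complex_pair
        moved = predicted.ligand.copy()
        moved.set_coords(moved.coords + np.array([0.6, 0.8, 0.0]))
        shifted = ComplexStructure(predicted.receptor, moved)
        assert rmsd_receptor_aligned(shifted, reference) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_lrmsd_ignores_rigid_placement(self, complex_pair, rng):
        predicted, reference = complex_pair
        rot, trans = _random_rigid(rng)
        moved = predicted.ligand.copy()
        moved.set_coords(rot.apply(moved.coords) + trans)
        assert lrmsd(moved, reference.ligand) == pytest.approx(0.0, abs=1e-6)
        assert rmsd_receptor_aligned(
            ComplexStructure(predicted.receptor, moved), reference
        ) > 1.0

    def test_hand_computed_rmsd(self, complex_pair, rng):
        predicted, reference = complex_pair
        moved = predicted.ligand.copy()
        displacement = rng.normal(0, 0.5, moved.coords.shape)
        moved.set_coords(moved.coords + displacement)
        shifted = ComplexStructure(predicted.receptor, moved)
        heavy = np.array(
            [a.element != "H" for a in reference.ligand.atoms]
        )
        expected = np.sqrt(np.mean(np.sum(
            displacement[heavy] ** 2, axis=1
        )))
        assert rmsd_receptor_aligned(shifted, reference) == pytest.approx(
            expected, abs=1e-9
        )

    def test_symmetry(self, complex_pair, rng):
        predicted, reference = complex_pair
        moved = predicted.ligand.copy()
        moved.set_coords(moved.coords + rng.normal(0, 0.4, moved.coords.shape))
        a = lrmsd(moved, reference.ligand)
        b = lrmsd(reference.ligand, moved)
        assert a == pytest.approx(b, abs=1e-9)

    def test_lrmsd_never_exceeds_receptor_aligned(self, complex_pair, rng):
        predicted, reference = complex_pair
        for _ in range(200):
            moved = predicted.ligand.copy()
            rot, trans = _random_rigid(rng)
            noisy = rot.apply(moved.coords) + trans
            noisy = noisy + rng.normal(0, 0.3, noisy.shape)
            moved.set_coords(noisy)
            value_l = lrmsd(moved, reference.ligand)
            value_r = rmsd_receptor_aligned(
                ComplexStructure(predicted.receptor, moved), reference
            )
            assert value_l <= value_r + 1e-9

    def test_metrics_invariant_under_global_rigid_motion(self, complex_pair, rng):
        predicted, reference = complex_pair
        moved_ligand = predicted.ligand.copy()
        moved_ligand.set_coords(
            moved_ligand.coords + rng.normal(0, 0.3, moved_ligand.coords.shape)
        )
        base = evaluate_prediction(
            ComplexStructure(predicted.receptor, moved_ligand), reference
        )
        rot, trans = _random_rigid(rng)
        receptor2 = predicted.receptor.copy()
        receptor2.set_coords(rot.apply(receptor2.coords) + trans)
        ligand2 = moved_ligand.copy()
        ligand2.set_coords(rot.apply(ligand2.coords) + trans)
        moved = evaluate_prediction(
            ComplexStructure(receptor2, ligand2), reference
        )
        assert moved.all_atom_rmsd == pytest.approx(base.all_atom_rmsd, abs=1e-6)
        assert moved.all_atom_lrmsd == pytest.approx(base.all_atom_lrmsd, abs=1e-6)

    def test_pairing_error_lists_missing_atoms(self, complex_pair):
        predicted, reference = complex_pair
        truncated = predicted.ligand.copy()
        heavy = [a for a in truncated.atoms if a.element != "H"]
        truncated.atoms = [a for a in truncated.atoms if a is not heavy[-1]]
        with pytest.raises(PairingError):
            rmsd_receptor_aligned(
                ComplexStructure(predicted.receptor, truncated), reference
            )


class TestSummarize:
    def _report(self, value):
        return EvaluationReport(value, value, value, value)

    def test_single_report(self):
        summary = summarize([self._report(1.5)])
        assert summary.mean["all_atom_rmsd"] == pytest.approx(1.5)
        assert summary.sd["all_atom_rmsd"] == 0.0

    def test_hand_arithmetic(self):
        reports = [self._report(v) for v in (1.0, 2.0, 3.0)]
        summary = summarize(reports, thresholds=(2.2, 2.5))
        assert summary.mean["all_atom_rmsd"] == pytest.approx(2.0)
        assert summary.sd["all_atom_rmsd"] == pytest.approx(1.0)
        assert summary.fraction_below[2.2] == pytest.approx(2 / 3)
        assert summary.fraction_below[2.5] == pytest.approx(2 / 3)
        assert summary.max["all_atom_rmsd"] == pytest.approx(3.0)

    def test_fractions_monotone_in_threshold(self):
        reports = [self._report(v) for v in (0.5, 1.4, 2.1, 2.4, 3.0)]
        summary = summarize(reports, thresholds=(2.0, 2.2, 2.5))
        values = [summary.fraction_below[t] for t in (2.0, 2.2, 2.5)]
        assert values == sorted(values)

    def test_perfectly_linear_covariate(self):
        reports = [self._report(v) for v in (1.0, 2.0, 3.0, 4.0)]
        summary = summarize(
            reports,
            covariates={"length": [8.0, 9.0, 10.0, 11.0]},
            correlations=[("all_atom_rmsd", "length")],
        )
        assert summary.pearson_r[("all_atom_rmsd", "length")] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_single_report_correlation_flagged_not_crashed(self):
        summary = summarize(
            [self._report(1.0)],
            covariates={"length": [9.0]},
            correlations=[("all_atom_rmsd", "length")],
        )
        assert np.isnan(summary.pearson_r[("all_atom_rmsd", "length")])

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestSequenceIdentity:
    @pytest.mark.parametrize("a, b, expected", [
        ("EVDPIGHLY", "ESDPIVAQY", 55),
        ("EVDPIGHLY", "EVDPIGHLY", 100),
        ("AAAA", "GGGG", 0),
    ])
    def test_identity_values(self, a, b, expected):
        assert sequence_identity(a, b) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("AAA", "AAAA")
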