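"""Superposition, the RMSD/LRMSD metric family, and batch summaries.

Two families of goodness-of-fit metrics are computed between a predicted
and a reference peptide-receptor complex. Receptor-aligned RMSDs superpose
the two receptors on their shared alpha carbons and measure the deviation
of the predicted peptide in the receptor frame, capturing both
conformational error and placement error in the cleft. LRMSDs superpose
the two peptide copies themselves and measure pure conformational
difference, irrespective of placement. Both come in all-heavy-atom and
alpha-carbon flavours; hydrogens are always excluded (crystal references
carry none, so this is the only correspondence-safe choice). A prediction
counts as a success when its receptor-aligned all-atom RMSD is strictly
below 2 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .structio import ComplexStructure, TypedMolecule

SUCCESS_RMSD = 2.0  # A, strict upper bound


class AlignmentError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class EvaluationReport:
    all_atom_rmsd: float
    ca_rmsd: float
    all_atom_lrmsd: float
    ca_lrmsd: float

    @property
    def success(self) -> bool:
        return self.all_atom_rmsd < SUCCESS_RMSD

    def as_dict(self) -> dict:
        return {
            "all_atom_rmsd": self.all_atom_rmsd,
            "ca_rmsd": self.ca_rmsd,
            "all_atom_lrmsd": self.all_atom_lrmsd,
            "ca_lrmsd": self.ca_lrmsd,
            "success": self.success,
        }


@dataclass
class BatchSummary:
    mean: dict[str, float]
    sd: dict[str, float]
    max: dict[str, float]
    fraction_below: dict[float, float]
    pearson_r: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None
) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation.apply(mobile) + translation`` best fits ``target`` with a
    proper rotation (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise AlignmentError("point sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise AlignmentError("superposition needs >= 3 points")
    if np.linalg.matrix_rank(mobile - mobile.mean(axis=0)) < 2:
        raise AlignmentError("degenerate (collinear) point configuration")
    rot, rssd = Rotation.align_vectors(
        target - target.mean(axis=0),
        mobile - mobile.mean(axis=0),
        weights=weights,
    )
    translation = target.mean(axis=0) - rot.apply(mobile.mean(axis=0))
    return rot, translation, float(rssd / np.sqrt(n))


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _matched_coords(
    predicted: TypedMolecule, reference: TypedMolecule, atom_set: str
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates paired by (residue_seq, atom name); heavy atoms only."""
    def table(mol: TypedMolecule) -> dict:
        out = {}
        for a in mol.atoms:
            if a.element == "H":
                continue
            if atom_set == "calpha" and a.name.strip() != "CA":
                continue
            out[(a.residue_seq, a.name.strip())] = a.position
        return out

    pt, rt = table(predicted), table(reference)
    shared = sorted(set(pt) & set(rt))
    missing = sorted(set(rt) - set(pt))
    if atom_set == "calpha" and not shared:
        return np.empty((0, 3)), np.empty((0, 3))
    if not shared or (atom_set == "all_heavy" and missing):
        raise PairingError(
            f"atom correspondence mismatch; unmatched reference atoms: {missing}"
        )
    return (
        np.array([pt[k] for k in shared]),
        np.array([rt[k] for k in shared]),
    )


def rmsd_receptor_aligned(
    predicted: ComplexStructure,
    reference: ComplexStructure,
    atom_set: str = "all_heavy",
) -> float:
    """Peptide RMSD after superposing the receptors on shared alpha carbons.

    Receptors without alpha carbons (synthetic pockets) are superposed on
    all shared heavy atoms instead.
    """
    mob, tgt = _matched_coords(predicted.receptor, reference.receptor, "calpha")
    if len(mob) < 3:
        mob, tgt = _matched_coords(
            predicted.receptor, reference.receptor, "all_heavy"
        )
    if len(mob) >= 3 and np.max(np.abs(mob - tgt)) > 1e-12:
        rot, trans, _ = kabsch_superpose(mob, tgt)
    else:  # identical receptors: nothing to fit
        rot, trans = Rotation.identity(), np.zeros(3)
    lig_p, lig_r = _matched_coords(predicted.ligand, reference.ligand, atom_set)
    return _rmsd(rot.apply(lig_p) + trans, lig_r)


def lrmsd(
    predicted_ligand: TypedMolecule,
    reference_ligand: TypedMolecule,
    atom_set: str = "all_heavy",
) -> float:
    """Least RMSD: peptide-on-peptide superposition, placement ignored."""
    mob, tgt = _matched_coords(predicted_ligand, reference_ligand, atom_set)
    _, _, value = kabsch_superpose(mob, tgt)
    return value


def evaluate_prediction(
    predicted: ComplexStructure, reference: ComplexStructure
) -> EvaluationReport:
    """The full metric family for one predicted complex."""
    return EvaluationReport(
        all_atom_rmsd=rmsd_receptor_aligned(predicted, reference, "all_heavy"),
        ca_rmsd=rmsd_receptor_aligned(predicted, reference, "calpha"),
        all_atom_lrmsd=lrmsd(predicted.ligand, reference.ligand, "all_heavy"),
        ca_lrmsd=lrmsd(predicted.ligand, reference.ligand, "calpha"),
    )


# ---------------------------------------------------------------------------
# Batch statistics
# ---------------------------------------------------------------------------

METRICS = ("all_atom_rmsd", "ca_rmsd", "all_atom_lrmsd", "ca_lrmsd")


def summarize(
    reports: list[EvaluationReport],
    covariates: dict[str, list[float]] | None = None,
    thresholds: tuple[float, ...] = (2.0, 2.2, 2.5),
    correlations: list[tuple[str, str]] | None = None,
) -> BatchSummary:
    """Mean/SD/max, threshold fractions, and requested Pearson correlations.

    ``covariates`` maps names (e.g. peptide length, DoF count) to
    per-complex values; ``correlations`` lists (metric, covariate) pairs.
    A correlation requested on fewer than two reports is returned as NaN.
    """
    if not reports:
        raise ValueError("summarize needs at least one report")
    values = {
        m: np.array([getattr(r, m) for r in reports]) for m in METRICS
    }
    all_atom = values["all_atom_rmsd"]
    summary = BatchSummary(
        mean={m: float(v.mean()) for m, v in values.items()},
        sd={
            m: float(v.std(ddof=1)) if len(v) > 1 else 0.0
            for m, v in values.items()
        },
        max={m: float(v.max()) for m, v in values.items()},
        fraction_below={
            t: float(np.mean(all_atom < t)) for t in thresholds
        },
    )
    for metric, cov in correlations or []:
        series = values[metric] if metric in values else np.array(
            covariates[metric]
        )
        cov_values = np.array(covariates[cov])
        if len(series) < 2 or np.std(series) == 0 or np.std(cov_values) == 0:
            summary.pearson_r[(metric, cov)] = float("nan")
        else:
            summary.pearson_r[(metric, cov)] = float(
                pearsonr(series, cov_values).statistic
            )
    return summary


def sequence_identity(seq_a: str, seq_b: str) -> int:
    """Ungapped position-wise identity, floored to an integer percent."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length (no alignment)")
    if not seq_a:
        raise ValueError("empty sequences")
    matches = sum(1 for a, b in zip(seq_a, seq_b) if a == b)
    return int(100 * matches // len(seq_a))
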