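"""The incremental meta-docking loop, batch execution and escalation.

One job grows the peptide over the fragment schedule: the initial fragment
is docked from a randomized start, the lowest-energy conformations
(``top_k``, default 10) are expanded by the next fragment and seed the
following round's GA, and the final round returns full-ligand poses ranked
by binding energy. A batch of independent jobs (default 20, each with its
own seed) is run per protocol; when re-docking against a known reference,
the escalation controller checks the best-of-batch against the reference
(receptor-aligned all-atom RMSD strictly below 2 A) and moves to the next
of five protocols on failure, so a full escalation is at most
``5 * 20 = 100`` jobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import evaluate, fragmenter, torsion
from .engine import (
    BindingBox,
    GAConfig,
    ReferenceEngine,
    ScoredPose,
    build_grids,
    random_pose,
)
from .structio import ComplexStructure, TypedMolecule
from .torsion import Pose


class BatchError(RuntimeError):
    pass


@dataclass
class Protocol:
    """One named bundle of meta-docking parameters."""

    name: str = "default"
    root_heuristic: str = "max_hbond"
    expansion_heuristic: str = "bfs"
    window_size: int = 6
    advance: int = 3
    top_k: int = 10
    ga: GAConfig = field(default_factory=GAConfig)
    grid_spacing: float = 0.375
    box_margin: float = 6.0
    #: Powell refinement of the top final poses (0 disables)
    final_polish_maxfev: int = 1200

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def default_protocols(base_ga: GAConfig | None = None) -> list[Protocol]:
    """The five-protocol escalation ladder.

    The ladder varies the axes the default decision tree exposes: root
    heuristic, window growth, expansion width and GA budget.
    """
    ga = base_ga or GAConfig()
    return [
        Protocol(name="p1-default", ga=ga),
        Protocol(name="p2-random-root", root_heuristic="random", ga=ga),
        Protocol(name="p3-slow-growth", advance=2, ga=ga),
        Protocol(name="p4-wide-expansion", top_k=2 * 10, ga=ga),
        Protocol(
            name="p5-double-budget",
            ga=replace(ga, n_runs=2 * ga.n_runs),
        ),
    ]


def load_protocol(text_or_path) -> Protocol:
    """Load a protocol from YAML (a path or a YAML string)."""
    try:
        with open(text_or_path) as fh:
            data = yaml.safe_load(fh)
    except (OSError, TypeError):
        data = yaml.safe_load(text_or_path)
    if not isinstance(data, dict):
        raise ValueError("protocol YAML must be a mapping")
    ga = GAConfig(**data.pop("ga", {}))
    return Protocol(ga=ga, **data)


@dataclass
class DockedResult:
    best: ScoredPose
    all_final: list[ScoredPose]
    rounds_executed: int
    protocol_used: str
    seed: int


@dataclass
class EscalationOutcome:
    success: bool
    jobs_executed: int
    protocols_tried: list[str]
    winning_result: DockedResult | None = None
    rmsd_vs_reference: float | None = None
    per_protocol_rmsd: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Randomized starts
# ---------------------------------------------------------------------------

def randomize_start(
    ligand: TypedMolecule,
    tree: torsion.TorsionTree,
    box: BindingBox,
    seed: int,
) -> Pose:
    """Systematically randomized input pose: uniform placement of the root
    group centroid in the box, uniform orientation, uniform torsions."""
    rng = np.random.default_rng(seed)
    ref = ligand.coords
    root_idx = sorted(tree.index_of[s] for s in tree.root_group)
    centroid = ref[root_idx].mean(axis=0)
    return random_pose(rng, box, tree.n_dofs, centroid)


# ---------------------------------------------------------------------------
# One job
# ---------------------------------------------------------------------------

def incremental_dock(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    protocol: Protocol,
    seed: int,
    box: BindingBox | None = None,
    engine=None,
    grids=None,
    job_id: int = 0,
) -> DockedResult:
    """Execute one incremental docking job.

    The fragment schedule is derived from the protocol; each round's GA is
    seeded with the previous round's ``top_k`` conformations. Identical
    (inputs, protocol, seed) give identical results.
    """
    engine = engine or ReferenceEngine()
    if box is None:
        box = BindingBox.around(
            ligand.coords, margin=protocol.box_margin,
            spacing=protocol.grid_spacing,
        )
    tree = torsion.detect_rotatable_bonds(ligand)
    root = fragmenter.select_root(
        tree, ligand, heuristic=protocol.root_heuristic, seed=seed,
        window_size=protocol.window_size,
    )
    tree = torsion.detect_rotatable_bonds(ligand, root=root)
    schedule = fragmenter.plan_rounds(
        tree,
        window_size=protocol.window_size,
        advance=protocol.advance,
        expansion_heuristic=protocol.expansion_heuristic,
        ligand=ligand,
    )
    if getattr(engine, "needs_grids", True) and grids is None:
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(receptor, box, classes=classes)

    seeds: list[Pose] | None = None
    fragment = schedule.rounds[0]
    poses: list[ScoredPose] = []
    for round_index in range(1, len(schedule.rounds) + 1):
        # the first round carries the global placement search: double budget
        ga = (
            replace(protocol.ga, max_evals=2 * protocol.ga.max_evals)
            if round_index == 1 and len(schedule.rounds) > 1
            else protocol.ga
        )
        try:
            poses = engine.dock(
                grids, ligand, tree, fragment, ga,
                seed=seed + 10_000 * round_index,
                init_poses=seeds, fragment_round=round_index, job_id=job_id,
            )
        except Exception as exc:  # annotate engine failures with the round
            raise BatchError(
                f"engine failed in round {round_index}: {exc}"
            ) from exc
        if grids is not None and protocol.final_polish_maxfev > 0:
            final = round_index == len(schedule.rounds)
            poses = _polish_top(
                poses, grids, ligand, tree, fragment,
                maxfev=protocol.final_polish_maxfev if final else 800,
                k_polish=5, job_id=job_id,
            )
        if round_index == len(schedule.rounds):
            break
        top = _diverse_top(poses, protocol.top_k)
        best_torsions = {
            k: float(top[0].pose.torsions[k])
            for k in schedule.rounds[round_index].frozen_dofs
        }
        fragment = fragmenter.expand_fragment(fragment, schedule, best_torsions)
        seeds = [sp.pose for sp in top]

    return DockedResult(
        best=poses[0],
        all_final=poses,
        rounds_executed=len(schedule.rounds),
        protocol_used=protocol.name,
        seed=seed,
    )


def _diverse_top(poses, k: int):
    """The ``k`` expansion seeds, preferring each GA run's own best.

    Independent runs converge to different basins; picking every run's
    best first keeps alternative placements alive through expansion
    instead of letting one run's population fill the whole top-k.
    """
    per_run: dict[int, ScoredPose] = {}
    for sp in poses:  # poses are ranked, first seen per run is its best
        if sp.run_id not in per_run:
            per_run[sp.run_id] = sp
    chosen = sorted(per_run.values(), key=lambda sp: sp.energy.total)[:k]
    seen = {id(sp) for sp in chosen}
    for sp in poses:
        if len(chosen) >= k:
            break
        if id(sp) not in seen:
            chosen.append(sp)
            seen.add(id(sp))
    return chosen


def _polish_top(
    poses, grids, ligand, tree, fragment, maxfev: int, k_polish: int,
    job_id: int,
):
    """Refine the top poses of a round to their basin bottoms and re-rank."""
    from .engine import LigandScorer, polish_pose
    from .torsion import apply_conformation

    scorer = LigandScorer(
        grids, ligand, fragment.atom_serials,
        n_active_dofs=len(fragment.active_dofs),
    )
    ref = ligand.coords
    k = min(k_polish, len(poses))
    refined = []
    for sp in poses[:k]:
        pose2, _ = polish_pose(scorer, tree, ref, sp.pose, maxfev)
        coords = apply_conformation(tree, ref, pose2)
        refined.append(ScoredPose(
            pose=pose2, energy=scorer.energy(coords), coords=coords,
            fragment_round=sp.fragment_round, job_id=job_id,
            run_id=sp.run_id,
        ))
    merged = refined + poses[k:]
    merged.sort(key=lambda sp: sp.energy.total)
    return merged


# ---------------------------------------------------------------------------
# Batches and escalation
# ---------------------------------------------------------------------------

def run_batch(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    protocol: Protocol,
    n_jobs: int = 20,
    base_seed: int = 0,
    reference: ComplexStructure | None = None,
    engine=None,
    parallel: bool = False,
    box: BindingBox | None = None,
    grids=None,
) -> tuple[list[DockedResult], DockedResult]:
    """Run ``n_jobs`` independent jobs (seeds ``base_seed + i``).

    Jobs share no mutable state; with ``parallel=True`` they are executed
    in worker processes with identical results. Individual job failures
    are tolerated unless every job fails. Returns (results, best-of-batch),
    the latter being the lowest-energy full-ligand pose across jobs.
    """
    if n_jobs < 1:
        raise ValueError("n_jobs must be >= 1")
    engine = engine or ReferenceEngine()
    if box is None:
        box = BindingBox.around(
            ligand.coords, margin=protocol.box_margin,
            spacing=protocol.grid_spacing,
        )
    if getattr(engine, "needs_grids", True) and grids is None:
        typed_receptor = receptor
        classes = tuple(sorted({a.atom_class for a in ligand.atoms}))
        grids = build_grids(typed_receptor, box, classes=classes)

    def one(i: int) -> DockedResult:
        return incremental_dock(
            receptor, ligand, protocol, seed=base_seed + i, box=box,
            engine=engine, grids=grids, job_id=i,
        )

    results: list[DockedResult] = []
    failures: list[Exception] = []
    if parallel:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=2, backend="loky")(
            delayed(one)(i) for i in range(n_jobs)
        )
        results = list(outcomes)
    else:
        for i in range(n_jobs):
            try:
                results.append(one(i))
            except Exception as exc:
                failures.append(exc)
    if not results:
        raise BatchError(f"all {n_jobs} jobs failed; first error: {failures[0]}")
    best = min(results, key=lambda r: r.best.energy.total)
    return results, best


def _predicted_complex(
    receptor: TypedMolecule, ligand: TypedMolecule, result: DockedResult
) -> ComplexStructure:
    predicted_ligand = ligand.copy()
    predicted_ligand.set_coords(result.best.coords)
    return ComplexStructure(receptor=receptor, ligand=predicted_ligand)


def escalate(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    reference: ComplexStructure,
    protocols: list[Protocol] | None = None,
    n_jobs: int = 20,
    base_seed: int = 0,
    engine=None,
    parallel: bool = False,
    box: BindingBox | None = None,
) -> EscalationOutcome:
    """Protocol escalation for re-docking experiments.

    Per protocol a batch of ``n_jobs`` jobs is run and the best-of-batch is
    compared to the reference; success is a receptor-aligned all-atom RMSD
    strictly below 2 A. All protocols exhausted without success means
    ``n_jobs * len(protocols)`` jobs were executed in vain.
    """
    if reference is None:
        raise ValueError("escalation requires a reference structure (re-docking only)")
    protocols = protocols if protocols is not None else default_protocols()
    if not protocols:
        raise ValueError("at least one protocol is required")

    tried: list[str] = []
    rmsds: list[float] = []
    jobs = 0
    for i, protocol in enumerate(protocols):
        _, best = run_batch(
            receptor, ligand, protocol, n_jobs=n_jobs,
            base_seed=base_seed + i * n_jobs, engine=engine,
            parallel=parallel, box=box,
        )
        jobs += n_jobs
        tried.append(protocol.name)
        predicted = _predicted_complex(receptor, ligand, best)
        rmsd = evaluate.rmsd_receptor_aligned(predicted, reference, "all_heavy")
        rmsds.append(rmsd)
        if rmsd < evaluate.SUCCESS_RMSD:
            return EscalationOutcome(
                success=True, jobs_executed=jobs, protocols_tried=tried,
                winning_result=best, rmsd_vs_reference=rmsd,
                per_protocol_rmsd=rmsds,
            )
    best_i = int(np.argmin(rmsds))
    return EscalationOutcome(
        success=False, jobs_executed=jobs, protocols_tried=tried,
        winning_result=None, rmsd_vs_reference=min(rmsds),
        per_protocol_rmsd=rmsds,
    )
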