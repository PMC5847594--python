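"""Reference docking engine: grid maps, semi-empirical scoring, Lamarckian GA.

The engine follows the AutoDock-4 design: interaction energies of the rigid
receptor are precomputed on a lattice over the binding box (one affinity
map per ligand atom class, an electrostatic map and desolvation maps); a
ligand pose is scored by trilinear interpolation of those maps plus
intramolecular terms between atom pairs more than three bonds apart and a
torsional entropy penalty proportional to the number of active rotatable
bonds. Sampling is a Lamarckian genetic algorithm: a real-coded GA over
(translation, orientation quaternion, torsions) whose individuals undergo
Solis-Wets local search with the improved genotype written back.

The meta-docking layer talks to the engine only through the
``dock(grids, ligand, tree, fragment, config, seed, init_poses)`` contract,
so alternative engines can be plugged in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from numba import njit

from . import params
from .fragmenter import Fragment
from .structio import TypedMolecule
from .torsion import Pose, TorsionTree, apply_conformation

#: clash guard: pair distances below this are evaluated at this distance
MIN_PAIR_DISTANCE = 0.01
#: per-atom penalty for leaving the binding box, kcal/mol (+ linear term)
OUTSIDE_PENALTY_BASE = 100.0
OUTSIDE_PENALTY_SLOPE = 50.0


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Binding box and grid maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingBox:
    center: tuple[float, float, float]
    dimensions: tuple[float, float, float]
    spacing: float = 0.375

    def __post_init__(self):
        if not all(d > 0 for d in self.dimensions):
            raise ConfigError("box dimensions must be positive")
        if not (0.0 < self.spacing <= 1.0):
            raise ConfigError("grid spacing must be in (0, 1] A")
        if min(self.shape) < 2:
            raise ConfigError("box must contain >= 2 grid points per axis")

    @property
    def origin(self) -> np.ndarray:
        return np.array(self.center) - 0.5 * np.array(self.dimensions)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(math.floor(d / self.spacing)) + 1 for d in self.dimensions
        )

    def axes(self) -> list[np.ndarray]:
        o = self.origin
        return [
            o[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)
        ]

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.shape) - 1)

    @classmethod
    def around(cls, coords: np.ndarray, margin: float = 6.0,
               spacing: float = 0.375) -> "BindingBox":
        """Bounding box of ``coords`` plus ``margin`` on every side."""
        coords = np.asarray(coords, dtype=float)
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        return cls(
            center=tuple((lo + hi) / 2.0),
            dimensions=tuple(hi - lo),
            spacing=spacing,
        )


@dataclass
class GridMaps:
    box: BindingBox
    vdw: dict[str, np.ndarray]      # per ligand atom class
    hbond: dict[str, np.ndarray]    # per ligand atom class
    electrostatic: np.ndarray       # multiply by ligand charge
    desolv_v: np.ndarray            # sum_j V_j G(r)
    desolv_s: np.ndarray            # sum_j S_j G(r)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.vdw)


def _smooth_r(r: np.ndarray, r_eq: float) -> np.ndarray:
    """Potential smoothing: shift r up to SMOOTH_HALF towards r_eq."""
    return r + np.clip(r_eq - r, -params.SMOOTH_HALF, params.SMOOTH_HALF)


def _pair_energy_arrays(r: np.ndarray, class_a: str, class_b: str) -> np.ndarray:
    """Weighted, smoothed 12-6 (or 12-10 hydrogen-bond) pair energies."""
    r = np.maximum(r, MIN_PAIR_DISTANCE)
    r_eq, eps, hb = params.effective_pair_params(class_a, class_b)
    x = r_eq / _smooth_r(r, r_eq)
    if hb:
        e = eps * (5.0 * x**12 - 6.0 * x**10)
    else:
        e = eps * (x**12 - 2.0 * x**6)
    return np.minimum(e, params.ENERGY_CLAMP)


def _elec_pair_arrays(r: np.ndarray, qq: np.ndarray) -> np.ndarray:
    r = np.maximum(r, MIN_PAIR_DISTANCE)
    return params.W_ELEC * params.COULOMB_K * qq / (params.dielectric(r) * r)


def _desolv_gauss(r: np.ndarray) -> np.ndarray:
    return np.exp(-(r**2) / (2.0 * params.DESOLV_SIGMA**2))


def build_grids(
    receptor: TypedMolecule,
    box: BindingBox,
    classes: tuple[str, ...] | None = None,
    cutoff: float = params.NB_CUTOFF,
    chunk: int = 8192,
) -> GridMaps:
    """Precompute receptor interaction maps over the binding box.

    ``classes`` restricts the affinity maps to the ligand atom classes that
    will actually be scored (all classes by default).
    """
    classes = classes or params.ATOM_CLASSES
    rec = [a for a in receptor.atoms if a.atom_class is not None]
    if not rec:
        raise ConfigError("receptor must be typed before grid construction")
    rcoords = np.array([a.position for a in rec])
    rclass = [a.atom_class for a in rec]
    rq = np.array([a.partial_charge for a in rec])
    r_sv = np.array([
        params.SOLV_PARAMS[c][1] + params.QASP * abs(q)
        for c, q in zip(rclass, rq)
    ])
    r_vol = np.array([params.SOLV_PARAMS[c][0] for c in rclass])
    by_class: dict[str, np.ndarray] = {}
    for c in sorted(set(rclass)):
        by_class[c] = np.array([i for i, cc in enumerate(rclass) if cc == c])

    ax = box.axes()
    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    n = len(pts)
    shape = box.shape

    vdw = {t: np.zeros(n) for t in classes}
    hbond = {t: np.zeros(n) for t in classes}
    elec = np.zeros(n)
    ds_v = np.zeros(n)
    ds_s = np.zeros(n)

    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d = np.linalg.norm(pts[sl, None, :] - rcoords[None, :, :], axis=2)
        within = d < cutoff
        dm = np.where(within, np.maximum(d, MIN_PAIR_DISTANCE), np.inf)
        for t in classes:
            acc_v = np.zeros(sl.stop - sl.start)
            acc_h = np.zeros(sl.stop - sl.start)
            for c, idx in by_class.items():
                e = _pair_energy_arrays(dm[:, idx], t, c)
                e = np.where(within[:, idx], e, 0.0)
                if params.is_hbond_pair(t, c):
                    acc_h += e.sum(axis=1)
                else:
                    acc_v += e.sum(axis=1)
            vdw[t][sl] = acc_v
            hbond[t][sl] = acc_h
        ec = params.W_ELEC * params.COULOMB_K * rq[None, :] / (
            params.dielectric(dm) * dm
        )
        elec[sl] = np.where(within, ec, 0.0).sum(axis=1)
        g = np.where(within, _desolv_gauss(dm), 0.0)
        ds_v[sl] = (g * r_vol[None, :]).sum(axis=1)
        ds_s[sl] = (g * r_sv[None, :]).sum(axis=1)

    return GridMaps(
        box=box,
        vdw={t: vdw[t].reshape(shape) for t in classes},
        hbond={t: hbond[t].reshape(shape) for t in classes},
        electrostatic=elec.reshape(shape),
        desolv_v=ds_v.reshape(shape),
        desolv_s=ds_s.reshape(shape),
    )


def save_grids(grids: GridMaps, path) -> None:
    """Persist grid maps as an NPZ container with a JSON header."""
    header = json.dumps({
        "center": list(grids.box.center),
        "dimensions": list(grids.box.dimensions),
        "spacing": grids.box.spacing,
        "classes": list(grids.classes),
    })
    arrays = {f"vdw_{t}": grids.vdw[t] for t in grids.classes}
    arrays |= {f"hbond_{t}": grids.hbond[t] for t in grids.classes}
    np.savez_compressed(
        path, header=np.frombuffer(header.encode(), dtype=np.uint8),
        electrostatic=grids.electrostatic, desolv_v=grids.desolv_v,
        desolv_s=grids.desolv_s, **arrays,
    )


def load_grids(path) -> GridMaps:
    data = np.load(path)
    header = json.loads(bytes(data["header"]).decode())
    box = BindingBox(
        center=tuple(header["center"]),
        dimensions=tuple(header["dimensions"]),
        spacing=header["spacing"],
    )
    return GridMaps(
        box=box,
        vdw={t: data[f"vdw_{t}"] for t in header["classes"]},
        hbond={t: data[f"hbond_{t}"] for t in header["classes"]},
        electrostatic=data["electrostatic"],
        desolv_v=data["desolv_v"],
        desolv_s=data["desolv_s"],
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    vdw: float
    hbond: float
    electrostatic: float
    desolvation: float
    torsional_penalty: float

    @property
    def total(self) -> float:
        return (self.vdw + self.hbond + self.electrostatic
                + self.desolvation + self.torsional_penalty)

    def as_dict(self) -> dict[str, float]:
        return {
            "vdw": self.vdw, "hbond": self.hbond,
            "electrostatic": self.electrostatic,
            "desolvation": self.desolvation,
            "torsional_penalty": self.torsional_penalty,
            "total": self.total,
        }


class LigandScorer:
    """Precomputed scoring context for one ligand (or ligand fragment).

    ``atom_subset`` is a set of atom serials restricting scoring to a
    fragment; ``n_active_dofs`` sets the torsional entropy penalty.
    """

    def __init__(
        self,
        grids: GridMaps,
        ligand: TypedMolecule,
        atom_subset: frozenset[int] | None = None,
        n_active_dofs: int = 0,
    ):
        self.grids = grids
        self.ligand = ligand
        self.n_active_dofs = n_active_dofs
        serials = [a.serial for a in ligand.atoms]
        if atom_subset is None:
            atom_subset = frozenset(serials)
        self.mask = np.array([s in atom_subset for s in serials])
        atoms = [a for a in ligand.atoms if a.serial in atom_subset]
        if any(a.atom_class is None for a in atoms):
            raise ConfigError("ligand must be typed before scoring")
        self.classes = [a.atom_class for a in atoms]
        self.charges = np.array([a.partial_charge for a in atoms])
        self.solv_s = np.array([
            params.SOLV_PARAMS[c][1] + params.QASP * abs(q)
            for c, q in zip(self.classes, self.charges)
        ])
        self.solv_v = np.array([params.SOLV_PARAMS[c][0] for c in self.classes])
        self.class_index: dict[str, np.ndarray] = {}
        for c in sorted(set(self.classes)):
            self.class_index[c] = np.array(
                [i for i, cc in enumerate(self.classes) if cc == c]
            )

        # stacked grid maps: one gather interpolates every term at once
        rows: list[np.ndarray] = []
        coefs: list[np.ndarray] = []
        terms: list[str] = []
        n_atoms = len(atoms)
        for c in sorted(self.class_index):
            coef = np.zeros(n_atoms)
            coef[self.class_index[c]] = 1.0
            rows.append(grids.vdw[c]); coefs.append(coef); terms.append("vdw")
            rows.append(grids.hbond[c]); coefs.append(coef); terms.append("hbond")
        rows.append(grids.electrostatic)
        coefs.append(self.charges.copy()); terms.append("elec")
        rows.append(grids.desolv_v)
        coefs.append(params.W_DESOLV * self.solv_s); terms.append("desolv")
        rows.append(grids.desolv_s)
        coefs.append(params.W_DESOLV * self.solv_v); terms.append("desolv")
        self._map_stack = np.stack(rows)
        self._map_coef = np.array(coefs)
        self._term_rows = {
            t: np.array([i for i, tt in enumerate(terms) if tt == t])
            for t in ("vdw", "hbond", "elec", "desolv")
        }

        # intramolecular pair list: graph distance > 3 bonds, inside subset
        graph = ligand.graph()
        keep = sorted(atom_subset, key=serials.index)
        pos_of = {s: i for i, s in enumerate(keep)}
        near = dict(nx.all_pairs_shortest_path_length(graph, cutoff=3))
        pairs = []
        for i, si in enumerate(keep):
            for sj in keep[i + 1:]:
                if sj not in near.get(si, {}):
                    pairs.append((pos_of[si], pos_of[sj]))
        self.pair_i = np.array([p[0] for p in pairs], dtype=int)
        self.pair_j = np.array([p[1] for p in pairs], dtype=int)
        self._pair_param = []
        if pairs:
            lookup = {}
            keys = np.empty(len(pairs), dtype=int)
            self._pair_param = []
            for n_, (i, j) in enumerate(pairs):
                key = (self.classes[i], self.classes[j])
                if key not in lookup:
                    lookup[key] = len(self._pair_param)
                    self._pair_param.append(params.effective_pair_params(*key))
                keys[n_] = lookup[key]
            self.pair_key = keys
            self.pair_req = np.array([p[0] for p in self._pair_param])
            self.pair_eps = np.array([p[1] for p in self._pair_param])
            self.pair_hb = np.array([p[2] for p in self._pair_param])
            self.pair_qq = self.charges[self.pair_i] * self.charges[self.pair_j]
        else:
            self.pair_key = np.empty(0, dtype=int)
            self.pair_req = np.empty(0)
            self.pair_eps = np.empty(0)
            self.pair_hb = np.empty(0, dtype=bool)
            self.pair_qq = np.empty(0)
        self.pair_ds = (
            self.solv_s[self.pair_i] * self.solv_v[self.pair_j]
            + self.solv_s[self.pair_j] * self.solv_v[self.pair_i]
        )
        self.mask_idx = np.flatnonzero(self.mask)
        self._box_origin = np.asarray(self.grids.box.origin, dtype=float)
        self._box_upper = np.asarray(self.grids.box.upper, dtype=float)
        self._box_shape = np.array(self.grids.box.shape, dtype=np.int64)
        # flattened per-pair parameters for the fast kernel
        self._pp_i = self.pair_i.astype(np.int64)
        self._pp_j = self.pair_j.astype(np.int64)
        if len(self.pair_key):
            self._pp_req = np.ascontiguousarray(self.pair_req[self.pair_key])
            self._pp_eps = np.ascontiguousarray(self.pair_eps[self.pair_key])
            self._pp_hb = np.ascontiguousarray(
                self.pair_hb[self.pair_key].astype(np.bool_)
            )
        else:
            self._pp_req = np.empty(0)
            self._pp_eps = np.empty(0)
            self._pp_hb = np.empty(0, dtype=np.bool_)

    def total(self, coords: np.ndarray) -> float:
        """Total energy only (fast path used by the sampler)."""
        sub = np.ascontiguousarray(np.asarray(coords, dtype=float)[self.mask_idx])
        inter = _grid_energy_kernel(
            self._map_stack, self._map_coef, sub,
            self._box_origin, self._box_upper,
            self._box_shape, self.grids.box.spacing,
        )
        intra = _intra_energy_kernel(
            sub, self._pp_i, self._pp_j, self._pp_req, self._pp_eps,
            self._pp_hb, self.pair_qq, self.pair_ds,
        )
        return float(inter + intra + params.W_TORSION * self.n_active_dofs)

    _CX = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    _CY = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    _CZ = np.array([0, 1, 0, 1, 0, 1, 0, 1])

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        """Energy breakdown of the fragment at the given full-ligand coords."""
        coords = np.asarray(coords, dtype=float)[self.mask]
        box = self.grids.box
        rel = (coords - box.origin) / box.spacing
        shape = np.array(box.shape)
        inside = np.all((rel >= 0) & (rel <= shape - 1), axis=1)
        relc = np.clip(rel, 0, shape - 1 - 1e-12)
        i0 = np.minimum(relc.astype(int), shape - 2)
        frac = relc - i0

        ix = i0[:, 0][None, :] + self._CX[:, None]
        iy = i0[:, 1][None, :] + self._CY[:, None]
        iz = i0[:, 2][None, :] + self._CZ[:, None]
        fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]
        wx = np.where(self._CX[:, None] == 1, fx[None, :], 1.0 - fx[None, :])
        wy = np.where(self._CY[:, None] == 1, fy[None, :], 1.0 - fy[None, :])
        wz = np.where(self._CZ[:, None] == 1, fz[None, :], 1.0 - fz[None, :])
        weights = wx * wy * wz  # (8, n_atoms)

        values = self._map_stack[:, ix, iy, iz]  # (n_maps, 8, n_atoms)
        interp = np.einsum("mkn,kn->mn", values, weights)
        contrib = interp * self._map_coef
        contrib[:, ~inside] = 0.0
        row_sum = contrib.sum(axis=1)
        vdw = float(row_sum[self._term_rows["vdw"]].sum())
        hb = float(row_sum[self._term_rows["hbond"]].sum())
        elec = float(row_sum[self._term_rows["elec"]].sum())
        desolv = float(row_sum[self._term_rows["desolv"]].sum())
        # atoms outside the box: distance-proportional penalty on the vdw term
        if not inside.all():
            out = coords[~inside]
            lo, hi = self.grids.box.origin, self.grids.box.upper
            excess = np.maximum(lo - out, 0) + np.maximum(out - hi, 0)
            dist = np.linalg.norm(excess, axis=1)
            vdw += float(
                OUTSIDE_PENALTY_BASE * len(out)
                + OUTSIDE_PENALTY_SLOPE * dist.sum()
            )

        # intramolecular terms (pairs > 3 bonds apart)
        if len(self.pair_i):
            d = np.linalg.norm(coords[self.pair_i] - coords[self.pair_j], axis=1)
            within = d < params.NB_CUTOFF
            if within.any():
                dm = np.maximum(d[within], MIN_PAIR_DISTANCE)
                req = self.pair_req[self.pair_key[within]]
                eps = self.pair_eps[self.pair_key[within]]
                ishb = self.pair_hb[self.pair_key[within]]
                x = req / (dm + np.clip(req - dm, -params.SMOOTH_HALF,
                                        params.SMOOTH_HALF))
                e126 = eps * (x**12 - 2.0 * x**6)
                e1210 = eps * (5.0 * x**12 - 6.0 * x**10)
                e = np.minimum(np.where(ishb, e1210, e126), params.ENERGY_CLAMP)
                vdw += float(e[~ishb].sum())
                hb += float(e[ishb].sum())
                elec += float(_elec_pair_arrays(dm, self.pair_qq[within]).sum())
                desolv += params.W_DESOLV * float((
                    (self.solv_s[self.pair_i] * self.solv_v[self.pair_j]
                     + self.solv_s[self.pair_j] * self.solv_v[self.pair_i]
                     )[within] * _desolv_gauss(dm)
                ).sum())

        return EnergyBreakdown(
            vdw=vdw, hbond=hb, electrostatic=elec, desolvation=desolv,
            torsional_penalty=params.W_TORSION * self.n_active_dofs,
        )


def score_pose(
    grids: GridMaps,
    ligand: TypedMolecule,
    coords: np.ndarray,
    atom_subset: frozenset[int] | None = None,
    n_active_dofs: int = 0,
) -> EnergyBreakdown:
    """One-shot scoring of ligand coordinates against precomputed grids."""
    return LigandScorer(grids, ligand, atom_subset, n_active_dofs).energy(coords)


# compile-time constants for the fast kernels
_K_ELEC = params.W_ELEC * params.COULOMB_K
_W_DS = params.W_DESOLV
_SIGMA22 = 2.0 * params.DESOLV_SIGMA**2
_CUT2 = params.NB_CUTOFF**2
_CLAMP = params.ENERGY_CLAMP
_MINR = MIN_PAIR_DISTANCE
_SMOOTH = params.SMOOTH_HALF
_MS_A = params._MS_A
_MS_B = params._MS_B
_MS_LB = params._MS_LAMBDA * params._MS_B
_MS_K = params._MS_K


@njit(cache=True)
def _grid_energy_kernel(stack, coef, coords, origin, upper, shape, spacing):
    m_maps = stack.shape[0]
    total = 0.0
    for a in range(coords.shape[0]):
        rx = (coords[a, 0] - origin[0]) / spacing
        ry = (coords[a, 1] - origin[1]) / spacing
        rz = (coords[a, 2] - origin[2]) / spacing
        if (rx < 0.0 or ry < 0.0 or rz < 0.0
                or rx > shape[0] - 1 or ry > shape[1] - 1
                or rz > shape[2] - 1):
            ex = max(origin[0] - coords[a, 0], coords[a, 0] - upper[0], 0.0)
            ey = max(origin[1] - coords[a, 1], coords[a, 1] - upper[1], 0.0)
            ez = max(origin[2] - coords[a, 2], coords[a, 2] - upper[2], 0.0)
            total += OUTSIDE_PENALTY_BASE + OUTSIDE_PENALTY_SLOPE * math.sqrt(
                ex * ex + ey * ey + ez * ez
            )
            continue
        i0 = min(int(rx), shape[0] - 2)
        j0 = min(int(ry), shape[1] - 2)
        k0 = min(int(rz), shape[2] - 2)
        fx = rx - i0
        fy = ry - j0
        fz = rz - k0
        w000 = (1 - fx) * (1 - fy) * (1 - fz)
        w001 = (1 - fx) * (1 - fy) * fz
        w010 = (1 - fx) * fy * (1 - fz)
        w011 = (1 - fx) * fy * fz
        w100 = fx * (1 - fy) * (1 - fz)
        w101 = fx * (1 - fy) * fz
        w110 = fx * fy * (1 - fz)
        w111 = fx * fy * fz
        for m in range(m_maps):
            cm = coef[m, a]
            if cm == 0.0:
                continue
            v = (
                w000 * stack[m, i0, j0, k0]
                + w001 * stack[m, i0, j0, k0 + 1]
                + w010 * stack[m, i0, j0 + 1, k0]
                + w011 * stack[m, i0, j0 + 1, k0 + 1]
                + w100 * stack[m, i0 + 1, j0, k0]
                + w101 * stack[m, i0 + 1, j0, k0 + 1]
                + w110 * stack[m, i0 + 1, j0 + 1, k0]
                + w111 * stack[m, i0 + 1, j0 + 1, k0 + 1]
            )
            total += cm * v
    return total


@njit(cache=True)
def _intra_energy_kernel(coords, pi, pj, req, eps, ishb, qq, ds):
    total = 0.0
    for p in range(pi.shape[0]):
        dx = coords[pi[p], 0] - coords[pj[p], 0]
        dy = coords[pi[p], 1] - coords[pj[p], 1]
        dz = coords[pi[p], 2] - coords[pj[p], 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= _CUT2:
            continue
        r = math.sqrt(r2)
        if r < _MINR:
            r = _MINR
        shift = req[p] - r
        if shift > _SMOOTH:
            shift = _SMOOTH
        elif shift < -_SMOOTH:
            shift = -_SMOOTH
        x = req[p] / (r + shift)
        x2 = x * x
        x6 = x2 * x2 * x2
        x10 = x6 * x2 * x2
        x12 = x6 * x6
        if ishb[p]:
            e = eps[p] * (5.0 * x12 - 6.0 * x10)
        else:
            e = eps[p] * (x12 - 2.0 * x6)
        if e > _CLAMP:
            e = _CLAMP
        eps_r = _MS_A + _MS_B / (1.0 + _MS_K * math.exp(-_MS_LB * r))
        e += _K_ELEC * qq[p] / (eps_r * r)
        e += _W_DS * ds[p] * math.exp(-r2 / _SIGMA22)
        total += e
    return total


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    n_runs: int = 50
    population: int = 150
    max_evals: int = 250_000
    max_generations: int = 27_000
    elitism: int = 1
    mutation_rate: float = 0.02
    crossover_rate: float = 0.8
    local_search_rate: float = 0.06
    local_search_iters: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.population <= 0 or self.max_evals <= 0 or self.n_runs <= 0:
            raise ConfigError("population, max_evals and n_runs must be positive")
        for rate in (self.mutation_rate, self.crossover_rate,
                     self.local_search_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError("rates must be in [0, 1]")

    def scaled(self, budget: float) -> "GAConfig":
        """A copy with run count and evaluation budget scaled by ``budget``."""
        return replace(
            self,
            n_runs=max(1, int(round(self.n_runs * budget))),
            max_evals=max(100, int(round(self.max_evals * budget))),
        )


@dataclass
class ScoredPose:
    pose: Pose
    energy: EnergyBreakdown
    coords: np.ndarray = None  # full-ligand coordinates
    fragment_round: int = 0
    job_id: int = 0
    run_id: int = 0


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake), quaternion in (x, y, z, w)."""
    u1, u2, u3 = rng.random(3)
    a, b = math.sqrt(1.0 - u1), math.sqrt(u1)
    return np.array([
        a * math.sin(2 * math.pi * u2),
        a * math.cos(2 * math.pi * u2),
        b * math.sin(2 * math.pi * u3),
        b * math.cos(2 * math.pi * u3),
    ])


def random_pose(
    rng: np.random.Generator,
    box: BindingBox,
    n_torsions: int,
    centroid: np.ndarray,
) -> Pose:
    """Uniform pose: centroid uniform in the box, uniform orientation,
    torsions uniform in (-pi, pi]."""
    point = box.origin + rng.random(3) * (box.upper - box.origin)
    torsions = rng.uniform(-math.pi, math.pi, size=n_torsions)
    return Pose(
        translation=point - np.asarray(centroid, dtype=float),
        orientation=random_unit_quaternion(rng),
        torsions=torsions,
    )


class _Genome:
    """Flat genome <-> Pose mapping with an active-dimension mask."""

    def __init__(self, tree: TorsionTree, fragment: Fragment | None):
        self.n_torsions = tree.n_dofs
        self.length = 7 + self.n_torsions
        if fragment is None:
            active_t = list(range(self.n_torsions))
            self.frozen_values = {}
        else:
            active_t = list(fragment.active_dofs)
            self.frozen_values = dict(fragment.frozen_values)
        self.active_torsions = np.array(sorted(active_t), dtype=int)
        self.active_dims = np.concatenate(
            [np.arange(7), 7 + self.active_torsions]
        )

    def encode(self, pose: Pose, pin_frozen: bool = True) -> np.ndarray:
        g = np.empty(self.length)
        g[0:3] = pose.translation
        g[3:7] = pose.orientation
        g[7:] = pose.torsions
        if pin_frozen:
            for k, v in self.frozen_values.items():
                g[7 + k] = v
        return g

    def decode(self, g: np.ndarray) -> Pose:
        return Pose(g[0:3].copy(), g[3:7].copy(), g[7:].copy())


def run_ga(
    grids: GridMaps,
    ligand: TypedMolecule,
    tree: TorsionTree,
    config: GAConfig,
    fragment: Fragment | None = None,
    init_poses: list[Pose] | None = None,
    fragment_round: int = 0,
    job_id: int = 0,
) -> list[ScoredPose]:
    """Run ``config.n_runs`` independent Lamarckian GA searches.

    Returns the final populations' poses of all runs merged and ranked by
    total energy (ascending). Identical configuration and seed give
    bit-identical output.
    """
    if fragment is not None and len(fragment.active_dofs) > 64:
        raise ConfigError("more than 64 active DoFs in one round")
    ref = ligand.coords
    genome = _Genome(tree, fragment)
    subset = fragment.atom_serials if fragment is not None else None
    n_active = len(genome.active_torsions)
    scorer = LigandScorer(grids, ligand, subset, n_active_dofs=n_active)
    root_idx = sorted(tree.index_of[s] for s in tree.root_group)
    centroid = ref[root_idx].mean(axis=0)

    results: list[ScoredPose] = []
    for run in range(config.n_runs):
        rng = np.random.default_rng(config.seed + run)
        results.extend(
            _ga_single_run(
                scorer, genome, tree, ref, config, rng, centroid,
                init_poses or [], fragment_round, job_id, run,
            )
        )
    results.sort(key=lambda sp: sp.energy.total)
    return results


def _ga_single_run(
    scorer: LigandScorer,
    genome: _Genome,
    tree: TorsionTree,
    ref: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    centroid: np.ndarray,
    init_poses: list[Pose],
    fragment_round: int,
    job_id: int,
    run_id: int,
) -> list[ScoredPose]:
    evals = 0
    box = scorer.grids.box

    def fitness(g: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        coords = apply_conformation(tree, ref, genome.decode(g))
        return scorer.total(coords)

    pop_n = config.population
    pop = np.empty((pop_n, genome.length))
    for i in range(pop_n):
        if i < len(init_poses):
            pop[i] = genome.encode(init_poses[i], pin_frozen=False)
        elif init_poses:
            # expansion round: inherit a seed's placement and frozen
            # torsions, explore the active (newly added) bonds
            g = genome.encode(
                init_poses[i % len(init_poses)], pin_frozen=False
            )
            g[0:3] += rng.normal(0.0, 0.5, size=3)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            from scipy.spatial.transform import Rotation

            delta = Rotation.from_rotvec(axis * rng.normal(0.0, 0.2))
            g[3:7] = (delta * Rotation.from_quat(
                g[3:7] / np.linalg.norm(g[3:7])
            )).as_quat()
            for k in genome.active_torsions:
                g[7 + k] = rng.uniform(-math.pi, math.pi)
            pop[i] = g
        else:
            pop[i] = genome.encode(
                random_pose(rng, box, genome.n_torsions, centroid)
            )
    fit = np.array([fitness(g) for g in pop])

    generation = 0
    while evals < config.max_evals and generation < config.max_generations:
        generation += 1
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        elite_n = max(config.elitism, 0)
        new_pop = [pop[i].copy() for i in range(min(elite_n, pop_n))]
        new_fit = [float(fit[i]) for i in range(min(elite_n, pop_n))]

        while len(new_pop) < pop_n:
            i1, i2 = rng.integers(pop_n, size=2)
            p1 = pop[i1] if fit[i1] <= fit[i2] else pop[i2]
            i3, i4 = rng.integers(pop_n, size=2)
            p2 = pop[i3] if fit[i3] <= fit[i4] else pop[i4]
            c = p1.copy()
            if rng.random() < config.crossover_rate:
                a, b = sorted(rng.integers(genome.length + 1, size=2))
                c[a:b] = p2[a:b]
            _mutate(c, genome, config, rng)
            c[3:7] /= np.linalg.norm(c[3:7])
            new_pop.append(c)
            new_fit.append(fitness(c))
            if evals >= config.max_evals:
                break
        pop = np.array(new_pop[:pop_n])
        fit = np.array(new_fit[:pop_n])

        # Lamarckian step: local search writes the genotype back
        for i in range(len(pop)):
            if evals >= config.max_evals:
                break
            if rng.random() < config.local_search_rate:
                g, e, used = _solis_wets(
                    pop[i], fit[i], fitness, genome, config, rng,
                    config.max_evals - evals,
                )
                pop[i], fit[i] = g, e

    order = np.argsort(fit)
    out = []
    for i in order:
        pose = genome.decode(pop[i])
        coords = apply_conformation(tree, ref, pose)
        out.append(
            ScoredPose(
                pose=pose, energy=scorer.energy(coords), coords=coords,
                fragment_round=fragment_round, job_id=job_id, run_id=run_id,
            )
        )
    return out


def _mutate(g: np.ndarray, genome: _Genome, config: GAConfig,
            rng: np.random.Generator) -> None:
    for d in range(3):
        if rng.random() < config.mutation_rate:
            g[d] += rng.standard_cauchy() * 0.3
    if rng.random() < config.mutation_rate:
        from scipy.spatial.transform import Rotation

        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        delta = Rotation.from_rotvec(axis * rng.normal(0.0, 0.3))
        q = (delta * Rotation.from_quat(g[3:7] / np.linalg.norm(g[3:7])))
        g[3:7] = q.as_quat()
    for k in genome.active_torsions:
        if rng.random() < config.mutation_rate:
            g[7 + k] = _wrap_angle(g[7 + k] + rng.standard_cauchy() * 0.3)


def _wrap_angle(a: float) -> float:
    return float((a + math.pi) % (2.0 * math.pi) - math.pi)


def _dim_scales(genome: "_Genome") -> np.ndarray:
    """Natural move scales per active genome dimension.

    Translations move in A (scale 1), quaternion components are unit-scale
    (0.15 ~ 17 degree rotations), torsions in radians (0.3 ~ 17 degrees).
    """
    scales = np.empty(len(genome.active_dims))
    for i, d in enumerate(genome.active_dims):
        if d < 3:
            scales[i] = 1.0
        elif d < 7:
            scales[i] = 0.15
        else:
            scales[i] = 0.3
    return scales


def _solis_wets(g, e, fitness, genome, config, rng, eval_budget):
    """Solis-Wets adaptive local search on the active genome dimensions."""
    dims = genome.active_dims
    scales = _dim_scales(genome)
    rho = 1.0
    bias = np.zeros(len(dims))
    succ = fail = used = 0
    g = g.copy()
    for _ in range(config.local_search_iters):
        if used >= eval_budget or rho < 1e-4:
            break
        dev = rng.normal(0.0, rho, size=len(dims)) * scales
        cand = g.copy()
        cand[dims] += bias + dev
        cand[3:7] /= np.linalg.norm(cand[3:7])
        e_cand = fitness(cand); used += 1
        if e_cand < e:
            g, e = cand, e_cand
            bias = 0.6 * bias + 0.4 * dev
            succ, fail = succ + 1, 0
        else:
            if used >= eval_budget:
                break
            cand2 = g.copy()
            cand2[dims] -= bias + dev
            cand2[3:7] /= np.linalg.norm(cand2[3:7])
            e2 = fitness(cand2); used += 1
            if e2 < e:
                g, e = cand2, e2
                bias = bias - 0.4 * dev
                succ, fail = succ + 1, 0
            else:
                succ, fail = 0, fail + 1
                bias *= 0.5
        if succ >= 4:
            rho *= 2.0; succ = 0
        if fail >= 4:
            rho *= 0.5; fail = 0
    return g, e, used


def polish_pose(
    scorer: LigandScorer,
    tree: TorsionTree,
    ref: np.ndarray,
    pose: Pose,
    maxfev: int = 1200,
) -> tuple[Pose, float]:
    """Local line-search refinement of a pose to its basin bottom.

    Powell minimization over (translation, rotation vector, all torsions);
    deterministic. Returns the refined pose and its total energy.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    x0 = np.concatenate([
        pose.translation,
        Rotation.from_quat(pose.orientation).as_rotvec(),
        pose.torsions,
    ])

    def objective(x):
        p = Pose(x[:3], Rotation.from_rotvec(x[3:6]).as_quat(), x[6:])
        return scorer.total(apply_conformation(tree, ref, p))

    result = minimize(
        objective, x0, method="Powell",
        options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-5},
    )
    if result.fun <= objective(x0):
        x = result.x
    else:  # Powell should never worsen, but stay safe
        x = x0
    refined = Pose(x[:3], Rotation.from_rotvec(x[3:6]).as_quat(), x[6:])
    return refined, float(objective(x))


class ReferenceEngine:
    """Default docking engine implementing the pluggable engine contract."""

    needs_grids = True

    def dock(
        self,
        grids: GridMaps,
        ligand: TypedMolecule,
        tree: TorsionTree,
        fragment: Fragment | None,
        config: GAConfig,
        seed: int,
        init_poses: list[Pose] | None = None,
        fragment_round: int = 0,
        job_id: int = 0,
    ) -> list[ScoredPose]:
        cfg = replace(config, seed=seed)
        return run_ga(
            grids, ligand, tree, cfg, fragment=fragment,
            init_poses=init_poses, fragment_round=fragment_round,
            job_id=job_id,
        )
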