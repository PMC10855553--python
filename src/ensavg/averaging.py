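"""Superposition, coordinate averaging and restrained regularization.

The averaging step is the core of the refinement protocol: the selected
(optimized) frames are rigidly superposed onto the best-ranked member, their
atomic coordinates are arithmetically averaged, and the average is then
regularized by a restrained conjugate-gradient minimization that repairs the
stereochemical artefacts averaging can introduce (shrunken bonds, flattened
side chains). The regularizer is a deliberately simple surrogate objective —
harmonic restraints pulling 1-2 distances toward a reference geometry plus a
positional anchor keeping atoms near the averaged coordinates:

    U(x) = k_bond * sum_bonds (|x_i - x_j| - d_ij_ref)^2
         + k_pos  * sum_atoms |x_i - x_i_avg|^2

Bonds are inferred from the reference geometry by a distance cutoff, so the
same machinery works on all-atom models and on CA-only traces (where no pair
falls under the cutoff and regularization reduces to the anchor term).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structure_io import AtomMap, KeyMode, MappingError, Structure, build_atom_map

__all__ = [
    "SuperpositionResult", "CGParams", "AvgModel", "GeometryError",
    "kabsch_superpose", "superpose_coords", "average_coordinates", "cg_regularize",
]

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # over mapped pairs, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CGParams:
    max_iters: int = 200
    grad_tol: float = 1e-4
    k_bond: float = 1.0
    k_pos: float = 0.1
    bond_detect_cutoff: float = 1.9

    def __post_init__(self) -> None:
        if self.max_iters < 1 or self.k_bond < 0 or self.k_pos < 0:
            raise ValueError("CGParams weights must be >= 0 and max_iters >= 1")


@dataclass
class AvgModel:
    structure: Structure
    n_members: int
    member_ids: list
    per_atom_spread: np.ndarray   # RMS deviation of members about the mean, per atom, Å
    converged: bool = True


def _fit_rotation(a_centered: np.ndarray, b_centered: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||R a - b||, via SVD (reflections excluded)."""
    h = a_centered.T @ b_centered
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def superpose_coords(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of one coordinate array onto another."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 mapped atom pairs")
    ca, cb = mobile.mean(axis=0), reference.mean(axis=0)
    am, bm = mobile - ca, reference - cb
    sv = np.linalg.svd(am, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) geometry: superposition undetermined")
    rot = _fit_rotation(am, bm)
    trans = cb - rot @ ca
    fitted = am @ rot.T + cb
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def kabsch_superpose(mobile: Structure, reference: Structure,
                     amap: AtomMap) -> SuperpositionResult:
    """Least-squares rigid transform of ``mobile`` onto ``reference``.

    The transform minimizes RMSD over the mapped atom pairs; the returned
    rotation is proper (no reflection).
    """
    ia, ib = amap.indices()
    return superpose_coords(mobile.coords[ia], reference.coords[ib])


def ca_rmsd(mobile: Structure, reference: Structure) -> float:
    """CA RMSD after optimal superposition (convenience for ranking oracles)."""
    amap = build_atom_map(mobile, reference, "ca_only")
    return kabsch_superpose(mobile, reference, amap).rmsd


def average_coordinates(members: Sequence[Structure],
                        map_mode: KeyMode = "all_atoms",
                        superpose: bool = True) -> AvgModel:
    """Superpose all members onto the first and average their coordinates.

    The first member is the superposition target by convention (callers pass
    the best-ranked frame first), which makes the result independent of the
    order of the remaining members. ``superpose=False`` averages in the given
    frame, for members that are already co-framed (e.g. frames of one
    trajectory); only then do symmetric perturbations cancel exactly, since
    a least-squares fit would absorb part of each perturbation into the rigid
    transform. Atoms absent from any member are dropped from the average;
    ``per_atom_spread`` records the RMS scatter of the members about the
    mean, per atom.
    """
    if not members:
        raise ValueError("need at least one member structure")
    target = members[0]
    common = set(target.key_index())
    for m in members[1:]:
        common &= set(m.key_index())
    if not common:
        raise MappingError("members share no atoms")
    keep = [i for i, a in enumerate(target.atoms) if a.key in common]
    dropped = len(target.atoms) - len(keep)
    if dropped:
        logger.info("averaging drops %d atoms outside the common set", dropped)
    base = target.subset(keep, label="avg")
    stacks = [base.coords]
    for m in members[1:]:
        amap = build_atom_map(base, m, "all_atoms")
        ia, ib = amap.indices()
        if len(ia) != len(base.atoms):
            raise MappingError("common-atom bookkeeping failed during averaging")
        coords = m.coords[ib]
        if superpose and len(coords) >= 3:
            try:
                coords = superpose_coords(coords, base.coords).apply(coords)
            except GeometryError:
                pass  # degenerate toy geometries: average in the given frame
        # reorder into base order
        ordered = np.empty_like(coords)
        ordered[ia] = coords
        stacks.append(ordered)
    stack = np.stack(stacks)
    mean = stack.mean(axis=0)
    spread = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    return AvgModel(structure=base.with_coords(mean), n_members=len(members),
                    member_ids=[m.label for m in members], per_atom_spread=spread)


def _detect_bonds(ref_coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Index pairs (i < j) closer than ``cutoff`` in the reference geometry."""
    pairs = cKDTree(ref_coords).query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


def cg_regularize(avg: AvgModel | Structure, geometry_reference: Structure,
                  params: CGParams | None = None,
                  trace: list[float] | None = None) -> Structure:
    """Regularize averaged coordinates against a reference geometry.

    Minimizes the harmonic-bond + positional-anchor objective by nonlinear
    conjugate gradient until the gradient norm falls below ``grad_tol`` or
    ``max_iters`` iterations. Non-convergence returns the best point found,
    with a warning.
    """
    params = params or CGParams()
    structure = avg.structure if isinstance(avg, AvgModel) else avg
    amap = build_atom_map(structure, geometry_reference, "all_atoms")
    if len(amap) != len(structure.atoms):
        raise MappingError("geometry reference does not cover the averaged atom set")
    ia, ib = amap.indices()
    ref_coords = np.empty((len(structure.atoms), 3))
    ref_coords[ia] = geometry_reference.coords[ib]

    x_avg = structure.coords
    bonds = _detect_bonds(ref_coords, params.bond_detect_cutoff)
    if params.k_bond == 0.0 or len(bonds) == 0:
        return structure.with_coords(x_avg)  # anchor term alone: already minimal

    d_ref = np.linalg.norm(ref_coords[bonds[:, 0]] - ref_coords[bonds[:, 1]], axis=1)
    i_idx, j_idx = bonds[:, 0], bonds[:, 1]
    n = len(structure.atoms)

    def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
        x = flat.reshape(n, 3)
        dv = x[i_idx] - x[j_idx]
        d = np.linalg.norm(dv, axis=1)
        stretch = d - d_ref
        dx = x - x_avg
        u = params.k_bond * np.sum(stretch ** 2) + params.k_pos * np.sum(dx ** 2)
        grad = 2.0 * params.k_pos * dx
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(d[:, None] > 0, dv / np.where(d[:, None] > 0, d[:, None], 1.0), 0.0)
        bond_force = 2.0 * params.k_bond * stretch[:, None] * unit
        np.add.at(grad, i_idx, bond_force)
        np.add.at(grad, j_idx, -bond_force)
        return float(u), grad.ravel()

    history: list[float] = [objective(x_avg.ravel())[0]] if trace is not None else []

    def callback(flat: np.ndarray) -> None:
        if trace is not None:
            history.append(objective(flat)[0])

    res = minimize(objective, x_avg.ravel(), jac=True, method="CG",
                   callback=callback,
                   options={"gtol": params.grad_tol, "maxiter": params.max_iters})
    if not res.success:
        warnings.warn(f"CG regularization did not converge in {params.max_iters} "
                      f"iterations (gradient norm {np.max(np.abs(res.jac)):.3g}); "
                      f"returning best point found", stacklevel=2)
    if trace is not None:
        trace.extend(history)
    return structure.with_coords(res.x.reshape(n, 3))
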