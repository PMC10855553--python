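"""Model-quality assessment: lDDT, GDT-HA, pocket RMSD, paired statistics.

Conventions adopted here (the published metric definitions leave the
inequality senses open):

* lDDT — superposition-free. Atom pairs are chosen on the *reference*: pairs
  of non-hetero atoms in different residues with reference distance strictly
  below the inclusion radius (15 Å default). For each threshold t in
  {0.5, 1.0, 2.0, 4.0} Å the fraction of pairs with |d_model - d_ref| <= t
  (inclusive) is computed; the score is the mean fraction, on [0, 1].
* GDT-HA — mean over cutoffs {0.5, 1.0, 2.0, 4.0} Å of the largest fraction
  of CA atoms that a least-squares superposition brings within the cutoff of
  their reference partners, on [0, 100]. The subset search is a deterministic
  seed-and-extend heuristic in the style of LGA: every contiguous window of
  each seed length starts an include/re-superpose iteration, followed by a
  fixed-cardinality trim pass; on chains of up to 12 residues every atom
  triple also seeds the search, making it effectively exhaustive there.
* Binding pocket — residues with any non-hetero atom within (<=) 4.0 Å of any
  ligand atom in the reference; pocket RMSD is the all-atom RMSD over common
  pocket atoms after least-squares superposition on those atoms.
* Wilcoxon signed rank — two-sided, zero differences dropped, mid-ranks for
  ties; exact distribution (equivalent to enumerating all 2^n sign
  assignments) for n <= 25 effective pairs, normal approximation with
  continuity and tie correction above.
"""

from __future__ import annotations

import math
from itertools import combinations
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .averaging import GeometryError, superpose_coords
from .structure_io import MappingError, Structure, build_atom_map

__all__ = [
    "LDDTParams", "GDTParams", "DeltaRecord", "GlobalMeanResult", "PairedTestResult",
    "UndefinedMetricError",
    "lddt", "gdt_ha", "pocket_residues", "pocket_rmsd",
    "delta_metric", "global_mean", "fitter_fraction", "wilcoxon_signed_rank",
]


class UndefinedMetricError(ValueError):
    pass


@dataclass
class LDDTParams:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    atom_scope: Literal["all_atoms", "ca_only"] = "all_atoms"

    def __post_init__(self) -> None:
        th = tuple(self.thresholds)
        if not th or any(t <= 0 for t in th) or list(th) != sorted(th):
            raise ValueError("thresholds must be positive and ascending")
        if self.inclusion_radius <= max(th):
            raise ValueError("inclusion radius must exceed the largest threshold")


@dataclass
class GDTParams:
    cutoffs: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    seed_lengths: tuple[int, ...] = (3, 5, 7)
    max_refine_iters: int = 10

    def __post_init__(self) -> None:
        cs = tuple(self.cutoffs)
        if not cs or any(c <= 0 for c in cs) or list(cs) != sorted(cs):
            raise ValueError("cutoffs must be positive and ascending")
        if any(s < 3 for s in self.seed_lengths):
            raise ValueError("seed lengths must be >= 3")


@dataclass
class DeltaRecord:
    metric_name: str
    avg_value: float
    final_values: list[float]
    delta: float


@dataclass
class GlobalMeanResult:
    values: list[float]
    n_targets: int
    global_mean: float


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: Literal["exact", "normal_approx", "degenerate"]


# ---------------------------------------------------------------------------
# lDDT


def _scoped_pairs(model: Structure, reference: Structure, params: LDDTParams):
    mode = "ca_only" if params.atom_scope == "ca_only" else "all_atoms"
    amap = build_atom_map(model, reference, mode)
    im, ir = amap.indices()
    if mode == "all_atoms":
        keep = [k for k, i in enumerate(im) if not model.atoms[i].is_hetero]
        im, ir = im[keep], ir[keep]
    if len(im) < 2:
        raise UndefinedMetricError("lDDT needs >= 2 common atoms in scope")
    res_ids = np.array([hash((reference.atoms[i].chain_id, reference.atoms[i].res_key))
                        for i in ir])
    return model.coords[im], reference.coords[ir], res_ids


def lddt(model: Structure, reference: Structure,
         params: LDDTParams | None = None) -> float:
    """Local Distance Difference Test score on [0, 1] (superposition-free)."""
    params = params or LDDTParams()
    xm, xr, res_ids = _scoped_pairs(model, reference, params)
    d_ref = np.sqrt(np.sum((xr[:, None] - xr[None, :]) ** 2, axis=2))
    d_mod = np.sqrt(np.sum((xm[:, None] - xm[None, :]) ** 2, axis=2))
    iu = np.triu_indices(len(xr), k=1)
    different_res = res_ids[iu[0]] != res_ids[iu[1]]
    included = different_res & (d_ref[iu] < params.inclusion_radius)
    if not np.any(included):
        raise UndefinedMetricError("no atom pairs inside the inclusion radius")
    diff = np.abs(d_mod[iu][included] - d_ref[iu][included])
    fractions = [float(np.mean(diff <= t)) for t in params.thresholds]
    return float(np.mean(fractions))


def lddt_many(models_coords: np.ndarray, reference: Structure,
              params: LDDTParams | None = None) -> np.ndarray:
    """Vectorized lDDT of many pre-mapped coordinate sets against one reference.

    ``models_coords`` has shape (n_models, n_atoms, 3) with rows in the
    reference's atom order (callers guarantee the correspondence); used for
    trajectory-long scans where per-frame mapping would dominate runtime.
    """
    params = params or LDDTParams()
    keep = [i for i, a in enumerate(reference.atoms)
            if (not a.is_hetero) and (params.atom_scope != "ca_only" or a.atom_name == "CA")]
    xr = reference.coords[keep]
    xs = np.asarray(models_coords, float)[:, keep, :]
    res_ids = np.array([hash((reference.atoms[i].chain_id, reference.atoms[i].res_key))
                        for i in keep])
    iu = np.triu_indices(len(keep), k=1)
    d_ref = np.sqrt(np.sum((xr[:, None] - xr[None, :]) ** 2, axis=2))[iu]
    included = (res_ids[iu[0]] != res_ids[iu[1]]) & (d_ref < params.inclusion_radius)
    if not np.any(included):
        raise UndefinedMetricError("no atom pairs inside the inclusion radius")
    ii, jj = iu[0][included], iu[1][included]
    d_ref = d_ref[included]
    d_mod = np.sqrt(np.sum((xs[:, ii] - xs[:, jj]) ** 2, axis=2))
    diff = np.abs(d_mod - d_ref)
    scores = np.mean([np.mean(diff <= t, axis=1) for t in params.thresholds], axis=0)
    return scores


# ---------------------------------------------------------------------------
# GDT-HA


def _gdt_fraction(xm: np.ndarray, xr: np.ndarray, cutoff: float,
                  params: GDTParams) -> float:
    """Largest fraction of CA pairs superposable within ``cutoff`` (heuristic)."""
    n = len(xm)
    best = 0
    seeds: list[np.ndarray] = []
    for seed_len in params.seed_lengths:
        seeds.extend(np.arange(start, start + seed_len)
                     for start in range(n - seed_len + 1))
    if n <= 12:
        # short chains: the O(n^3) triple seed set is cheap and makes the
        # search effectively exhaustive (valid subsets need not be contiguous)
        seeds.extend(np.array(t) for t in combinations(range(n), 3))
    for seed in seeds:
        current = seed
        dist = None
        for _ in range(params.max_refine_iters):
            try:
                sup = superpose_coords(xm[current], xr[current])
            except GeometryError:
                break
            moved = sup.apply(xm)
            dist = np.linalg.norm(moved - xr, axis=1)
            # the current set is a valid subset if its own superposition
            # keeps every member within the cutoff
            if np.all(dist[current] <= cutoff):
                best = max(best, len(current))
            nxt = np.flatnonzero(dist <= cutoff)
            if len(nxt) < 3 or np.array_equal(nxt, current):
                break
            current = nxt
        if dist is None:
            continue
        # trim pass: for decreasing cardinality k, iterate "superpose on the
        # k closest, recompute" at fixed size until stable, accepting k when
        # the subset validates under its own superposition
        for k in range(n, max(best, 2), -1):
            d_all = dist
            subset = np.sort(np.argsort(d_all, kind="stable")[:k])
            found = False
            for _ in range(params.max_refine_iters):
                try:
                    sup = superpose_coords(xm[subset], xr[subset])
                except GeometryError:
                    break
                d_all = np.linalg.norm(sup.apply(xm) - xr, axis=1)
                if np.all(d_all[subset] <= cutoff):
                    found = True
                    break
                nxt = np.sort(np.argsort(d_all, kind="stable")[:k])
                if np.array_equal(nxt, subset):
                    break
                subset = nxt
            if found:
                best = max(best, k)
                break
    return best / n


def gdt_ha(model: Structure, reference: Structure,
           params: GDTParams | None = None) -> float:
    """High-accuracy Global Distance Test score on [0, 100]."""
    params = params or GDTParams()
    amap = build_atom_map(model, reference, "ca_only")
    im, ir = amap.indices()
    if len(im) < 3:
        raise GeometryError("GDT-HA needs >= 3 mapped CA atoms")
    xm, xr = model.coords[im], reference.coords[ir]
    fractions = [_gdt_fraction(xm, xr, c, params) for c in params.cutoffs]
    return 100.0 * float(np.mean(fractions))


# ---------------------------------------------------------------------------
# Binding pocket


def pocket_residues(protein: Structure, ligand: Structure,
                    cutoff: float = 4.0) -> set[tuple[str, str]]:
    """Residues with any non-hetero atom within ``cutoff`` (inclusive) of the ligand."""
    lig_coords = np.array([a.coords for a in ligand.atoms], float)
    if lig_coords.size == 0:
        raise ValueError("empty ligand")
    out: set[tuple[str, str]] = set()
    for a in protein.atoms:
        if a.is_hetero:
            continue
        d = np.linalg.norm(lig_coords - np.array(a.coords), axis=1)
        if np.min(d) <= cutoff:
            out.add((a.chain_id, a.res_key))
    return out


def pocket_rmsd(model: Structure, reference: Structure,
                pocket: set[tuple[str, str]]) -> float:
    """All-atom RMSD over pocket residues after superposition on those atoms."""
    if not pocket:
        raise ValueError("empty pocket residue set")
    amap = build_atom_map(model, reference, "all_atoms")
    pairs = [(i, j) for i, j in amap.pairs
             if not model.atoms[i].is_hetero
             and (model.atoms[i].chain_id, model.atoms[i].res_key) in pocket]
    if len(pairs) < 3:
        raise MappingError("fewer than 3 common pocket atoms")
    im = np.array([p[0] for p in pairs])
    ir = np.array([p[1] for p in pairs])
    return superpose_coords(model.coords[im], reference.coords[ir]).rmsd


# ---------------------------------------------------------------------------
# Aggregation


def delta_metric(avg_value: float, final_values: Sequence[float],
                 metric_name: str = "") -> DeltaRecord:
    """AVG-minus-mean(FINAL) difference for one assessment metric."""
    finals = [float(v) for v in final_values]
    if not finals:
        raise ValueError("need at least one FINAL-model value")
    return DeltaRecord(metric_name=metric_name, avg_value=float(avg_value),
                       final_values=finals,
                       delta=float(avg_value) - float(np.mean(finals)))


def global_mean(per_target_values: Sequence[float]) -> GlobalMeanResult:
    """Arithmetic mean of a per-target feature over an analysis set."""
    values = [float(v) for v in per_target_values]
    if not values:
        raise ValueError("need at least one per-target value")
    return GlobalMeanResult(values=values, n_targets=len(values),
                            global_mean=float(np.mean(values)))


def fitter_fraction(intermediate_scores: Sequence[float], final_score: float,
                    direction: Literal["higher_is_better", "lower_is_better"]
                    = "higher_is_better") -> float:
    """Percentage of intermediates strictly better than the run's final model."""
    scores = np.asarray(list(intermediate_scores), float)
    if scores.size == 0:
        raise ValueError("need at least one intermediate score")
    if direction == "higher_is_better":
        better = scores > final_score
    else:
        better = scores < final_score
    return 100.0 * float(np.mean(better))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    """Mid-ranks of |d|, doubled so that tied mid-ranks stay integral."""
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(absd), float)
    sorted_abs = absd[order]
    i = 0
    while i < len(sorted_abs):
        j = i
        while j + 1 < len(sorted_abs) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        ranks[order[i:j + 1]] = midrank
        i = j + 1
    return ranks


def _exact_p(pos_ranks2: np.ndarray, w_obs2: int, total2: int) -> float:
    """Two-sided exact p for W+ via the sign-assignment distribution.

    Dynamic program over the generating polynomial prod(1 + x^(2 r_i)); counts
    assignments with W+ <= w or W+ >= total - w, exactly as full enumeration
    of the 2^n sign patterns would.
    """
    counts = np.zeros(total2 + 1, dtype=float)
    counts[0] = 1.0
    for r in pos_ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total2 + 1 - r]
        counts = counts + shifted
    n_total = counts.sum()
    low = counts[:w_obs2 + 1].sum()
    high = counts[total2 - w_obs2:].sum()
    return float(min(1.0, (low + high) / n_total))


def wilcoxon_signed_rank(paired_a: Sequence[float],
                         paired_b: Sequence[float]) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; |d| are ranked with mid-ranks for ties;
    the statistic is W = min(W+, W-). The exact null distribution is used for
    up to 25 effective pairs, the tie-corrected normal approximation with
    continuity correction beyond.
    """
    a = np.asarray(list(paired_a), float)
    b = np.asarray(list(paired_b), float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired samples must be non-empty and equally long")
    diffs = a - b
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return PairedTestResult(statistic=0.0, p_value=1.0, n_effective=0,
                                method="degenerate")
    ranks = _signed_ranks(diffs)
    w_plus = float(np.sum(ranks[diffs > 0]))
    w_minus = float(np.sum(ranks[diffs < 0]))
    w = min(w_plus, w_minus)
    if n <= 25:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        total2 = int(ranks2.sum())
        w2 = int(round(2.0 * w))
        p = _exact_p(ranks2, w2, total2)
        return PairedTestResult(statistic=w, p_value=p, n_effective=n, method="exact")
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean + 0.5) / math.sqrt(var)
    from scipy.stats import norm
    p = float(min(1.0, 2.0 * norm.cdf(z)))
    return PairedTestResult(statistic=w, p_value=p, n_effective=n,
                            method="normal_approx")
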