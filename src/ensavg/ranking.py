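"""Frame scoring, ranking and top-fraction selection.

Raw pool frames are scored with a pluggable scorer — statistical potentials in
the original protocol, treated strictly as black-box rankers — sorted in the
scorer's better-first direction, and the top fraction forms the raw averaging
set. The averaging itself then uses each selected frame's optimized
counterpart, obtained through the pool's raw↔optimized pairing.

Three scorer kinds are provided:

* ``builtin_contact`` — a self-contained residue-contact pseudo-energy used as
  a stand-in ranker (it is *not* a re-implementation of any published
  potential): clashing CB pairs are penalized, CB pairs in a native-like
  contact window are rewarded.
* ``oracle_rmsd`` — CA RMSD to a known native; only meaningful on synthetic
  benchmarks where the native is available, where it gives the best selection
  any ranker could achieve.
* ``external_adapter`` — wraps an arbitrary shell command (dDFIRE/SBROD-style
  binaries, Smina, ...) that reads a PDB file and prints a score.
"""

from __future__ import annotations

import math
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .averaging import ca_rmsd
from .pool import ConfigPool, Frame, PoolError
from .structure_io import Structure, write_structure

__all__ = [
    "Scorer", "ScoredPool", "Selection", "ScoringError",
    "builtin_contact_score", "contact_scorer", "oracle_rmsd_scorer",
    "external_scorer_adapter", "blend_scorers", "score_pool", "select_top",
]

Direction = Literal["lower_is_better", "higher_is_better"]

# contact stand-in parameters: clash penalty below 3.0 Å, reward in the
# 3.5–8.0 Å contact well, minimum sequence separation 3
CONTACT_CLASH_DIST = 3.0
CONTACT_WELL = (3.5, 8.0)
CONTACT_CLASH_PENALTY = 10.0
CONTACT_WELL_REWARD = -1.0
CONTACT_MIN_SEQ_SEP = 3


class ScoringError(RuntimeError):
    pass


@dataclass
class Scorer:
    name: str
    direction: Direction
    kind: Literal["builtin_contact", "external_adapter", "oracle_rmsd", "custom"]
    fn: Callable[[Structure], float]

    def __call__(self, structure: Structure) -> float:
        return self.fn(structure)


@dataclass
class ScoredPool:
    pool: ConfigPool
    scores: dict[tuple[int, int, str], float]
    scorer: Scorer

    def raw_ids(self) -> list[tuple[int, int, str]]:
        return [f.fid for f in self.pool.frames if f.stage == "raw"]


@dataclass
class Selection:
    fraction: float
    raw_ids: list[tuple[int, int, str]]
    optimized_ids: list[tuple[int, int, str]]
    scores: dict[tuple[int, int, str], float] = field(default_factory=dict)


def _cb_or_gly_ca(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """One interaction centre per residue: CB, or CA for glycine."""
    coords, order = [], []
    residue_rank: dict[tuple[str, str], int] = {}
    for rk in structure.residue_keys():
        residue_rank[rk] = len(residue_rank)
    chosen: dict[tuple[str, str], tuple[int, np.ndarray]] = {}
    for a in structure.atoms:
        if a.is_hetero:
            continue
        rk = (a.chain_id, a.res_key)
        if a.atom_name == "CB":
            chosen[rk] = (residue_rank[rk], np.array(a.coords))
        elif a.atom_name == "CA" and a.res_name == "GLY" and rk not in chosen:
            chosen[rk] = (residue_rank[rk], np.array(a.coords))
    for rank, xyz in sorted(chosen.values(), key=lambda t: t[0]):
        order.append(rank)
        coords.append(xyz)
    return np.array(order, dtype=int), np.array(coords, dtype=float)


def builtin_contact_score(structure: Structure) -> float:
    """Contact stand-in pseudo-energy; lower is better.

    Sums, over residue pairs at sequence separation >= 3, a +10 clash term for
    CB–CB distances under 3.0 Å and a -1 reward for distances in [3.5, 8.0] Å.
    """
    ranks, coords = _cb_or_gly_ca(structure)
    if len(coords) < 2:
        raise ScoringError("contact score needs >= 2 residues with CB (or GLY CA)")
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff ** 2, axis=2))
    sep = np.abs(ranks[:, None] - ranks[None, :])
    iu = np.triu_indices(len(coords), k=1)
    d, sep = d[iu], sep[iu]
    eligible = sep >= CONTACT_MIN_SEQ_SEP
    clash = np.sum(eligible & (d < CONTACT_CLASH_DIST))
    well = np.sum(eligible & (d >= CONTACT_WELL[0]) & (d <= CONTACT_WELL[1]))
    return float(CONTACT_CLASH_PENALTY * clash + CONTACT_WELL_REWARD * well)


def contact_scorer() -> Scorer:
    return Scorer("contact", "lower_is_better", "builtin_contact", builtin_contact_score)


def oracle_rmsd_scorer(native: Structure) -> Scorer:
    """CA RMSD to a known native structure (synthetic benchmarks only)."""
    return Scorer("rmsd-oracle", "lower_is_better", "oracle_rmsd",
                  lambda s: ca_rmsd(s, native))


_FLOAT_RE = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def external_scorer_adapter(command_template: str,
                            workdir: str | Path | None = None,
                            score_pattern: str = _FLOAT_RE,
                            direction: Direction = "lower_is_better",
                            timeout: float = 120.0,
                            name: str = "external") -> Scorer:
    """Wrap a shell command that scores one PDB file.

    ``command_template`` must contain a ``{pdb}`` placeholder; the adapter
    writes each frame to a temporary PDB, substitutes its path, runs the
    command through the shell, and parses the first match of
    ``score_pattern`` in stdout as the score.
    """
    if "{pdb}" not in command_template:
        raise ValueError("command template must contain a {pdb} placeholder")
    pattern = re.compile(score_pattern)
    base = Path(workdir) if workdir is not None else None

    def fn(structure: Structure) -> float:
        with tempfile.TemporaryDirectory(dir=base) as tmp:
            pdb_path = Path(tmp) / "frame.pdb"
            write_structure(structure, pdb_path)
            cmd = command_template.format(pdb=pdb_path)
            try:
                proc = subprocess.run(cmd, shell=True, capture_output=True,
                                      text=True, timeout=timeout)
            except subprocess.TimeoutExpired as exc:
                raise ScoringError(f"external scorer timed out: {cmd}") from exc
            if proc.returncode != 0:
                raise ScoringError(f"external scorer failed ({proc.returncode}): "
                                   f"{cmd}\nstderr: {proc.stderr.strip()}")
            m = pattern.search(proc.stdout)
            if m is None:
                raise ScoringError(f"no score parsable from output of {cmd!r}: "
                                   f"{proc.stdout.strip()!r}")
            return float(m.group(0))

    return Scorer(name, direction, "external_adapter", fn)


def blend_scorers(primary: Scorer, secondary: Scorer, weight: float = 0.0,
                  name: str = "blend") -> Scorer:
    """Weighted sum of two scorers: primary + weight * secondary.

    Intended for mixing a protein-ligand score (e.g. a Smina adapter) into the
    primary statistical-potential ranking; weight 0 disables the blend. Both
    scorers must share a direction.
    """
    if primary.direction != secondary.direction:
        raise ValueError("blended scorers must share a direction")
    if weight == 0.0:
        return primary
    return Scorer(name, primary.direction, "custom",
                  lambda s: primary(s) + weight * secondary(s))


def score_pool(pool: ConfigPool, scorer: Scorer) -> ScoredPool:
    """Score every raw frame of the pool exactly once."""
    if len(pool) == 0:
        raise PoolError("cannot score an empty pool")
    scores: dict[tuple[int, int, str], float] = {}
    for frame in pool.frames:
        if frame.stage != "raw":
            continue
        try:
            value = scorer(frame.structure)
        except ScoringError:
            raise
        except Exception as exc:
            raise ScoringError(f"scorer {scorer.name!r} failed on frame "
                               f"{frame.fid}: {exc}") from exc
        if not math.isfinite(value):
            raise ScoringError(f"non-finite score for frame {frame.fid}")
        scores[frame.fid] = float(value)
    if not scores:
        raise PoolError("pool contains no raw frames to score")
    return ScoredPool(pool=pool, scores=scores, scorer=scorer)


def select_top(scored: ScoredPool, fraction: float) -> Selection:
    """Select the top fraction of raw frames, rounding up with a floor of one.

    Frames sort by score in the scorer's better-first direction, ties broken
    by (run_id, step_index). Optimized counterparts come from the pool
    pairing; with an empty pairing the selection is self-paired.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    sign = 1.0 if scored.scorer.direction == "lower_is_better" else -1.0
    ranked = sorted(scored.scores,
                    key=lambda fid: (sign * scored.scores[fid], fid[0], fid[1]))
    n_sel = max(1, math.ceil(fraction * len(ranked)))
    raw_ids = ranked[:n_sel]
    pairing = scored.pool.pairing
    if pairing:
        missing = [fid for fid in raw_ids if fid not in pairing]
        if missing:
            raise PoolError(f"selected frames lack optimized counterparts: {missing}")
        optimized_ids = [pairing[fid] for fid in raw_ids]
    else:
        optimized_ids = list(raw_ids)
    return Selection(fraction=fraction, raw_ids=raw_ids, optimized_ids=optimized_ids,
                     scores={fid: scored.scores[fid] for fid in raw_ids})
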