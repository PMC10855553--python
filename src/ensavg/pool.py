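"""Configurations-pool construction from multi-run trajectories.

A pool merges the intermediate frames of several independent annealing runs of
the same target: frames are extracted at a fixed stride (every 34 timesteps in
the protocol this package reproduces, giving 149 frames per run), optionally
thinned by a gap factor (gap = 2 keeps even-indexed frames only), and
concatenated across runs. Frames carry their provenance (run id, step index,
stage) so that a raw frame can later be paired with its optimized counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .structure_io import Structure, build_atom_map, MappingError

__all__ = [
    "Frame", "PoolSpec", "ConfigPool", "PoolError",
    "extract_frames", "apply_gap", "merge_runs", "pair_stages",
]

Stage = Literal["raw", "optimized", "final"]

DEFAULT_STRIDE = 34
DEFAULT_FRAMES_PER_RUN = 149


class PoolError(ValueError):
    pass


@dataclass
class Frame:
    structure: Structure
    run_id: int
    step_index: int
    stage: Stage = "raw"

    @property
    def fid(self) -> tuple[int, int, str]:
        """Unique frame identifier within a pool."""
        return (self.run_id, self.step_index, self.stage)

    @property
    def key(self) -> tuple[int, int]:
        """(run_id, step_index) — shared between raw and optimized stages."""
        return (self.run_id, self.step_index)


@dataclass
class PoolSpec:
    n_runs: int = 1
    stride: int = DEFAULT_STRIDE
    gap: int = 1
    frames_per_run: int = DEFAULT_FRAMES_PER_RUN

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.stride < 1 or self.frames_per_run < 1:
            raise PoolError("n_runs, stride and frames_per_run must be positive")
        if self.gap not in (1, 2):
            raise PoolError(f"gap must be 1 or 2, got {self.gap}")


@dataclass
class ConfigPool:
    frames: list[Frame]
    spec: PoolSpec
    pairing: dict[tuple[int, int, str], tuple[int, int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fids = [f.fid for f in self.frames]
        if len(set(fids)) != len(fids):
            raise PoolError("duplicate (run_id, step_index, stage) in pool")
        known = set(fids)
        for k, v in self.pairing.items():
            if k not in known or v not in known:
                raise PoolError(f"pairing references frame absent from pool: {k} -> {v}")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_by_id(self, fid: tuple[int, int, str]) -> Frame:
        for f in self.frames:
            if f.fid == fid:
                return f
        raise KeyError(fid)


def extract_frames(trajectory: Sequence[Structure], stride: int,
                   run_id: int = 1, stage: Stage = "raw") -> list[Frame]:
    """Keep trajectory elements at indices 0, stride, 2·stride, ...

    ``step_index`` counts kept frames from 0 in extraction order.
    """
    if stride < 1:
        raise PoolError(f"stride must be >= 1, got {stride}")
    if not trajectory:
        raise PoolError("empty trajectory")
    return [Frame(structure=s, run_id=run_id, step_index=k, stage=stage)
            for k, s in enumerate(trajectory[::stride])]


def apply_gap(frames: Sequence[Frame], gap: int) -> list[Frame]:
    """Gap subsampling: gap=1 is the identity, gap=2 keeps even step indices."""
    if gap == 1:
        return list(frames)
    if gap == 2:
        return [f for f in frames if f.step_index % 2 == 0]
    raise PoolError(f"gap must be 1 or 2, got {gap}")


def merge_runs(runs: Sequence[Sequence[Frame]], spec: PoolSpec) -> ConfigPool:
    """Concatenate per-run frame lists (run order preserved) into one pool.

    All runs must share a common atom set; the first frame of each run is
    checked for full correspondence against the first frame of the first run.
    """
    if not runs:
        raise PoolError("need at least one run")
    ref = runs[0][0].structure
    for run in runs[1:]:
        try:
            amap = build_atom_map(ref, run[0].structure, "all_atoms")
        except MappingError as exc:
            raise MappingError(f"atom-set mismatch across runs: {exc}") from exc
        if len(amap) != len(ref.atoms) or len(amap) != len(run[0].structure.atoms):
            raise MappingError(
                f"atom-set mismatch across runs: run {run[0].run_id} shares "
                f"{len(amap)} of {len(ref.atoms)} atoms")
    frames = [f for run in runs for f in run]
    return ConfigPool(frames=frames, spec=spec)


def pair_stages(raw_pool: ConfigPool, optimized_pool: ConfigPool) -> ConfigPool:
    """Pair each raw frame with the optimized frame sharing (run_id, step_index).

    A pool may be paired with itself (self-pairing) for pipelines without a
    separate optimized stage. Both key sets must match exactly.
    """
    raw_keys = {f.key: f.fid for f in raw_pool.frames}
    opt_keys = {f.key: f.fid for f in optimized_pool.frames}
    missing = sorted(set(raw_keys) ^ set(opt_keys))
    if missing:
        raise PoolError(f"raw/optimized key sets differ; unmatched (run, step) keys: "
                        f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    frames = list(raw_pool.frames)
    self_paired = {f.fid for f in raw_pool.frames} == {f.fid for f in optimized_pool.frames}
    if not self_paired:
        frames += list(optimized_pool.frames)
    pairing = {raw_keys[k]: opt_keys[k] for k in raw_keys}
    return ConfigPool(frames=frames, spec=raw_pool.spec, pairing=pairing)
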