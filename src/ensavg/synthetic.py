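"""Synthetic natives and annealing-like trajectories with known ground truth.

The generator emulates what matters statistically about annealing-refinement
trajectories of a homology run, not their physics: each run starts at a
randomly displaced configuration, drifts toward the native as a systematic
bias decays exponentially, and carries stationary, lag-1-autocorrelated
Gaussian noise on every coordinate. Because consecutive frames are strongly
correlated (redundant), a late intermediate frame can by chance sit closer to
the native than the run's final frame — the effect the averaging protocol
exploits.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` splits, so every fixture is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .averaging import CGParams, cg_regularize
from .structure_io import Atom, Structure

__all__ = [
    "ToySpec", "TrajectorySpec", "GenerationError",
    "make_toy_native", "simulate_run", "make_benchmark_case", "make_optimized_run",
]

Geometry = Literal["ca_trace", "ca_cb_trace", "pocket_toy"]


class GenerationError(RuntimeError):
    pass


@dataclass
class ToySpec:
    n_residues: int = 30
    geometry: Geometry = "ca_trace"
    ca_spacing: float = 3.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")


@dataclass
class TrajectorySpec:
    n_steps: int = 149
    start_offset: float = 5.0      # Å, RMS magnitude of the initial systematic displacement
    bias_half_life: float | None = None   # steps; default n_steps / 5
    noise_sigma: float = 1.0       # Å, stationary per-coordinate noise std
    noise_rho: float = 0.9         # lag-1 autocorrelation of the noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.noise_sigma < 0:
            raise ValueError("n_steps must be >= 1 and noise_sigma >= 0")
        if not 0.0 <= self.noise_rho < 1.0:
            raise ValueError("noise_rho must lie in [0, 1)")
        if self.bias_half_life is None:
            self.bias_half_life = self.n_steps / 5.0

    def with_seed(self, seed: int) -> "TrajectorySpec":
        return replace(self, seed=seed)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Counter-based seed splitting: one root seed, named substreams."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=tuple(stream)))


def _self_avoiding_walk(n: int, spacing: float, rng: np.random.Generator,
                        min_sep: float = 3.5, max_retries: int = 200) -> np.ndarray:
    xyz = np.zeros((n, 3))
    for i in range(1, n):
        for attempt in range(max_retries):
            # persistent direction keeps the chain extended, protein-like
            step = rng.normal(size=3)
            if i >= 2:
                step += 1.2 * (xyz[i - 1] - xyz[i - 2]) / spacing
            step *= spacing / np.linalg.norm(step)
            cand = xyz[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(xyz[:i - 1] - cand, axis=1)) >= min_sep:
                xyz[i] = cand
                break
        else:
            raise GenerationError(f"self-avoiding walk stuck at residue {i}")
    return xyz


def make_toy_native(spec: ToySpec) -> Structure:
    """Deterministic toy native: CA trace, CA+CB trace, or pocket toy.

    The pocket toy is a CA+CB trace plus one 4-atom HETATM ligand placed
    ~3.2 Å from the CB atoms of two mid-chain residues, so the 4.0 Å pocket
    rule selects at least two residues by construction.
    """
    rng = _rng(spec.seed, 0)
    ca = _self_avoiding_walk(spec.n_residues, spec.ca_spacing, rng)
    atoms: list[Atom] = []
    cb_dirs = None
    if spec.geometry in ("ca_cb_trace", "pocket_toy"):
        # CB placed 1.53 Å off the CA, roughly perpendicular to the chain
        cb_dirs = np.zeros_like(ca)
        for i in range(spec.n_residues):
            prev_v = ca[i] - ca[i - 1] if i > 0 else ca[1] - ca[0]
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(prev_v / np.linalg.norm(prev_v), ref)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            d = np.cross(prev_v, ref)
            cb_dirs[i] = d / np.linalg.norm(d)
    for i in range(spec.n_residues):
        res = i + 1
        atoms.append(Atom("A", res, "ALA", "CA", "C", tuple(ca[i])))
        if cb_dirs is not None:
            atoms.append(Atom("A", res, "ALA", "CB", "C",
                              tuple(ca[i] + 1.53 * cb_dirs[i])))
    if spec.geometry == "pocket_toy":
        mid = spec.n_residues // 2
        anchor_a = ca[mid] + 1.53 * cb_dirs[mid]
        anchor_b = ca[mid + 1] + 1.53 * cb_dirs[mid + 1]
        centre = 0.5 * (anchor_a + anchor_b)
        away = np.cross(anchor_b - anchor_a, cb_dirs[mid])
        away /= np.linalg.norm(away)
        base = centre + 2.0 * away
        offsets = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0],
                            [0.0, 1.4, 0.0], [0.0, 0.0, 1.4]])
        for k, off in enumerate(offsets, start=1):
            atoms.append(Atom("L", 1, "LIG", f"C{k}", "C",
                              tuple(base + off), is_hetero=True))
    return Structure(atoms=atoms, label=f"toy-native-{spec.seed}")


def simulate_run(native: Structure, spec: TrajectorySpec) -> list[Structure]:
    """One annealing-like run drifting toward the native.

    Frame t = native + offset_field * 2^(-t / half_life) + eps_t, where the
    offset field is a per-atom Gaussian displacement of RMS norm
    ``start_offset`` and eps follows a stationary AR(1) process per coordinate
    (lag-1 correlation ``noise_rho``, marginal std ``noise_sigma``). The last
    frame is the run's FINAL model.
    """
    rng = _rng(spec.seed, 1)
    x0 = native.coords
    n_atoms = len(native.atoms)
    field = rng.normal(size=(n_atoms, 3))
    rms = np.sqrt(np.mean(np.sum(field ** 2, axis=1)))
    field *= spec.start_offset / rms if rms > 0 else 0.0
    rho, sigma = spec.noise_rho, spec.noise_sigma
    eps = rng.normal(scale=sigma, size=(n_atoms, 3)) if sigma > 0 else np.zeros((n_atoms, 3))
    frames = []
    for t in range(spec.n_steps):
        if t > 0 and sigma > 0:
            eps = rho * eps + math.sqrt(1.0 - rho ** 2) * rng.normal(
                scale=sigma, size=(n_atoms, 3))
        decay = 2.0 ** (-t / spec.bias_half_life)
        frames.append(native.with_coords(x0 + decay * field + eps,
                                         label=f"run{spec.seed}-t{t}"))
    return frames


def make_optimized_run(raw_frames: Sequence[Structure],
                       params: CGParams | None = None) -> list[Structure]:
    """Synthetic 'optimized' counterparts: each raw frame regularized in place.

    Each frame is conjugate-gradient regularized against its own geometry,
    which exercises the two-pool raw/optimized protocol without altering toy
    structures that are already at their restraint minimum.
    """
    return [cg_regularize(f, f, params) for f in raw_frames]


def make_benchmark_case(n_runs: int, toy: ToySpec, traj: TrajectorySpec
                        ) -> tuple[Structure, list[list[Structure]], list[Structure]]:
    """Native + ``n_runs`` independent runs + their FINAL models.

    Runs share the native and trajectory parameters but use seeds
    ``traj.seed + 1 .. traj.seed + n_runs``, giving each run an independently
    perturbed start and noise stream.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    native = make_toy_native(toy)
    runs = [simulate_run(native, traj.with_seed(traj.seed + r))
            for r in range(1, n_runs + 1)]
    finals = [run[-1] for run in runs]
    return native, runs, finals
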