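"""PDB structure input/output and atom correspondence.

Structures are flat, ordered lists of atom records. The unit of identity for
cross-frame correspondence is the key ``(chain_id, residue key, atom_name,
is_hetero)``, where the residue key folds any insertion code into the residue
number as a suffix (``"52"``, ``"52A"``). Reading goes through :mod:`gemmi`;
writing uses fixed-column PDB v3.3 formatting so that coordinates round-trip
bit-stably at the format's three-decimal precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "AtomMap",
    "FormatError",
    "MappingError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "build_atom_map",
]

KeyMode = Literal["all_atoms", "ca_only", "backbone"]

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class FormatError(ValueError):
    """Raised when a file contains no parsable records or a malformed field."""


class MappingError(ValueError):
    """Raised when two structures share no atoms under the requested key mode."""


@dataclass(frozen=True)
class Atom:
    """One atom record: identity keys plus Cartesian coordinates in Å."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    is_hetero: bool = False
    icode: str = ""

    @property
    def res_key(self) -> str:
        """Residue number with the insertion code folded in as a suffix."""
        return f"{self.res_seq}{self.icode}"

    @property
    def key(self) -> tuple[str, str, str, bool]:
        return (self.chain_id, self.res_key, self.atom_name, self.is_hetero)

    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms with a free-text label."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.coords):
                raise ValueError(f"non-finite coordinates for atom {a.key}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with coordinates replaced row-for-row."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape {(len(self.atoms), 3)}, got {xyz.shape}")
        atoms = [replace(a, coords=(float(x), float(y), float(z)))
                 for a, (x, y, z) in zip(self.atoms, xyz)]
        return Structure(atoms=atoms, label=self.label if label is None else label)

    def subset(self, indices: Sequence[int], label: str | None = None) -> "Structure":
        return Structure(atoms=[self.atoms[i] for i in indices],
                         label=self.label if label is None else label)

    def key_index(self) -> dict[tuple, int]:
        return {a.key: i for i, a in enumerate(self.atoms)}

    def residue_keys(self, include_hetero: bool = False) -> list[tuple[str, str]]:
        """Ordered unique (chain_id, res_key) pairs."""
        seen: dict[tuple[str, str], None] = {}
        for a in self.atoms:
            if a.is_hetero and not include_hetero:
                continue
            seen.setdefault((a.chain_id, a.res_key), None)
        return list(seen)


@dataclass
class AtomMap:
    """Index pairs establishing atom correspondence between two structures."""

    pairs: list[tuple[int, int]]
    key_mode: KeyMode = "all_atoms"

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        ia = np.array([p[0] for p in self.pairs], dtype=int)
        ib = np.array([p[1] for p in self.pairs], dtype=int)
        return ia, ib


# ---------------------------------------------------------------------------
# Reading


def _from_gemmi_model(model: gemmi.Model, label: str, keep_hetero: bool) -> Structure | None:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            hetero = res.het_flag == "H"
            if hetero and not keep_hetero:
                continue
            seen_names: set[str] = set()
            for at in res:
                # alternate locations: keep the first conformer encountered
                if at.name in seen_names:
                    continue
                seen_names.add(at.name)
                atoms.append(Atom(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    res_name=res.name,
                    atom_name=at.name,
                    element=at.element.name,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    is_hetero=hetero,
                    icode=res.seqid.icode.strip(),
                ))
    if not atoms:
        return None
    return Structure(atoms=atoms, label=label)


def read_structure(path: str | Path, keep_hetero: bool = True) -> Structure:
    """Read the first model of a PDB file.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM or HETATM record.
    keep_hetero:
        Include HETATM records (ligands, ions) when True.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    parsed = _from_gemmi_model(st[0], label=path.stem, keep_hetero=keep_hetero)
    if parsed is None:
        raise FormatError(f"{path}: no parsable ATOM/HETATM records"
                          + ("" if keep_hetero else " (heteroatoms excluded)"))
    return parsed


def read_ensemble(paths_or_multimodel: str | Path | Sequence[str | Path],
                  keep_hetero: bool = True) -> list[Structure]:
    """Read an ordered ensemble of frames.

    Accepts a multi-MODEL PDB file, a directory of per-frame PDB files
    (sorted lexicographically), or an explicit sequence of paths. Frames with
    differing atom sets are restricted to their common atoms with a warning.
    """
    frames: list[Structure] = []
    if isinstance(paths_or_multimodel, (str, Path)):
        p = Path(paths_or_multimodel)
        if p.is_dir():
            files = sorted(f for f in p.iterdir() if f.suffix.lower() in (".pdb", ".ent"))
            if not files:
                raise FileNotFoundError(f"no PDB files in directory {p}")
            frames = [read_structure(f, keep_hetero=keep_hetero) for f in files]
        else:
            if not p.exists():
                raise FileNotFoundError(f"no such ensemble input: {p}")
            st = gemmi.read_pdb(str(p))
            for model in st:
                parsed = _from_gemmi_model(model, label=f"{p.stem}:{model.num}",
                                           keep_hetero=keep_hetero)
                if parsed is not None:
                    frames.append(parsed)
            if not frames:
                raise FormatError(f"{p}: no parsable models")
    else:
        paths = list(paths_or_multimodel)
        if not paths:
            raise ValueError("empty ensemble input")
        frames = [read_structure(f, keep_hetero=keep_hetero) for f in paths]
    return restrict_to_common_atoms(frames)


def restrict_to_common_atoms(frames: list[Structure]) -> list[Structure]:
    """Restrict every frame to the atom keys present in all frames.

    No-op (same objects) when the frames already share one atom set; otherwise
    a warning reports how many atoms survive.
    """
    if not frames:
        return frames
    key_sets = [set(f.key_index()) for f in frames]
    common = set.intersection(*key_sets)
    if not common:
        raise MappingError("ensemble frames share no atoms")
    if all(len(ks) == len(common) for ks in key_sets):
        return frames
    warnings.warn(
        f"ensemble frames differ in atom content; restricting all frames to "
        f"{len(common)} common atoms", stacklevel=2)
    out = []
    for f in frames:
        keep = [i for i, a in enumerate(f.atoms) if a.key in common]
        out.append(f.subset(keep))
    return out


# ---------------------------------------------------------------------------
# Writing


def _format_atom_line(a: Atom, serial: int) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
    x, y, z = a.coords
    return (f"{record}{serial:>5} {name:<4} {a.res_name:>3} {a.chain_id[:1]:1}"
            f"{a.res_seq:>4}{(a.icode or ' '):1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2}")


def _atom_lines(structure: Structure, serial0: int = 1) -> list[str]:
    lines = []
    serial = serial0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and not a.is_hetero and a.chain_id != prev_chain:
            lines.append("TER")
        if not a.is_hetero:
            prev_chain = a.chain_id
        lines.append(_format_atom_line(a, serial))
        serial += 1
    return lines


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single structure as fixed-column PDB."""
    lines = _atom_lines(structure) + ["TER", "END", ""]
    Path(path).write_text("\n".join(lines))


def write_ensemble(frames: Iterable[Structure], path: str | Path) -> None:
    """Write frames as a multi-MODEL PDB file."""
    lines: list[str] = []
    for i, frame in enumerate(frames, start=1):
        lines.append(f"MODEL {i:>8}")
        lines.extend(_atom_lines(frame))
        lines.append("ENDMDL")
    lines += ["END", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Correspondence


def _eligible(a: Atom, key_mode: KeyMode) -> bool:
    if key_mode == "all_atoms":
        return True
    if a.is_hetero or a.is_hydrogen():
        return False
    if key_mode == "ca_only":
        return a.atom_name == "CA"
    return a.atom_name in _BACKBONE_NAMES


def build_atom_map(a: Structure, b: Structure, key_mode: KeyMode = "all_atoms") -> AtomMap:
    """Pair atoms of ``a`` and ``b`` sharing identical identity keys.

    Pairs are emitted in ``a``'s atom order. ``ca_only`` keeps CA atoms of
    non-hetero residues; ``backbone`` keeps N/CA/C/O.
    """
    b_index = {}
    for j, atom in enumerate(b.atoms):
        if _eligible(atom, key_mode):
            b_index.setdefault(atom.key, j)
    pairs = []
    for i, atom in enumerate(a.atoms):
        if _eligible(atom, key_mode) and atom.key in b_index:
            pairs.append((i, b_index[atom.key]))
    if not pairs:
        raise MappingError(f"no common atoms between {a.label!r} and {b.label!r} "
                           f"under key mode {key_mode!r}")
    return AtomMap(pairs=pairs, key_mode=key_mode)
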