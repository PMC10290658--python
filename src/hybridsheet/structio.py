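"""Structure and trajectory I/O plus the distance primitives used by every feature.

The working format is fixed-column PDB (v3.3 dialect).  A multi-frame
trajectory is a multi-MODEL PDB file with a uniform topology: one
:class:`Structure` of atom identities plus one coordinate array per frame.
Coordinates are in Å throughout; no periodic-image handling is performed
(the analysed active-site region sits far from any box edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ResidueSelector",
    "PDBParseError",
    "PDBWriteError",
    "SelectionError",
    "parse_structure",
    "write_structure",
    "parse_trajectory",
    "write_trajectory",
    "min_residue_distance",
]


class PDBParseError(ValueError):
    """Malformed or empty PDB input."""


class PDBWriteError(ValueError):
    """Structure cannot be expressed in fixed-column PDB."""


class SelectionError(KeyError):
    """A residue/atom selector did not resolve in the target structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position in Å."""

    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    record_index: int = 0
    hetatm: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.residue_number < 0:
            raise ValueError("residue_number must be >= 0")


@dataclass
class Structure:
    """An ordered collection of atoms (one PDB MODEL)."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure requires at least one atom")
        keys = [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom_name) in Structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Same topology with replaced positions (used to realise trajectory frames)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} does not match {len(self.atoms)} atoms")
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, title=self.title)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_number, residue_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int]] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if key not in seen:
                seen[key] = a.residue_name
                order.append(key)
        return [(c, r, seen[(c, r)]) for c, r in order]

    def select(self, selector: "ResidueSelector") -> list[AtomRecord]:
        """Resolve a selector; raises :class:`SelectionError` when nothing matches."""
        atoms = [
            a
            for a in self.atoms
            if a.chain_id == selector.chain_id
            and a.residue_number == selector.residue_number
            and (selector.atom_names is None or a.atom_name in selector.atom_names)
        ]
        if not atoms:
            names = "" if selector.atom_names is None else f" atoms {sorted(selector.atom_names)}"
            raise SelectionError(
                f"selector chain {selector.chain_id!r} residue {selector.residue_number}{names} "
                f"matched no atom"
            )
        return atoms


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``timestep`` is the time between consecutive frames in ns.
    """

    topology: Structure
    frames: list[np.ndarray]
    timestep: float = 1.0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        n = len(self.topology.atoms)
        frames = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i} has shape {f.shape}, expected ({n}, 3)")
            frames.append(f)
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Total simulated span in ns (frame count × timestep)."""
        return len(self.frames) * self.timestep

    def frame(self, i: int) -> Structure:
        return self.topology.with_coordinates(self.frames[i])

    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.timestep


@dataclass(frozen=True)
class ResidueSelector:
    """Selects one residue, optionally narrowed to named atoms.

    The config string form is ``"chain:residue_number"`` (e.g. ``"A:385"``),
    optionally ``"chain:residue_number:ATOM"``.
    """

    chain_id: str
    residue_number: int
    atom_names: frozenset[str] | None = None

    @classmethod
    def parse(cls, text: str) -> "ResidueSelector":
        parts = text.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"selector {text!r}: expected 'chain:resnum' or 'chain:resnum:atom'")
        chain, resnum = parts[0], int(parts[1])
        names = frozenset([parts[2]]) if len(parts) == 3 else None
        return cls(chain_id=chain, residue_number=resnum, atom_names=names)

    def with_atoms(self, *names: str) -> "ResidueSelector":
        return ResidueSelector(self.chain_id, self.residue_number, frozenset(names))


# ---------------------------------------------------------------------------
# PDB parsing

def _parse_float(line: str, lo: int, hi: int, lineno: int, what: str) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def _parse_int(line: str, lo: int, hi: int, lineno: int, what: str) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def parse_structure(source: str) -> list[Structure]:
    """Parse PDB text into one :class:`Structure` per MODEL.

    A file without MODEL records yields a single structure.  Alternate
    locations keep the highest occupancy (ties go to the first seen);
    insertion codes are rejected; HETATM records (waters included) are kept.
    """
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    # altloc bookkeeping per model: key -> (index in current, occupancy)
    alt_seen: dict[tuple[str, int, str], tuple[int, float]] = {}
    title = ""
    in_model = False
    any_model_records = False

    def close_model() -> None:
        nonlocal current, alt_seen
        if current:
            models.append(current)
        current = []
        alt_seen = {}

    for lineno, line in enumerate(source.splitlines(), start=1):
        rec = line[:6]
        if rec == "TITLE ":
            title = (title + " " + line[10:80].strip()).strip()
        elif rec == "MODEL ":
            any_model_records = True
            if in_model and current:
                close_model()
            in_model = True
        elif rec == "ENDMDL":
            close_model()
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            icode = line[26].strip()
            if icode:
                raise PDBParseError(f"line {lineno}: insertion code {icode!r} not supported")
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or " "
            resnum = _parse_int(line, 22, 26, lineno, "residue number")
            x = _parse_float(line, 30, 38, lineno, "x coordinate")
            y = _parse_float(line, 38, 46, lineno, "y coordinate")
            z = _parse_float(line, 46, 54, lineno, "z coordinate")
            occ_text = line[54:60].strip()
            occ = float(occ_text) if occ_text else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1]
            atom = AtomRecord(
                atom_name=name,
                element=element,
                residue_number=resnum,
                residue_name=resname,
                chain_id=chain,
                position=np.array([x, y, z]),
                record_index=len(current),
                hetatm=(rec == "HETATM"),
                occupancy=occ,
            )
            key = (chain, resnum, name)
            if altloc:
                if key in alt_seen:
                    idx, best_occ = alt_seen[key]
                    if occ > best_occ:
                        current[idx] = replace(atom, record_index=idx)
                        alt_seen[key] = (idx, occ)
                    continue
                alt_seen[key] = (len(current), occ)
            current.append(atom)
    if current:
        if in_model:
            # unterminated MODEL block
            close_model()
        else:
            close_model()
    if not models or all(len(m) == 0 for m in models):
        raise PDBParseError("no ATOM/HETATM records found in input")
    del any_model_records
    return [Structure(atoms=m, title=title) for m in models]


_PDB_ATOM_FMT = (
    "{rec:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element right-justified in columns 13-14 for 1-letter
    # elements, so short names are blank-padded on the left.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_structure(s: Structure) -> str:
    """Emit fixed-column PDB text that reparses to an equal structure."""
    return _write_models([s], title=s.title)


def _write_models(models: Sequence[Structure], title: str = "") -> str:
    lines: list[str] = []
    if title:
        lines.append(f"TITLE     {title:<70s}".rstrip())
    multi = len(models) > 1
    for m_i, s in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m_i:>4d}")
        for i, a in enumerate(s.atoms, start=1):
            if np.any(np.abs(a.position) >= 1e4):
                raise PDBWriteError(
                    f"atom {a.atom_name!r} of residue {a.chain_id}:{a.residue_number}: "
                    f"coordinate magnitude >= 10^4 Å cannot be formatted"
                )
            lines.append(
                _PDB_ATOM_FMT.format(
                    rec="HETATM" if a.hetatm else "ATOM",
                    serial=min(i, 99999),
                    name=_format_atom_name(a.atom_name, a.element),
                    altloc=" ",
                    resname=a.residue_name[:3],
                    chain=(a.chain_id or " ")[:1],
                    resnum=a.residue_number,
                    icode=" ",
                    x=a.position[0],
                    y=a.position[1],
                    z=a.position[2],
                    occ=a.occupancy,
                    b=0.0,
                    element=a.element[:2],
                ).rstrip()
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def parse_trajectory(source: str, timestep: float = 1.0) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory with uniform topology."""
    models = parse_structure(source)
    top = models[0]
    n = len(top.atoms)
    for i, m in enumerate(models):
        if len(m.atoms) != n:
            raise PDBParseError(f"MODEL {i + 1} has {len(m.atoms)} atoms, expected {n}")
    frames = [m.coordinates for m in models]
    return Trajectory(topology=top, frames=frames, timestep=timestep)


def write_trajectory(traj: Trajectory) -> str:
    """Emit a trajectory as multi-MODEL PDB text."""
    models = [traj.frame(i) for i in range(len(traj))]
    return _write_models(models, title=traj.topology.title)


# ---------------------------------------------------------------------------
# Distance primitives

def min_residue_distance(s: Structure, a: ResidueSelector, b: ResidueSelector) -> float:
    """Minimum Euclidean distance (Å) over all atom pairs of two residues."""
    atoms_a = s.select(a)
    atoms_b = s.select(b)
    pa = np.array([at.position for at in atoms_a])
    pb = np.array([at.position for at in atoms_b])
    return float(cdist(pa, pb).min())
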