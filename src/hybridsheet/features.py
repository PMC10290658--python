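"""Per-frame structural features of the protease active site.

Implements the feature stack used to characterise intramembrane-protease
enzyme–substrate complexes:

* the two-distance *active geometry* criterion (catalytic hydrogen bond
  ``d1`` and nucleophile proximity ``d2``),
* Kabsch–Sander hydrogen-bond-energy secondary structure (reduced to
  E/H/C) and the β3 strand-occupancy statistic,
* hydration of the catalytic dyad (5 Å water count and per-water
  residence times),
* the K380–L432 Cα–Cα gap width, and the S2′ contact list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import (
    AtomRecord,
    ResidueSelector,
    SelectionError,
    Structure,
    Trajectory,
)

__all__ = [
    "CatalyticSpec",
    "ActiveSiteGeometry",
    "FeatureSeries",
    "FeatureError",
    "active_geometry",
    "count_catalytic_waters",
    "water_residence_times",
    "gap_width",
    "assign_secondary_structure",
    "beta3_fraction",
    "s2_contacts",
    "extract_features",
    "DEFAULT_WATER_NAMES",
]

log = logging.getLogger(__name__)

DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: atom names accepted as the carboxyl proton of the protonated aspartate
_CARBOXYL_H_NAMES = ("HD2", "HD1", "HOD2", "HOD1", "HD")
_CARBOXYL_O_NAMES = ("OD1", "OD2")


class FeatureError(ValueError):
    """A feature could not be computed from the given frame."""


@dataclass
class CatalyticSpec:
    """Residue selectors and thresholds defining the active site.

    ``prot_asp`` is the protonated aspartate (which of D257/D385 carries the
    proton is a modelling choice held here); ``deprot_asp`` the charged one.
    ``scissile_c``/``scissile_o`` point at the carbonyl C/O of the P1 residue.
    Thresholds default to the active-geometry criterion d1 < 2.5 Å,
    d2 < 5.6 Å with a 5 Å hydration shell and 5 Å contact radius.
    """

    prot_asp: ResidueSelector
    deprot_asp: ResidueSelector
    scissile_c: ResidueSelector
    scissile_o: ResidueSelector
    substrate_register: dict[str, ResidueSelector] = field(default_factory=dict)
    anchor_k380: ResidueSelector | None = None
    anchor_l432: ResidueSelector | None = None
    anchor_l418: ResidueSelector | None = None
    d1_max: float = 2.5
    d2_max: float = 5.6
    water_radius: float = 5.0
    contact_radius: float = 5.0
    water_names: frozenset[str] = DEFAULT_WATER_NAMES

    def __post_init__(self) -> None:
        if self.d1_max <= 0:
            raise ValueError("d1_max must be > 0")
        if self.d2_max <= self.d1_max:
            raise ValueError("d2_max must exceed d1_max")
        if (self.prot_asp.chain_id, self.prot_asp.residue_number) == (
            self.deprot_asp.chain_id,
            self.deprot_asp.residue_number,
        ):
            raise ValueError("prot_asp and deprot_asp must differ")
        keys = [
            (s.chain_id, s.residue_number) for s in self.substrate_register.values()
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("substrate register positions must be distinct residues")


@dataclass(frozen=True)
class ActiveSiteGeometry:
    """The two distances of the active-geometry criterion and the verdict."""

    d1: float
    d2: float
    is_active: bool
    used_heavy_atom_fallback: bool = False


def _single_atom(frame: Structure, sel: ResidueSelector, what: str) -> AtomRecord:
    atoms = frame.select(sel)
    if len(atoms) != 1:
        raise FeatureError(
            f"{what}: selector {sel.chain_id}:{sel.residue_number} resolved "
            f"{len(atoms)} atoms, expected exactly 1"
        )
    return atoms[0]


def active_geometry(frame: Structure, spec: CatalyticSpec) -> ActiveSiteGeometry:
    """Evaluate d1/d2 and the strict-inequality active-geometry flag.

    d1 is the hydrogen-to-acceptor distance from the carboxyl proton of the
    protonated aspartate to the scissile carbonyl O (a 2.5 Å cutoff is
    physically an H···O criterion).  If the proton is absent from the model
    the minimum carboxyl-O to carbonyl-O distance is used and flagged.
    d2 is the distance from the deprotonated aspartate Cγ to the scissile
    carbonyl C.
    """
    prot_atoms = frame.select(spec.prot_asp)
    o_sciss = _single_atom(frame, spec.scissile_o, "scissile carbonyl O")
    c_sciss = _single_atom(frame, spec.scissile_c, "scissile carbonyl C")

    by_name = {a.atom_name: a for a in prot_atoms}
    h_atoms = [by_name[n] for n in _CARBOXYL_H_NAMES if n in by_name]
    fallback = False
    if h_atoms:
        d1 = min(float(np.linalg.norm(a.position - o_sciss.position)) for a in h_atoms)
    else:
        o_atoms = [by_name[n] for n in _CARBOXYL_O_NAMES if n in by_name]
        if not o_atoms:
            raise FeatureError(
                f"protonated Asp {spec.prot_asp.chain_id}:{spec.prot_asp.residue_number} "
                f"has neither a carboxyl hydrogen nor carboxyl oxygens"
            )
        fallback = True
        d1 = min(float(np.linalg.norm(a.position - o_sciss.position)) for a in o_atoms)

    deprot_atoms = {a.atom_name: a for a in frame.select(spec.deprot_asp)}
    if "CG" not in deprot_atoms:
        raise FeatureError(
            f"deprotonated Asp {spec.deprot_asp.chain_id}:"
            f"{spec.deprot_asp.residue_number} is missing its Cγ atom"
        )
    d2 = float(np.linalg.norm(deprot_atoms["CG"].position - c_sciss.position))
    return ActiveSiteGeometry(
        d1=d1,
        d2=d2,
        is_active=bool(d1 < spec.d1_max and d2 < spec.d2_max),
        used_heavy_atom_fallback=fallback,
    )


def _water_groups(frame: Structure, spec: CatalyticSpec) -> dict[tuple[str, int], np.ndarray]:
    """Water molecules keyed by (chain, residue number) -> atom coordinates."""
    groups: dict[tuple[str, int], list[np.ndarray]] = {}
    for a in frame.atoms:
        if a.residue_name in spec.water_names:
            groups.setdefault((a.chain_id, a.residue_number), []).append(a.position)
    return {k: np.array(v) for k, v in groups.items()}


def _dyad_coords(frame: Structure, spec: CatalyticSpec) -> np.ndarray:
    coords = [a.position for a in frame.select(spec.prot_asp)]
    coords += [a.position for a in frame.select(spec.deprot_asp)]
    return np.array(coords)


def count_catalytic_waters(frame: Structure, spec: CatalyticSpec) -> int:
    """Number of distinct waters with any atom within ``water_radius`` of either Asp."""
    dyad = _dyad_coords(frame, spec)
    n = 0
    for coords in _water_groups(frame, spec).values():
        if cdist(coords, dyad).min() < spec.water_radius:
            n += 1
    return n


def water_residence_times(
    traj: Trajectory, spec: CatalyticSpec, grace_frames: int = 0
) -> dict[tuple[str, int], list[float]]:
    """Dwell durations (ns) per water molecule inside the catalytic shell.

    A dwell is a maximal run of consecutive frames in which the water
    satisfies the same any-atom 5 Å membership criterion used for counting;
    its duration is run length × timestep.  ``grace_frames`` consecutive
    outside frames are tolerated before a dwell is considered ended
    (default 0: a single frame outside terminates the dwell).
    """
    water_ids = sorted(_water_groups(traj.frame(0), spec).keys())
    membership = {w: np.zeros(len(traj), dtype=bool) for w in water_ids}
    for i in range(len(traj)):
        frame = traj.frame(i)
        dyad = _dyad_coords(frame, spec)
        groups = _water_groups(frame, spec)
        for w in water_ids:
            membership[w][i] = cdist(groups[w], dyad).min() < spec.water_radius

    out: dict[tuple[str, int], list[float]] = {}
    for w, inside in membership.items():
        dwells: list[float] = []
        run = 0
        gap = 0
        for flag in inside:
            if flag:
                if run > 0 and gap:
                    run += gap  # bridged by grace
                gap = 0
                run += 1
            else:
                if run > 0:
                    gap += 1
                    if gap > grace_frames:
                        dwells.append(run * traj.timestep)
                        run = 0
                        gap = 0
        if run > 0:
            dwells.append(run * traj.timestep)
        out[w] = dwells
    return out


def gap_width(frame: Structure, spec: CatalyticSpec) -> float:
    """Cα–Cα distance (Å) between the L432 and K380 anchors (the water gateway)."""
    if spec.anchor_k380 is None or spec.anchor_l432 is None:
        raise FeatureError("gap width requires anchor_k380 and anchor_l432 selectors")
    ca = []
    for sel, label in ((spec.anchor_l432, "L432 anchor"), (spec.anchor_k380, "K380 anchor")):
        atoms = {a.atom_name: a for a in frame.select(sel)}
        if "CA" not in atoms:
            raise FeatureError(
                f"{label} {sel.chain_id}:{sel.residue_number} has no Cα atom"
            )
        ca.append(atoms["CA"].position)
    return float(np.linalg.norm(ca[0] - ca[1]))


# ---------------------------------------------------------------------------
# Kabsch–Sander secondary structure (E/H/C reduction)

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_Q1Q2_F = 27.888  # kcal/mol·Å, electrostatic H-bond model constant
_CHAIN_BREAK_CN = 2.5  # Å


@dataclass
class _BBResidue:
    chain: str
    resnum: int
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None
    segment: int = 0


def _backbone_residues(frame: Structure) -> list[_BBResidue]:
    per_res: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    order: list[tuple[str, int]] = []
    names: dict[tuple[str, int], str] = {}
    for a in frame.atoms:
        key = (a.chain_id, a.residue_number)
        if key not in per_res:
            per_res[key] = {}
            order.append(key)
            names[key] = a.residue_name
        per_res[key][a.atom_name] = a.position
    residues: list[_BBResidue] = []
    for key in order:
        if names[key] in DEFAULT_WATER_NAMES:
            continue
        atoms = per_res[key]
        if not all(n in atoms for n in ("N", "CA", "C", "O")):
            continue
        residues.append(
            _BBResidue(
                chain=key[0],
                resnum=key[1],
                n=atoms["N"],
                ca=atoms["CA"],
                c=atoms["C"],
                o=atoms["O"],
                h=atoms.get("H"),
            )
        )
    # segment assignment: break on chain change or C–N gap > 2.5 Å
    seg = 0
    for i, r in enumerate(residues):
        if i > 0:
            prev = residues[i - 1]
            if r.chain != prev.chain or np.linalg.norm(r.n - prev.c) > _CHAIN_BREAK_CN:
                seg += 1
        r.segment = seg
    # construct missing amide H: 1.01 Å from N, anti to the preceding carbonyl O
    for i, r in enumerate(residues):
        if r.h is not None:
            continue
        if i > 0 and residues[i - 1].segment == r.segment:
            prev = residues[i - 1]
            direction = prev.c - prev.o
            norm = np.linalg.norm(direction)
            if norm > 1e-9:
                r.h = r.n + 1.01 * direction / norm
    return residues


def _hbond_energy(acc: _BBResidue, don: _BBResidue) -> float:
    """Kabsch–Sander electrostatic energy: C=O of ``acc`` accepting from N–H of ``don``."""
    if don.h is None:
        return 0.0
    r_on = np.linalg.norm(acc.o - don.n)
    r_ch = np.linalg.norm(acc.c - don.h)
    r_oh = np.linalg.norm(acc.o - don.h)
    r_cn = np.linalg.norm(acc.c - don.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return _HB_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(frame: Structure) -> dict[tuple[str, int], str]:
    """Kabsch–Sander style assignment reduced to {'E', 'H', 'C'}.

    Hydrogen bonds use the electrostatic energy model with a −0.5 kcal/mol
    cutoff; amide hydrogens are constructed when absent.  β-bridges
    (antiparallel and parallel, including isolated bridges) map to E,
    α-helical 4-turn repeats to H, everything else to C.  Residues missing
    backbone atoms are labelled C; chain breaks (C–N > 2.5 Å) delimit
    segments rather than raising.
    """
    residues = _backbone_residues(frame)
    nres = len(residues)
    # hb[i][j]: C=O of residue i accepts an H-bond from N–H of residue j
    hb = np.zeros((nres, nres), dtype=bool)
    for i in range(nres):
        for j in range(nres):
            if i == j:
                continue
            if residues[i].segment == residues[j].segment and abs(i - j) < 2:
                continue
            hb[i, j] = _hbond_energy(residues[i], residues[j]) < _HB_ENERGY_CUTOFF

    def neighbors_ok(i: int, j: int) -> bool:
        return (
            0 <= i < nres
            and 0 <= j < nres
            and residues[i].segment == residues[j].segment
        )

    labels = ["C"] * nres

    # β-bridges
    is_bridge = np.zeros(nres, dtype=bool)
    for i in range(nres):
        for j in range(i + 1, nres):
            same_seg = residues[i].segment == residues[j].segment
            if same_seg and j - i < 3:
                continue
            anti = (hb[i, j] and hb[j, i]) or (
                neighbors_ok(i - 1, i)
                and neighbors_ok(j, j + 1)
                and neighbors_ok(j - 1, j)
                and neighbors_ok(i, i + 1)
                and hb[i - 1, j + 1]
                and hb[j - 1, i + 1]
            )
            para = (
                neighbors_ok(i - 1, i)
                and neighbors_ok(i, i + 1)
                and hb[i - 1, j]
                and hb[j, i + 1]
            ) or (
                neighbors_ok(j - 1, j)
                and neighbors_ok(j, j + 1)
                and hb[j - 1, i]
                and hb[i, j + 1]
            )
            if anti or para:
                is_bridge[i] = True
                is_bridge[j] = True
    for i in np.nonzero(is_bridge)[0]:
        labels[i] = "E"

    # α-helix: two consecutive 4-turns
    turn4 = np.zeros(nres, dtype=bool)
    for i in range(nres - 4):
        if residues[i].segment == residues[i + 4].segment and hb[i, i + 4]:
            turn4[i] = True
    # two consecutive 4-turns at i−1 and i make residues i..i+3 helical
    for i in range(1, nres - 4):
        if turn4[i - 1] and turn4[i]:
            for k in range(i, i + 4):
                labels[k] = "H"

    return {(r.chain, r.resnum): labels[i] for i, r in enumerate(residues)}


def beta3_fraction(
    occupancy: dict[str, float], register: dict[str, ResidueSelector] | None = None
) -> float:
    """β3 statistic: mean strand occupancy of the P2′ and P3′ register positions.

    ``occupancy`` maps register labels ('P2p', 'P3p') to per-simulation
    strand-occupation fractions.  Substrates too short to have a P3′ residue
    use the single available occupancy (β3 = β(P2′)).
    """
    if "P2p" not in occupancy:
        raise FeatureError("register is missing the P2' position")
    has_p3 = "P3p" in occupancy
    if register is not None:
        has_p3 = has_p3 and "P3p" in register
    vals = [occupancy["P2p"]]
    if has_p3:
        vals.append(occupancy["P3p"])
    for v in vals:
        if not (0.0 <= v <= 1.0):
            raise FeatureError(f"occupancy fraction {v} outside [0, 1]")
    return float(np.mean(vals))


def s2_contacts(
    frame: Structure, spec: CatalyticSpec, enzyme_chain: str
) -> list[tuple[int, str]]:
    """Enzyme residues with any atom within ``contact_radius`` of substrate P2′.

    Returns (residue_number, residue_name) pairs sorted by residue number;
    waters and substrate residues are excluded.
    """
    if "P2p" not in spec.substrate_register:
        raise FeatureError("substrate register does not define P2'")
    p2 = spec.substrate_register["P2p"]
    p2_coords = np.array([a.position for a in frame.select(p2)])
    substrate_keys = {
        (s.chain_id, s.residue_number) for s in spec.substrate_register.values()
    }
    per_res: dict[tuple[int, str], list[np.ndarray]] = {}
    for a in frame.atoms:
        if a.chain_id != enzyme_chain:
            continue
        if a.residue_name in spec.water_names:
            continue
        if (a.chain_id, a.residue_number) in substrate_keys:
            continue
        per_res.setdefault((a.residue_number, a.residue_name), []).append(a.position)
    hits = [
        key
        for key, coords in per_res.items()
        if spec.contact_radius > 0
        and cdist(np.array(coords), p2_coords).min() < spec.contact_radius
    ]
    return sorted(hits)


@dataclass
class FeatureSeries:
    """Per-frame feature values extracted from one trajectory."""

    times: np.ndarray  # ns
    active_flags: np.ndarray  # bool
    beta_p2p: np.ndarray  # 0/1 per frame
    beta_p3p: np.ndarray | None  # 0/1 per frame, None if substrate lacks P3'
    water_counts: np.ndarray  # int
    gap_widths: np.ndarray  # Å
    rc_values: np.ndarray | None = None  # Å

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("active_flags", "beta_p2p", "water_counts", "gap_widths"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        for arr in (self.beta_p3p, self.rc_values):
            if arr is not None and len(arr) != n:
                raise ValueError("series length mismatch")
        if np.any(self.water_counts < 0):
            raise ValueError("water counts must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def active_fraction(self) -> float:
        return float(np.mean(self.active_flags))

    @property
    def beta3_series(self) -> np.ndarray:
        """Per-frame β3 indicator (mean of the available register indicators)."""
        if self.beta_p3p is None:
            return np.asarray(self.beta_p2p, dtype=float)
        return (np.asarray(self.beta_p2p, float) + np.asarray(self.beta_p3p, float)) / 2.0

    @property
    def strand_occupancy(self) -> dict[str, float]:
        occ = {"P2p": float(np.mean(self.beta_p2p))}
        if self.beta_p3p is not None:
            occ["P3p"] = float(np.mean(self.beta_p3p))
        return occ

    @property
    def beta3(self) -> float:
        return beta3_fraction(self.strand_occupancy)

    def to_dataframe(self):
        import pandas as pd

        data = {
            "time_ns": self.times,
            "active": self.active_flags.astype(int),
            "beta_P2p": np.asarray(self.beta_p2p, dtype=float),
            "beta_P3p": (
                np.full(len(self), np.nan)
                if self.beta_p3p is None
                else np.asarray(self.beta_p3p, dtype=float)
            ),
            "beta3": self.beta3_series,
            "n_waters": self.water_counts,
            "gap_width_A": self.gap_widths,
            "rc_A": (
                np.full(len(self), np.nan) if self.rc_values is None else self.rc_values
            ),
        }
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rc_value(frame: Structure, spec: CatalyticSpec) -> float | None:
    """Reaction coordinate: Cα–Cα distance between the L418 anchor and substrate P2′."""
    if spec.anchor_l418 is None or "P2p" not in spec.substrate_register:
        return None
    ca = []
    for sel in (spec.anchor_l418, spec.substrate_register["P2p"]):
        atoms = {a.atom_name: a for a in frame.select(sel)}
        if "CA" not in atoms:
            return None
        ca.append(atoms["CA"].position)
    return float(np.linalg.norm(ca[0] - ca[1]))


def extract_features(
    traj: Trajectory, spec: CatalyticSpec, stride: float | None = None
) -> FeatureSeries:
    """Run the full feature stack at a fixed cadence over a trajectory.

    ``stride`` is in ns and must be a multiple of the trajectory timestep
    (default: every frame).  A stride longer than the trajectory collapses
    to a single-frame series with a logged warning.
    """
    if stride is None:
        step = 1
    else:
        ratio = stride / traj.timestep
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"stride {stride} ns is not a positive multiple of the "
                f"timestep {traj.timestep} ns"
            )
        step = int(round(ratio))
    if step >= len(traj) and len(traj) > 1:
        warnings.warn(
            "stride exceeds trajectory duration; returning a single-frame series",
            stacklevel=2,
        )
        log.warning("stride %s ns exceeds trajectory duration; single-frame series", stride)
        step = len(traj)  # keeps only frame 0

    idx = list(range(0, len(traj), step))
    has_p3 = "P3p" in spec.substrate_register
    times, active, b2, b3, waters, gaps, rcs = [], [], [], [], [], [], []
    have_rc = True
    for i in idx:
        frame = traj.frame(i)
        times.append(i * traj.timestep)
        active.append(active_geometry(frame, spec).is_active)
        ss = assign_secondary_structure(frame)
        p2 = spec.substrate_register["P2p"]
        b2.append(1.0 if ss.get((p2.chain_id, p2.residue_number)) == "E" else 0.0)
        if has_p3:
            p3 = spec.substrate_register["P3p"]
            b3.append(1.0 if ss.get((p3.chain_id, p3.residue_number)) == "E" else 0.0)
        waters.append(count_catalytic_waters(frame, spec))
        gaps.append(gap_width(frame, spec))
        rc = _rc_value(frame, spec)
        if rc is None:
            have_rc = False
        else:
            rcs.append(rc)
    return FeatureSeries(
        times=np.array(times),
        active_flags=np.array(active, dtype=bool),
        beta_p2p=np.array(b2),
        beta_p3p=np.array(b3) if has_p3 else None,
        water_counts=np.array(waters, dtype=int),
        gap_widths=np.array(gaps),
        rc_values=np.array(rcs) if have_rc else None,
    )
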