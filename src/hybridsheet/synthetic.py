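"""Synthetic inputs: dialed-in active-site/β-sheet structures, trajectories
with planted dissociation events, and 1-D toy reaction-coordinate potentials
with analytically known free-energy profiles.

Fixtures use idealised geometry (standard bond lengths, flat pleat): only
the backbone and the few named side-chain atoms that the feature stack
reads (Asp Cγ/Oδ/Hδ, water O/H, anchor Cα) are built.  The two-strand
sheet builder places mutual N–H···O=C pairs on alternating residues, the
exact hydrogen-bond topology of an ideal antiparallel sheet, so that both
this package's secondary-structure assignment and an independent DSSP
implementation label the interior residues E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .features import CatalyticSpec
from .structio import AtomRecord, ResidueSelector, Structure, Trajectory

__all__ = [
    "ToyPotential",
    "PlantedTrajectoryTruth",
    "GenerationError",
    "make_active_site_fixture",
    "make_beta_sheet_fixture",
    "make_dissociation_trajectory",
    "make_toy_rc_potential",
    "fixture_catalytic_spec",
]


class GenerationError(ValueError):
    """A fixture request is geometrically or numerically infeasible."""


# ---------------------------------------------------------------------------
# low-level residue builders

_SPACING = 3.5  # Å, Cα–Cα rise per residue along an extended strand
_N_OFF = 1.12  # Å, N behind Cα along the chain direction
_C_OFF = 1.05  # Å, C ahead of Cα
_CO_LEN = 1.23  # Å, C=O
_NH_LEN = 1.01  # Å, N–H
_HB_GAP = 1.90  # Å, target H···O distance across the sheet
#: strand separation giving the target H···O gap for facing residues
_SHEET_SEP = _HB_GAP + _CO_LEN + _NH_LEN  # 4.14 Å


def _atom(name: str, element: str, resnum: int, resname: str, chain: str,
          pos, het: bool = False) -> AtomRecord:
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_number=resnum,
        residue_name=resname,
        chain_id=chain,
        position=np.asarray(pos, dtype=float),
        hetatm=het,
    )


def _strand_residue(chain: str, resnum: int, resname: str, ca, direction: int,
                    face: int, with_h: bool = True) -> list[AtomRecord]:
    """One extended-strand residue in the sheet plane.

    ``direction`` is ±1 along x; ``face`` is ±1: the side (±y) the carbonyl
    O and amide H point to.
    """
    ca = np.asarray(ca, dtype=float)
    n = ca - direction * np.array([_N_OFF, 0.0, 0.0])
    c = ca + direction * np.array([_C_OFF, 0.0, 0.0])
    o = c + np.array([0.0, face * _CO_LEN, 0.0])
    atoms = [
        _atom("N", "N", resnum, resname, chain, n),
        _atom("CA", "C", resnum, resname, chain, ca),
        _atom("C", "C", resnum, resname, chain, c),
        _atom("O", "O", resnum, resname, chain, o),
    ]
    if with_h:
        h = n + np.array([0.0, face * _NH_LEN, 0.0])
        atoms.append(_atom("H", "H", resnum, resname, chain, h))
    return atoms


def _isolated_residue(chain: str, resnum: int, resname: str, origin,
                      extra: dict[str, tuple[str, np.ndarray]] | None = None) -> list[AtomRecord]:
    """A residue with backbone plus named side-chain atoms at fixed offsets."""
    origin = np.asarray(origin, dtype=float)
    atoms = [
        _atom("N", "N", resnum, resname, chain, origin + [-1.2, 0.8, 0.0]),
        _atom("CA", "C", resnum, resname, chain, origin),
        _atom("C", "C", resnum, resname, chain, origin + [1.2, 0.8, 0.0]),
        _atom("O", "O", resnum, resname, chain, origin + [1.2, 2.03, 0.0]),
    ]
    if extra:
        for name, (element, off) in extra.items():
            atoms.append(_atom(name, element, resnum, resname, chain, origin + off))
    return atoms


def _water(chain: str, resnum: int, o_pos) -> list[AtomRecord]:
    o_pos = np.asarray(o_pos, dtype=float)
    return [
        _atom("O", "O", resnum, "HOH", chain, o_pos, het=True),
        _atom("H1", "H", resnum, "HOH", chain, o_pos + [0.96, 0.0, 0.0], het=True),
        _atom("H2", "H", resnum, "HOH", chain, o_pos + [-0.24, 0.93, 0.0], het=True),
    ]


def _sphere_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


# ---------------------------------------------------------------------------
# active-site fixture

def fixture_catalytic_spec(**overrides) -> CatalyticSpec:
    """The CatalyticSpec matching the fixtures built by this module.

    Enzyme chain 'E' (protonated Asp 385, deprotonated Asp 257, anchors
    K380/L432/L418), substrate chain 'S' with the ε49 register
    (P1 = 49 … P4′ = 53).
    """
    kwargs = dict(
        prot_asp=ResidueSelector("E", 385),
        deprot_asp=ResidueSelector("E", 257),
        scissile_c=ResidueSelector("S", 49, frozenset({"C"})),
        scissile_o=ResidueSelector("S", 49, frozenset({"O"})),
        substrate_register={
            "P1": ResidueSelector("S", 49),
            "P1p": ResidueSelector("S", 50),
            "P2p": ResidueSelector("S", 51),
            "P3p": ResidueSelector("S", 52),
            "P4p": ResidueSelector("S", 53),
        },
        anchor_k380=ResidueSelector("E", 380),
        anchor_l432=ResidueSelector("E", 432),
        anchor_l418=ResidueSelector("E", 418),
    )
    kwargs.update(overrides)
    return CatalyticSpec(**kwargs)


def make_active_site_fixture(
    d1: float, d2: float, n_waters: int = 0, water_shell: float = 5.0
) -> Structure:
    """Two-Asp active site with requested d1/d2 and a placeable water shell.

    The scissile carbonyl belongs to a substrate dipeptide (chain S,
    residues 49–50); the protonated Asp (E:385) carries a carboxyl proton
    HD2 placed exactly ``d1`` from the carbonyl O, and the deprotonated Asp
    (E:257) has its Cγ exactly ``d2`` from the carbonyl C.  ``n_waters``
    3-site waters are placed with nearest approach ``water_shell − 0.5`` Å
    from the deprotonated Asp Cγ.
    """
    if d1 <= 1.0 or d2 <= 1.0:
        raise GenerationError("d1 and d2 must exceed 1.0 Å")
    if n_waters < 0:
        raise GenerationError("n_waters must be >= 0")
    if d2 < d1:
        raise GenerationError(f"infeasible request: d2 ({d2}) < d1 ({d1})")

    atoms: list[AtomRecord] = []
    # substrate dipeptide; P1 carbonyl C at the origin, O along +y
    c1 = np.array([0.0, 0.0, 0.0])
    o1 = c1 + [0.0, _CO_LEN, 0.0]
    ca1 = c1 + [-_C_OFF - 0.4, -0.3, 0.0]
    n1 = ca1 + [-_N_OFF, 0.4, 0.0]
    atoms += [
        _atom("N", "N", 49, "LEU", "S", n1),
        _atom("CA", "C", 49, "LEU", "S", ca1),
        _atom("C", "C", 49, "LEU", "S", c1),
        _atom("O", "O", 49, "LEU", "S", o1),
    ]
    ca2 = c1 + [2.4, -0.6, 0.0]
    atoms += [
        _atom("N", "N", 50, "VAL", "S", c1 + [1.33, -0.3, 0.0]),
        _atom("CA", "C", 50, "VAL", "S", ca2),
        _atom("C", "C", 50, "VAL", "S", ca2 + [1.2, 0.8, 0.0]),
        _atom("O", "O", 50, "VAL", "S", ca2 + [1.2, 2.03, 0.0]),
    ]
    # protonated Asp E:385 stacked above the carbonyl O along +y
    hd2 = o1 + [0.0, d1, 0.0]
    od2 = hd2 + [0.0, 0.98, 0.0]
    cg_p = od2 + [0.8, 0.9, 0.0]
    atoms += _isolated_residue(
        "E", 385, "ASP", cg_p + [0.0, 2.5, 0.0],
        extra={
            "CB": ("C", cg_p + [0.0, 1.3, 0.0] - (cg_p + [0.0, 2.5, 0.0])),
        },
    )
    atoms += [
        _atom("CG", "C", 385, "ASP", "E", cg_p),
        _atom("OD1", "O", 385, "ASP", "E", cg_p + [1.1, 0.6, 0.0]),
        _atom("OD2", "O", 385, "ASP", "E", od2),
        _atom("HD2", "H", 385, "ASP", "E", hd2),
    ]
    # deprotonated Asp E:257 out of plane, Cγ at d2 from the carbonyl C
    cg_d = c1 + [0.0, 0.0, -d2]
    atoms += _isolated_residue("E", 257, "ASP", cg_d + [0.0, 1.8, -1.5])
    atoms += [
        _atom("CB", "C", 257, "ASP", "E", cg_d + [0.0, 1.0, -0.9]),
        _atom("CG", "C", 257, "ASP", "E", cg_d),
        _atom("OD1", "O", 257, "ASP", "E", cg_d + [1.1, -0.5, 0.0]),
        _atom("OD2", "O", 257, "ASP", "E", cg_d + [-1.1, -0.5, 0.0]),
    ]
    # waters on a shell around the deprotonated Asp Cγ
    if n_waters:
        radius = max(water_shell - 0.5, 1.5)
        for i, u in enumerate(_sphere_directions(n_waters)):
            atoms += _water("W", 1000 + i, cg_d + radius * u)
    return Structure(atoms=atoms, title="synthetic active-site fixture")


# ---------------------------------------------------------------------------
# β-sheet fixture

def _build_sheet(
    n_res: int,
    separation: float,
    twist: float = 0.0,
    chain_a: str = "A",
    chain_b: str = "B",
    start_a: int = 1,
    start_b: int = 1,
    resname: str = "ALA",
    origin=(0.0, 0.0, 0.0),
    n_strands: int = 2,
) -> list[AtomRecord]:
    """Two antiparallel strands along x; mutual H-bond pairs on even pair indices.

    ``twist`` is the total accumulated sheet twist in degrees: cross-section
    (pair) ``i`` is rigidly rotated about the mid-sheet x-axis by
    ``twist·i/(n_res−1)``, which preserves every intra-pair hydrogen bond
    exactly while introducing the pleat twist.
    """
    origin = np.asarray(origin, dtype=float)
    mid_y = separation / 2.0

    def rotate(atoms: list[AtomRecord], angle_deg: float) -> list[AtomRecord]:
        if abs(angle_deg) < 1e-12:
            return atoms
        t = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        out = []
        for a in atoms:
            yz = a.position[1:] - np.array([mid_y, 0.0])
            yz = rot @ yz + np.array([mid_y, 0.0])
            pos = np.array([a.position[0], yz[0], yz[1]])
            out.append(
                AtomRecord(a.atom_name, a.element, a.residue_number, a.residue_name,
                           a.chain_id, pos, a.record_index, a.hetatm, a.occupancy)
            )
        return out

    per_pair = twist / max(n_res - 1, 1)
    atoms_a: list[AtomRecord] = []
    atoms_b: list[AtomRecord] = []
    for i in range(n_res):
        face = 1 if i % 2 == 0 else -1
        ca_a = origin + [i * _SPACING, 0.0, 0.0]
        # the chain's first residue carries a free amine, not an amide
        # proton, so no H is emitted for it (matching DSSP convention)
        res_a = _strand_residue(chain_a, start_a + i, resname, ca_a, direction=1,
                                face=face, with_h=i > 0)
        atoms_a += rotate(res_a, per_pair * i)
        if n_strands > 1:
            # partner residue, vertically aligned, running −x
            k = n_res - 1 - i  # pair index of this B residue
            ca_b = origin + [k * _SPACING, separation, 0.0]
            face_b = -1 if k % 2 == 0 else 1
            res_b = _strand_residue(chain_b, start_b + i, resname, ca_b, direction=-1,
                                    face=face_b, with_h=i > 0)
            atoms_b += rotate(res_b, per_pair * k)
    return atoms_a + atoms_b


def make_beta_sheet_fixture(
    n_res_per_strand: int,
    registry: str = "antiparallel",
    twist: float = 0.0,
    n_strands: int = 2,
) -> Structure:
    """Two-strand antiparallel β-sheet with ideal inter-strand hydrogen bonds.

    The H···O distance of every formed bond is 1.9 Å.  ``n_strands=1``
    builds the isolated-strand variant (no bridge partner, hence no E
    labels).
    """
    if n_res_per_strand < 3:
        raise GenerationError("need at least 3 residues per strand")
    if registry != "antiparallel":
        raise GenerationError(f"unsupported registry {registry!r}")
    atoms = _build_sheet(n_res_per_strand, _SHEET_SEP, twist=twist, n_strands=n_strands)
    return Structure(atoms=atoms, title="synthetic antiparallel beta-sheet fixture")


# ---------------------------------------------------------------------------
# ideal α-helix (internal-coordinate chain growth)

def _nerf(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d given a–b–c with |c−d| = bond, ∠(b,c,d) = angle and
    dihedral(a,b,c,d); angles in degrees."""
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_helix_fixture(n_res: int, phi: float = -57.0, psi: float = -47.0) -> Structure:
    """Ideal α-helix built from standard internal coordinates.

    Backbone grown with bond lengths N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å,
    trans peptide (ω = 180°) and the requested φ/ψ; carbonyl O placed in
    the peptide plane.  Interior residues of the default geometry are
    4-turn hydrogen bonded and label H.
    """
    if n_res < 5:
        raise GenerationError("need at least 5 residues for a helix")
    # seed triad for the first residue
    coords: list[tuple[str, str, np.ndarray]] = []  # (atom, element, pos)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = _nerf(np.array([0.0, 1.0, 0.0]), n0, ca0, 1.525, 111.2, 0.0)
    prev_n, prev_ca, prev_c = n0, ca0, c0
    per_res: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        n = _nerf(prev_n, prev_ca, prev_c, 1.329, 116.2, psi)
        ca = _nerf(prev_ca, prev_c, n, 1.458, 121.7, 180.0)  # ω trans
        c = _nerf(prev_c, n, ca, 1.525, 111.2, phi)
        per_res.append({"N": n, "CA": ca, "C": c})
        prev_n, prev_ca, prev_c = n, ca, c
    atoms: list[AtomRecord] = []
    for i, r in enumerate(per_res):
        # O anti to the next N across the peptide plane
        if i + 1 < n_res:
            o = _nerf(per_res[i + 1]["N"], r["CA"], r["C"], 1.231, 120.8, 180.0)
        else:
            o = _nerf(r["N"], r["CA"], r["C"], 1.231, 120.8, psi + 180.0)
        atoms.append(_atom("N", "N", i + 1, "ALA", "A", r["N"]))
        atoms.append(_atom("CA", "C", i + 1, "ALA", "A", r["CA"]))
        atoms.append(_atom("C", "C", i + 1, "ALA", "A", r["C"]))
        atoms.append(_atom("O", "O", i + 1, "ALA", "A", o))
    return Structure(atoms=atoms, title="synthetic ideal alpha-helix fixture")


# ---------------------------------------------------------------------------
# planted dissociation trajectory

@dataclass
class PlantedTrajectoryTruth:
    """Ground truth planted into a generated trajectory."""

    active_flags: np.ndarray
    beta3_series: np.ndarray
    water_counts: np.ndarray
    gap_widths: np.ndarray
    rc_values: np.ndarray
    dissociation_frame: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "active_flags": [bool(b) for b in self.active_flags],
                "beta3_series": [float(v) for v in self.beta3_series],
                "water_counts": [int(v) for v in self.water_counts],
                "gap_widths": [float(v) for v in self.gap_widths],
                "rc_values": [float(v) for v in self.rc_values],
                "dissociation_frame": int(self.dissociation_frame),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTrajectoryTruth":
        d = json.loads(text)
        return cls(
            active_flags=np.array(d["active_flags"], dtype=bool),
            beta3_series=np.array(d["beta3_series"], dtype=float),
            water_counts=np.array(d["water_counts"], dtype=int),
            gap_widths=np.array(d["gap_widths"], dtype=float),
            rc_values=np.array(d["rc_values"], dtype=float),
            dissociation_frame=d["dissociation_frame"],
        )


# geometry constants of the planted complex
_ASSOC_GAP = 11.0  # Å, K380–L432 Cα–Cα, hybrid sheet closed
_DISSOC_GAP = 14.0
_ASSOC_RC = 9.0  # Å, L418–P2′ Cα–Cα
_DISSOC_SHIFT = 7.0  # Å, substrate displacement at dissociation
_ASSOC_D1 = 1.9
_ASSOC_D2 = 4.8
_N_WATERS = 6


def _complex_frame(dissociated: bool) -> Structure:
    """One frame of the enzyme–substrate complex scene (uniform topology)."""
    shift = _DISSOC_SHIFT if dissociated else 0.0
    atoms: list[AtomRecord] = []

    # enzyme β2 strand (E:377–381) at y=0; substrate strand (S:49–53)
    # antiparallel at the sheet separation (+shift when dissociated).
    sep = _SHEET_SEP + shift
    atoms += _build_sheet(
        5, sep, chain_a="E", chain_b="S", start_a=377, start_b=49, resname="ALA"
    )

    # anchors.  K380 Cα sits at (3·spacing, 0, 0); L432 closes the gap in z.
    k380_ca = np.array([3 * _SPACING, 0.0, 0.0])
    gap = _DISSOC_GAP if dissociated else _ASSOC_GAP
    atoms += _isolated_residue("E", 418, "LEU", np.array([2 * _SPACING, _SHEET_SEP - _ASSOC_RC, 0.0]))
    atoms += _isolated_residue("E", 432, "LEU", k380_ca + [0.0, 0.0, gap])

    # substrate P1 (S:49) pairs with enzyme 381 → pair index 4, CA at x = 4·spacing.
    # Its backbone C/O are the scissile carbonyl; the Asp dyad is placed
    # relative to the ASSOCIATED carbonyl position and does not move.
    p1_face = -1  # pair index 4 is even → carbonyl faces the enzyme strand
    p1_ca = np.array([4 * _SPACING, _SHEET_SEP, 0.0])
    p1_c = p1_ca - np.array([_C_OFF, 0.0, 0.0])  # direction −1
    p1_o = p1_c + np.array([0.0, p1_face * _CO_LEN, 0.0])
    hd2 = p1_o + np.array([0.0, 0.0, _ASSOC_D1])
    od2 = hd2 + np.array([0.0, 0.0, 0.98])
    cg_p = od2 + np.array([0.8, 0.0, 0.9])
    atoms += _isolated_residue("E", 385, "ASP", cg_p + [0.0, -1.0, 2.2])
    atoms += [
        _atom("CG", "C", 385, "ASP", "E", cg_p),
        _atom("OD1", "O", 385, "ASP", "E", cg_p + [1.1, 0.0, 0.6]),
        _atom("OD2", "O", 385, "ASP", "E", od2),
        _atom("HD2", "H", 385, "ASP", "E", hd2),
    ]
    cg_d = p1_c + np.array([0.0, 0.0, -_ASSOC_D2])
    atoms += _isolated_residue("E", 257, "ASP", cg_d + [0.5, 1.8, -1.5])
    atoms += [
        _atom("CB", "C", 257, "ASP", "E", cg_d + [0.0, 1.0, -0.9]),
        _atom("CG", "C", 257, "ASP", "E", cg_d),
        _atom("OD1", "O", 257, "ASP", "E", cg_d + [1.1, -0.5, 0.0]),
        _atom("OD2", "O", 257, "ASP", "E", cg_d + [-1.1, -0.5, 0.0]),
    ]

    # waters: one resident in the associated state, all six near the dyad
    # once the gate is open.
    dirs = _sphere_directions(_N_WATERS)
    far = np.array([-30.0, -30.0, -30.0])
    for i in range(_N_WATERS):
        if dissociated:
            pos = cg_d + 4.5 * dirs[i]
        elif i == 0:
            pos = cg_d + 4.5 * dirs[0]
        else:
            pos = far + 8.0 * i * np.array([1.0, 0.3, 0.1])
        atoms += _water("W", 1000 + i, pos)

    atoms.sort(key=lambda a: (a.chain_id, a.residue_number))
    return Structure(atoms=atoms, title="synthetic enzyme-substrate complex")


def make_dissociation_trajectory(
    n_frames: int,
    event_frame: int,
    seed: int = 0,
    timestep: float = 1.0,
    noise: float = 0.2,
) -> tuple[Trajectory, PlantedTrajectoryTruth]:
    """Trajectory with a planted β3-dissociation event at ``event_frame``.

    Frames before the event show the associated complex (gap ≈ 11 Å,
    one resident water, intact strand, active geometry); frames from the
    event on show the dissociated complex (gap 14 Å, six waters, broken
    strand, inactive).  Isotropic Gaussian coordinate noise of ``noise`` Å
    (seeded) is added to every frame; a noise of 0 gives the exactly
    recoverable variant.
    """
    if not (0 < event_frame < n_frames):
        raise GenerationError("event_frame must satisfy 0 < event_frame < n_frames")
    assoc = _complex_frame(dissociated=False)
    dissoc = _complex_frame(dissociated=True)
    assoc_xyz = assoc.coordinates
    dissoc_xyz = dissoc.coordinates
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        base = assoc_xyz if i < event_frame else dissoc_xyz
        xyz = base.copy()
        if noise > 0:
            xyz = xyz + rng.normal(0.0, noise, size=xyz.shape)
        frames.append(xyz)
    traj = Trajectory(topology=assoc, frames=frames, timestep=timestep)
    pre = np.arange(n_frames) < event_frame
    truth = PlantedTrajectoryTruth(
        active_flags=pre.copy(),
        beta3_series=np.where(pre, 1.0, 0.0),
        water_counts=np.where(pre, 1, _N_WATERS).astype(int),
        gap_widths=np.where(pre, _ASSOC_GAP, _DISSOC_GAP).astype(float),
        rc_values=np.where(pre, _ASSOC_RC, _ASSOC_RC + _DISSOC_SHIFT).astype(float),
        dissociation_frame=int(event_frame),
    )
    return traj, truth


# ---------------------------------------------------------------------------
# toy reaction-coordinate potentials

@dataclass
class ToyPotential:
    """1-D potential along the reaction coordinate with known PMF.

    For a one-dimensional system the potential of mean force equals the
    potential itself (up to an additive constant), so ``analytic_pmf`` is
    the ``evaluator``.
    """

    evaluator: Callable[[np.ndarray], np.ndarray]
    analytic_pmf: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    ddg_target: float | None = None
    assoc_min: float | None = None

    def __call__(self, x):
        return self.evaluator(x)


def make_toy_rc_potential(
    ddg_target: float,
    barrier: float = 1.0,
    assoc_min: float = 9.0,
    dissoc_plateau: float = 15.0,
    wall_k: float = 2.0,
) -> ToyPotential:
    """Smooth double-feature potential emulating a β3 association profile.

    Global minimum (value 0) at ``assoc_min``; a smooth rise of height
    ``ddg_target`` completed by ``dissoc_plateau`` (so PMF(16 Å) − min =
    ``ddg_target`` exactly); a compact bump of height ``barrier`` centred
    in the transition band; a harmonic wall below ``assoc_min``.
    """
    for name, v in (("ddg_target", ddg_target), ("barrier", barrier),
                    ("assoc_min", assoc_min), ("dissoc_plateau", dissoc_plateau)):
        if not np.isfinite(v):
            raise GenerationError(f"{name} must be finite")
    if not (assoc_min < 11.0 < dissoc_plateau <= 17.0):
        raise GenerationError("require assoc_min < 11 < dissoc_plateau <= 17")
    if dissoc_plateau > 16.0:
        raise GenerationError("plateau must be reached by 16 Å for the ΔΔG rule")

    a, p = float(assoc_min), float(dissoc_plateau)

    def u(x):
        x = np.asarray(x, dtype=float)
        t = np.clip((x - a) / (p - a), 0.0, 1.0)
        step = t * t * t * (t * (6.0 * t - 15.0) + 10.0)  # C2 smootherstep
        bump = np.where(
            (t > 0.15) & (t < 0.85),
            np.sin(np.pi * (t - 0.15) / 0.7) ** 2,
            0.0,
        )
        wall = np.where(x < a, 0.5 * wall_k * (x - a) ** 2, 0.0)
        return ddg_target * step + barrier * bump + wall

    return ToyPotential(
        evaluator=u,
        analytic_pmf=u,
        domain=(a - 1.5, 18.0),
        ddg_target=float(ddg_target),
        assoc_min=a,
    )
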