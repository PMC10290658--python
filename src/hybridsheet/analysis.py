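"""Feature-vs-reaction-coordinate profiles, regime classification,
replicate statistics, the gap-distance structure survey, and a simplified
residue-wise interaction-energy decomposition (VDW + electrostatics; the
Poisson–Boltzmann polar-solvation term is deliberately absent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import FeatureSeries, gap_width, CatalyticSpec
from .structio import ResidueSelector, Structure

__all__ = [
    "BinnedProfile",
    "ResidueEnergyTable",
    "DecompositionConfig",
    "bin_by_rc",
    "classify_regime",
    "correlate_features",
    "aggregate_replicates",
    "survey_gap_distance",
    "residue_decomposition",
    "estimate_changepoint",
    "COULOMB_KCAL",
]

log = logging.getLogger(__name__)

#: Coulomb constant for q in e, r in Å, E in kcal/mol
COULOMB_KCAL = 332.0636


@dataclass
class BinnedProfile:
    """Per-bin means and standard errors of the features along the RC."""

    edges: np.ndarray  # length n_bins + 1; bins are [edge, edge+width)
    means: pd.DataFrame  # one row per bin, one column per feature
    stderrs: pd.DataFrame
    counts: np.ndarray
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    def to_dataframe(self) -> pd.DataFrame:
        out = self.means.add_prefix("mean_").join(self.stderrs.add_prefix("sem_"))
        out.insert(0, "rc_center_A", self.centers)
        out["n"] = self.counts
        return out


def bin_by_rc(
    series: FeatureSeries, lo: float = 7.0, hi: float = 18.0, width: float = 1.0
) -> BinnedProfile:
    """Bin per-frame features by reaction coordinate into [edge, edge+width) bins.

    The default 7–18 Å grid at 1 Å width gives 11 bins.  Samples outside
    [lo, hi) are dropped and the count logged.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if series.rc_values is None:
        raise ValueError("series has no reaction-coordinate values")
    rc = np.asarray(series.rc_values, dtype=float)
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    in_range = (rc >= lo) & (rc < hi)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        log.info("bin_by_rc: dropped %d of %d samples outside [%g, %g)", n_dropped, len(rc), lo, hi)
    if not in_range.any():
        raise ValueError("all samples fall outside the binning range")
    df = pd.DataFrame(
        {
            "active": series.active_flags.astype(float),
            "beta3": series.beta3_series,
            "n_waters": series.water_counts.astype(float),
        }
    )[in_range]
    idx = np.floor((rc[in_range] - lo) / width).astype(int)
    grouped = df.groupby(idx)
    all_bins = np.arange(n_bins)
    means = grouped.mean().reindex(all_bins)
    sems = grouped.sem(ddof=1).reindex(all_bins)
    counts = grouped.size().reindex(all_bins, fill_value=0).to_numpy()
    return BinnedProfile(edges=edges, means=means, stderrs=sems, counts=counts, n_dropped=n_dropped)


def classify_regime(rc: float) -> str:
    """Band along the association pathway: 'I' dissociated (RC > 16 Å),
    'II' transition (12 ≤ RC ≤ 16 Å), 'III' associated (RC < 12 Å)."""
    if not np.isfinite(rc):
        raise ValueError("rc must be finite")
    if rc > 16.0:
        return "I"
    if rc >= 12.0:
        return "II"
    return "III"


def correlate_features(a, b) -> float:
    """Pearson correlation between two aligned per-interval feature series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("series must be 1-D, equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and standard deviation of the mean across replicate scalars.

    sdm = sample standard deviation / √n; requires n ≥ 2 for the sdm
    (n = 1 yields mean with sdm = NaN).
    """
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("at least one replicate required")
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, float("nan")
    sdm = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    return mean, sdm


def survey_gap_distance(
    structures: list[tuple[str, Structure]],
    k380: ResidueSelector,
    l432: ResidueSelector,
) -> pd.DataFrame:
    """Cα–Cα gap-width survey over a set of identified structures.

    Entries whose anchor residues are missing are reported with status
    'unresolved' rather than raising (deposited structures frequently lack
    one of the anchors).
    """
    rows = []
    for ident, s in structures:
        spec_kwargs = dict(
            prot_asp=ResidueSelector("_", 1),
            deprot_asp=ResidueSelector("_", 2),
            scissile_c=ResidueSelector("_", 1, frozenset({"C"})),
            scissile_o=ResidueSelector("_", 1, frozenset({"O"})),
            anchor_k380=k380,
            anchor_l432=l432,
        )
        try:
            d = gap_width(s, CatalyticSpec(**spec_kwargs))
            rows.append({"id": ident, "status": "resolved", "distance_A": round(d, 2)})
        except Exception as exc:  # per-entry status, never a hard failure
            rows.append({"id": ident, "status": "unresolved", "distance_A": np.nan})
            log.info("survey: %s unresolved (%s)", ident, exc)
    return pd.DataFrame(rows, columns=["id", "status", "distance_A"])


# ---------------------------------------------------------------------------
# simplified residue-wise energy decomposition

#: generic per-element Lennard-Jones classes (σ in Å, ε in kcal/mol) and
#: point charges (e) for fixture-scale decompositions
_DEFAULT_LJ = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "H": (1.07, 0.0157),
    "S": (3.56, 0.250),
}
_DEFAULT_CHARGES = {"C": 0.35, "N": -0.40, "O": -0.50, "H": 0.15, "S": -0.10}


@dataclass
class DecompositionConfig:
    """Parameters of the simplified VDW + EEL decomposition.

    ``dielectric`` scales the implemented Coulomb term (default 1, gas
    phase).  ``solvent_dielectric`` and ``salt_molar`` are recorded for
    provenance only: they parameterise the polar-solvation term that this
    simplified decomposition intentionally omits.
    """

    dielectric: float = 1.0
    lj_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LJ)
    )
    charges: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CHARGES))
    averaging_window_ns: float = 5.0
    solvent_dielectric: float = 80.0  # metadata only (POL term out of scope)
    salt_molar: float = 0.15  # metadata only

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")
        for cls, (_, eps) in self.lj_params.items():
            if eps < 0:
                raise ValueError(f"negative ε for class {cls!r}")


class DecompositionError(ValueError):
    """Missing parameters or topology mismatch in the decomposition."""


@dataclass
class ResidueEnergyTable:
    """Per-substrate-residue interaction-energy differences vs. a reference.

    total = vdw + eel per residue; the polar-solvation (POL) contribution
    is explicitly absent from this simplified decomposition.
    """

    rows: pd.DataFrame  # index: register label; columns: vdw, eel, total
    reference_rc: float

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows.copy()


def _atom_params(cls: str, config: DecompositionConfig) -> tuple[float, float, float]:
    if cls not in config.lj_params or cls not in config.charges:
        raise DecompositionError(f"no LJ/charge parameters for atom class {cls!r}")
    sigma, eps = config.lj_params[cls]
    return sigma, eps, config.charges[cls]


def pair_interaction_energy(
    frame: Structure,
    group_a: list[ResidueSelector],
    group_b_atoms: list,
    config: DecompositionConfig,
) -> tuple[float, float]:
    """(VDW, EEL) between the atoms of ``group_a`` residues and ``group_b_atoms``.

    Lorentz–Berthelot combination (σ_ij arithmetic, ε_ij geometric) and
    Coulomb 332.0636·q_iq_j/(ε·r_ij).
    """
    atoms_a = [a for sel in group_a for a in frame.select(sel)]
    return _pair_energy_atoms(atoms_a, group_b_atoms, config)


def _pair_energy_atoms(atoms_a, atoms_b, config) -> tuple[float, float]:
    if not atoms_a or not atoms_b:
        return 0.0, 0.0
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([b.position for b in atoms_b])
    params_a = [_atom_params(a.element, config) for a in atoms_a]
    params_b = [_atom_params(b.element, config) for b in atoms_b]
    sig_a = np.array([p[0] for p in params_a])
    eps_a = np.array([p[1] for p in params_a])
    q_a = np.array([p[2] for p in params_a])
    sig_b = np.array([p[0] for p in params_b])
    eps_b = np.array([p[1] for p in params_b])
    q_b = np.array([p[2] for p in params_b])
    r = cdist(pa, pb)
    sig = (sig_a[:, None] + sig_b[None, :]) / 2.0
    eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
    sr6 = (sig / r) ** 6
    vdw = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    eel = float(np.sum(COULOMB_KCAL * q_a[:, None] * q_b[None, :] / (config.dielectric * r)))
    return vdw, eel


def _enzyme_atoms(frame: Structure, register: dict[str, ResidueSelector],
                  enzyme_chain: str, water_names) -> list:
    substrate_keys = {(s.chain_id, s.residue_number) for s in register.values()}
    return [
        a
        for a in frame.atoms
        if a.chain_id == enzyme_chain
        and a.residue_name not in water_names
        and (a.chain_id, a.residue_number) not in substrate_keys
    ]


def residue_decomposition(
    assoc_frames: list[Structure],
    ref_frames: list[Structure],
    register: dict[str, ResidueSelector],
    config: DecompositionConfig | None = None,
    enzyme_chain: str = "E",
    positions: tuple[str, ...] = ("P1p", "P2p", "P3p"),
    reference_rc: float = 16.0,
    water_names=frozenset({"HOH", "WAT", "TIP3", "SOL"}),
) -> ResidueEnergyTable:
    """ΔΔH decomposition: per-residue enzyme interaction energy, associated
    ensemble minus the dissociated reference ensemble.

    For each substrate register position the Lennard-Jones 12-6 plus
    Coulomb energy against all enzyme atoms is averaged over
    ``assoc_frames`` and over ``ref_frames`` (reference at the dissociated
    RC); the table holds the differences.  Unweighted per-frame means.
    """
    if config is None:
        config = DecompositionConfig()
    present = [p for p in positions if p in register]

    def ensemble_means(frames: list[Structure]) -> dict[str, tuple[float, float]]:
        sums = {p: np.zeros(2) for p in present}
        for frame in frames:
            enz = _enzyme_atoms(frame, register, enzyme_chain, water_names)
            for p in present:
                vdw, eel = pair_interaction_energy(frame, [register[p]], enz, config)
                sums[p] += (vdw, eel)
        return {p: tuple(sums[p] / max(len(frames), 1)) for p in present}

    assoc = ensemble_means(assoc_frames)
    ref = ensemble_means(ref_frames)
    rows = []
    for p in present:
        vdw = assoc[p][0] - ref[p][0]
        eel = assoc[p][1] - ref[p][1]
        rows.append({"position": p, "vdw": vdw, "eel": eel, "total": vdw + eel})
    df = pd.DataFrame(rows).set_index("position")
    return ResidueEnergyTable(rows=df, reference_rc=reference_rc)


def estimate_changepoint(series) -> int:
    """Index of the most likely single change point in a scalar series.

    Two-segment least squares: the split minimising the summed within-
    segment squared deviation from the segment means.  Returns the index of
    the first sample after the change.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("series too short for a change point")
    best_k, best_cost = 1, np.inf
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def sse(i, j):  # [i, j)
        m = j - i
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        return s2 - s * s / m

    for k in range(1, n):
        cost = sse(0, k) + sse(k, n)
        if cost < best_cost:
            best_cost, best_k = cost, k
    return int(best_k)
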