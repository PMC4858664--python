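"""Per-conformation geometric features.

Solvent-accessible surface area (Shrake-Rupley on a deterministic
golden-spiral lattice), relative exposure, backbone and chi1 dihedrals,
Kabsch-Sander beta-bridge assignment, and the collective variables used
as free-energy-surface axes: antiparallel/parallel beta content
(switching-function RMSD to internally built ideal two-strand templates)
and the AlphaBeta dihedral-similarity variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from . import _build
from ._geom import dihedral, rmsd
from .errors import ConfigError, InputError
from .structio import Structure

__all__ = [
    "MAX_SASA",
    "ExposureProfile",
    "DihedralSet",
    "SSAssignment",
    "CVValues",
    "SwitchingParams",
    "sphere_lattice",
    "shrake_rupley_sasa",
    "relative_exposure",
    "exposure_profile",
    "backbone_and_chi1_dihedrals",
    "alphabeta_cv",
    "kabsch_sander_bridges",
    "antibeta_cv",
    "parabeta_cv",
    "compute_cvs",
]

#: Maximum residue SASA (Angstrom^2) in a Gly-X-Gly tripeptide context
#: (Tien et al. 2013, theoretical values), used to normalize exposure.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: gamma atom completing the chi1 quadruplet N-CA-CB-gamma
_CHI1_GAMMA = _build.GAMMA_ATOM

#: side chains counted as hydrophobic for the AB collective variable
HYDROPHOBIC = frozenset("AVLIMFWC")

_KS_COUPLING = 27.888  # 0.084 * 332, kcal/mol * Angstrom
_HBOND_CUTOFF = -0.5  # kcal/mol


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n_points)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


def shrake_rupley_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's solvent sphere (radius r_atom + probe) is sampled on a
    deterministic golden-spiral lattice; a point is buried if it falls
    inside any neighbour's solvent sphere.  Returns ``(per_atom,
    per_residue)`` areas in Angstrom^2.  Hydrogens are excluded by
    default (crystal structures lack them and the radii table treats
    heavy atoms as united atoms).
    """
    if n_points < 32:
        raise ConfigError(f"n_points must be >= 32, got {n_points}")
    if probe_radius < 0:
        raise ConfigError("probe_radius must be >= 0")
    coords, radii, owner = structure.all_atom_coords()
    if not include_hydrogens:
        names_elements = [a.element for r in structure.residues for a in r.atoms]
        keep = np.array([el != "H" for el in names_elements])
        coords, radii, owner = coords[keep], radii[keep], owner[keep]
    n_atoms = coords.shape[0]
    ext = radii + probe_radius
    lattice = sphere_lattice(n_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    per_atom = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + ext[i] * lattice
        neighbours = tree.query_ball_point(coords[i], ext[i] + max_ext)
        neighbours = [j for j in neighbours if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        per_atom[i] = exposed.mean() * 4.0 * np.pi * ext[i] ** 2
    per_residue = np.zeros(len(structure.residues))
    np.add.at(per_residue, owner, per_atom)
    return per_atom, per_residue


def relative_exposure(
    residue_sasa: np.ndarray,
    residue_codes: str,
    max_sasa_table: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-residue exposure e_i = clamp(SASA_i / maxSASA(aa_i), 0, 1)."""
    table = max_sasa_table or MAX_SASA
    residue_sasa = np.asarray(residue_sasa, dtype=float)
    if len(residue_codes) != residue_sasa.shape[0]:
        raise InputError("SASA vector and residue codes differ in length")
    missing = sorted({c for c in residue_codes if c not in table})
    if missing:
        raise ConfigError(f"max-SASA table missing residues {missing}")
    max_vals = np.array([table[c] for c in residue_codes])
    return np.clip(residue_sasa / max_vals, 0.0, 1.0)


@lru_cache(maxsize=8)
def united_gxg_max_sasa(n_points: int = 960, probe_radius: float = 1.4) -> dict[str, float]:
    """Model-consistent max-SASA reference: each residue X measured in an
    extended Gly-X-Gly tripeptide built with the package's own
    united-atom (backbone + CB + pseudo-gamma) geometry.

    Use this instead of the full-side-chain Tien values when normalizing
    exposures of structures generated by the internal builder, so a
    fully exposed residue actually reaches e close to 1.
    """
    table = {}
    for aa in MAX_SASA:
        gxg = _build.build_chain(f"G{aa}G", _build.STRAND_PHI_PSI)
        _, per_res = shrake_rupley_sasa(gxg, probe_radius=probe_radius, n_points=n_points)
        table[aa] = float(per_res[1])
    return table


@dataclass
class ExposureProfile:
    """Absolute (Angstrom^2) and relative per-residue solvent exposure."""

    sasa: np.ndarray
    relative: np.ndarray


def exposure_profile(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    max_sasa_table: dict[str, float] | None = None,
) -> ExposureProfile:
    """SASA plus normalized exposure for one conformation."""
    _, per_res = shrake_rupley_sasa(structure, probe_radius, n_points)
    codes = "".join(r.code for r in structure.residues)
    return ExposureProfile(sasa=per_res, relative=relative_exposure(per_res, codes, max_sasa_table))


# ---------------------------------------------------------------------------
# Dihedrals and AlphaBeta CVs
# ---------------------------------------------------------------------------

@dataclass
class DihedralSet:
    """Backbone phi/psi and side-chain chi1 angles (radians; NaN = undefined)."""

    phi: np.ndarray
    psi: np.ndarray
    chi1: np.ndarray
    hydrophobic_chi1_mask: np.ndarray

    @property
    def backbone_angles(self) -> np.ndarray:
        """All defined phi and psi values, concatenated."""
        vals = np.concatenate([self.phi, self.psi])
        return vals[~np.isnan(vals)]

    @property
    def hydrophobic_chi1(self) -> np.ndarray:
        return self.chi1[self.hydrophobic_chi1_mask]


def backbone_and_chi1_dihedrals(structure: Structure) -> DihedralSet:
    """Standard IUPAC dihedrals per residue.

    The first residue's phi and the last residue's psi are undefined
    (NaN), as is any angle with a missing atom; chi1 is undefined for Gly
    and Ala.  The hydrophobic mask selects chi1-bearing hydrophobic side
    chains (V/L/I/M/F/W/C) whose chi1 could be computed.
    """
    n = len(structure.residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    chi1 = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    res = structure.residues
    for i, r in enumerate(res):
        a = {at.name: at.coords for at in r.atoms}
        if i > 0:
            prev_c = res[i - 1].atom("C")
            if prev_c is not None and all(k in a for k in ("N", "CA", "C")):
                phi[i] = dihedral(prev_c.coords, a["N"], a["CA"], a["C"])
        if i < n - 1:
            next_n = res[i + 1].atom("N")
            if next_n is not None and all(k in a for k in ("N", "CA", "C")):
                psi[i] = dihedral(a["N"], a["CA"], a["C"], next_n.coords)
        gamma = _CHI1_GAMMA.get(r.code)
        if gamma is not None and all(k in a for k in ("N", "CA", "CB", gamma)):
            chi1[i] = dihedral(a["N"], a["CA"], a["CB"], a[gamma])
            mask[i] = r.code in HYDROPHOBIC
    return DihedralSet(phi=phi, psi=psi, chi1=chi1, hydrophobic_chi1_mask=mask)


def alphabeta_cv(dihedral_values: np.ndarray, reference_values: np.ndarray) -> float:
    """AlphaBeta similarity: sum_k 1/2 [1 + cos(theta_k - theta_k^ref)].

    Bounded in [0, N]; N at perfect agreement, 0 when every angle is pi
    away; invariant to 2*pi wrapping.  NaN pairs (undefined angles) are
    excluded.
    """
    theta = np.asarray(dihedral_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if theta.shape != ref.shape:
        raise InputError(f"value/reference length mismatch: {theta.shape} vs {ref.shape}")
    ok = ~(np.isnan(theta) | np.isnan(ref))
    return float(np.sum(0.5 * (1.0 + np.cos(theta[ok] - ref[ok]))))


# ---------------------------------------------------------------------------
# Kabsch-Sander bridges
# ---------------------------------------------------------------------------

@dataclass
class SSAssignment:
    """Residue-level beta-bridge assignment.

    ``antiparallel`` / ``parallel`` map residue index (0-based) to the
    set of partner indices; ``beta`` flags residues in >= 1 bridge.
    """

    antiparallel: list[set[int]]
    parallel: list[set[int]]

    @property
    def beta(self) -> np.ndarray:
        return np.array(
            [bool(a) or bool(p) for a, p in zip(self.antiparallel, self.parallel)]
        )


def _hbond_matrix(structure: Structure) -> np.ndarray:
    """hb[i, j] = True when N-H of residue i donates to C=O of residue j.

    The amide H is reconstructed 1.0 A from N opposite the bisector of
    C(i-1)-N-CA (standard practice, crystal structures lack hydrogens).
    Residue 0 (no preceding C) and prolines (no amide H) never donate;
    incomplete residues are skipped in the roles their missing atoms
    serve.
    """
    n = len(structure.residues)
    hb = np.zeros((n, n), dtype=bool)
    res = structure.residues
    for i in range(1, n):
        if res[i].code == "P":
            continue
        ni, cai = res[i].atom("N"), res[i].atom("CA")
        prev_c = res[i - 1].atom("C")
        if ni is None or cai is None or prev_c is None:
            continue
        h = _build._amide_h(prev_c.coords, ni.coords, cai.coords)
        for j in range(n):
            if abs(i - j) < 2:
                continue
            cj, oj = res[j].atom("C"), res[j].atom("O")
            if cj is None or oj is None:
                continue
            e = _build._hb_energy(ni.coords, h, cj.coords, oj.coords)
            hb[i, j] = e < _HBOND_CUTOFF
    return hb


def kabsch_sander_bridges(structure: Structure) -> SSAssignment:
    """Beta-bridge assignment from backbone H-bond patterns.

    An H-bond exists when the Kabsch-Sander electrostatic energy
    0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) is below
    -0.5 kcal/mol.  Bridges between non-adjacent residues i, j
    (|i - j| >= 3) follow the Kabsch-Sander patterns: antiparallel when
    [Hb(i,j) and Hb(j,i)] or [Hb(i-1,j+1) and Hb(j-1,i+1)]; parallel
    when [Hb(i-1,j) and Hb(j,i+1)] or [Hb(j-1,i) and Hb(i,j+1)].
    The partner relation is symmetric by construction.
    """
    n = len(structure.residues)
    hb = _hbond_matrix(structure)
    anti: list[set[int]] = [set() for _ in range(n)]
    para: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 3, n):
            anti_bridge = (hb[i, j] and hb[j, i]) or (
                i >= 1 and j + 1 < n and hb[i - 1, j + 1] and hb[j - 1, i + 1]
            )
            para_bridge = (
                i >= 1 and i + 1 < n and hb[i - 1, j] and hb[j, i + 1]
            ) or (
                j + 1 < n and hb[j - 1, i] and hb[i, j + 1]
            )
            if anti_bridge:
                anti[i].add(j)
                anti[j].add(i)
            if para_bridge:
                para[i].add(j)
                para[j].add(i)
    return SSAssignment(antiparallel=anti, parallel=para)


# ---------------------------------------------------------------------------
# Segment-RMSD beta-content CVs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching S(r) = (1-(r/r0)^n) / (1-(r/r0)^m)."""

    r0: float = 1.0  # Angstrom
    n: int = 8
    m: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.n <= 0 or self.m <= self.n:
            raise ConfigError("switching requires r0 > 0 and m > n > 0")

    def __call__(self, r: float) -> float:
        x = r / self.r0
        if abs(x - 1.0) < 1e-9:
            return self.n / self.m
        return (1.0 - x**self.n) / (1.0 - x**self.m)


_TEMPLATE_ATOMS = ("N", "CA", "C", "O")


@lru_cache(maxsize=4)
def _pair_template(kind: str) -> np.ndarray:
    """(24, 3) ideal two-segment template from an optimized 5-residue pair.

    The middle three residues of each strand of the internally built
    H-bond-optimal pair are used, so the template carries the canonical
    registry without edge effects.
    """
    if kind == "antiparallel":
        a, b = _build.antiparallel_pair(5)
    else:
        a, b = _build.parallel_pair(5)
    coords = []
    for strand in (a, b):
        for res in strand.residues[1:4]:
            for name in _TEMPLATE_ATOMS:
                coords.append(res.atom(name).coords)
    return np.asarray(coords)


def _segment_coords(structure: Structure, start: int) -> np.ndarray | None:
    """(12, 3) backbone coords of residues start..start+2, or None."""
    out = []
    for res in structure.residues[start : start + 3]:
        for name in _TEMPLATE_ATOMS:
            a = res.atom(name)
            if a is None:
                return None
            out.append(a.coords)
    arr = np.asarray(out)
    # degenerate segments (coincident atoms) cannot be superposed
    if np.any(np.all(np.abs(arr - arr[0]) < 1e-9, axis=1) & (np.arange(12) > 0)):
        return None
    return arr


def _beta_content(structure: Structure, kind: str, switching: SwitchingParams) -> float:
    if len(structure.residues) < 6:
        raise InputError("beta-content CVs need at least 6 residues")
    template = _pair_template(kind)
    n = len(structure.residues)
    segments = {i: _segment_coords(structure, i) for i in range(n - 2)}
    total = 0.0
    for i in range(n - 5):
        si = segments.get(i)
        if si is None:
            continue
        for j in range(i + 3, n - 2):
            sj = segments.get(j)
            if sj is None:
                continue
            r = rmsd(np.vstack([si, sj]), template, superposition=True)
            total += switching(r)
    return float(total)


def antibeta_cv(structure: Structure, switching: SwitchingParams | None = None) -> float:
    """Antiparallel beta content: sum over non-overlapping 3-residue
    segment pairs of S(RMSD to the ideal antiparallel template)."""
    return _beta_content(structure, "antiparallel", switching or SwitchingParams())


def parabeta_cv(structure: Structure, switching: SwitchingParams | None = None) -> float:
    """Parallel beta content (same construction, parallel template)."""
    return _beta_content(structure, "parallel", switching or SwitchingParams())


# ---------------------------------------------------------------------------
# Combined CV evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVValues:
    """The four collective variables of one conformation."""

    beta: float  # antiparallel beta content
    pbeta: float  # parallel beta content
    ab: float  # AlphaBeta over hydrophobic chi1
    bbab: float  # AlphaBeta over all phi/psi


def compute_cvs(
    structure: Structure,
    reference: DihedralSet | None = None,
    switching: SwitchingParams | None = None,
) -> CVValues:
    """Evaluate all four CVs.

    ``reference`` supplies the AlphaBeta reference angles (typically the
    dihedrals of an ensemble's first conformation); when omitted the
    structure is its own reference, making AB and bbAB equal their upper
    bounds.
    """
    dih = backbone_and_chi1_dihedrals(structure)
    ref = reference if reference is not None else dih
    mask = dih.hydrophobic_chi1_mask & ref.hydrophobic_chi1_mask
    ab = alphabeta_cv(dih.chi1[mask], ref.chi1[mask])
    bbab = alphabeta_cv(
        np.concatenate([dih.phi, dih.psi]),
        np.concatenate([ref.phi, ref.psi]),
    )
    return CVValues(
        beta=antibeta_cv(structure, switching),
        pbeta=parabeta_cv(structure, switching),
        ab=ab,
        bbab=bbab,
    )
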