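"""Internal-coordinate construction of idealized peptide backbones.

Shared by the collective-variable templates (ideal two-strand
beta-pairings) and by the synthetic-structure generator.  Backbones are
grown atom by atom with the NeRF construction from one table of standard
bond lengths and angles; two-strand pairings are produced by rigidly
placing a second strand so that the canonical inter-strand hydrogen
bonds are optimal under the Kabsch-Sander energy.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from ._geom import place_atom
from .structio import Atom, Residue, Structure, Sequence

__all__ = [
    "BACKBONE_GEOMETRY",
    "STRAND_PHI_PSI",
    "HELIX_PHI_PSI",
    "build_chain",
    "strand_coords",
    "antiparallel_pair",
    "parallel_pair",
]

#: Standard backbone geometry (Engh-Huber-like): bond lengths in Angstrom,
#: angles in degrees.
BACKBONE_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "CA-CB": 1.521,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "N-CA-CB": 110.5,
    "C-N-CA-CB": 122.6,  # torsion placing CB off the backbone plane
    "CB-G": 1.52,
    "CA-CB-G": 114.0,
    "chi1": 180.0,  # trans gamma placement
}

#: gamma atom completing the chi1 quadruplet N-CA-CB-gamma, per residue
GAMMA_ATOM = {
    "R": "CG", "N": "CG", "D": "CG", "C": "SG", "Q": "CG", "E": "CG",
    "H": "CG", "I": "CG1", "L": "CG", "K": "CG", "M": "CG", "F": "CG",
    "P": "CG", "S": "OG", "T": "OG1", "W": "CG", "Y": "CG", "V": "CG1",
}

STRAND_PHI_PSI = (np.deg2rad(-139.0), np.deg2rad(135.0))
HELIX_PHI_PSI = (np.deg2rad(-57.0), np.deg2rad(-47.0))

_RAD = np.deg2rad


def build_chain(
    sequence: Sequence | str,
    phi_psi: tuple[float, float] | list[tuple[float, float]],
    omega: float = np.pi,
    structure_id: str = "built",
    with_cb: bool = True,
) -> Structure:
    """Grow a backbone (N, CA, C, O and CB except Gly) from dihedrals.

    ``phi_psi`` is either one (phi, psi) pair applied to every residue or
    a per-residue list (phi of the first residue and psi of the last are
    still consumed, the former only fixing the O placement convention).
    Dihedrals are recovered exactly (to numerical precision) by
    :func:`aggscape.structfeat.backbone_and_chi1_dihedrals`.
    """
    codes = sequence.residues if isinstance(sequence, Sequence) else str(sequence)
    n = len(codes)
    if isinstance(phi_psi, tuple):
        angles = [phi_psi] * n
    else:
        angles = list(phi_psi)
        if len(angles) != n:
            raise ValueError(f"need {n} (phi, psi) pairs, got {len(angles)}")

    g = BACKBONE_GEOMETRY
    coords_n = np.zeros((n, 3))
    coords_ca = np.zeros((n, 3))
    coords_c = np.zeros((n, 3))

    # first residue fixes the frame
    coords_n[0] = (0.0, 0.0, 0.0)
    coords_ca[0] = (g["N-CA"], 0.0, 0.0)
    alpha = np.pi - _RAD(g["N-CA-C"])
    coords_c[0] = coords_ca[0] + g["CA-C"] * np.array([np.cos(alpha), np.sin(alpha), 0.0])

    for i in range(1, n):
        psi_prev = angles[i - 1][1]
        phi_i = angles[i][0]
        coords_n[i] = place_atom(
            coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
            g["C-N"], _RAD(g["CA-C-N"]), psi_prev,
        )
        coords_ca[i] = place_atom(
            coords_ca[i - 1], coords_c[i - 1], coords_n[i],
            g["N-CA"], _RAD(g["C-N-CA"]), omega,
        )
        coords_c[i] = place_atom(
            coords_c[i - 1], coords_n[i], coords_ca[i],
            g["CA-C"], _RAD(g["N-CA-C"]), phi_i,
        )

    residues = []
    for i, code in enumerate(codes):
        psi_i = angles[i][1]
        o_coord = place_atom(
            coords_n[i], coords_ca[i], coords_c[i],
            g["C=O"], _RAD(g["CA-C-O"]), psi_i + np.pi,
        )
        atoms = [
            Atom("N", "N", coords_n[i]),
            Atom("CA", "C", coords_ca[i]),
            Atom("C", "C", coords_c[i]),
            Atom("O", "O", o_coord),
        ]
        if with_cb and code != "G":
            cb = place_atom(
                coords_c[i], coords_n[i], coords_ca[i],
                g["CA-CB"], _RAD(g["N-CA-CB"]), _RAD(g["C-N-CA-CB"]),
            )
            atoms.append(Atom("CB", "C", cb))
            gamma_name = GAMMA_ATOM.get(code)
            if gamma_name is not None:
                # pseudo gamma atom at trans chi1: coarse side-chain bulk
                # (and a defined chi1) without rotamer modelling
                gamma = place_atom(
                    coords_n[i], coords_ca[i], cb,
                    g["CB-G"], _RAD(g["CA-CB-G"]), _RAD(g["chi1"]),
                )
                element = "O" if gamma_name.startswith("O") else (
                    "S" if gamma_name.startswith("S") else "C")
                atoms.append(Atom(gamma_name, element, gamma))
        residues.append(Residue(index=i + 1, code=code, atoms=atoms))
    return Structure(id=structure_id, residues=residues)


def strand_coords(n_res: int) -> Structure:
    """Ideal extended beta-strand of ``n_res`` alanines."""
    return build_chain("A" * n_res, STRAND_PHI_PSI, structure_id="strand")


# ---------------------------------------------------------------------------
# Two-strand pairing by hydrogen-bond optimization
# ---------------------------------------------------------------------------

_KS_COUPLING = 27.888  # 0.084 * 332 kcal/mol * Angstrom, Kabsch-Sander


def _strand_arrays(struct: Structure):
    get = lambda name: np.array([r.atom(name).coords for r in struct.residues])
    return get("N"), get("CA"), get("C"), get("O")


def _amide_h(prev_c: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """H 1.0 A from N, opposite the bisector of C(i-1)-N-CA."""
    u = (prev_c - n) / np.linalg.norm(prev_c - n)
    v = (ca - n) / np.linalg.norm(ca - n)
    d = -(u + v)
    return n + d / np.linalg.norm(d)


def _hb_energy(n_d, h_d, c_a, o_a) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol)."""
    r_on = np.linalg.norm(o_a - n_d)
    r_ch = np.linalg.norm(c_a - h_d)
    r_oh = np.linalg.norm(o_a - h_d)
    r_cn = np.linalg.norm(c_a - n_d)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0  # clash, not a bond
    return _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _apply_rigid(coords: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Rotate (xyz Euler angles) about the centroid, then translate."""
    ax, ay, az, tx, ty, tz = params
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    centroid = coords.mean(axis=0)
    return (coords - centroid) @ rot.T + centroid + np.array([tx, ty, tz])


def _paired_strand(n_res: int, bonds: str) -> tuple[Structure, Structure]:
    """Build strand A and rigidly place strand B to optimize H-bonds.

    ``bonds`` selects the registry: "antiparallel" pairs residue i of A
    with residue n-1-i of B (both directions of the mutual H-bond pair),
    "parallel" uses the canonical offset registry.
    """
    a = strand_coords(n_res)
    b = strand_coords(n_res)
    n_a, ca_a, c_a, o_a = _strand_arrays(a)
    b_coords, _, _ = b.all_atom_coords()

    def donors_acceptors(bc: np.ndarray):
        # unpack transformed B coordinates back into per-residue arrays
        per_res = len(b.residues[0].atoms)
        names = [at.name for at in b.residues[0].atoms]
        idx = {nm: k for k, nm in enumerate(names)}
        arr = bc.reshape(n_res, per_res, 3)
        return arr[:, idx["N"]], arr[:, idx["CA"]], arr[:, idx["C"]], arr[:, idx["O"]]

    a_all, _, _ = a.all_atom_coords()

    def _bond_penalty(n_d, h_d, o_a_) -> float:
        # least-squares pull toward ideal H-bond geometry: N...O 2.9 A,
        # H...O 1.95 A (implies near-linear N-H...O)
        r_on = np.linalg.norm(o_a_ - n_d)
        r_oh = np.linalg.norm(o_a_ - h_d)
        return (r_on - 2.9) ** 2 + (r_oh - 1.95) ** 2

    def energy(params: np.ndarray) -> float:
        bc = _apply_rigid(b_coords, params)
        n_b, ca_b, c_b, o_b = donors_acceptors(bc)
        total = 0.0
        # canonical beta-ladder H-bonds alternate along the strand: mutual
        # ("narrow") pairs at every other rung; the intervening rungs are
        # bridged by the wide-pair pattern without direct bonds
        for i in range(1, n_res - 1, 2):
            if bonds == "antiparallel":
                j = n_res - 1 - i
                if not 1 <= j <= n_res - 1:
                    continue
                h_a = _amide_h(c_a[i - 1], n_a[i], ca_a[i])
                h_b = _amide_h(c_b[j - 1], n_b[j], ca_b[j])
                total += _bond_penalty(n_a[i], h_a, o_b[j])
                total += _bond_penalty(n_b[j], h_b, o_a[i])
        if bonds == "parallel":
            # rung i: Hb(A_{i-1} -> B_i) and Hb(B_i -> A_{i+1})
            for i in range(2, n_res - 1, 2):
                h_prev_a = _amide_h(c_a[i - 2], n_a[i - 1], ca_a[i - 1])
                total += _bond_penalty(n_a[i - 1], h_prev_a, o_b[i])
                h_b = _amide_h(c_b[i - 1], n_b[i], ca_b[i])
                if i + 1 <= n_res - 1:
                    total += _bond_penalty(n_b[i], h_b, o_a[i + 1])
        # steric repulsion between all inter-strand atom pairs
        d = np.linalg.norm(a_all[:, None, :] - bc[None, :, :], axis=-1)
        close = d < 2.4
        if np.any(close):
            total += 10.0 * np.sum((2.4 - d[close]) ** 2)
        # keep the optimizer in the intended topology: strand directions
        # must stay (anti)aligned
        dir_a = ca_a[-1] - ca_a[0]
        dir_b = ca_b[-1] - ca_b[0]
        cosang = np.dot(dir_a, dir_b) / (np.linalg.norm(dir_a) * np.linalg.norm(dir_b))
        target = -1.0 if bonds == "antiparallel" else 1.0
        total += 50.0 * (1.0 - target * cosang)
        return total

    if bonds == "antiparallel":
        x0 = np.array([0.0, 0.0, np.pi, 0.0, 4.9, 0.0])
    else:
        x0 = np.array([0.0, 0.0, 0.0, 1.7, 4.9, 0.0])
    best = None
    for dy in (-0.5, 0.0, 0.5):
        for dx in (-1.6, -0.8, 0.0, 0.8, 1.6):
            for dz in (-0.3, 0.0, 0.3):
                start = x0 + np.array([0, 0, dz, dx, dy, 0])
                res = minimize(energy, start, method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
                if best is None or res.fun < best.fun:
                    best = res
    placed = _apply_rigid(b_coords, best.x)
    per_res = len(b.residues[0].atoms)
    arr = placed.reshape(n_res, per_res, 3)
    for i, resd in enumerate(b.residues):
        for k, at in enumerate(resd.atoms):
            at.coords = arr[i, k]
    return a, b


@lru_cache(maxsize=8)
def antiparallel_pair(n_res: int = 3) -> tuple[Structure, Structure]:
    """Ideal antiparallel strand pair with canonical H-bond registry."""
    return _paired_strand(n_res, "antiparallel")


@lru_cache(maxsize=8)
def parallel_pair(n_res: int = 3) -> tuple[Structure, Structure]:
    """Ideal parallel strand pair with canonical H-bond registry."""
    return _paired_strand(n_res, "parallel")
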