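"""Core structural data model and file I/O.

Defines the containers shared by the whole pipeline — :class:`Sequence`,
:class:`Atom`, :class:`Residue`, :class:`Structure`, :class:`Ensemble` —
and readers/writers for the plain-text formats the pipeline exchanges:
multi-record FASTA, fixed-column PDB (including multi-MODEL ensembles and
altloc records), TSV profile tables and TSV per-conformation weight files.

Conventions
-----------
* Residues are re-indexed 1-based and contiguous per chain after parsing;
  the original PDB numbering is kept as metadata only, because all
  downstream bookkeeping (profiles, mutation sites, strand tables) works
  in sequence positions.
* Non-standard residues (MSE and friends) are rejected rather than
  silently mapped to a parent amino acid.
* Ensembles are exchanged as multi-MODEL PDB; binary trajectory formats
  are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import InputError, ConfigError

__all__ = [
    "CANONICAL_AA",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "ELEMENT_RADII",
    "Sequence",
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "read_fasta",
    "write_fasta",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "write_profile_table",
    "read_profile_table",
    "read_weights",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Bondi-type van der Waals radii (Angstrom) used for SASA.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

_BACKBONE = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Sequence:
    """An amino-acid sequence in one-letter code."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_AA:
                raise InputError(
                    f"sequence {self.id!r}: non-canonical residue {aa!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def mutate(self, site: int, new_aa: str) -> "Sequence":
        """Return a copy with the residue at 1-based ``site`` replaced."""
        if not 1 <= site <= len(self):
            raise InputError(f"site {site} outside sequence of length {len(self)}")
        if new_aa not in CANONICAL_AA:
            raise InputError(f"non-canonical substitution {new_aa!r}")
        res = self.residues[: site - 1] + new_aa + self.residues[site:]
        return Sequence(f"{self.id}_{self.residues[site - 1]}{site}{new_aa}", res)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    radius: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InputError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.radius is None:
            self.radius = ELEMENT_RADII.get(self.element)
        if self.radius is not None and self.radius <= 0:
            raise InputError(f"atom {self.name}: radius must be positive")


@dataclass
class Residue:
    """One amino-acid residue: 1-based chain position, code, ordered atoms."""

    index: int
    code: str
    atoms: list[Atom] = field(default_factory=list)
    pdb_number: int | None = None  # original author numbering, metadata only
    chain_id: str = "A"

    @property
    def resname(self) -> str:
        return ONE_TO_THREE[self.code]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_complete(self) -> bool:
        """True when all four backbone atoms N, CA, C, O are present."""
        return all(self.atom(n) is not None for n in _BACKBONE)


@dataclass
class Structure:
    """One conformation: an ordered residue list (a single chain after
    selection, or concatenated chains)."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"structure {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self, atom_name: str = "CA") -> np.ndarray:
        """(N, 3) coordinates of the named atom per residue; NaN rows where missing."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, res in enumerate(self.residues):
            a = res.atom(atom_name)
            if a is not None:
                out[i] = a.coords
        return out

    def all_atom_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (coords, radii, residue_index_per_atom) arrays."""
        coords, radii, owner = [], [], []
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                coords.append(a.coords)
                radii.append(a.radius if a.radius is not None else 1.7)
                owner.append(i)
        return np.asarray(coords), np.asarray(radii), np.asarray(owner, dtype=int)


@dataclass
class Ensemble:
    """Ordered conformations sharing one sequence, with normalized weights."""

    conformations: list[Structure]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.conformations:
            raise InputError("ensemble must contain at least one conformation")
        seqs = {extract_sequence(s).residues for s in self.conformations}
        if len(seqs) != 1:
            raise InputError("ensemble conformations have differing residue composition")
        n = len(self.conformations)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (n,):
                raise InputError(
                    f"expected {n} weights, got {w.shape}"
                )
            if np.any(w < 0) or not np.all(np.isfinite(w)):
                raise InputError("weights must be finite and non-negative")
            total = w.sum()
            if total <= 0:
                raise InputError("weights sum to zero")
            self.weights = w / total

    def __len__(self) -> int:
        return len(self.conformations)

    @property
    def sequence(self) -> Sequence:
        return extract_sequence(self.conformations[0])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a multi-record FASTA file into validated :class:`Sequence` objects.

    Whitespace and digits inside the sequence body are stripped and case is
    normalized to upper before validation against the canonical 20-letter
    alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        body = "".join(str(rec.seq).split()).upper()
        body = "".join(ch for ch in body if not ch.isdigit())
        out.append(Sequence(rec.id, body))
    return out


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

#: Modified amino acids that must not be silently dropped with the HETATMs.
_MODIFIED_AA = {"MSE", "SEC", "PYL", "SEP", "TPO", "PTR", "CSO", "HYP", "MLY"}


def read_pdb(
    path: str | Path,
    model_policy: str = "all",
    chain: str | None = None,
) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an :class:`Ensemble`.

    Parameters
    ----------
    model_policy:
        ``"all"`` keeps every MODEL (uniform weights); ``"first"`` keeps
        only the first.
    chain:
        Chain identifier to keep.  Default: the first chain encountered.

    Altloc records are resolved to the highest-occupancy alternative
    (ties broken by file order, Biopython's policy); waters and ligand
    HETATMs are dropped; modified amino acids (MSE etc.) raise instead
    of being silently remapped; residues missing backbone atoms are kept
    but flagged incomplete so downstream operations can refuse or skip
    them.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"PDB file not found: {path}")
    if model_policy not in ("first", "all"):
        raise ConfigError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_struct = parser.get_structure(path.stem, str(path))
    models = list(bio_struct.get_models())
    if not models:
        raise InputError(f"no ATOM records in {path}")
    if model_policy == "first":
        models = models[:1]

    structures = []
    for m_i, model in enumerate(models, start=1):
        chains = list(model.get_chains())
        if not chains:
            raise InputError(f"{path.name} model {m_i}: no chains")
        target_chain = chain if chain is not None else chains[0].id
        matching = [c for c in chains if c.id == target_chain]
        if not matching:
            raise InputError(f"{path.name} model {m_i}: chain {target_chain!r} not found")
        residues: list[Residue] = []
        for bio_res in matching[0].get_residues():
            hetfield, resseq, _icode = bio_res.id
            resname = bio_res.get_resname().strip()
            if hetfield == "W":
                continue
            if resname in _MODIFIED_AA:
                raise InputError(
                    f"{path.name} model {m_i}: non-standard residue "
                    f"{resname} {resseq} (chain {target_chain})"
                )
            if hetfield != " ":
                continue  # ligand HETATM
            if resname not in THREE_TO_ONE:
                raise InputError(
                    f"{path.name} model {m_i}: non-standard residue "
                    f"{resname} {resseq} (chain {target_chain})"
                )
            res = Residue(
                index=len(residues) + 1,
                code=THREE_TO_ONE[resname],
                pdb_number=resseq,
                chain_id=target_chain,
            )
            # iterating a disordered atom yields its selected (highest
            # occupancy, ties -> first in file) altloc only
            for bio_atom in bio_res.get_atoms():
                occ = bio_atom.get_occupancy()
                res.atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or bio_atom.get_name()[:1]).strip(),
                        coords=np.asarray(bio_atom.get_coord(), dtype=float),
                        occupancy=1.0 if occ is None else float(occ),
                    )
                )
            residues.append(res)
        if not residues:
            raise InputError(f"{path.name} model {m_i}: chain {target_chain!r} empty")
        structures.append(Structure(id=f"{path.stem}#{m_i}", residues=residues))
    return Ensemble(conformations=structures)


def write_pdb(obj: Structure | Ensemble, path: str | Path) -> None:
    """Write a structure or ensemble as fixed-column (multi-MODEL) PDB."""
    if isinstance(obj, Structure):
        ens = Ensemble(conformations=[obj])
    else:
        ens = obj
    multi = len(ens) > 1
    with open(path, "w") as fh:
        for m_i, struct in enumerate(ens.conformations, start=1):
            if multi:
                fh.write(f"MODEL     {m_i:4d}\n")
            serial = 0
            for res in struct.residues:
                for a in res.atoms:
                    serial += 1
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    fh.write(
                        f"ATOM  {serial:5d} {name:4s} {res.resname:3s} "
                        f"{res.chain_id:1s}{res.index:4d}    "
                        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                        f"{a.occupancy:6.2f}{0.0:6.2f}          "
                        f"{a.element:>2s}\n"
                    )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def extract_sequence(structure: Structure) -> Sequence:
    """One-letter sequence of a structure, in residue order."""
    return Sequence(structure.id, "".join(r.code for r in structure.residues))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_profile_table(profile, path: str | Path) -> None:
    """Serialize a per-residue profile as TSV (columns index, code, score).

    Scores are written with 6 decimals so a read-back reproduces them to
    1e-6.
    """
    values = np.asarray(profile.values, dtype=float)
    seq = profile.sequence
    if values.size == 0:
        raise InputError("refusing to write an empty profile")
    if values.shape[0] != len(seq):
        raise InputError("profile length does not match its sequence")
    df = pd.DataFrame(
        {
            "index": np.arange(1, len(seq) + 1),
            "code": list(seq.residues),
            "score": [f"{v:.6f}" for v in values],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read back a profile TSV written by :func:`write_profile_table`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"profile table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"index", "code", "score"}
    if not required.issubset(df.columns):
        raise InputError(f"profile table {path} missing columns {required - set(df.columns)}")
    return df


def read_weights(path: str | Path, n_expected: int | None = None) -> np.ndarray:
    """Read a per-conformation weight file (one weight per line, order-matched)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"weight file not found: {path}")
    values = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line.split()[0]))
        except ValueError as exc:
            raise InputError(f"{path}:{ln}: not a number: {line!r}") from exc
    w = np.asarray(values, dtype=float)
    if n_expected is not None and w.shape[0] != n_expected:
        raise InputError(f"{path}: expected {n_expected} weights, found {w.shape[0]}")
    if np.any(w < 0):
        raise InputError(f"{path}: weights must be non-negative")
    return w
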