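"""File I/O and the core structural data model."""

import numpy as np
import pytest

from aggscape import (
    AggProfile,
    Ensemble,
    InputError,
    Sequence,
    extract_sequence,
    intrinsic_profile,
    read_fasta,
    read_pdb,
    read_profile_table,
    read_weights,
    write_pdb,
    write_profile_table,
)
from aggscape.synthgen import SynthSpec, build_chain, make_sequence
from aggscape._build import STRAND_PHI_PSI


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "body, expected",
    [(">x\nACDE\n", "ACDE"), (">x\nacde\n", "ACDE"), (">x\nAC DE\n12\n", "ACDE")],
)
def test_fasta_parsing_normalizes_case_and_whitespace(tmp_path, body, expected):
    p = tmp_path / "in.fasta"
    p.write_text(body)
    seqs = read_fasta(p)
    assert len(seqs) == 1
    assert seqs[0].id == "x"
    assert seqs[0].residues == expected


def test_fasta_rejects_noncanonical_letter_with_position(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">y\nBCDE\n")
    with pytest.raises(InputError, match="position 1"):
        read_fasta(p)


def test_fasta_empty_file_is_a_format_error(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(InputError):
        read_fasta(p)


def test_sequence_mutate_is_positional_and_validated():
    s = Sequence("s", "ACDE")
    assert s.mutate(2, "W").residues == "AWDE"
    with pytest.raises(InputError):
        s.mutate(0, "W")
    with pytest.raises(InputError):
        s.mutate(1, "B")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _write_ensemble(tmp_path, n_models=3, name="ens.pdb"):
    spec = SynthSpec(seed=5, length=12, hotspots=((5, 7),))
    seq = make_sequence(spec)
    confs = []
    rng = np.random.default_rng(0)
    for k in range(n_models):
        s = build_chain(seq, STRAND_PHI_PSI, structure_id=f"m{k}")
        for res in s.residues:
            for a in res.atoms:
                a.coords = a.coords + rng.normal(0, 0.1, 3)
        confs.append(s)
    ens = Ensemble(conformations=confs)
    path = tmp_path / name
    write_pdb(ens, path)
    return ens, path


def test_multimodel_roundtrip_preserves_counts_and_coords(tmp_path):
    ens, path = _write_ensemble(tmp_path)
    back = read_pdb(path, model_policy="all")
    assert len(back) == 3
    np.testing.assert_allclose(back.weights, 1.0 / 3.0)
    for orig, got in zip(ens.conformations, back.conformations):
        assert got.n_atoms == orig.n_atoms
        assert len(got.residues) == len(orig.residues)
        np.testing.assert_allclose(
            got.coords("CA"), orig.coords("CA"), atol=1e-3
        )
    # a second write/read cycle is stable
    write_pdb(back, tmp_path / "again.pdb")
    again = read_pdb(tmp_path / "again.pdb")
    np.testing.assert_allclose(
        again.conformations[0].coords("CA"), back.conformations[0].coords("CA"),
        atol=1e-3,
    )


def test_model_policy_first_keeps_one_conformation(tmp_path):
    _, path = _write_ensemble(tmp_path)
    assert len(read_pdb(path, model_policy="first")) == 1


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N",
        "ATOM      2  N  BALA A   1       9.000   9.000   9.000  0.40  0.00           N",
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
        "END",
    ]
    p = tmp_path / "altloc.pdb"
    p.write_text("\n".join(lines) + "\n")
    struct = read_pdb(p).conformations[0]
    np.testing.assert_allclose(struct.residues[0].atom("N").coords, [0, 0, 0])


def test_waters_and_ligands_dropped_but_mse_rejected(tmp_path):
    base = [
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O",
        "HETATM    5  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O",
    ]
    p = tmp_path / "waters.pdb"
    p.write_text("\n".join(base + ["END"]) + "\n")
    struct = read_pdb(p).conformations[0]
    assert extract_sequence(struct).residues == "G"

    mse = base + [
        "HETATM    6  N   MSE A   2       3.000   1.000   0.000  1.00  0.00           N",
        "END",
    ]
    p2 = tmp_path / "mse.pdb"
    p2.write_text("\n".join(mse) + "\n")
    with pytest.raises(InputError, match="MSE"):
        read_pdb(p2)


def test_extract_sequence_in_residue_order():
    s = build_chain("ACDEF", STRAND_PHI_PSI)
    assert extract_sequence(s).residues == "ACDEF"


def test_ensemble_requires_identical_composition():
    a = build_chain("ACDEF", STRAND_PHI_PSI)
    b = build_chain("ACDEW", STRAND_PHI_PSI)
    with pytest.raises(InputError):
        Ensemble(conformations=[a, b])


def test_ensemble_weight_normalization_is_idempotent():
    a = build_chain("ACDEF", STRAND_PHI_PSI)
    ens = Ensemble(conformations=[a, a, a], weights=np.array([2.0, 2.0, 4.0]))
    np.testing.assert_allclose(ens.weights.sum(), 1.0)
    ens2 = Ensemble(conformations=[a, a, a], weights=ens.weights)
    np.testing.assert_allclose(ens2.weights, ens.weights)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def test_profile_table_roundtrip_to_6_decimals(tmp_path, rng):
    seq = Sequence("p", "ACDEFGHIKL")
    prof = AggProfile(sequence=seq, values=rng.normal(size=10))
    path = tmp_path / "prof.tsv"
    write_profile_table(prof, path)
    df = read_profile_table(path)
    assert list(df.columns) == ["index", "code", "score"]
    assert len(df) == 10
    assert np.max(np.abs(df["score"].to_numpy() - prof.values)) < 1e-6


def test_empty_profile_refused(tmp_path):
    seq = Sequence("p", "AC")
    prof = intrinsic_profile(seq)
    prof.values = np.array([])
    with pytest.raises(InputError):
        write_profile_table(prof, tmp_path / "x.tsv")


def test_weights_file_parsing(tmp_path):
    p = tmp_path / "w.tsv"
    p.write_text("# comment\n1.0\n2.0\n3.0\n")
    w = read_weights(p, n_expected=3)
    np.testing.assert_allclose(w, [1.0, 2.0, 3.0])
    with pytest.raises(InputError):
        read_weights(p, n_expected=2)
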