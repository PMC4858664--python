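"""Geometric features: SASA, dihedrals, bridges, collective variables."""

import numpy as np
import pytest

from aggscape import (
    ConfigError,
    Sequence,
    alphabeta_cv,
    antibeta_cv,
    backbone_and_chi1_dihedrals,
    build_chain,
    kabsch_sander_bridges,
    parabeta_cv,
    relative_exposure,
    shrake_rupley_sasa,
)
from aggscape.structio import Atom, Residue, Structure
from aggscape.structfeat import MAX_SASA, SwitchingParams, _pair_template, _TEMPLATE_ATOMS
from aggscape._build import STRAND_PHI_PSI, HELIX_PHI_PSI
from aggscape._geom import dihedral
from conftest import random_coil


def _atom_cluster(coords, radius=1.7):
    res = Residue(index=1, code="A",
                  atoms=[Atom(f"C{i}", "C", c) for i, c in enumerate(coords)])
    return Structure(id="cluster", residues=[res])


def _mc_sasa(coords, radii, probe, n_samples, rng):
    """Independent Monte-Carlo point-sampling SASA oracle."""
    coords = np.asarray(coords, float)
    ext = np.asarray(radii) + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + ext[i] * v
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.sum((pts - coords[j]) ** 2, axis=1) > ext[j] ** 2
        areas[i] = exposed.mean() * 4 * np.pi * ext[i] ** 2
    return areas


class TestSASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = _atom_cluster([[0.0, 0.0, 0.0]])
        per_atom, per_res = shrake_rupley_sasa(s, probe_radius=1.4, n_points=960)
        analytic = 4 * np.pi * 3.1**2
        assert per_atom[0] == pytest.approx(analytic, rel=1e-9)
        assert per_res[0] == per_atom[0]

    def test_distant_atoms_do_not_occlude(self):
        s = _atom_cluster([[0.0, 0, 0], [10.0, 0, 0]])
        per_atom, _ = shrake_rupley_sasa(s, n_points=960)
        analytic = 4 * np.pi * 3.1**2
        np.testing.assert_allclose(per_atom, analytic, rtol=1e-9)

    def test_atom_inside_a_shell_is_fully_buried(self, rng):
        # dense shell of neighbours 3 A out occludes the whole sphere
        shell = rng.normal(size=(80, 3))
        shell = 3.0 * shell / np.linalg.norm(shell, axis=1)[:, None]
        s = _atom_cluster(np.vstack([[0.0, 0, 0], shell]))
        per_atom, _ = shrake_rupley_sasa(s, n_points=960)
        assert per_atom[0] == 0.0

    def test_rigid_motion_near_invariance(self, rng):
        # the lattice is space-fixed, so rotation invariance is only
        # approximate; the residual must be small relative to the areas
        # (~100 A^2 per residue here) and shrink as the lattice densifies
        coords = rng.normal(scale=3.0, size=(20, 3))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = coords @ rot.T + np.array([5.0, -3.0, 2.0])
        devs = []
        for n in (240, 3840):
            _, base = shrake_rupley_sasa(_atom_cluster(coords), n_points=n)
            _, turned = shrake_rupley_sasa(_atom_cluster(moved), n_points=n)
            devs.append(abs(base[0] - turned[0]))
        assert devs[-1] < 0.01 * base[0]
        assert devs[-1] < devs[0]

    def test_total_area_converges_with_lattice_density(self, rng):
        coords = rng.normal(scale=3.0, size=(15, 3))
        s = _atom_cluster(coords)
        totals = [shrake_rupley_sasa(s, n_points=n)[0].sum() for n in (96, 192, 384, 960)]
        ref = totals[-1]
        errors = [abs(t - ref) for t in totals[:-1]]
        assert errors[0] >= errors[-1]  # denser lattice is closer
        assert errors[-1] / ref < 0.01

    def test_agrees_with_monte_carlo_oracle(self, rng):
        coords = rng.normal(scale=3.0, size=(20, 3))
        per_atom, _ = shrake_rupley_sasa(_atom_cluster(coords), n_points=960)
        oracle = _mc_sasa(coords, np.full(20, 1.7), 1.4, 40000, rng)
        total, ototal = per_atom.sum(), oracle.sum()
        assert abs(total - ototal) / ototal < 0.01

    def test_accuracy_floor_on_point_count(self):
        with pytest.raises(ConfigError):
            shrake_rupley_sasa(_atom_cluster([[0.0, 0, 0]]), n_points=16)


class TestRelativeExposure:
    def test_clamped_ratio(self):
        e = relative_exposure(np.array([0.0, MAX_SASA["A"], 1.2 * MAX_SASA["C"]]), "AAC")
        np.testing.assert_allclose(e, [0.0, 1.0, 1.0])

    def test_missing_table_entry_is_a_config_error(self):
        with pytest.raises(ConfigError):
            relative_exposure(np.array([1.0]), "A", {"G": 104.0})


class TestDihedrals:
    def test_builder_roundtrip_recovers_angles(self):
        s = build_chain("AVLF", STRAND_PHI_PSI)
        dih = backbone_and_chi1_dihedrals(s)
        np.testing.assert_allclose(dih.phi[1:], STRAND_PHI_PSI[0], atol=1e-6)
        np.testing.assert_allclose(dih.psi[:-1], STRAND_PHI_PSI[1], atol=1e-6)
        assert np.isnan(dih.phi[0]) and np.isnan(dih.psi[-1])

    def test_glycine_and_alanine_have_no_chi1(self):
        s = build_chain("GAV", STRAND_PHI_PSI)
        dih = backbone_and_chi1_dihedrals(s)
        assert np.isnan(dih.chi1[0]) and np.isnan(dih.chi1[1])
        assert not np.isnan(dih.chi1[2])

    def test_single_residue_chain_has_no_backbone_dihedrals(self):
        s = build_chain("A", STRAND_PHI_PSI)
        dih = backbone_and_chi1_dihedrals(s)
        assert np.isnan(dih.phi[0]) and np.isnan(dih.psi[0])

    def test_hydrophobic_mask_excludes_polar_chi1(self):
        s = build_chain("VSLT", STRAND_PHI_PSI)
        dih = backbone_and_chi1_dihedrals(s)
        assert dih.hydrophobic_chi1_mask.tolist() == [True, False, True, False]


class TestAlphaBeta:
    def test_reference_gives_n(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 10)
        assert alphabeta_cv(theta, theta) == pytest.approx(10.0)

    def test_pi_offsets_give_zero(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 7)
        assert alphabeta_cv(theta + np.pi, theta) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_offset_contributes_half(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 10)
        shifted = theta.copy()
        shifted[0] += np.pi / 2
        assert alphabeta_cv(shifted, theta) == pytest.approx(9.5)

    def test_wrap_invariance(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 50)
        ref = rng.uniform(-np.pi, np.pi, 50)
        wrapped = theta + 2 * np.pi * rng.integers(-3, 4, size=50)
        assert alphabeta_cv(wrapped, ref) == pytest.approx(alphabeta_cv(theta, ref))

    def test_bounded_in_zero_n(self, rng):
        theta = rng.uniform(-20, 20, 30)
        ref = rng.uniform(-20, 20, 30)
        val = alphabeta_cv(theta, ref)
        assert 0.0 <= val <= 30.0


class TestBridges:
    def test_hairpin_interior_residues_form_antiparallel_ladder(self, hairpin):
        ss = kabsch_sander_bridges(hairpin)
        pairs = sorted((i, j) for i, p in enumerate(ss.antiparallel) for j in p if i < j)
        # 5 per strand + 2-residue linker: interior rungs (n-2 per strand)
        assert pairs == [(1, 10), (2, 9), (3, 8)]
        assert sum(len(p) for p in ss.parallel) == 0

    def test_longer_hairpin_gains_one_bridge_per_added_rung(self, hairpin7):
        ss = kabsch_sander_bridges(hairpin7)
        n_bridges = sum(len(p) for p in ss.antiparallel) // 2
        assert n_bridges == 5
        interior = list(range(1, 6)) + list(range(10, 15))
        assert all(ss.beta[i] for i in interior)

    def test_helix_has_no_beta_bridges(self, helix):
        assert kabsch_sander_bridges(helix).beta.sum() == 0

    def test_isolated_strand_has_no_bridges(self, extended):
        assert kabsch_sander_bridges(extended).beta.sum() == 0

    def test_partner_relation_symmetric_on_random_fixtures(self, rng):
        for _ in range(25):
            coil = random_coil(14, rng)
            ss = kabsch_sander_bridges(coil)
            for rel in (ss.antiparallel, ss.parallel):
                for i, partners in enumerate(rel):
                    for j in partners:
                        assert i in rel[j]


class TestBetaContentCV:
    def test_template_pair_scores_exactly_one(self):
        coords = _pair_template("antiparallel")
        residues = []
        k = 0
        for i in range(6):
            atoms = [Atom(nm, nm[0], coords[k + a]) for a, nm in enumerate(_TEMPLATE_ATOMS)]
            k += len(_TEMPLATE_ATOMS)
            residues.append(Residue(index=i + 1, code="A", atoms=atoms))
        s = Structure(id="tmpl", residues=residues)
        assert antibeta_cv(s) == pytest.approx(1.0)

    def test_extended_chain_scores_near_zero(self, extended):
        assert antibeta_cv(extended) < 0.05
        assert parabeta_cv(extended) < 0.05

    def test_hairpin_dominates_helix_in_antiparallel_content(self, hairpin, helix):
        assert antibeta_cv(hairpin) > 5 * antibeta_cv(helix)

    def test_hairpin_has_little_parallel_content(self, hairpin):
        assert parabeta_cv(hairpin) < 0.2 * antibeta_cv(hairpin)

    def test_switching_function_limits(self):
        s = SwitchingParams(r0=1.0, n=8, m=12)
        assert s(0.0) == pytest.approx(1.0)
        assert s(1.0) == pytest.approx(8 / 12)
        assert s(5.0) == pytest.approx(5.0 ** (8 - 12), rel=0.05)  # r^(n-m) tail

    def test_too_short_chain_rejected(self):
        s = build_chain("AAAAA", STRAND_PHI_PSI)
        from aggscape import InputError

        with pytest.raises(InputError):
            antibeta_cv(s)
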