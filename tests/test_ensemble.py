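"""Structural correction, ensemble averaging, populations, RMSF, FES."""

import copy

import numpy as np
import pytest

from aggscape import (
    Ensemble,
    InputError,
    KernelParams,
    build_chain,
    build_hairpin,
    build_helix,
    corrected_profile,
    ensemble_average_profile,
    extract_sequence,
    fes_from_samples,
    intrinsic_profile,
    marginalize_fes,
    rmsf_profile,
    strand_beta_populations,
)
from aggscape.ensemble import KB_KJ_PER_MOL_K
from aggscape._build import STRAND_PHI_PSI


@pytest.fixture(scope="module")
def chain_and_profile():
    struct = build_chain("STGVILFVSTGSTSTG", STRAND_PHI_PSI)
    seq = extract_sequence(struct)
    return struct, intrinsic_profile(seq)


class TestCorrectedProfile:
    def test_full_exposure_and_narrow_kernel_recover_intrinsic(self, chain_and_profile):
        struct, intr = chain_and_profile
        kern = KernelParams(sigma_d=1e-9, cutoff=8.0)
        corr = corrected_profile(intr, struct, kern, exposure=np.ones(len(intr)))
        np.testing.assert_allclose(corr.values, intr.values, atol=1e-9)

    def test_buried_residue_scores_zero(self, chain_and_profile):
        struct, intr = chain_and_profile
        e = np.ones(len(intr))
        e[4] = 0.0
        corr = corrected_profile(intr, struct, exposure=e)
        assert corr.values[4] == 0.0

    def test_burial_lowers_hot_spot_monotonically(self, chain_and_profile):
        struct, intr = chain_and_profile
        hot = slice(3, 8)
        peaks = []
        for level in (1.0, 0.5, 0.1):
            e = np.ones(len(intr))
            e[hot] = level
            corr = corrected_profile(intr, struct, exposure=e)
            peaks.append(corr.values[hot].max())
        assert peaks[0] > peaks[1] > peaks[2]

    def test_bounded_by_exposure_times_max_intrinsic(self, chain_and_profile, rng):
        struct, intr = chain_and_profile
        e = rng.uniform(0, 1, len(intr))
        corr = corrected_profile(intr, struct, exposure=e)
        bound = e * np.max(np.abs(intr.values))
        assert np.all(np.abs(corr.values) <= bound + 1e-12)

    def test_sequence_mismatch_rejected(self, chain_and_profile):
        struct, _ = chain_and_profile
        other = intrinsic_profile(extract_sequence(build_chain("AAAA", STRAND_PHI_PSI)))
        with pytest.raises(InputError):
            corrected_profile(other, struct)


class TestEnsembleAverage:
    def test_identical_conformations_have_zero_se(self, chain_and_profile):
        struct, intr = chain_and_profile
        ens = Ensemble(conformations=[copy.deepcopy(struct) for _ in range(4)])
        kern = KernelParams(sasa_points=128)
        _, scores = ensemble_average_profile(ens, intr, kern)
        assert scores.se == pytest.approx(0.0, abs=1e-12)

    def test_single_conformation_flagged(self, chain_and_profile):
        struct, intr = chain_and_profile
        ens = Ensemble(conformations=[struct])
        _, scores = ensemble_average_profile(ens, intr, KernelParams(sasa_points=128))
        assert scores.single_conformation and scores.se == 0.0

    def test_mean_total_equals_total_of_mean_profile(self, chain_and_profile, rng):
        struct, intr = chain_and_profile
        confs = []
        for k in range(5):
            c = copy.deepcopy(struct)
            for res in c.residues:
                for a in res.atoms:
                    a.coords = a.coords + rng.normal(0, 0.4, 3)
            confs.append(c)
        ens = Ensemble(conformations=confs, weights=rng.uniform(0.5, 2.0, 5))
        avg, scores = ensemble_average_profile(ens, intr, KernelParams(sasa_points=128))
        assert scores.mean == pytest.approx(avg.total, abs=1e-12)
        assert min(scores.per_conformation) <= scores.mean <= max(scores.per_conformation)


class TestStrandPopulations:
    def test_hairpin_strands_fully_beta(self, hairpin7):
        ens = Ensemble(conformations=[hairpin7])
        pops = strand_beta_populations(ens, [("S1", 2, 6), ("S2", 11, 15)])
        np.testing.assert_allclose(pops.populations, 1.0)

    def test_helix_strands_zero(self, helix):
        ens = Ensemble(conformations=[helix])
        pops = strand_beta_populations(ens, [("H", 2, 10)])
        np.testing.assert_allclose(pops.populations, 0.0)

    def test_mixed_ensemble_averages_populations(self, hairpin7):
        seq = extract_sequence(hairpin7)
        unfolded = build_chain(seq, STRAND_PHI_PSI)
        ens = Ensemble(conformations=[hairpin7, unfolded])
        pops = strand_beta_populations(ens, [("S1", 2, 6)])
        assert pops.populations[0] == pytest.approx(0.5)

    def test_overlapping_strands_rejected(self, hairpin7):
        ens = Ensemble(conformations=[hairpin7])
        with pytest.raises(InputError):
            strand_beta_populations(ens, [("a", 1, 5), ("b", 5, 9)])


class TestRMSF:
    def test_duplicated_conformation_gives_zero(self, extended):
        ens = Ensemble(conformations=[extended, copy.deepcopy(extended)])
        np.testing.assert_allclose(rmsf_profile(ens), 0.0, atol=1e-9)

    def test_rigid_rotation_cancelled_by_superposition(self, extended):
        rotated = copy.deepcopy(extended)
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        for res in rotated.residues:
            for a in res.atoms:
                a.coords = rot @ a.coords + np.array([3.0, -1.0, 7.0])
        ens = Ensemble(conformations=[extended, rotated])
        np.testing.assert_allclose(rmsf_profile(ens), 0.0, atol=1e-6)

    def test_planted_wobble_elevates_only_the_loop(self, rng):
        base = build_chain("A" * 30, STRAND_PHI_PSI)
        confs = []
        for k in range(8):
            c = copy.deepcopy(base)
            shift = rng.normal(0, 1.0, 3)
            for res in c.residues[12:15]:
                for a in res.atoms:
                    a.coords = a.coords + shift
            confs.append(c)
        ens = Ensemble(conformations=confs)
        rmsf = rmsf_profile(ens)
        background = np.concatenate([rmsf[:10], rmsf[20:]])
        assert rmsf[12:15].min() > 2 * background.max()

    def test_requires_two_conformations(self, extended):
        with pytest.raises(InputError):
            rmsf_profile(Ensemble(conformations=[extended]))


class TestFES:
    def test_uniform_two_bins_flat_surface(self):
        samples = np.array([[0.25], [0.75]] * 50)
        fes = fes_from_samples(samples, [np.array([0.0, 0.5, 1.0])])
        np.testing.assert_allclose(fes.free_energy, 0.0, atol=1e-12)

    def test_e_to_one_ratio_gives_kbt(self):
        n1 = 2718
        n0 = 1000
        samples = np.concatenate([np.full(n1, 0.25), np.full(n0, 0.75)])[:, None]
        fes = fes_from_samples(samples, [np.array([0.0, 0.5, 1.0])], temperature=310.0)
        expected = KB_KJ_PER_MOL_K * 310.0 * np.log(n1 / n0)
        assert fes.free_energy[0] == 0.0
        assert fes.free_energy[1] == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(2.578, abs=2e-3)

    def test_uniform_weight_rescaling_is_invariant(self, rng):
        samples = rng.uniform(0, 1, (500, 2))
        edges = [np.linspace(0, 1, 6)] * 2
        w = rng.uniform(0.1, 1.0, 500)
        a = fes_from_samples(samples, edges, weights=w)
        b = fes_from_samples(samples, edges, weights=7.7 * w)
        np.testing.assert_allclose(a.free_energy, b.free_energy, equal_nan=True)

    def test_single_occupied_bin_is_a_valid_surface(self):
        samples = np.full((10, 1), 0.2)
        fes = fes_from_samples(samples, [np.array([0.0, 0.5, 1.0])])
        assert fes.free_energy[0] == 0.0
        assert np.isinf(fes.free_energy[1])

    def test_out_of_range_samples_counted(self):
        samples = np.array([[0.2], [0.8], [1.7]])
        fes = fes_from_samples(samples, [np.array([0.0, 0.5, 1.0])])
        assert fes.n_outside == 1


class TestMarginalization:
    def test_separable_samples_match_direct_1d(self, rng):
        x = rng.normal(0.0, 1.0, 4000)
        y = rng.normal(0.0, 2.0, 4000)
        samples = np.column_stack([x, y])
        ex = np.linspace(-4, 4, 9)
        ey = np.linspace(-8, 8, 9)
        fes2 = fes_from_samples(samples, [ex, ey], axes=("x", "y"))
        marg = marginalize_fes(fes2, ["x"])
        direct = fes_from_samples(x[:, None], [ex], axes=("x",))
        ok = np.isfinite(marg.free_energy) & np.isfinite(direct.free_energy)
        assert np.allclose(marg.free_energy[ok], direct.free_energy[ok], atol=1e-9)

    def test_keep_all_axes_is_identity(self, rng):
        samples = rng.uniform(0, 1, (200, 2))
        fes = fes_from_samples(samples, [np.linspace(0, 1, 5)] * 2, axes=("a", "b"))
        same = marginalize_fes(fes, ["a", "b"])
        np.testing.assert_allclose(same.free_energy, fes.free_energy, equal_nan=True)

    def test_dropping_single_bin_axis_preserves_values(self, rng):
        samples = np.column_stack([rng.uniform(0, 1, 300), np.full(300, 0.5)])
        fes = fes_from_samples(
            samples, [np.linspace(0, 1, 6), np.array([0.0, 1.0])], axes=("a", "b")
        )
        marg = marginalize_fes(fes, ["a"])
        np.testing.assert_allclose(
            marg.free_energy, fes.free_energy[:, 0], equal_nan=True, atol=1e-12
        )

    def test_empty_keep_set_rejected(self, rng):
        samples = rng.uniform(0, 1, (50, 1))
        fes = fes_from_samples(samples, [np.linspace(0, 1, 4)], axes=("a",))
        with pytest.raises(InputError):
            marginalize_fes(fes, [])
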