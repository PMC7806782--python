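"""Dihedral extraction, MI estimation, normalisation and coupling reports."""
import numpy as np
import pytest

from tandemrrm.coupling import (
    DihedralEnsemble,
    compute_dihedrals,
    coupling_report,
    mutual_information,
    residue_mi_matrix,
    shuffle_null,
)
from tandemrrm.errors import ValidationError
from tandemrrm.structures import DomainDefinition
from tandemrrm.synthetic import (
    TrajectorySpec,
    build_backbone,
    gen_correlated_angles,
    gen_trajectory,
)
from tandemrrm.trajectory import TrajectoryEnsemble


def backbone_ensemble(phi, psi, n_copies=2, start=1):
    coords = build_backbone(phi, psi)
    coords = np.repeat(coords, n_copies, axis=0)
    n_res = phi.shape[1]
    topo = tuple((start + i, n) for i in range(n_res) for n in ("N", "CA", "C"))
    return TrajectoryEnsemble(replicas=[coords], topology=topo)


class TestComputeDihedrals:
    def test_roundtrip_of_planted_torsions(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-170, 170, (5, 6))
        psi = rng.uniform(-170, 170, (5, 6))
        ens = backbone_ensemble(phi, psi, n_copies=1)
        dih = compute_dihedrals(ens)
        for r in range(2, 7):
            np.testing.assert_allclose(dih.angles[(r, "phi")], phi[:, r - 1], atol=5e-4)
        for r in range(1, 6):
            np.testing.assert_allclose(dih.angles[(r, "psi")], psi[:, r - 1], atol=5e-4)

    def test_terminal_torsions_omitted(self):
        phi = np.full((2, 4), -63.0)
        psi = np.full((2, 4), -42.0)
        dih = compute_dihedrals(backbone_ensemble(phi, psi, n_copies=1))
        assert (1, "phi") not in dih.angles
        assert (4, "psi") not in dih.angles
        assert (2, "phi") in dih.angles and (1, "psi") in dih.angles

    def test_extended_chain_is_trans(self):
        phi = np.full((1, 5), 180.0)
        psi = np.full((1, 5), 180.0)
        dih = compute_dihedrals(backbone_ensemble(phi, psi, n_copies=2))
        for key, arr in dih.angles.items():
            assert np.abs(np.abs(arr) - 180.0).max() < 1e-3, key

    def test_mirror_image_negates_torsions(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(-150, 150, (3, 5))
        psi = rng.uniform(-150, 150, (3, 5))
        ens = backbone_ensemble(phi, psi, n_copies=1)
        mirrored = [rep * np.array([1.0, 1.0, -1.0]) for rep in ens.replicas]
        ens_m = TrajectoryEnsemble(replicas=mirrored, topology=ens.topology)
        d, dm = compute_dihedrals(ens), compute_dihedrals(ens_m)
        for key in d.angles:
            np.testing.assert_allclose(dm.angles[key], -d.angles[key], atol=1e-3)

    def test_missing_backbone_atom_rejected(self):
        topo = ((1, "N"), (1, "CA"), (2, "N"), (2, "CA"), (2, "C"))
        reps = [np.random.default_rng(2).normal(size=(3, 5, 3))]
        with pytest.raises(ValidationError, match="backbone atom C"):
            compute_dihedrals(TrajectoryEnsemble(replicas=reps, topology=topo))

    def test_collinear_atoms_rejected(self):
        topo = tuple((r, n) for r in (1, 2) for n in ("N", "CA", "C"))
        coords = np.zeros((2, 6, 3))
        coords[:, :, 0] = np.arange(6)  # all atoms on the x axis
        with pytest.raises(ValidationError, match="collinear"):
            compute_dihedrals(TrajectoryEnsemble(replicas=[coords], topology=topo))


class TestMutualInformation:
    def test_self_information_of_uniform_series(self):
        x, _ = gen_correlated_angles(20000, 0.0, seed=3)
        mi = mutual_information(x, x, bin_count=24)
        assert mi == pytest.approx(np.log(24), rel=0.02)

    def test_symmetry_exact(self):
        x, y = gen_correlated_angles(2000, 0.5, seed=4)
        assert mutual_information(x, y, bin_count=12) == mutual_information(y, x, bin_count=12)

    def test_independent_series_near_zero_after_correction(self):
        x, y = gen_correlated_angles(10000, 0.0, seed=5)
        mi = mutual_information(x, y, bias_correction="shuffle", seed=6)
        _, null_sd = shuffle_null(x, y, seed=6)
        assert abs(mi) < 3.0 * null_sd + 1e-4

    def test_copula_closed_form(self):
        x, y = gen_correlated_angles(50000, 0.8, seed=7)
        mi = mutual_information(x, y, bias_correction="shuffle", seed=8)
        assert mi == pytest.approx(-0.5 * np.log(1 - 0.8**2), rel=0.10)

    def test_uncorrected_mi_nonnegative(self):
        x, y = gen_correlated_angles(5000, 0.3, seed=9)
        assert mutual_information(x, y, bin_count=18) >= 0.0

    def test_coarser_binning_does_not_inflate_mi(self):
        x, y = gen_correlated_angles(30000, 0.7, seed=10)
        fine = mutual_information(x, y, bin_count=24, bias_correction="shuffle", seed=1)
        coarse = mutual_information(x, y, bin_count=8, bias_correction="shuffle", seed=1)
        assert coarse <= fine + 0.02

    @pytest.mark.parametrize("kwargs, err", [
        (dict(bin_count=1), "bin_count"),
        (dict(bias_correction="jackknife"), "bias_correction"),
    ])
    def test_bad_arguments_rejected(self, kwargs, err):
        x, y = gen_correlated_angles(1000, 0.0, seed=11)
        with pytest.raises((ValidationError, ValueError), match=err):
            mutual_information(x, y, bin_count=kwargs.get("bin_count", 2),
                               bias_correction=kwargs.get("bias_correction", "none"))

    def test_length_and_sample_size_guards(self):
        x, y = gen_correlated_angles(100, 0.0, seed=12)
        with pytest.raises(ValidationError, match="samples"):
            mutual_information(x, y, bin_count=24)
        with pytest.raises(ValidationError, match="equal-length"):
            mutual_information(x, y[:-1], bin_count=2)


class TestResidueMatrix:
    def _dih(self, series_map, n=3000):
        return DihedralEnsemble(angles={k: v for k, v in series_map.items()})

    def test_copied_series_give_normalized_one(self):
        x, _ = gen_correlated_angles(3000, 0.0, seed=13)
        y, _ = gen_correlated_angles(3000, 0.0, seed=14)
        dih = self._dih({(1, "phi"): x, (1, "psi"): y, (2, "phi"): x, (2, "psi"): y})
        mi = residue_mi_matrix(dih, bias_correction="none")
        assert mi.normalized[0, 1] == pytest.approx(1.0, abs=0.05)
        assert mi.normalized[0, 0] == 1.0  # self-coupling convention

    def test_independent_residues_stay_below_threshold(self):
        rng_series = [gen_correlated_angles(3000, 0.0, seed=20 + i)[0] for i in range(8)]
        angles = {}
        for r in range(4):
            angles[(r + 1, "phi")] = rng_series[2 * r]
            angles[(r + 1, "psi")] = rng_series[2 * r + 1]
        mi = residue_mi_matrix(self._dih(angles), seed=15)
        off = mi.normalized[~np.eye(4, dtype=bool)]
        assert off.max() < 0.3

    def test_symmetry_and_range(self):
        angles = {}
        for r in range(3):
            angles[(r + 1, "phi")], angles[(r + 1, "psi")] = gen_correlated_angles(
                2000, 0.4, seed=30 + r
            )
        mi = residue_mi_matrix(self._dih(angles), seed=16)
        np.testing.assert_allclose(mi.normalized, mi.normalized.T)
        np.testing.assert_allclose(mi.raw, mi.raw.T)
        assert mi.normalized.min() >= 0.0 and mi.normalized.max() <= 1.0

    def test_planted_pairs_recovered_in_trajectory(self):
        spec = TrajectorySpec(n_residues=40, start_residue=1, domain1=(2, 18),
                              domain2=(22, 39), n_replicas=2, n_frames=400,
                              jitter_sd=0.0, torsion_noise_sd=12.0,
                              coupled_residues=((10, 30),), copula_rho=0.9, seed=17)
        ens, _ = gen_trajectory(spec)
        mi = residue_mi_matrix(compute_dihedrals(ens), seed=18)
        report = coupling_report(mi, spec.domains, threshold=0.3)
        found = {(i, j) for i, j, _ in report.pairs}
        assert found == {(10, 30)}
        assert report.classes[(10, 30)] == "inter-domain"


class TestCouplingReport:
    def _matrix(self, entries, residues):
        m = len(residues)
        normalized = np.zeros((m, m))
        np.fill_diagonal(normalized, 1.0)
        for (i, j), v in entries.items():
            a, b = residues.index(i), residues.index(j)
            normalized[a, b] = normalized[b, a] = v
        from tandemrrm.coupling import MIMatrix

        return MIMatrix(residue_numbers=list(residues), raw=normalized.copy(),
                        normalized=normalized, bin_count=24, bias_corrected=True)

    def test_empty_report_flags_undefined_ratio(self):
        mi = self._matrix({}, [1, 2, 30, 31])
        rep = coupling_report(mi, (DomainDefinition("RRM1", 1, 10),
                                   DomainDefinition("RRM2", 25, 40)))
        assert rep.pairs == []
        assert rep.inter_intra_ratio is None

    def test_classification_of_each_pair_kind(self):
        residues = [1, 2, 15, 30, 31]
        mi = self._matrix({(1, 2): 0.5, (30, 31): 0.6, (1, 30): 0.7, (15, 30): 0.4},
                          residues)
        rep = coupling_report(mi, (DomainDefinition("RRM1", 1, 10),
                                   DomainDefinition("RRM2", 25, 40)))
        assert rep.classes[(1, 2)] == "intra-RRM1"
        assert rep.classes[(30, 31)] == "intra-RRM2"
        assert rep.classes[(1, 30)] == "inter-domain"
        assert rep.classes[(15, 30)] == "linker-involving"

    def test_equal_strength_classes_give_unit_ratio(self):
        mi = self._matrix({(1, 2): 0.5, (30, 31): 0.5, (1, 30): 0.5}, [1, 2, 30, 31])
        rep = coupling_report(mi, (DomainDefinition("RRM1", 1, 10),
                                   DomainDefinition("RRM2", 25, 40)))
        assert rep.inter_intra_ratio == pytest.approx(1.0)

    def test_overlapping_domains_rejected(self):
        mi = self._matrix({}, [1, 2, 3])
        with pytest.raises(ValidationError, match="overlap"):
            coupling_report(mi, (DomainDefinition("RRM1", 1, 10),
                                 DomainDefinition("RRM2", 5, 20)))
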