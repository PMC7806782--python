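"""RMSD series, RMSF profiles and the delta-RMSF significance rule."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_ca_ensemble
from tandemrrm.errors import ValidationError
from tandemrrm.structures import DomainDefinition
from tandemrrm.synthetic import TrajectorySpec, gen_trajectory
from tandemrrm.trajectory import (
    RmsfProfile,
    delta_rmsf,
    domain_overlay_rmsd,
    read_trajectory_pdb,
    rmsd_series,
    rmsf_profile,
    write_trajectory_pdb,
)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, static_ensemble):
        series = rmsd_series(static_ensemble)
        assert series.mean == pytest.approx(0.0, abs=1e-12)
        assert all(np.allclose(s, 0.0) for s in series.per_replica)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 20, (15, 3))
        frames = []
        for _ in range(6):
            rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            frames.append(ref @ rot.T + rng.normal(size=3) * 5)
        ens = make_ca_ensemble([np.array(frames)])
        assert rmsd_series(ens).mean == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_jitter_closed_form(self):
        """Clean reference frame + jittered frames: E[RMSD] ~ sqrt(3)*sigma."""
        rng = np.random.default_rng(1)
        sigma = 0.5
        ref = rng.uniform(0, 50, (200, 3))
        frames = np.concatenate(
            [ref[None], ref[None] + rng.normal(0, sigma, (400, 200, 3))]
        )
        ens = make_ca_ensemble([frames])
        series = rmsd_series(ens)
        vals = series.pooled()[1:]  # skip the zero reference frame
        assert vals.mean() == pytest.approx(np.sqrt(3) * sigma, rel=0.03)

    def test_pooled_mean_is_frameweighted_replica_mean(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(0, 20, (10, 3))
        r1 = np.concatenate([ref[None], ref[None] + rng.normal(0, 0.3, (4, 10, 3))])
        r2 = np.concatenate([ref[None], ref[None] + rng.normal(0, 0.9, (9, 10, 3))])
        series = rmsd_series(make_ca_ensemble([r1, r2]))
        means = [s.mean() for s in series.per_replica]
        weights = [s.size for s in series.per_replica]
        assert series.mean == pytest.approx(np.average(means, weights=weights), abs=1e-12)

    def test_empty_selection_rejected(self, static_ensemble):
        with pytest.raises(ValidationError, match="selection"):
            rmsd_series(static_ensemble, residue_range=(900, 950))


class TestDomainOverlay:
    def test_hinge_moves_full_but_not_domains(self):
        spec = TrajectorySpec(n_residues=60, start_residue=1, domain1=(3, 25),
                              domain2=(35, 58), n_replicas=2, n_frames=80,
                              jitter_sd=0.05, torsion_noise_sd=0.0,
                              hinge_amplitude=12.0, seed=3)
        ens, _ = gen_trajectory(spec)
        d1, d2 = spec.domains
        full = rmsd_series(ens)
        dom = max(domain_overlay_rmsd(ens, d1).mean, domain_overlay_rmsd(ens, d2).mean)
        assert full.mean > 3.0 * dom

    def test_identical_frames_zero(self, static_ensemble):
        dom = DomainDefinition("d", 1, 8)
        assert domain_overlay_rmsd(static_ensemble, dom).mean == pytest.approx(0.0, abs=1e-12)


class TestRmsf:
    def test_static_trajectory_exactly_zero(self, static_ensemble):
        prof = rmsf_profile(static_ensemble)
        assert all(v == 0.0 for v in prof.values.values())

    def test_isotropic_jitter_closed_form(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 50, (150, 3))
        sigma = 0.5
        frames = ref[None] + rng.normal(0, sigma, (1200, 150, 3))
        prof = rmsf_profile(make_ca_ensemble([frames]))
        vals = np.array(list(prof.values.values()))
        assert vals.mean() == pytest.approx(np.sqrt(3) * sigma, rel=0.03)

    def test_replica_average_is_mean_of_profiles(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0, 50, (60, 3))
        r1 = ref[None] + rng.normal(0, 0.2, (500, 60, 3))
        r2 = ref[None] + rng.normal(0, 0.6, (500, 60, 3))
        prof = rmsf_profile(make_ca_ensemble([r1, r2]))
        for r in prof.values:
            manual = np.mean([prof.per_replica[0][r], prof.per_replica[1][r]])
            assert prof.values[r] == pytest.approx(manual, abs=1e-12)
        # each replica's level tracks its own jitter scale
        m1 = np.mean(list(prof.per_replica[0].values()))
        m2 = np.mean(list(prof.per_replica[1].values()))
        assert m1 == pytest.approx(np.sqrt(3) * 0.2, rel=0.05)
        assert m2 == pytest.approx(np.sqrt(3) * 0.6, rel=0.05)

    def test_rmsf_equals_covariance_trace_oracle(self):
        """RMSF_i^2 == trace of atom i's positional covariance after fitting."""
        rng = np.random.default_rng(6)
        ref = rng.uniform(0, 10, (8, 3))
        frames = ref[None] + rng.normal(0, 0.4, (40, 8, 3))
        ens = make_ca_ensemble([frames])
        prof = rmsf_profile(ens)
        from tandemrrm._geometry import fit_frames_to_reference

        fitted = fit_frames_to_reference(frames, frames[0])
        mean_structure = fitted.mean(axis=0)
        fitted = fit_frames_to_reference(frames, mean_structure)
        dev = fitted - fitted.mean(axis=0)
        for i, r in enumerate(sorted(prof.values)):
            cov = np.cov(dev[:, i, :].T, bias=True)
            assert prof.values[r] == pytest.approx(np.sqrt(np.trace(cov)), rel=1e-9)

    def test_global_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(0, 20, (20, 3))
        frames = ref[None] + rng.normal(0, 0.3, (50, 20, 3))
        rot = Rotation.from_rotvec([1.0, -0.4, 2.2]).as_matrix()
        moved = frames @ rot.T + np.array([10.0, -5.0, 3.0])
        p1 = rmsf_profile(make_ca_ensemble([frames]))
        p2 = rmsf_profile(make_ca_ensemble([moved]))
        for r in p1.values:
            assert p1.values[r] == pytest.approx(p2.values[r], abs=1e-9)
        s1 = rmsd_series(make_ca_ensemble([frames]))
        s2 = rmsd_series(make_ca_ensemble([moved]))
        assert s1.mean == pytest.approx(s2.mean, abs=1e-9)


class TestDeltaRmsf:
    def _profiles(self, n=40, bump_at=None):
        base = {i: 1.0 for i in range(1, n + 1)}
        teth = {i: 2.0 for i in range(1, n + 1)}
        if bump_at is not None:
            teth[bump_at] = 4.0
        return (
            RmsfProfile(values=teth),
            RmsfProfile(values={i: base[i] for i in base if i <= n // 2}),
            RmsfProfile(values={i: base[i] for i in base if i > n // 2}),
        )

    def test_identical_profiles_select_nothing(self):
        p = RmsfProfile(values={i: 1.5 for i in range(1, 21)})
        d1, d2 = DomainDefinition("RRM1", 1, 10), DomainDefinition("RRM2", 11, 20)
        res = delta_rmsf(p, RmsfProfile(values=p.values), RmsfProfile(values=p.values), (d1, d2))
        assert all(v == 0.0 for v in res.delta.values())
        assert res.selected == set()

    def test_single_bump_selected_by_mean_plus_sd(self):
        teth, iso1, iso2 = self._profiles(40, bump_at=7)
        d1, d2 = DomainDefinition("RRM1", 1, 20), DomainDefinition("RRM2", 21, 40)
        res = delta_rmsf(teth, iso1, iso2, (d1, d2))
        deltas = np.array(list(res.delta.values()))
        assert res.threshold == pytest.approx(deltas.mean() + deltas.std(ddof=1))
        assert res.selected == {7}

    def test_linker_residues_reported_separately(self):
        teth = RmsfProfile(values={i: 1.0 for i in range(1, 31)})
        iso1 = RmsfProfile(values={i: 0.5 for i in range(1, 13)})
        iso2 = RmsfProfile(values={i: 0.5 for i in range(18, 31)})
        d1, d2 = DomainDefinition("RRM1", 1, 12), DomainDefinition("RRM2", 18, 30)
        res = delta_rmsf(teth, iso1, iso2, (d1, d2))
        assert set(res.outside_domains) == set(range(13, 18))
        assert not (res.selected & set(range(13, 18)))

    def test_coverage_gap_rejected(self):
        teth = RmsfProfile(values={i: 1.0 for i in range(1, 21)})
        iso1 = RmsfProfile(values={i: 0.5 for i in range(1, 9)})  # missing 9, 10
        iso2 = RmsfProfile(values={i: 0.5 for i in range(11, 21)})
        d1, d2 = DomainDefinition("RRM1", 1, 10), DomainDefinition("RRM2", 11, 20)
        with pytest.raises(ValidationError, match="missing"):
            delta_rmsf(teth, iso1, iso2, (d1, d2))


class TestTrajectoryIO:
    def test_multi_model_roundtrip(self, tmp_path):
        spec = TrajectorySpec(n_residues=12, start_residue=1, domain1=(1, 5),
                              domain2=(7, 12), n_replicas=2, n_frames=4,
                              jitter_sd=0.2, torsion_noise_sd=0.0, seed=8)
        ens, _ = gen_trajectory(spec)
        paths = []
        for i, rep in enumerate(ens.replicas):
            p = tmp_path / f"rep{i}.pdb"
            write_trajectory_pdb(rep, ens.topology, p)
            paths.append(p)
        back = read_trajectory_pdb(paths)
        assert back.topology == ens.topology
        for a, b in zip(back.replicas, ens.replicas):
            np.testing.assert_allclose(a, b, atol=1.5e-3)  # PDB stores 3 decimals
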