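"""Analysis suite vs closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macroioncg.analysis import (FitWindowError, GeometryError,
                                 MissingChannelError, ShellLimitError,
                                 UndefinedAxisError, cluster_aggregates,
                                 compute_msd, compute_rdf,
                                 coordination_number, diffusion_coefficient,
                                 energy_distance_profile,
                                 macroion_force_series,
                                 mean_first_neighbor_count,
                                 radial_projection)
from macroioncg.system import SP_SOLVENT
from macroioncg.trajectory import Frame, Trajectory


def _traj(frames_positions, box, species=None, mol=None, charges=None,
          times=None, **frame_kwargs):
    n = len(frames_positions[0])
    species = np.full(n, SP_SOLVENT, np.int8) if species is None else species
    mol = np.full(n, -1, np.int32) if mol is None else mol
    charges = np.zeros(n) if charges is None else charges
    frames = []
    for k, pos in enumerate(frames_positions):
        t = float(k) if times is None else times[k]
        kw = {key: (val[k] if isinstance(val, list) else val)
              for key, val in frame_kwargs.items()}
        frames.append(Frame(box=box, time=t, positions=np.asarray(pos, float),
                            images=np.zeros((n, 3), np.int32), **kw))
    return Trajectory(species=species, mol=mol, charges=charges,
                      frames=frames)


class TestRDF:
    def test_ideal_gas_is_flat_unity(self, rng):
        n, box = 1000, 50.0
        traj = _traj([rng.random((n, 3)) * box for _ in range(10)], box)
        rdf = compute_rdf(traj, "solvent", bin_width=0.5)
        mask = rdf.r > 1.0  # first bins have few ideal-gas counts
        assert np.abs(rdf.g[mask] - 1.0).max() < 0.1

    def test_two_fixed_particles_single_bin(self):
        box = 100.0
        pos = [[[10.0, 50, 50], [22.0, 50, 50]]] * 5
        traj = _traj(pos, box)
        rdf = compute_rdf(traj, "solvent", bin_width=0.5, r_max=30.0)
        nz = np.flatnonzero(rdf.g > 0)
        assert len(nz) == 1
        assert rdf.r[nz[0]] == pytest.approx(12.0, abs=0.5)

    def test_simple_cubic_peaks_at_lattice_shells(self):
        # lattice oracle: shells at a and a*sqrt(2)
        a, nc, = 10.0, 5
        grid = np.array([[i, j, k] for i in range(nc) for j in range(nc)
                         for k in range(nc)], dtype=float) * a
        traj = _traj([grid], box=nc * a)
        rdf = compute_rdf(traj, "solvent", bin_width=0.5, r_max=20.0)
        peaks = np.flatnonzero(rdf.g > 1.0)
        assert rdf.r[peaks[0]] == pytest.approx(a, abs=0.5)
        assert rdf.r[peaks[1]] == pytest.approx(a * np.sqrt(2), abs=0.5)

    def test_r_max_beyond_half_box_rejected(self, rng):
        traj = _traj([rng.random((10, 3)) * 20], box=20.0)
        with pytest.raises(GeometryError):
            compute_rdf(traj, "solvent", r_max=15.0)


class TestCoordination:
    def test_ideal_gas_closed_form(self, rng):
        n, box = 1000, 50.0
        traj = _traj([rng.random((n, 3)) * box for _ in range(10)], box)
        rdf = compute_rdf(traj, "solvent", bin_width=0.5)
        expected = 4.0 / 3.0 * np.pi * 10.0 ** 3 * (n / box ** 3)
        assert coordination_number(rdf, r_limit=10.0) == \
            pytest.approx(expected, rel=0.03)

    def test_simple_cubic_first_shell_is_six(self):
        a, nc = 10.0, 5
        grid = np.array([[i, j, k] for i in range(nc) for j in range(nc)
                         for k in range(nc)], dtype=float) * a
        traj = _traj([grid], box=nc * a)
        rdf = compute_rdf(traj, "solvent", bin_width=0.25, r_max=20.0)
        # integrate just past the first shell (direct pair-count oracle: 6)
        assert coordination_number(rdf, r_limit=12.0) == \
            pytest.approx(6.0, rel=0.02)

    def test_isolated_dimer_counts_one_neighbor(self):
        box = 200.0
        pos = [[[90.0, 100, 100], [117.0, 100, 100]]] * 20
        traj = _traj(pos, box)
        rdf = compute_rdf(traj, "solvent", bin_width=0.5, r_max=60.0)
        assert coordination_number(rdf, r_limit=30.0) == \
            pytest.approx(1.0, abs=0.05)

    def test_auto_limit_requires_a_minimum(self):
        # a lone contact pair: g(r) is identically zero in the search
        # window, so there is no local minimum to find
        box = 200.0
        pos = [[[90.0, 100, 100], [102.0, 100, 100]]] * 5
        traj = _traj(pos, box)
        rdf = compute_rdf(traj, "solvent", bin_width=0.5, r_max=60.0)
        with pytest.raises(ShellLimitError):
            coordination_number(rdf, r_limit="auto",
                                search_window=(25.0, 50.0))


class TestMSD:
    def test_static_frames_give_zero(self):
        pos = [[[1.0, 2, 3], [4.0, 5, 6]]] * 10
        traj = _traj(pos, box=50.0)
        msd = compute_msd(traj, "solvent")
        assert np.abs(msd.msd).max() < 1e-10

    def test_ballistic_motion_is_quadratic(self):
        v = 0.3
        pos = [[[10.0 + v * k, 20, 20]] for k in range(40)]
        traj = _traj(pos, box=1000.0)
        msd = compute_msd(traj, "solvent")
        assert np.allclose(msd.msd, (v * msd.lag) ** 2, rtol=1e-10)

    def test_random_walk_slope(self, rng):
        # ensemble oracle: MSD(k) = 3 s^2 k for isotropic steps of std s
        s = 0.8
        n_walkers, n_steps = 3000, 60
        steps = rng.standard_normal((n_steps, n_walkers, 3)) * s
        pos = np.cumsum(steps, axis=0)
        traj = _traj(list(pos), box=1e6)
        msd = compute_msd(traj, "solvent")
        k = np.arange(1, len(msd.lag))
        assert np.allclose(msd.msd[1:], 3 * s * s * k, rtol=0.05)

    def test_wrapped_only_trajectory_rejected(self):
        frames = [Frame(box=50.0, time=float(k),
                        positions=np.zeros((3, 3))) for k in range(4)]
        traj = Trajectory(species=np.full(3, SP_SOLVENT, np.int8),
                          mol=np.full(3, -1, np.int32), charges=np.zeros(3),
                          frames=frames)
        from macroioncg.trajectory import UnwrapError
        with pytest.raises(UnwrapError):
            compute_msd(traj, "solvent")


class TestDiffusion:
    def test_exact_line_and_factor_four(self):
        # <r^2> = 6 t (A^2/ps) -> D_raw = 1e-4 cm^2/s, reported /4
        pos = None
        lag = np.arange(50, dtype=float)
        from macroioncg.analysis import MSDResult
        msd = MSDResult(lag=lag, msd=6.0 * lag, species="solvent",
                        n_particles=1)
        out = diffusion_coefficient(msd, scale_factor=4.0)
        assert out.d_raw == pytest.approx(1e-4)
        assert out.d_reported == pytest.approx(2.5e-5)

    def test_unit_scale_factor_is_identity(self):
        from macroioncg.analysis import MSDResult
        lag = np.arange(50, dtype=float)
        msd = MSDResult(lag=lag, msd=2.0 * lag, species="solvent",
                        n_particles=1)
        out = diffusion_coefficient(msd, scale_factor=1.0)
        assert out.d_reported == out.d_raw

    def test_negative_slope_raises(self):
        from macroioncg.analysis import MSDResult
        lag = np.arange(50, dtype=float)
        msd = MSDResult(lag=lag, msd=100.0 - lag, species="solvent",
                        n_particles=1)
        with pytest.raises(FitWindowError):
            diffusion_coefficient(msd)


class TestProjection:
    def test_sign_convention_toward_partner_is_negative(self):
        p = radial_projection(np.array([1.0, 0, 0]), np.array([0.0, 0, 0]),
                              np.array([60.0, 0, 0]))
        assert p == pytest.approx(-1.0)

    def test_perpendicular_force_projects_to_zero(self):
        p = radial_projection(np.array([0.0, 2.5, 0]), np.array([0.0, 0, 0]),
                              np.array([60.0, 0, 0]))
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_counterion_at_midpoint_attracts_both(self):
        # direct Coulomb vector-sum oracle: one charged bead per macroion
        # facing a +1 counterion at the midpoint -> both projections negative
        from macroioncg.forcefield import coulomb_pair
        com_a, com_b = np.array([0.0, 0, 0]), np.array([40.0, 0, 0])
        bead_a, bead_b = np.array([12.5, 0, 0]), np.array([27.5, 0, 0])
        ci = np.array([20.0, 0, 0])
        for bead, com, other in ((bead_a, com_a, com_b),
                                 (bead_b, com_b, com_a)):
            d = bead - ci
            r = np.linalg.norm(d)
            pair = coulomb_pair(r, -1.0, 1.0)
            force = pair.force * d / r      # attraction toward the midpoint
            assert radial_projection(force, com, other) < 0

    def test_coincident_centers_rejected(self):
        with pytest.raises(UndefinedAxisError):
            radial_projection(np.ones(3), np.zeros(3), np.zeros(3))


class TestClustering:
    def test_chain_is_transitively_one_cluster(self):
        coms = np.array([[10.0, 10, 10], [40.0, 10, 10], [70.0, 10, 10]])
        res = cluster_aggregates(coms, box=200.0, contact_cutoff=35.0)
        assert res.n_clusters == 1
        assert res.largest == 3

    def test_distant_macroions_are_singletons(self, rng):
        coms = np.array([[10.0, 10, 10], [100.0, 100, 100],
                         [150.0, 30, 170]])
        res = cluster_aggregates(coms, box=400.0, contact_cutoff=32.0)
        assert res.n_clusters == 3
        assert np.array_equal(res.labels, [0, 1, 2])

    def _brute_force(self, coms, box, cutoff):
        # label spreading to fixpoint: each cluster ends up named by its
        # lowest member index
        n = len(coms)
        labels = np.arange(n)
        changed = True
        while changed:
            changed = False
            for i in range(n):
                for j in range(n):
                    d = coms[i] - coms[j]
                    d -= box * np.round(d / box)
                    if (d ** 2).sum() <= cutoff ** 2:
                        m = min(labels[i], labels[j])
                        if labels[i] != m or labels[j] != m:
                            labels[i] = labels[j] = m
                            changed = True
        return labels

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_union(self, seed):
        rng = np.random.default_rng(seed)
        coms = rng.random((12, 3)) * 120.0
        res = cluster_aggregates(coms, box=120.0, contact_cutoff=40.0)
        brute = self._brute_force(coms, 120.0, 40.0)
        # same partition: equal label arrays after lowest-member naming
        assert np.array_equal(res.labels, brute)
        assert res.sizes.sum() == 12

    def test_cluster_count_non_increasing_in_cutoff(self, rng):
        coms = rng.random((15, 3)) * 100.0
        counts = [cluster_aggregates(coms, 100.0, c).n_clusters
                  for c in (10, 20, 30, 40, 60)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestForceSeries:
    def _rigid_pair_traj(self):
        n_beads = 4
        mol = np.array([0] * n_beads + [1] * n_beads, dtype=np.int32)
        species = np.zeros(2 * n_beads, dtype=np.int8)
        offs = np.array([[2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0]])
        frames = []
        rng = np.random.default_rng(0)
        fv = [rng.standard_normal((8, 3)) for _ in range(3)]
        fc = [rng.standard_normal((8, 3)) for _ in range(3)]
        for k in range(3):
            pos = np.vstack([offs + [20.0, 30, 30], offs + [50.0, 30, 30]])
            frames.append(Frame(box=100.0, time=float(k), positions=pos,
                                images=np.zeros((8, 3), np.int32),
                                f_vdw=fv[k], f_coul=fc[k]))
        traj = Trajectory(species=species, mol=mol,
                          charges=np.zeros(8), frames=frames)
        return traj, fv, fc

    def test_net_force_is_sum_of_bead_forces(self):
        traj, fv, fc = self._rigid_pair_traj()
        trace = macroion_force_series(traj, pair=(0, 1))
        for k in range(3):
            assert np.allclose(trace.net_coul[k, 0], fc[k][:4].sum(axis=0),
                               atol=1e-10)
            assert np.allclose(trace.net_vdw[k, 1], fv[k][4:].sum(axis=0),
                               atol=1e-10)
        assert trace.distance[0] == pytest.approx(30.0)

    def test_missing_channels_rejected(self):
        traj, _, _ = self._rigid_pair_traj()
        for f in traj.frames:
            f.f_vdw = f.f_coul = None
        with pytest.raises(MissingChannelError):
            macroion_force_series(traj)


class TestEnergyProfile:
    def _pair_traj(self, distances, energies):
        mol = np.array([0, 1], dtype=np.int32)
        frames = []
        for k, (d, e) in enumerate(zip(distances, energies)):
            pos = np.array([[10.0, 50, 50], [10.0 + d, 50, 50]])
            frames.append(Frame(box=200.0, time=float(k), positions=pos,
                                images=np.zeros((2, 3), np.int32),
                                e_coul=e))
        return Trajectory(species=np.zeros(2, np.int8), mol=mol,
                          charges=np.zeros(2), frames=frames)

    def test_constant_energy_flat_profile(self):
        traj = self._pair_traj([30, 35, 40, 45], [-5.0] * 4)
        prof = energy_distance_profile(traj, bin_width=2.0)
        occupied = prof["count"] > 0
        assert np.allclose(prof["mean"][occupied], -5.0)

    def test_opposite_charges_recover_coulomb_curve(self):
        from macroioncg.units import KQ_KJMOL
        dists = np.array([20.0, 30.0, 40.0, 50.0])
        energies = -KQ_KJMOL / dists
        traj = self._pair_traj(dists, energies)
        prof = energy_distance_profile(traj, bin_width=1.0)
        occupied = np.flatnonzero(prof["count"] > 0)
        for d in dists:
            b = occupied[np.argmin(np.abs(prof["r"][occupied] - d))]
            assert prof["mean"][b] == pytest.approx(-KQ_KJMOL / d, rel=0.05)

    def test_empty_bins_flagged_not_interpolated(self):
        traj = self._pair_traj([20.0, 50.0], [-1.0, -2.0])
        prof = energy_distance_profile(traj, bin_width=1.0)
        mid = (prof["r"] > 25) & (prof["r"] < 45)
        assert np.all(np.isnan(prof["mean"][mid]))
        assert np.all(prof["count"][mid] == 0)


class TestNeighborCount:
    def test_compact_cluster_counts_all_neighbors(self):
        # 4 macroions in a tight tetrahedron: 3 neighbors each
        edge = 28.0
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float) * edge / (2 * np.sqrt(2))
        pos = verts + 100.0
        mol = np.repeat(np.arange(4), 1).astype(np.int32)
        frames = [Frame(box=200.0, time=float(k), positions=pos.copy(),
                        images=np.zeros((4, 3), np.int32)) for k in range(5)]
        traj = Trajectory(species=np.zeros(4, np.int8), mol=mol,
                          charges=np.zeros(4), frames=frames)
        assert mean_first_neighbor_count(traj, cutoff=32.0) == \
            pytest.approx(3.0)
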