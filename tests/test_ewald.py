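"""Periodic electrostatics against independent oracles.

Validation triple: (a) an isolated pair recovers the non-periodic closed
form, (b) a rock-salt lattice recovers the NaCl Madelung constant computed
here by an Evjen (charge-weighted expanding-cube) brute-force sum, (c) the
result is independent of the splitting parameter on a random neutral plasma.
"""

import numpy as np
import pytest

from conftest import free_config
from macroioncg.ewald import EwaldSettings
from macroioncg.forces import ForceCalculator
from macroioncg.system import NeutralityError
from macroioncg.units import KQ_KJMOL


def evjen_madelung(n_shells: int = 30) -> float:
    """Brute-force NaCl Madelung constant: expanding cube with fractional
    weights for boundary sites (Evjen's method)."""
    m = 0.0
    n = n_shells
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for c in (i, j, k):
                    if abs(c) == n:
                        w *= 0.5
                r = np.sqrt(i * i + j * j + k * k)
                m += w * (-1.0) ** (i + j + k) / r
    return -m


class TestEwald:
    def test_isolated_pair_matches_bare_coulomb(self):
        cfg = free_config([[50, 50, 50], [55, 50, 50]], charges=[1, -1],
                          box=200.0)
        fc = ForceCalculator(coulomb="ewald",
                             ewald=EwaldSettings(accuracy=1e-6, r_cut=30.0))
        res = fc.compute(cfg, all_pairs=True)
        exact = -KQ_KJMOL / 5.0
        assert res.e_coul_kjmol == pytest.approx(exact, rel=1e-3)

    def test_rock_salt_recovers_madelung_constant(self):
        a, ncell = 4.0, 4
        pos, q = [], []
        for i in range(ncell):
            for j in range(ncell):
                for k in range(ncell):
                    pos.append([i * a, j * a, k * a])
                    q.append((-1.0) ** (i + j + k))
        cfg = free_config(pos, charges=q, box=ncell * a)
        fc = ForceCalculator(coulomb="ewald",
                             ewald=EwaldSettings(accuracy=1e-8, r_cut=7.9))
        res = fc.compute(cfg, all_pairs=True)
        # E_total = -(N/2) M k_q / a
        m_sim = -res.e_coul_kjmol * a / (len(pos) / 2) / KQ_KJMOL
        m_ref = evjen_madelung(24)
        assert m_ref == pytest.approx(1.747565, abs=1e-4)  # sanity of oracle
        assert m_sim == pytest.approx(m_ref, abs=2e-4)

    def test_alpha_independence_on_random_plasma(self, rng):
        n = 64
        pos = rng.random((n, 3)) * 20.0
        q = np.repeat([1.0, -1.0], n // 2)
        cfg = free_config(pos, charges=q, box=20.0)
        base = ForceCalculator(coulomb="ewald",
                               ewald=EwaldSettings(accuracy=1e-7, r_cut=9.9))
        tight = ForceCalculator(
            coulomb="ewald",
            ewald=EwaldSettings(accuracy=1e-7, r_cut=9.9, alpha=0.55,
                                nmax=14))
        ra = base.compute(cfg, all_pairs=True)
        rb = tight.compute(cfg, all_pairs=True)
        rms = np.sqrt(np.mean((ra.f_coul - rb.f_coul) ** 2))
        scale = np.sqrt(np.mean(ra.f_coul ** 2))
        assert rms / scale < 1e-4
        assert ra.e_coul == pytest.approx(rb.e_coul, rel=1e-5)

    def test_forces_match_energy_gradient(self, rng):
        n = 10
        pos = rng.random((n, 3)) * 15.0
        q = np.repeat([1.0, -1.0], n // 2)
        cfg = free_config(pos, charges=q, box=15.0)
        fc = ForceCalculator(coulomb="ewald",
                             ewald=EwaldSettings(accuracy=1e-7, r_cut=7.0))
        res = fc.compute(cfg, all_pairs=True)
        h = 1e-5
        for i in (0, 7):
            for ax in range(3):
                cp, cm = cfg.copy(), cfg.copy()
                cp.positions[i, ax] += h
                cm.positions[i, ax] -= h
                fd = -(fc.compute(cp, all_pairs=True).e_coul
                       - fc.compute(cm, all_pairs=True).e_coul) / (2 * h)
                assert res.f_coul[i, ax] == pytest.approx(fd, rel=1e-4,
                                                          abs=1e-3)

    def test_forces_sum_to_zero(self, rng):
        # jittered lattice: no pathological overlaps, forces O(10) not O(1e5)
        grid = np.array([[i, j, k] for i in range(3) for j in range(3)
                         for k in range(3)], dtype=float) * 8.0 + 1.0
        pos = grid + rng.standard_normal((27, 3)) * 0.6
        q = np.array([1.0] * 13 + [-1.0] * 13 + [0.0])  # neutral, odd count
        cfg = free_config(pos, charges=q, box=24.0)
        fc = ForceCalculator(coulomb="ewald",
                             ewald=EwaldSettings(accuracy=1e-6, r_cut=11.9))
        res = fc.compute(cfg, all_pairs=True)
        assert np.abs(res.f_total.sum(axis=0)).max() < 1e-8

    def test_zero_charges_short_circuit(self):
        cfg = free_config([[5, 5, 5], [9, 5, 5]], box=40.0)
        fc = ForceCalculator(coulomb="auto")
        res = fc.compute(cfg)
        assert res.e_coul == 0.0
        assert np.all(res.f_coul == 0.0)

    def test_net_charge_rejected(self):
        cfg = free_config([[5, 5, 5], [9, 5, 5]], charges=[1.0, 0.0], box=40.0)
        fc = ForceCalculator(coulomb="ewald")
        with pytest.raises(NeutralityError):
            fc.compute(cfg, all_pairs=True)


class TestDSF:
    def test_dsf_tracks_ewald_forces_on_screened_system(self, rng):
        # DSF is a truncation surrogate: on a thermally perturbed rock-salt
        # arrangement its force error vs Ewald must stay a bounded fraction
        # of the typical force (tens of percent at cutoffs of half a small
        # box; contact pairs are far more faithful, tested below)
        a, nc = 6.0, 4
        pos, q = [], []
        for i in range(nc):
            for j in range(nc):
                for k in range(nc):
                    pos.append([i * a, j * a, k * a])
                    q.append((-1.0) ** (i + j + k))
        pos = np.asarray(pos) + rng.standard_normal((nc ** 3, 3)) * 0.3
        cfg = free_config(pos, charges=q, box=nc * a)
        ew = ForceCalculator(coulomb="ewald",
                             ewald=EwaldSettings(accuracy=1e-6, r_cut=11.9))
        dsf = ForceCalculator(coulomb="dsf",
                              ewald=EwaldSettings(r_cut=11.9))
        fa = ew.compute(cfg, all_pairs=True).f_coul
        fb = dsf.compute(cfg, all_pairs=True).f_coul
        rms = np.sqrt(np.mean((fa - fb) ** 2))
        scale = np.sqrt(np.mean(fa ** 2))
        assert rms / scale < 0.25

    def test_dsf_contact_pair_force_near_bare_coulomb(self):
        # the physics the implicit-solvent mode must keep: a counterion in
        # contact with a charged bead feels >= 85% of the bare attraction
        from macroioncg.units import KQ
        cfg = free_config([[50.0, 50, 50], [55.0, 50, 50]],
                          charges=[1.0, -1.0], box=100.0)
        dsf = ForceCalculator(coulomb="dsf",
                              ewald=EwaldSettings(r_cut=20.0))
        res = dsf.compute(cfg, all_pairs=True)
        bare = KQ / 25.0
        assert abs(res.f_coul[0, 0]) / bare > 0.85
        assert res.f_coul[0, 0] > 0  # attraction: toward the partner at +x
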