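"""Minima search, harmonic thermodynamics, and multiwell free energies."""

import math

import numpy as np
import pytest

import gridock as g
from gridock.energetics import dihedral_angle
from gridock.gadock import apply_torsions
from gridock.multiwell import (
    H_KCAL_S,
    KB_KCAL,
    OMEGA2_CONV,
    ComplexModel,
    EnergyModel,
    FLMParams,
    FreeLigandModel,
    LocalMinimum,
    MinimaPool,
    binding_free_energy,
    harmonic_frequencies,
    mc_minima_search,
    multiwell_free_energy,
    rotational_free_energy,
    strain_energy,
    translational_free_energy,
    vibrational_free_energy,
    well_free_energy,
    well_populations,
)

T = 298.15
KT = KB_KCAL * T


class _Quadratic(EnergyModel):
    """Single isotropic well at the origin for one atom."""

    def __init__(self, k=8.0, mass=12.0):
        self.k = k
        self.masses = np.array([mass])

    def energy(self, coords):
        c = np.asarray(coords).reshape(-1, 3)
        return 0.5 * self.k * float(np.sum(c[0] ** 2))


class _TorsionDoubleWell(EnergyModel):
    """Symmetric double well in the single torsion: A(1 + cos 2φ)."""

    def __init__(self, topo, ref, amplitude=2.0):
        self.topo = topo
        self.amplitude = amplitude
        self.masses = np.array([a.mass for a in topo.atoms])
        self._rest = FreeLigandModel(topo, ref)

    def energy(self, coords):
        c = np.asarray(coords).reshape(-1, 3)
        i, a, b, j = self.topo.rotatable_torsions[0].quadruple
        phi = dihedral_angle(c[i], c[a], c[b], c[j])
        return self.amplitude * (1 + math.cos(2 * phi)) + self._rest._restraint_energy(c)


def _point_topology():
    atom = g.AtomRecord(element="C", position=np.zeros(3))
    return g.LigandTopology(atoms=[atom], bonds=[])


class TestMinimaSearch:
    def test_single_well_single_minimum(self):
        em = _Quadratic()
        topo = _point_topology()
        start = g.Conformer(np.array([[1.5, -0.5, 0.7]]))
        pool = mc_minima_search(
            em, topo, start, FLMParams(n_starts=20, seed=0, translation_step=1.0)
        )
        assert len(pool.minima) == 1
        np.testing.assert_allclose(pool.best.conformer.coords, np.zeros((1, 3)), atol=1e-3)
        assert pool.best.e0 == pytest.approx(0.0, abs=1e-8)

    def test_symmetric_double_well_two_minima(self):
        """A 1-torsion ligand in a symmetric 2-fold well: exactly two minima
        with equal energies, matching a dense torsion scan."""
        topo, conf = g.make_toy_ligand(1, seed=0)
        em = _TorsionDoubleWell(topo, conf)
        pool = MinimaPool(dedup_align=True)
        pool = mc_minima_search(
            em, topo, conf,
            FLMParams(n_starts=40, seed=3, translation_step=0.01, rotation_step=0.05),
            pool=pool,
        )
        assert len(pool.minima) == 2
        assert abs(pool.minima[0].e0 - pool.minima[1].e0) < 1e-6
        # dense scan oracle for the well depth
        i, a, b, j = topo.rotatable_torsions[0].quadruple
        phi0 = dihedral_angle(*conf.coords[[i, a, b, j]])
        scan = min(
            2.0 * (1 + math.cos(2 * phi))
            for phi in np.linspace(-math.pi, math.pi, 2001)
        )
        assert pool.best.e0 == pytest.approx(scan, abs=1e-6)

    def test_same_seed_identical_pool(self):
        topo, conf = g.make_toy_ligand(1, seed=0)
        em = _TorsionDoubleWell(topo, conf)
        params = FLMParams(n_starts=15, seed=9)
        p1 = mc_minima_search(em, topo, conf, params, pool=MinimaPool(dedup_align=True))
        p2 = mc_minima_search(em, topo, conf, params, pool=MinimaPool(dedup_align=True))
        assert [m.e0 for m in p1.minima] == [m.e0 for m in p2.minima]

    def test_capacity_eviction_keeps_lowest(self):
        pool = MinimaPool(capacity=3, dedup_de=1e-12)
        conf = g.Conformer(np.zeros((1, 3)))
        for e in (5.0, 1.0, 3.0, 2.0, 4.0):
            pool.insert(
                LocalMinimum(conformer=g.Conformer(np.full((1, 3), e)), e0=e)
            )
        assert [m.e0 for m in pool.minima] == [1.0, 2.0, 3.0]


class TestHarmonicFrequencies:
    def test_one_dimensional_closed_form(self):
        kf, m = 100.0, 12.0

        class OneD(EnergyModel):
            masses = np.array([m])

            def energy(self, coords):
                c = np.asarray(coords).reshape(-1, 3)
                return 0.5 * kf * float(c[0, 0] ** 2)

        nu = harmonic_frequencies(
            OneD(), _point_topology(), g.Conformer(np.zeros((1, 3))), project_rigid=False
        )
        expected = math.sqrt(kf / m * OMEGA2_CONV) / (2 * math.pi)
        assert nu.shape == (1,)
        assert nu[0] == pytest.approx(expected, rel=1e-4)

    def test_frequencies_invariant_under_rotation(self):
        topo, conf = g.make_toy_ligand(0, seed=0)
        em = FreeLigandModel(topo, conf)
        nu1 = harmonic_frequencies(em, topo, conf)

        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.4, 0.9, -0.2])
        conf_rot = g.Conformer(rot.apply(conf.coords))
        em2 = FreeLigandModel(topo, conf_rot)
        nu2 = harmonic_frequencies(em2, topo, conf_rot)
        np.testing.assert_allclose(np.sort(nu1), np.sort(nu2), rtol=1e-3)

    def test_saddle_point_rejected(self):
        class Saddle(EnergyModel):
            masses = np.array([12.0])

            def energy(self, coords):
                c = np.asarray(coords).reshape(-1, 3)
                # barrier top of a 1-D double well in x, bound in y/z
                return -2.0 * float(c[0, 0] ** 2) + float(c[0, 1] ** 2 + c[0, 2] ** 2)

        with pytest.raises(ValueError, match="not a minimum"):
            harmonic_frequencies(
                Saddle(), _point_topology(), g.Conformer(np.zeros((1, 3))),
                project_rigid=False,
            )


class TestWellThermodynamics:
    def test_mode_at_kt_contributes_nothing(self):
        nu0 = KT / H_KCAL_S
        assert vibrational_free_energy(np.array([nu0]), T) == pytest.approx(0.0, abs=1e-12)

    def test_stiffening_adds_kt_ln2_per_mode(self):
        nu = np.array([1e12, 5e12, 2e13])
        g1 = vibrational_free_energy(nu, T)
        g2 = vibrational_free_energy(2 * nu, T)
        assert g2 - g1 == pytest.approx(3 * KT * math.log(2), rel=1e-12)

    def test_mass_doubling_lowers_g_t(self):
        delta = translational_free_energy(24.0, T) - translational_free_energy(12.0, T)
        assert delta == pytest.approx(-1.5 * KT * math.log(2), rel=1e-12)

    def test_rotor_limits(self):
        assert rotational_free_energy(np.zeros(3), T) == 0.0
        linear = rotational_free_energy(np.array([0.0, 50.0, 50.0]), T)
        nonlinear = rotational_free_energy(np.array([20.0, 50.0, 50.0]), T)
        assert math.isfinite(linear) and math.isfinite(nonlinear)

    def test_well_free_energy_totals(self):
        m = LocalMinimum(
            conformer=g.Conformer(np.zeros((1, 3))), e0=-4.0,
            frequencies=np.array([KT / H_KCAL_S]),
        )
        out = well_free_energy(m, mass=12.0, inertia=np.zeros(3), temperature=T)
        assert out.g_total == pytest.approx(-4.0 + out.g_v + out.g_t + out.g_r)
        assert out.g_v == pytest.approx(0.0, abs=1e-12)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            vibrational_free_energy(np.array([0.0]), T)


def _pool_with(gs):
    pool = MinimaPool(temperature=T, dedup_de=0.0)
    for k, gt in enumerate(gs):
        pool.minima.append(
            LocalMinimum(conformer=g.Conformer(np.full((1, 3), float(k))), e0=gt)
        )
    return pool


class TestMultiwell:
    def test_single_well_is_its_g_total(self):
        pool = _pool_with([-3.7])
        assert multiwell_free_energy(pool) == pytest.approx(-3.7, abs=1e-12)

    def test_two_equal_wells_lower_by_kt_ln2(self):
        pool = _pool_with([-3.0, -3.0])
        assert multiwell_free_energy(pool) == pytest.approx(
            -3.0 - KT * math.log(2), abs=1e-9
        )
        assert KT * math.log(2) == pytest.approx(0.411, abs=1e-3)

    def test_bounded_by_minimum(self):
        rng = np.random.default_rng(0)
        pool = _pool_with(list(rng.normal(-2, 3, size=30)))
        assert multiwell_free_energy(pool) <= min(m.g_total for m in pool.minima)

    def test_high_well_negligible(self):
        pool = _pool_with([-5.0])
        g1 = multiwell_free_energy(pool)
        pool.minima.append(
            LocalMinimum(conformer=g.Conformer(np.ones((1, 3))), e0=-5.0 + 20 * KT)
        )
        g2 = multiwell_free_energy(pool)
        assert abs(g2 - g1) < 1e-8

    def test_monotone_in_added_minima(self):
        pool = _pool_with([-1.0])
        prev = multiwell_free_energy(pool)
        for e in (-0.5, -2.0, 0.0):
            pool.minima.append(
                LocalMinimum(conformer=g.Conformer(np.zeros((1, 3))), e0=e)
            )
            cur = multiwell_free_energy(pool)
            assert cur <= prev + 1e-12
            prev = cur

    def test_populations_sum_to_one(self):
        rng = np.random.default_rng(1)
        pool = _pool_with(list(rng.normal(0, 2, size=12)))
        assert well_populations(pool).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            multiwell_free_energy(MinimaPool())


class TestStrainAndBinding:
    def test_strain_zero_at_free_minimum(self):
        topo, conf = g.make_toy_ligand(1, seed=0)
        em = FreeLigandModel(topo, conf)
        pool = mc_minima_search(
            em, topo, conf, FLMParams(n_starts=30, seed=1),
            pool=MinimaPool(dedup_align=True),
        )
        strain = strain_energy(pool.best.conformer, pool, topo)
        assert strain == pytest.approx(0.0, abs=1e-6)

    def test_strain_nonnegative_and_matches_torsion_gap(self):
        """Strain of an eclipsed bound pose equals the torsion-profile gap."""
        topo, conf = g.make_toy_ligand(1, seed=0)
        em = FreeLigandModel(topo, conf)
        pool = mc_minima_search(
            em, topo, conf, FLMParams(n_starts=30, seed=1),
            pool=MinimaPool(dedup_align=True),
        )
        i, a, b, j = topo.rotatable_torsions[0].quadruple
        phi0 = dihedral_angle(*conf.coords[[i, a, b, j]])
        eclipsed = apply_torsions(topo, conf, np.array([-phi0]))  # phi = 0
        strain = strain_energy(eclipsed, pool, topo)
        profile = [
            g.ligand_internal_energy(
                topo, apply_torsions(topo, conf, np.array([phi - phi0]))
            )
            for phi in np.linspace(-math.pi, math.pi, 721)
        ]
        gap = g.ligand_internal_energy(topo, eclipsed) - min(profile)
        assert strain >= 0.0
        assert strain == pytest.approx(gap, abs=1e-4)

    def test_identical_pools_bind_zero(self):
        pool = _pool_with([-2.0, -1.0])
        assert binding_free_energy(pool, pool) == 0.0

    def test_single_well_pools_reduce_to_difference(self):
        assert binding_free_energy(_pool_with([-8.0]), _pool_with([-3.0])) == pytest.approx(-5.0)

    def test_deepening_complex_is_lipschitz(self):
        base = _pool_with([-4.0, -3.0])
        free = _pool_with([-1.0])
        g1 = binding_free_energy(base, free)
        deeper = _pool_with([-4.5, -3.0])
        g2 = binding_free_energy(deeper, free)
        assert g1 - 0.5 <= g2 <= g1

    def test_temperature_mismatch_rejected(self):
        a = _pool_with([-1.0])
        b = _pool_with([-1.0])
        b.temperature = 310.0
        with pytest.raises(ValueError):
            binding_free_energy(a, b)
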