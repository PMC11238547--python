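"""Interaction-engine contracts: closed forms, symmetry, linearity."""

import numpy as np
import pytest
from scipy.special import erf

from excitonci.engines import (CapabilityError, Density, DiscreteChargeEngine,
                               EngineError, GaussianSEngine)
from excitonci.site_model import SpinBlockedTDM


def _singlet_density(fid, matrix):
    matrix = np.asarray(matrix, dtype=float)
    zero = np.zeros_like(matrix)
    return SpinBlockedTDM(fid, 0, 0, {"aa": matrix / 2, "bb": matrix / 2,
                                      "ab": zero, "ba": zero})


class TestDiscreteChargeEngine:
    def setup_method(self):
        self.eng = DiscreteChargeEngine({
            1: np.array([[0.0, 0.0, 0.0]]),
            2: np.array([[0.0, 0.0, 1.0]]),
        })

    def test_point_charge_coulomb_law(self):
        rho = Density(1, np.array([[1.0]]))
        e = self.eng.density_charge_energy(rho, [(1.0, np.array([0, 0, 2.0]))])
        assert e == pytest.approx(0.5, abs=1e-14)

    def test_empty_charge_list(self):
        rho = Density(1, np.array([[1.0]]))
        assert self.eng.density_charge_energy(rho, []) == 0.0

    def test_unit_densities_one_bohr(self):
        j = self.eng.coulomb_J(Density(1, [[1.0]]), Density(2, [[1.0]]))
        assert j == pytest.approx(1.0, abs=1e-14)

    def test_coulomb_symmetric(self, rng):
        eng = DiscreteChargeEngine({1: rng.uniform(-2, 2, (3, 3)),
                                    2: rng.uniform(4, 8, (4, 3))})
        wf = rng.normal(size=3)
        wg = rng.normal(size=4)
        j1 = eng.coulomb_J(Density(1, np.diag(wf)), Density(2, np.diag(wg)))
        j2 = eng.coulomb_J(Density(2, np.diag(wg)), Density(1, np.diag(wf)))
        assert j1 == pytest.approx(j2, abs=1e-12)

    def test_same_fragment_rejected(self):
        with pytest.raises(EngineError, match="site energies"):
            self.eng.coulomb_J(Density(1, [[1.0]]), Density(1, [[1.0]]))

    def test_coincident_points_raise(self):
        rho = Density(1, np.array([[1.0]]))
        with pytest.raises(EngineError, match="coincident"):
            self.eng.density_charge_energy(rho, [(1.0, np.zeros(3))])

    def test_exchange_unsupported(self):
        with pytest.raises(CapabilityError):
            self.eng.exchange_K(_singlet_density(1, [[1.0]]),
                                _singlet_density(2, [[1.0]]))


class TestGaussianSEngine:
    def setup_method(self):
        self.r = 3.0
        self.eng = GaussianSEngine({
            1: [(np.zeros(3), 1.0)],
            2: [(np.array([0.0, 0.0, self.r]), 1.0)],
        })

    def test_density_charge_closed_form(self):
        # |phi|^2 of an alpha=1 s-Gaussian is an alpha=2 charge distribution
        v = self.eng.density_charge_energy(
            Density(1, [[1.0]]), [(1.0, np.array([0.0, 0.0, self.r]))])
        assert v == pytest.approx(erf(np.sqrt(2.0) * self.r) / self.r, rel=1e-12)

    def test_coulomb_two_center_closed_form(self):
        j = self.eng.coulomb_J(Density(1, [[1.0]]), Density(2, [[1.0]]))
        # alpha_eff = (2*2)/(2+2) = 1
        assert j == pytest.approx(erf(self.r) / self.r, rel=1e-12)

    def test_closed_shell_exchange_is_half_spatial(self):
        g1 = _singlet_density(1, [[1.0]])
        g2 = _singlet_density(2, [[1.0]])
        k = self.eng.exchange_K(g1, g2)
        # K_spatial contracts the full spatial densities P = 2 * (P/2)
        pair_fg = self.eng._pair_data(1, 2)
        x = self.eng._eri_cross(pair_fg, pair_fg)
        k_spatial = float(np.einsum("pq,rs,qrps->", [[1.0]], [[1.0]], x))
        assert k == pytest.approx(0.5 * k_spatial, rel=1e-12)

    def test_spin_block_orthogonality_zero(self):
        zero = np.zeros((1, 1))
        trip = SpinBlockedTDM(1, 0, 1, {"aa": zero, "bb": zero,
                                        "ab": np.array([[0.7]]), "ba": zero})
        sing = _singlet_density(2, [[1.0]])
        assert self.eng.exchange_K(trip, sing) == 0.0

    def test_overlap_monotone_on_approach(self):
        vals = []
        for r in (10.0, 8.0, 6.0, 4.0, 2.0):
            eng = GaussianSEngine({1: [(np.zeros(3), 1.0)],
                                   2: [(np.array([0, 0, r]), 1.0)]})
            vals.append(eng.overlap_measure(_singlet_density(1, [[1.0]]),
                                            _singlet_density(2, [[1.0]])))
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[0] >= 0.0

    def test_point_limit_matches_discrete(self):
        # very tight Gaussians approach point charges
        tight = 4000.0
        eng = GaussianSEngine({1: [(np.zeros(3), tight)],
                               2: [(np.array([0, 0, 2.0]), tight)]})
        j = eng.coulomb_J(Density(1, [[1.0]]), Density(2, [[1.0]]))
        disc = DiscreteChargeEngine({1: np.zeros((1, 3)),
                                     2: np.array([[0, 0, 2.0]])})
        jd = disc.coulomb_J(Density(1, [[1.0]]), Density(2, [[1.0]]))
        assert j == pytest.approx(jd, abs=1e-6)

    def test_bilinearity(self, rng):
        eng = GaussianSEngine({
            1: [(np.zeros(3), 1.0), (np.array([1.0, 0, 0]), 0.6)],
            2: [(np.array([0, 0, 5.0]), 0.8)],
        })
        a = rng.normal(size=(2, 2))
        b = rng.normal(size=(2, 2))
        c = rng.normal(size=(1, 1))
        lhs = eng.coulomb_J(Density(1, 2.0 * a + 0.3 * b), Density(2, c))
        rhs = (2.0 * eng.coulomb_J(Density(1, a), Density(2, c))
               + 0.3 * eng.coulomb_J(Density(1, b), Density(2, c)))
        assert lhs == pytest.approx(rhs, abs=1e-12)
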