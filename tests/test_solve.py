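"""Diagonalization, PR / E_n diagnostics, oscillator strengths, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excitonci.basis import enumerate_esds, select_ms
from excitonci.fixtures import make_point_chromophore_dimer
from excitonci.hamiltonian import assemble, dipole_matrices
from excitonci.solve import (ECIResult, excitation_rank_weights,
                             gaussian_broadening, oscillator_strengths,
                             participation_ratio, solve)
from excitonci.spin_adaptation import build_ecsfs, transformation_matrix


class TestSolve:
    def test_diagonal_matrix(self):
        vals, vecs = solve(np.diag([3.0, 1.0, 2.0]))
        assert np.allclose(vals, [1.0, 2.0, 3.0])
        assert np.allclose(np.abs(vecs), np.eye(3)[:, [1, 2, 0]])

    def test_two_level_coupling(self):
        v = 0.3
        vals, vecs = solve(np.array([[0.0, v], [v, 0.0]]))
        assert np.allclose(vals, [-v, v])
        assert np.allclose(np.abs(vecs), np.full((2, 2), 1 / np.sqrt(2)))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="asymmetry"):
            solve(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestDiagnostics:
    def test_pr_single_and_equal(self):
        assert participation_ratio(np.array([1.0])) == pytest.approx(1.0)
        for ell in (2, 5, 9):
            c = np.full(ell, 1.0 / np.sqrt(ell))
            assert participation_ratio(c) == pytest.approx(float(ell))

    def test_pr_mixed(self):
        c = np.array([np.sqrt(0.8), np.sqrt(0.2)])
        assert participation_ratio(c) == pytest.approx(1.0 / 0.68)

    def test_pr_zero_vector(self):
        with pytest.raises(ValueError):
            participation_ratio(np.zeros(3))

    def test_rank_weights_pure_and_mixed(self):
        w = excitation_rank_weights(np.array([1.0, 0.0]), [0, 1])
        assert w == {0: 1.0, 1: 0.0}
        w = excitation_rank_weights(
            np.array([0, 1, 1]) / np.sqrt(2), [0, 1, 2])
        assert w[1] == pytest.approx(0.5) and w[2] == pytest.approx(0.5)

    @given(st.integers(min_value=1, max_value=40), st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rank_weights_partition_unity(self, n, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(size=n)
        c /= np.linalg.norm(c)
        ranks = rng.integers(0, 4, size=n).tolist()
        w = excitation_rank_weights(c, ranks)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        assert 1.0 <= participation_ratio(c) <= n + 1e-9


class TestOscillatorStrengths:
    def test_closed_form(self):
        e = np.array([0.0, 1.5])
        c = np.eye(2)
        mu = np.zeros((3, 2, 2))
        mu[0, 0, 1] = mu[0, 1, 0] = np.sqrt(2.0)
        f, _ = oscillator_strengths(e, c, mu)
        assert f[1] == pytest.approx(2.0, abs=1e-12)
        assert f[0] == 0.0

    def test_dark_state(self):
        e = np.array([0.0, 1.0])
        f, _ = oscillator_strengths(e, np.eye(2), np.zeros((3, 2, 2)))
        assert np.all(f == 0.0)

    def test_esd_vs_ecsf_contraction_agree(self):
        data, engine = make_point_chromophore_dimer(separation=8.0)
        esds = select_ms(enumerate_esds(data, 2), 0.0)
        ecsfs, _ = build_ecsfs(esds, 0.0, data)
        h = assemble(esds, data, engine, use_exchange=False).matrix
        mu_esd = dipole_matrices(esds, data)
        res = ECIResult.from_block(0.0, h, esds, ecsfs, dipoles_esd=mu_esd)
        # recompute f from the ESD-basis coefficient expansion directly
        c = res.coefficients_esd
        f2, _ = oscillator_strengths(res.energies, c, mu_esd)
        assert np.abs(res.osc_strengths - f2).max() < 1e-10


class TestResultInvariants:
    @pytest.fixture(scope="class")
    def result(self):
        data, engine = make_point_chromophore_dimer(
            separation=8.0, dipole_strengths=(1.0, 0.7),
            excitation_energies=(0.15, 0.16))
        esds = select_ms(enumerate_esds(data, 2), 0.0)
        ecsfs, _ = build_ecsfs(esds, 0.0, data)
        h = assemble(esds, data, engine, use_exchange=False).matrix
        mu = dipole_matrices(esds, data)
        return ECIResult.from_block(0.0, h, esds, ecsfs, dipoles_esd=mu), h

    def test_columns_orthonormal_and_weights_sum(self, result):
        res, _ = result
        c = res.coefficients
        assert np.allclose(c.T @ c, np.eye(c.shape[1]), atol=1e-8)
        for w in res.rank_weights:
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-8)
        assert np.all(res.pr >= 1.0 - 1e-12)
        assert np.all(res.pr <= len(res.ecsfs) + 1e-9)

    def test_observables_invariant_under_ecsf_rotation(self, result):
        """E, f, PR-bounds survive an arbitrary rotation among degenerate
        ECSFs (here: a random orthogonal mix of the full ECSF basis used
        only to re-express H; the spectrum must not change)."""
        res, h = result
        rng = np.random.default_rng(3)
        n = len(res.ecsfs)
        q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        t = transformation_matrix(res.ecsfs, res.esds) @ q
        h_rot = t.T @ h @ t
        vals, _ = solve(h_rot)
        assert np.abs(vals - res.energies).max() < 1e-10

    def test_json_round_trip(self, result, tmp_path):
        res, _ = result
        path = tmp_path / "out.json"
        res.to_json(str(path))
        import json
        doc = json.loads(path.read_text())
        assert doc["n_ecsf"] == len(res.ecsfs)
        assert len(doc["oscillator_strengths"]) == len(res.energies)


def test_gaussian_broadening_conserves_peak_position():
    grid = np.linspace(0.0, 5.0, 2001)
    y = gaussian_broadening([(2.5, 1.0)], grid, fwhm=0.3)
    assert grid[np.argmax(y)] == pytest.approx(2.5, abs=0.01)
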