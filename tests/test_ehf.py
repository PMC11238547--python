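"""RESP fitting and the self-consistent embedding (EHF) loop."""

import numpy as np
import pytest

from excitonci.backend import ToyModelBackend
from excitonci.basis import enumerate_esds, select_ms
from excitonci.ehf import (RespConfig, ehf_loop, embedding_mode, mk_grid,
                           resp_fit)
from excitonci.hamiltonian import assemble
from excitonci.oracle import ModelSystem, polar_toy_dimer


def _esp_of_charges(charges, positions, points):
    v = np.zeros(len(points))
    for q, r in zip(charges, positions):
        v += q / np.linalg.norm(points - r, axis=1)
    return v


class TestRespFit:
    def test_single_atom_unit_charge(self):
        pos = np.zeros((1, 3))
        cfg = RespConfig(restraint_a=0.0)
        grid = mk_grid(["C"], pos, cfg)
        v = _esp_of_charges([1.0], pos, grid)
        q = resp_fit(v, grid, pos, net_charge=1.0, config=cfg)
        assert q[0] == pytest.approx(1.0, abs=1e-8)

    def test_total_charge_constraint_exact(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        cfg = RespConfig()      # restraint on
        grid = mk_grid(["C", "O", "H"], pos, cfg)
        v = _esp_of_charges([0.2, -0.5, 0.1], pos, grid)
        q = resp_fit(v, grid, pos, net_charge=-0.2, config=cfg)
        assert q.sum() == pytest.approx(-0.2, abs=1e-10)

    def test_exact_linear_recovery(self):
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        cfg = RespConfig(restraint_a=0.0, points_per_ang2=3.0)
        grid = mk_grid(["C", "C"], pos, cfg)
        v = _esp_of_charges([0.3, -0.3], pos, grid)
        q = resp_fit(v, grid, pos, net_charge=0.0, config=cfg)
        assert np.abs(q - [0.3, -0.3]).max() < 1e-6

    def test_restraint_shrinks_charges(self):
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        grid = mk_grid(["C", "C"], pos, RespConfig())
        v = _esp_of_charges([0.3, -0.3], pos, grid)
        free = resp_fit(v, grid, pos, 0.0, RespConfig(restraint_a=0.0))
        tight = resp_fit(v, grid, pos, 0.0, RespConfig(restraint_a=0.05))
        assert np.abs(tight).max() < np.abs(free).max()


class TestEHFLoop:
    @pytest.fixture(scope="class")
    def backend(self):
        return ToyModelBackend(polar_toy_dimer())

    @pytest.fixture(scope="class")
    def resp(self):
        return RespConfig(restraint_a=0.0)

    def test_noninteracting_fragments_converge_first_cycle(self, resp):
        model = polar_toy_dimer(separation=1e6)
        backend = ToyModelBackend(model)
        state = ehf_loop(backend, resp_config=resp)
        assert state.converged and state.cycles == 2
        # cycle 1 installs the isolated-fragment ESP charges, cycle 2 confirms
        assert state.history[1][1] < 1e-10

    def test_symmetric_fragments_symmetric_charges(self, backend, resp):
        state = ehf_loop(backend, resp_config=resp)
        assert state.converged
        # second fragment is the mirror image of the first
        assert np.abs(state.charges[1] - state.charges[2][::-1]).max() < 1e-8

    def test_fixed_point_from_two_guesses(self, backend, resp):
        a = ehf_loop(backend, resp_config=resp)
        esp = ehf_loop(backend, max_cycles=1, resp_config=resp)
        b = ehf_loop(backend, resp_config=resp, initial=esp.charges)
        assert a.converged and b.converged
        for f in (1, 2):
            assert np.abs(a.charges[f] - b.charges[f]).max() < 1e-6

    def test_energy_monotone_nonincreasing(self, backend, resp):
        state = ehf_loop(backend, resp_config=resp)
        e = [row[2] for row in state.history]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(e, e[1:]))

    def test_nonconvergence_is_flagged_not_raised(self, backend, resp):
        state = ehf_loop(backend, t_q=1e-12, max_cycles=1, resp_config=resp)
        assert not state.converged

    def test_brillouin_reduction(self, backend, resp):
        """Converged charges suppress the GS-LE block relative to Q = 0."""
        def gsle_max(charges):
            data = backend.site_data(charges)
            esds = select_ms(enumerate_esds(data, 1), 0.0)
            h = assemble(esds, data, backend.engine()).matrix
            gs = next(i for i, e in enumerate(esds) if e.rank == 0)
            return max(abs(h[gs, i]) for i, e in enumerate(esds)
                       if e.rank == 1)
        zero = {f: np.zeros(2) for f in (1, 2)}
        ehf = ehf_loop(backend, resp_config=resp).charges
        assert gsle_max(ehf) < gsle_max(zero)

    def test_complete_basis_spectrum_charge_independent(self, backend, resp):
        """Full-rank ECI with a complete site-state set: FDA and EHF charges
        give the same eigenvalues (the embedding only rotates the basis)."""
        def eigs(charges):
            data = backend.site_data(charges)
            esds = select_ms(enumerate_esds(data, 2), 0.0)
            h = assemble(esds, data, backend.engine()).matrix
            return np.sort(np.linalg.eigvalsh(h))
        zero = {f: np.zeros(2) for f in (1, 2)}
        ehf = ehf_loop(backend, resp_config=resp).charges
        assert np.abs(eigs(zero) - eigs(ehf)).max() < 1e-6


class TestEmbeddingMode:
    def test_fda_zero_and_override(self):
        backend = ToyModelBackend(polar_toy_dimer())
        charges = embedding_mode(backend, "fda")
        assert all(np.all(q == 0.0) for q in charges.values())
        charges = embedding_mode(backend, "fda",
                                 special_charges={(1, 0): 2.0})
        assert charges[1][0] == 2.0 and charges[1][1] == 0.0

    def test_unknown_override_rejected(self):
        backend = ToyModelBackend(polar_toy_dimer())
        with pytest.raises(KeyError):
            embedding_mode(backend, "fda", special_charges={(9, 0): 1.0})

    def test_esp_is_one_cycle(self):
        backend = ToyModelBackend(polar_toy_dimer())
        resp = RespConfig(restraint_a=0.0)
        esp = embedding_mode(backend, "esp", resp_config=resp)
        one = ehf_loop(backend, max_cycles=1, resp_config=resp).charges
        for f in (1, 2):
            assert np.abs(esp[f] - one[f]).max() < 1e-12
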