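"""Rule-based matrix elements against the determinant oracle, embedding
invariance, limiting behaviours, FEM mode, dipole matrices."""

import copy

import numpy as np
import pytest

from excitonci.basis import enumerate_esds, select_ms
from excitonci.engines import NullEngine
from excitonci.fixtures import make_point_chromophore_dimer
from excitonci.hamiltonian import (MissingTDMError, TDMProvider, assemble,
                                   dipole_matrices, expand_tdm_components)
from excitonci.oracle import ModelSystem, build_site_data, make_oracle


class TestOracleEquivalence:
    """The central exactness property of the matrix-element rules."""

    @pytest.mark.parametrize("seed", range(6))
    def test_two_fragment_all_elements(self, seed):
        model = ModelSystem.random((2, 2), (2, 2), seed=100 + seed)
        data, engine, oracle = make_oracle(model)
        esds = enumerate_esds(data, max_rank=2)
        h = assemble(esds, data, engine, require_uniform_ms=False).matrix
        ref = oracle.product_basis_matrix([e.occupation for e in esds])
        assert np.abs(h - ref).max() < 1e-10

    @pytest.mark.parametrize("seed", (0, 1))
    def test_three_fragment_all_elements_and_ranks(self, seed):
        model = ModelSystem.random((2, 2, 2), (2, 2, 2), seed=200 + seed)
        data, engine, oracle = make_oracle(model)
        esds = enumerate_esds(data, max_rank=3)
        h = assemble(esds, data, engine, require_uniform_ms=False).matrix
        ref = oracle.product_basis_matrix([e.occupation for e in esds])
        assert np.abs(h - ref).max() < 1e-10

    def test_full_rank_eigenvalues_match_brute_force(self, small_oracle):
        data, engine, oracle = small_oracle
        esds = enumerate_esds(data, max_rank=2)
        h = assemble(esds, data, engine, require_uniform_ms=False).matrix
        assert np.abs(np.sort(np.linalg.eigvalsh(h))
                      - oracle.sector_eigenvalues()).max() < 1e-8

    def test_principal_only_container_equivalent(self):
        """Ladder-expanded TDM components reproduce the oracle elements."""
        model = ModelSystem.random((2, 2), (2, 2), seed=42)
        _, engine, oracle = make_oracle(model)
        slim, _, _ = build_site_data(model, store_all_tdms=False)
        esds = enumerate_esds(slim, max_rank=2)
        h = assemble(esds, slim, engine, require_uniform_ms=False).matrix
        ref = oracle.product_basis_matrix([e.occupation for e in esds])
        assert np.abs(h - ref).max() < 1e-10


class TestTDMExpansion:
    def test_matches_stored_blocks(self, small_model):
        full, _, _ = make_oracle(small_model, store_all_tdms=True)
        slim, _, _ = build_site_data(small_model, store_all_tdms=False)
        states = [s.state_index for s in full.states[1]]
        for b in states:
            for k in states:
                ref = full.get_tdm(1, b, k)
                gen = expand_tdm_components(slim, 1, b, k)
                for key in ("aa", "bb", "ab", "ba"):
                    assert np.abs(ref.blocks[key] - gen.blocks[key]).max() < 1e-10

    def test_idempotent_on_principal_pair(self, small_oracle):
        data, _, _ = small_oracle
        trip = next(s for s in data.states[1] if s.spin_s == 1.0
                    and s.spin_ms == 1.0)
        stored = data.get_tdm(1, trip.state_index, trip.state_index)
        gen = expand_tdm_components(data, 1, trip.state_index, trip.state_index)
        for key in ("aa", "bb", "ab", "ba"):
            assert np.allclose(stored.blocks[key], gen.blocks[key], atol=1e-12)

    def test_missing_principal_pair_raises(self, small_model):
        slim, _, _ = build_site_data(small_model, store_all_tdms=False)
        victim = next(iter(slim.tdms[1]))
        del slim.tdms[1][victim]
        with pytest.raises(MissingTDMError):
            TDMProvider(slim).get(1, victim[0], victim[1])


class TestEmbeddingInvariance:
    def test_hamiltonian_independent_of_charges(self, small_oracle, rng):
        """Random charges Q' via the nonvariational pathway == Q = 0."""
        data, engine, _ = small_oracle
        esds = enumerate_esds(data, max_rank=2)
        h0 = assemble(esds, data, engine, require_uniform_ms=False).matrix
        data_q = copy.deepcopy(data)
        for frag in data_q.fragments:
            frag.embedding_charges = rng.uniform(-1, 1, len(frag.atoms))
        h1 = assemble(esds, data_q, engine, nonvariational=True,
                      require_uniform_ms=False).matrix
        assert np.abs(h1 - h0).max() < 1e-8


class TestLimitingBehaviours:
    def test_zero_cross_terms_give_site_energy_sums(self):
        # atom-free model: the nuclear-frame constant vanishes as well
        model = ModelSystem.random((2, 2), (2, 2), seed=7, with_geometry=False)
        data, _, _ = make_oracle(model)
        esds = enumerate_esds(data, max_rank=2)
        h = assemble(esds, data, NullEngine({1: 2, 2: 2}),
                     require_uniform_ms=False).matrix
        assert np.abs(h - np.diag(np.diag(h))).max() == 0.0
        for i, e in enumerate(esds):
            want = sum(data.state(f, a).energy
                       for f, a in zip(e.fragment_ids, e.occupation))
            assert h[i, i] == pytest.approx(want, abs=1e-12)

    def test_nonvariational_defaults_off(self, small_oracle):
        data, engine, _ = small_oracle
        esds = select_ms(enumerate_esds(data, 1), 0.0)
        h_var = assemble(esds, data, engine).matrix
        h_non = assemble(esds, data, engine, nonvariational=True).matrix
        # with Q = 0 the two pathways coincide
        assert np.abs(h_var - h_non).max() < 1e-12

    def test_odd_electron_fragments_gated(self):
        model = ModelSystem.random((2, 2), (1, 2), seed=9)
        data, engine, _ = make_oracle(model)
        esds = select_ms(enumerate_esds(data, 1),
                         enumerate_esds(data, 1)[0].ms)
        with pytest.raises(ValueError, match="odd electron"):
            assemble(esds, data, engine)


class TestFEMMode:
    def test_gs_le_couplings_zero_and_diagonal_bare(self):
        data, engine = make_point_chromophore_dimer(separation=6.0)
        esds = select_ms(enumerate_esds(data, 1), 0.0)
        h = assemble(esds, data, engine, mode="fem", use_exchange=False)
        gs = [i for i, e in enumerate(esds) if e.rank == 0][0]
        les = [i for i, e in enumerate(esds) if e.rank == 1]
        for i in les:
            assert h.matrix[gs, i] == 0.0
        for i, e in enumerate(esds):
            want = sum(data.state(f, a).energy
                       for f, a in zip(e.fragment_ids, e.occupation))
            assert h.matrix[i, i] == pytest.approx(want, abs=1e-14)

    def test_eci_vs_fem_differ_by_bookkeeping_terms(self):
        """ECI minus FEM: rule-I couplings and the diagonal J - K only."""
        data, engine = make_point_chromophore_dimer(separation=6.0)
        esds = select_ms(enumerate_esds(data, 1), 0.0)
        h_eci = assemble(esds, data, engine, use_exchange=False,
                         dump_elements=True)
        h_fem = assemble(esds, data, engine, mode="fem", use_exchange=False)
        diff = h_eci.matrix - h_fem.matrix
        rules = {(i, j): r for i, j, r, _, _ in h_eci.provenance}
        n = len(esds)
        for i in range(n):
            for j in range(i, n):
                if i == j or rules.get((i, j)) == "I":
                    continue  # diagonal J-K terms and rule-I couplings differ
                assert diff[i, j] == pytest.approx(0.0, abs=1e-14)

    def test_fem_rejects_higher_ranks(self):
        data, engine = make_point_chromophore_dimer()
        esds = enumerate_esds(data, 2)
        with pytest.raises(ValueError, match="rank"):
            assemble(select_ms(esds, 0.0), data, engine, mode="fem")


class TestDipoleMatrices:
    def test_differ_rules(self):
        data, engine = make_point_chromophore_dimer(separation=8.0)
        esds = select_ms(enumerate_esds(data, 2), 0.0)
        mu = dipole_matrices(esds, data)
        by_occ = {e.occupation: i for i, e in enumerate(esds)}
        # differ-by-two -> zero
        assert np.abs(mu[:, by_occ[(1, 1)], by_occ[(0, 0)]]).max() == 0.0
        # differ-by-one -> the single site transition dipole (magnitude 1)
        v = mu[:, by_occ[(1, 0)], by_occ[(0, 0)]]
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_neutral_system_origin_independence(self):
        data, engine = make_point_chromophore_dimer(separation=8.0)
        esds = select_ms(enumerate_esds(data, 1), 0.0)
        mu0 = dipole_matrices(esds, data)
        shifted = copy.deepcopy(data)
        shift = np.array([1.0, 1.0, 1.0])
        for frag in shifted.fragments:
            for atom in frag.atoms:
                atom.R = atom.R + shift
            for key, val in list(frag.__dict__.items()):
                pass
        # electronic dipoles pick up -N_el * shift per fragment
        for f in (1, 2):
            for (b, k), v in list(shifted.dipoles[f].items()):
                if b == k:
                    shifted.dipoles[f].set(b, k, v - 2 * shift)
        mu1 = dipole_matrices(esds, shifted)
        gs = [i for i, e in enumerate(esds) if e.rank == 0][0]
        assert np.abs(mu1[:, gs, gs] - mu0[:, gs, gs]).max() < 1e-10
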