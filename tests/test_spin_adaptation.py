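"""S^2 blocks, ECSF extraction, and the spin-counting arithmetic."""

import itertools

import numpy as np
import pytest

from excitonci.basis import enumerate_esds, select_ms
from excitonci.fixtures import make_guanine_like_counting_fixture
from excitonci.spin_adaptation import (build_ecsfs, ecsf_spin_census,
                                       family_key, s2_matrix,
                                       transformation_matrix)


@pytest.fixture(scope="module")
def reduced():
    """The 6-excited-singlet + 3-triplet per fragment (post-screening) set."""
    return make_guanine_like_counting_fixture(n_singlets=6)


def _family(data, occupations, ms):
    esds = enumerate_esds(data, max_rank=2)
    block = [e for e in esds if e.occupation in set(occupations)]
    return [e for e in block if e.ms == ms]


class TestS2Matrix:
    def test_all_singlet_esd_is_trivial(self, reduced):
        esds = enumerate_esds(reduced, 1)
        gs = [esds[0]]
        mat = s2_matrix(gs, reduced)
        assert mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_two_triplet_family_eigenvalues(self, reduced):
        # T1 on fragments 1 and 2, all m_s combinations with M_S = 0
        occs = [tuple([a, b, 0, 0]) for a in (7, 8, 9) for b in (7, 8, 9)]
        fam = _family(reduced, occs, 0.0)
        assert len(fam) == 3
        vals = np.sort(np.linalg.eigvalsh(s2_matrix(fam, reduced)))
        assert np.allclose(vals, [0.0, 2.0, 6.0], atol=1e-12)

    def test_singlet_combination_is_clebsch_gordan(self, reduced):
        occs = [tuple([a, b, 0, 0]) for a in (7, 8, 9) for b in (7, 8, 9)]
        fam = sorted(_family(reduced, occs, 0.0), key=lambda e: e.ordinal)
        ecsfs, _ = build_ecsfs(fam, 0.0, reduced)
        assert len(ecsfs) == 1
        # order the coefficients as (|+1,-1>, |0,0>, |-1,+1>)
        def ms_pair(e):
            sa = reduced.state(1, e.occupation[0]).spin_ms
            return -sa
        ordered = sorted(fam, key=ms_pair)
        c = [ecsfs[0].coefficients.get(e.ordinal, 0.0) for e in ordered]
        ref = np.array([1.0, -1.0, 1.0]) / np.sqrt(3.0)
        assert (np.allclose(c, ref, atol=1e-10)
                or np.allclose(c, -ref, atol=1e-10))

    def test_mixed_family_rejected(self, reduced):
        esds = enumerate_esds(reduced, 1)
        with pytest.raises(Exception, match="mixes"):
            s2_matrix([esds[0], esds[1]], reduced)


class TestECSFCounts:
    def test_ecis_singlets(self, reduced):
        block = select_ms(enumerate_esds(reduced, 1), 0.0)
        ecsfs, esd_set = build_ecsfs(block, 0.0, reduced)
        assert len(ecsfs) == 25 and len(esd_set) == 25

    def test_ecisd_singlets(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 0.0)
        ecsfs, esd_set = build_ecsfs(block, 0.0, reduced)
        assert len(ecsfs) == 295 and len(esd_set) == 403

    def test_ecisd_triplets(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 1.0)
        ecsfs, esd_set = build_ecsfs(block, 1.0, reduced)
        assert len(ecsfs) == 282 and len(esd_set) == 336

    def test_ecisd_quintets(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 2.0)
        ecsfs, esd_set = build_ecsfs(block, 2.0, reduced)
        assert len(ecsfs) == 54 and len(esd_set) == 54

    def test_full_set_counts(self, counting_fixture):
        # the 7-excited-singlet set of the same four-fragment system
        block0 = select_ms(enumerate_esds(counting_fixture, 2), 0.0)
        ecsfs0, esds0 = build_ecsfs(block0, 0.0, counting_fixture)
        assert len(ecsfs0) == 377 and len(esds0) == 485
        block1 = select_ms(enumerate_esds(counting_fixture, 2), 1.0)
        ecsfs1, esds1 = build_ecsfs(block1, 1.0, counting_fixture)
        assert len(ecsfs1) == 318 and len(esds1) == 372


class TestECSFProperties:
    def test_normalization_and_orthonormality(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 1.0)
        ecsfs, _ = build_ecsfs(block, 1.0, reduced)
        t = transformation_matrix(ecsfs, block)
        gram = t.T @ t
        assert np.allclose(gram, np.eye(len(ecsfs)), atol=1e-10)

    def test_members_share_family_and_rank(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 0.0)
        ecsfs, _ = build_ecsfs(block, 0.0, reduced)
        by_ord = {e.ordinal: e for e in block}
        for c in ecsfs:
            members = [by_ord[o] for o in c.coefficients]
            assert len({family_key(m, reduced) for m in members}) == 1
            assert all(m.rank == c.rank for m in members)

    def test_s2_eigenvalue_residual(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 0.0)
        ecsfs, _ = build_ecsfs(block, 0.0, reduced)
        groups = {}
        for e in block:
            groups.setdefault(family_key(e, reduced), []).append(e)
        for c in ecsfs[:40]:
            fam = sorted(groups[c.family_id], key=lambda e: e.ordinal)
            mat = s2_matrix(fam, reduced)
            v = np.array([c.coefficients.get(e.ordinal, 0.0) for e in fam])
            assert np.linalg.norm(mat @ v - 0.0 * v) < 1e-8

    def test_deterministic_sign_convention(self, reduced):
        block = select_ms(enumerate_esds(reduced, 2), 0.0)
        a, _ = build_ecsfs(block, 0.0, reduced)
        b, _ = build_ecsfs(block, 0.0, reduced)
        for x, y in zip(a, b):
            assert x.coefficients == y.coefficients
            assert max(x.coefficients.values(), key=abs) > 0


class TestMultiplicityBookkeeping:
    @pytest.mark.parametrize("spins", [(1, 1), (1, 1, 1), (1, 1, 1, 1),
                                       (0.5, 0.5), (1.5, 1)])
    def test_census_matches_angular_momentum_addition(self, spins):
        """S^2 eigen-census per family == Clebsch-Gordan decomposition."""
        from excitonci.site_model import (Atom, FragmentSpec, SiteData,
                                          SiteState)

        data = SiteData()
        for i, s in enumerate(spins, start=1):
            data.add_fragment(FragmentSpec(i, [Atom("X", 1.0, np.zeros(3))],
                                           2, {"kind": "synthetic"}))
            data.add_state(SiteState(i, 0, 0.0, 0.0, 0.0, f"F{i}GS", ""))
            idx = 1
            two_s = int(round(2 * s))
            for two_m in range(two_s, -two_s - 1, -2):
                data.add_state(SiteState(i, idx, 0.1, s, two_m / 2.0,
                                         f"F{i}M", ""))
                idx += 1
        esds = enumerate_esds(data, max_rank=len(spins))
        top = [e for e in esds if e.rank == len(spins)]
        # reference: decompose the product of the spins by CG recursion
        def couple(js):
            out = {js[0]: 1}
            for j in js[1:]:
                new = {}
                for j1, n in out.items():
                    lo, hi = abs(j1 - j), j1 + j
                    jj = lo
                    while jj <= hi + 1e-9:
                        new[round(jj, 1)] = new.get(round(jj, 1), 0) + n
                        jj += 1.0
                out = new
            return out
        expected = couple([float(s) for s in spins])
        for total_m in sorted({e.ms for e in top}):
            block = [e for e in top if e.ms == total_m]
            census = ecsf_spin_census(block, data)
            want = {s: n for s, n in expected.items() if s >= abs(total_m) - 1e-9}
            assert census == want
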