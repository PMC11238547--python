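"""Spin adaptation: from ESDs to excitonic configuration-state functions.

ESDs carry a definite total spin projection M_S but are generally not
eigenfunctions of the total S^2.  Within one *family* -- the set of ESDs
sharing the same spatial configuration (the same occupied multiplet on every
fragment) and the same M_S, differing only in how m_s is distributed -- S^2
is block diagonal and is diagonalized numerically.  Eigenvectors with
eigenvalue S(S+1) are the ECSFs of total spin S.

S^2 = sum_F s_F^2 + 2 sum_{F<G} [s_zF s_zG + (s+_F s-_G + s-_F s+_G)/2]
with Condon-Shortley ladder phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .basis import ESD
from .site_model import SiteData
from .spinutil import ladder_factor, s_from_eigval

__all__ = ["ECSF", "family_key", "s2_matrix", "build_ecsfs",
           "ecsf_spin_census", "transformation_matrix", "SpinAdaptationError"]

S2_EIGTOL = 1e-8
COEFF_PRUNE = 1e-12


class SpinAdaptationError(RuntimeError):
    pass


@dataclass
class ECSF:
    """A spin-adapted, unit-normalized linear combination of ESDs."""

    total_s: float
    family_id: Tuple
    coefficients: Dict[int, float]      # ESD ordinal -> coefficient
    rank: int

    def vector(self, ordinal_to_pos: Dict[int, int], n: int) -> np.ndarray:
        v = np.zeros(n)
        for o, c in self.coefficients.items():
            v[ordinal_to_pos[o]] = c
        return v


def family_key(esd: ESD, site_data: SiteData) -> Tuple:
    """Spatial-configuration key: the occupied multiplet on every fragment."""
    return tuple(
        site_data.state(f, a).multiplet_id
        for f, a in zip(esd.fragment_ids, esd.occupation)
    )


def _spins(esd: ESD, site_data: SiteData) -> List[Tuple[float, float]]:
    out = []
    for f, a in zip(esd.fragment_ids, esd.occupation):
        st = site_data.state(f, a)
        out.append((st.spin_s, st.spin_ms))
    return out


def s2_matrix(family: Sequence[ESD], site_data: SiteData) -> np.ndarray:
    """Matrix of total S^2 over ESDs sharing one multiplet-occupation pattern."""
    if not family:
        return np.zeros((0, 0))
    key0 = family_key(family[0], site_data)
    ms0 = family[0].two_ms
    for e in family[1:]:
        if family_key(e, site_data) != key0:
            raise SpinAdaptationError("S^2 block mixes spatial configurations")
        if e.two_ms != ms0:
            raise SpinAdaptationError("S^2 block mixes M_S values")
    spins = [_spins(e, site_data) for e in family]
    n = len(family)
    m_frag = len(key0)
    mat = np.zeros((n, n))
    for i in range(n):
        si = spins[i]
        diag = sum(s * (s + 1.0) for s, _ in si)
        diag += 2.0 * sum(si[a][1] * si[b][1]
                          for a in range(m_frag) for b in range(a + 1, m_frag))
        mat[i, i] = diag
        for j in range(i + 1, n):
            sj = spins[j]
            diff = [k for k in range(m_frag) if abs(si[k][1] - sj[k][1]) > 1e-9]
            if len(diff) != 2:
                continue
            a, b = diff
            da = si[a][1] - sj[a][1]
            db = si[b][1] - sj[b][1]
            if abs(da + db) > 1e-9 or abs(abs(da) - 1.0) > 1e-9:
                continue
            # <i| s+_a s-_b |j> (or the mirrored term), acting on ket j
            if da > 0:
                val = (ladder_factor(sj[a][0], sj[a][1], up=True)
                       * ladder_factor(sj[b][0], sj[b][1], up=False))
            else:
                val = (ladder_factor(sj[a][0], sj[a][1], up=False)
                       * ladder_factor(sj[b][0], sj[b][1], up=True))
            mat[i, j] = mat[j, i] = val
    return mat


def _group_families(esds: Sequence[ESD], site_data: SiteData
                    ) -> Dict[Tuple, List[ESD]]:
    fams: Dict[Tuple, List[ESD]] = {}
    for e in esds:
        fams.setdefault(family_key(e, site_data), []).append(e)
    return fams


def _canonical_subspace(vectors: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal basis of span(columns of vectors).

    Gram-Schmidt of the projector columns in canonical (ESD-ordinal) order;
    makes degenerate-eigenvector rotations reproducible.
    """
    n, k = vectors.shape
    proj = vectors @ vectors.T
    out = []
    for i in range(n):
        w = proj[:, i].copy()
        for v in out:
            w -= v * (v @ w)
        nrm = np.linalg.norm(w)
        if nrm > 1e-8:
            out.append(w / nrm)
        if len(out) == k:
            break
    if len(out) != k:
        raise SpinAdaptationError("failed to canonicalize degenerate subspace")
    return np.array(out).T


def _fix_sign(coeffs: Dict[int, float]) -> Dict[int, float]:
    best = max(coeffs.items(), key=lambda kv: (abs(kv[1]), -kv[0]))
    if best[1] < 0:
        coeffs = {o: -c for o, c in coeffs.items()}
    return coeffs


def build_ecsfs(esds: Sequence[ESD], total_s: float, site_data: SiteData
                ) -> Tuple[List[ECSF], Set[int]]:
    """Extract all ECSFs of spin ``total_s`` from an M_S = S block of ESDs.

    Returns the ECSFs (deterministically ordered and sign-fixed) and the set
    of ordinals of all contributing ESDs.
    """
    two_s = int(round(2 * total_s))
    for e in esds:
        if e.two_ms != two_s:
            raise SpinAdaptationError(
                f"build_ecsfs expects the M_S = S block; ESD {e} has M_S = {e.ms}")
    target = total_s * (total_s + 1.0)
    ecsfs: List[ECSF] = []
    contributing: Set[int] = set()
    for key, family in sorted(_group_families(esds, site_data).items(),
                              key=lambda kv: kv[1][0].ordinal):
        family = sorted(family, key=lambda e: e.ordinal)
        mat = s2_matrix(family, site_data)
        vals, vecs = np.linalg.eigh(mat)
        for lam in vals:
            if s_from_eigval(lam, S2_EIGTOL) is None:
                raise SpinAdaptationError(
                    f"S^2 eigenvalue {lam} in family {key} matches no S(S+1)")
        sel = np.abs(vals - target) < S2_EIGTOL
        if not np.any(sel):
            continue
        block = _canonical_subspace(vecs[:, sel])
        for col in range(block.shape[1]):
            v = block[:, col]
            coeffs = {family[i].ordinal: float(v[i])
                      for i in range(len(family)) if abs(v[i]) > COEFF_PRUNE}
            norm = np.sqrt(sum(c * c for c in coeffs.values()))
            coeffs = _fix_sign({o: c / norm for o, c in coeffs.items()})
            ecsfs.append(ECSF(total_s, key, coeffs, family[0].rank))
            contributing.update(coeffs)
    ecsfs.sort(key=lambda e: min(e.coefficients))
    return ecsfs, contributing


def ecsf_spin_census(esds: Sequence[ESD], site_data: SiteData
                     ) -> Dict[float, int]:
    """Count S^2 eigenvectors per total spin S in an M_S block."""
    census: Dict[float, int] = {}
    for family in _group_families(esds, site_data).values():
        vals = np.linalg.eigvalsh(s2_matrix(family, site_data))
        for lam in vals:
            s = s_from_eigval(lam, S2_EIGTOL)
            if s is None:
                raise SpinAdaptationError(f"S^2 eigenvalue {lam} matches no S(S+1)")
            census[s] = census.get(s, 0) + 1
    return census


def transformation_matrix(ecsfs: Sequence[ECSF], esds: Sequence[ESD]
                          ) -> np.ndarray:
    """Dense (n_ESD x n_ECSF) basis-change matrix T with orthonormal columns."""
    pos = {e.ordinal: i for i, e in enumerate(esds)}
    t = np.zeros((len(esds), len(ecsfs)))
    for j, c in enumerate(ecsfs):
        for o, v in c.coefficients.items():
            t[pos[o], j] = v
    return t
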