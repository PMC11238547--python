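"""Interfragment interaction engines.

Every matrix element of the excitonic Hamiltonian reduces to four interaction
primitives between quantities living on two *different* fragments:

* ``density_charge_energy`` -- electrostatic energy of a (transition) density
  with a set of point charges (nuclear / embedding attraction terms),
* ``coulomb_J``            -- density-density Coulomb repulsion,
* ``exchange_K``           -- spin-blocked density-matrix exchange,
* ``overlap_measure``      -- a non-negative measure of how strongly the
  orbital spaces of two site states overlap (strong-orthogonality screening).

All engines return bare electrostatic kernels (no electron sign); the
Hamiltonian rules apply signs and the (Z - Q) embedding substitution.

Three engines ship:

``DiscreteChargeEngine``
    densities are weighted point sets; Coulomb only.  Fast, exact for
    point-chromophore toys.
``GaussianSEngine``
    s-type Gaussian AO bases with closed-form (erf / Boys) integrals,
    including exchange and the overlap measure.
``ModelIntegralEngine`` (in :mod:`excitonci.oracle`)
    contracts densities with the integral tensors of a model system with
    fragment-disjoint orthonormal orbitals; the engine the determinant
    oracle certifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .site_model import SpinBlockedTDM

__all__ = [
    "Density", "EngineError", "CapabilityError",
    "InteractionEngine", "DiscreteChargeEngine", "GaussianSEngine", "NullEngine",
]


class EngineError(ValueError):
    pass


class CapabilityError(EngineError):
    """An engine was asked for an integral class it does not support."""


@dataclass
class Density:
    """Spatial part of a (transition) density in a fragment's AO basis."""

    fragment_id: int
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim == 1:           # diagonal shorthand
            self.matrix = np.diag(self.matrix)


class InteractionEngine:
    """Contract for interfragment integral evaluation."""

    has_exchange: bool = False
    has_overlap_measure: bool = False

    def n_ao(self, fragment_id: int) -> int:
        raise NotImplementedError

    def density_charge_energy(self, rho: Density,
                              charges: Sequence[Tuple[float, np.ndarray]]) -> float:
        """integral rho(r) * sum_c q_c / |r - R_c| dr (kernel, no sign)."""
        raise NotImplementedError

    def coulomb_J(self, rho_f: Density, rho_g: Density) -> float:
        raise NotImplementedError

    def exchange_K(self, gamma_f: SpinBlockedTDM, gamma_g: SpinBlockedTDM) -> float:
        raise CapabilityError(f"{type(self).__name__} does not support exchange")

    def overlap_measure(self, gamma_f: SpinBlockedTDM, gamma_g: SpinBlockedTDM) -> float:
        raise CapabilityError(f"{type(self).__name__} has no overlap measure")

    def _check_pair(self, f: int, g: int) -> None:
        if f == g:
            raise EngineError(
                "intra-fragment terms live inside the site energies; "
                f"got fragment pair ({f},{g})")

    def _check_dim(self, rho: Density) -> None:
        n = self.n_ao(rho.fragment_id)
        if rho.matrix.shape != (n, n):
            raise EngineError(
                f"AO-basis mismatch on fragment {rho.fragment_id}: "
                f"density is {rho.matrix.shape}, basis dimension is {n}")


class NullEngine(InteractionEngine):
    """All cross-fragment terms are zero (noninteracting limit)."""

    has_exchange = True
    has_overlap_measure = True

    def __init__(self, dims: Dict[int, int] | None = None):
        self._dims = dims or {}

    def n_ao(self, fragment_id: int) -> int:
        return self._dims.get(fragment_id, 0)

    def density_charge_energy(self, rho, charges):
        return 0.0

    def coulomb_J(self, rho_f, rho_g):
        self._check_pair(rho_f.fragment_id, rho_g.fragment_id)
        return 0.0

    def exchange_K(self, gamma_f, gamma_g):
        return 0.0

    def overlap_measure(self, gamma_f, gamma_g):
        return 0.0


class DiscreteChargeEngine(InteractionEngine):
    """Densities as weighted point sets with pairwise Coulomb sums.

    The AO 'basis' of fragment F is a list of points; only the diagonal of a
    density matrix carries weight (off-diagonal products of distinct points
    have no spatial extent and must be zero).
    """

    has_exchange = False
    has_overlap_measure = False

    def __init__(self, points: Dict[int, np.ndarray]):
        self.points = {f: np.asarray(p, dtype=float).reshape(-1, 3)
                       for f, p in points.items()}

    def n_ao(self, fragment_id: int) -> int:
        return len(self.points[fragment_id])

    @staticmethod
    def _weights(rho: Density) -> np.ndarray:
        off = rho.matrix - np.diag(np.diag(rho.matrix))
        if np.abs(off).max(initial=0.0) > 1e-12:
            raise EngineError(
                "DiscreteChargeEngine requires diagonal density matrices")
        return np.diag(rho.matrix)

    def density_charge_energy(self, rho, charges):
        self._check_dim(rho)
        w = self._weights(rho)
        pts = self.points[rho.fragment_id]
        total = 0.0
        for q, pos in charges:
            d = np.linalg.norm(pts - np.asarray(pos, dtype=float), axis=1)
            if np.any(d < 1e-12):
                raise EngineError("coincident point positions (r = 0)")
            total += q * float(np.sum(w / d))
        return total

    def coulomb_J(self, rho_f, rho_g):
        self._check_pair(rho_f.fragment_id, rho_g.fragment_id)
        self._check_dim(rho_f)
        self._check_dim(rho_g)
        wf = self._weights(rho_f)
        wg = self._weights(rho_g)
        pf = self.points[rho_f.fragment_id]
        pg = self.points[rho_g.fragment_id]
        d = np.linalg.norm(pf[:, None, :] - pg[None, :, :], axis=2)
        if np.any(d < 1e-12):
            raise EngineError("coincident point positions (r = 0)")
        return float(wf @ (1.0 / d) @ wg)


def _boys0(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    small = t < 1e-12
    ts = np.where(small, 1.0, t)
    out = np.where(small, 1.0 - t / 3.0, 0.5 * np.sqrt(np.pi / ts) * erf(np.sqrt(ts)))
    return out


class GaussianSEngine(InteractionEngine):
    """Closed-form integrals over normalized s-type Gaussian AOs.

    Fragment F's basis is a list of (center, exponent) pairs.  Overlap,
    nuclear attraction and two-electron integrals over s-Gaussians reduce to
    erf/Boys expressions, which is all that is needed for physically
    meaningful toy chromophores without an external integral library.
    """

    has_exchange = True
    has_overlap_measure = True

    def __init__(self, shells: Dict[int, List[Tuple[np.ndarray, float]]]):
        self.shells = {
            f: [(np.asarray(c, dtype=float).reshape(3), float(a)) for c, a in sh]
            for f, sh in shells.items()
        }
        self._pairs: Dict[Tuple[int, int], tuple] = {}

    def n_ao(self, fragment_id: int) -> int:
        return len(self.shells[fragment_id])

    @staticmethod
    def _norm(alpha: float) -> float:
        return (2.0 * alpha / np.pi) ** 0.75

    def _pair_data(self, f: int, g: int):
        """Composite-Gaussian data for all (mu in f, nu in g) AO products."""
        key = (f, g)
        if key in self._pairs:
            return self._pairs[key]
        A = self.shells[f]
        B = self.shells[g]
        nf, ng = len(A), len(B)
        P = np.zeros((nf, ng, 3))
        expo = np.zeros((nf, ng))
        coef = np.zeros((nf, ng))
        for i, (Ra, aa) in enumerate(A):
            for j, (Rb, ab) in enumerate(B):
                p = aa + ab
                mu = aa * ab / p
                P[i, j] = (aa * Ra + ab * Rb) / p
                expo[i, j] = p
                coef[i, j] = (self._norm(aa) * self._norm(ab)
                              * np.exp(-mu * np.dot(Ra - Rb, Ra - Rb)))
        self._pairs[key] = (P, expo, coef)
        return self._pairs[key]

    def overlap_matrix(self, f: int, g: int) -> np.ndarray:
        P, expo, coef = self._pair_data(f, g)
        return coef * (np.pi / expo) ** 1.5

    def density_charge_energy(self, rho, charges):
        self._check_dim(rho)
        f = rho.fragment_id
        P, expo, coef = self._pair_data(f, f)
        total = 0.0
        for q, pos in charges:
            r2 = np.sum((P - np.asarray(pos, dtype=float)) ** 2, axis=2)
            V = coef * (2.0 * np.pi / expo) * _boys0(expo * r2)
            total += q * float(np.sum(rho.matrix * V))
        return total

    def _eri_cross(self, fpair, gpair) -> np.ndarray:
        """(mu nu | la si) with (mu,nu) from fpair and (la,si) from gpair."""
        P1, p1, c1 = fpair
        P2, p2, c2 = gpair
        sh1 = P1.shape[:2]
        sh2 = P2.shape[:2]
        P1f = P1.reshape(-1, 3)
        P2f = P2.reshape(-1, 3)
        p1f = p1.reshape(-1)
        p2f = p2.reshape(-1)
        r2 = np.sum((P1f[:, None, :] - P2f[None, :, :]) ** 2, axis=2)
        pq = p1f[:, None] * p2f[None, :]
        psum = p1f[:, None] + p2f[None, :]
        pref = 2.0 * np.pi ** 2.5 / (pq * np.sqrt(psum))
        eri = (c1.reshape(-1)[:, None] * c2.reshape(-1)[None, :]
               * pref * _boys0(pq / psum * r2))
        return eri.reshape(sh1 + sh2)

    def coulomb_J(self, rho_f, rho_g):
        self._check_pair(rho_f.fragment_id, rho_g.fragment_id)
        self._check_dim(rho_f)
        self._check_dim(rho_g)
        eri = self._eri_cross(
            self._pair_data(rho_f.fragment_id, rho_f.fragment_id),
            self._pair_data(rho_g.fragment_id, rho_g.fragment_id))
        return float(np.einsum("pq,rs,pqrs->", rho_f.matrix, rho_g.matrix, eri))

    def exchange_K(self, gamma_f, gamma_g):
        f, g = gamma_f.fragment_id, gamma_g.fragment_id
        self._check_pair(f, g)
        # X[q, r, p, s] = (q_F r_G | p_F s_G); K = sum_{st} gF^{st} gG^{ts} X
        X = self._eri_cross(self._pair_data(f, g), self._pair_data(f, g))
        X = X.transpose(0, 1, 2, 3)  # already (qF, rG, pF, sG)
        total = 0.0
        for st, ts in (("aa", "aa"), ("bb", "bb"), ("ab", "ba"), ("ba", "ab")):
            total += np.einsum("pq,rs,qrps->",
                               gamma_f.blocks[st], gamma_g.blocks[ts], X)
        return float(total)

    def overlap_measure(self, gamma_f, gamma_g):
        f, g = gamma_f.fragment_id, gamma_g.fragment_id
        self._check_pair(f, g)
        S = self.overlap_matrix(f, g)
        Df = gamma_f.spatial()
        Dg = gamma_g.spatial()
        return float(np.trace(Df @ S @ Dg @ S.T))
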