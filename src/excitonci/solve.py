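"""Diagonalization of spin blocks and analysis of the full-system states.

States are obtained per total-spin block by transforming the ESD-basis
Hamiltonian into the ECSF basis and diagonalizing densely.  Diagnostics:

* participation ratio  PR(I) = (sum_K c_KI^2)^2 / sum_K c_KI^4 -- the
  effective number of ECSFs contributing to state I (1 for a single ECSF,
  L for L equal-weight contributions);
* excitation-rank weights E_n(I) = sum over ECSFs of rank n of c_KI^2,
  which partition unity over n = 0 (aufbau), 1 (LE), 2 (DLE), ...

Oscillator strengths use the length gauge, f = (2/3) dE |mu|^2 in a.u.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .basis import ESD
from .spin_adaptation import ECSF, transformation_matrix

__all__ = [
    "ECIResult", "solve", "participation_ratio", "excitation_rank_weights",
    "oscillator_strengths", "gaussian_broadening", "HARTREE_TO_EV",
]

HARTREE_TO_EV = 27.211386245988


def _canonicalize_columns(vals: np.ndarray, vecs: np.ndarray,
                          tol: float = 1e-10) -> np.ndarray:
    """Deterministic eigenvectors: Gram-Schmidt within degenerate clusters
    against the canonical basis order, leading coefficient positive."""
    n = vecs.shape[1]
    out = vecs.copy()
    i = 0
    while i < n:
        j = i + 1
        while j < n and abs(vals[j] - vals[i]) < tol * max(1.0, abs(vals[i])):
            j += 1
        if j - i > 1:
            block = out[:, i:j]
            proj = block @ block.T
            basis = []
            for row in range(proj.shape[0]):
                w = proj[:, row].copy()
                for v in basis:
                    w -= v * (v @ w)
                nrm = np.linalg.norm(w)
                if nrm > 1e-8:
                    basis.append(w / nrm)
                if len(basis) == j - i:
                    break
            out[:, i:j] = np.array(basis).T
        for c in range(i, j):
            lead = np.argmax(np.abs(out[:, c]) > 1e-12)
            if out[lead, c] < 0:
                out[:, c] = -out[:, c]
        i = j
    return out


def solve(h: np.ndarray, symmetry_tol: float = 1e-8
          ) -> Tuple[np.ndarray, np.ndarray]:
    """Ascending eigenvalues and canonicalized eigenvectors of a symmetric H."""
    h = np.asarray(h, dtype=float)
    if h.size and np.abs(h - h.T).max() > symmetry_tol:
        raise ValueError(
            f"Hamiltonian asymmetry {np.abs(h - h.T).max():.2e} exceeds "
            f"{symmetry_tol}")
    vals, vecs = np.linalg.eigh(0.5 * (h + h.T))
    return vals, _canonicalize_columns(vals, vecs)


def participation_ratio(c: np.ndarray) -> float:
    c = np.asarray(c, dtype=float)
    s2 = float(np.sum(c ** 2))
    if s2 <= 0.0:
        raise ValueError("zero coefficient vector")
    return s2 ** 2 / float(np.sum(c ** 4))


def excitation_rank_weights(c: np.ndarray, ranks: Sequence[int]
                            ) -> Dict[int, float]:
    c = np.asarray(c, dtype=float)
    out: Dict[int, float] = {}
    for ci, r in zip(c, ranks):
        out[r] = out.get(r, 0.0) + float(ci * ci)
    return out


def oscillator_strengths(energies: np.ndarray, c: np.ndarray,
                         dipoles: np.ndarray, reference: int = 0
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Length-gauge f and transition dipoles from the reference state.

    ``dipoles`` are the (3, N, N) matrices in the same basis as the
    coefficient matrix ``c``.
    """
    mu_state = np.einsum("i,xij,jn->xn", c[:, reference], dipoles, c)
    de = energies - energies[reference]
    f = (2.0 / 3.0) * de * np.sum(mu_state ** 2, axis=0)
    return f, mu_state


def gaussian_broadening(sticks: Sequence[Tuple[float, float]],
                        grid: np.ndarray, fwhm: float) -> np.ndarray:
    """Broaden (energy, intensity) sticks on a grid with Gaussians of fwhm."""
    grid = np.asarray(grid, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = np.zeros_like(grid)
    for e0, inten in sticks:
        y += inten * np.exp(-0.5 * ((grid - e0) / sigma) ** 2)
    return y


@dataclass
class ECIResult:
    """Per-spin-block solution of the excitonic CI problem."""

    total_s: float
    energies: np.ndarray                  # hartree, ascending
    coefficients: np.ndarray              # ECSF basis, columns = states
    ecsfs: List[ECSF]
    esds: List[ESD]
    coefficients_esd: np.ndarray = field(default=None)
    pr: np.ndarray = field(default=None)
    rank_weights: List[Dict[int, float]] = field(default_factory=list)
    osc_strengths: Optional[np.ndarray] = None
    dipoles: Optional[np.ndarray] = None  # (3, n_states) from reference
    meta: Dict = field(default_factory=dict)

    @classmethod
    def from_block(cls, total_s: float, h_esd: np.ndarray, esds: Sequence[ESD],
                   ecsfs: Sequence[ECSF],
                   dipoles_esd: Optional[np.ndarray] = None,
                   reference: int = 0, meta: Optional[Dict] = None
                   ) -> "ECIResult":
        t = transformation_matrix(ecsfs, esds)
        h_ecsf = t.T @ h_esd @ t
        vals, vecs = solve(h_ecsf)
        res = cls(total_s=total_s, energies=vals, coefficients=vecs,
                  ecsfs=list(ecsfs), esds=list(esds), meta=meta or {})
        res.coefficients_esd = t @ vecs
        res.pr = np.array([participation_ratio(vecs[:, i])
                           for i in range(vecs.shape[1])])
        ranks = [c.rank for c in ecsfs]
        res.rank_weights = [excitation_rank_weights(vecs[:, i], ranks)
                            for i in range(vecs.shape[1])]
        if dipoles_esd is not None:
            mu_ecsf = np.einsum("ik,xij,jl->xkl", t, dipoles_esd, t)
            f, mu = oscillator_strengths(vals, vecs, mu_ecsf, reference)
            res.osc_strengths = f
            res.dipoles = mu
        return res

    def excitation_energies_ev(self, reference: int = 0) -> np.ndarray:
        return (self.energies - self.energies[reference]) * HARTREE_TO_EV

    def leading_ecsfs(self, state: int, n: int = 3
                      ) -> List[Tuple[int, float]]:
        c = self.coefficients[:, state]
        order = np.argsort(-np.abs(c))[:n]
        return [(int(k), float(c[k])) for k in order]

    def to_dict(self) -> Dict:
        d = {
            "total_s": self.total_s,
            "n_ecsf": len(self.ecsfs),
            "n_esd": len(self.esds),
            "energies_hartree": self.energies.tolist(),
            "excitation_energies_ev": self.excitation_energies_ev().tolist(),
            "participation_ratio": self.pr.tolist(),
            "rank_weights": [{str(k): v for k, v in rw.items()}
                             for rw in self.rank_weights],
            "leading_ecsfs": [self.leading_ecsfs(i)
                              for i in range(len(self.energies))],
            "meta": self.meta,
        }
        if self.osc_strengths is not None:
            d["oscillator_strengths"] = self.osc_strengths.tolist()
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def spectrum_csv(self, path: str, reference: int = 0) -> None:
        if self.osc_strengths is None:
            raise ValueError("no oscillator strengths computed")
        ev = self.excitation_energies_ev(reference)
        with open(path, "w") as fh:
            fh.write("state,E_exc_eV,f,PR\n")
            for i in range(len(ev)):
                if i == reference:
                    continue
                fh.write(f"{i},{ev[i]:.6f},{self.osc_strengths[i]:.6f},"
                         f"{self.pr[i]:.4f}\n")
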