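"""Excitonic Hartree-Fock: self-consistent point-charge embedding.

The embedding charges only deform the site states -- the full-system
Hamiltonian operator does not depend on them -- so they can be optimized
variationally.  Restricting every atom's charge to be the RESP charge of its
fragment's embedded ground state turns the minimization of the ground-state
product energy into a fixed-point iteration:

1. guess embedding charges (all zero by default);
2. compute the embedded ground state of every fragment in the field of the
   other fragments' charges;
3. RESP-fit each embedded ground-state density;
4. replace the embedding charges by the fitted ones;
5. repeat until max |delta Q| < t_Q;
6. evaluate the ground-state product energy with the final charges.

Zero cycles of this loop is the frozen-density approximation (FDA), one
cycle gives isolated-fragment ESP embedding, convergence gives EHF charges
-- the excitonic analogue of canonical Hartree-Fock orbitals (with
converged charges the ground-state/local-excitation couplings become small:
the excitonic analogue of Brillouin's theorem).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .backend import SiteBackend
from .basis import enumerate_esds
from .hamiltonian import assemble

logger = logging.getLogger(__name__)

__all__ = ["RespConfig", "EHFState", "mk_grid", "resp_fit", "ehf_loop",
           "embedding_mode", "ehf_energy"]

#: Bondi van der Waals radii, angstrom (fallback 1.5 for unknown elements)
VDW_RADII = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "X": 1.50,
}
ANGSTROM_TO_BOHR = 1.8897259886


@dataclass
class RespConfig:
    """Restrained ESP fit settings (Merz-Kollman-style shells)."""

    shell_scales: Tuple[float, ...] = (1.4, 1.6, 1.8, 2.0)
    points_per_ang2: float = 1.0
    restraint_a: float = 0.0005      # hyperbolic restraint strength, a.u.
    restraint_b: float = 0.1         # tightness, e
    max_iter: int = 50
    tol: float = 1e-6
    vdw_radii: Dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def radius(self, element: str) -> float:
        return self.vdw_radii.get(element, 1.5) * ANGSTROM_TO_BOHR


@dataclass
class EHFState:
    """Result of the self-consistent embedding loop."""

    cycles: int
    charges: Dict[int, np.ndarray]
    energy: float
    max_dq: float
    converged: bool
    history: List[Tuple[int, float, float]] = field(default_factory=list)
    #: rows (cycle, max|dQ|, E_0)

    def history_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("cycle,max_dq,E0\n")
            for c, dq, e0 in self.history:
                fh.write(f"{c},{dq:.3e},{e0:.12f}\n")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def mk_grid(elements: Sequence[str], positions: np.ndarray,
            config: RespConfig) -> np.ndarray:
    """Deterministic Merz-Kollman-style shell grid around a fragment."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.array([config.radius(e) for e in elements])
    points = []
    for scale in config.shell_scales:
        for a, (ra, pa) in enumerate(zip(radii, positions)):
            r = scale * ra
            area_ang2 = 4.0 * np.pi * (r / ANGSTROM_TO_BOHR) ** 2
            n = max(8, int(np.ceil(config.points_per_ang2 * area_ang2)))
            sphere = pa + r * _fibonacci_sphere(n)
            keep = np.ones(len(sphere), dtype=bool)
            for b, (rb, pb) in enumerate(zip(radii, positions)):
                if b == a:
                    continue
                keep &= (np.linalg.norm(sphere - pb, axis=1)
                         >= scale * rb - 1e-9)
            points.append(sphere[keep])
    return np.vstack(points)


def resp_fit(esp_values: np.ndarray, points: np.ndarray,
             atom_positions: np.ndarray, net_charge: float,
             config: Optional[RespConfig] = None) -> np.ndarray:
    """Charges minimizing the ESP residual under a total-charge constraint.

    Iteratively reweighted hyperbolic restraint; with restraint_a = 0 this is
    a plain constrained least-squares ESP fit that recovers an exact
    point-charge potential to numerical precision.
    """
    config = config or RespConfig()
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    atom_positions = np.asarray(atom_positions, dtype=float).reshape(-1, 3)
    esp_values = np.asarray(esp_values, dtype=float)
    n_at = len(atom_positions)
    design = 1.0 / np.linalg.norm(
        points[:, None, :] - atom_positions[None, :, :], axis=2)
    m = design.T @ design
    b = design.T @ esp_values
    if np.linalg.cond(m) > 1e12 and config.restraint_a == 0.0:
        raise np.linalg.LinAlgError(
            "singular ESP normal equations; add grid points or a restraint")
    q = np.zeros(n_at)
    for _ in range(max(config.max_iter, 1)):
        rst = (config.restraint_a
               / np.sqrt(q ** 2 + config.restraint_b ** 2))
        lhs = np.zeros((n_at + 1, n_at + 1))
        lhs[:n_at, :n_at] = m + np.diag(rst)
        lhs[:n_at, n_at] = 1.0
        lhs[n_at, :n_at] = 1.0
        rhs = np.concatenate([b, [net_charge]])
        sol = np.linalg.solve(lhs, rhs)
        q_new = sol[:n_at]
        if np.max(np.abs(q_new - q)) < config.tol:
            q = q_new
            break
        q = q_new
    return q


def ehf_energy(backend: SiteBackend, charges: Dict[int, np.ndarray]) -> float:
    """Ground-state product energy, rule-0 element via the single code path."""
    data = backend.site_data(charges, n_multiplets=1)
    engine = backend.engine()
    esds = enumerate_esds(data, max_rank=1)
    gs = [e for e in esds if e.rank == 0]
    h = assemble(gs, data, engine)
    return float(h.matrix[0, 0])


def ehf_loop(backend: SiteBackend, t_q: float = 1e-4, max_cycles: int = 50,
             resp_config: Optional[RespConfig] = None,
             initial: Optional[Dict[int, np.ndarray]] = None,
             mixing: Optional[float] = None) -> EHFState:
    """Iterate embedded ground states and RESP fits to self-consistency."""
    resp_config = resp_config or RespConfig()
    fids = backend.fragment_ids()
    charges = {f: np.zeros(len(backend.atoms(f))) for f in fids}
    if initial:
        for f, q in initial.items():
            charges[f] = np.asarray(q, dtype=float).copy()
    history: List[Tuple[int, float, float]] = []
    converged = False
    dq_trace: List[float] = []
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        new_charges: Dict[int, np.ndarray] = {}
        for f in fids:
            ext = []
            for g in fids:
                if g == f:
                    continue
                for q, (_, r) in zip(charges[g], backend.atoms(g)):
                    if abs(q) > 0.0:
                        ext.append((float(q), r))
            _, density = backend.embedded_ground_state(f, ext)
            atoms = backend.atoms(f)
            elements = ["X"] * len(atoms)
            pos = np.array([r for _, r in atoms])
            grid = mk_grid(elements, pos, resp_config)
            v = backend.esp_values(f, density, grid)
            new_charges[f] = resp_fit(v, grid, pos, backend.net_charge(f),
                                      resp_config)
        max_dq = max(np.max(np.abs(new_charges[f] - charges[f])) for f in fids)
        if mixing is not None:
            for f in fids:
                new_charges[f] = ((1.0 - mixing) * charges[f]
                                  + mixing * new_charges[f])
        charges = new_charges
        e0 = ehf_energy(backend, charges)
        history.append((cycle, float(max_dq), e0))
        logger.info("EHF cycle %d: max|dQ| = %.3e, E0 = %.10f", cycle, max_dq, e0)
        dq_trace.append(float(max_dq))
        if max_dq < t_q:
            converged = True
            break
        if (len(dq_trace) >= 4 and mixing is None
                and abs(dq_trace[-1] - dq_trace[-3]) < 1e-12
                and abs(dq_trace[-2] - dq_trace[-4]) < 1e-12):
            logger.warning("EHF charges oscillate with period 2; "
                           "consider mixing=0.5")
    if not converged:
        logger.warning("EHF did not converge in %d cycles (max|dQ| = %.3e)",
                       max_cycles, history[-1][1] if history else np.nan)
    e0 = history[-1][2] if history else ehf_energy(backend, charges)
    return EHFState(cycles=cycle, charges=charges, energy=e0,
                    max_dq=history[-1][1] if history else 0.0,
                    converged=converged, history=history)


def embedding_mode(backend: SiteBackend, mode: str,
                   special_charges: Optional[Dict[Tuple[int, int], float]] = None,
                   t_q: float = 1e-4, max_cycles: int = 50,
                   resp_config: Optional[RespConfig] = None
                   ) -> Dict[int, np.ndarray]:
    """Charge set for site-state generation: 'fda', 'esp' or 'ehf'.

    FDA returns all-zero charges (with per-atom overrides honored, e.g. a
    bare +2 on a metal-cation fragment); ESP runs one embedding cycle; EHF
    iterates to convergence.
    """
    if mode not in ("fda", "esp", "ehf"):
        raise ValueError(f"unknown embedding mode {mode!r}")
    fids = backend.fragment_ids()
    if mode == "fda":
        charges = {f: np.zeros(len(backend.atoms(f))) for f in fids}
    else:
        cycles = 1 if mode == "esp" else max_cycles
        state = ehf_loop(backend, t_q=t_q, max_cycles=cycles,
                         resp_config=resp_config)
        charges = state.charges
    for (f, a), q in (special_charges or {}).items():
        if f not in charges or not 0 <= a < len(charges[f]):
            raise KeyError(f"charge override on unknown atom ({f},{a})")
        charges[f][a] = q
    return charges
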