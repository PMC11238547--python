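"""Pluggable backends for embedded site-state generation.

The ECI core is agnostic to how site states are produced: any object
implementing the :class:`SiteBackend` contract can supply embedded energies,
spin-blocked TDMs, dipoles and electrostatic-potential values.  One reference
backend ships -- :class:`ToyModelBackend`, exact diagonalization of the
oracle's model Hamiltonians with point-charge embedding -- so the whole
embedding/EHF machinery runs without any external electronic-structure
engine.  An adapter for a real integral/CIS engine would subclass
:class:`SiteBackend` and translate its outputs into the same bundle; the
core never imports backend internals.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .oracle import (ModelIntegralEngine, ModelSystem, Multiplet,
                     build_site_data, fragment_eigenstates)
from .site_model import SiteData

__all__ = ["SiteBackend", "ToyModelBackend"]

Charge = Tuple[float, np.ndarray]


class SiteBackend:
    """Contract for embedded monomer calculations."""

    capabilities: Dict[str, object] = {
        "max_multiplicity": None,
        "provides_tdm_spin_blocks": False,
        "provides_esp_grid": False,
    }

    def fragment_ids(self) -> List[int]:
        raise NotImplementedError

    def atoms(self, fragment_id: int) -> List[Tuple[float, np.ndarray]]:
        """(Z, R) pairs of the fragment's nuclei, bohr."""
        raise NotImplementedError

    def net_charge(self, fragment_id: int) -> float:
        raise NotImplementedError

    def embedded_ground_state(self, fragment_id: int,
                              ext_charges: Sequence[Charge]):
        """(energy, spatial GS density matrix) in the embedding field."""
        raise NotImplementedError

    def esp_values(self, fragment_id: int, density: np.ndarray,
                   points: np.ndarray) -> np.ndarray:
        """Electrostatic potential of nuclei + electron density at points."""
        raise NotImplementedError

    def site_data(self, charges: Dict[int, np.ndarray],
                  n_multiplets: Optional[int] = None) -> SiteData:
        """Full embedded site-state bundle for an ECI calculation."""
        raise NotImplementedError


def _charge_key(charges: Sequence[Charge]) -> bytes:
    if not charges:
        return b""
    arr = np.array([[q, *np.asarray(r, dtype=float)] for q, r in charges])
    return np.round(arr, 12).tobytes()


class ToyModelBackend(SiteBackend):
    """Exact-diagonalization backend over a point-orbital model system.

    Embedding charges enter the fragment Hamiltonian through the
    point-orbital attraction integrals; results are cached on the charge
    set, so repeated identical calls return the identical bundle.
    """

    capabilities = {
        "max_multiplicity": None,       # full CI: every multiplicity
        "provides_tdm_spin_blocks": True,
        "provides_esp_grid": True,
    }

    def __init__(self, model: ModelSystem):
        self.model = model
        self._cache: Dict[Tuple[int, bytes], Tuple[List[Multiplet], dict]] = {}
        for frag in model.fragments:
            if frag.orb_pos is None:
                raise ValueError("ToyModelBackend needs orbital positions")

    def fragment_ids(self) -> List[int]:
        return list(range(1, self.model.n_frag + 1))

    def atoms(self, fragment_id: int):
        return self.model.fragments[fragment_id - 1].atoms

    def net_charge(self, fragment_id: int) -> float:
        frag = self.model.fragments[fragment_id - 1]
        return float(sum(z for z, _ in frag.atoms) - frag.n_el)

    def _solve(self, fragment_id: int, ext_charges: Sequence[Charge]):
        key = (fragment_id, _charge_key(ext_charges))
        if key not in self._cache:
            mults, sectors = fragment_eigenstates(
                self.model, fragment_id - 1, ext_charges)
            self._cache[key] = (mults, sectors)
        return self._cache[key]

    def embedded_ground_state(self, fragment_id: int,
                              ext_charges: Sequence[Charge]):
        from .oracle import tdm_blocks

        mults, sectors = self._solve(fragment_id, ext_charges)
        gs = mults[0]
        two_m = max(gs.vectors)
        dets = sectors[two_m]
        blocks = tdm_blocks(self.model.fragments[fragment_id - 1].n_orb,
                            dets, gs.vectors[two_m], dets, gs.vectors[two_m])
        return gs.energy, blocks["aa"] + blocks["bb"]

    def esp_values(self, fragment_id: int, density: np.ndarray,
                   points: np.ndarray) -> np.ndarray:
        frag = self.model.fragments[fragment_id - 1]
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        v = np.zeros(len(points))
        for z, r in frag.atoms:
            v += z / np.linalg.norm(points - r, axis=1)
        pops = np.diag(density)
        for p, w in enumerate(pops):
            v -= w / np.linalg.norm(points - frag.orb_pos[p], axis=1)
        return v

    def site_data(self, charges: Dict[int, np.ndarray],
                  n_multiplets: Optional[int] = None) -> SiteData:
        mult_lists = []
        charge_arrays = []
        for fid in self.fragment_ids():
            ext: List[Charge] = []
            for gid in self.fragment_ids():
                if gid == fid:
                    continue
                qg = charges.get(gid)
                if qg is None:
                    continue
                for q, (z, r) in zip(qg, self.atoms(gid)):
                    if abs(q) > 0.0:
                        ext.append((float(q), r))
            mults, _ = self._solve(fid, ext)
            mult_lists.append(mults)
            qf = charges.get(fid)
            charge_arrays.append(
                np.zeros(len(self.atoms(fid))) if qf is None else np.asarray(qf))
        data, _, _ = build_site_data(
            self.model, multiplets=mult_lists, n_multiplets=n_multiplets,
            charges=charge_arrays)
        return data

    def engine(self) -> ModelIntegralEngine:
        return ModelIntegralEngine(self.model)
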