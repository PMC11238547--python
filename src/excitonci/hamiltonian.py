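"""Effective full-system Hamiltonian and dipole matrices in the ESD basis.

The matrix elements follow Slater-Condon-like rules with fragments playing
the role of electrons and site states the role of orbitals:

* rule 0  (bra == ket): sum of embedded site energies plus, for every
  fragment pair, the modified Coulomb term J~ (nuclear frame constant with
  the (Z - Q) embedding substitution, density-to-(Z - Q) attraction,
  density-density repulsion) minus the exchange term K;
* rule I  (one differing site state): transition density of the changed
  fragment against the state densities / embedding-corrected nuclei of every
  other fragment (J~ - K), plus the site-Hamiltonian cross term in
  nonvariational mode;
* rule II (two differing site states): electron-electron J - K only;
* more than two differing site states: zero.

Spin selection shortcuts (a spin-traced transition density vanishes unless
m_s is conserved on the fragment; |delta m_s| > 1 kills all one-particle
blocks) are applied before any integral is evaluated.

TDM blocks for non-principal m_s components are generated on demand from the
principal-pair blocks by the Wigner-Eckart relations for the scalar and
vector parts of a+_{p sigma} a_{q tau} (Condon-Shortley phases, consistent
with the ladder construction of the oracle and of the S^2 machinery).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .basis import ESD
from .engines import Density, InteractionEngine
from .site_model import SiteData, SiteState, SpinBlockedTDM
from .spinutil import clebsch_gordan

__all__ = [
    "MissingTDMError", "TDMProvider", "expand_tdm_components",
    "VariationalSiteHamiltonian", "NonvariationalSiteHamiltonian",
    "HamiltonianMatrix", "assemble", "dipole_matrices",
]

SQRT2 = float(np.sqrt(2.0))


class MissingTDMError(KeyError):
    pass


# ---------------------------------------------------------------------------
# spin-component expansion of stored (principal) TDM blocks
# ---------------------------------------------------------------------------

def expand_tdm_components(site_data: SiteData, fragment_id: int,
                          bra_index: int, ket_index: int) -> SpinBlockedTDM:
    """TDM blocks for an arbitrary (m_s bra, m_s ket) multiplet-component pair.

    Only the principal (m_s = s) pair of each multiplet pair needs stored
    blocks; the scalar part D = gamma^aa + gamma^bb and the vector part
    (t+, t_z, t-) of the one-body operator are carried to other components
    with Clebsch-Gordan ratios.  The generation is linear in the stored
    blocks and idempotent (expanding a principal pair returns it unchanged).
    """
    bra = site_data.state(fragment_id, bra_index)
    ket = site_data.state(fragment_id, ket_index)
    pb = site_data.principal_member(fragment_id, bra.multiplet_id)
    pk = site_data.principal_member(fragment_id, ket.multiplet_id)
    t0 = site_data.get_tdm(fragment_id, pb.state_index, pk.state_index)
    if t0 is None:
        raise MissingTDMError(
            f"fragment {fragment_id}: no stored TDM for principal pair "
            f"({pb.state_index},{pk.state_index}) of multiplets "
            f"({bra.multiplet_id},{ket.multiplet_id})")
    n = t0.n_ao
    zeros = lambda: np.zeros((n, n))
    blocks = {"aa": zeros(), "bb": zeros(), "ab": zeros(), "ba": zeros()}

    sb, sk = bra.spin_s, ket.spin_s
    mb, mk = bra.spin_ms, ket.spin_ms
    out = SpinBlockedTDM(fragment_id, bra_index, ket_index, blocks)
    if abs(sb - sk) > 1.0 + 1e-9 or abs(mb - mk) > 1.0 + 1e-9:
        return out          # no one-particle pathway between the multiplets

    # reduced (matrix-valued) elements from the principal pair
    r0 = (t0.blocks["aa"] + t0.blocks["bb"]) if abs(sb - sk) < 1e-9 else None
    qstar = sb - sk
    if abs(qstar) < 1e-9:
        t1_star = 0.5 * (t0.blocks["aa"] - t0.blocks["bb"])
    elif qstar > 0:
        t1_star = -t0.blocks["ab"] / SQRT2
    else:
        t1_star = t0.blocks["ba"] / SQRT2
    cg_star = clebsch_gordan(sk, sk, 1.0, qstar, sb, sb)
    r1 = None if abs(cg_star) < 1e-12 else t1_star / cg_star

    q = mb - mk
    if abs(q) < 1e-9:
        d = r0 if (r0 is not None and abs(mb - mk) < 1e-9) else None
        tz = None
        if r1 is not None:
            cg = clebsch_gordan(sk, mk, 1.0, 0.0, sb, mb)
            tz = cg * r1
        aa = zeros()
        bb = zeros()
        if d is not None:
            aa += 0.5 * d
            bb += 0.5 * d
        if tz is not None:
            aa += tz
            bb -= tz
        out.blocks["aa"] = aa
        out.blocks["bb"] = bb
    elif q > 0:
        if r1 is not None:
            cg = clebsch_gordan(sk, mk, 1.0, 1.0, sb, mb)
            out.blocks["ab"] = -SQRT2 * cg * r1
    else:
        if r1 is not None:
            cg = clebsch_gordan(sk, mk, 1.0, -1.0, sb, mb)
            out.blocks["ba"] = SQRT2 * cg * r1
    return out


class TDMProvider:
    """Cached access to spin-blocked TDMs, expanding components on demand."""

    def __init__(self, site_data: SiteData):
        self.site_data = site_data
        self._cache: Dict[Tuple[int, int, int], SpinBlockedTDM] = {}

    def get(self, fragment_id: int, bra_index: int, ket_index: int) -> SpinBlockedTDM:
        key = (fragment_id, bra_index, ket_index)
        if key in self._cache:
            return self._cache[key]
        stored = self.site_data.get_tdm(fragment_id, bra_index, ket_index)
        tdm = stored if stored is not None else expand_tdm_components(
            self.site_data, fragment_id, bra_index, ket_index)
        self._cache[key] = tdm
        return tdm


# ---------------------------------------------------------------------------
# site-Hamiltonian terms (variational vs nonvariational site states)
# ---------------------------------------------------------------------------

class VariationalSiteHamiltonian:
    """Site states are eigenstates of their embedded site Hamiltonian.

    Diagonal terms are the stored embedded energies; cross terms vanish.
    """

    def __init__(self, site_data: SiteData):
        self.site_data = site_data

    def diagonal(self, fragment_id: int, state_index: int) -> float:
        return self.site_data.state(fragment_id, state_index).energy

    def cross(self, fragment_id: int, bra_index: int, ket_index: int) -> float:
        return 0.0


class NonvariationalSiteHamiltonian:
    """Site-Hamiltonian matrix elements <a|H~_F|b> rebuilt from densities.

    For site states that are *not* eigenstates of the embedded site
    Hamiltonian (here: states stored with their bare, unembedded energies
    while the assembly runs with embedding charges Q), the diagonal site
    energies acquire the nuclear- and electron-embedding corrections and
    rule I acquires the cross term.  Off-diagonal bare elements <a|H_F|b>
    default to zero (eigenstates of the bare Hamiltonian) but can be
    supplied for diabatic-like site bases.
    """

    def __init__(self, site_data: SiteData, engine: InteractionEngine,
                 provider: Optional[TDMProvider] = None,
                 bare_offdiagonal: Optional[Dict[Tuple[int, int, int], float]] = None):
        self.site_data = site_data
        self.engine = engine
        self.provider = provider or TDMProvider(site_data)
        self.bare = bare_offdiagonal or {}

    def _q_charges(self, other_id: int):
        frag = self.site_data.fragment(other_id)
        return [(q, r) for q, r in zip(frag.embedding_charges, frag.positions)
                if abs(q) > 0.0]

    def _nuc_const(self, fragment_id: int) -> float:
        frag = self.site_data.fragment(fragment_id)
        e = 0.0
        for other in self.site_data.fragments:
            if other.fragment_id == fragment_id:
                continue
            for z, r in zip(frag.nuclear_charges, frag.positions):
                for q, rg in zip(other.embedding_charges, other.positions):
                    if abs(q) > 0.0:
                        e += z * q / np.linalg.norm(r - rg)
        return e

    def _embed_term(self, fragment_id: int, bra: int, ket: int) -> float:
        tdm = self.provider.get(fragment_id, bra, ket)
        rho = Density(fragment_id, tdm.spatial())
        e = 0.0
        for other in self.site_data.fragments:
            if other.fragment_id == fragment_id:
                continue
            charges = self._q_charges(other.fragment_id)
            if charges:
                e -= self.engine.density_charge_energy(rho, charges)
        return e

    def diagonal(self, fragment_id: int, state_index: int) -> float:
        e = self.site_data.state(fragment_id, state_index).energy
        return e + self._nuc_const(fragment_id) + self._embed_term(
            fragment_id, state_index, state_index)

    def cross(self, fragment_id: int, bra_index: int, ket_index: int) -> float:
        bra = self.site_data.state(fragment_id, bra_index)
        ket = self.site_data.state(fragment_id, ket_index)
        if bra.two_ms != ket.two_ms or bra.two_s != ket.two_s:
            return 0.0
        e = self.bare.get((fragment_id, bra_index, ket_index), 0.0)
        return e + self._embed_term(fragment_id, bra_index, ket_index)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class HamiltonianMatrix:
    matrix: np.ndarray
    esds: List[ESD]
    mode: str
    provenance: Optional[List[Tuple[int, int, str, float, float]]] = None
    #: rows (i, j, rule, J_total, K_total) when element dumping is enabled

    def dump_elements(self, path: str) -> None:
        if self.provenance is None:
            raise ValueError("assemble(..., dump_elements=True) required")
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bra", "ket", "rule", "J", "K", "total"])
            for i, j, rule, jv, kv in self.provenance:
                w.writerow([i, j, rule, jv, kv, self.matrix[i, j]])


class _Assembler:
    def __init__(self, site_data: SiteData, engine: InteractionEngine,
                 site_h, provider: TDMProvider, use_exchange: bool):
        self.data = site_data
        self.engine = engine
        self.site_h = site_h
        self.provider = provider
        self.use_exchange = use_exchange and engine.has_exchange
        self._jk_cache: Dict[Tuple, Tuple[float, float]] = {}
        self._zq: Dict[int, list] = {}
        self._vnn: Dict[Tuple[int, int], float] = {}

    def zq_charges(self, fragment_id: int):
        if fragment_id not in self._zq:
            frag = self.data.fragment(fragment_id)
            self._zq[fragment_id] = [
                (z - q, r) for z, q, r in zip(
                    frag.nuclear_charges, frag.embedding_charges, frag.positions)]
        return self._zq[fragment_id]

    def vnn_mod(self, f: int, g: int) -> float:
        key = (min(f, g), max(f, g))
        if key not in self._vnn:
            ff = self.data.fragment(key[0])
            gg = self.data.fragment(key[1])
            e = 0.0
            for zf, qf, rf in zip(ff.nuclear_charges, ff.embedding_charges,
                                  ff.positions):
                for zg, qg, rg in zip(gg.nuclear_charges, gg.embedding_charges,
                                      gg.positions):
                    d = np.linalg.norm(rf - rg)
                    e += (zf * zg - zf * qg - qf * zg) / d
            self._vnn[key] = e
        return self._vnn[key]

    def _dms(self, f: int, bra: int, ket: int) -> int:
        b = self.data.state(f, bra)
        k = self.data.state(f, ket)
        return b.two_ms - k.two_ms

    def jk_pair(self, f: int, pf: Tuple[int, int], g: int, pg: Tuple[int, int]
                ) -> Tuple[float, float]:
        """Modified J~ and K for state pairs (bra, ket) on fragments f, g."""
        key = (f, pf, g, pg)
        if key in self._jk_cache:
            return self._jk_cache[key]
        bf, kf = pf
        bg, kg = pg
        dmf = self._dms(f, bf, kf)
        dmg = self._dms(g, bg, kg)
        j = 0.0
        if dmf == 0 and dmg == 0:
            tf = self.provider.get(f, bf, kf)
            tg = self.provider.get(g, bg, kg)
            rf = Density(f, tf.spatial())
            rg = Density(g, tg.spatial())
            if bf == kf and bg == kg:
                j += self.vnn_mod(f, g)
            if bg == kg:
                charges = self.zq_charges(g)
                if charges:
                    j -= self.engine.density_charge_energy(rf, charges)
            if bf == kf:
                charges = self.zq_charges(f)
                if charges:
                    j -= self.engine.density_charge_energy(rg, charges)
            j += self.engine.coulomb_J(rf, rg)
        k = 0.0
        if self.use_exchange and dmf + dmg == 0 and abs(dmf) <= 2:
            tf = self.provider.get(f, bf, kf)
            tg = self.provider.get(g, bg, kg)
            k = self.engine.exchange_K(tf, tg)
        self._jk_cache[key] = (j, k)
        return (j, k)

    # -- rules -------------------------------------------------------------

    def rule0(self, esd: ESD) -> Tuple[float, float, float]:
        fids = esd.fragment_ids
        e = sum(self.site_h.diagonal(f, a) for f, a in zip(fids, esd.occupation))
        jtot = ktot = 0.0
        for i in range(len(fids)):
            for jdx in range(i + 1, len(fids)):
                f, g = fids[i], fids[jdx]
                a, c = esd.occupation[i], esd.occupation[jdx]
                jv, kv = self.jk_pair(f, (a, a), g, (c, c))
                jtot += jv
                ktot += kv
        return e + jtot - ktot, jtot, ktot

    def rule1(self, bra: ESD, ket: ESD, pos: int) -> Tuple[float, float, float]:
        fids = bra.fragment_ids
        f = fids[pos]
        b, a = bra.occupation[pos], ket.occupation[pos]
        jtot = ktot = 0.0
        for i, g in enumerate(fids):
            if i == pos:
                continue
            c = bra.occupation[i]
            jv, kv = self.jk_pair(f, (b, a), g, (c, c))
            jtot += jv
            ktot += kv
        e = self.site_h.cross(f, b, a)
        return e + jtot - ktot, jtot, ktot

    def rule2(self, bra: ESD, ket: ESD, pos1: int, pos2: int
              ) -> Tuple[float, float, float]:
        fids = bra.fragment_ids
        f, g = fids[pos1], fids[pos2]
        jv, kv = self.jk_pair(
            f, (bra.occupation[pos1], ket.occupation[pos1]),
            g, (bra.occupation[pos2], ket.occupation[pos2]))
        return jv - kv, jv, kv


def assemble(esds: Sequence[ESD], site_data: SiteData,
             engine: InteractionEngine, mode: str = "eci",
             nonvariational: bool = False,
             site_hamiltonian=None,
             use_exchange: bool = True,
             allow_odd_electron: bool = False,
             dump_elements: bool = False,
             require_uniform_ms: bool = True,
             provider: Optional[TDMProvider] = None) -> HamiltonianMatrix:
    """Assemble the full-system Hamiltonian matrix over one M_S block of ESDs.

    ``mode='fem'`` builds the Frenkel exciton Hamiltonian instead: diagonal
    elements are bare sums of site energies and the only couplings kept are
    those between local excitations on two different fragments.
    """
    esds = list(esds)
    if mode not in ("eci", "fem"):
        raise ValueError(f"unknown mode {mode!r}")
    if esds and require_uniform_ms:
        ms0 = esds[0].two_ms
        for e in esds:
            if e.two_ms != ms0:
                raise ValueError("Hamiltonian block must have uniform M_S")
    for frag in site_data.fragments:
        if frag.n_electrons % 2 == 1 and not allow_odd_electron:
            raise ValueError(
                f"fragment {frag.fragment_id} has an odd electron count; "
                "assembly for odd-electron fragments is gated behind "
                "allow_odd_electron=True (parity phases not certified)")
    if mode == "fem" and any(e.rank > 1 for e in esds):
        raise ValueError("FEM mode expects a rank <= 1 (GS + LE) basis")

    provider = provider or TDMProvider(site_data)
    if site_hamiltonian is None:
        site_hamiltonian = (NonvariationalSiteHamiltonian(site_data, engine, provider)
                            if nonvariational else
                            VariationalSiteHamiltonian(site_data))
    asm = _Assembler(site_data, engine, site_hamiltonian, provider, use_exchange)

    n = len(esds)
    mat = np.zeros((n, n))
    prov: Optional[List[Tuple[int, int, str, float, float]]] = (
        [] if dump_elements else None)

    for i in range(n):
        for j in range(i, n):
            bra, ket = esds[i], esds[j]
            diff = [p for p in range(len(bra.occupation))
                    if bra.occupation[p] != ket.occupation[p]]
            if len(diff) > 2:
                continue
            if mode == "fem":
                if i == j:
                    val = sum(site_data.state(f, a).energy
                              for f, a in zip(bra.fragment_ids, bra.occupation))
                    jv = kv = 0.0
                    rule = "0"
                elif (len(diff) == 2 and bra.rank == 1 and ket.rank == 1):
                    val, jv, kv = asm.rule2(bra, ket, diff[0], diff[1])
                    rule = "II"
                else:
                    continue
            else:
                if len(diff) == 0:
                    val, jv, kv = asm.rule0(bra)
                    rule = "0"
                elif len(diff) == 1:
                    val, jv, kv = asm.rule1(bra, ket, diff[0])
                    rule = "I"
                else:
                    val, jv, kv = asm.rule2(bra, ket, diff[0], diff[1])
                    rule = "II"
            mat[i, j] = mat[j, i] = val
            if prov is not None:
                prov.append((i, j, rule, jv, kv))
    return HamiltonianMatrix(mat, esds, mode, prov)


# ---------------------------------------------------------------------------
# dipole matrices
# ---------------------------------------------------------------------------

def _site_dipole(site_data: SiteData, f: int, bra: int, ket: int
                 ) -> Optional[np.ndarray]:
    """Electronic (transition) dipole for a site-state pair, spin-resolved.

    The dipole operator is a spin scalar: nonzero only between states of the
    same multiplet spin with the same m_s, and independent of m_s, so the
    stored principal-pair value is reused for the other components.
    """
    b = site_data.state(f, bra)
    k = site_data.state(f, ket)
    if b.two_s != k.two_s or b.two_ms != k.two_ms:
        return np.zeros(3)
    mu = site_data.dipoles[f].get(bra, ket)
    if mu is not None:
        return mu
    pb = site_data.principal_member(f, b.multiplet_id).state_index
    pk = site_data.principal_member(f, k.multiplet_id).state_index
    return site_data.dipoles[f].get(pb, pk)


def dipole_matrices(esds: Sequence[ESD], site_data: SiteData) -> np.ndarray:
    """(3, N, N) array of ESD-basis dipole matrices (electronic + nuclear)."""
    esds = list(esds)
    n = len(esds)
    out = np.zeros((3, n, n))
    nuc = {f.fragment_id: f.nuclear_dipole() for f in site_data.fragments}
    for i in range(n):
        for j in range(i, n):
            bra, ket = esds[i], esds[j]
            diff = [p for p in range(len(bra.occupation))
                    if bra.occupation[p] != ket.occupation[p]]
            if len(diff) > 1:
                continue
            if len(diff) == 0:
                mu = np.zeros(3)
                for f, a in zip(bra.fragment_ids, bra.occupation):
                    el = _site_dipole(site_data, f, a, a)
                    if el is None:
                        raise KeyError(f"missing dipole for state ({f},{a})")
                    mu = mu + el + nuc[f]
            else:
                p = diff[0]
                f = bra.fragment_ids[p]
                mu = _site_dipole(site_data, f, bra.occupation[p],
                                  ket.occupation[p])
                if mu is None:
                    raise KeyError(
                        f"missing transition dipole ({f},{bra.occupation[p]},"
                        f"{ket.occupation[p]})")
            out[:, i, j] = out[:, j, i] = mu
    return out
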