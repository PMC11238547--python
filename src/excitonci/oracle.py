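"""Brute-force determinant-space oracle for model multichromophoric systems.

The group-function matrix-element rules are exact when (i) the site-state
products are strongly orthogonal and (ii) the Hamiltonian contains no terms
moving electrons between fragments.  A :class:`ModelSystem` realizes both by
construction: fragments own disjoint sets of orthonormal spatial orbitals,
the one-electron part has no cross-fragment (hopping) blocks, and the
two-electron integrals are restricted to the fragment-number-conserving
classes -- intra-fragment, Coulomb (FF|GG) and exchange (FG|GF).  Charge
transfer is excluded on purpose, which makes the non-CT product basis
complete and the "exact within group-function theory" claim literally
testable; this is the oracle's scope, not a statement about real systems.

Everything here is plain full CI: fragment eigenstates come from exact
diagonalization per (N_el, m_s) sector with spin multiplets assembled by
ladder operators (Condon-Shortley phases); full-system matrix elements are
obtained by expanding antisymmetrized products into determinants and applying
the untruncated Hamiltonian.  No group-function shortcut is used anywhere in
this module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engines import Density, InteractionEngine
from .site_model import (Atom, FragmentSpec, SiteData, SiteState,
                         SpinBlockedTDM)
from .spinutil import ladder_factor

__all__ = [
    "ModelFragment", "ModelSystem", "Multiplet", "fragment_eigenstates",
    "ModelIntegralEngine", "DeterminantOracle", "build_site_data",
]


# ---------------------------------------------------------------------------
# determinant utilities (bitmask alpha/beta strings, alpha block then beta)
# ---------------------------------------------------------------------------

def _occ(mask: int) -> List[int]:
    out = []
    p = 0
    while mask:
        if mask & 1:
            out.append(p)
        mask >>= 1
        p += 1
    return out


def _bits_between(i: int, j: int) -> int:
    lo, hi = (i, j) if i < j else (j, i)
    return ((1 << hi) - 1) & ~((1 << (lo + 1)) - 1)


def _single_phase(mask: int, hole: int, part: int) -> int:
    return -1 if bin(mask & _bits_between(hole, part)).count("1") % 2 else 1


def _ann_phase_alpha(amask: int, p: int) -> int:
    return -1 if bin(amask & ((1 << p) - 1)).count("1") % 2 else 1


def _ann_phase_beta(amask: int, bmask: int, p: int) -> int:
    n = bin(amask).count("1") + bin(bmask & ((1 << p) - 1)).count("1")
    return -1 if n % 2 else 1


Det = Tuple[int, int]


def slater_condon(det1: Det, det2: Det, h: np.ndarray, eri: np.ndarray) -> float:
    """<det1| H |det2> for a general number-conserving (h, eri) pair.

    eri is the chemist-notation coefficient tensor of
    1/2 sum_{ijkl, st} (ij|kl) a+_{is} a+_{kt} a_{lt} a_{js}; only hermiticity
    symmetry (ij|kl) = (kl|ij) = (ji|lk) is assumed, never (ij|kl) = (ji|kl).
    """
    a1, b1 = det1
    a2, b2 = det2
    if bin(a1).count("1") != bin(a2).count("1"):
        return 0.0          # H conserves n_alpha and n_beta separately
    da, db = a1 ^ a2, b1 ^ b2
    deg = (bin(da).count("1") + bin(db).count("1")) // 2
    if deg > 2:
        return 0.0

    if deg == 0:
        occ_a, occ_b = _occ(a1), _occ(b1)
        e = sum(h[p, p] for p in occ_a) + sum(h[p, p] for p in occ_b)
        occ_all = [(p, 0) for p in occ_a] + [(p, 1) for p in occ_b]
        for i, (p, sp) in enumerate(occ_all):
            for q, sq in occ_all[i + 1:]:
                e += eri[p, p, q, q]
                if sp == sq:
                    e -= eri[p, q, q, p]
        return float(e)

    if deg == 1:
        if bin(da).count("1") == 2:
            mask1, mask2 = a1, a2
            hole = _occ(da & a2)[0]
            part = _occ(da & a1)[0]
            same_occ = _occ(a1 & a2)
            other_occ = _occ(b1)
            phase = _single_phase(a2, hole, part)
        else:
            mask1, mask2 = b1, b2
            hole = _occ(db & b2)[0]
            part = _occ(db & b1)[0]
            same_occ = _occ(b1 & b2)
            other_occ = _occ(a1)
            phase = _single_phase(b2, hole, part)
        e = h[part, hole]
        for q in same_occ:
            e += eri[part, hole, q, q] - eri[part, q, q, hole]
        for q in other_occ:
            e += eri[part, hole, q, q]
        return float(phase * e)

    # deg == 2
    na, nb = bin(da).count("1"), bin(db).count("1")
    if na == 4:  # both excitations in the alpha channel
        holes = _occ(da & a2)
        parts = _occ(da & a1)
        i, j = holes
        k, l = parts
        ph = _single_phase(a2, i, k)
        mid = (a2 & ~(1 << i)) | (1 << k)
        ph *= _single_phase(mid, j, l)
        return float(ph * (eri[k, i, l, j] - eri[l, i, k, j]))
    if nb == 4:
        holes = _occ(db & b2)
        parts = _occ(db & b1)
        i, j = holes
        k, l = parts
        ph = _single_phase(b2, i, k)
        mid = (b2 & ~(1 << i)) | (1 << k)
        ph *= _single_phase(mid, j, l)
        return float(ph * (eri[k, i, l, j] - eri[l, i, k, j]))
    # one alpha, one beta excitation
    i = _occ(da & a2)[0]
    k = _occ(da & a1)[0]
    j = _occ(db & b2)[0]
    l = _occ(db & b1)[0]
    ph = _single_phase(a2, i, k) * _single_phase(b2, j, l)
    return float(ph * eri[k, i, l, j])


def build_hamiltonian(dets: Sequence[Det], h: np.ndarray, eri: np.ndarray,
                      const: float = 0.0) -> np.ndarray:
    n = len(dets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = slater_condon(dets[i], dets[j], h, eri)
            mat[i, j] = mat[j, i] = v
        mat[i, i] += const
    return mat


# ---------------------------------------------------------------------------
# model systems
# ---------------------------------------------------------------------------

@dataclass
class ModelFragment:
    """A model chromophore: its own orthonormal orbitals and point nuclei."""

    n_orb: int
    n_el: int
    h: np.ndarray                               # intra one-electron block
    atoms: List[Tuple[float, np.ndarray]] = field(default_factory=list)
    orb_pos: Optional[np.ndarray] = None        # (n_orb, 3), point-orbital rule

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        if self.h.shape != (self.n_orb, self.n_orb):
            raise ValueError("h block shape mismatch")
        self.atoms = [(float(z), np.asarray(r, dtype=float).reshape(3))
                      for z, r in self.atoms]
        if self.orb_pos is not None:
            self.orb_pos = np.asarray(self.orb_pos, dtype=float).reshape(self.n_orb, 3)

    @property
    def e_nuc(self) -> float:
        e = 0.0
        for i, (zi, ri) in enumerate(self.atoms):
            for zj, rj in self.atoms[i + 1:]:
                e += zi * zj / np.linalg.norm(ri - rj)
        return e

    def attraction(self, pos: np.ndarray) -> np.ndarray:
        """Point-orbital potential integrals: delta_pq / |R_p - pos|."""
        if self.orb_pos is None:
            return np.zeros((self.n_orb, self.n_orb))
        d = np.linalg.norm(self.orb_pos - np.asarray(pos, dtype=float), axis=1)
        if np.any(d < 1e-10):
            raise ValueError("charge coincides with an orbital site")
        return np.diag(1.0 / d)


class ModelSystem:
    """Fragments with disjoint orthonormal orbitals + restricted integrals."""

    def __init__(self, fragments: List[ModelFragment], eri: np.ndarray):
        self.fragments = fragments
        self.n_orb = sum(f.n_orb for f in fragments)
        self.offsets = np.cumsum([0] + [f.n_orb for f in fragments])[:-1]
        self.eri = np.asarray(eri, dtype=float)
        if self.eri.shape != (self.n_orb,) * 4:
            raise ValueError("eri shape mismatch")

    def slice(self, f: int) -> slice:
        return slice(int(self.offsets[f]), int(self.offsets[f] + self.fragments[f].n_orb))

    @property
    def n_frag(self) -> int:
        return len(self.fragments)

    # -- constructors ------------------------------------------------------

    @classmethod
    def random(cls, n_orbs: Sequence[int], n_els: Sequence[int], seed: int,
               scale: float = 0.3, with_geometry: bool = True) -> "ModelSystem":
        """Random hermitian model restricted to number-conserving classes."""
        rng = np.random.default_rng(seed)
        frags = []
        n_tot = int(sum(n_orbs))
        pos_all = rng.uniform(-4.0, 4.0, size=(n_tot, 3))
        k = 0
        for idx, (no, ne) in enumerate(zip(n_orbs, n_els)):
            h = rng.normal(0.0, scale, (no, no))
            h = 0.5 * (h + h.T) + np.diag(np.arange(no, dtype=float))
            opos = pos_all[k:k + no] + idx * np.array([10.0, 0.0, 0.0])
            atoms = []
            if with_geometry:
                z_each = max(ne, 1) / no
                atoms = [(z_each, opos[g]) for g in range(no)]
            frags.append(ModelFragment(no, ne, h, atoms,
                                       opos if with_geometry else None))
            k += no
        raw = rng.normal(0.0, scale, (n_tot,) * 4)
        # hermiticity group: (ij|kl) = (kl|ij) = (ji|lk) = (lk|ji)
        eri = (raw + raw.transpose(2, 3, 0, 1)
               + raw.transpose(1, 0, 3, 2) + raw.transpose(3, 2, 1, 0)) / 4.0
        eri *= cls._class_mask(n_orbs)
        return cls(frags, eri)

    @classmethod
    def geometric(cls, frag_specs: Sequence[dict]) -> "ModelSystem":
        """Point-orbital electrostatic model (one orbital per atom).

        Each spec: {"Z": [...], "R": (n,3) bohr, "h": (n,n), "U": [...],
        "n_el": int}.  Two-electron integrals are classical 1/R between
        orbital sites ((pp|qq) classes), plus the on-site Hubbard U; the
        cross-fragment exchange class vanishes for point orbitals.
        """
        frags = []
        for spec in frag_specs:
            R = np.asarray(spec["R"], dtype=float).reshape(-1, 3)
            Z = np.asarray(spec["Z"], dtype=float)
            frags.append(ModelFragment(
                n_orb=len(Z), n_el=int(spec["n_el"]), h=spec["h"],
                atoms=list(zip(Z, R)), orb_pos=R))
        n_tot = sum(f.n_orb for f in frags)
        eri = np.zeros((n_tot,) * 4)
        offs = np.cumsum([0] + [f.n_orb for f in frags])[:-1]
        pos = np.vstack([f.orb_pos for f in frags])
        for p in range(n_tot):
            for q in range(n_tot):
                if p == q:
                    continue
                eri[p, p, q, q] = 1.0 / np.linalg.norm(pos[p] - pos[q])
        for f, spec in zip(range(len(frags)), frag_specs):
            U = np.asarray(spec.get("U", np.zeros(frags[f].n_orb)), dtype=float)
            for g in range(frags[f].n_orb):
                p = offs[f] + g
                eri[p, p, p, p] = U[g]
        return cls(frags, eri)

    @staticmethod
    def _class_mask(n_orbs: Sequence[int]) -> np.ndarray:
        n_tot = int(sum(n_orbs))
        frag_of = np.concatenate([np.full(no, i) for i, no in enumerate(n_orbs)])
        fi = frag_of[:, None, None, None]
        fj = frag_of[None, :, None, None]
        fk = frag_of[None, None, :, None]
        fl = frag_of[None, None, None, :]
        coulomb = (fi == fj) & (fk == fl)
        exchange = (fi == fl) & (fj == fk)
        return (coulomb | exchange).astype(float)

    # -- full-system operator ----------------------------------------------

    def h_full(self) -> Tuple[np.ndarray, float]:
        """Block one-electron matrix (incl. cross nuclear attraction), const."""
        h = np.zeros((self.n_orb, self.n_orb))
        const = 0.0
        for f, frag in enumerate(self.fragments):
            sl = self.slice(f)
            h[sl, sl] = frag.h
            const += frag.e_nuc
            for g, other in enumerate(self.fragments):
                if g == f:
                    continue
                for z, r in other.atoms:
                    h[sl, sl] -= z * frag.attraction(r)
        for f in range(self.n_frag):
            for g in range(f + 1, self.n_frag):
                const += self.vnn_cross(f, g)
        return h, const

    def vnn_cross(self, f: int, g: int) -> float:
        e = 0.0
        for zf, rf in self.fragments[f].atoms:
            for zg, rg in self.fragments[g].atoms:
                e += zf * zg / np.linalg.norm(rf - rg)
        return e


# ---------------------------------------------------------------------------
# fragment eigenstates with proper multiplets
# ---------------------------------------------------------------------------

@dataclass
class Multiplet:
    s: float
    energy: float
    vectors: Dict[int, np.ndarray]      # two_ms -> CI vector in that sector

    @property
    def degeneracy(self) -> int:
        return int(round(2 * self.s)) + 1


def _sector_dets(n_orb: int, n_a: int, n_b: int) -> List[Det]:
    alphas = [sum(1 << p for p in c)
              for c in itertools.combinations(range(n_orb), n_a)]
    betas = [sum(1 << p for p in c)
             for c in itertools.combinations(range(n_orb), n_b)]
    return [(a, b) for a in alphas for b in betas]


def _apply_sminus(dets_from: Sequence[Det], dets_to: Sequence[Det],
                  vec: np.ndarray) -> np.ndarray:
    """S- = sum_p a+_{p beta} a_{p alpha} between m and m-1 sectors."""
    index = {d: i for i, d in enumerate(dets_to)}
    out = np.zeros(len(dets_to))
    for i, (a, b) in enumerate(dets_from):
        c = vec[i]
        if abs(c) < 1e-15:
            continue
        for p in _occ(a):
            if b & (1 << p):
                continue
            ph = _ann_phase_alpha(a, p)
            a2 = a & ~(1 << p)
            ph *= _ann_phase_beta(a2, b, p)
            out[index[(a2, b | (1 << p))]] += ph * c
    return out


def fragment_eigenstates(model: ModelSystem, f: int,
                         ext_charges: Sequence[Tuple[float, np.ndarray]] = (),
                         ) -> Tuple[List[Multiplet], Dict[int, List[Det]]]:
    """Exact (embedded) eigenstates of fragment f, grouped into multiplets.

    Multiplet members for m_s < s are generated by the lowering operator, so
    all ladder (Condon-Shortley) phase relations hold exactly.  Returns the
    multiplets sorted by energy and the per-sector determinant lists.
    """
    frag = model.fragments[f]
    sl = model.slice(f)
    h = frag.h.copy()
    const = frag.e_nuc
    for q, pos in ext_charges:
        h -= q * frag.attraction(pos)
        for z, r in frag.atoms:
            const += q * z / np.linalg.norm(np.asarray(pos) - r)
    eri = model.eri[sl, sl, sl, sl]
    n, ne = frag.n_orb, frag.n_el
    if ne < 0 or ne > 2 * n:
        raise ValueError("impossible electron count")
    two_m_max = min(ne, 2 * n - ne)
    sectors: Dict[int, List[Det]] = {}
    hams: Dict[int, np.ndarray] = {}
    for two_m in range(two_m_max, -two_m_max - 1, -2):
        n_a = (ne + two_m) // 2
        n_b = ne - n_a
        dets = _sector_dets(n, n_a, n_b)
        if len(dets) > 1000:
            raise ValueError("fragment determinant space too large for the oracle")
        sectors[two_m] = dets
        hams[two_m] = build_hamiltonian(dets, h, eri, const)

    multiplets: List[Multiplet] = []
    for two_m in range(two_m_max, -two_m_max - 1, -2):
        dets = sectors[two_m]
        dim = len(dets)
        laddered = []
        for mult in multiplets:
            if (two_m + 2) in mult.vectors and two_m >= -2 * mult.s:
                m_up = (two_m + 2) / 2.0
                fac = ladder_factor(mult.s, m_up, up=False)
                v = _apply_sminus(sectors[two_m + 2], dets,
                                  mult.vectors[two_m + 2]) / fac
                mult.vectors[two_m] = v
                laddered.append(v)
        k = len(laddered)
        if k >= dim:
            continue
        if laddered:
            L = np.array(laddered).T
            proj = np.eye(dim) - L @ L.T
        else:
            proj = np.eye(dim)
        w_vals, w_vecs = np.linalg.eigh(proj)
        W = w_vecs[:, w_vals > 0.5]
        hw = W.T @ hams[two_m] @ W
        vals, vecs = np.linalg.eigh(hw)
        for i in range(len(vals)):
            v = W @ vecs[:, i]
            multiplets.append(Multiplet(s=two_m / 2.0, energy=float(vals[i]),
                                        vectors={two_m: v}))
    multiplets.sort(key=lambda m: (m.energy, m.s))
    return multiplets, sectors


def s2_expectation(dets: Sequence[Det], vec: np.ndarray) -> float:
    """<S^2> of a CI vector, via S-S+ + Sz^2 + Sz in determinant space."""
    if not len(dets):
        return 0.0
    n_a = bin(dets[0][0]).count("1")
    n_b = bin(dets[0][1]).count("1")
    m = (n_a - n_b) / 2.0
    # S+ v lives in the sector with one more alpha
    n_orb = 0
    for a, b in dets:
        n_orb = max(n_orb, (max(a, b)).bit_length())
    up = {}
    for i, (a, b) in enumerate(dets):
        c = vec[i]
        if abs(c) < 1e-15:
            continue
        for p in _occ(b):
            if a & (1 << p):
                continue
            ph = _ann_phase_beta(a, b, p)
            b2 = b & ~(1 << p)
            ph *= _ann_phase_alpha(a, p)
            key = (a | (1 << p), b2)
            up[key] = up.get(key, 0.0) + ph * c
    norm_up = sum(v * v for v in up.values())
    return norm_up + m * m + m


# ---------------------------------------------------------------------------
# TDMs and dipoles from CI vectors
# ---------------------------------------------------------------------------

def tdm_blocks(n_orb: int, bra_dets: Sequence[Det], bra_vec: np.ndarray,
               ket_dets: Sequence[Det], ket_vec: np.ndarray) -> Dict[str, np.ndarray]:
    """gamma^{st}[p,q] = <bra| a+_{ps} a_{qt} |ket> for all four spin blocks."""
    blocks = {k: np.zeros((n_orb, n_orb)) for k in ("aa", "bb", "ab", "ba")}
    index = {d: i for i, d in enumerate(bra_dets)}

    def add(key, p, q, amp):
        blocks[key][p, q] += amp

    for i, (a, b) in enumerate(ket_dets):
        c = ket_vec[i]
        if abs(c) < 1e-14:
            continue
        # a_{q alpha} then a+_{p alpha}
        for q in _occ(a):
            ph1 = _ann_phase_alpha(a, q)
            a1 = a & ~(1 << q)
            for p in range(n_orb):
                if a1 & (1 << p):
                    continue
                ph2 = _ann_phase_alpha(a1, p)
                d = (a1 | (1 << p), b)
                j = index.get(d)
                if j is not None:
                    add("aa", p, q, ph1 * ph2 * c * bra_vec[j])
        for q in _occ(b):
            ph1 = _ann_phase_beta(a, b, q)
            b1 = b & ~(1 << q)
            # a+_{p beta}
            for p in range(n_orb):
                if b1 & (1 << p):
                    continue
                ph2 = _ann_phase_beta(a, b1, p)
                d = (a, b1 | (1 << p))
                j = index.get(d)
                if j is not None:
                    add("bb", p, q, ph1 * ph2 * c * bra_vec[j])
            # a+_{p alpha}
            for p in range(n_orb):
                if a & (1 << p):
                    continue
                ph2 = _ann_phase_alpha(a, p)
                d = (a | (1 << p), b1)
                j = index.get(d)
                if j is not None:
                    add("ab", p, q, ph1 * ph2 * c * bra_vec[j])
        for q in _occ(a):
            ph1 = _ann_phase_alpha(a, q)
            a1 = a & ~(1 << q)
            for p in range(n_orb):
                if b & (1 << p):
                    continue
                ph2 = _ann_phase_beta(a1, b, p)
                d = (a1, b | (1 << p))
                j = index.get(d)
                if j is not None:
                    add("ba", p, q, ph1 * ph2 * c * bra_vec[j])
    return blocks


# ---------------------------------------------------------------------------
# the model integral engine (GFT side of the equivalence tests)
# ---------------------------------------------------------------------------

class ModelIntegralEngine(InteractionEngine):
    """Interaction engine contracting densities with a model's integrals.

    Orbital spaces of different fragments are disjoint and orthonormal, so
    the overlap measure is identically zero.
    """

    has_exchange = True
    has_overlap_measure = True

    def __init__(self, model: ModelSystem):
        self.model = model

    def n_ao(self, fragment_id: int) -> int:
        return self.model.fragments[fragment_id - 1].n_orb

    def density_charge_energy(self, rho: Density, charges) -> float:
        self._check_dim(rho)
        frag = self.model.fragments[rho.fragment_id - 1]
        total = 0.0
        for q, pos in charges:
            total += q * float(np.sum(rho.matrix * frag.attraction(pos)))
        return total

    def coulomb_J(self, rho_f: Density, rho_g: Density) -> float:
        self._check_pair(rho_f.fragment_id, rho_g.fragment_id)
        sf = self.model.slice(rho_f.fragment_id - 1)
        sg = self.model.slice(rho_g.fragment_id - 1)
        blk = self.model.eri[sf, sf, sg, sg]
        return float(np.einsum("pq,rs,pqrs->", rho_f.matrix, rho_g.matrix, blk))

    def exchange_K(self, gamma_f: SpinBlockedTDM, gamma_g: SpinBlockedTDM) -> float:
        self._check_pair(gamma_f.fragment_id, gamma_g.fragment_id)
        sf = self.model.slice(gamma_f.fragment_id - 1)
        sg = self.model.slice(gamma_g.fragment_id - 1)
        x = self.model.eri[sf, sg, sg, sf]   # (p_F s_G | r_G q_F)
        total = 0.0
        for st, ts in (("aa", "aa"), ("bb", "bb"), ("ab", "ba"), ("ba", "ab")):
            total += np.einsum("pq,rs,psrq->",
                               gamma_f.blocks[st], gamma_g.blocks[ts], x)
        return float(total)

    def overlap_measure(self, gamma_f, gamma_g) -> float:
        self._check_pair(gamma_f.fragment_id, gamma_g.fragment_id)
        return 0.0


# ---------------------------------------------------------------------------
# site-data bundling and the full-space oracle
# ---------------------------------------------------------------------------

def build_site_data(model: ModelSystem,
                    multiplets: Optional[List[List[Multiplet]]] = None,
                    n_multiplets: Optional[int] = None,
                    store_all_tdms: bool = True,
                    charges: Optional[List[np.ndarray]] = None,
                    ) -> Tuple[SiteData, List[List[Multiplet]],
                               List[Dict[int, List[Det]]]]:
    """Exact site states of every fragment, packaged as :class:`SiteData`.

    State indices enumerate multiplets in energy order, expanded into their
    m_s components in descending m_s; index 0 is the principal member of the
    lowest multiplet.  When ``store_all_tdms`` is False, only principal-pair
    TDM blocks are stored (the ladder-expansion code path must regenerate the
    rest).
    """
    data = SiteData()
    all_mults: List[List[Multiplet]] = []
    all_sectors: List[Dict[int, List[Det]]] = []
    for f, frag in enumerate(model.fragments):
        fid = f + 1
        q = None if charges is None else charges[f]
        data.add_fragment(FragmentSpec(
            fragment_id=fid,
            atoms=[Atom("X", z, r) for z, r in frag.atoms],
            n_electrons=frag.n_el,
            ao_basis={"kind": "model", "n_orb": frag.n_orb},
            embedding_charges=q))
        if multiplets is None:
            mults, sectors = fragment_eigenstates(model, f)
        else:
            mults = multiplets[f]
            _, sectors = fragment_eigenstates(model, f)  # det lists only
        if n_multiplets is not None:
            mults = mults[:n_multiplets]
        all_mults.append(mults)
        all_sectors.append(sectors)

        index = 0
        member_idx: Dict[Tuple[int, int], int] = {}
        for mi, mult in enumerate(mults):
            for two_m in sorted(mult.vectors, reverse=True):
                data.add_state(SiteState(
                    fragment_id=fid, state_index=index,
                    energy=mult.energy, spin_s=mult.s, spin_ms=two_m / 2.0,
                    multiplet_id=f"F{fid}M{mi}",
                    label=f"s={mult.s} #{mi}"))
                member_idx[(mi, two_m)] = index
                index += 1

        def members(mi):
            mult = mults[mi]
            if store_all_tdms:
                return [(two_m, member_idx[(mi, two_m)])
                        for two_m in sorted(mult.vectors, reverse=True)]
            top = max(mult.vectors)
            return [(top, member_idx[(mi, top)])]

        for mi in range(len(mults)):
            for mj in range(mi, len(mults)):
                for tmb, ib in members(mi):
                    for tmk, ik in members(mj):
                        if mj == mi and ik < ib:
                            continue
                        blocks = tdm_blocks(
                            frag.n_orb,
                            sectors[tmb], mults[mi].vectors[tmb],
                            sectors[tmk], mults[mj].vectors[tmk])
                        data.add_tdm(SpinBlockedTDM(fid, ib, ik, blocks))
                        if frag.orb_pos is not None:
                            d = blocks["aa"] + blocks["bb"]
                            mu = -np.einsum("pp,px->x", d, frag.orb_pos)
                            data.dipoles[fid].set(ib, ik, mu)
    return data, all_mults, all_sectors


class DeterminantOracle:
    """Full-CI reference for ESD matrix elements of a model system."""

    def __init__(self, model: ModelSystem,
                 multiplets: List[List[Multiplet]],
                 sectors: List[Dict[int, List[Det]]]):
        self.model = model
        self.multiplets = multiplets
        self.sectors = sectors
        self._space()

    def _space(self):
        model = self.model
        per_frag_dets = []
        for f, frag in enumerate(model.fragments):
            combos = []
            for two_m, dets in self.sectors[f].items():
                combos.extend((two_m, d) for d in dets)
            per_frag_dets.append(combos)
        dets_full: List[Det] = []
        for combo in itertools.product(*per_frag_dets):
            a = b = 0
            for f, (_, (am, bm)) in enumerate(combo):
                off = int(self.model.offsets[f])
                a |= am << off
                b |= bm << off
            dets_full.append((a, b))
        self.dets = sorted(set(dets_full))
        self.index = {d: i for i, d in enumerate(self.dets)}
        h, const = model.h_full()
        self.H = build_hamiltonian(self.dets, h, model.eri, const)

    # state addressing mirrors build_site_data: (multiplet index, two_m)
    def state_addr(self, f: int, state_index: int) -> Tuple[int, int]:
        idx = 0
        for mi, mult in enumerate(self.multiplets[f]):
            for two_m in sorted(mult.vectors, reverse=True):
                if idx == state_index:
                    return mi, two_m
                idx += 1
        raise KeyError((f, state_index))

    def esd_vector(self, occupation: Sequence[int]) -> np.ndarray:
        """Expand an antisymmetrized product into full-space determinants."""
        model = self.model
        frag_parts = []
        n_alphas = []
        for f, a in enumerate(occupation):
            mi, two_m = self.state_addr(f, a)
            vec = self.multiplets[f][mi].vectors[two_m]
            dets = self.sectors[f][two_m]
            frag_parts.append((dets, vec))
            n_a = (model.fragments[f].n_el + two_m) // 2
            n_b = model.fragments[f].n_el - n_a
            n_alphas.append((n_a, n_b))
        # fragment-major operator order -> alpha-block-major determinant order
        sign = 1
        for f in range(len(occupation)):
            n_b = n_alphas[f][1]
            n_a_after = sum(n_alphas[g][0] for g in range(f + 1, len(occupation)))
            if (n_b * n_a_after) % 2:
                sign = -sign
        v = np.zeros(len(self.dets))
        idx_lists = [range(len(dets)) for dets, _ in frag_parts]
        for combo in itertools.product(*idx_lists):
            coef = sign
            a = b = 0
            for f, i in enumerate(combo):
                dets, vec = frag_parts[f]
                coef *= vec[i]
                off = int(self.model.offsets[f])
                a |= dets[i][0] << off
                b |= dets[i][1] << off
            if coef:
                v[self.index[(a, b)]] += coef
        return v

    def matrix_element(self, occ_bra: Sequence[int], occ_ket: Sequence[int]) -> float:
        vb = self.esd_vector(occ_bra)
        vk = self.esd_vector(occ_ket)
        return float(vb @ self.H @ vk)

    def product_basis_matrix(self, occupations: Sequence[Sequence[int]]) -> np.ndarray:
        vs = np.array([self.esd_vector(o) for o in occupations])
        return vs @ self.H @ vs.T

    def sector_eigenvalues(self) -> np.ndarray:
        """All eigenvalues of H in the fragment-number-conserving sector."""
        return np.linalg.eigvalsh(self.H)


def polar_toy_dimer(separation: float = 6.0, bond: float = 1.5,
                    tilt: Tuple[float, float] = (-1.0, -0.55),
                    hopping: float = -0.3, u_onsite: float = 0.8
                    ) -> ModelSystem:
    """A polar two-site-per-fragment dimer for embedding/EHF tests.

    Each fragment has two atoms (Z = 1) with one point orbital each and two
    electrons; the asymmetric on-site energies ``tilt`` polarize the ground
    state, so the fragments carry static dipoles (anti-aligned: the second
    fragment is mirrored), embedding matters, and an untruncated-basis probe
    of Brillouin-like behaviour is meaningful.
    """
    h1 = np.array([[tilt[0], hopping], [hopping, tilt[1]]])
    h2 = np.array([[tilt[1], hopping], [hopping, tilt[0]]])
    r1 = np.array([[0.0, 0.0, 0.0], [bond, 0.0, 0.0]])
    r2 = r1 + np.array([0.0, 0.0, separation])
    return ModelSystem.geometric([
        {"Z": [1.0, 1.0], "R": r1, "h": h1, "U": [u_onsite, u_onsite],
         "n_el": 2},
        {"Z": [1.0, 1.0], "R": r2, "h": h2, "U": [u_onsite, u_onsite],
         "n_el": 2},
    ])


def make_oracle(model: ModelSystem, n_multiplets: Optional[int] = None,
                store_all_tdms: bool = True):
    """Convenience: site data + engine + determinant oracle for one model."""
    data, mults, sectors = build_site_data(
        model, n_multiplets=n_multiplets, store_all_tdms=store_all_tdms)
    engine = ModelIntegralEngine(model)
    oracle = DeterminantOracle(model, mults, sectors)
    return data, engine, oracle
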