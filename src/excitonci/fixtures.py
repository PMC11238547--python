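"""Synthetic site-data generators.

Two families of fixtures ship:

* :func:`make_guanine_like_counting_fixture` -- a stand-in (synthetic) for a
  stacked tetramer of nucleobase-like chromophores in which every fragment
  supplies one singlet ground state, a configurable number of excited
  singlets and triplet multiplets (all three m_s components).  The energies
  and densities are placeholders; the fixture exists to drive the pure
  basis-counting and spin-adaptation arithmetic, including the expulsion of
  one Rydberg-like high-overlap singlet by the strong-orthogonality screen.
* :func:`make_point_chromophore_dimer` -- two few-level chromophores whose
  state and transition densities are small point-charge sets, giving
  analytic dipole-dipole couplings for spectrum-level tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .engines import DiscreteChargeEngine
from .site_model import (Atom, FragmentSpec, SiteData, SiteState,
                         SpinBlockedTDM)

__all__ = ["make_guanine_like_counting_fixture", "make_point_chromophore_dimer"]


def make_guanine_like_counting_fixture(
        n_fragments: int = 4,
        n_singlets: int = 7,
        n_triplets: int = 3,
        rydberg_overlap: float = 10.0,
        rydberg_state: Optional[int] = None,
        extra_single_state_fragment: bool = False,
        seed: int = 0) -> SiteData:
    """Synthetic tetramer-like site-state set for basis counting.

    Each of ``n_fragments`` identical fragments carries a singlet ground
    state, ``n_singlets`` excited singlets and ``n_triplets`` triplet
    multiplets expanded into m_s = +1, 0, -1 components.  The last excited
    singlet is marked Rydberg-like: its stored overlap measure with every
    partner state is ``rydberg_overlap`` times the fragment-pair minimum, so
    the overlap screen with t_O close to 1 expels exactly the ESDs containing
    it.  ``extra_single_state_fragment`` appends a closed-shell one-state
    fragment (a bare divalent cation-like site), which must leave every count
    unchanged.

    Energies are placeholder values (eV-scale spacings in hartree); densities
    are 1x1 unit matrices so that trace invariants hold for a 2-electron
    fragment model.
    """
    rng = np.random.default_rng(seed)
    if rydberg_state is None:
        rydberg_state = n_singlets          # state index of the last singlet
    data = SiteData()
    n_frag_total = n_fragments + (1 if extra_single_state_fragment else 0)
    for f in range(1, n_fragments + 1):
        pos = np.array([[0.0, 0.0, 6.0 * (f - 1)]])
        data.add_fragment(FragmentSpec(
            fragment_id=f,
            atoms=[Atom("C", 6.0, pos[0])],
            n_electrons=2,
            ao_basis={"kind": "synthetic", "n_ao": 1},
            embedding_charges=np.zeros(1)))
        data.add_state(SiteState(f, 0, 0.0, 0.0, 0.0, f"F{f}S0", "S0"))
        idx = 1
        for s in range(1, n_singlets + 1):
            e = 0.20 + 0.01 * s + 1e-4 * rng.standard_normal() * 0
            data.add_state(SiteState(f, idx, e, 0.0, 0.0, f"F{f}S{s}", f"S{s}"))
            idx += 1
        for t in range(1, n_triplets + 1):
            e = 0.15 + 0.01 * t
            for ms in (1.0, 0.0, -1.0):
                data.add_state(SiteState(f, idx, e, 1.0, ms,
                                         f"F{f}T{t}", f"T{t}(ms={ms:+.0f})"))
                idx += 1
        gs_blocks = {"aa": np.array([[1.0]]), "bb": np.array([[1.0]]),
                     "ab": np.zeros((1, 1)), "ba": np.zeros((1, 1))}
        data.add_tdm(SpinBlockedTDM(f, 0, 0, gs_blocks))
    if extra_single_state_fragment:
        f = n_fragments + 1
        data.add_fragment(FragmentSpec(
            fragment_id=f,
            atoms=[Atom("Mg", 12.0, np.array([0.0, 0.0, -6.0]))],
            n_electrons=10,
            ao_basis={"kind": "synthetic", "n_ao": 1},
            embedding_charges=np.zeros(1)))
        data.add_state(SiteState(f, 0, -1.0, 0.0, 0.0, f"F{f}S0", "S0"))

    # stored overlap measures: separable extents, Rydberg-like state 10x
    def extent(f: int, a: int) -> float:
        if f > n_fragments:      # the extra closed-shell fragment is compact
            return 1.0
        return rydberg_overlap if a == rydberg_state else 1.0

    fids = [fr.fragment_id for fr in data.fragments]
    for i, f in enumerate(fids):
        for g in fids[i + 1:]:
            for sa in data.states[f]:
                for sb in data.states[g]:
                    data.overlaps[(f, sa.state_index, g, sb.state_index)] = (
                        extent(f, sa.state_index) * extent(g, sb.state_index))
    return data


def make_point_chromophore_dimer(
        separation: float = 10.0,
        dipole_strengths: Tuple[float, float] = (1.0, 1.0),
        excitation_energies: Tuple[float, float] = (0.15, 0.15),
        with_triplet: bool = False,
        triplet_energy: float = 0.10,
        seed: int = 0) -> Tuple[SiteData, DiscreteChargeEngine]:
    """Two 2-level (optionally 3-level, one triplet) point chromophores.

    Each fragment is a pair of opposite point sites 1 bohr apart ("bond"
    along x); the S0->S1 transition density is an antisymmetric weight pair
    whose dipole has magnitude ``dipole_strengths[i]``; the ground-state
    density is symmetric and neutral against the nuclei, so GS products do
    not interact.  Fragments are displaced by ``separation`` bohr along z.
    In the large-separation limit the LE-LE coupling approaches the ideal
    dipole-dipole formula mu1*mu2/R^3 for this geometry.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    del rng  # geometry is fully determined; the seed fixes future noise hooks
    data = SiteData()
    points = {}
    bond = 1.0
    for i, f in enumerate((1, 2)):
        origin = np.array([0.0, 0.0, separation * i])
        pts = np.array([origin + [-bond / 2, 0, 0], origin + [bond / 2, 0, 0]])
        points[f] = pts
        data.add_fragment(FragmentSpec(
            fragment_id=f,
            atoms=[Atom("H", 1.0, pts[0]), Atom("H", 1.0, pts[1])],
            n_electrons=2,
            ao_basis={"kind": "points", "n_ao": 2},
            embedding_charges=np.zeros(2)))
        e_exc = excitation_energies[i]
        data.add_state(SiteState(f, 0, 0.0, 0.0, 0.0, f"F{f}S0", "S0"))
        data.add_state(SiteState(f, 1, e_exc, 0.0, 0.0, f"F{f}S1", "S1"))
        idx = 2
        if with_triplet:
            for ms in (1.0, 0.0, -1.0):
                data.add_state(SiteState(f, idx, triplet_energy, 1.0, ms,
                                         f"F{f}T1", f"T1({ms:+.0f})"))
                idx += 1
        # densities as diagonal weights over the two points
        gs = np.diag([1.0, 1.0])            # neutralizes the two unit nuclei
        mu = dipole_strengths[i]
        trans = np.diag([mu / bond, -mu / bond])
        zero = np.zeros((2, 2))
        data.add_tdm(SpinBlockedTDM(f, 0, 0, {
            "aa": gs / 2, "bb": gs / 2, "ab": zero, "ba": zero}))
        data.add_tdm(SpinBlockedTDM(f, 1, 1, {
            "aa": gs / 2, "bb": gs / 2, "ab": zero, "ba": zero}))
        data.add_tdm(SpinBlockedTDM(f, 0, 1, {
            "aa": trans / 2, "bb": trans / 2, "ab": zero, "ba": zero}))
        if with_triplet:
            # triplet state density equals the GS density (point model);
            # S0->T1 spatial transition density vanishes (spin selection)
            data.add_tdm(SpinBlockedTDM(f, 2, 2, {
                "aa": gs, "bb": zero, "ab": zero, "ba": zero}))
            data.add_tdm(SpinBlockedTDM(f, 0, 2, {
                "aa": zero, "bb": zero, "ab": -trans / np.sqrt(2), "ba": zero}))
        # electronic dipoles (electron charge -1): mu_el = -sum w_i r_i
        for a in range(2):
            w = [data.get_tdm(f, a, a).spatial()[p, p] for p in (0, 1)]
            data.dipoles[f].set(a, a, -(w[0] * pts[0] + w[1] * pts[1]))
        tw = [trans[p, p] for p in (0, 1)]
        data.dipoles[f].set(0, 1, -(tw[0] * pts[0] + tw[1] * pts[1]))
        if with_triplet:
            wt = [data.get_tdm(f, 2, 2).spatial()[p, p] for p in (0, 1)]
            data.dipoles[f].set(2, 2, -(wt[0] * pts[0] + wt[1] * pts[1]))
            data.dipoles[f].set(0, 2, np.zeros(3))
    # uniform stored overlap measures: the point model carries no AO overlap,
    # so screening at any t_O keeps the full basis
    for sa in data.states[1]:
        for sb in data.states[2]:
            data.overlaps[(1, sa.state_index, 2, sb.state_index)] = 1.0
    engine = DiscreteChargeEngine(points)
    return data, engine
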