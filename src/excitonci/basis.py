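"""Enumeration, truncation and M_S selection of excitonic Slater determinants.

An ESD assigns one site state to every fragment; its excitation rank is the
number of fragments not in their ground site state.  Rank truncation yields
the ECIS / ECISD / ... hierarchies; overlap screening expels ESDs whose site
states violate strong orthogonality most; M_S selection picks the spin
projection block that is actually diagonalized.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .engines import Density, InteractionEngine
from .site_model import SiteData

logger = logging.getLogger(__name__)

__all__ = ["ESD", "BasisReport", "enumerate_esds", "overlap_screen",
           "select_ms", "make_overlap_table"]


@dataclass(frozen=True)
class ESD:
    """An excitonic Slater determinant: one site state per fragment."""

    occupation: Tuple[int, ...]       # state_index per fragment, model order
    fragment_ids: Tuple[int, ...]
    rank: int
    two_ms: int                       # doubled total spin projection
    ordinal: int                      # canonical position in the enumeration

    @property
    def ms(self) -> float:
        return self.two_ms / 2.0

    def excited_sites(self) -> Tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.occupation) if a != 0)

    def __str__(self):
        parts = [f"{f}:{a}" for f, a in zip(self.fragment_ids, self.occupation)]
        return "|" + ",".join(parts) + ">"


@dataclass
class BasisReport:
    """Basis bookkeeping mirroring the counting quantities of a calculation."""

    n_initial: int = 0
    n_after_overlap: int = 0
    counts_per_ms: Dict[float, int] = field(default_factory=dict)
    counts_per_rank: Dict[int, int] = field(default_factory=dict)
    ecsf_counts: Dict[float, Tuple[int, int]] = field(default_factory=dict)
    #: per total spin S: (number of ECSFs, number of contributing ESDs)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_after_overlap": self.n_after_overlap,
            "counts_per_ms": {str(k): v for k, v in sorted(self.counts_per_ms.items())},
            "counts_per_rank": {str(k): v for k, v in sorted(self.counts_per_rank.items())},
            "ecsf_counts": {str(k): list(v) for k, v in sorted(self.ecsf_counts.items())},
        }


def enumerate_esds(site_data: SiteData, max_rank: int) -> List[ESD]:
    """Enumerate all ESDs up to the given excitation rank, canonically ordered.

    Ordering: by rank, then lexicographically in (excited fragment positions,
    their state indices); the ground-state product comes first.  The ordering
    is deterministic, which fixes coefficient signs downstream.
    """
    frags = site_data.fragments
    m = len(frags)
    if not 1 <= max_rank <= m:
        raise ValueError(f"max_rank must be in [1, {m}], got {max_rank}")
    excited: List[List[int]] = []
    ms_of: List[Dict[int, int]] = []
    for f in frags:
        states = site_data.states[f.fragment_id]
        if not states or states[0].state_index != 0:
            raise ValueError(f"fragment {f.fragment_id} supplies no ground site state")
        excited.append([s.state_index for s in states if s.state_index != 0])
        ms_of.append({s.state_index: s.two_ms for s in states})
    fragment_ids = tuple(f.fragment_id for f in frags)

    esds: List[ESD] = []
    gs_ms = sum(ms_of[i][0] for i in range(m))
    esds.append(ESD((0,) * m, fragment_ids, 0, gs_ms, 0))
    ordinal = 1
    for rank in range(1, max_rank + 1):
        for sites in itertools.combinations(range(m), rank):
            for choice in itertools.product(*(excited[i] for i in sites)):
                occ = [0] * m
                for i, a in zip(sites, choice):
                    occ[i] = a
                two_ms = sum(ms_of[i][occ[i]] for i in range(m))
                esds.append(ESD(tuple(occ), fragment_ids, rank, two_ms, ordinal))
                ordinal += 1
    return esds


def make_overlap_table(site_data: SiteData,
                       engine: Optional[InteractionEngine] = None,
                       ) -> Callable[[int, int, int, int], float]:
    """Return a lookup O(F, a_F, G, a_G) of site-state overlap measures.

    Prefers a table stored in the container (synthetic fixtures); otherwise
    evaluates the engine's overlap measure on state densities.  m_s components
    of one multiplet share the verdict: the measure is evaluated for the
    principal member and reused.
    """
    table = dict(site_data.overlaps)

    def canonical(f: int, a: int) -> int:
        st = site_data.state(f, a)
        return site_data.principal_member(f, st.multiplet_id).state_index

    def lookup(f: int, a: int, g: int, b: int) -> float:
        a, b = canonical(f, a), canonical(g, b)
        if (f, a, g, b) in table:
            return table[(f, a, g, b)]
        if (g, b, f, a) in table:
            return table[(g, b, f, a)]
        if engine is None or not engine.has_overlap_measure:
            raise ValueError(
                "no stored overlap table and no engine with an overlap measure")
        tf = site_data.get_tdm(f, a, a)
        tg = site_data.get_tdm(g, b, b)
        if tf is None or tg is None:
            raise ValueError(f"missing state density for overlap ({f},{a})/({g},{b})")
        val = engine.overlap_measure(tf, tg)
        table[(f, a, g, b)] = val
        return val

    return lookup


def overlap_screen(esds: Sequence[ESD], site_data: SiteData, t_o: float,
                   engine: Optional[InteractionEngine] = None,
                   ) -> Tuple[List[ESD], List[Tuple[ESD, Tuple]]]:
    """Expel ESDs containing strongly overlapping site-state pairs.

    For every fragment pair (F, G) the pairwise minimum O_min^{FG} over all
    site-state pairs is computed; an ESD is kept iff for every contained pair
    O_min^{FG} / O(a_F, a_G) >= t_o.  t_o = 0 keeps everything; t_o = 1 with
    uniform overlaps keeps everything; high-overlap (Rydberg-like) states are
    expelled.  Expelled ESDs are returned with their offending pair.
    """
    if not 0.0 <= t_o <= 1.0:
        raise ValueError(f"t_O must be in [0, 1], got {t_o}")
    if t_o == 0.0 or not esds:
        return list(esds), []

    lookup = make_overlap_table(site_data, engine)
    fids = esds[0].fragment_ids
    m = len(fids)
    all_states = {f.fragment_id: [s.state_index for s in site_data.states[f.fragment_id]]
                  for f in site_data.fragments}

    o_min: Dict[Tuple[int, int], float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            f, g = fids[i], fids[j]
            vals = [lookup(f, a, g, b)
                    for a in all_states[f] for b in all_states[g]]
            o_min[(i, j)] = min(vals)

    kept: List[ESD] = []
    expelled: List[Tuple[ESD, Tuple]] = []
    for esd in esds:
        offender = None
        for i in range(m):
            for j in range(i + 1, m):
                o = lookup(fids[i], esd.occupation[i], fids[j], esd.occupation[j])
                omin = o_min[(i, j)]
                if o <= 0.0 and omin <= 0.0:
                    continue
                if o > 0.0 and omin <= 0.0:
                    offender = (fids[i], esd.occupation[i],
                                fids[j], esd.occupation[j], o, omin)
                    break
                if omin / o < t_o:
                    offender = (fids[i], esd.occupation[i],
                                fids[j], esd.occupation[j], o, omin)
                    break
            if offender:
                break
        if offender:
            logger.debug("expelling %s: pair %s", esd, offender)
            expelled.append((esd, offender))
        else:
            kept.append(esd)
    if expelled:
        logger.info("overlap screening expelled %d of %d ESDs (t_O=%.3g)",
                    len(expelled), len(esds), t_o)
    return kept, expelled


def select_ms(esds: Sequence[ESD], ms: float) -> List[ESD]:
    """ESDs whose total spin projection equals ms exactly."""
    two = int(round(2 * ms))
    if abs(2 * ms - two) > 1e-9:
        raise ValueError(f"M_S must be a half-integer, got {ms}")
    return [e for e in esds if e.two_ms == two]


def basis_report(esds_initial: Sequence[ESD],
                 esds_kept: Sequence[ESD]) -> BasisReport:
    rep = BasisReport(n_initial=len(esds_initial), n_after_overlap=len(esds_kept))
    for e in esds_kept:
        rep.counts_per_ms[e.ms] = rep.counts_per_ms.get(e.ms, 0) + 1
        rep.counts_per_rank[e.rank] = rep.counts_per_rank.get(e.rank, 0) + 1
    return rep
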