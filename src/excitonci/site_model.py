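"""Domain types for fragments and site states, and the site-data container.

A multichromophoric system is described fragment by fragment ("site" by
"site"): each fragment carries its own nuclei, electrons, AO basis handle and
a set of electronic eigenstates (site states).  Everything the excitonic CI
needs downstream -- site energies, spin-blocked one-particle (transition)
density matrices and (transition) dipole moments -- lives in a single
:class:`SiteData` object with an HDF5 (or JSON sidecar) serialization.

Internal units are hartree / bohr / elementary charge throughout.  Geometries
supplied in angstrom must be converted at the reader boundary
(:data:`ANGSTROM_TO_BOHR`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .spinutil import twice

ANGSTROM_TO_BOHR = 1.8897259886

CONTAINER_VERSION = "1"

#: density-matrix convention stored in container attrs; see docs/methods.md.
TDM_CONVENTION = "gamma[sigma,tau][p,q] = <bra| a+_{p sigma} a_{q tau} |ket>"

SPIN_BLOCK_KEYS = ("aa", "bb", "ab", "ba")


class SiteDataFormatError(ValueError):
    """Raised when a container does not match the expected layout."""


class SiteDataValidationError(ValueError):
    """Raised when container contents violate a model invariant."""


@dataclass
class Atom:
    element: str
    Z: float
    R: np.ndarray  # (3,) bohr

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3)
        if self.Z <= 0:
            raise SiteDataValidationError(f"nuclear charge must be positive, got {self.Z}")


@dataclass
class FragmentSpec:
    """Static description of one fragment (nuclei, electron count, basis, Q)."""

    fragment_id: int
    atoms: List[Atom]
    n_electrons: int
    ao_basis: dict
    embedding_charges: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.n_electrons < 0:
            raise SiteDataValidationError(
                f"fragment {self.fragment_id}: negative electron count")
        if self.embedding_charges is None:
            self.embedding_charges = np.zeros(len(self.atoms))
        self.embedding_charges = np.asarray(self.embedding_charges, dtype=float)
        if len(self.embedding_charges) != len(self.atoms):
            raise SiteDataValidationError(
                f"fragment {self.fragment_id}: len(Q) != len(atoms)")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.R for a in self.atoms]).reshape(-1, 3)

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([a.Z for a in self.atoms])

    def nuclear_dipole(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros(3)
        return (self.nuclear_charges[:, None] * self.positions).sum(axis=0)


@dataclass(frozen=True)
class SiteState:
    """One electronic state of one fragment.

    ``state_index`` 0 is the site ground state.  ``multiplet_id`` groups the
    2s+1 m_s components that belong to one spin multiplet.
    """

    fragment_id: int
    state_index: int
    energy: float
    spin_s: float
    spin_ms: float
    multiplet_id: str
    label: str = ""

    def __post_init__(self):
        if self.spin_s < 0:
            raise SiteDataValidationError("spin_s must be non-negative")
        if abs(self.spin_ms) > self.spin_s + 1e-9:
            raise SiteDataValidationError(
                f"state ({self.fragment_id},{self.state_index}): |m_s| > s")
        twice(self.spin_s), twice(self.spin_ms)  # must be half-integers

    @property
    def two_s(self) -> int:
        return twice(self.spin_s)

    @property
    def two_ms(self) -> int:
        return twice(self.spin_ms)


@dataclass
class SpinBlockedTDM:
    """Spin-blocked one-particle (transition) density matrix of one fragment.

    Blocks are AO x AO arrays keyed 'aa', 'bb', 'ab', 'ba' with the convention
    gamma^{sigma tau}_{pq} = <bra| a+_{p sigma} a_{q tau} |ket>.
    """

    fragment_id: int
    bra_index: int
    ket_index: int
    blocks: Dict[str, np.ndarray]

    def __post_init__(self):
        shapes = set()
        for k in SPIN_BLOCK_KEYS:
            if k not in self.blocks:
                raise SiteDataValidationError(
                    f"TDM ({self.fragment_id},{self.bra_index},{self.ket_index}):"
                    f" missing spin block '{k}'")
            self.blocks[k] = np.asarray(self.blocks[k], dtype=float)
            shapes.add(self.blocks[k].shape)
        if len(shapes) != 1 or any(s[0] != s[1] for s in shapes):
            raise SiteDataValidationError(
                f"TDM ({self.fragment_id},{self.bra_index},{self.ket_index}):"
                " inconsistent block shapes")

    @property
    def is_transition(self) -> bool:
        return self.bra_index != self.ket_index

    @property
    def n_ao(self) -> int:
        return self.blocks["aa"].shape[0]

    def spatial(self) -> np.ndarray:
        """Spin-traced (spatial) density matrix, gamma^aa + gamma^bb."""
        return self.blocks["aa"] + self.blocks["bb"]

    def transposed(self) -> "SpinBlockedTDM":
        """TDM of the reversed state pair (real wave functions assumed)."""
        return SpinBlockedTDM(
            self.fragment_id, self.ket_index, self.bra_index,
            {
                "aa": self.blocks["aa"].T.copy(),
                "bb": self.blocks["bb"].T.copy(),
                "ab": self.blocks["ba"].T.copy(),
                "ba": self.blocks["ab"].T.copy(),
            },
        )


class SiteDipoleSet:
    """Electronic (transition) dipole moments of site-state pairs, a.u.

    Only the electronic part is stored; the nuclear dipole of a fragment is
    added downstream for bra == ket.
    """

    def __init__(self, fragment_id: int):
        self.fragment_id = fragment_id
        self._mu: Dict[Tuple[int, int], np.ndarray] = {}

    def set(self, bra: int, ket: int, mu) -> None:
        self._mu[(bra, ket)] = np.asarray(mu, dtype=float).reshape(3)

    def get(self, bra: int, ket: int) -> Optional[np.ndarray]:
        if (bra, ket) in self._mu:
            return self._mu[(bra, ket)]
        if (ket, bra) in self._mu:
            return self._mu[(ket, bra)]
        return None

    def items(self):
        return self._mu.items()

    def __len__(self):
        return len(self._mu)


class SiteData:
    """Everything the ECI pipeline consumes, for all fragments."""

    def __init__(self):
        self.fragments: List[FragmentSpec] = []
        self.states: Dict[int, List[SiteState]] = {}
        self.tdms: Dict[int, Dict[Tuple[int, int], SpinBlockedTDM]] = {}
        self.dipoles: Dict[int, SiteDipoleSet] = {}
        #: optional overlap table {(F, a, G, b): measure}, F < G
        self.overlaps: Dict[Tuple[int, int, int, int], float] = {}
        self.meta: Dict[str, str] = {
            "version": CONTAINER_VERSION,
            "tdm_convention": TDM_CONVENTION,
        }

    # -- construction ------------------------------------------------------

    def add_fragment(self, frag: FragmentSpec) -> None:
        if any(f.fragment_id == frag.fragment_id for f in self.fragments):
            raise SiteDataValidationError(f"duplicate fragment id {frag.fragment_id}")
        self.fragments.append(frag)
        self.states[frag.fragment_id] = []
        self.tdms[frag.fragment_id] = {}
        self.dipoles[frag.fragment_id] = SiteDipoleSet(frag.fragment_id)

    def add_state(self, state: SiteState) -> None:
        if state.fragment_id not in self.states:
            raise SiteDataValidationError(f"unknown fragment {state.fragment_id}")
        if any(s.state_index == state.state_index
               for s in self.states[state.fragment_id]):
            raise SiteDataValidationError(
                f"duplicate state ({state.fragment_id},{state.state_index})")
        self.states[state.fragment_id].append(state)
        self.states[state.fragment_id].sort(key=lambda s: s.state_index)

    def add_tdm(self, tdm: SpinBlockedTDM) -> None:
        self.tdms[tdm.fragment_id][(tdm.bra_index, tdm.ket_index)] = tdm

    # -- lookup ------------------------------------------------------------

    def fragment(self, fragment_id: int) -> FragmentSpec:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(fragment_id)

    def state(self, fragment_id: int, state_index: int) -> SiteState:
        for s in self.states[fragment_id]:
            if s.state_index == state_index:
                return s
        raise KeyError((fragment_id, state_index))

    def ms_components_of(self, fragment_id: int, multiplet_id: str) -> List[SiteState]:
        """The 2s+1 members of a multiplet, ordered by descending m_s."""
        members = [s for s in self.states[fragment_id]
                   if s.multiplet_id == multiplet_id]
        if not members:
            raise SiteDataValidationError(
                f"multiplet {multiplet_id!r} not registered on fragment {fragment_id}")
        members.sort(key=lambda s: -s.two_ms)
        expected = members[0].two_s + 1
        got = {s.two_ms for s in members}
        want = set(range(-members[0].two_s, members[0].two_s + 1, 2))
        if len(members) != expected or got != want:
            raise SiteDataValidationError(
                f"multiplet {multiplet_id!r} on fragment {fragment_id} is incomplete:"
                f" found m_s components {sorted(x / 2 for x in got)}")
        return members

    def principal_member(self, fragment_id: int, multiplet_id: str) -> SiteState:
        return self.ms_components_of(fragment_id, multiplet_id)[0]

    def multiplet_ids(self, fragment_id: int) -> List[str]:
        seen, out = set(), []
        for s in self.states[fragment_id]:
            if s.multiplet_id not in seen:
                seen.add(s.multiplet_id)
                out.append(s.multiplet_id)
        return out

    def get_tdm(self, fragment_id: int, bra: int, ket: int) -> Optional[SpinBlockedTDM]:
        store = self.tdms[fragment_id]
        if (bra, ket) in store:
            return store[(bra, ket)]
        if (ket, bra) in store:
            return store[(ket, bra)].transposed()
        return None

    # -- validation --------------------------------------------------------

    def validate(self, trace_tol: float = 1e-6, energy_tol: float = 1e-8) -> None:
        """Check every invariant of the data model; raise on violation."""
        for frag in self.fragments:
            fid = frag.fragment_id
            states = self.states[fid]
            if not states or states[0].state_index != 0:
                raise SiteDataValidationError(
                    f"fragment {fid}: missing ground site state (index 0)")
            by_mult: Dict[str, List[SiteState]] = {}
            for s in states:
                by_mult.setdefault(s.multiplet_id, []).append(s)
            for mid, members in by_mult.items():
                e0, s0 = members[0].energy, members[0].two_s
                for s in members[1:]:
                    if abs(s.energy - e0) > energy_tol:
                        raise SiteDataValidationError(
                            f"multiplet {mid!r} on fragment {fid}: members"
                            f" differ in energy by {abs(s.energy - e0):.2e}")
                    if s.two_s != s0:
                        raise SiteDataValidationError(
                            f"multiplet {mid!r} on fragment {fid}: mixed spin_s")
                if len({s.two_ms for s in members}) != len(members):
                    raise SiteDataValidationError(
                        f"multiplet {mid!r} on fragment {fid}: repeated m_s")
                self.ms_components_of(fid, mid)  # completeness
            for (bra, ket), tdm in self.tdms[fid].items():
                if bra == ket:
                    tr = np.trace(tdm.spatial())
                    # trace rule assumes an orthonormal AO metric; basis
                    # handles with an explicit metric carry it in ao_basis
                    metric = self._metric(frag)
                    if metric is not None:
                        tr = float(np.sum(tdm.spatial() * metric.T))
                    if abs(tr - frag.n_electrons) > trace_tol:
                        raise SiteDataValidationError(
                            f"fragment {fid} state {bra}: density trace {tr:.6f}"
                            f" != N_el = {frag.n_electrons}")

    @staticmethod
    def _metric(frag: FragmentSpec) -> Optional[np.ndarray]:
        m = frag.ao_basis.get("metric") if isinstance(frag.ao_basis, dict) else None
        return None if m is None else np.asarray(m, dtype=float)

    def missing_tdm_pairs(self) -> List[Tuple[int, int, int]]:
        """Principal-member state pairs without stored TDM blocks."""
        missing = []
        for frag in self.fragments:
            fid = frag.fragment_id
            mids = self.multiplet_ids(fid)
            principals = [self.principal_member(fid, m).state_index for m in mids]
            for i, b in enumerate(principals):
                for k in principals[i:]:
                    if self.get_tdm(fid, b, k) is None:
                        missing.append((fid, b, k))
        return missing


# -- serialization ----------------------------------------------------------


def _state_key(idx: int) -> str:
    return f"{idx:04d}"


def write_site_data(data: SiteData, path: str) -> None:
    """Write a :class:`SiteData` container (HDF5 or ``.json`` sidecar)."""
    if str(path).endswith(".json"):
        _write_json(data, path)
        return
    import h5py

    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        for k, v in data.meta.items():
            meta.attrs[k] = v
        for frag in data.fragments:
            g = fh.create_group(f"fragments/{frag.fragment_id}")
            g.create_dataset("elements",
                             data=np.array([a.element for a in frag.atoms], dtype="S8"))
            g.create_dataset("Z", data=frag.nuclear_charges)
            g.create_dataset("R_bohr", data=frag.positions)
            g.attrs["n_electrons"] = frag.n_electrons
            g.attrs["ao_basis"] = json.dumps(frag.ao_basis, default=_np_default)
            g.create_dataset("Q", data=frag.embedding_charges)
            for s in data.states[frag.fragment_id]:
                sg = g.create_group(f"states/{_state_key(s.state_index)}")
                sg.attrs["energy_hartree"] = s.energy
                sg.attrs["s"] = s.spin_s
                sg.attrs["ms"] = s.spin_ms
                sg.attrs["multiplet_id"] = s.multiplet_id
                sg.attrs["label"] = s.label
            for (bra, ket), tdm in data.tdms[frag.fragment_id].items():
                tg = g.create_group(f"tdm/{_state_key(bra)}__{_state_key(ket)}")
                for k in SPIN_BLOCK_KEYS:
                    tg.create_dataset(k, data=tdm.blocks[k])
            for (bra, ket), mu in data.dipoles[frag.fragment_id].items():
                g.create_dataset(f"dipole/{_state_key(bra)}__{_state_key(ket)}", data=mu)
        if data.overlaps:
            keys = np.array(sorted(data.overlaps), dtype=np.int64)
            vals = np.array([data.overlaps[tuple(k)] for k in keys], dtype=float)
            og = fh.create_group("overlaps")
            og.create_dataset("keys", data=keys)
            og.create_dataset("values", data=vals)


def read_site_data(path: str, validate: bool = True) -> SiteData:
    """Read a container written by :func:`write_site_data`."""
    if str(path).endswith(".json"):
        data = _read_json(path)
    else:
        data = _read_h5(path)
    if validate:
        data.validate()
    return data


def _read_h5(path: str) -> SiteData:
    import h5py

    data = SiteData()
    with h5py.File(path, "r") as fh:
        if "meta" not in fh or "fragments" not in fh:
            raise SiteDataFormatError(f"{path}: missing /meta or /fragments group")
        data.meta = dict(fh["meta"].attrs)
        for fkey in sorted(fh["fragments"], key=int):
            g = fh[f"fragments/{fkey}"]
            for req in ("elements", "Z", "R_bohr", "Q"):
                if req not in g:
                    raise SiteDataFormatError(
                        f"/fragments/{fkey}: missing dataset '{req}'")
            elements = [e.decode() for e in g["elements"][...]]
            Z = g["Z"][...]
            R = g["R_bohr"][...].reshape(-1, 3)
            atoms = [Atom(e, z, r) for e, z, r in zip(elements, Z, R)]
            frag = FragmentSpec(
                fragment_id=int(fkey),
                atoms=atoms,
                n_electrons=int(g.attrs["n_electrons"]),
                ao_basis=json.loads(g.attrs["ao_basis"]),
                embedding_charges=g["Q"][...],
            )
            data.add_fragment(frag)
            if "states" not in g:
                raise SiteDataFormatError(f"/fragments/{fkey}: missing 'states'")
            for skey in sorted(g["states"]):
                sg = g[f"states/{skey}"]
                data.add_state(SiteState(
                    fragment_id=int(fkey),
                    state_index=int(skey),
                    energy=float(sg.attrs["energy_hartree"]),
                    spin_s=float(sg.attrs["s"]),
                    spin_ms=float(sg.attrs["ms"]),
                    multiplet_id=str(sg.attrs["multiplet_id"]),
                    label=str(sg.attrs.get("label", "")),
                ))
            if "tdm" in g:
                for tkey in g["tdm"]:
                    bra, ket = (int(x) for x in tkey.split("__"))
                    tg = g[f"tdm/{tkey}"]
                    blocks = {k: tg[k][...] for k in SPIN_BLOCK_KEYS if k in tg}
                    if len(blocks) != 4:
                        raise SiteDataFormatError(
                            f"/fragments/{fkey}/tdm/{tkey}: incomplete spin blocks")
                    data.add_tdm(SpinBlockedTDM(int(fkey), bra, ket, blocks))
            if "dipole" in g:
                for dkey in g["dipole"]:
                    bra, ket = (int(x) for x in dkey.split("__"))
                    data.dipoles[int(fkey)].set(bra, ket, g[f"dipole/{dkey}"][...])
        if "overlaps" in fh:
            keys = fh["overlaps/keys"][...]
            vals = fh["overlaps/values"][...]
            data.overlaps = {tuple(int(x) for x in k): float(v)
                             for k, v in zip(keys, vals)}
    return data


def _np_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o))


def _write_json(data: SiteData, path: str) -> None:
    doc = {"meta": data.meta, "fragments": {}}
    for frag in data.fragments:
        fid = frag.fragment_id
        doc["fragments"][str(fid)] = {
            "elements": [a.element for a in frag.atoms],
            "Z": frag.nuclear_charges.tolist(),
            "R_bohr": frag.positions.tolist(),
            "n_electrons": frag.n_electrons,
            "ao_basis": frag.ao_basis,
            "Q": frag.embedding_charges.tolist(),
            "states": {
                str(s.state_index): {
                    "energy_hartree": s.energy, "s": s.spin_s, "ms": s.spin_ms,
                    "multiplet_id": s.multiplet_id, "label": s.label,
                } for s in data.states[fid]
            },
            "tdm": {
                f"{b}__{k}": {key: t.blocks[key].tolist() for key in SPIN_BLOCK_KEYS}
                for (b, k), t in data.tdms[fid].items()
            },
            "dipole": {f"{b}__{k}": mu.tolist()
                       for (b, k), mu in data.dipoles[fid].items()},
        }
    if data.overlaps:
        doc["overlaps"] = [[*k, v] for k, v in sorted(data.overlaps.items())]
    with open(path, "w") as fh:
        json.dump(doc, fh, default=_np_default)


def _read_json(path: str) -> SiteData:
    with open(path) as fh:
        doc = json.load(fh)
    if "fragments" not in doc:
        raise SiteDataFormatError(f"{path}: missing 'fragments' key")
    data = SiteData()
    data.meta = dict(doc.get("meta", data.meta))
    for fkey in sorted(doc["fragments"], key=int):
        rec = doc["fragments"][fkey]
        atoms = [Atom(e, z, r) for e, z, r in
                 zip(rec["elements"], rec["Z"], rec["R_bohr"])]
        data.add_fragment(FragmentSpec(
            fragment_id=int(fkey), atoms=atoms,
            n_electrons=int(rec["n_electrons"]),
            ao_basis=rec["ao_basis"], embedding_charges=rec["Q"]))
        for skey, s in rec["states"].items():
            data.add_state(SiteState(
                fragment_id=int(fkey), state_index=int(skey),
                energy=s["energy_hartree"], spin_s=s["s"], spin_ms=s["ms"],
                multiplet_id=s["multiplet_id"], label=s.get("label", "")))
        for tkey, blocks in rec.get("tdm", {}).items():
            bra, ket = (int(x) for x in tkey.split("__"))
            data.add_tdm(SpinBlockedTDM(
                int(fkey), bra, ket,
                {k: np.array(v) for k, v in blocks.items()}))
        for dkey, mu in rec.get("dipole", {}).items():
            bra, ket = (int(x) for x in dkey.split("__"))
            data.dipoles[int(fkey)].set(bra, ket, mu)
    for item in doc.get("overlaps", []):
        *k, v = item
        data.overlaps[tuple(int(x) for x in k)] = float(v)
    return data
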