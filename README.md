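# excitonci

Fragment-based excited-state electronic structure for multichromophoric
assemblies (molecular aggregates, stacked nucleobase tetramers,
chromophore-metal complexes): full-system electronic states are expanded in
antisymmetrized products of monomer ("site") states and the Hamiltonian is
evaluated **only** from site energies and one-particle (transition) density
matrices, under the strong-orthogonality group-function formalism.

## The method

Each fragment *F* supplies site states |*Fa*⟩ with energies *Ẽ<sub>Fa</sub>*,
spin quantum numbers (*s*, *m<sub>s</sub>*) and spin-blocked one-particle
(transition) densities γ<sup>στ</sup>. An *excitonic Slater determinant*
(ESD) puts one site state on every fragment; its excitation rank is the
number of fragments out of their ground state, giving the truncation
hierarchy ECIS, ECISD, … (the Frenkel exciton model is the rank-1 basis with
the diagonal cross-fragment terms and GS–LE couplings dropped). Matrix
elements follow Slater–Condon-like rules with fragments in place of
electrons:

* **rule 0** (diagonal): Σ<sub>F</sub> *Ẽ<sub>Fa</sub>* +
  Σ<sub>F&lt;G</sub> (*J̃* − *K*), where *J̃* contains the internuclear
  constant, density–nuclear attraction and density–density Coulomb terms,
* **rule I** (one differing site state): transition density of the changed
  fragment against every partner's state density and nuclei (*J̃* − *K*),
* **rule II** (two differing site states): electron–electron *J* − *K* only,
* three or more differing site states: zero.

Embedding enters through arbitrary point charges *Q*: the site states are
computed in the field of the other fragments' charges and the rules replace
nuclear charges *Z* by (*Z* − *Q*). Since the charges are added and
subtracted from the same Hamiltonian, the operator — and, in a complete
basis, the spectrum — does not depend on them; they are variational tuning
parameters. The *excitonic Hartree–Fock* (EHF) loop fixes each atom's charge
to the RESP charge of its fragment's embedded ground state and iterates to
self-consistency, which minimizes the ground-product energy and suppresses
the GS–LE block (an excitonic Brillouin theorem). Spin adaptation builds
excitonic configuration-state functions (ECSFs) by numerically diagonalizing
S² inside each family of ESDs sharing a multiplet-occupation pattern.
Per-state diagnostics: participation ratio PR = (Σc²)²/Σc⁴ and
excitation-rank weights E<sub>n</sub> = Σ<sub>rank K = n</sub> c<sub>K</sub>².

Every matrix-element rule is certified against a brute-force determinant
oracle: model systems with fragment-disjoint orthonormal orbitals and
number-conserving integrals only, where the rules are provably exact — the
package tests agreement to 10⁻¹⁰ on hundreds of randomized models.

## Worked example

Two point-dipole chromophores (transition dipoles 1 a.u. along the "bond",
site excitation energy 0.15 hartree) stacked 10 bohr apart:

```python
from excitonci import run_eci, RunConfig
from excitonci.fixtures import make_point_chromophore_dimer

data, engine = make_point_chromophore_dimer(separation=10.0)
out = run_eci(data, engine, RunConfig(max_rank=1, spins=(0.0,),
                                      use_exchange=False))
res = out.results[0.0]
ev = res.excitation_energies_ev()
for i in range(1, len(ev)):
    print(f"state {i}: E_exc = {ev[i]:.4f} eV  "
          f"f = {res.osc_strengths[i]:.4f}  PR = {res.pr[i]:.2f}")
```

prints

```
state 1: E_exc = 4.0547 eV  f = 0.0000  PR = 2.00
state 2: E_exc = 4.1087 eV  f = 0.2013  PR = 2.00
```

— the two local excitations split by twice the dipole–dipole coupling
μ₁μ₂/R³ = 10⁻³ hartree (0.0544 eV) around the site energy (4.08 eV), into a
dark lower and a bright upper state, each an equal mix of the two LE ECSFs
(PR = 2): H-aggregate behaviour.

The same pipeline runs from the shell:

```sh
eci count --rank sd --t-o 0.95 --spins 0,1,2   # basis bookkeeping
eci fixtures --kind point-dimer dimer.json
eci run --rank s --t-o 0 dimer.json            # spectrum + diagnostics JSON
eci ehf --mode ehf --log cycles.csv            # embedding self-consistency
eci oracle-compare --models 25                 # rules vs determinant oracle
```

`eci count` reproduces the full basis bookkeeping of a four-fragment
nucleobase-like tetramer where each fragment carries 7 excited singlets and
3 triplets and one Rydberg-like singlet violates strong orthogonality: 1601
ESDs in ECISD, 1411 after overlap screening, 631 in the M_S = 0 block, 295
singlet / 282 triplet / 54 quintet ECSFs after spin adaptation.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the ESD/ECSF counts of the four-fragment counting
scenario (initial ECIS/ECISD sizes, post-screening sizes, M_S block sizes,
and spin-adapted ECSF counts per total spin) by running the enumeration,
screening, M_S selection and S² diagonalization machinery of the package,
and writes them as JSON keyed t1–t10.

## Scope notes

The basis deliberately contains no charge-transfer products, and
diagonalization is dense (the shipped systems stay below a few thousand
ECSFs). Reproducing ab initio tetramer spectra requires a monomer CIS
backend at real basis-set scale; the backend contract
(`excitonci.backend.SiteBackend`) and the HDF5 site-data container define
that workflow, while the shipped reference backend is an exact
toy-model diagonalizer. See `docs/methods.md` for assumptions, numerical
choices and limitations.
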