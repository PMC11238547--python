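# Methods

This note documents the model, the conventions, and the numerical choices of
`excitonci`, and states precisely what the shipped tests do and do not
establish.

## Model and assumptions

The full-system wave function is expanded in antisymmetrized products of
fragment ("site") states, one per fragment. Two assumptions carry the whole
formalism:

1. **Strong orthogonality** — products of site states from different
   fragments integrate to zero in one shared electronic coordinate. Under
   it, every Hamiltonian matrix element reduces to site energies plus
   two-fragment Coulomb (*J*) and exchange (*K*) contractions of
   one-particle (transition) densities, with Slater–Condon-like selection
   rules on the number of differing site states (0, I, II, else zero).
2. **Spin purity of site states** — each site state is an eigenstate of its
   fragment's S² with definite (*s*, *m<sub>s</sub>*); total-spin adaptation
   then only couples the m<sub>s</sub> distributions inside one
   multiplet-occupation pattern ("family").

The excitonic basis contains ground, local-excitation and multi-local-
excitation products only; **charge-transfer products are out of scope** by
design. Consequences: the basis cannot describe interfragment electron
transfer, and "full rank" means complete only within the
fragment-number-conserving sector.

### Conventions

* Units: hartree / bohr / elementary charge. 1 Å = 1.8897259886 bohr;
  1 hartree = 27.211386245988 eV.
* Density matrices: `gamma[sigma,tau][p,q] = <bra| a+_{p sigma} a_{q tau} |ket>`
  (stored in container attrs). State densities are symmetric; reversing a
  pair transposes the spatial indices and swaps the αβ/βα blocks.
* Exchange contraction (spin-orbital result):
  K = Σ<sub>στ</sub> Σ γ<sub>F</sub><sup>στ</sup>[p,q] γ<sub>G</sub><sup>τσ</sup>[r,s] (p<sub>F</sub> s<sub>G</sub> | r<sub>G</sub> q<sub>F</sub>).
  The index placement is *not* a matter of taste: on integral tensors
  without within-pair symmetry the alternatives disagree, and the
  determinant oracle fixes this one (see below). The J − K sign convention
  is likewise certified by the oracle, not assumed.
* Ladder phases: Condon–Shortley throughout (S² matrices, multiplet
  generation, Wigner–Eckart TDM expansion, Clebsch–Gordan coefficients via
  sympy).
* Only the principal (m<sub>s</sub> = s) member of each multiplet pair needs
  stored TDM blocks. Other components are generated from the scalar part
  D = γ<sup>αα</sup>+γ<sup>ββ</sup> and the vector part (t⁺, t_z, t⁻) of
  a⁺a by Clebsch–Gordan ratios; the construction is linear, idempotent, and
  tested against directly contracted oracle TDMs to 10⁻¹⁰.

## Embedding and EHF

Embedding point charges Q are added *and subtracted* from the Hamiltonian,
so the operator is independent of them; they only deform the site states.
In the matrix-element rules this shows up as the substitution Z → (Z − Q)
in the nuclear attraction and in the internuclear constant
Σ (Z<sub>f</sub>Z<sub>g</sub> − Z<sub>f</sub>Q<sub>g</sub> − Q<sub>f</sub>Z<sub>g</sub>)/R —
note there is **no Q·Q self-term**: the subtracted embedding operators are
linear in Q, which the element-wise embedding-invariance test confirms.
When site states are *not* eigenstates of the embedded site Hamiltonian
(nonvariational mode), the diagonal site energies acquire the nuclear- and
electron-embedding corrections and rule I acquires the ⟨a|H̃|b⟩ cross term,
both rebuilt from densities; two-particle density corrections are not
implemented (out of scope).

The EHF loop: all-zero initial charges → embedded ground state per fragment
→ RESP fit → replace → iterate until max|ΔQ| < t<sub>Q</sub> (default
10⁻⁴ e, max 50 cycles, no damping; optional linear mixing α = 0.5 for
oscillatory cases, detected as a period-2 pattern in max|ΔQ|).
Non-convergence returns a flagged state, not an exception. The final energy
is the rule-0 element of the ground product — the same code path as any
other diagonal element. Open-shell fragment ground states are accepted by
the data model, but the spin adaptation of an open-shell ground *product*
before the energy evaluation is untested territory and flagged experimental.

**RESP details** (a decision of this package, labeled standard point-charge
RESP): Merz–Kollman-style shells at 1.4/1.6/1.8/2.0 × Bondi vdW radii,
about 1 point/Å² per shell on deterministic Fibonacci spheres, points inside
another atom's shell discarded; hyperbolic restraint a = 0.0005 a.u.,
b = 0.1 e, iteratively reweighted to 10⁻⁶; total charge enforced by a
Lagrange multiplier. With the restraint off the fit recovers an exact
point-charge potential to numerical precision, which is what the EHF
fixed-point tests exploit. A multipole-augmented RESP is not implemented.

## Overlap screening

The strong-orthogonality violation measure for a site-state pair is
Tr[γ<sub>F</sub> S<sub>FG</sub> γ<sub>G</sub> S<sub>GF</sub>] with S the
cross-fragment AO overlap. This specific integrand is a choice of this
package (monotone-equivalent measures leave the screening decision
unchanged, since only ratios enter). An ESD is kept iff for every contained
fragment pair O<sub>min</sub><sup>FG</sup>/O(a<sub>F</sub>,a<sub>G</sub>) ≥ t<sub>O</sub>
(default 0.95), where O<sub>min</sub> is the smallest overlap among all
site-state pairs of that fragment pair. The inequality direction reproduces
both limiting cases (t<sub>O</sub> = 0 keeps everything; t<sub>O</sub> = 1
with uniform overlaps keeps everything) and expels diffuse, Rydberg-like
states whose measure exceeds the fragment-pair floor. A zero floor with a
nonzero pair overlap counts as expulsion and is logged. m<sub>s</sub>
components of one multiplet share the verdict.

## Spin adaptation

ECSFs are obtained by *numerical* diagonalization of S² per family (no
genealogical formulas), keeping eigenvectors with |λ − S(S+1)| < 10⁻⁸ at
M<sub>S</sub> = S, pruning coefficients below 10⁻¹² and renormalizing.
S² provably never couples across families, which is why the blocks stay
small. Degenerate eigenvectors are canonicalized by Gram–Schmidt against
the canonical ESD order and sign-fixed (largest |c| positive, ties broken
by lowest ordinal); physical observables are invariant to this choice
(tested by randomized rotations), it only pins coefficient signs for
reproducibility.

## The determinant oracle and what "green" means

The oracle builds model systems whose fragments own disjoint orthonormal
orbitals, with no cross-fragment one-electron (hopping) terms and
two-electron integrals restricted to the number-conserving classes
(intra-fragment, (FF|GG) Coulomb, (FG|GF) exchange). Random tensors carry
only the hermiticity symmetry group, deliberately *not* the within-pair
index symmetry of real spatial integrals — this is what makes the oracle
sharp enough to detect wrong index placements in the J/K contractions.
Fragment eigenstates come from per-sector full CI with multiplets assembled
by lowering operators; antisymmetrized products are expanded into
determinants (fragment-major creation-operator order; the parity bookkeeping
is certified only for even-electron fragments, and odd-electron assembly is
gated behind a flag).

On these models the rules are exact, and the tests verify element-wise
agreement to 10⁻¹⁰ and full-rank eigenvalue agreement to 10⁻⁸ over hundreds
of randomized 2–3-fragment cases. **What this establishes:** the
implementation of the rules, spin machinery, TDM expansion and embedding
algebra is correct within strong orthogonality. **What it does not:** any
statement about real chromophores, where strong orthogonality is
approximate, CT products may matter, and site states come from approximate
monomer calculations. The synthetic fixtures likewise emulate bookkeeping
(state counts, multiplet structure, a synthetic overlap table with a 10×
Rydberg-like outlier) and idealized electrostatics (point densities,
s-Gaussian densities), not real wave functions.

## Numerical choices and degenerate inputs

* Dense symmetric eigensolvers only; iterative (Davidson-type)
  diagonalization is future work, acceptable because shipped systems stay
  below a few thousand ECSFs.
* Hermiticity guard: `solve` rejects asymmetry above 10⁻⁸; assembly fills
  the upper triangle and mirrors it.
* Spin shortcuts are applied before integral work: spin-traced transition
  densities vanish unless Δm<sub>s</sub> = 0 on the fragment, |Δm<sub>s</sub>| > 1
  kills all one-particle blocks, and rule II requires compensating
  Δm<sub>s</sub> on the two changed fragments.
* Degenerate full-system eigenvectors are canonicalized the same way as
  degenerate ECSFs (deterministic Gram–Schmidt + sign fix).
* The discrete point-charge engine refuses coincident points (r = 0) rather
  than regularizing; physical inputs never need them. It also refuses
  densities with off-diagonal weight, which has no spatial meaning for
  point sets.
* The s-Gaussian engine evaluates overlap, attraction, Coulomb and exchange
  in closed form (Boys/erf); it exists so that spatially meaningful toys run
  without an external integral library. An adapter for a real AO integral
  engine would implement the same four-method engine contract,
  pair-of-fragments at a time.
* No integral prescreening or distance cutoffs are applied by default.

## Known limitations

* No charge-transfer products, spin–orbit couplings, gradients or
  nonadiabatic couplings.
* Odd-electron (open-shell between-fragment) parity phases unverified and
  gated off.
* The counting fixture's energies/densities are placeholders; it must not
  be used for energetics.
* RESP restrains all atoms uniformly (no hydrogen exemption, no equivalence
  groups yet); restraint-free fits are used wherever exactness is asserted.
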