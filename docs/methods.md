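# Methods

## Model

`editchains` studies Markov chains whose states are edge subsets
`E ⊆ E(H)` of a fixed simple host graph `H = (V, E)` with `n` vertices and
`m` edges.  One step samples a *graph edit* from a finite weighted family
and applies it to the current subset.  An edit is an idempotent map on
subsets; in canonical form it is a partial map from edges to
`{add, delete}`: every edge in its *support* is forced present or absent,
every other edge is untouched.  Edits are memoryless — applying an edit is
independent of history and of whether its edges are already in the desired
state.

Under the product "rightmost factor acts first", the edits generate a
**left regular band** (LRB): `x² = x` and `xyx = xy`.  Two consequences
drive everything in the package:

1. **Closed-form eigenvalues.**  The transition matrix of the walk on the
   chambers (full-support elements, which biject with edge subsets) is
   diagonalizable with eigenvalues indexed by the union-closed lattice `L`
   generated by the edit supports and `∅`:

       λ_X = Σ { w_x : supp(x) ⊆ X },   X ∈ L.

   Multiplicities follow by Möbius inversion of chamber counts:
   `m_X = Σ_{Y ⊇ X} μ(X, Y) c_Y`, where `c_X` counts chambers fixed by a
   representative edit with support `X`.

2. **Mixing bounds.**  The walk satisfies
   `‖P^t(x₀,·) − π‖_TV ≤ Σ_{X ∈ L*} m_X λ_X^t` (L* = non-maximal lattice
   elements), giving `TV ≤ e^{−c}` after
   `t ≥ m(c + 2 ln m)` steps for the simple process,
   `t ≥ (m ln 2 + c)/(1 − λ*)` for a general compound family, and
   `t ≥ (ln M + c)/(1 − λ*)` when the chamber count is bounded by `M`.
   All logarithms are natural; the proofs of these thresholds rest on
   `ln(1 + x) ≤ x`, and the bound-domination property tests would falsify
   a weaker base.

### The simple edit process

With edge probabilities `0 < p_e < 1`, the family
`{e⁺ : w = p_e/m, e⁻ : w = (1 − p_e)/m}` realizes the process "pick an
edge uniformly; make it present with probability p_e, absent otherwise".
Its stationary law is the edge-independent product measure
`π(E) = Π_{e∈E} p_e Π_{e∉E} (1 − p_e)`, the chain is reversible, and the
spectrum is `{|T|/m : T ⊆ E}`, each subset contributing multiplicity one —
independent of `p`.  On a complete host this stationary law reproduces any
edge-independent random graph (Erdős–Rényi, Chung–Lu expected degrees,
two-block stochastic block model); `models.edge_probability_model` builds
the corresponding probability vectors.

### Eigenvectors, hitting and commute times (simple process)

For each `T ⊆ E` the row vector

    φ_T(E) = (−1)^{#edges outside E∪T} · Π_{e∈T∩E} p_e · Π_{e∈T∖E} (1 − p_e)

satisfies `φ_T P = (|T|/m) φ_T`, with `φ_E = π`.  The normalized family
`ψ_T = s_T · φ_T Π^{−1/2}` with `s_T = √(Π_{e∉T} p_e(1 − p_e))` is an
orthonormal system of left eigenvectors of the symmetrized operator
`Q = Π^{1/2} P Π^{−1/2}`.  This normalization is the unique reading under
which `⟨ψ_T, ψ_T⟩ = 1` and the spectral hitting/commute formulas agree
with the fundamental-matrix solve; the test suite enforces both.

Hitting times use the `t ≥ 0` convention (`H(x, x) = 0`) and the
reversible-chain spectral representation with the ratio vectors
`r_T(E) = ψ_T(E)/√π(E) = s_T φ_T(E)/π(E)`:

    H(x, y) = Σ_{T ≠ E} (1 − |T|/m)^{-1} · r_T(y)(r_T(y) − r_T(x)),
    C(x, y) = H(x, y) + H(y, x) = Σ_{T ≠ E} m/(m − |T|) (r_T(x) − r_T(y))².

**Restricted commute sum.**  Writing `φ_T(E)/π(E)` as a product over
`e ∉ T` of `p_e^{-1}` (edge present) or `(p_e − 1)^{-1}` (edge absent),
the factor at `e` coincides between states `E` and `F` exactly when
`e ∉ E△F`.  Hence a term vanishes exactly when `T ⊇ E△F`, and the commute
sum may be restricted to subsets `T` that *miss at least one edge of the
symmetric difference* (`(E△F)∖T ≠ ∅`).  Note this is the complement-side
condition — restricting instead to `T` meeting `E△F` would drop the
nonvanishing `T = ∅` term and is refuted by the worked path example below.
The implementation asserts restricted = full = linear-solver values on
every state pair of every test host.

Spectral sums accumulate terms in descending `|T|` with `math.fsum`
(compensated); the tolerance budget against the solver oracle is `1e-8`.

### Compound showcases

**Moran process.**  Pick an edge `{u, v}` uniformly and an endpoint `u`
uniformly; delete all edges at `u` and add `{u, v}`.  As an edit family:
one edit `y_(u,v)` per oriented edge, weight `1/(2m)`, support `N(u)`.
The eigenvalue lattice is generated by the vertex edge-neighborhoods, with
`λ_X = Σ_{v : N(v) ⊆ X} d_v/(2m)`; the second-largest eigenvalue is at
most `1 − δ(H)/m` (minimum degree δ).  Mixing:
`t ≥ m(m ln 2 + c)/δ(H)` in general, sharpened on `K_n` to
`t ≥ (n² ln n + c n)/2` via the spanning-forest count bound
`F_n ≤ (n−1)^n`.  On `K_n` the stationary law is the Moran forest, a
random-forest genealogy model; the package verifies on K3/K4 that the
recurrent states of the exact digraph are precisely the chambers of the
generated subsemigroup and are acyclic, rather than assuming it.

**Dynamic random intersection graph.**  On the complete bipartite host
`K_{n,N}` the edit `y_{v,A}` pins the neighborhood of left vertex `v` to
`A ⊆ Ω′`, with weight `(1/n)·μ(|A|)/C(N,|A|)` for a size law `μ` on
`{0, …, N}`.  Supports are the disjoint neighborhoods `N(v)`, so
eigenvalues are `λ_B = |B|/n` per `B ⊆ Ω` and the spectral gap is `1/n`
for every `μ`; with full-support `μ` all `2^{nN}` subsets are chambers.
An exact enumeration (guarded at `n·2^N ≤ 10⁵`) and a distributionally
identical lazy sampler are both provided.

## Numerical and design choices

- **State encoding.**  Edge `i` (canonical order: sorted endpoint-index
  pairs) is bit `i` of an integer bitmask; bitstrings print edge 0 first.
  Vertex labels made of digits sort numerically before other labels
  (lexicographic); this keeps state indices reproducible.
- **Transition matrices** are dense over all `2^m` subsets (guarded at
  `m ≤ 14`); spectral statements about compound chains apply to the
  recurrent (chamber) block, and transient states are reported by the
  recurrent-class analysis, never silently dropped.
- **Chamber-count representative.**  `c_X` uses the product of the
  greedily chosen first generators whose supports union to `X`.  Whether
  `c_X` is representative-independent in an arbitrary generated
  subsemigroup is validated, not assumed: multiplicities must be
  nonnegative and sum to the chamber count (hard error otherwise), and a
  test compares all representatives on K3.
- **Eigenvalue comparisons** against brute-force eigendecompositions group
  at absolute tolerance `1e-9`.
- **RNG contract.**  One integer seed per run; edits are sampled by
  inverse CDF over the family's fixed edit order, so trajectories are
  bit-reproducible across platforms.
- **Bounds** are returned as integer ceilings of the real thresholds.
- Lattice closures beyond `10⁵` elements and semigroup closures beyond
  their cap (default `3^m`, tight for the full simple semigroup) are
  refused with explicit errors.

## Worked sizes and what the tests show

All verification is exact at desk scale: hosts with `m ≤ 6` edges
(path fixtures, the 5-cycle, K3, K4, K_{2,3}), state spaces up to 64, and
the compound showcases Moran-K4 (37 recurrent forest states) and the
intersection process at `n = 3, N = 2`.  Monte-Carlo checks use `10⁴`
round trips or `10⁵` steps with fixed seeds and 3–4 standard-error bands
(inflated by the chain's relaxation time where samples are correlated).
These instances exercise every closed form against an independent oracle
(numeric eigendecomposition, fundamental-matrix solves, exact matrix
powers for TV, brute-force semigroup closure); they do not probe
large-`m` numerical conditioning, and the dense-matrix machinery
deliberately stops at `m = 14` — beyond that only simulation and the
closed-form bounds apply.

## Known limitations

- Closed-form eigenvectors exist only for the simple process; compound
  chains use numeric eigendecomposition of the chamber block.
- The closed-form stationary law of the Moran forest is not computed,
  only sampled and solved numerically on small hosts.
- No effective-resistance interpretation of commute times is implemented.
- Hosts are simple undirected graphs; the bipartite host stores its
  bipartition but is otherwise ordinary.
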