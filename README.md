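# editchains

Exact spectral analysis and simulation of **graph edit Markov chains** —
stochastically evolving subgraphs of a fixed host graph.

Many dynamic networks can be modelled as a walk on the edge subsets of a
host graph `H = (V, E)`: at each step a random *edit* is applied, forcing
one or several edges present or absent regardless of the current state.
Because such edits generate a left regular band semigroup
(`x² = x`, `xyx = xy`), the walk's transition matrix has **closed-form
eigenvalues** indexed by a union-closed lattice of edit supports,

    λ_X = Σ { w_x : supp(x) ⊆ X },

with multiplicities obtained by Möbius inversion of chamber counts, and
explicit total-variation mixing guarantees.  For the *simple* process
(single-edge edits with probabilities `p_e`) the package additionally
provides the closed-form eigenvectors `φ_T`, the orthonormal family `ψ_T`
of the symmetrized operator `Q = Π^{1/2} P Π^{−1/2}`, and spectral
hitting/commute times.  Built-in compound families cover the **Moran
forest** process (a population-genealogy model) and a **dynamic random
intersection graph** process.  Every closed form is cross-checked against
brute-force linear algebra at desk scale.

Intended users: researchers in stochastic network dynamics, applied
probability, and algebraic combinatorics who want exact, reproducible
desk-scale computations for these chains.

## Worked example

The path on three vertices with edges `a = {1,2}`, `b = {2,3}` and
`p_a = p_b = 0.25`:

```python
import numpy as np
from editchains import (EditFamily, fixture_host, transition_matrix,
                        stationary_simple, psi_family, commute_time_spectral)

host = fixture_host("p3")
p = np.array([0.25, 0.25])
family = EditFamily.simple_process(host, p)

P = transition_matrix(family).P          # states indexed by bitmask
print(P[3])                              # row from the full subgraph {a,b}
# [0.    0.375 0.375 0.25 ]  -> to {}, {a}, {b}, {a,b}

print(stationary_simple(host, p))        # product law over {}, {a}, {b}, {a,b}
# [0.5625 0.1875 0.1875 0.0625]

print(np.sort(np.linalg.eigvals(P).real).round(12))
# [0.  0.5 0.5 1. ]                      # = {|T|/2 : T subset of {a,b}}

sys = psi_family(host, p)
print(commute_time_spectral("10", "01", sys))   # {a} <-> {b}
# 21.33333333333334                      # = 4 / (p(1-p))
print(commute_time_spectral("11", "00", sys))   # {a,b} <-> {}
# 28.444444444444443                     # = 1 / (p^2 (1-p)^2)
```

The eigenvalues `{0, 1/2, 1/2, 1}` are `|T|/m` over the four subsets
`T ⊆ {a, b}` — independent of `p` — and the commute times are the
closed-form round-trip expectations between subgraph states.

The same computations are available from the shell:

```sh
editchains spectrum --fixture p3 --model simple
editchains bound --kind simple --m 5 --c 1          # -> 22 steps to TV <= 1/e
editchains simulate --fixture k4 --model moran --steps 100 --seed 7
editchains commute --fixture p3 --p 0.25 --from 10 --to 01
editchains validate --suite all                     # cross-oracle harness
```

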