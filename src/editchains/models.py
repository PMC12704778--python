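"""Model zoo: edge-probability builders on complete hosts, the Moran
forest edit process, and the dynamic random intersection graph process.

The simple edit process on K_n with a suitable probability vector has as
its stationary law any edge-independent random graph model; builders are
provided for Erdos-Renyi, Chung-Lu (expected degrees), and two-community
stochastic block models.

The Moran edit process picks a uniform edge {u, v} and a uniform endpoint,
deletes every edge at that endpoint, and re-attaches it by {u, v}; on K_n
its stationary law is the Moran forest, a genealogy model from population
biology.  The dynamic random intersection process resamples the whole
bipartite neighborhood of a uniformly chosen left vertex according to a
size law mu; its spectral gap is 1/n regardless of mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .host import EdgeSubset, HostGraph, build_host, fixture_host
from .edits import CompoundEdit, ADD, DELETE
from .chain import EditFamily, mixing_bound, recurrent_classes, transition_matrix
from .lattice import ChainSpectrum, family_spectrum, support_semilattice

__all__ = [
    "edge_probability_model",
    "MoranSpec",
    "moran_family",
    "moran_spectrum_and_bounds",
    "moran_recurrent_states",
    "IntersectionSpec",
    "IntersectionSampler",
    "intersection_family",
]

EXACT_INTERSECTION_LIMIT = 100_000


# ---------------------------------------------------------------------------
# Edge-probability builders (stationary laws of simple processes on K_n)
# ---------------------------------------------------------------------------


def _complete_host(labels: Sequence[str]) -> HostGraph:
    labels = [str(x) for x in labels]
    return build_host(
        [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    )


def edge_probability_model(model: str, **params) -> tuple[HostGraph, np.ndarray]:
    """Edge probabilities on a complete host for a named random graph model.

    - ``er``: n, p — every edge has probability p.
    - ``chung_lu``: degrees (expected degree sequence k_v, which must
      satisfy max_v k_v <= (sum_v k_v)^{1/2}); p_uv = k_u k_v / sum_w k_w.
    - ``sbm``: parts=(A, B) disjoint nonempty label lists, p, q — p within
      a part, q across.

    Returns (host, p) with p aligned to the host's canonical edge order.
    """
    model = model.lower()
    if model == "er":
        n, p = int(params["n"]), float(params["p"])
        if not (0.0 < p < 1.0):
            raise ValueError("er requires 0 < p < 1")
        host = _complete_host([str(i) for i in range(1, n + 1)])
        return host, np.full(host.m, p)
    if model == "chung_lu":
        k = np.asarray(params["degrees"], dtype=float)
        if np.any(k <= 0):
            raise ValueError("chung_lu requires positive expected degrees")
        total = k.sum()
        if k.max() > math.sqrt(total):
            raise ValueError(
                "chung_lu degree condition violated: "
                "max_v k_v <= (sum_v k_v)^(1/2) must hold"
            )
        labels = [str(i) for i in range(1, len(k) + 1)]
        host = _complete_host(labels)
        kmap = {lab: kv for lab, kv in zip(labels, k)}
        p = np.empty(host.m)
        for idx in range(host.m):
            u, v = host.edge_label(idx)
            p[idx] = kmap[u] * kmap[v] / total
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("chung_lu probabilities must lie strictly in (0,1)")
        return host, p
    if model == "sbm":
        A = [str(x) for x in params["parts"][0]]
        B = [str(x) for x in params["parts"][1]]
        p, q = float(params["p"]), float(params["q"])
        if not A or not B or set(A) & set(B):
            raise ValueError("sbm requires nonempty disjoint parts")
        if not (0.0 < p < 1.0 and 0.0 < q < 1.0):
            raise ValueError("sbm requires 0 < p, q < 1")
        host = _complete_host(A + B)
        inA, inB = set(A), set(B)
        probs = np.empty(host.m)
        for idx in range(host.m):
            u, v = host.edge_label(idx)
            same = ({u, v} <= inA) or ({u, v} <= inB)
            probs[idx] = p if same else q
        return host, probs
    raise ValueError(f"unknown edge-probability model: {model!r}")


# ---------------------------------------------------------------------------
# Moran forest process
# ---------------------------------------------------------------------------


@dataclass
class MoranSpec:
    """The Moran edit family on a host, with its closed-form spectral data.

    One edit y_(u,v) per oriented edge: delete every edge incident to u,
    then add {u, v}; weight 1/(2m) each.  supp y_(u,v) = N(u), so the
    eigenvalue lattice is generated by the vertex edge-neighborhoods, with

        lambda_X = sum over v with N(v) within X of d_v / (2m),

    and the second-largest eigenvalue is at most 1 - delta(H)/m.
    """

    host: HostGraph
    family: EditFamily
    oriented_edges: tuple[tuple[str, str], ...]

    @property
    def second_eigenvalue_bound(self) -> float:
        return 1.0 - self.host.min_degree / self.host.m

    def lattice(self):
        return support_semilattice(
            [self.host.neighborhood(v) for v in self.host.vertices], m=self.host.m
        )

    def lambda_closed_form(self, X) -> float:
        Xb = self.host.as_subset(X).bits
        total = 0.0
        for v in self.host.vertices:
            Nv = self.host.neighborhood(v).bits
            if Nv & ~Xb == 0:
                total += self.host.degree(v) / (2.0 * self.host.m)
        return total

    def spectrum(self, cap: Optional[int] = None) -> ChainSpectrum:
        return family_spectrum(self.family, cap=cap)

    def mixing_time(self, c: float) -> int:
        """ceil(m (m ln 2 + c) / delta(H)), the general compound bound with
        lambda* replaced by its 1 - delta/m estimate."""
        m, delta = self.host.m, self.host.min_degree
        return math.ceil(m * (m * math.log(2.0) + c) / delta)

    @staticmethod
    def forest_count_bound(n: int) -> float:
        """F_n <= (n-1)^n, an upper bound on spanning forests of K_n."""
        return float((n - 1) ** n)

    @staticmethod
    def kn_mixing_time(n: int, c: float) -> int:
        """Sharpened K_n bound ceil((n^2 ln n + c n) / 2) via the forest count."""
        return math.ceil((n * n * math.log(n) + c * n) / 2.0)


def moran_family(host: HostGraph) -> tuple[EditFamily, MoranSpec]:
    """Build the 2m Moran edits (one per oriented edge), weight 1/(2m) each."""
    if host.min_degree == 0:
        raise ValueError("Moran process undefined on hosts with isolated vertices")
    edits = []
    oriented = []
    for k in range(host.m):
        u_lab, v_lab = host.edge_label(k)
        for (a, b) in ((u_lab, v_lab), (v_lab, u_lab)):
            actions = {e: DELETE for e in host.neighborhood(a).edge_indices()}
            actions[k] = ADD
            edits.append(CompoundEdit(host, actions))
            oriented.append((a, b))
    weights = np.full(len(edits), 1.0 / (2 * host.m))
    family = EditFamily(edits, weights)
    return family, MoranSpec(host, family, tuple(oriented))


def moran_spectrum_and_bounds(
    spec: MoranSpec, c: float, cap: Optional[int] = None
) -> tuple[ChainSpectrum, int]:
    """Closed-form spectrum plus the guaranteed mixing threshold for TV <= e^{-c}."""
    spectrum = spec.spectrum(cap=cap)
    return spectrum, spec.mixing_time(c)


def moran_recurrent_states(host: HostGraph) -> list[EdgeSubset]:
    """Recurrent states of the exact Moran state digraph (sorted bitmasks)."""
    family, _ = moran_family(host)
    T = transition_matrix(family)
    classes = recurrent_classes(T)
    states = sorted(s for cls in classes for s in cls)
    return [EdgeSubset(s, host.m) for s in states]


# ---------------------------------------------------------------------------
# Dynamic random intersection graph process
# ---------------------------------------------------------------------------


def _check_mu(mu: Sequence[float], N: int) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (N + 1,):
        raise ValueError("mu must be a distribution on {0, ..., N}")
    if np.any(mu < 0) or abs(mu.sum() - 1.0) > 1e-12:
        raise ValueError("mu must be a probability distribution")
    return mu


@dataclass
class IntersectionSpec:
    """The neighborhood-resampling process on the complete bipartite host.

    Left vertices Omega (size n) index the moving neighborhoods; right
    vertices Omega' (size N) are the ground symbols.  The edit y_{v,A}
    pins v's neighborhood to A, with weight (1/n) mu(|A|) / C(N, |A|).
    Eigenvalues are lambda_B = |B|/n per B within Omega; the gap is 1/n
    independent of mu, and with full-support mu every one of the 2^{nN}
    subsets is a chamber.
    """

    n: int
    N: int
    mu: np.ndarray
    host: HostGraph

    @property
    def left(self) -> list[str]:
        return sorted(self.host.bipartition[0], key=lambda s: int(s[1:]))

    @property
    def spectral_gap(self) -> float:
        return 1.0 / self.n

    def lambda_B(self, B: Sequence[str]) -> float:
        return len(set(B)) / self.n

    @property
    def full_support(self) -> bool:
        return bool(np.all(self.mu > 0))

    @property
    def chamber_count(self) -> Optional[int]:
        return (1 << (self.n * self.N)) if self.full_support else None

    def mixing_time(self, c: float) -> int:
        """ceil(n (n N ln 2 + c)) from the compound bound at lambda* = 1 - 1/n."""
        return mixing_bound(
            "compound", m=self.n * self.N, c=c, lambda_star=1.0 - 1.0 / self.n
        )


@dataclass
class IntersectionSampler:
    """Lazy edit sampler, distributionally identical to the exact family."""

    spec: IntersectionSpec

    @property
    def host(self) -> HostGraph:
        return self.spec.host

    def sample_edit(self, rng: np.random.Generator) -> CompoundEdit:
        spec = self.spec
        host = spec.host
        v = spec.left[rng.integers(spec.n)]
        size = rng.choice(spec.N + 1, p=spec.mu)
        nbhd = host.neighborhood(v).edge_indices()
        chosen = set(rng.choice(spec.N, size=size, replace=False).tolist())
        actions = {
            e: (ADD if i in chosen else DELETE) for i, e in enumerate(nbhd)
        }
        return CompoundEdit(host, actions)


def intersection_family(
    n: int,
    N: int,
    mu: Sequence[float],
    mode: str = "exact",
):
    """The dynamic random intersection edit family on K_{n,N}.

    ``exact`` mode enumerates all n * 2^N edits y_{v,A} with their weights
    (guarded; use ``lazy`` beyond n * 2^N = 10^5).  ``lazy`` mode returns a
    sampler drawing v uniformly, |A| from mu, and A uniformly at that size.

    Returns (EditFamily, IntersectionSpec) or (IntersectionSampler,
    IntersectionSpec).
    """
    if n < 1 or N < 1:
        raise ValueError("n and N must be positive")
    mu = _check_mu(mu, N)
    host = fixture_host(f"knn:{n},{N}")
    spec = IntersectionSpec(n, N, mu, host)
    if mode == "lazy":
        return IntersectionSampler(spec), spec
    if mode != "exact":
        raise ValueError(f"unknown mode: {mode!r}")
    if n * (1 << N) > EXACT_INTERSECTION_LIMIT:
        raise ValueError(
            "exact intersection family too large "
            f"(n * 2^N > {EXACT_INTERSECTION_LIMIT}); use mode='lazy'"
        )
    edits = []
    weights = []
    for v in spec.left:
        nbhd = host.neighborhood(v).edge_indices()  # index i <-> right vertex i
        for Abits in range(1 << N):
            size = Abits.bit_count()
            actions = {
                e: (ADD if (Abits >> i) & 1 else DELETE)
                for i, e in enumerate(nbhd)
            }
            edits.append(CompoundEdit(host, actions))
            weights.append(mu[size] / (n * math.comb(N, size)))
    return EditFamily(edits, np.asarray(weights)), spec
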