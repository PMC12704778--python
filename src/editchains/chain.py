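"""Edit-family Markov chains: transition matrices, stationary laws,
simulation, total variation, and mixing-time bounds.

An :class:`EditFamily` is a finite set of compound edits with a probability
weight vector; one step of the chain samples an edit by its weight and
applies it to the current edge subset.  The simple edit process with edge
probabilities ``p`` is the family {e+ with weight p_e/m, e- with weight
(1-p_e)/m}; its stationary law is the edge-independent product measure

    pi(E) = prod_{e in E} p_e * prod_{e not in E} (1 - p_e),

and the chain is reversible with respect to it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .host import EdgeSubset, HostGraph
from .edits import CompoundEdit, all_simple_edits
from .lattice import ChainSpectrum

__all__ = [
    "EditFamily",
    "TransitionData",
    "Trajectory",
    "transition_matrix",
    "stationary_simple",
    "stationary_numeric",
    "recurrent_classes",
    "simulate",
    "simulate_sampler",
    "tv_distance",
    "tv_from_stationary",
    "tv_decay_bound",
    "mixing_bound",
]

DENSE_M_LIMIT = 14
WEIGHT_TOL = 1e-12


class EditFamily:
    """Compound edits with a probability weight vector over one host.

    Duplicate action maps are merged (weights summed) with a warning, so
    the weight of each distinct edit is well defined.
    """

    def __init__(self, edits: Sequence[CompoundEdit], weights: Sequence[float]):
        edits = list(edits)
        weights = np.asarray(weights, dtype=float)
        if len(edits) == 0:
            raise ValueError("family must contain at least one edit")
        if weights.shape != (len(edits),):
            raise ValueError("weights length must match edit count")
        host = edits[0].host
        for e in edits:
            if e.host != host:
                raise ValueError("edits belong to different hosts")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(weights.sum() - 1.0) > WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 (got {weights.sum()!r})")
        merged: dict[CompoundEdit, float] = {}
        for e, w in zip(edits, weights):
            if e in merged:
                merged[e] += w
            else:
                merged[e] = w
        if len(merged) < len(edits):
            warnings.warn(
                "duplicate edits in family; weights were summed", stacklevel=2
            )
        self.host: HostGraph = host
        self.edits: tuple[CompoundEdit, ...] = tuple(merged)
        self.weights: np.ndarray = np.array([merged[e] for e in self.edits])
        # mask arrays for fast simulation
        self._touch = np.array([e.touch_mask for e in self.edits], dtype=np.int64)
        self._add = np.array([e.add_mask for e in self.edits], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.edits)

    @classmethod
    def simple_process(cls, host: HostGraph, p: Sequence[float]) -> "EditFamily":
        """The 2m-edit family realizing the simple edit process.

        Weight p_e/m on e+ and (1-p_e)/m on e-; its transition matrix
        coincides with the pick-an-edge-uniformly description.
        """
        p = np.asarray(p, dtype=float)
        if p.shape != (host.m,):
            raise ValueError("p must have one entry per edge")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("edge probabilities must lie strictly in (0,1)")
        edits = all_simple_edits(host)
        weights = np.empty(2 * host.m)
        weights[0::2] = p / host.m
        weights[1::2] = (1.0 - p) / host.m
        return cls(edits, weights)

    @property
    def supports(self) -> list[EdgeSubset]:
        return [e.support for e in self.edits]


@dataclass
class TransitionData:
    """Dense transition matrix over all 2^m edge subsets.

    Row/column index equals the subset bitmask, so state ``i`` is the edge
    subset with bits ``i``.
    """

    host: HostGraph
    P: np.ndarray

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    def state_subset(self, i: int) -> EdgeSubset:
        return EdgeSubset(i, self.host.m)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            labels = [EdgeSubset(i, self.host.m).bitstring() for i in range(self.n_states)]
            fh.write("state\t" + "\t".join(labels) + "\n")
            for i, row in enumerate(self.P):
                fh.write(labels[i] + "\t" + "\t".join(repr(v) for v in row) + "\n")


def transition_matrix(family: EditFamily) -> TransitionData:
    """Exact transition matrix: P(E, F) = total weight of edits mapping E to F."""
    m = family.host.m
    if m > DENSE_M_LIMIT:
        raise ValueError(
            f"dense transition matrix limited to m <= {DENSE_M_LIMIT}; "
            "use simulate() for larger hosts"
        )
    n = 1 << m
    P = np.zeros((n, n))
    states = np.arange(n, dtype=np.int64)
    for touch, add, w in zip(family._touch, family._add, family.weights):
        targets = (states & ~touch) | add
        P[states, targets] += w
    return TransitionData(family.host, P)


def stationary_simple(host: HostGraph, p: Sequence[float]) -> np.ndarray:
    """Product-form stationary law of the simple edit process over 2^m states."""
    p = np.asarray(p, dtype=float)
    if p.shape != (host.m,):
        raise ValueError("p must have one entry per edge")
    n = 1 << host.m
    pi = np.ones(n)
    states = np.arange(n)
    for e in range(host.m):
        present = (states >> e) & 1 == 1
        pi *= np.where(present, p[e], 1.0 - p[e])
    return pi


def recurrent_classes(T: TransitionData) -> list[list[int]]:
    """Recurrent classes of the exact state digraph (strongly connected
    components with no outgoing edges)."""
    A = sp.csr_matrix(T.P > 0)
    n_comp, labels = connected_components(A, directed=True, connection="strong")
    leaves = np.ones(n_comp, dtype=bool)
    rows, cols = A.nonzero()
    for i, j in zip(rows, cols):
        if labels[i] != labels[j]:
            leaves[labels[i]] = False
    out = []
    for comp in range(n_comp):
        if leaves[comp]:
            out.append(sorted(np.flatnonzero(labels == comp).tolist()))
    return out


def stationary_numeric(T: TransitionData) -> np.ndarray:
    """Left Perron vector (oracle): solved on the unique recurrent class.

    Raises when the chain has several recurrent classes (no unique
    stationary distribution); transient states get probability zero.
    """
    classes = recurrent_classes(T)
    if len(classes) != 1:
        desc = "; ".join(
            "{" + ",".join(EdgeSubset(s, T.host.m).bitstring() for s in c[:8])
            + (",..." if len(c) > 8 else "") + "}"
            for c in classes
        )
        raise ValueError(
            f"chain has {len(classes)} recurrent classes: {desc}"
        )
    states = classes[0]
    k = len(states)
    sub = T.P[np.ix_(states, states)]
    A = sub.T - np.eye(k)
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    sol = np.linalg.solve(A, b)
    pi = np.zeros(T.n_states)
    pi[states] = sol
    return pi


@dataclass
class Trajectory:
    """A simulated path of edge subsets (stored as bitmasks)."""

    host: HostGraph
    states: np.ndarray  # int64 bitmasks, length steps + 1
    seed: int
    initial: int
    steps: int
    family_size: int = 0

    def subsets(self) -> list[EdgeSubset]:
        return [EdgeSubset(int(b), self.host.m) for b in self.states]

    def to_jsonl(self, fh) -> None:
        m = self.host.m
        for t, b in enumerate(self.states):
            s = EdgeSubset(int(b), m).bitstring()
            fh.write(f'{{"t": {t}, "state": "{s}"}}\n')

    def empirical_distribution(self, burn_in: int = 0) -> np.ndarray:
        """State-visit frequencies over all 2^m states after burn-in."""
        counts = np.bincount(
            self.states[burn_in:], minlength=1 << self.host.m
        ).astype(float)
        return counts / counts.sum()


def simulate(
    family: EditFamily,
    E0: Union[EdgeSubset, int],
    steps: int,
    seed: int,
) -> Trajectory:
    """Run the chain: at each step sample an edit by weight and apply it.

    Sampling is inverse-CDF over the family's fixed edit order, so
    trajectories are bit-reproducible given (seed, family, E0, steps).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    host = family.host
    bits = host.as_subset(E0).bits
    rng = np.random.default_rng(seed)
    cum = np.cumsum(family.weights)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(steps), side="right")
    states = np.empty(steps + 1, dtype=np.int64)
    states[0] = bits
    touch, add = family._touch, family._add
    for t in range(steps):
        k = idx[t]
        bits = (bits & ~int(touch[k])) | int(add[k])
        states[t + 1] = bits
    return Trajectory(host, states, seed, int(states[0]), steps, len(family))


def simulate_sampler(sampler, E0, steps: int, seed: int) -> Trajectory:
    """Like :func:`simulate` but drawing edits from a lazy sampler with a
    ``sample_edit(rng) -> CompoundEdit`` method (for families too large to
    enumerate)."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    host = sampler.host
    bits = host.as_subset(E0).bits
    rng = np.random.default_rng(seed)
    states = np.empty(steps + 1, dtype=np.int64)
    states[0] = bits
    for t in range(steps):
        edit = sampler.sample_edit(rng)
        bits = edit.apply_bits(bits)
        states[t + 1] = bits
    return Trajectory(host, states, seed, int(states[0]), steps)


def tv_distance(mu: np.ndarray, nu: np.ndarray) -> float:
    """Total variation distance: half the L1 distance."""
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if mu.shape != nu.shape:
        raise ValueError("distributions have different state spaces")
    return 0.5 * float(np.abs(mu - nu).sum())


def tv_from_stationary(
    P: np.ndarray,
    pi: np.ndarray,
    t: int,
    states: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Exact TV distance ||P^t(x, .) - pi|| for each initial state."""
    Pt = np.linalg.matrix_power(P, t)
    rows = Pt if states is None else Pt[list(states), :]
    return 0.5 * np.abs(rows - pi[None, :]).sum(axis=1)


def tv_decay_bound(t: int, spectrum: ChainSpectrum) -> float:
    """Semigroup-walk TV bound: sum over non-maximal lattice elements of
    m_X * lambda_X^t; decreasing in t, equal to (#chambers - 1) at t=0."""
    if t < 0:
        raise ValueError("t must be >= 0")
    top = spectrum.top
    return float(
        sum(mult * lam**t for X, lam, mult in spectrum.entries if X != top)
    )


def mixing_bound(
    kind: str,
    *,
    m: Optional[int] = None,
    c: float = 1.0,
    lambda_star: Optional[float] = None,
    M: Optional[float] = None,
) -> int:
    """Integer time guaranteeing TV <= e^{-c} (natural logarithms).

    - ``simple``: ceil(m (c + 2 ln m)) for the simple edit process;
    - ``compound``: ceil((m ln 2 + c) / (1 - lambda*));
    - ``compound_sharpened``: ceil((ln M + c) / (1 - lambda*)) for a chamber
      count bounded by M.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    if kind == "simple":
        if m is None or m < 1:
            raise ValueError("simple bound requires m >= 1")
        return math.ceil(m * (c + 2.0 * math.log(m)))
    if kind in ("compound", "compound_sharpened"):
        if lambda_star is None or not (0.0 <= lambda_star < 1.0):
            raise ValueError("compound bounds require 0 <= lambda* < 1")
        if kind == "compound":
            if m is None or m < 1:
                raise ValueError("compound bound requires m >= 1")
            return math.ceil((m * math.log(2.0) + c) / (1.0 - lambda_star))
        if M is None or M < 1:
            raise ValueError("sharpened bound requires chamber bound M >= 1")
        return math.ceil((math.log(M) + c) / (1.0 - lambda_star))
    raise ValueError(f"unknown bound kind: {kind!r}")
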