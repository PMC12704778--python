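"""Closed-form eigenvectors and spectral hitting/commute times for the
simple edit process.

For each subset T of edges, the row vector

    phi_T(E) = (-1)^{#edges outside both E and T}
               * prod_{e in T∩E} p_e * prod_{e in T\\E} (1 - p_e)

is a left eigenvector of the transition matrix with eigenvalue |T|/m, and
phi_E (T = all edges) equals the stationary distribution.  The normalized
family

    psi_T = sqrt(prod_{e not in T} p_e (1 - p_e)) * phi_T * Pi^{-1/2}

is orthonormal for the symmetrized operator Q = Pi^{1/2} P Pi^{-1/2}.

Hitting and commute times follow from the spectral representation for
reversible chains (with the t >= 0 hitting convention, so H(x, x) = 0),
and the commute-time sum may be restricted to subsets meeting the
symmetric difference of the two states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .host import EdgeSubset, HostGraph
from .chain import EditFamily, transition_matrix, stationary_simple

__all__ = [
    "EigenSystem",
    "HittingResult",
    "phi_eigenvector",
    "psi_family",
    "hitting_times_spectral",
    "hitting_times_solve",
    "commute_time_spectral",
    "commute_time_full_sum",
    "estimate_commute_mc",
]


def phi_eigenvector(T, host: HostGraph, p: Sequence[float]) -> np.ndarray:
    """phi_T over all 2^m states (index = subset bitmask)."""
    Tbits = host.as_subset(T).bits
    p = np.asarray(p, dtype=float)
    n = 1 << host.m
    states = np.arange(n)
    out = np.ones(n)
    for e in range(host.m):
        present = (states >> e) & 1 == 1
        if (Tbits >> e) & 1:
            out *= np.where(present, p[e], 1.0 - p[e])
        else:
            out *= np.where(present, 1.0, -1.0)
    return out


@dataclass
class EigenSystem:
    """Complete left eigensystem of the simple edit process.

    Row index of ``phi``/``psi``/``ratio`` is the subset bitmask T; column
    index is the state bitmask E.  ``ratio`` holds psi_T(E) / sqrt(pi(E)),
    the vectors entering the hitting/commute representations.
    """

    host: HostGraph
    p: np.ndarray
    pi: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    ratio: np.ndarray
    Q: np.ndarray

    @property
    def m(self) -> int:
        return self.host.m

    def eigenvalue(self, T: int) -> float:
        return T.bit_count() / self.host.m


def psi_family(host: HostGraph, p: Sequence[float]) -> EigenSystem:
    """Build phi_T, psi_T, Pi, and Q = Pi^{1/2} P Pi^{-1/2} for all T."""
    p = np.asarray(p, dtype=float)
    if p.shape != (host.m,):
        raise ValueError("p must have one entry per edge")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("edge probabilities must lie strictly in (0,1)")
    m = host.m
    n = 1 << m
    pi = stationary_simple(host, p)
    sqrt_pi = np.sqrt(pi)
    phi = np.empty((n, n))
    psi = np.empty((n, n))
    q = p * (1.0 - p)
    for T in range(n):
        phi[T] = phi_eigenvector(T, host, p)
        scale = 1.0
        for e in range(m):
            if not (T >> e) & 1:
                scale *= q[e]
        psi[T] = math.sqrt(scale) * phi[T] / sqrt_pi
    ratio = psi / sqrt_pi[None, :]
    P = transition_matrix(EditFamily.simple_process(host, p)).P
    Q = sqrt_pi[:, None] * P / sqrt_pi[None, :]
    return EigenSystem(host, p, pi, phi, psi, ratio, Q)


@dataclass
class HittingResult:
    """Expected hitting times H(x, y) and commute times C = H + H^T.

    Hitting convention tau_y = first t >= 0 at y, so the diagonal is zero.
    """

    H: np.ndarray
    C: np.ndarray

    def to_tsv(self, path, host: HostGraph, which: str = "C") -> None:
        M = self.C if which == "C" else self.H
        labels = [EdgeSubset(i, host.m).bitstring() for i in range(M.shape[0])]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("state\t" + "\t".join(labels) + "\n")
            for i, row in enumerate(M):
                fh.write(labels[i] + "\t" + "\t".join(repr(v) for v in row) + "\n")


def _sum_order(n: int, m: int) -> list[int]:
    """Non-top subsets in descending cardinality (compensates roundoff by
    accumulating large-|T| terms first)."""
    full = n - 1
    return sorted(
        (T for T in range(n) if T != full),
        key=lambda T: -T.bit_count(),
    )


def hitting_times_spectral(sys: EigenSystem) -> HittingResult:
    """H(x, y) = sum over T != full of (phi-ratio terms) / (1 - |T|/m)."""
    m = sys.m
    n = 1 << m
    H = np.zeros((n, n))
    for T in _sum_order(n, m):
        lam = T.bit_count() / m
        coef = 1.0 / (1.0 - lam)
        r = sys.ratio[T]
        # H[x, y] += coef * r[y] * (r[y] - r[x])
        H += coef * (r[None, :] * (r[None, :] - r[:, None]))
    C = H + H.T
    return HittingResult(H, C)


def hitting_times_solve(P: np.ndarray) -> np.ndarray:
    """Fundamental-matrix oracle: solve (I - P_{-y}) h = 1 per target y."""
    n = P.shape[0]
    H = np.zeros((n, n))
    for y in range(n):
        idx = [x for x in range(n) if x != y]
        A = np.eye(n - 1) - P[np.ix_(idx, idx)]
        h = np.linalg.solve(A, np.ones(n - 1))
        H[idx, y] = h
    return H


def commute_time_spectral(
    E: Union[EdgeSubset, int, str],
    F: Union[EdgeSubset, int, str],
    sys: EigenSystem,
) -> float:
    """Commute time via the restricted spectral sum.

    A term's ratio difference vanishes exactly when T contains the whole
    symmetric difference of E and F (every factor of the product form of
    phi_T/pi then coincides between the two states), so the sum runs over
    subsets T that miss at least one edge of E△F.  T = full edge set is
    thereby excluded automatically, and C(E, E) is an empty sum.
    """
    host = sys.host
    Eb = host.as_subset(E).bits
    Fb = host.as_subset(F).bits
    diff = Eb ^ Fb
    m = sys.m
    n = 1 << m
    terms = []
    for T in _sum_order(n, m):
        if diff & ~T == 0:
            continue
        k = T.bit_count()
        d = sys.ratio[T, Eb] - sys.ratio[T, Fb]
        terms.append((m / (m - k)) * d * d)
    return math.fsum(terms)


def commute_time_full_sum(
    E: Union[EdgeSubset, int, str],
    F: Union[EdgeSubset, int, str],
    sys: EigenSystem,
) -> float:
    """Commute time via the unrestricted spectral sum over all T != full."""
    host = sys.host
    Eb = host.as_subset(E).bits
    Fb = host.as_subset(F).bits
    m = sys.m
    n = 1 << m
    terms = []
    for T in _sum_order(n, m):
        k = T.bit_count()
        d = sys.ratio[T, Eb] - sys.ratio[T, Fb]
        terms.append((m / (m - k)) * d * d)
    return math.fsum(terms)


def estimate_commute_mc(
    family: EditFamily,
    x: Union[EdgeSubset, int, str],
    y: Union[EdgeSubset, int, str],
    n_trips: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo commute time: mean and standard error over round trips
    x -> y -> x of the simulated chain."""
    host = family.host
    xb = host.as_subset(x).bits
    yb = host.as_subset(y).bits
    rng = np.random.default_rng(seed)
    cum = np.cumsum(family.weights)
    cum[-1] = 1.0
    touch = family._touch
    add = family._add
    chunk = 4096
    buf = np.searchsorted(cum, rng.random(chunk), side="right")
    pos = 0
    times = np.empty(n_trips)
    state = xb
    for trip in range(n_trips):
        steps = 0
        for target in (yb, xb):
            while state != target:
                if pos == chunk:
                    buf = np.searchsorted(cum, rng.random(chunk), side="right")
                    pos = 0
                k = buf[pos]
                pos += 1
                state = (state & ~int(touch[k])) | int(add[k])
                steps += 1
        times[trip] = steps
    mean = float(times.mean())
    se = float(times.std(ddof=1) / math.sqrt(n_trips))
    return mean, se
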