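"""Support semilattices, Möbius functions, and closed-form spectra.

The transition matrix of any edit-family chain is diagonalizable, with
eigenvalues indexed by the union-closed family (join semilattice) generated
by the edit supports together with the empty set:

    lambda_X = sum of weights w_x over family edits x with supp(x) within X.

Multiplicities come from chamber counts by Möbius inversion over the
lattice:  c_X counts the chambers fixed by a representative edit of support
X, and m_X = sum over Y >= X of mu(X, Y) * c_Y.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import reduce
from typing import Optional, Sequence

import numpy as np

from .edits import EditSemigroup, chambers, compose, generate_semigroup, identity_edit
from .host import EdgeSubset

__all__ = [
    "SupportLattice",
    "ChainSpectrum",
    "support_semilattice",
    "mobius_function",
    "eigenvalue",
    "chamber_counts",
    "multiplicities",
    "family_spectrum",
    "simple_spectrum",
]

MAX_LATTICE = 100_000


@dataclass(frozen=True)
class SupportLattice:
    """A union-closed family of edge subsets containing the empty set.

    Elements are bitmasks sorted by (cardinality, value); inclusion is the
    order.  The Möbius table is computed lazily by :func:`mobius_function`.
    """

    m: int
    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        elems = set(self.elements)
        if 0 not in elems:
            raise ValueError("lattice must contain the empty set")
        for X in self.elements:
            for Y in self.elements:
                if (X | Y) not in elems:
                    raise ValueError("lattice not closed under union")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __contains__(self, bits: int) -> bool:
        return bits in set(self.elements)

    @property
    def top(self) -> int:
        """The maximal element (union of everything)."""
        return reduce(lambda a, b: a | b, self.elements, 0)

    def subsets(self) -> list[EdgeSubset]:
        return [EdgeSubset(X, self.m) for X in self.elements]


def support_semilattice(supports: Sequence, m: Optional[int] = None) -> SupportLattice:
    """Smallest union-closed family containing the empty set and the inputs."""
    bits_in = []
    for s in supports:
        if isinstance(s, EdgeSubset):
            if m is None:
                m = s.m
            elif m != s.m:
                raise ValueError("supports over different hosts")
            bits_in.append(s.bits)
        else:
            bits_in.append(int(s))
    if m is None:
        raise ValueError("m must be given when supports are plain integers")
    elems = {0}
    frontier = set(bits_in)
    while frontier:
        elems |= frontier
        if len(elems) > MAX_LATTICE:
            raise ValueError(f"lattice too large (limit {MAX_LATTICE})")
        new = set()
        for X in frontier:
            for Y in elems:
                U = X | Y
                if U not in elems and U not in new:
                    new.add(U)
        frontier = new
    ordered = tuple(sorted(elems, key=lambda b: (b.bit_count(), b)))
    return SupportLattice(m, ordered)


def mobius_function(L: SupportLattice) -> dict[tuple[int, int], int]:
    """Möbius values mu(X, Y) for all ordered pairs X <= Y in the lattice.

    mu(X, X) = 1 and sum over X <= Z <= Y of mu(X, Z) vanishes for X < Y.
    """
    order = L.elements  # sorted by cardinality, so Z < Y precedes Y
    mu: dict[tuple[int, int], int] = {}
    for X in order:
        mu[(X, X)] = 1
        for Y in order:
            if Y == X or (X & ~Y) != 0:
                continue
            total = 0
            for Z in order:
                if Z != Y and (X & ~Z) == 0 and (Z & ~Y) == 0:
                    total += mu[(X, Z)]
            mu[(X, Y)] = -total
    return mu


def eigenvalue(X, family) -> float:
    """lambda_X: total weight of family edits supported within X."""
    if isinstance(X, EdgeSubset):
        X = X.bits
    total = 0.0
    for edit, w in zip(family.edits, family.weights):
        if edit.touch_mask & ~X == 0:
            total += float(w)
    return total


def _representative(L: SupportLattice, S: EditSemigroup, X: int):
    """Product of the greedily chosen first generators whose supports union to X."""
    if X == 0:
        return identity_edit(S.host)
    rep = None
    covered = 0
    for g in S.generators:
        if g.touch_mask & ~X:
            continue
        if g.touch_mask & ~covered:
            rep = g if rep is None else compose(rep, g)
            covered |= g.touch_mask
            if covered == X:
                return rep
    raise ValueError(
        f"no product of generators has support {X:b}; not a lattice of this semigroup"
    )


def chamber_counts(L: SupportLattice, S: EditSemigroup) -> dict[int, int]:
    """c_X: number of chambers fixed by a representative edit of support X.

    A chamber c satisfies x*c == c exactly when c agrees with x's actions on
    supp(x), so c_X counts chambers matching the representative's add/delete
    pattern on X.
    """
    cs, _ = chambers(S)
    counts = {}
    for X in L.elements:
        rep = _representative(L, S, X)
        counts[X] = sum(1 for c in cs if (c.add_mask & X) == (rep.add_mask & X))
    return counts


def multiplicities(
    L: SupportLattice, S: EditSemigroup
) -> dict[int, int]:
    """m_X by Möbius inversion of the chamber counts; validated.

    Raises when any m_X is negative or the multiplicities fail to sum to
    the number of chambers (an inconsistent lattice/chamber structure).
    """
    mu = mobius_function(L)
    c = chamber_counts(L, S)
    mult = {}
    for X in L.elements:
        mX = sum(mu[(X, Y)] * c[Y] for Y in L.elements if (X & ~Y) == 0)
        if mX < 0:
            raise ValueError(
                f"inconsistent lattice/chambers: negative multiplicity at {X:b}"
            )
        mult[X] = mX
    total = sum(mult.values())
    cs, _ = chambers(S)
    if total != len(cs):
        raise ValueError(
            "inconsistent lattice/chambers: multiplicities sum to "
            f"{total}, expected {len(cs)} chambers"
        )
    return mult


@dataclass(frozen=True)
class ChainSpectrum:
    """Eigenvalues lambda_X with multiplicities, indexed by lattice elements."""

    m: int
    entries: tuple[tuple[int, float, int], ...]  # (subset bits, lambda, mult)

    def __post_init__(self) -> None:
        for _, lam, mult in self.entries:
            if mult < 0:
                raise ValueError("negative multiplicity")
            if not (-1e-12 <= lam <= 1 + 1e-12):
                raise ValueError(f"eigenvalue {lam} outside [0, 1]")

    @property
    def top(self) -> int:
        return reduce(lambda a, b: a | b, (X for X, _, _ in self.entries), 0)

    @property
    def lambda_star(self) -> float:
        """Second-largest distinct eigenvalue (largest below the top's 1)."""
        top = self.top
        vals = [lam for X, lam, mult in self.entries if X != top and mult > 0]
        return max(vals, default=0.0)

    @property
    def total_multiplicity(self) -> int:
        return sum(mult for _, _, mult in self.entries)

    def eigenvalues_multiset(self) -> np.ndarray:
        """All eigenvalues repeated by multiplicity, descending."""
        out = []
        for _, lam, mult in self.entries:
            out.extend([lam] * mult)
        return np.sort(np.asarray(out))[::-1]

    def grouped(self, tol: float = 1e-9) -> list[tuple[float, int]]:
        """Distinct eigenvalues with aggregated multiplicities."""
        items = sorted(self.entries, key=lambda t: t[1])
        groups: list[tuple[float, int]] = []
        for _, lam, mult in items:
            if mult == 0:
                continue
            if groups and abs(groups[-1][0] - lam) <= tol:
                groups[-1] = (groups[-1][0], groups[-1][1] + mult)
            else:
                groups.append((lam, mult))
        return groups

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subset\tlambda_fraction\tlambda\tmultiplicity\n")
            for X, lam, mult in self.entries:
                frac = Fraction(lam).limit_denominator(10**6)
                fh.write(
                    f"{EdgeSubset(X, self.m).bitstring()}\t{frac}\t{lam!r}\t{mult}\n"
                )


def family_spectrum(family, cap: Optional[int] = None) -> ChainSpectrum:
    """Closed-form spectrum of an edit-family chain.

    Generates the subsemigroup of the family's edits, builds the support
    semilattice, and combines the eigenvalue formula with Möbius-inverted
    chamber counts.
    """
    host = family.host
    S = generate_semigroup(list(family.edits), cap=cap)
    L = support_semilattice([e.support for e in family.edits], m=host.m)
    mult = multiplicities(L, S)
    entries = tuple(
        (X, eigenvalue(X, family), mult[X]) for X in L.elements
    )
    return ChainSpectrum(host.m, entries)


def simple_spectrum(m: int) -> ChainSpectrum:
    """Spectrum of the simple edit process: lambda_T = |T|/m, multiplicity
    one per subset T (so value k/m has aggregate multiplicity C(m, k)).

    Independent of the edge probabilities.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > 16:
        raise ValueError("explicit subset-indexed spectrum limited to m <= 16")
    entries = tuple(
        (T, T.bit_count() / m, 1) for T in range(1 << m)
    )
    return ChainSpectrum(m, entries)
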