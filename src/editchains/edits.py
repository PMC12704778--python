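"""Graph edits as idempotent maps and the edit semigroup.

A *simple edit* forces a single edge present (``e+``) or absent (``e-``),
regardless of the current state.  A *compound edit* is a product of simple
edits; its canonical form is a partial map from edge indices to an action
sign (+1 add, -1 delete), because acting on every edge subset determines
the map and vice versa.  Two edit words are equal exactly when their maps
are equal.

The product ``x * y`` applies ``y`` first and ``x`` second (the rightmost
factor acts first), so per edge the later factor's action wins.  Under this
product the edit semigroup is a left regular band: ``x*x == x`` and
``x*y*x == x*y``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .host import EdgeSubset, HostGraph

__all__ = [
    "CompoundEdit",
    "EditSemigroup",
    "LrbReport",
    "identity_edit",
    "simple_edit",
    "all_simple_edits",
    "apply_edit",
    "compose",
    "support",
    "generate_semigroup",
    "chambers",
    "check_lrb",
]

ADD = 1
DELETE = -1


class CompoundEdit:
    """A canonical reduced edit: a partial map edge index -> {+1, -1}.

    The empty map is the identity edit.  Instances are immutable and
    hashable; equality is extensional (same host, same action map).
    """

    __slots__ = ("host", "items", "add_mask", "touch_mask", "_hash")

    def __init__(self, host: HostGraph, actions: Mapping[int, int]) -> None:
        items = []
        add_mask = 0
        touch_mask = 0
        for e, sign in sorted(actions.items()):
            if not (0 <= e < host.m):
                raise ValueError(f"edge index {e} out of range")
            if sign not in (ADD, DELETE):
                raise ValueError(f"invalid action sign {sign!r} (use +1 or -1)")
            items.append((e, sign))
            touch_mask |= 1 << e
            if sign == ADD:
                add_mask |= 1 << e
        self.host = host
        self.items = tuple(items)
        self.add_mask = add_mask
        self.touch_mask = touch_mask
        self._hash = hash((host, self.items))

    @property
    def actions(self) -> dict[int, int]:
        return dict(self.items)

    @property
    def support(self) -> EdgeSubset:
        """The edges on which this edit acts nontrivially."""
        return EdgeSubset(self.touch_mask, self.host.m)

    @property
    def is_identity(self) -> bool:
        return not self.items

    @property
    def is_chamber(self) -> bool:
        """Full support: the edit forces every edge of the host."""
        return self.touch_mask == (1 << self.host.m) - 1

    # -- action on subsets -------------------------------------------------
    def apply_bits(self, bits: int) -> int:
        return (bits & ~self.touch_mask) | self.add_mask

    def apply(self, E: Union[EdgeSubset, int]) -> Union[EdgeSubset, int]:
        if isinstance(E, EdgeSubset):
            if E.m != self.host.m:
                raise ValueError("edit and subset belong to different hosts")
            return EdgeSubset(self.apply_bits(E.bits), self.host.m)
        return self.apply_bits(E)

    def __call__(self, E):
        return self.apply(E)

    # -- product -----------------------------------------------------------
    def __mul__(self, other: "CompoundEdit") -> "CompoundEdit":
        return compose(self, other)

    # -- identity ------------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CompoundEdit)
            and self.host == other.host
            and self.items == other.items
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        if not self.items:
            return "CompoundEdit(identity)"
        body = " ".join(
            "{}{}{}".format(*self.host.edge_label(e), "+" if s == ADD else "-")
            for e, s in self.items
        )
        return f"CompoundEdit({body})"

    def to_json_obj(self) -> dict:
        """JSON form: {"u,v": "+"|"-"} per acted edge."""
        return {
            ",".join(self.host.edge_label(e)): ("+" if s == ADD else "-")
            for e, s in self.items
        }


def identity_edit(host: HostGraph) -> CompoundEdit:
    return CompoundEdit(host, {})


def simple_edit(host: HostGraph, edge, sign) -> CompoundEdit:
    """``e+`` or ``e-`` for a single edge (index or label pair)."""
    if isinstance(edge, int):
        k = edge
    else:
        k = host.edge_index(*edge)
    if sign in ("+", ADD):
        return CompoundEdit(host, {k: ADD})
    if sign in ("-", DELETE):
        return CompoundEdit(host, {k: DELETE})
    raise ValueError(f"invalid sign {sign!r}")


def all_simple_edits(host: HostGraph) -> list[CompoundEdit]:
    """All 2m simple edits in the order e0+, e0-, e1+, e1-, ..."""
    out = []
    for k in range(host.m):
        out.append(CompoundEdit(host, {k: ADD}))
        out.append(CompoundEdit(host, {k: DELETE}))
    return out


def apply_edit(x: CompoundEdit, E):
    """Apply an edit to an edge subset (functional form of ``x.apply``)."""
    return x.apply(E)


def compose(later: CompoundEdit, earlier: CompoundEdit) -> CompoundEdit:
    """Canonical product ``later * earlier`` (``earlier`` acts first).

    Per edge, the later edit's action wins; edges only the earlier edit
    touches keep its action.  Satisfies
    ``compose(y, x).apply(E) == y.apply(x.apply(E))`` for every subset E.
    """
    if later.host != earlier.host:
        raise ValueError("edits belong to different hosts")
    merged = dict(earlier.items)
    merged.update(later.items)
    return CompoundEdit(later.host, merged)


def support(x: CompoundEdit) -> EdgeSubset:
    return x.support


# -- order relations ----------------------------------------------------------


def leq(x: CompoundEdit, y: CompoundEdit) -> bool:
    """Partial order: x <= y iff x*y == y (iff simple(x) is a subset of simple(y))."""
    return compose(x, y) == y


def preceq(x: CompoundEdit, y: CompoundEdit) -> bool:
    """Support preorder: x precedes y iff y*x == y (iff supp x within supp y)."""
    return compose(y, x) == y


@dataclass(frozen=True)
class EditSemigroup:
    """A set of compound edits closed under the product, with its generators."""

    host: HostGraph
    elements: tuple[CompoundEdit, ...]
    generators: tuple[CompoundEdit, ...]

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __contains__(self, x: CompoundEdit) -> bool:
        return x in set(self.elements)

    def to_tsv(self, path) -> None:
        """Export element table: id, action map, support bitstring, is_chamber."""
        import json

        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tactions\tsupport\tis_chamber\n")
            for i, x in enumerate(self.elements):
                fh.write(
                    f"{i}\t{json.dumps(x.to_json_obj(), sort_keys=True)}"
                    f"\t{x.support.bitstring()}\t{int(x.is_chamber)}\n"
                )


def generate_semigroup(
    generators: Sequence[CompoundEdit], cap: Optional[int] = None
) -> EditSemigroup:
    """Closure of the generators under the product, including the identity.

    Worklist BFS over left- and right-products with the generators.  The cap
    (default ``3**m``, tight for the full simple-edit semigroup) bounds the
    element count; exceeding it raises.
    """
    generators = list(generators)
    if not generators:
        raise ValueError("at least one generator required")
    host = generators[0].host
    for g in generators:
        if g.host != host:
            raise ValueError("generators belong to different hosts")
    if cap is None:
        cap = 3 ** host.m
    elements: dict[CompoundEdit, None] = {identity_edit(host): None}
    queue: deque[CompoundEdit] = deque()
    for g in generators:
        if g not in elements:
            elements[g] = None
            queue.append(g)
    while queue:
        x = queue.popleft()
        for g in generators:
            for z in (compose(x, g), compose(g, x)):
                if z not in elements:
                    if len(elements) >= cap:
                        raise ValueError(f"semigroup too large (cap={cap})")
                    elements[z] = None
                    queue.append(z)
    ordered = tuple(sorted(elements, key=lambda e: (len(e.items), e.items)))
    return EditSemigroup(host, ordered, tuple(generators))


def chambers(
    S: EditSemigroup,
) -> tuple[list[CompoundEdit], dict[CompoundEdit, EdgeSubset]]:
    """Full-support elements and their bijection onto edge subsets.

    A chamber ``c`` corresponds to the subset of edges it forces present,
    ``{e : c(e) = add}``; the map is injective on chambers.
    """
    cs = [x for x in S.elements if x.is_chamber]
    mapping = {c: EdgeSubset(c.add_mask, S.host.m) for c in cs}
    return cs, mapping


@dataclass(frozen=True)
class LrbReport:
    """Result of a left-regular-band check; a failure carries a witness."""

    passed: bool
    witness: Optional[dict]
    pairs_checked: int
    exhaustive: bool

    def __bool__(self) -> bool:
        return self.passed


def _as_map(x, m: int) -> Callable[[int], int]:
    if isinstance(x, CompoundEdit):
        return x.apply_bits
    if callable(x):
        return x
    raise TypeError(f"cannot interpret {x!r} as a map on edge subsets")


def check_lrb(
    elements: Iterable,
    m: Optional[int] = None,
    seed: int = 0,
    pair_cap: int = 10_000,
) -> LrbReport:
    """Verify idempotence (x(x(E)) = x(E)) and memorylessness
    (x(y(x(E))) = x(y(E))) extensionally over all 2^m subsets.

    Accepts compound edits or arbitrary callables ``bits -> bits`` (to
    falsify non-examples such as an edge toggle).  All pairs are checked
    when there are at most ``pair_cap``; otherwise ``pair_cap`` uniform
    pairs are sampled with the given seed.  A failed check is reported with
    its first counterexample, not raised.
    """
    elems = list(elements)
    if m is None:
        for x in elems:
            if isinstance(x, CompoundEdit):
                m = x.host.m
                break
        else:
            raise ValueError("m must be given when no CompoundEdit is present")
    maps = [_as_map(x, m) for x in elems]
    n_states = 1 << m

    for x, fx in zip(elems, maps):
        for E in range(n_states):
            once = fx(E)
            if fx(once) != once:
                return LrbReport(
                    False,
                    {"kind": "idempotence", "x": repr(x), "E": E},
                    0,
                    True,
                )

    k = len(elems)
    exhaustive = k * k <= pair_cap
    if exhaustive:
        pairs = [(i, j) for i in range(k) for j in range(k)]
    else:
        rng = np.random.default_rng(seed)
        pairs = [tuple(ij) for ij in rng.integers(0, k, size=(pair_cap, 2))]
    for i, j in pairs:
        fx, fy = maps[i], maps[j]
        for E in range(n_states):
            xy = fx(fy(E))
            xyx = fx(fy(fx(E)))
            if xy != xyx:
                return LrbReport(
                    False,
                    {
                        "kind": "memorylessness",
                        "x": repr(elems[i]),
                        "y": repr(elems[j]),
                        "E": E,
                        "xyE": xy,
                        "xyxE": xyx,
                    },
                    len(pairs),
                    exhaustive,
                )
    return LrbReport(True, None, len(pairs), exhaustive)
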