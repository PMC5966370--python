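"""Subgraph-isomorphism verification (VF2-style backtracking).

Substructure semantics: the query must embed as a (not necessarily induced)
subgraph of the target under one global injective atom mapping — a
multi-fragment query therefore needs non-overlapping placements for all of
its fragments.  Atom and bond compatibility is a declared convention:

* elements must be equal, aromatic flags must be equal;
* formal charges must be equal (unless ``charge_sensitive`` is off);
* an isotope constrains the target only when the query specifies one;
* a bracket-written hydrogen count on a query atom demands at least that
  many hydrogens on the target atom; a bare query atom imposes none;
* an aromatic query bond matches only an aromatic target bond, a
  non-aromatic query bond only a non-aromatic target bond of equal order.
  No Kekulé-to-aromatic bridging is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .molgraph import Atom, Bond, Molecule

__all__ = [
    "MatchOptions",
    "MatchUndecided",
    "Embedding",
    "atoms_compatible",
    "bonds_compatible",
    "is_substructure",
    "count_embeddings",
    "find_embeddings",
]


class MatchUndecided(RuntimeError):
    """The state limit was exceeded before the search finished; neither a
    positive nor a negative answer is available."""


@dataclass(frozen=True)
class MatchOptions:
    charge_sensitive: bool = True
    isotope_sensitive: bool = True
    limit: Optional[int] = None  # cap on explored search states; None = exact

    def __post_init__(self):
        if self.limit is not None and self.limit <= 0:
            raise ValueError("limit must be positive")


@dataclass(frozen=True)
class Embedding:
    """Injective query-atom -> target-atom mapping."""

    mapping: tuple  # mapping[i] = target atom for query atom i


def atoms_compatible(q: Atom, t: Atom, opts: MatchOptions = MatchOptions()) -> bool:
    if q.element != t.element or q.aromatic != t.aromatic:
        return False
    if opts.charge_sensitive and q.charge != t.charge:
        return False
    if opts.isotope_sensitive and q.isotope is not None and q.isotope != t.isotope:
        return False
    if q.h_explicit and t.h_count < q.h_count:
        return False
    return True


def bonds_compatible(q: Bond, t: Bond) -> bool:
    if q.aromatic != t.aromatic:
        return False
    return q.aromatic or q.order == t.order


def _match_order(query: Molecule) -> list[int]:
    """Connectivity-first visit order: highest degree first, then atoms with
    the most already-ordered neighbours.  Heuristic only; never affects the
    result set."""
    n = query.n_atoms
    ordered: list[int] = []
    placed = [False] * n
    while len(ordered) < n:
        best = None
        best_key = None
        for i in range(n):
            if placed[i]:
                continue
            anchored = sum(1 for j in query.neighbors(i) if placed[j])
            key = (anchored, query.degree(i), -i)
            if best_key is None or key > best_key:
                best, best_key = i, key
        ordered.append(best)
        placed[best] = True
    return ordered


def find_embeddings(
    query: Molecule, target: Molecule, opts: MatchOptions = MatchOptions()
) -> Iterator[Embedding]:
    """Yield every embedding of ``query`` into ``target``.

    Raises :class:`MatchUndecided` if ``opts.limit`` search states are
    exhausted before the enumeration completes.
    """
    nq, nt = query.n_atoms, target.n_atoms
    if nq == 0:
        yield Embedding(mapping=())
        return
    if nq > nt:
        return

    order = _match_order(query)
    qmap = [-1] * nq
    used = [False] * nt
    states = 0

    # precompute, per position, the query neighbours already mapped
    mapped_nbrs: list[list[tuple[int, int]]] = []  # (neighbour atom, query bond)
    pos_of = {q: p for p, q in enumerate(order)}
    for p, q in enumerate(order):
        nbrs = []
        for bi in query.bonds_of(q):
            j = query.bonds[bi].other(q)
            if pos_of[j] < p:
                nbrs.append((j, bi))
        mapped_nbrs.append(nbrs)

    def candidates(p: int) -> Iterator[int]:
        q = order[p]
        nbrs = mapped_nbrs[p]
        if nbrs:
            anchor_t = qmap[nbrs[0][0]]
            pool = sorted(target.neighbors(anchor_t))
        else:
            pool = range(nt)
        for t in pool:
            if used[t]:
                continue
            if not atoms_compatible(query.atoms[q], target.atoms[t], opts):
                continue
            if target.degree(t) < query.degree(q):
                continue
            ok = True
            for j, qbi in nbrs:
                tbi = target.bond_between(t, qmap[j])
                if tbi is None or not bonds_compatible(query.bonds[qbi], target.bonds[tbi]):
                    ok = False
                    break
            if ok:
                yield t

    def recurse(p: int) -> Iterator[Embedding]:
        nonlocal states
        states += 1
        if opts.limit is not None and states > opts.limit:
            raise MatchUndecided(f"state limit {opts.limit} exceeded")
        if p == nq:
            yield Embedding(mapping=tuple(qmap))
            return
        q = order[p]
        for t in candidates(p):
            qmap[q] = t
            used[t] = True
            yield from recurse(p + 1)
            used[t] = False
            qmap[q] = -1

    yield from recurse(0)


def is_substructure(
    query: Molecule, target: Molecule, opts: MatchOptions = MatchOptions()
) -> bool:
    """True iff at least one embedding of ``query`` into ``target`` exists."""
    for _ in find_embeddings(query, target, opts):
        return True
    return False


def count_embeddings(
    query: Molecule, target: Molecule, opts: MatchOptions = MatchOptions()
) -> int:
    """Exact number of distinct embeddings (atom-mapping level; automorphic
    images are counted separately)."""
    return sum(1 for _ in find_embeddings(query, target, opts))
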