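"""Molecular graph data model, SMILES parsing/writing, and SSSR ring perception.

Molecules are attributed undirected graphs.  Hydrogens are never graph
nodes: they are folded into each heavy atom's ``h_count``.  Aromaticity is
taken from the input notation only (lowercase atoms / ``:`` bonds); no
electronic aromaticity perception is performed, so Kekulé-written benzene
(``C1=CC=CC=C1``) and aromatic-written benzene (``c1ccccc1``) are distinct
inputs throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Ring",
    "SmilesError",
    "parse_smiles",
    "write_smiles",
    "read_smiles_file",
    "sssr",
    "ring_bond_count",
]

# Standard valences used to fill implicit hydrogens on organic-subset atoms.
VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

ORGANIC_SUBSET = set(VALENCES)

# Aromatic atoms contributing a pi bond to the ring need one extra unit of
# valence; ether-like heteroatoms (o, s, se) contribute a lone pair instead.
_AROMATIC_PI = {"B": 1, "C": 1, "N": 1, "P": 1, "As": 1, "O": 0, "S": 0, "Se": 0}

# Fixed element table (bracket atoms may use any of these).
ELEMENTS = set(
    """
    He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I
    Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U
    """.split()
)

_AROMATIC_ORGANIC = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S"}
_AROMATIC_BRACKET = {"b", "c", "n", "o", "p", "s", "se", "as"}


class SmilesError(ValueError):
    """Malformed SMILES input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Atom:
    """A heavy atom.  ``h_explicit`` records whether the hydrogen count was
    bracket-specified in the input (queries use it as a matching constraint)."""

    element: str
    charge: int = 0
    isotope: Optional[int] = None
    aromatic: bool = False
    h_count: int = 0
    h_explicit: bool = False

    def type_tuple(self) -> tuple:
        """(element, charge, aromatic) class used by fingerprint atom typing."""
        return (self.element, self.charge, self.aromatic)


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: int = 1
    aromatic: bool = False

    def other(self, i: int) -> int:
        return self.b if i == self.a else self.a

    @property
    def endpoints(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def bonds_of(self, i: int) -> list[int]:
        self._ensure_adjacency()
        return self._adj[i]

    def neighbors(self, i: int) -> list[int]:
        return [self.bonds[bi].other(i) for bi in self.bonds_of(i)]

    def degree(self, i: int) -> int:
        return len(self.bonds_of(i))

    def bond_between(self, i: int, j: int) -> Optional[int]:
        for bi in self.bonds_of(i):
            if self.bonds[bi].other(i) == j:
                return bi
        return None

    def _ensure_adjacency(self) -> None:
        adj = getattr(self, "_adj", None)
        if adj is None or len(adj) != len(self.atoms):
            adj = [[] for _ in self.atoms]
            for bi, b in enumerate(self.bonds):
                adj[b.a].append(bi)
                adj[b.b].append(bi)
            self._adj = adj

    def components(self) -> list[list[int]]:
        """Connected components as sorted atom-index lists, in order of
        smallest member."""
        seen = [False] * self.n_atoms
        comps = []
        for start in range(self.n_atoms):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(v)
                for w in self.neighbors(v):
                    if not seen[w]:
                        seen[w] = True
                        stack.append(w)
            comps.append(sorted(comp))
        return comps

    def to_dict(self) -> dict:
        return {
            "atoms": [
                [a.element, a.charge, a.isotope, int(a.aromatic), a.h_count, int(a.h_explicit)]
                for a in self.atoms
            ],
            "bonds": [[b.a, b.b, b.order, int(b.aromatic)] for b in self.bonds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Molecule":
        atoms = [
            Atom(e, c, iso, bool(ar), h, bool(hx)) for e, c, iso, ar, h, hx in d["atoms"]
        ]
        bonds = [Bond(a, b, o, bool(ar)) for a, b, o, ar in d["bonds"]]
        return cls(atoms, bonds)


@dataclass(frozen=True)
class Ring:
    """An ordered cycle: consecutive atoms (cyclically) are bonded."""

    atom_cycle: tuple
    bond_cycle: tuple  # bond indices, bond_cycle[i] joins atom_cycle[i] and atom_cycle[(i+1) % n]

    def __len__(self) -> int:
        return len(self.atom_cycle)


# ---------------------------------------------------------------------------
# SMILES parsing
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<symbol>[A-Z][a-z]?|as|se|[bcnops])"
    r"(?P<chiral>@{1,2})?"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>\+\+|--|[+-]\d*)?"
    r"(?::\d+)?\]"
)

_BOND_SYMBOLS = {"-": (1, False), "=": (2, False), "#": (3, False), ":": (1, True)}


def implicit_h_count(element: str, aromatic: bool, bond_order_sum: int) -> int:
    """Implicit hydrogens from standard valences.

    For aromatic atoms each ring bond counts one unit and elements that
    contribute a pi bond to the aromatic system get one extra unit of used
    valence; heteroatoms donating a lone pair (o, s) get none.
    """
    valences = VALENCES.get(element)
    if valences is None:
        return 0
    used = bond_order_sum
    if aromatic:
        used += _AROMATIC_PI.get(element, 1)
    for v in valences:
        if v >= used:
            return v - used
    return 0


def _parse_bracket(text: str, i: int) -> tuple[Atom, int]:
    m = _BRACKET_RE.match(text, i)
    if not m:
        raise SmilesError("malformed bracket atom", i)
    sym = m.group("symbol")
    if sym == "*":
        raise SmilesError("wildcard atoms are not supported", i)
    aromatic = sym in _AROMATIC_BRACKET
    element = sym.capitalize() if aromatic else sym
    if element == "H":
        raise SmilesError("explicit hydrogen atoms are not supported", i)
    if element not in ELEMENTS:
        raise SmilesError(f"unknown element {sym!r}", i)
    isotope = int(m.group("isotope")) if m.group("isotope") else None
    h = m.group("hcount")
    if h is None:
        h_count = 0
    elif h == "H":
        h_count = 1
    else:
        h_count = int(h[1:])
    c = m.group("charge")
    if c is None:
        charge = 0
    elif c == "++":
        charge = 2
    elif c == "--":
        charge = -2
    elif c in ("+", "-"):
        charge = 1 if c == "+" else -1
    else:
        charge = int(c[1:]) * (1 if c[0] == "+" else -1)
    atom = Atom(element, charge, isotope, aromatic, h_count, h_explicit=True)
    return atom, m.end()


def _cycle_bond_indices(n_atoms: int, bonds: Sequence[Bond]) -> set[int]:
    """Indices of bonds lying on a cycle (non-bridges), via DFS low-links."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n_atoms)]
    for bi, b in enumerate(bonds):
        adj[b.a].append((b.b, bi))
        adj[b.b].append((b.a, bi))
    visited = [False] * n_atoms
    tin = [0] * n_atoms
    low = [0] * n_atoms
    bridges: set[int] = set()
    timer = 0
    for root in range(n_atoms):
        if visited[root]:
            continue
        stack = [(root, -1, iter(adj[root]))]
        visited[root] = True
        tin[root] = low[root] = timer
        timer += 1
        while stack:
            v, pbond, it = stack[-1]
            advanced = False
            for w, bi in it:
                if bi == pbond:
                    continue
                if visited[w]:
                    low[v] = min(low[v], tin[w])
                else:
                    visited[w] = True
                    tin[w] = low[w] = timer
                    timer += 1
                    stack.append((w, bi, iter(adj[w])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                if stack:
                    parent = stack[-1][0]
                    low[parent] = min(low[parent], low[v])
                    if low[v] > tin[parent]:
                        bridges.add(pbond)
    return set(range(len(bonds))) - bridges


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string (organic subset + bracket atoms, ring closures,
    branches, dot-separated fragments; stereo markers accepted and ignored).

    Raises :class:`SmilesError` naming the offending position on malformed
    input or an unmatched ring-closure digit.
    """
    atoms: list[Atom] = []
    raw_bonds: list[tuple[int, int, Optional[str], int]] = []  # a, b, symbol, pos
    prev: Optional[int] = None
    pending: Optional[str] = None
    pending_pos = 0
    stack: list[Optional[int]] = []
    ring_open: dict[int, tuple[int, Optional[str], int]] = {}
    i = 0
    n = len(text)

    def add_atom(atom: Atom) -> None:
        nonlocal prev, pending
        atoms.append(atom)
        idx = len(atoms) - 1
        if prev is not None:
            raw_bonds.append((prev, idx, pending, pending_pos))
        elif pending is not None:
            raise SmilesError("bond symbol with no preceding atom", pending_pos)
        prev = idx
        pending = None

    def ring_closure(num: int, pos: int) -> None:
        nonlocal pending
        if prev is None:
            raise SmilesError("ring closure before any atom", pos)
        if num in ring_open:
            a, sym_a, pos_a = ring_open.pop(num)
            sym = pending if pending is not None else sym_a
            if pending is not None and sym_a is not None and pending != sym_a:
                raise SmilesError("conflicting ring-closure bond symbols", pos)
            if a == prev:
                raise SmilesError("ring closure to the same atom", pos)
            raw_bonds.append((a, prev, sym, pos))
        else:
            ring_open[num] = (prev, pending, pos)
        pending = None

    while i < n:
        c = text[i]
        if c == "(":
            if prev is None:
                raise SmilesError("branch with no preceding atom", i)
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise SmilesError("unmatched ')'", i)
            if pending is not None:
                raise SmilesError("dangling bond symbol before ')'", i)
            prev = stack.pop()
            i += 1
        elif c == ".":
            if pending is not None:
                raise SmilesError("bond symbol before '.'", i)
            prev = None
            i += 1
        elif c in "-=#:":
            if pending is not None:
                raise SmilesError("duplicate bond symbol", i)
            pending = c
            pending_pos = i
            i += 1
        elif c in "/\\":
            # stereo bond markers: treated as plain single bonds
            if pending is None:
                pending = "-"
                pending_pos = i
            i += 1
        elif c == "%":
            m = re.match(r"%(\d\d)", text[i:])
            if not m:
                raise SmilesError("malformed %nn ring closure", i)
            ring_closure(int(m.group(1)), i)
            i += 2 + 1
        elif c.isdigit():
            ring_closure(int(c), i)
            i += 1
        elif c == "[":
            atom, j = _parse_bracket(text, i)
            add_atom(atom)
            i = j
        elif c == "*":
            raise SmilesError("wildcard atoms are not supported", i)
        else:
            two = text[i : i + 2]
            if two in ("Cl", "Br"):
                add_atom(Atom(two))
                i += 2
            elif c in "BCNOPSFI":
                elem = "I" if c == "I" else c
                add_atom(Atom(elem))
                i += 1
            elif c in _AROMATIC_ORGANIC:
                add_atom(Atom(_AROMATIC_ORGANIC[c], aromatic=True))
                i += 1
            else:
                raise SmilesError(f"unexpected character {c!r}", i)

    if pending is not None:
        raise SmilesError("dangling bond symbol at end of input", pending_pos)
    if stack:
        raise SmilesError("unclosed branch '('", n)
    if ring_open:
        num, (_, _, pos) = next(iter(ring_open.items()))
        raise SmilesError(f"unmatched ring-closure digit {num}", pos)

    # Resolve bond orders.  An implicit bond between two aromatic atoms is
    # aromatic when it lies on a cycle (benzene ring bonds) or when it joins
    # acyclic aromatic atoms (the fragment query "cc"); a bridge between two
    # ring systems (the biphenyl inter-ring bond) stays single.
    seen_pairs: set[frozenset] = set()
    provisional = []
    for a, b, sym, pos in raw_bonds:
        pair = frozenset((a, b))
        if pair in seen_pairs:
            raise SmilesError("duplicate bond between one atom pair", pos)
        seen_pairs.add(pair)
        provisional.append(Bond(a, b, 1, False))
    cyclic = _cycle_bond_indices(len(atoms), provisional)
    cyclic_atoms = {x for bi in cyclic for x in (provisional[bi].a, provisional[bi].b)}
    bonds: list[Bond] = []
    for bi, (a, b, sym, pos) in enumerate(raw_bonds):
        if sym is not None:
            order, arom = _BOND_SYMBOLS[sym]
        elif atoms[a].aromatic and atoms[b].aromatic and (
            bi in cyclic or not (a in cyclic_atoms and b in cyclic_atoms)
        ):
            order, arom = 1, True
        else:
            order, arom = 1, False
        bonds.append(Bond(a, b, order, arom))

    # Fill implicit hydrogens for organic-subset atoms written without brackets.
    mol = Molecule(atoms, bonds)
    filled = []
    for idx, atom in enumerate(atoms):
        if atom.h_explicit:
            filled.append(atom)
            continue
        order_sum = sum(
            1 if bonds[bi].aromatic else bonds[bi].order for bi in mol.bonds_of(idx)
        )
        h = implicit_h_count(atom.element, atom.aromatic, order_sum)
        filled.append(replace(atom, h_count=h))
    return Molecule(filled, bonds)


# ---------------------------------------------------------------------------
# SMILES writing
# ---------------------------------------------------------------------------


def _atom_token(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    symbol = a.element.lower() if a.aromatic else a.element
    plain_ok = (
        a.element in ORGANIC_SUBSET
        and a.charge == 0
        and a.isotope is None
        and (not a.aromatic or a.element in _AROMATIC_PI)
    )
    if plain_ok:
        order_sum = sum(
            1 if mol.bonds[bi].aromatic else mol.bonds[bi].order for bi in mol.bonds_of(idx)
        )
        if implicit_h_count(a.element, a.aromatic, order_sum) == a.h_count:
            return symbol
    parts = ["["]
    if a.isotope is not None:
        parts.append(str(a.isotope))
    parts.append(symbol)
    if a.h_count == 1:
        parts.append("H")
    elif a.h_count > 1:
        parts.append(f"H{a.h_count}")
    if a.charge == 1:
        parts.append("+")
    elif a.charge == -1:
        parts.append("-")
    elif a.charge > 1:
        parts.append(f"+{a.charge}")
    elif a.charge < -1:
        parts.append(f"-{-a.charge}")
    parts.append("]")
    return "".join(parts)


def _bond_token(mol: Molecule, bi: int, cyclic: set[int], cyclic_atoms: set[int]) -> str:
    b = mol.bonds[bi]
    aa, ab = mol.atoms[b.a], mol.atoms[b.b]
    if b.aromatic:
        # implicit only where reparsing will re-derive the aromatic flag
        if aa.aromatic and ab.aromatic and (
            bi in cyclic or not (b.a in cyclic_atoms and b.b in cyclic_atoms)
        ):
            return ""
        return ":"
    if b.order == 2:
        return "="
    if b.order == 3:
        return "#"
    if aa.aromatic and ab.aromatic:
        return "-"
    return ""


def write_smiles(mol: Molecule) -> str:
    """Serialize to SMILES.  Round-trips: ``parse_smiles(write_smiles(m))``
    is atom-for-atom identical to ``m`` up to the ``h_explicit`` flags."""
    if mol.n_atoms == 0:
        return ""
    cyclic = _cycle_bond_indices(mol.n_atoms, mol.bonds)
    cyclic_atoms = {x for bi in cyclic for x in (mol.bonds[bi].a, mol.bonds[bi].b)}
    ring_num = [0]
    fragments = []
    for comp in mol.components():
        fragments.append(_write_fragment(mol, comp[0], cyclic, cyclic_atoms, ring_num))
    return ".".join(fragments)


def _next_ring_label(counter: list[int]) -> str:
    counter[0] += 1
    n = counter[0]
    if n > 99:
        raise ValueError("too many ring closures for SMILES output")
    return str(n) if n <= 9 else f"%{n:02d}"


def _write_fragment(mol: Molecule, start: int, cyclic: set[int], cyclic_atoms: set[int], ring_num: list[int]) -> str:
    # DFS spanning tree; back edges become ring closures.
    visited = {start}
    tree_children: dict[int, list[tuple[int, int]]] = {start: []}
    back_edges: list[tuple[int, int, int]] = []  # (from, to, bond)
    seen_bonds: set[int] = set()

    def visit(v: int) -> None:
        for bi in sorted(mol.bonds_of(v)):
            if bi in seen_bonds:
                continue
            w = mol.bonds[bi].other(v)
            seen_bonds.add(bi)
            if w in visited:
                back_edges.append((v, w, bi))
            else:
                visited.add(w)
                tree_children.setdefault(v, []).append((w, bi))
                tree_children.setdefault(w, [])
                visit(w)

    visit(start)

    closures: dict[int, list[tuple[str, int]]] = {}
    for v, w, bi in back_edges:
        label = _next_ring_label(ring_num)
        closures.setdefault(v, []).append((label, bi))
        closures.setdefault(w, []).append((label, -1))

    out: list[str] = []

    def emit(v: int, in_bond: int) -> None:
        if in_bond >= 0:
            out.append(_bond_token(mol, in_bond, cyclic, cyclic_atoms))
        out.append(_atom_token(mol, v))
        for label, bi in closures.get(v, []):
            if bi >= 0:
                out.append(_bond_token(mol, bi, cyclic, cyclic_atoms))
            out.append(label)
        children = tree_children.get(v, [])
        for k, (w, bi) in enumerate(children):
            last = k == len(children) - 1
            if not last:
                out.append("(")
            emit(w, bi)
            if not last:
                out.append(")")

    emit(start, -1)
    return "".join(out)


# ---------------------------------------------------------------------------
# File reading
# ---------------------------------------------------------------------------


def read_smiles_file(path, on_error=None) -> Iterator[tuple[str, Molecule]]:
    """Yield ``(identifier, Molecule)`` records from a .smi file.

    Each nonempty line is ``SMILES`` or ``SMILES<TAB>identifier``; ``#`` at
    line start marks a comment.  Lines that fail to parse are skipped; if
    ``on_error`` is given it is called with ``(line_number, line, exception)``
    for each failure so callers can report a failure count.
    """
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"line{lineno}"
            try:
                mol = parse_smiles(smiles)
            except SmilesError as exc:
                if on_error is not None:
                    on_error(lineno, line, exc)
                continue
            yield ident, mol


# ---------------------------------------------------------------------------
# Ring perception (SSSR)
# ---------------------------------------------------------------------------


def _shortest_cycle_through(mol: Molecule, bi: int) -> Optional[Ring]:
    """Smallest cycle containing bond ``bi``: BFS from one endpoint to the
    other avoiding the bond itself.  Deterministic for fixed atom order."""
    b = mol.bonds[bi]
    src, dst = b.a, b.b
    parent: dict[int, tuple[int, int]] = {src: (-1, -1)}
    frontier = [src]
    while frontier and dst not in parent:
        nxt = []
        for v in frontier:
            for bj in sorted(mol.bonds_of(v)):
                if bj == bi:
                    continue
                w = mol.bonds[bj].other(v)
                if w not in parent:
                    parent[w] = (v, bj)
                    nxt.append(w)
        frontier = nxt
    if dst not in parent:
        return None
    atom_path = [dst]
    bond_path = []
    v = dst
    while v != src:
        p, bj = parent[v]
        bond_path.append(bj)
        atom_path.append(p)
        v = p
    atom_path.reverse()  # src ... dst
    bond_path.reverse()
    return Ring(tuple(atom_path), tuple(bond_path) + (bi,))


def sssr(mol: Molecule) -> list[Ring]:
    """Smallest Set of Smallest Rings: exactly ``bonds - atoms + components``
    rings, greedily chosen smallest-first so that each ring covers a bond not
    covered by previously selected rings; remaining slots (fused cage corner
    cases) are filled with the smallest independent candidate cycles.

    Ties between equal-length candidates are broken by the lexicographically
    smallest sorted bond-index set, making the output deterministic.
    """
    n_rings = mol.n_bonds - mol.n_atoms + len(mol.components())
    if n_rings <= 0:
        return []
    candidates = []
    for bi in range(mol.n_bonds):
        ring = _shortest_cycle_through(mol, bi)
        if ring is not None:
            candidates.append(ring)
    candidates.sort(key=lambda r: (len(r.bond_cycle), tuple(sorted(r.bond_cycle))))

    selected: list[Ring] = []
    seen_sets: set[frozenset] = set()
    basis: list[int] = []  # GF(2) row-reduced bond-incidence bitmasks

    def reduce_add(mask: int) -> bool:
        for row in basis:
            mask = min(mask, mask ^ row)
        if mask:
            basis.append(mask)
            basis.sort(reverse=True)
            return True
        return False

    for ring in candidates:
        if len(selected) == n_rings:
            break
        bond_set = frozenset(ring.bond_cycle)
        if bond_set in seen_sets:
            continue
        seen_sets.add(bond_set)
        mask = 0
        for bi in bond_set:
            mask |= 1 << bi
        # accept only cycles linearly independent of already-selected ones;
        # smallest-first order makes each accepted ring a smallest cycle
        # through some not-yet-covered bond
        if reduce_add(mask):
            selected.append(ring)
    return selected[:n_rings]


def ring_bond_count(mol: Molecule, subgraph: Iterable[int]) -> int:
    """Cyclomatic number (#bonds - #atoms + 1) of a connected bond subgraph
    given as bond indices.  Raises ``ValueError`` if disconnected."""
    bond_ids = sorted(set(subgraph))
    if not bond_ids:
        raise ValueError("empty bond subgraph")
    atoms: set[int] = set()
    for bi in bond_ids:
        b = mol.bonds[bi]
        atoms.update((b.a, b.b))
    # connectivity check over the subgraph only
    bond_set = set(bond_ids)
    start = next(iter(atoms))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for bi in mol.bonds_of(v):
            if bi not in bond_set:
                continue
            w = mol.bonds[bi].other(v)
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if seen != atoms:
        raise ValueError("bond subgraph is disconnected")
    return len(bond_ids) - len(atoms) + 1
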