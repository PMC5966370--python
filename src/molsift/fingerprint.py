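"""Substructural fingerprints.

Three feature families are computed per molecule:

* **atom-type** — one feature per distinct atom class, with its occurrence
  count.  The class is (element, charge, aromatic); atoms carrying a
  specified isotope additionally emit an isotope-qualified feature.  Keeping
  the isotope out of the base class is what makes screening sound: a query
  atom written without an isotope may match any isotope of the element, so an
  isotope-blind count is the only count that is guaranteed not to shrink when
  the query is extended.
* **ring** — one feature per distinct SSSR ring shape, counted with
  multiplicity.  Ring features are indexed for every stored compound; the
  query planner deliberately does not screen on them (see
  :mod:`molsift.search`), because a cycle of a query graph need not be an
  SSSR ring of a larger molecule containing the query.
* **subgraph** — one feature per distinct shape of a connected subgraph with
  at most one ring and at most ``graph_size`` bonds (default 7), counted with
  multiplicity.

Feature multiplicity c is encoded as one bit per power of two <= c, so a bit
at tier p means "the shape occurs at least p times" — a monotone statement
preserved under structural extension.  Each bit folds (family, shape hash,
tier) into a 36-bit identifier with a splitmix64-style avalanche; collisions
can only ever create false positives in screening, never false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .molgraph import Atom, Molecule, ring_bond_count, sssr

__all__ = [
    "FeatureId",
    "FeatureSet",
    "FingerprintParams",
    "KIND_ATOM_TYPE",
    "KIND_RING",
    "KIND_SUBGRAPH",
    "atom_type_features",
    "enumerate_subgraphs",
    "tree_hash",
    "ring_features",
    "subgraph_features",
    "encode_multiplicity",
    "fingerprint",
]

KIND_ATOM_TYPE = "atom_type"
KIND_RING = "ring"
KIND_SUBGRAPH = "subgraph"

_KIND_CODE = {KIND_ATOM_TYPE: 1, KIND_RING: 2, KIND_SUBGRAPH: 3}

_MASK64 = (1 << 64) - 1
MASK36 = (1 << 36) - 1


def splitmix64(x: int) -> int:
    """Fixed public 64-bit avalanche mixer (splitmix64 finalizer)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _mix(*values: int) -> int:
    h = 0x243F6A8885A308D3  # arbitrary fixed seed
    for v in values:
        h = splitmix64(h ^ (v & _MASK64))
    return h


def _str_int(s: str) -> int:
    return int.from_bytes(s.encode("ascii"), "big")


def _atom_label(atom: Atom) -> int:
    # isotope deliberately excluded; see module docstring
    return _mix(0xA70, _str_int(atom.element), atom.charge + 512, int(atom.aromatic))


def _bond_label(order: int, aromatic: bool) -> int:
    return _mix(0xB0D, 4 if aromatic else order)


@dataclass(frozen=True, order=True)
class FeatureId:
    """A 36-bit fingerprint-bit identifier."""

    value: int
    kind: str = field(compare=False)
    tier: int = field(compare=False)

    def __post_init__(self):
        assert 0 <= self.value <= MASK36


def feature_id(kind: str, shape_hash: int, tier: int) -> FeatureId:
    value = _mix(_KIND_CODE[kind], shape_hash, tier) & MASK36
    return FeatureId(value=value, kind=kind, tier=tier)


@dataclass(frozen=True)
class FingerprintParams:
    """``graph_size`` caps the bond count of enumerated subgraph features."""

    graph_size: int = 7

    def __post_init__(self):
        if self.graph_size < 1:
            raise ValueError("graph_size must be >= 1")


@dataclass
class FeatureSet:
    """Fingerprint of one molecule.

    ``counts`` maps each tier-1 base feature to its occurrence count;
    ``bits`` holds all multiplicity-tier bits; ``coverage`` maps every bit to
    the query atoms it covers (the union over instances); ``atoms`` is the
    full atom-index set of the source molecule.  ``instances`` records, for
    ring/subgraph base features, the bond sets of the concrete occurrences —
    the raw material for subsumption reduction on the query side.
    """

    counts: dict[FeatureId, int] = field(default_factory=dict)
    bits: set[FeatureId] = field(default_factory=set)
    coverage: dict[FeatureId, frozenset] = field(default_factory=dict)
    atoms: set[int] = field(default_factory=set)
    instances: dict[FeatureId, tuple] = field(default_factory=dict)
    base_of: dict[FeatureId, FeatureId] = field(default_factory=dict)
    qualified: set[FeatureId] = field(default_factory=set)  # isotope-qualified atom-type bits

    def merge(self, other: "FeatureSet") -> "FeatureSet":
        self.counts.update(other.counts)
        self.bits |= other.bits
        self.coverage.update(other.coverage)
        self.atoms |= other.atoms
        self.instances.update(other.instances)
        self.base_of.update(other.base_of)
        self.qualified |= other.qualified
        return self


def encode_multiplicity(count: int) -> set[int]:
    """Powers of two up to ``count``: the multiplicity tiers a count implies."""
    if count < 1:
        raise ValueError("count must be >= 1")
    tiers = set()
    p = 1
    while p <= count:
        tiers.add(p)
        p *= 2
    return tiers


def _emit_family(
    kind: str,
    shapes: dict[int, tuple[int, set[int], list]],
    fs: FeatureSet,
    qualified: Iterable[int] = (),
) -> None:
    """shapes: shape_hash -> (count, covered atoms, instance bond sets)."""
    qualified = set(qualified)
    for shape_hash, (count, cover, inst) in shapes.items():
        base = feature_id(kind, shape_hash, 1)
        fs.counts[base] = count
        cover_f = frozenset(cover)
        for tier in encode_multiplicity(count):
            fid = feature_id(kind, shape_hash, tier)
            fs.bits.add(fid)
            fs.coverage[fid] = cover_f
            fs.base_of[fid] = base
            if inst:
                fs.instances[fid] = tuple(inst)
            if shape_hash in qualified:
                fs.qualified.add(fid)


def atom_type_features(mol: Molecule) -> FeatureSet:
    """One base feature per distinct atom class, plus isotope-qualified
    features for atoms with a specified isotope."""
    fs = FeatureSet(atoms=set(range(mol.n_atoms)))
    shapes: dict[int, tuple[int, set, list]] = {}

    def bump(shape_hash: int, idx: int) -> None:
        count, cover, inst = shapes.setdefault(shape_hash, (0, set(), []))
        cover.add(idx)
        shapes[shape_hash] = (count + 1, cover, inst)

    qualified = set()
    for idx, atom in enumerate(mol.atoms):
        bump(_mix(0x717E, _atom_label(atom)), idx)
        if atom.isotope is not None:
            h = _mix(0x717E, _atom_label(atom), atom.isotope)
            bump(h, idx)
            qualified.add(h)
    _emit_family(KIND_ATOM_TYPE, shapes, fs, qualified)
    return fs


def enumerate_subgraphs(mol: Molecule, max_bonds: int) -> list[frozenset]:
    """All connected bond-subgraphs with 1..max_bonds bonds and cyclomatic
    number <= 1, each exactly once, as frozensets of bond indices.

    Connected bond sets are connected vertex sets of the bond-adjacency
    (line) graph; they are enumerated uniquely with the ESU scheme, pruning
    any branch whose cyclomatic number already exceeds one (adding bonds can
    never remove a cycle).
    """
    if max_bonds < 1:
        raise ValueError("max_bonds must be >= 1")
    nb = mol.n_bonds
    line_adj: list[set[int]] = [set() for _ in range(nb)]
    for i in range(nb):
        bi = mol.bonds[i]
        for v in (bi.a, bi.b):
            for bj in mol.bonds_of(v):
                if bj != i:
                    line_adj[i].add(bj)

    results: list[frozenset] = []

    def extend(sub: list[int], ext: set[int], nbh: set[int], v0: int, atoms: set[int]) -> None:
        if len(sub) - len(atoms) + 1 > 1:  # >1 ring; no extension can fix it
            return
        results.append(frozenset(sub))
        if len(sub) == max_bonds:
            return
        ext = set(ext)
        while ext:
            w = min(ext)
            ext.remove(w)
            # exclusive neighbourhood: bonds touching w but not the current
            # subgraph — the ESU rule that makes each bond set appear once
            add = {u for u in line_adj[w] if u > v0 and u not in nbh}
            b = mol.bonds[w]
            sub.append(w)
            extend(sub, ext | add, nbh | line_adj[w], v0, atoms | {b.a, b.b})
            sub.pop()

    for v0 in range(nb):
        b = mol.bonds[v0]
        ext0 = {u for u in line_adj[v0] if u > v0}
        extend([v0], ext0, line_adj[v0] | {v0}, v0, {b.a, b.b})
    return results


def tree_hash(mol: Molecule, subgraph) -> int:
    """Isomorphism-invariant 36-bit hash of a connected <=1-ring bond subgraph.

    Leaves are removed in rounds, folding each leaf's accumulated hash with
    its incident bond label into its neighbour through an order-independent
    (sorted) combiner.  Acyclic subgraphs terminate at a 1- or 2-atom centre,
    the 2-atom centre being combined symmetrically; 1-ring subgraphs
    terminate at the ring, whose cyclic (atom hash, bond label) sequence is
    hashed in its lexically minimal rotation over both directions.
    """
    bond_ids = sorted(set(subgraph))
    cyclo = ring_bond_count(mol, bond_ids)  # validates connectivity
    if cyclo > 1:
        raise ValueError("subgraph has more than one ring")

    bond_set = set(bond_ids)
    atoms: set[int] = set()
    for bi in bond_ids:
        atoms.update((mol.bonds[bi].a, mol.bonds[bi].b))
    adj: dict[int, list[int]] = {a: [] for a in atoms}
    for bi in bond_ids:
        b = mol.bonds[bi]
        adj[b.a].append(bi)
        adj[b.b].append(bi)

    acc = {a: _atom_label(mol.atoms[a]) for a in atoms}
    pending: dict[int, list[int]] = {a: [] for a in atoms}  # child messages
    alive = set(atoms)
    deg = {a: len(adj[a]) for a in atoms}

    def fold(atom: int) -> int:
        h = acc[atom]
        for m in sorted(pending[atom]):
            h = splitmix64(h ^ m)
        return h

    while True:
        leaves = [a for a in alive if deg[a] == 1]
        if not leaves:
            break
        if cyclo == 0 and len(alive) <= 2:
            break
        for leaf in leaves:
            msg_base = fold(leaf)
            bi = next(b for b in adj[leaf] if b in bond_set)
            bond = mol.bonds[bi]
            parent = bond.other(leaf)
            msg = _mix(0x1EAF, msg_base, _bond_label(bond.order, bond.aromatic))
            pending[parent].append(msg)
            alive.discard(leaf)
            bond_set.discard(bi)
            deg[parent] -= 1
            deg[leaf] = 0

    if cyclo == 0:
        rest = sorted(alive)
        if len(rest) == 1:
            return _mix(0xCE27, fold(rest[0])) & MASK36
        a, b = rest
        bi = next(iter(bond_set))
        bond = mol.bonds[bi]
        ha, hb = sorted((fold(a), fold(b)))
        return _mix(0x2CE7, _bond_label(bond.order, bond.aromatic), ha, hb) & MASK36

    # ring remains: build the cyclic sequence of (atom hash, bond label)
    ring_atoms = sorted(alive)
    folded = {a: fold(a) for a in ring_atoms}
    start = ring_atoms[0]
    best = None
    for first in ring_atoms:
        for direction in (0, 1):
            seq = _ring_sequence(mol, bond_set, folded, first, direction)
            if best is None or seq < best:
                best = seq
    h = 0x216
    for item in best:
        h = splitmix64(h ^ item)
    return h & MASK36


def _ring_sequence(mol, bond_set, folded, first, direction):
    nbrs = sorted(b for b in bond_set if first in (mol.bonds[b].a, mol.bonds[b].b))
    out_bond = nbrs[direction]
    seq = []
    prev_bond = None
    atom = first
    bond_id = out_bond
    while True:
        bond = mol.bonds[bond_id]
        seq.append(folded[atom])
        seq.append(_bond_label(bond.order, bond.aromatic))
        atom = bond.other(atom)
        if atom == first:
            break
        nxt = [b for b in bond_set if atom in (mol.bonds[b].a, mol.bonds[b].b) and b != bond_id]
        bond_id = nxt[0]
    return tuple(seq)


def ring_features(mol: Molecule) -> FeatureSet:
    """One base feature per distinct SSSR ring shape, counted with
    multiplicity; coverage is the union of the atoms of all instances."""
    fs = FeatureSet(atoms=set(range(mol.n_atoms)))
    shapes: dict[int, tuple[int, set, list]] = {}
    for ring in sssr(mol):
        bond_set = frozenset(ring.bond_cycle)
        h = tree_hash(mol, bond_set)
        count, cover, inst = shapes.setdefault(h, (0, set(), []))
        cover.update(ring.atom_cycle)
        inst.append(bond_set)
        shapes[h] = (count + 1, cover, inst)
    _emit_family(KIND_RING, shapes, fs)
    return fs


def subgraph_features(mol: Molecule, params: FingerprintParams) -> FeatureSet:
    fs = FeatureSet(atoms=set(range(mol.n_atoms)))
    shapes: dict[int, tuple[int, set, list]] = {}
    for bond_set in enumerate_subgraphs(mol, params.graph_size):
        h = tree_hash(mol, bond_set)
        count, cover, inst = shapes.setdefault(h, (0, set(), []))
        for bi in bond_set:
            cover.add(mol.bonds[bi].a)
            cover.add(mol.bonds[bi].b)
        inst.append(bond_set)
        shapes[h] = (count + 1, cover, inst)
    _emit_family(KIND_SUBGRAPH, shapes, fs)
    return fs


def fingerprint(mol: Molecule, params: FingerprintParams = FingerprintParams()) -> FeatureSet:
    """Full fingerprint: atom-type, ring, and subgraph families with
    multiplicity tiers and the bit -> covered-atoms map."""
    fs = FeatureSet(atoms=set(range(mol.n_atoms)))
    if mol.n_atoms == 0:
        return fs
    fs.merge(atom_type_features(mol))
    fs.merge(ring_features(mol))
    fs.merge(subgraph_features(mol, params))
    return fs
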