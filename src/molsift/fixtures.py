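"""Deterministic synthetic molecules and queries.

Every test and evaluation run is self-contained: a small named corpus of
textbook molecules anchors the worked examples, and a seeded generator
produces valence-respecting random molecules (random spanning tree plus
optional ring-closing edges) together with random connected subqueries that
are substructures of their parent by construction.

The generator is not a sampler of realistic chemistry: elements default to
{C, N, O, S}, aromatic rings appear only as complete six-membered flagged
cycles, and charges/isotopes are injected at a low rate purely to exercise
atom-type distinctions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .fingerprint import splitmix64
from .molgraph import Atom, Bond, Molecule, parse_smiles, write_smiles

__all__ = [
    "GeneratorConfig",
    "TOY_SMILES",
    "toy_corpus",
    "random_molecule",
    "random_subquery",
    "random_corpus",
    "write_corpus",
]

TOY_SMILES = {
    "methane": "C",
    "ethane": "CC",
    "propane": "CCC",
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "biphenyl": "c1ccccc1-c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "pyridine": "c1ccncc1",
    "cycloheptane": "C1CCCCCC1",
    "phenol": "Oc1ccccc1",
    "acetic_acid": "CC(=O)O",
}

# free-valence capacities before charges; C<=4, N<=3, O<=2, S<=2
_CAPACITY = {"C": 4, "N": 3, "O": 2, "S": 2}


def toy_corpus() -> dict[str, Molecule]:
    """Named textbook molecules (parsed); anchors the worked examples."""
    return {name: parse_smiles(smi) for name, smi in TOY_SMILES.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_molecules: int = 100
    atom_count_range: tuple[int, int] = (4, 12)
    elements: tuple[str, ...] = ("C", "N", "O", "S")
    element_weights: tuple[float, ...] = (0.7, 0.1, 0.15, 0.05)
    ring_probability: float = 0.4
    aromatic_fraction: float = 0.5  # of ring events that are aromatic 6-cycles
    double_bond_probability: float = 0.1
    decoration_probability: float = 0.02  # charge/isotope injection per atom

    def __post_init__(self):
        lo, hi = self.atom_count_range
        if not (1 <= lo <= hi):
            raise ValueError("atom_count_range must be a nonempty positive range")
        if not 0.0 <= self.ring_probability <= 1.0:
            raise ValueError("ring_probability must be in [0, 1]")


def _rng(config_seed: int, index: int) -> random.Random:
    return random.Random(splitmix64((config_seed << 20) ^ index))


def random_molecule(config: GeneratorConfig, index: int) -> Molecule:
    """Connected random molecule, deterministic for (config.seed, index)."""
    rng = _rng(config.seed, index)
    lo, hi = config.atom_count_range
    n = rng.randint(lo, hi)

    elements: list[str] = []
    aromatic: list[bool] = []
    bonds: list[tuple[int, int, int, bool]] = []  # a, b, order, aromatic
    used: list[int] = []  # valence units consumed

    def free(i: int) -> int:
        return _CAPACITY[elements[i]] - used[i] - (1 if aromatic[i] else 0)

    make_ring = n >= 6 and rng.random() < config.ring_probability
    aromatic_ring = make_ring and rng.random() < config.aromatic_fraction
    if aromatic_ring:
        for i in range(6):
            elements.append("C")
            aromatic.append(True)
            used.append(0)
        for i in range(6):
            j = (i + 1) % 6
            bonds.append((i, j, 1, True))
            used[i] += 1
            used[j] += 1
    elif make_ring:
        size = rng.randint(3, min(6, n))
        for i in range(size):
            elements.append(rng.choices(config.elements, config.element_weights)[0])
            aromatic.append(False)
            used.append(0)
        for i in range(size):
            j = (i + 1) % size
            bonds.append((i, j, 1, False))
            used[i] += 1
            used[j] += 1
    else:
        elements.append(rng.choices(config.elements, config.element_weights)[0])
        aromatic.append(False)
        used.append(0)

    # grow a random spanning tree on the remaining atoms
    while len(elements) < n:
        anchors = [i for i in range(len(elements)) if free(i) >= 1]
        if not anchors:
            break
        anchor = rng.choice(anchors)
        elem = rng.choices(config.elements, config.element_weights)[0]
        elements.append(elem)
        aromatic.append(False)
        used.append(0)
        new = len(elements) - 1
        order = 1
        if (
            rng.random() < config.double_bond_probability
            and not aromatic[anchor]
            and free(anchor) >= 2
            and _CAPACITY[elem] >= 2
        ):
            order = 2
        bonds.append((anchor, new, order, False))
        used[anchor] += order
        used[new] += order

    # occasional extra aliphatic ring closure
    if rng.random() < config.ring_probability * 0.3:
        bonded = {frozenset((a, b)) for a, b, _, _ in bonds}
        pool = [
            (i, j)
            for i in range(len(elements))
            for j in range(i + 1, len(elements))
            if not aromatic[i]
            and not aromatic[j]
            and free(i) >= 1
            and free(j) >= 1
            and frozenset((i, j)) not in bonded
        ]
        if pool:
            i, j = rng.choice(pool)
            bonds.append((i, j, 1, False))
            used[i] += 1
            used[j] += 1

    atoms: list[Atom] = []
    for i, elem in enumerate(elements):
        charge = 0
        isotope = None
        h = free(i)
        if rng.random() < config.decoration_probability:
            if rng.random() < 0.5:
                isotope = {"C": 13, "N": 15, "O": 18, "S": 34}[elem]
            elif elem == "O" and h >= 1:
                charge, h = -1, h - 1
            elif elem == "N":
                charge, h = 1, h + 1
        atoms.append(
            Atom(elem, charge=charge, isotope=isotope, aromatic=aromatic[i], h_count=h)
        )
    return Molecule(atoms, [Bond(a, b, o, ar) for a, b, o, ar in bonds])


def random_subquery(mol: Molecule, seed: int) -> Molecule:
    """A connected random subgraph of ``mol`` as a standalone molecule; by
    construction it is a substructure of ``mol`` (the sub-atoms keep their
    element/charge/isotope/aromatic attributes and carry no explicit-H
    constraint)."""
    if mol.n_atoms == 0:
        raise ValueError("cannot draw a subquery from an empty molecule")
    rng = random.Random(splitmix64(seed ^ 0x5B0))
    if mol.n_bonds == 0:
        idx = rng.randrange(mol.n_atoms)
        return Molecule([replace(mol.atoms[idx], h_explicit=False)], [])
    target_size = rng.randint(1, mol.n_bonds)
    start = rng.randrange(mol.n_bonds)
    chosen = {start}
    frontier = set(_adjacent_bonds(mol, start)) - chosen
    while len(chosen) < target_size and frontier:
        nxt = rng.choice(sorted(frontier))
        chosen.add(nxt)
        frontier |= set(_adjacent_bonds(mol, nxt))
        frontier -= chosen
    atom_ids = sorted(
        {mol.bonds[bi].a for bi in chosen} | {mol.bonds[bi].b for bi in chosen}
    )
    remap = {a: i for i, a in enumerate(atom_ids)}
    atoms = [replace(mol.atoms[a], h_explicit=False) for a in atom_ids]
    bonds = [
        Bond(remap[mol.bonds[bi].a], remap[mol.bonds[bi].b], mol.bonds[bi].order, mol.bonds[bi].aromatic)
        for bi in sorted(chosen)
    ]
    return Molecule(atoms, bonds)


def _adjacent_bonds(mol: Molecule, bi: int) -> list[int]:
    b = mol.bonds[bi]
    out = []
    for v in (b.a, b.b):
        for bj in mol.bonds_of(v):
            if bj != bi:
                out.append(bj)
    return out


def random_corpus(config: GeneratorConfig) -> list[tuple[str, Molecule]]:
    """``n_molecules`` generated records with stable identifiers."""
    return [
        (f"mol{config.seed}_{i}", random_molecule(config, i))
        for i in range(config.n_molecules)
    ]


def write_corpus(records, path) -> None:
    """Write (identifier, Molecule) records as a .smi file."""
    with open(path, "w", encoding="utf-8") as fh:
        for ident, mol in records:
            fh.write(f"{write_smiles(mol)}\t{ident}\n")
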