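"""Fingerprint families, subgraph enumeration, tree hashing, multiplicity tiers."""

import itertools
import random

import pytest
from hypothesis import given, strategies as st

from molsift.fingerprint import (
    KIND_ATOM_TYPE,
    KIND_RING,
    KIND_SUBGRAPH,
    FingerprintParams,
    atom_type_features,
    encode_multiplicity,
    enumerate_subgraphs,
    fingerprint,
    ring_features,
    tree_hash,
)
from molsift.fixtures import GeneratorConfig, random_molecule, random_subquery
from molsift.molgraph import Bond, Molecule, parse_smiles


def brute_force_subgraphs(mol, max_bonds):
    """Oracle: all bond subsets, filtered connected and at most one ring."""
    out = set()
    bonds = range(mol.n_bonds)
    for k in range(1, max_bonds + 1):
        for combo in itertools.combinations(bonds, k):
            atoms = set()
            for bi in combo:
                atoms.update((mol.bonds[bi].a, mol.bonds[bi].b))
            # connectivity by BFS over the chosen bonds
            start = next(iter(atoms))
            seen = {start}
            frontier = [start]
            while frontier:
                v = frontier.pop()
                for bi in combo:
                    b = mol.bonds[bi]
                    if v in (b.a, b.b):
                        w = b.other(v)
                        if w not in seen:
                            seen.add(w)
                            frontier.append(w)
            if seen != atoms:
                continue
            if len(combo) - len(atoms) + 1 > 1:
                continue
            out.add(frozenset(combo))
    return out


def screening_bits(fs):
    """The closure-safe bit families used to screen (ring bits are index-only)."""
    return {b for b in fs.bits if b.kind != KIND_RING}


class TestAtomTypeFeatures:
    def test_ethanol_two_classes(self):
        fs = atom_type_features(parse_smiles("CCO"))
        assert sorted(fs.counts.values()) == [1, 2]

    def test_benzene_one_aromatic_class(self):
        fs = atom_type_features(parse_smiles("c1ccccc1"))
        assert list(fs.counts.values()) == [6]

    def test_charge_distinguishes_classes(self):
        ammonium = atom_type_features(parse_smiles("[NH4+]"))
        amine = atom_type_features(parse_smiles("N"))
        assert set(ammonium.counts) != set(amine.counts)

    def test_isotope_emits_qualified_and_class_bits(self):
        fs = atom_type_features(parse_smiles("[13CH4]"))
        plain = atom_type_features(parse_smiles("C"))
        assert len(fs.counts) == 2  # class bit + isotope-qualified bit
        assert set(plain.counts) < set(fs.counts)


class TestEnumerateSubgraphs:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("CC", 1), ("CCC", 3), ("c1ccccc1", 31)],
    )
    def test_known_counts(self, smiles, expected):
        mol = parse_smiles(smiles)
        subs = enumerate_subgraphs(mol, 7)
        assert len(subs) == expected
        assert set(subs) == brute_force_subgraphs(mol, 7)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force(self, seed):
        cfg = GeneratorConfig(seed=21, atom_count_range=(3, 9), ring_probability=0.7)
        mol = random_molecule(cfg, seed)
        if mol.n_bonds > 10:
            mol = Molecule(mol.atoms, mol.bonds[:10])
        for max_bonds in (3, 7):
            got = enumerate_subgraphs(mol, max_bonds)
            assert len(got) == len(set(got)), "duplicate subgraph emitted"
            assert set(got) == brute_force_subgraphs(mol, max_bonds)


def _permuted(mol, rng):
    perm = list(range(mol.n_atoms))
    rng.shuffle(perm)
    atoms = [None] * mol.n_atoms
    for old, new in enumerate(perm):
        atoms[new] = mol.atoms[old]
    bonds = [Bond(perm[b.a], perm[b.b], b.order, b.aromatic) for b in mol.bonds]
    return Molecule(atoms, bonds), perm


class TestTreeHash:
    def test_invariant_under_atom_relabeling(self):
        rng = random.Random(5)
        cfg = GeneratorConfig(seed=31, atom_count_range=(3, 10), ring_probability=0.7)
        checked = 0
        for i in range(60):
            mol = random_molecule(cfg, i)
            shuffled, _ = _permuted(mol, rng)
            subs = enumerate_subgraphs(mol, 7)
            if not subs:
                continue
            for bond_set in rng.sample(subs, min(5, len(subs))):
                # bond indices are preserved by _permuted (same bond order)
                assert tree_hash(mol, bond_set) == tree_hash(shuffled, bond_set)
                checked += 1
        assert checked >= 200

    def test_distinct_edges_hash_differently(self):
        cc = parse_smiles("CC")
        cn = parse_smiles("CN")
        assert tree_hash(cc, {0}) != tree_hash(cn, {0})

    def test_bond_order_matters(self):
        single = parse_smiles("CC")
        double = parse_smiles("C=C")
        assert tree_hash(single, {0}) != tree_hash(double, {0})

    def test_benzene_ring_rotation_invariant(self):
        rng = random.Random(1)
        benzene = parse_smiles("c1ccccc1")
        reference = tree_hash(benzene, set(range(6)))
        for _ in range(10):
            shuffled, _ = _permuted(benzene, rng)
            assert tree_hash(shuffled, set(range(6))) == reference

    def test_rejects_two_ring_subgraph(self):
        naph = parse_smiles("c1ccc2ccccc2c1")
        with pytest.raises(ValueError):
            tree_hash(naph, set(range(naph.n_bonds)))


class TestEncodeMultiplicity:
    @pytest.mark.parametrize("count, tiers", [(1, {1}), (5, {1, 2, 4}), (8, {1, 2, 4, 8})])
    def test_examples(self, count, tiers):
        assert encode_multiplicity(count) == tiers

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            encode_multiplicity(0)

    @given(st.integers(min_value=1, max_value=10**6))
    def test_tiers_are_powers_of_two_below_count(self, count):
        tiers = encode_multiplicity(count)
        assert all(t <= count and t & (t - 1) == 0 for t in tiers)
        assert max(tiers) * 2 > count


class TestRingFeatures:
    def test_benzene(self):
        fs = ring_features(parse_smiles("c1ccccc1"))
        assert list(fs.counts.values()) == [1]
        (cover,) = [fs.coverage[b] for b in fs.bits]
        assert cover == frozenset(range(6))

    def test_naphthalene_isomorphic_rings_collapse(self):
        fs = ring_features(parse_smiles("c1ccc2ccccc2c1"))
        assert list(fs.counts.values()) == [2]

    def test_acyclic_no_ring_features(self):
        assert ring_features(parse_smiles("CCO")).counts == {}


class TestFingerprint:
    def test_empty_molecule(self):
        fs = fingerprint(Molecule())
        assert not fs.bits and not fs.counts

    def test_benzene_composition(self):
        # Oracle-derived: 31 subgraphs collapse to 6 shapes (paths of 1..5
        # bonds, count 6 each -> tiers {1,2,4}; the 6-bond ring, count 1);
        # one aromatic-carbon class, count 6; one SSSR ring shape, count 1.
        fs = fingerprint(parse_smiles("c1ccccc1"))
        by_kind = {}
        for base, count in fs.counts.items():
            by_kind.setdefault(base.kind, []).append(count)
        assert sorted(by_kind[KIND_SUBGRAPH]) == [1, 6, 6, 6, 6, 6]
        assert by_kind[KIND_ATOM_TYPE] == [6]
        assert by_kind[KIND_RING] == [1]
        assert len([b for b in fs.bits if b.kind == KIND_SUBGRAPH]) == 16
        assert len(fs.bits) == 20

    @pytest.mark.parametrize("seed", range(40))
    def test_substructure_closure(self, seed):
        """The zero-false-negative guarantee: every screening bit of a
        subgraph query is present in its parent's fingerprint."""
        cfg = GeneratorConfig(seed=43, atom_count_range=(4, 12), ring_probability=0.6)
        mol = random_molecule(cfg, seed)
        params = FingerprintParams(graph_size=7 if seed % 2 else 3)
        parent_bits = fingerprint(mol, params).bits
        for j in range(8):
            sub = random_subquery(mol, seed * 100 + j)
            assert screening_bits(fingerprint(sub, params)) <= parent_bits

    def test_closure_through_isotope_labelled_atoms(self):
        labelled = parse_smiles("CC[13CH3]")
        plain_query = parse_smiles("CCC")
        assert screening_bits(fingerprint(plain_query)) <= fingerprint(labelled).bits

    def test_ring_bits_are_not_closure_safe(self):
        """The naphthalene perimeter is a 10-cycle of the query but not an
        SSSR ring of naphthalene itself: this is why the query planner never
        screens on ring-family bits."""
        naph = parse_smiles("c1ccc2ccccc2c1")
        fused_bond = next(
            bi for bi, b in enumerate(naph.bonds)
            if naph.degree(b.a) == 3 and naph.degree(b.b) == 3
        )
        perimeter = [bi for bi in range(naph.n_bonds) if bi != fused_bond]
        sub = Molecule(naph.atoms, [naph.bonds[bi] for bi in perimeter])
        ring_bits = {b for b in fingerprint(sub).bits if b.kind == KIND_RING}
        assert ring_bits and not ring_bits <= fingerprint(naph).bits

    def test_isomorphism_invariance(self):
        rng = random.Random(77)
        cfg = GeneratorConfig(seed=88, atom_count_range=(4, 10), ring_probability=0.6)
        for i in range(15):
            mol = random_molecule(cfg, i)
            shuffled, _ = _permuted(mol, rng)
            assert fingerprint(mol).bits == fingerprint(shuffled).bits

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_graph_size(self, seed):
        cfg = GeneratorConfig(seed=91, atom_count_range=(4, 10), ring_probability=0.6)
        mol = random_molecule(cfg, seed)
        previous = set()
        for g in (1, 2, 3, 5, 7):
            bits = fingerprint(mol, FingerprintParams(graph_size=g)).bits
            assert previous <= bits
            previous = bits
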