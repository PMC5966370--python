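"""VF2 matcher: compatibility semantics, embedding counts, oracle agreement."""

import itertools
import random
from dataclasses import replace

import pytest
from rdkit import Chem

from molsift.fixtures import GeneratorConfig, random_molecule, random_subquery, toy_corpus
from molsift.matcher import (
    MatchOptions,
    MatchUndecided,
    atoms_compatible,
    bonds_compatible,
    count_embeddings,
    find_embeddings,
    is_substructure,
)
from molsift.molgraph import Atom, Bond, Molecule, parse_smiles, write_smiles


def oracle_embeddings(query, target, opts=MatchOptions()):
    """Independent oracle: exhaustive enumeration of injective mappings."""
    count = 0
    for perm in itertools.permutations(range(target.n_atoms), query.n_atoms):
        if not all(
            atoms_compatible(query.atoms[i], target.atoms[perm[i]], opts)
            for i in range(query.n_atoms)
        ):
            continue
        ok = True
        for qb in query.bonds:
            tbi = target.bond_between(perm[qb.a], perm[qb.b])
            if tbi is None or not bonds_compatible(qb, target.bonds[tbi]):
                ok = False
                break
        if ok:
            count += 1
    return count


class TestAtomCompatibility:
    def test_plain_carbon_matches(self):
        assert atoms_compatible(Atom("C"), Atom("C"))

    def test_aromatic_flag_must_agree(self):
        assert not atoms_compatible(Atom("C", aromatic=True), Atom("C"))
        assert not atoms_compatible(Atom("C"), Atom("C", aromatic=True))

    def test_charge_sensitivity(self):
        q, t = Atom("N", charge=1), Atom("N", charge=0)
        assert not atoms_compatible(q, t)
        assert atoms_compatible(q, t, MatchOptions(charge_sensitive=False))

    def test_isotope_constrains_only_when_query_specifies(self):
        assert atoms_compatible(Atom("C"), Atom("C", isotope=13))
        assert not atoms_compatible(Atom("C", isotope=13), Atom("C"))
        assert atoms_compatible(Atom("C", isotope=13), Atom("C", isotope=13))

    def test_explicit_hydrogen_count_is_a_lower_bound(self):
        q = Atom("C", h_count=3, h_explicit=True)
        assert atoms_compatible(q, Atom("C", h_count=4))
        assert not atoms_compatible(q, Atom("C", h_count=2))
        bare = Atom("C", h_count=4, h_explicit=False)
        assert atoms_compatible(bare, Atom("C", h_count=0))


class TestBondCompatibility:
    def test_aromatic_never_bridges_kekule(self):
        assert not bonds_compatible(Bond(0, 1, 1, True), Bond(0, 1, 2, False))
        assert not bonds_compatible(Bond(0, 1, 2, False), Bond(0, 1, 1, True))
        assert bonds_compatible(Bond(0, 1, 1, True), Bond(0, 1, 1, True))

    def test_order_must_match_for_plain_bonds(self):
        assert bonds_compatible(Bond(0, 1, 2), Bond(0, 1, 2))
        assert not bonds_compatible(Bond(0, 1, 1), Bond(0, 1, 2))


class TestIsSubstructure:
    def test_benzene_in_toluene(self):
        assert is_substructure(parse_smiles("c1ccccc1"), parse_smiles("Cc1ccccc1"))

    def test_cycloheptane_not_in_benzene(self):
        assert not is_substructure(parse_smiles("C1CCCCCC1"), parse_smiles("c1ccccc1"))

    def test_multifragment_needs_nonoverlapping_placements(self):
        two_rings = parse_smiles("c1ccccc1.c1ccccc1")
        assert is_substructure(two_rings, parse_smiles("c1ccccc1-c1ccccc1"))
        assert not is_substructure(two_rings, parse_smiles("c1ccccc1"))
        # naphthalene holds two fused rings but cannot host two disjoint ones
        assert not is_substructure(two_rings, parse_smiles("c1ccc2ccccc2c1"))

    def test_identity_embedding(self, toy_mols):
        for mol in toy_mols.values():
            assert is_substructure(mol, mol)

    def test_monotone_under_target_extension(self):
        cfg = GeneratorConfig(seed=17, atom_count_range=(3, 8))
        for i in range(20):
            target = random_molecule(cfg, i)
            query = random_subquery(target, seed=i)
            extended = Molecule(
                target.atoms + [Atom("C", h_count=3)],
                target.bonds + [Bond(0, target.n_atoms, 1, False)],
            )
            if target.atoms[0].h_count < 1 or target.atoms[0].aromatic:
                continue
            assert is_substructure(query, target)
            assert is_substructure(query, extended)


class TestCountEmbeddings:
    def test_benzene_in_benzene_backtracks_twelve_times(self):
        benzene = parse_smiles("c1ccccc1")
        assert count_embeddings(benzene, benzene) == 12

    def test_single_carbon_in_ethane(self):
        assert count_embeddings(parse_smiles("C"), parse_smiles("CC")) == 2

    def test_aromatic_edge_in_benzene(self):
        assert count_embeddings(parse_smiles("cc"), parse_smiles("c1ccccc1")) == 12

    def test_positive_count_iff_substructure(self):
        cfg = GeneratorConfig(seed=23, atom_count_range=(2, 7))
        for i in range(30):
            q = random_molecule(cfg, 2 * i)
            t = random_molecule(cfg, 2 * i + 1)
            assert (count_embeddings(q, t) > 0) == is_substructure(q, t)


class TestStateLimit:
    def test_limit_raises_undecided(self):
        query = parse_smiles("C1CCCCCCCCCCC1")  # 12-ring
        target = parse_smiles("C1CCCCCCCCCCC1")
        with pytest.raises(MatchUndecided):
            count_embeddings(query, target, MatchOptions(limit=3))

    def test_no_limit_is_exact(self):
        benzene = parse_smiles("c1ccccc1")
        assert count_embeddings(benzene, benzene, MatchOptions(limit=10**6)) == 12


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        qcfg = GeneratorConfig(seed=201, atom_count_range=(2, 5), ring_probability=0.5)
        tcfg = GeneratorConfig(seed=202, atom_count_range=(4, 7), ring_probability=0.5)
        q = random_molecule(qcfg, seed)
        t = random_molecule(tcfg, seed)
        assert count_embeddings(q, t) == oracle_embeddings(q, t)
        sub = random_subquery(t, seed)
        if sub.n_atoms <= 5:
            assert count_embeddings(sub, t) == oracle_embeddings(sub, t) > 0

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_rdkit_on_aliphatic_molecules(self, seed):
        """RDKit as an independent oracle, restricted to single-bond aliphatic
        molecules where its sanitization cannot reperceive aromaticity."""
        cfg = GeneratorConfig(
            seed=301,
            atom_count_range=(3, 9),
            ring_probability=0.5,
            aromatic_fraction=0.0,
            double_bond_probability=0.0,
            decoration_probability=0.0,
        )
        t = random_molecule(cfg, seed)
        q = random_subquery(t, seed + 1000)
        q2 = random_molecule(replace(cfg, atom_count_range=(2, 5)), seed + 2000)
        rt = Chem.MolFromSmiles(write_smiles(t))
        for query in (q, q2):
            rq = Chem.MolFromSmiles(write_smiles(_relax_hydrogens(query)))
            assert rt is not None and rq is not None
            assert is_substructure(query, t) == rt.HasSubstructMatch(rq)


def _relax_hydrogens(mol):
    """Reset each atom's hydrogen count to the valence-implied value for its
    own bonding context, so the query serializes without bracket atoms and
    both matchers treat hydrogens as unconstrained."""
    from molsift.molgraph import implicit_h_count

    atoms = []
    for i, a in enumerate(mol.atoms):
        order_sum = sum(
            1 if mol.bonds[bi].aromatic else mol.bonds[bi].order for bi in mol.bonds_of(i)
        )
        atoms.append(replace(a, h_count=implicit_h_count(a.element, a.aromatic, order_sum)))
    return Molecule(atoms, list(mol.bonds))
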