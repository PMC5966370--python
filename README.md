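# molsift

A self-contained substructure search engine for small-molecule corpora:
substructural fingerprints, an inverted keyword index, statistical query-bit
selection, and VF2 subgraph verification.

Substructure search — retrieving every database molecule that contains a
query fragment as a subgraph — hinges on two components: a *screening*
filter that cheaply discards compounds provably unable to match, and a
*verification* step that runs an exact (and worst-case exponential)
subgraph-isomorphism test on whatever survives. molsift implements the whole
pipeline as a Python library plus a small CLI, for desk-scale corpora: it is
aimed at method experimentation and teaching, not at 10⁸-compound
production deployments.

## The method

**Fingerprint.** Each molecule is decomposed into three families of
substructural features, every feature folded into a 36-bit identifier:

* *atom types* — one feature per distinct atom class (element, formal
  charge, aromatic flag), with its occurrence count; atoms carrying a
  specified isotope also emit an isotope-qualified feature;
* *rings* — one feature per distinct SSSR ring shape (SSSR = Smallest Set
  of Smallest Rings, a minimum cycle basis with exactly
  bonds − atoms + components members);
* *subgraphs* — one feature per distinct shape of a connected subgraph with
  at most one ring and at most *GraphSize* bonds (default 7), hashed by a
  tree-hashing scheme that peels leaves inward and canonicalizes any
  remaining ring by its lexically minimal rotation.

A feature occurring *c* times sets one bit per power of two ≤ *c*
("occurs at least 2ᵏ times"), which is monotone under structural extension.
The defining guarantee is **closure**: every screening bit of a fragment is
present in the fingerprint of any molecule containing that fragment, so
screening can produce false positives but never false negatives.

**Index.** Each 36-bit bit is rendered as a 6-character base64 keyword; an
inverted index maps keywords to sorted posting lists of compound ordinals
(varint delta-encoded on disk). Screening is posting-list intersection. A
bit's document frequency over the corpus gives its occurrence *F*, the
inverse of its filtering power.

**Query planning.** A query fingerprint is first reduced by subsumption
(only the top multiplicity tier per feature; shapes implied by retained
larger shapes dropped), then filtered by the bit-selection loop: visit bits
in descending filtering power and keep a bit only while some covered query
atom has been covered fewer than *MinCover* times (default 2), stopping at
*MaxBits* bits (default 32).

**Verification.** Candidates are checked with a VF2-style backtracking
matcher. Aromaticity is purely notational (lowercase atoms/`:` bonds; no
electronic perception), so Kekulé-written and aromatic-written rings are
distinct — see `docs/methods.md` for the exact compatibility table.

## Worked example

Index the built-in toy corpus and search for benzene:

```
$ python -c 'from molsift.fixtures import TOY_SMILES
open("corpus.smi","w").write("".join(f"{s}\t{n}\n" for n,s in TOY_SMILES.items()))'
$ molsift index build --input corpus.smi --out idx --graph-size 7
indexed 12 compounds (0 skipped), 316 keywords -> idx
$ molsift search --index idx --query "c1ccccc1" --stats
identifier	verified
benzene	true
toluene	true
biphenyl	true
naphthalene	true
phenol	true
# candidates=5 verified=5
# precision=1 fpr=0
```

Screening admitted exactly the five aromatic compounds (precision 1, false
positive rate 0); verification confirmed each one, since every one of them
contains a benzene ring. The matcher can also count embeddings — a benzene
query on a benzene target has 12 distinct atom mappings (6 rotations × 2
directions):

```
$ molsift match --query "c1ccccc1" --target "c1ccccc1" --count
12
```

Other subcommands: `molsift eval` (per-query precision/FPR table over a
query file), `molsift fixtures generate` (deterministic random corpora),
`molsift inspect features` (dump a molecule's fingerprint as TSV).

As a library:

```python
from molsift import build_index, parse_smiles, search, screening_stats
from molsift.fixtures import toy_corpus

index = build_index(list(toy_corpus().items()))
result = search(index, parse_smiles("c1ccccc1"))
print([index.identifier(o) for o in result.verified])
# ['benzene', 'toluene', 'biphenyl', 'naphthalene', 'phenol']
print(screening_stats(result))
# (1.0, 0.0)
```

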