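# Methods

This note documents the models, conventions, and numerical choices behind
molsift, and what the test suite does and does not demonstrate.

## Molecular graph model

Molecules are undirected attributed graphs. Heavy atoms carry element,
formal charge, optional isotope, an aromatic flag, and a hydrogen count;
hydrogens are never graph nodes. Bonds carry an integer order (1–3) and an
aromatic flag. Molecules may be disconnected (dot-separated SMILES
fragments). Atom indices are 0-based everywhere.

### SMILES subset

The parser accepts the organic subset (B, C, N, O, P, S, F, Cl, Br, I),
bracket atoms with isotope/charge/explicit hydrogens, bond symbols
`- = # :`, lowercase aromatic atoms, ring closures (`1`–`9`, `%nn`),
branches, and dots. Stereo markers (`/ \ @ @@`) are parsed and discarded;
wildcard atoms (`*`) and explicit hydrogen atoms (`[H]`) are rejected.
Implicit hydrogen counts follow standard valences (N 3/5, S 2/4/6, P 3/5).

**Aromaticity is notational.** An atom is aromatic iff written lowercase; a
bond is aromatic iff written `:` or implied. No Hückel-style perception is
performed, so Kekulé benzene (`C1=CC=CC=C1`) and aromatic benzene
(`c1ccccc1`) are *different* inputs that do not match each other. This is a
deliberate simplification; cartridges that normalize aromaticity
electronically will disagree on such inputs.

An implicit bond between two aromatic atoms is resolved aromatic when it
lies on a cycle, or when it joins acyclic aromatic atoms (so the fragment
query `cc` means an aromatic bond); a bridge between two ring systems
(biphenyl's inter-ring bond) is single. For aromatic atoms the implicit
hydrogen count charges one extra valence unit for elements that contribute
a π bond to the ring (B, C, N, P) and none for lone-pair donors (O, S, Se):
benzene carbons get 1 H, pyridine nitrogen 0, thiophene sulfur 0.

### SSSR

Ring perception returns exactly bonds − atoms + components rings. Candidate
cycles are the BFS-shortest cycle through each non-bridge bond; candidates
are sorted by (length, sorted bond-index set) and accepted greedily under
GF(2) linear independence of their bond-incidence vectors. The sorted-bond
tie-break makes the output deterministic for a fixed input ordering; tests
check the ring-size multiset against networkx's minimum cycle basis.

## Fingerprint

Three families; every bit is a 36-bit identifier obtained by mixing
(family, shape hash, multiplicity tier) through a fixed splitmix64-style
avalanche and truncating. Collisions across the 2³⁶ space are tolerated:
a collision can only merge posting lists, i.e. create false positives,
never false negatives.

* **Atom types.** The base class is (element, charge, aromatic) with the
  count of *all* atoms in the class. Atoms with a specified isotope emit an
  additional isotope-qualified feature with its exact count. The isotope is
  deliberately kept out of the base class and out of subgraph atom labels:
  matching lets an isotope-free query atom bind any isotope of the element,
  so any isotope-aware count could shrink when a fragment is extended and
  would break closure. With this split, an isotope-free query only consumes
  isotope-blind counts (sound), while an isotope-labelled query still gets
  a sharp isotope-qualified bit.
* **Rings.** One feature per distinct SSSR ring shape, counted with
  multiplicity; coverage is the union of the instance atom sets.
* **Subgraphs.** All connected bond subgraphs with 1..GraphSize bonds
  (default 7) and cyclomatic number ≤ 1, enumerated uniquely via the ESU
  scheme on the bond-adjacency graph with pruning of >1-ring branches.
  Single atoms are not subgraph features (the atom-type family covers
  them).

**Tree hash.** Shape hashing peels all current leaves each round, folding a
leaf's accumulated hash together with its incident bond label into its
neighbour through an order-independent (sorted) combiner. Acyclic shapes
terminate at a 1-atom centre or a symmetric 2-atom centre; unicyclic shapes
terminate at the ring, whose cyclic (atom hash, bond label) sequence is
hashed at its lexically minimal rotation over both starting points *and
both directions* — reflection is included so the hash is a true isomorphism
invariant. Atom labels are (element, charge, aromatic); bond labels are the
order, with aromatic bonds a distinct symbol.

**Multiplicity.** Count *c* sets tiers {2ᵏ : 2ᵏ ≤ c}; tier *p* reads as
"occurs at least *p* times", which is monotone under extension — the load-
bearing property behind closure.

## Index

Keywords are the 36-bit values written as six base64 characters (RFC 4648
alphabet, big-endian 6-bit groups); the encoding is injective. Posting
lists are sorted compound ordinals, varint delta-encoded on disk. The index
directory holds `manifest.json` (format version, graph size, counts),
`vocab` (keyword, byte offset, length per line), `postings` (the varint
blob), and `store` (JSON-lines serialized molecules with identifiers).
Loading verifies the format version, blob length, record counts, and strict
monotonicity of posting lists; failures raise integrity errors rather than
returning wrong answers. When query-time parameters disagree with the
manifest, the manifest wins (with a logged warning): the fingerprint the
index was built with is the only one its postings answer for.

A bit's occurrence is its posting-list length over the corpus size
(document frequency); filtering power is its inverse.

## Query planning

**Step 1 — subsumption.** Within each base feature only the highest tier is
kept (the tier-4 posting list is a subset of tier-1's by construction).
The tier-*p* bit of subgraph shape *s* is dropped when a single retained
larger shape instance contains ≥ *p* instances of *s* — occurrence counts
inside a shape are isomorphism invariants, so any compound holding the big
shape's bit necessarily holds the dropped bit. A count-1 atom-type bit is
dropped when an atom of its class lies inside a retained subgraph instance.
Every drop is implied by a retained bit, so the candidate set is unchanged.

**Ring bits are never used for screening.** A cycle of the query graph need
not be an SSSR ring of a molecule containing the query: the 10-bond
perimeter of naphthalene is its own SSSR ring as a standalone query, while
naphthalene's SSSR is two 6-rings. Screening on query ring bits would
therefore lose true matches. Ring bits are still computed and indexed for
every stored compound — harmless there, and rings of ≤ GraphSize bonds are
screened anyway through their identical subgraph-family shapes. The test
suite contains the naphthalene-perimeter counterexample.

**Step 2 — bit selection.** Bits are visited in ascending occurrence
(descending filtering power), ties broken by ascending identifier value so
runs are deterministic. A per-atom counter array starts at zero; a bit is
kept iff some atom it covers has a counter below MinCover, whereupon all
its covered atoms' counters increment; a hard cap of MaxBits kept bits is
enforced before the cover test. Defaults MinCover = 2, MaxBits = 32. Bits
with occurrence 0 sort first: their empty posting lists legitimately screen
out everything. Coverage of a multi-instance feature is the union of its
instance atom sets (the conservative choice: the bit is credited to every
atom that could have caused it).

A query whose reduced fingerprint is empty (an empty molecule) falls back
to full-corpus verification with a logged warning — it carries no screening
information, and silently returning nothing would be wrong.

## Matching semantics

VF2-style backtracking with a connectivity-first ordering heuristic
(highest degree, then most already-placed neighbours); the heuristic never
affects results. Compatibility:

* elements equal; aromatic flags equal (atoms and bonds — no
  Kekulé-to-aromatic bridging);
* charges equal unless `charge_sensitive` is disabled;
* an isotope constrains the target only when the query specifies one;
* bracket-written hydrogen counts on query atoms are a lower bound on the
  target atom's hydrogens; bare atoms impose none;
* non-aromatic bonds must match in order.

Multi-fragment queries need one global injective mapping, so *n* disjoint
benzene rings only match targets that can host *n* non-overlapping rings.
An optional state limit turns pathological exponential cases into an
explicit "undecided" outcome (an exception, reported separately by the
search layer) rather than a silent wrong answer; the default is unlimited.

Note that `charge_sensitive=False` weakens the matcher below what the
fingerprint assumes (charges are part of the atom class), so it should only
be used for direct matching, not through the screened search path.

## Screening metrics

Precision = TP / (TP + FP) over screened positives, defined as 1 when
screening admits nothing (no decision was wrong — the definition would
otherwise divide by zero). FPR = FP / negatives, 0 when there are no
negatives. `evaluate` reports per-query rows plus medians and the fraction
of queries at or below FPR thresholds (the survival framing used for
screening-efficiency curves).

## Synthetic data

The generator emulates small organic-like graphs, not chemistry: elements
{C, N, O, S} weighted toward carbon, a random spanning tree grown under
fixed valence capacities (C 4, N 3, O 2, S 2), optional rings — aromatic
rings only as complete six-membered flagged cycles, aliphatic rings of
size 3–6, occasional extra ring-closing edges — plus ~10% double bonds and
~2% charge/isotope decorations. Defaults: 100 molecules of 4–12 atoms,
ring probability 0.4. Everything is seeded (splitmix64-expanded) and fully
deterministic per (seed, index). Subqueries are random connected bond
subsets of a parent, returned with explicit-H constraints cleared, so they
are substructures of the parent by construction.

What passing tests show: the engine's invariants (closure, screening
soundness, isomorphism invariance, determinism) hold over this family of
graphs, which includes fused/bridged rings, multi-tier multiplicities, and
charged/labelled atoms. What they do not show: behaviour on real-database
pathologies (macrocycles, high-symmetry cages, tautomer conventions,
sanitization disagreements between toolkits), or performance at database
scale.

## Problem sizes and determinism

The randomized suites use sizes chosen to exercise the combinatorics while
keeping the whole suite in tens of seconds: screening soundness runs 500
trials against a brute-force full-scan oracle over two 200-compound corpora
indexed at GraphSize 3 and 7, crossing MinCover {1, 2, 5} with selection
on/off; matcher correctness compares 2000 random pairs (queries ≤ 6 atoms,
targets ≤ 8) against exhaustive injective-mapping enumeration; plan-size
and subgraph-size caps are checked over 1000 random queries/molecules.
Hypothesis-based property tests run derandomized. RDKit serves as an
independent matching oracle on aliphatic single-bond molecules only, where
its sanitization cannot reperceive aromaticity and thus both engines'
semantics provably coincide.

## Known limitations

* No aromaticity perception: results differ from electronically
  normalizing cartridges on Kekulé-written aromatic rings.
* No stereochemistry, no wildcard atoms, no SMARTS logic, no tautomer or
  charge normalization.
* The inverted index is single-file, rebuilt from scratch; no incremental
  updates or sharding.
* Ring-family bits add index volume but only pay off for rings larger than
  GraphSize on the *indexed* side of some future query scheme; with the
  current sound planner they are never intersected.
* `count_embeddings` is intended for test-scale molecules; symmetric
  structures have exponentially many embeddings.
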