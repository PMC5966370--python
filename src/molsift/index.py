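"""Inverted index over fingerprint keywords.

Each 36-bit fingerprint bit is rendered as a 6-character word over the
RFC 4648 base64 alphabet (big-endian 6-bit groups), and every compound's
ordinal is appended to the posting list of each of its keywords.  The index
persists as a small directory: a JSON manifest, a text vocabulary with byte
offsets, varint delta-encoded posting lists, and a JSON-lines compound
store.  A bit's document frequency is simply its posting-list length, which
is the source of the filtering-power statistic used in query planning.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .fingerprint import FeatureId, FingerprintParams, fingerprint
from .molgraph import Molecule

__all__ = [
    "FORMAT_VERSION",
    "B64_ALPHABET",
    "IndexError_",
    "IndexFormatError",
    "IndexIntegrityError",
    "Keyword",
    "OccurrenceTable",
    "InvertedIndex",
    "encode_keyword",
    "build_index",
    "candidates",
    "occurrence",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

# RFC 4648 standard alphabet
B64_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789+/"

Keyword = str


class IndexError_(Exception):
    """Base class for index storage errors."""


class IndexFormatError(IndexError_):
    """Unsupported on-disk format version."""


class IndexIntegrityError(IndexError_):
    """Corrupted or truncated index files."""


def encode_keyword(bit: FeatureId | int) -> Keyword:
    """36-bit identifier -> 6-character base64 word (big-endian 6-bit groups).
    Injective on the 36-bit domain."""
    value = bit.value if isinstance(bit, FeatureId) else bit
    if not 0 <= value < (1 << 36):
        raise ValueError("keyword value out of 36-bit range")
    chars = []
    for shift in range(30, -1, -6):
        chars.append(B64_ALPHABET[(value >> shift) & 0x3F])
    return "".join(chars)


# ---------------------------------------------------------------------------
# varint (LEB128) posting-list codec
# ---------------------------------------------------------------------------


def _encode_varint(n: int, out: bytearray) -> None:
    while True:
        byte = n & 0x7F
        n >>= 7
        if n:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return


def _decode_varints(data: bytes) -> list[int]:
    values = []
    cur = 0
    shift = 0
    for byte in data:
        cur |= (byte & 0x7F) << shift
        if byte & 0x80:
            shift += 7
        else:
            values.append(cur)
            cur = 0
            shift = 0
    if shift:
        raise IndexIntegrityError("truncated varint in posting list")
    return values


def encode_postings(ordinals: list[int]) -> bytes:
    out = bytearray()
    prev = -1
    for o in ordinals:
        _encode_varint(o - prev - 1, out)
        prev = o
    return bytes(out)


def decode_postings(data: bytes) -> list[int]:
    deltas = _decode_varints(data)
    out = []
    prev = -1
    for d in deltas:
        prev = prev + d + 1
        out.append(prev)
    return out


# ---------------------------------------------------------------------------
# occurrence statistics
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceTable:
    """Per-keyword document frequency; ``occurrence`` is the fraction of
    corpus compounds whose fingerprint sets the bit (filtering power is its
    inverse)."""

    frequency: dict[Keyword, int] = field(default_factory=dict)
    total: int = 0

    def occurrence_of(self, bit: FeatureId) -> float:
        if self.total <= 0:
            raise ValueError("occurrence undefined for an empty corpus")
        return self.frequency.get(encode_keyword(bit), 0) / self.total


def occurrence(table: OccurrenceTable, bit: FeatureId) -> float:
    return table.occurrence_of(bit)


# ---------------------------------------------------------------------------
# the index
# ---------------------------------------------------------------------------


@dataclass
class InvertedIndex:
    graph_size: int
    postings: dict[Keyword, list[int]] = field(default_factory=dict)
    store: list[tuple[str, Molecule]] = field(default_factory=list)
    n_failures: int = 0

    @property
    def total(self) -> int:
        return len(self.store)

    @property
    def params(self) -> FingerprintParams:
        return FingerprintParams(graph_size=self.graph_size)

    def identifier(self, ordinal: int) -> str:
        return self.store[ordinal][0]

    def molecule(self, ordinal: int) -> Molecule:
        return self.store[ordinal][1]

    def occurrence_table(self) -> OccurrenceTable:
        return OccurrenceTable(
            frequency={k: len(v) for k, v in self.postings.items()}, total=self.total
        )

    def candidates(self, bits: Iterable[FeatureId]) -> list[int]:
        return candidates(self, bits)


def candidates(index: InvertedIndex, bits: Iterable[FeatureId]) -> list[int]:
    """Sorted intersection of the posting lists of ``bits``.  A bit absent
    from the vocabulary yields the empty set; an empty bit set yields every
    ordinal (no screening information)."""
    keywords = {encode_keyword(b) for b in bits}
    if not keywords:
        return list(range(index.total))
    lists = []
    for kw in keywords:
        postings = index.postings.get(kw)
        if not postings:
            return []
        lists.append(postings)
    lists.sort(key=len)
    result = set(lists[0])
    for lst in lists[1:]:
        result &= set(lst)
        if not result:
            return []
    return sorted(result)


def build_index(
    records: Iterable[tuple[str, Molecule]],
    params: FingerprintParams = FingerprintParams(),
    out_path: Optional[str] = None,
    n_failures: int = 0,
) -> InvertedIndex:
    """Fingerprint every compound and post its ordinal under each of its
    bits' keywords.  ``n_failures`` carries the parse-failure count from the
    reader for the manifest.  If ``out_path`` is given the index is saved."""
    index = InvertedIndex(graph_size=params.graph_size, n_failures=n_failures)
    seen_ids: set[str] = set()
    for ident, mol in records:
        if ident in seen_ids:
            raise ValueError(f"duplicate compound identifier {ident!r}")
        seen_ids.add(ident)
        ordinal = len(index.store)
        index.store.append((ident, mol))
        fs = fingerprint(mol, params)
        for bit in fs.bits:
            index.postings.setdefault(encode_keyword(bit), []).append(ordinal)
    if out_path is not None:
        save_index(index, out_path)
    return index


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_index(index: InvertedIndex, path: str) -> None:
    """Persist to a directory: manifest.json, vocab (text), postings
    (varint deltas), store (JSON lines)."""
    os.makedirs(path, exist_ok=True)
    postings_blob = bytearray()
    vocab_lines = []
    for kw in sorted(index.postings):
        data = encode_postings(index.postings[kw])
        vocab_lines.append(f"{kw}\t{len(postings_blob)}\t{len(data)}\n")
        postings_blob.extend(data)
    manifest = {
        "format_version": FORMAT_VERSION,
        "graph_size": index.graph_size,
        "n_compounds": index.total,
        "n_keywords": len(index.postings),
        "n_failures": index.n_failures,
        "postings_bytes": len(postings_blob),
    }
    with open(os.path.join(path, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    with open(os.path.join(path, "vocab"), "w", encoding="utf-8") as fh:
        fh.writelines(vocab_lines)
    with open(os.path.join(path, "postings"), "wb") as fh:
        fh.write(postings_blob)
    with open(os.path.join(path, "store"), "w", encoding="utf-8") as fh:
        for ident, mol in index.store:
            fh.write(json.dumps({"id": ident, "mol": mol.to_dict()}) + "\n")


def load_index(path: str) -> InvertedIndex:
    """Load an index directory; raises :class:`IndexFormatError` on a version
    mismatch and :class:`IndexIntegrityError` on truncated files."""
    try:
        with open(os.path.join(path, "manifest.json"), "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
    except FileNotFoundError as exc:
        raise IndexIntegrityError(f"missing manifest in {path!r}") from exc
    except json.JSONDecodeError as exc:
        raise IndexIntegrityError("corrupted manifest") from exc
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise IndexFormatError(
            f"unsupported index format version {version!r} (expected {FORMAT_VERSION})"
        )
    with open(os.path.join(path, "postings"), "rb") as fh:
        blob = fh.read()
    if len(blob) != manifest["postings_bytes"]:
        raise IndexIntegrityError("postings file length does not match manifest")
    postings: dict[Keyword, list[int]] = {}
    with open(os.path.join(path, "vocab"), "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            try:
                kw, offset, length = line.rstrip("\n").split("\t")
                offset, length = int(offset), int(length)
            except ValueError as exc:
                raise IndexIntegrityError("malformed vocab line") from exc
            if offset + length > len(blob):
                raise IndexIntegrityError("vocab offset past end of postings")
            postings[kw] = decode_postings(blob[offset : offset + length])
    store: list[tuple[str, Molecule]] = []
    with open(os.path.join(path, "store"), "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                store.append((rec["id"], Molecule.from_dict(rec["mol"])))
            except (json.JSONDecodeError, KeyError) as exc:
                raise IndexIntegrityError("corrupted store record") from exc
    if len(store) != manifest["n_compounds"]:
        raise IndexIntegrityError("store length does not match manifest")
    if len(postings) != manifest["n_keywords"]:
        raise IndexIntegrityError("vocabulary size does not match manifest")
    index = InvertedIndex(
        graph_size=manifest["graph_size"],
        postings=postings,
        store=store,
        n_failures=manifest.get("n_failures", 0),
    )
    for lst in postings.values():
        if any(b <= a for a, b in zip(lst, lst[1:])) or (lst and lst[-1] >= index.total):
            raise IndexIntegrityError("posting list not strictly increasing in range")
    return index
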