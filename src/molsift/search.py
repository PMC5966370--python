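"""Query planning, screening, verification, and screening-efficiency metrics.

A query fingerprint is reduced in two steps before it touches the index:

1. **Subsumption reduction** — bits whose presence in a matching compound is
   implied by other retained bits are discarded.  Within each base feature
   only the highest multiplicity tier survives (a compound holding the
   tier-4 bit necessarily holds tiers 1 and 2).  A once-occurring subgraph
   bit is dropped when its bond set lies inside another retained subgraph
   instance, and a once-occurring atom-type bit is dropped when an atom of
   that class sits inside a retained subgraph instance.  Ring-family bits
   are excluded from the screening query altogether: an SSSR ring of the
   query graph need not be an SSSR ring of a larger molecule that contains
   the query (a fused system covers the same edges with smaller rings), so
   screening on them could create false negatives.  None of the retained
   implications can lose a true match.
2. **Statistical bit selection** — bits are visited in descending filtering
   power (ascending corpus occurrence, ties by identifier value); a bit is
   kept iff some atom it covers has been covered fewer than ``min_cover``
   times so far, whereupon all its covered atoms' counters increment, with a
   hard stop after ``max_bits`` kept bits.

Screening then intersects the posting lists of the selected bits, and every
candidate is verified with the matcher.  Precision is TP over all screened
positives (1 when nothing was screened in); FPR is FP over all negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .fingerprint import (
    KIND_ATOM_TYPE,
    KIND_RING,
    KIND_SUBGRAPH,
    FeatureId,
    FeatureSet,
    fingerprint,
)
from .index import InvertedIndex, OccurrenceTable
from .matcher import MatchOptions, MatchUndecided, is_substructure
from .molgraph import Molecule

__all__ = [
    "SelectionParams",
    "QueryPlan",
    "SearchResult",
    "subsumption_reduce",
    "select_bits",
    "search",
    "screening_stats",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    min_cover: int = 2
    max_bits: int = 32
    select_enabled: bool = True

    def __post_init__(self):
        if self.min_cover < 1:
            raise ValueError("min_cover must be >= 1")
        if self.max_bits < 1:
            raise ValueError("max_bits must be >= 1")


@dataclass
class QueryPlan:
    selected_bits: list[FeatureId] = field(default_factory=list)
    discarded_subsumed: int = 0
    discarded_selected: int = 0
    full_scan: bool = False


@dataclass
class SearchResult:
    candidates: list[int] = field(default_factory=list)
    verified: list[int] = field(default_factory=list)
    undecided: list[int] = field(default_factory=list)
    true_positive_count: int = 0
    false_positive_count: int = 0
    negative_count: int = 0
    plan: Optional[QueryPlan] = None


def subsumption_reduce(fs: FeatureSet) -> FeatureSet:
    """Step-1 reduction of a query fingerprint (see module docstring).

    Every dropped bit is implied by a retained one through fingerprint
    closure, so the candidate set cannot lose a true match.
    """
    top_tier: dict[FeatureId, FeatureId] = {}
    for bit in fs.bits:
        if bit.kind == KIND_RING:
            continue  # not closure-safe on the query side
        base = fs.base_of[bit]
        cur = top_tier.get(base)
        if cur is None or bit.tier > cur.tier:
            top_tier[base] = bit
    kept = set(top_tier.values())

    # subgraph containment: the tier-p bit of shape s is implied by a bigger
    # retained shape t whenever one instance of t contains >= p instances of
    # s (shape occurrence counts inside a shape are isomorphism invariants,
    # so the implication carries over to any molecule holding t's bit).
    # Larger shapes are decided first so implication chains stay grounded in
    # retained bits.
    sub_feats = sorted(
        (b for b in kept if b.kind == KIND_SUBGRAPH),
        key=lambda b: (-len(next(iter(fs.instances[b]))), b.value),
    )
    retained: list[FeatureId] = []
    for b in sub_feats:
        insts = fs.instances[b]
        size = len(next(iter(insts)))
        implied = False
        for f in retained:
            if len(next(iter(fs.instances[f]))) <= size:
                continue
            for container in fs.instances[f]:
                if sum(1 for inst in insts if inst <= container) >= b.tier:
                    implied = True
                    break
            if implied:
                break
        if implied:
            kept.discard(b)
        else:
            retained.append(b)

    # atom-type bits implied by a retained subgraph instance containing an
    # atom of the class (isotope-qualified bits are never implied: subgraph
    # atom labels are isotope-blind)
    atom_class_cover: set[int] = set()
    for b in kept:
        if b.kind == KIND_SUBGRAPH:
            atom_class_cover |= set(fs.coverage.get(b, frozenset()))
    for b in list(kept):
        if b.kind != KIND_ATOM_TYPE or b.tier != 1:
            continue
        if fs.counts.get(fs.base_of[b], 0) != 1:
            continue
        if b in fs.qualified:
            # subgraph atom labels are isotope-blind; nothing implies this bit
            continue
        cover = fs.coverage.get(b, frozenset())
        if cover & atom_class_cover:
            kept.discard(b)

    reduced = FeatureSet(atoms=set(fs.atoms))
    kept_bases = {fs.base_of[b] for b in kept}
    for b in kept:
        reduced.bits.add(b)
        reduced.coverage[b] = fs.coverage.get(b, frozenset())
        reduced.base_of[b] = fs.base_of[b]
        if b in fs.instances:
            reduced.instances[b] = fs.instances[b]
        if b in fs.qualified:
            reduced.qualified.add(b)
    for base, count in fs.counts.items():
        if base in kept_bases:
            reduced.counts[base] = count
    return reduced


def select_bits(
    fs: FeatureSet, table: OccurrenceTable, params: SelectionParams = SelectionParams()
) -> QueryPlan:
    """Statistical bit selection over a reduced query fingerprint.

    Bits never seen in the corpus have occurrence 0 and sort first: their
    empty posting lists legitimately screen out everything.
    """
    ranked = sorted(fs.bits, key=lambda b: (table.occurrence_of(b), b.value))
    counters = {a: 0 for a in fs.atoms}
    plan = QueryPlan()
    for bit in ranked:
        if len(plan.selected_bits) >= params.max_bits:
            plan.discarded_selected += 1
            continue
        cover = fs.coverage.get(bit, frozenset())
        if any(counters[a] < params.min_cover for a in cover):
            for a in cover:
                counters[a] += 1
            plan.selected_bits.append(bit)
        else:
            plan.discarded_selected += 1
    return plan


def search(
    index: InvertedIndex,
    query: Molecule,
    sel: SelectionParams = SelectionParams(),
    opts: MatchOptions = MatchOptions(),
) -> SearchResult:
    """Screen the index with the planned query bits, then verify every
    candidate with the matcher.

    A query whose reduced fingerprint is empty falls back to verifying the
    whole corpus (with a logged warning): it carries no screening
    information.  Matcher time-outs (state limit) are reported in
    ``undecided``, never silently dropped.
    """
    fs = fingerprint(query, index.params)
    reduced = subsumption_reduce(fs)
    plan = QueryPlan(discarded_subsumed=len(fs.bits) - len(reduced.bits))
    if sel.select_enabled:
        selection = select_bits(reduced, index.occurrence_table(), sel)
        plan.selected_bits = selection.selected_bits
        plan.discarded_selected = selection.discarded_selected
    else:
        plan.selected_bits = sorted(reduced.bits, key=lambda b: b.value)
    if not plan.selected_bits:
        logger.warning(
            "query produced no screening bits; falling back to full-corpus verification"
        )
        plan.full_scan = True
        cands = list(range(index.total))
    else:
        cands = index.candidates(plan.selected_bits)

    result = SearchResult(candidates=cands, plan=plan)
    for ordinal in cands:
        try:
            if is_substructure(query, index.molecule(ordinal), opts):
                result.verified.append(ordinal)
        except MatchUndecided:
            result.undecided.append(ordinal)
    result.true_positive_count = len(result.verified)
    result.false_positive_count = (
        len(cands) - len(result.verified) - len(result.undecided)
    )
    result.negative_count = index.total - result.true_positive_count
    return result


def screening_stats(result: SearchResult) -> tuple[float, float]:
    """(precision, fpr).  Precision is 1 when screening admitted nothing —
    no decision was wrong; FPR is 0 when there are no negatives."""
    tp = result.true_positive_count
    fp = result.false_positive_count
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    neg = result.negative_count
    fpr = 0.0 if neg <= 0 else fp / neg
    return precision, fpr


def evaluate(
    index: InvertedIndex,
    queries: Sequence[tuple[str, Molecule]],
    sel: SelectionParams = SelectionParams(),
    opts: MatchOptions = MatchOptions(),
    fpr_thresholds: Iterable[float] = (1e-1, 1e-2, 1e-3),
) -> tuple[pd.DataFrame, dict]:
    """Run every query; return a per-query table and an aggregate summary
    (median FPR/precision and the fraction of queries below each FPR
    threshold, the survival framing used for screening-efficiency curves)."""
    rows = []
    for ident, query in queries:
        result = search(index, query, sel, opts)
        precision, fpr = screening_stats(result)
        rows.append(
            {
                "query": ident,
                "n_candidates": len(result.candidates),
                "n_verified": len(result.verified),
                "n_undecided": len(result.undecided),
                "n_selected_bits": len(result.plan.selected_bits),
                "precision": precision,
                "fpr": fpr,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "query",
            "n_candidates",
            "n_verified",
            "n_undecided",
            "n_selected_bits",
            "precision",
            "fpr",
        ],
    )
    summary = {
        "n_queries": len(table),
        "median_fpr": float(table["fpr"].median()) if len(table) else 0.0,
        "median_precision": float(table["precision"].median()) if len(table) else 1.0,
    }
    for thr in fpr_thresholds:
        frac = float((table["fpr"] <= thr).mean()) if len(table) else 1.0
        summary[f"frac_fpr_le_{thr:g}"] = frac
    return table, summary
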