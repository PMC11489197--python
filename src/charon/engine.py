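"""Deterministic traversal, scoring and ranking of the decision tree.

Three-valued evaluation
-----------------------
Each predicate evaluates to TRUE, FALSE or UNKNOWN on a findings record.
A TRUE/FALSE outcome follows the corresponding branch.  An UNKNOWN
outcome is handled by *consistent resolution*: the unknown base features
of the predicate are enumerated over present/absent, each resolution is
substituted into the record, and the descent continues with the
substituted record.  Substitution persists downstream, so a branch taken
under the hypothesis "dentate hyperintensity present" cannot later be
contradicted by a node that re-examines the same feature.  Every leaf
reached through such a fork is demoted to the INDETERMINATE tier.

This gives the engine its central guarantee: the set of candidate
entities returned for a record with unknowns equals the union of the
candidate sets over all concrete resolutions of those unknowns --
missing data can widen a differential but never exclude the truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import product
from typing import Any, Iterable

from . import __version__ as _ENGINE_VERSION
from .findings import (
    FIELD_SPECS,
    AtrophyPattern,
    PatientFindings,
    TriState,
    classify_atrophy_pattern,
    findings_to_dict,
    possible_atrophy_patterns,
)
from .knowledge import (
    ANY_T2_FEATURE,
    ATROPHY_PATTERN_FEATURE,
    T2_SIGNAL_FEATURES,
    ChildRef,
    Comparator,
    LeafCluster,
    Polarity,
    Predicate,
    RuleTree,
)

__all__ = [
    "Truth",
    "Tier",
    "EngineError",
    "ProbeError",
    "TraceStep",
    "ScoredCandidate",
    "Differential",
    "evaluate_predicate",
    "traverse",
    "score_leaf",
    "rank_candidates",
    "run_charon",
    "probe_decision_boundary",
]


class Truth(Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


class Tier(str, Enum):
    """STRICT: reached without any unknown fork on its path."""

    STRICT = "strict"
    INDETERMINATE = "indeterminate"


class EngineError(RuntimeError):
    pass


class ProbeError(EngineError):
    """The requested decision boundary does not exist in the interval."""


# ---------------------------------------------------------------------------
# predicate evaluation
# ---------------------------------------------------------------------------

def _kleene_or(values: Iterable[TriState]) -> Truth:
    saw_unknown = False
    for v in values:
        if v is TriState.PRESENT:
            return Truth.TRUE
        if v is TriState.UNKNOWN:
            saw_unknown = True
    return Truth.UNKNOWN if saw_unknown else Truth.FALSE


def _negate(t: Truth) -> Truth:
    if t is Truth.TRUE:
        return Truth.FALSE
    if t is Truth.FALSE:
        return Truth.TRUE
    return Truth.UNKNOWN


def evaluate_predicate(p: Predicate, f: PatientFindings) -> Truth:
    """Three-valued evaluation of a single predicate.

    UNKNOWN is returned exactly when the available assertions are
    compatible with both outcomes (including the unresolvable
    atrophy-pattern combinations).
    """
    c = p.comparator

    if p.feature == ATROPHY_PATTERN_FEATURE:
        target = AtrophyPattern(p.state)
        possible = possible_atrophy_patterns(f)
        if AtrophyPattern.INDETERMINATE in possible:
            return Truth.UNKNOWN
        if possible == {target}:
            return Truth.TRUE
        if target in possible:
            return Truth.UNKNOWN
        return Truth.FALSE

    if p.feature == ANY_T2_FEATURE:
        result = _kleene_or(getattr(f, g) for g in T2_SIGNAL_FEATURES)
        return result if c is Comparator.IS_PRESENT else _negate(result)

    spec = FIELD_SPECS[p.feature]
    value = getattr(f, p.feature)

    if spec.kind == "tristate":
        if c not in (Comparator.IS_PRESENT, Comparator.IS_ABSENT):
            raise EngineError(f"comparator {c.value} on tri-state "
                              f"feature {p.feature}")
        if value is TriState.UNKNOWN:
            return Truth.UNKNOWN
        hit = (value is TriState.PRESENT) == (c is Comparator.IS_PRESENT)
        return Truth.TRUE if hit else Truth.FALSE

    if spec.kind == "number":
        if value is None:
            return Truth.UNKNOWN
        threshold = p.threshold
        if c is Comparator.LT:
            hit = value < threshold
        elif c is Comparator.LE:
            hit = value <= threshold
        elif c is Comparator.GT:
            hit = value > threshold
        elif c is Comparator.GE:
            hit = value >= threshold
        else:
            raise EngineError(f"comparator {c.value} on numeric "
                              f"feature {p.feature}")
        return Truth.TRUE if hit else Truth.FALSE

    # categorical
    if c is not Comparator.EQUALS_STATE:
        raise EngineError(f"comparator {c.value} on categorical "
                          f"feature {p.feature}")
    if value.value == "unknown":
        return Truth.UNKNOWN
    return Truth.TRUE if value.value == p.state else Truth.FALSE


def _unknown_tristate_bases(p: Predicate, f: PatientFindings) -> tuple[str, ...]:
    return tuple(
        name for name in p.base_features()
        if FIELD_SPECS[name].kind == "tristate"
        and getattr(f, name) is TriState.UNKNOWN
    )


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceStep:
    node_id: str
    description: str
    outcome: Truth
    branches: tuple[str, ...]  # subset of ("true", "false")
    citation: str = ""


def traverse(tree: RuleTree,
             f: PatientFindings) -> tuple[dict[str, Tier], list[TraceStep]]:
    """Descend the tree; returns reached leaves with tiers, plus the trace.

    Deterministic: identical inputs give identical leaf sets and traces.
    """
    hits: dict[str, Tier] = {}
    step_order: list[str] = []
    step_data: dict[str, dict[str, Any]] = {}

    def note_step(node_id: str, outcome: Truth, branch: str | None) -> None:
        data = step_data.get(node_id)
        if data is None:
            node = tree.nodes[node_id]
            data = {"outcome": outcome, "branches": set(),
                    "description": node.predicate.describe(),
                    "citation": node.citation}
            step_data[node_id] = data
            step_order.append(node_id)
        if branch is not None:
            data["branches"].add(branch)

    def visit_leaf(leaf_id: str, forked: bool) -> None:
        tier = Tier.INDETERMINATE if forked else Tier.STRICT
        if hits.get(leaf_id) is not Tier.STRICT:
            hits[leaf_id] = tier

    def descend(ref: ChildRef, record: PatientFindings, forked: bool) -> None:
        kind, ident = ref
        if kind == "leaf":
            visit_leaf(ident, forked)
            return
        node = tree.nodes[ident]
        outcome = evaluate_predicate(node.predicate, record)
        if outcome is Truth.TRUE:
            note_step(ident, outcome, "true")
            descend(node.if_true, record, forked)
            return
        if outcome is Truth.FALSE:
            note_step(ident, outcome, "false")
            descend(node.if_false, record, forked)
            return
        note_step(ident, outcome, None)
        unknowns = _unknown_tristate_bases(node.predicate, record)
        if unknowns:
            for combo in product((TriState.PRESENT, TriState.ABSENT),
                                 repeat=len(unknowns)):
                resolved = replace(record, **dict(zip(unknowns, combo)))
                sub = evaluate_predicate(node.predicate, resolved)
                if sub is Truth.TRUE:
                    note_step(ident, outcome, "true")
                    descend(node.if_true, resolved, True)
                elif sub is Truth.FALSE:
                    note_step(ident, outcome, "false")
                    descend(node.if_false, resolved, True)
                else:
                    # e.g. isolated hemispheric atrophy: no assigned branch
                    note_step(ident, outcome, "true")
                    note_step(ident, outcome, "false")
                    descend(node.if_true, resolved, True)
                    descend(node.if_false, resolved, True)
        else:
            # unknown numeric value (or irreducibly unassigned pattern)
            note_step(ident, outcome, "true")
            note_step(ident, outcome, "false")
            descend(node.if_true, record, True)
            descend(node.if_false, record, True)

    descend(tree.root, f, False)

    trace = [
        TraceStep(
            node_id=node_id,
            description=step_data[node_id]["description"],
            outcome=step_data[node_id]["outcome"],
            branches=tuple(
                b for b in ("true", "false")
                if b in step_data[node_id]["branches"]),
            citation=step_data[node_id]["citation"],
        )
        for node_id in step_order
    ]
    return hits, trace


# ---------------------------------------------------------------------------
# scoring and ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredCandidate:
    entity: str
    tier: Tier
    supports: int
    contradictions: int
    leaf_ids: tuple[str, ...]
    fired: tuple[str, ...] = ()  # citations of fired discriminators


def score_leaf(leaf: LeafCluster, f: PatientFindings,
               tier: Tier = Tier.STRICT) -> list[ScoredCandidate]:
    """Count satisfied discriminators per candidate, split by polarity.

    Discriminators whose predicate evaluates UNKNOWN count for neither
    supports nor contradictions.
    """
    supports: dict[str, int] = {code: 0 for code in leaf.candidates}
    contras: dict[str, int] = {code: 0 for code in leaf.candidates}
    fired: dict[str, list[str]] = {code: [] for code in leaf.candidates}
    for d in leaf.discriminators:
        if evaluate_predicate(d.predicate, f) is not Truth.TRUE:
            continue
        if d.polarity is Polarity.SUPPORTS:
            supports[d.entity] += 1
            fired[d.entity].append(f"+ {d.citation or d.predicate.describe()}")
        else:
            contras[d.entity] += 1
            fired[d.entity].append(f"- {d.citation or d.predicate.describe()}")
    return [
        ScoredCandidate(entity=code, tier=tier,
                        supports=supports[code],
                        contradictions=contras[code],
                        leaf_ids=(leaf.leaf_id,),
                        fired=tuple(fired[code]))
        for code in leaf.candidates
    ]


@dataclass(frozen=True)
class Differential:
    """Ranked differential with full decision trace."""

    candidates: tuple[ScoredCandidate, ...]
    trace: tuple[TraceStep, ...] = ()
    atrophy_pattern: AtrophyPattern | None = None
    kb_version: str = ""
    engine_version: str = _ENGINE_VERSION
    input_digest: str = ""

    def entity_set(self) -> frozenset[str]:
        return frozenset(c.entity for c in self.candidates)

    def top(self, n: int = 1) -> tuple[str, ...]:
        return tuple(c.entity for c in self.candidates[:n])

    def to_dict(self) -> dict[str, Any]:
        return {
            "atrophy_pattern": (self.atrophy_pattern.value
                                if self.atrophy_pattern else None),
            "candidates": [
                {
                    "entity": c.entity,
                    "tier": c.tier.value,
                    "supports": c.supports,
                    "contradictions": c.contradictions,
                    "leaves": list(c.leaf_ids),
                    "fired": list(c.fired),
                }
                for c in self.candidates
            ],
            "trace": [
                {
                    "node": s.node_id,
                    "predicate": s.description,
                    "outcome": s.outcome.value,
                    "branches": list(s.branches),
                    "citation": s.citation,
                }
                for s in self.trace
            ],
            "kb_version": self.kb_version,
            "engine_version": self.engine_version,
            "input_digest": self.input_digest,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def render(self) -> str:
        """Human-readable narrative report."""
        lines = ["CHARON differential"]
        if self.atrophy_pattern is not None:
            lines.append(
                f"cerebellar atrophy pattern: {self.atrophy_pattern.value}")
        lines.append("")
        lines.append("decision path:")
        for s in self.trace:
            arrow = "/".join(s.branches) or "-"
            lines.append(f"  [{s.node_id}] {s.description} "
                         f"-> {s.outcome.value} (branch: {arrow})")
        lines.append("")
        lines.append("ranked candidates:")
        lines.append(f"  {'#':>2}  {'entity':<8} {'tier':<13} "
                     f"{'support':>7} {'against':>7}  leaves")
        for i, c in enumerate(self.candidates, start=1):
            lines.append(
                f"  {i:>2}  {c.entity:<8} {c.tier.value:<13} "
                f"{c.supports:>7} {c.contradictions:>7}  "
                f"{','.join(c.leaf_ids)}")
            for note in c.fired:
                lines.append(f"        {note}")
        return "\n".join(lines)


def _rank_key(tree: RuleTree):
    def key(c: ScoredCandidate):
        rank = tree.entities[c.entity].prevalence_rank \
            if c.entity in tree.entities else 10 ** 6
        return (0 if c.tier is Tier.STRICT else 1,
                -c.supports, c.contradictions, rank, c.entity)
    return key


def rank_candidates(cands: Iterable[ScoredCandidate],
                    tree: RuleTree, **extra: Any) -> Differential:
    """Total ordering: STRICT tier first, then supports descending,
    contradictions ascending, prevalence rank ascending, entity code."""
    cands = list(cands)
    if not cands:
        raise EngineError("cannot rank an empty candidate list")
    ordered = tuple(sorted(cands, key=_rank_key(tree)))
    return Differential(candidates=ordered, kb_version=tree.version, **extra)


def _merge(existing: ScoredCandidate, new: ScoredCandidate) -> ScoredCandidate:
    """Multi-leaf merge: best tier, max supports, min contradictions."""
    return ScoredCandidate(
        entity=existing.entity,
        tier=Tier.STRICT if Tier.STRICT in (existing.tier, new.tier)
        else Tier.INDETERMINATE,
        supports=max(existing.supports, new.supports),
        contradictions=min(existing.contradictions, new.contradictions),
        leaf_ids=existing.leaf_ids + new.leaf_ids,
        fired=existing.fired + tuple(
            n for n in new.fired if n not in existing.fired),
    )


def run_charon(f: PatientFindings, tree: RuleTree) -> Differential:
    """Full pipeline: pattern -> traversal -> scoring -> ranked differential."""
    pattern = classify_atrophy_pattern(f)
    hits, trace = traverse(tree, f)
    merged: dict[str, ScoredCandidate] = {}
    for leaf_id, tier in hits.items():
        for cand in score_leaf(tree.leaves[leaf_id], f, tier):
            if cand.entity in merged:
                merged[cand.entity] = _merge(merged[cand.entity], cand)
            else:
                merged[cand.entity] = cand
    digest = hashlib.sha256(
        json.dumps(findings_to_dict(f), sort_keys=True).encode()
    ).hexdigest()[:16]
    return rank_candidates(
        merged.values(), tree,
        trace=tuple(trace),
        atrophy_pattern=pattern,
        input_digest=digest,
    )


# ---------------------------------------------------------------------------
# decision-boundary probing
# ---------------------------------------------------------------------------

def probe_decision_boundary(tree: RuleTree, template: PatientFindings,
                            feature: str, lo: float, hi: float,
                            tol: float = 0.01) -> float:
    """Bisect the value of a numeric feature at which the top-1 entity
    switches; deterministic.

    Raises :class:`ProbeError` when the top-1 entity does not differ
    between ``feature=lo`` and ``feature=hi`` (including the case where
    the feature is never tested on the active path).
    """
    if FIELD_SPECS.get(feature) is None or FIELD_SPECS[feature].kind != "number":
        raise ProbeError(f"{feature!r} is not a numeric findings field")
    if not lo < hi:
        raise ProbeError(f"need lo < hi, got [{lo}, {hi}]")
    if tol <= 0:
        raise ProbeError("tolerance must be positive")

    def top1(value: float) -> str:
        probe = replace(template, **{feature: value})
        return run_charon(probe, tree).candidates[0].entity

    at_lo = top1(lo)
    at_hi = top1(hi)
    if at_lo == at_hi:
        raise ProbeError(
            f"top-1 entity ({at_lo}) does not switch over "
            f"{feature} in [{lo}, {hi}]")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if top1(mid) == at_lo:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
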