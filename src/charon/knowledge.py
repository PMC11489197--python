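"""Declarative knowledge base: the decision tree the engine walks.

The tree is pure data -- predicate nodes, leaf clusters of candidate
entities, and per-entity discriminators -- loaded from YAML (or an
equivalent mapping) and validated structurally before use.  Every node
and discriminator carries a citation string naming the radiological or
clinical rationale for the split, so a differential can always be
audited back to its source statements.

Two *derived* features may appear in predicates in addition to the raw
findings fields:

``atrophy_pattern``
    The top-level cerebellar atrophy classification (global /
    selective_vermian / none), derived from the three atrophy
    components.

``mri_any_infratentorial_t2_change``
    Three-valued OR over the T2-signal features (dentate hyperintensity,
    Hot Cross Bun sign, middle-cerebellar-peduncle, splenium and lateral
    pontine lesions): present if any is present, absent if all are
    absent, otherwise unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

from .findings import (
    ATROPHY_COMPONENT_FIELDS,
    FIELD_SPECS,
    AtrophyPattern,
)

__all__ = [
    "ATROPHY_PATTERN_FEATURE",
    "ANY_T2_FEATURE",
    "T2_SIGNAL_FEATURES",
    "Comparator",
    "Polarity",
    "Predicate",
    "Entity",
    "Discriminator",
    "DecisionNode",
    "LeafCluster",
    "RuleTree",
    "KBError",
    "KBLoadError",
    "KBIntegrityError",
    "load_knowledge_base",
    "default_knowledge_base",
    "default_kb_text",
    "validate_tree",
    "ValidationReport",
    "enumerate_paths",
    "LeafPath",
    "PathStep",
    "paths_to_markdown",
    "paths_to_dot",
    "top_level_branches",
    "group_a_t2_node",
    "signal_pattern_branches",
    "onset_split_decade",
]

ATROPHY_PATTERN_FEATURE = "atrophy_pattern"
ANY_T2_FEATURE = "mri_any_infratentorial_t2_change"
T2_SIGNAL_FEATURES: tuple[str, ...] = (
    "mri_dn_t2_hyperintensity",
    "mri_hcb_sign",
    "mri_mcp_wm_lesions",
    "mri_splenium_wm_lesions",
    "mri_lateral_pons_lesions",
)

_ATROPHY_PATTERN_STATES = ("global", "selective_vermian", "none")

DEFAULT_KB_RESOURCE = "charon_kb.yaml"


class KBError(ValueError):
    pass


class KBLoadError(KBError):
    """The document does not conform to the knowledge-base schema."""


class KBIntegrityError(KBError):
    """The document parses but violates a structural invariant."""


class Comparator(str, Enum):
    IS_PRESENT = "is_present"
    IS_ABSENT = "is_absent"
    LT = "lt"
    LE = "le"
    GT = "gt"
    GE = "ge"
    EQUALS_STATE = "equals_state"


_NUMERIC_COMPARATORS = {Comparator.LT, Comparator.LE,
                        Comparator.GT, Comparator.GE}
_COMPARATOR_SYMBOL = {Comparator.LT: "<", Comparator.LE: "<=",
                      Comparator.GT: ">", Comparator.GE: ">="}


class Polarity(str, Enum):
    SUPPORTS = "supports"
    CONTRADICTS = "contradicts"


@dataclass(frozen=True)
class Predicate:
    """A single three-valued test on a findings record."""

    feature: str
    comparator: Comparator
    threshold: float | None = None
    state: str | None = None
    unit: str | None = None

    def describe(self) -> str:
        if self.comparator in (Comparator.IS_PRESENT, Comparator.IS_ABSENT):
            word = "present" if self.comparator is Comparator.IS_PRESENT \
                else "absent"
            return f"{self.feature} is {word}"
        if self.comparator is Comparator.EQUALS_STATE:
            return f"{self.feature} = {self.state}"
        unit = f" {self.unit}" if self.unit else ""
        return (f"{self.feature} "
                f"{_COMPARATOR_SYMBOL[self.comparator]} {self.threshold}{unit}")

    def base_features(self) -> tuple[str, ...]:
        """Concrete findings fields this predicate depends on."""
        if self.feature == ATROPHY_PATTERN_FEATURE:
            return ATROPHY_COMPONENT_FIELDS
        if self.feature == ANY_T2_FEATURE:
            return T2_SIGNAL_FEATURES
        return (self.feature,)

    def problems(self) -> list[str]:
        """Schema/typing problems; empty when well-formed."""
        issues: list[str] = []
        c = self.comparator
        if self.feature == ATROPHY_PATTERN_FEATURE:
            if c is not Comparator.EQUALS_STATE:
                issues.append(f"{self.feature} only admits equals_state")
            elif self.state not in _ATROPHY_PATTERN_STATES:
                issues.append(
                    f"invalid atrophy pattern state {self.state!r}")
            return issues
        if self.feature == ANY_T2_FEATURE:
            if c not in (Comparator.IS_PRESENT, Comparator.IS_ABSENT):
                issues.append(
                    f"{self.feature} only admits is_present/is_absent")
            return issues
        spec = FIELD_SPECS.get(self.feature)
        if spec is None:
            issues.append(f"unknown feature {self.feature!r}")
            return issues
        if c in (Comparator.IS_PRESENT, Comparator.IS_ABSENT):
            if spec.kind != "tristate":
                issues.append(
                    f"{c.value} requires a tri-state feature, "
                    f"{self.feature} is {spec.kind}")
        elif c in _NUMERIC_COMPARATORS:
            if spec.kind != "number":
                issues.append(
                    f"{c.value} requires a numeric feature, "
                    f"{self.feature} is {spec.kind}")
            elif not isinstance(self.threshold, (int, float)) \
                    or isinstance(self.threshold, bool):
                issues.append("numeric comparator needs a numeric threshold")
            elif self.threshold < 0:
                issues.append("threshold must be non-negative")
            if self.unit is not None and spec.unit is not None \
                    and self.unit != spec.unit:
                issues.append(
                    f"threshold unit {self.unit!r} incompatible with "
                    f"feature unit {spec.unit!r}")
        elif c is Comparator.EQUALS_STATE:
            if spec.kind != "category":
                issues.append(
                    f"equals_state requires a categorical feature, "
                    f"{self.feature} is {spec.kind}")
            elif self.state not in spec.states or self.state == "unknown":
                issues.append(f"invalid state {self.state!r} for "
                              f"{self.feature}")
        return issues


@dataclass(frozen=True)
class Entity:
    code: str
    full_name: str
    prevalence_rank: int


@dataclass(frozen=True)
class Discriminator:
    entity: str
    predicate: Predicate
    polarity: Polarity
    citation: str = ""


# child references: ("node", id) or ("leaf", id)
ChildRef = tuple[str, str]


@dataclass(frozen=True)
class DecisionNode:
    node_id: str
    predicate: Predicate
    if_true: ChildRef
    if_false: ChildRef
    citation: str = ""


@dataclass(frozen=True)
class LeafCluster:
    leaf_id: str
    candidates: tuple[str, ...]
    discriminators: tuple[Discriminator, ...] = ()
    pattern: str | None = None
    citation: str = ""


@dataclass(frozen=True)
class RuleTree:
    version: str
    entities: dict[str, Entity]
    nodes: dict[str, DecisionNode]
    leaves: dict[str, LeafCluster]
    root: ChildRef
    constants: dict[str, float] = field(default_factory=dict)

    def resolve(self, ref: ChildRef) -> DecisionNode | LeafCluster:
        kind, ident = ref
        table = self.nodes if kind == "node" else self.leaves
        return table[ident]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _as_ref(raw: Any, where: str) -> ChildRef:
    if not isinstance(raw, Mapping) or len(raw) != 1:
        raise KBLoadError(
            f"{where}: child reference must be a one-key mapping "
            "{node: id} or {leaf: id}")
    (kind, ident), = raw.items()
    if kind not in ("node", "leaf") or not isinstance(ident, str):
        raise KBLoadError(f"{where}: invalid child reference {raw!r}")
    return (kind, ident)


def _parse_predicate(raw: Mapping[str, Any], where: str) -> Predicate:
    try:
        comparator = Comparator(raw["comparator"])
    except KeyError:
        raise KBLoadError(f"{where}: missing comparator") from None
    except ValueError:
        raise KBLoadError(
            f"{where}: unknown comparator {raw['comparator']!r}") from None
    feature = raw.get("feature")
    if not isinstance(feature, str):
        raise KBLoadError(f"{where}: missing feature name")
    pred = Predicate(
        feature=feature,
        comparator=comparator,
        threshold=raw.get("threshold"),
        state=raw.get("state"),
        unit=raw.get("unit"),
    )
    issues = pred.problems()
    if issues:
        raise KBLoadError(f"{where}: {'; '.join(issues)}")
    return pred


def load_knowledge_base(source: Mapping[str, Any] | str | Path) -> RuleTree:
    """Load and structurally validate a knowledge-base document.

    ``source`` may be an already-parsed mapping or a filesystem path to
    a YAML/JSON document.  Schema violations raise :class:`KBLoadError`
    with the path to the offending element; structural violations
    (cycles, dangling references, duplicate parents, discriminators on
    unknown entities) raise :class:`KBIntegrityError`.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, Mapping):
        raise KBLoadError("knowledge base document must be a mapping")

    version = str(doc.get("version", "0"))
    constants = dict(doc.get("constants", {}) or {})

    raw_entities = doc.get("entities")
    if not isinstance(raw_entities, list) or not raw_entities:
        raise KBLoadError("entities: must be a non-empty list")
    entities: dict[str, Entity] = {}
    for i, raw in enumerate(raw_entities):
        where = f"entities[{i}]"
        try:
            ent = Entity(code=str(raw["code"]),
                         full_name=str(raw["full_name"]),
                         prevalence_rank=int(raw["prevalence_rank"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise KBLoadError(f"{where}: {exc}") from None
        if ent.code in entities:
            raise KBIntegrityError(f"{where}: duplicate entity {ent.code}")
        entities[ent.code] = ent
    ranks = sorted(e.prevalence_rank for e in entities.values())
    if ranks != list(range(1, len(entities) + 1)):
        raise KBIntegrityError(
            "entities: prevalence_rank values must be a permutation of "
            f"1..{len(entities)}")

    nodes: dict[str, DecisionNode] = {}
    for i, raw in enumerate(doc.get("nodes") or []):
        where = f"nodes[{i}]"
        node_id = raw.get("id")
        if not isinstance(node_id, str):
            raise KBLoadError(f"{where}: missing id")
        if node_id in nodes:
            raise KBIntegrityError(f"{where}: duplicate node id {node_id}")
        nodes[node_id] = DecisionNode(
            node_id=node_id,
            predicate=_parse_predicate(raw, where),
            if_true=_as_ref(raw.get("if_true"), f"{where}.if_true"),
            if_false=_as_ref(raw.get("if_false"), f"{where}.if_false"),
            citation=str(raw.get("citation", "")),
        )

    leaves: dict[str, LeafCluster] = {}
    raw_leaves = doc.get("leaves")
    if not isinstance(raw_leaves, list) or not raw_leaves:
        raise KBLoadError("leaves: must be a non-empty list")
    for i, raw in enumerate(raw_leaves):
        where = f"leaves[{i}]"
        leaf_id = raw.get("id")
        if not isinstance(leaf_id, str):
            raise KBLoadError(f"{where}: missing id")
        if leaf_id in leaves:
            raise KBIntegrityError(f"{where}: duplicate leaf id {leaf_id}")
        candidates = raw.get("candidates")
        if not isinstance(candidates, list) or not candidates:
            raise KBLoadError(f"{where}: candidates must be non-empty")
        for code in candidates:
            if code not in entities:
                raise KBIntegrityError(
                    f"{where}: unknown entity code {code!r}")
        discriminators: list[Discriminator] = []
        for j, rawd in enumerate(raw.get("discriminators") or []):
            dwhere = f"{where}.discriminators[{j}]"
            code = rawd.get("entity")
            if code not in entities:
                raise KBIntegrityError(
                    f"{dwhere}: unknown entity code {code!r}")
            if code not in candidates:
                raise KBIntegrityError(
                    f"{dwhere}: {code} is not a candidate of {leaf_id}")
            try:
                polarity = Polarity(rawd.get("polarity"))
            except ValueError:
                raise KBLoadError(
                    f"{dwhere}: invalid polarity "
                    f"{rawd.get('polarity')!r}") from None
            discriminators.append(Discriminator(
                entity=code,
                predicate=_parse_predicate(rawd, dwhere),
                polarity=polarity,
                citation=str(rawd.get("citation", "")),
            ))
        leaves[leaf_id] = LeafCluster(
            leaf_id=leaf_id,
            candidates=tuple(candidates),
            discriminators=tuple(discriminators),
            pattern=raw.get("pattern"),
            citation=str(raw.get("citation", "")),
        )

    root = _as_ref(doc.get("root"), "root")
    tree = RuleTree(version=version, entities=entities, nodes=nodes,
                    leaves=leaves, root=root, constants=constants)
    _check_structure(tree)
    return tree


def _check_structure(tree: RuleTree) -> None:
    """Rooted-binary-tree integrity: refs resolve, one parent, no cycles."""
    seen: set[ChildRef] = set()

    def walk(ref: ChildRef, path: tuple[str, ...]) -> None:
        kind, ident = ref
        table = tree.nodes if kind == "node" else tree.leaves
        if ident not in table:
            raise KBIntegrityError(
                f"dangling reference to {kind} {ident!r} "
                f"(path: {' -> '.join(path) or 'root'})")
        if ref in seen:
            raise KBIntegrityError(
                f"{kind} {ident!r} reached twice (cycle or duplicate "
                f"parent; path: {' -> '.join(path) or 'root'})")
        seen.add(ref)
        if kind == "node":
            node = tree.nodes[ident]
            walk(node.if_true, path + (ident,))
            walk(node.if_false, path + (ident,))

    walk(tree.root, ())


def default_kb_text() -> str:
    """The packaged default knowledge base, verbatim YAML."""
    return (resources.files("charon") / "data"
            / DEFAULT_KB_RESOURCE).read_text()


def default_knowledge_base() -> RuleTree:
    return load_knowledge_base(yaml.safe_load(default_kb_text()))


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    unreachable_nodes: tuple[str, ...]
    unreachable_leaves: tuple[str, ...]
    uncovered_entities: tuple[str, ...]
    predicate_problems: tuple[str, ...]
    discriminator_problems: tuple[str, ...]
    n_entities: int
    n_reachable_entities: int

    @property
    def passed(self) -> bool:
        return not (self.unreachable_nodes or self.unreachable_leaves
                    or self.uncovered_entities or self.predicate_problems
                    or self.discriminator_problems)

    def render(self) -> str:
        lines = [
            f"knowledge base validation: {'PASS' if self.passed else 'FAIL'}",
            f"{self.n_reachable_entities}/{self.n_entities} "
            "entities reachable",
        ]
        for label, items in (
            ("unreachable nodes", self.unreachable_nodes),
            ("unreachable leaves", self.unreachable_leaves),
            ("entities never appearing in a leaf", self.uncovered_entities),
            ("predicate problems", self.predicate_problems),
            ("discriminator problems", self.discriminator_problems),
        ):
            if items:
                lines.append(f"{label}: {', '.join(items)}")
        return "\n".join(lines)


def validate_tree(tree: RuleTree) -> ValidationReport:
    """Full validation report; never raises."""
    reachable: set[ChildRef] = set()
    stack = [tree.root]
    while stack:
        ref = stack.pop()
        if ref in reachable:
            continue
        kind, ident = ref
        table = tree.nodes if kind == "node" else tree.leaves
        if ident not in table:
            continue  # dangling refs surface as unreachable targets
        reachable.add(ref)
        if kind == "node":
            node = tree.nodes[ident]
            stack.append(node.if_true)
            stack.append(node.if_false)

    unreachable_nodes = tuple(sorted(
        n for n in tree.nodes if ("node", n) not in reachable))
    unreachable_leaves = tuple(sorted(
        l for l in tree.leaves if ("leaf", l) not in reachable))

    covered: set[str] = set()
    for leaf_id, leaf in tree.leaves.items():
        if ("leaf", leaf_id) in reachable:
            covered.update(leaf.candidates)
    uncovered = tuple(sorted(set(tree.entities) - covered))

    predicate_problems: list[str] = []
    for node in tree.nodes.values():
        for issue in node.predicate.problems():
            predicate_problems.append(f"node {node.node_id}: {issue}")

    discriminator_problems: list[str] = []
    for leaf in tree.leaves.values():
        for d in leaf.discriminators:
            if d.entity not in leaf.candidates:
                discriminator_problems.append(
                    f"leaf {leaf.leaf_id}: discriminator entity {d.entity} "
                    "not a candidate")
            for issue in d.predicate.problems():
                discriminator_problems.append(
                    f"leaf {leaf.leaf_id} ({d.entity}): {issue}")

    return ValidationReport(
        unreachable_nodes=unreachable_nodes,
        unreachable_leaves=unreachable_leaves,
        uncovered_entities=uncovered,
        predicate_problems=tuple(predicate_problems),
        discriminator_problems=tuple(discriminator_problems),
        n_entities=len(tree.entities),
        n_reachable_entities=len(covered),
    )


# ---------------------------------------------------------------------------
# path enumeration / export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStep:
    node_id: str
    predicate: Predicate
    taken: bool  # branch polarity on the way to the leaf


@dataclass(frozen=True)
class LeafPath:
    leaf_id: str
    steps: tuple[PathStep, ...]


def enumerate_paths(tree: RuleTree) -> list[LeafPath]:
    """Root-to-leaf predicate chains, one entry per reachable leaf."""
    out: list[LeafPath] = []

    def walk(ref: ChildRef, steps: tuple[PathStep, ...]) -> None:
        kind, ident = ref
        if kind == "leaf":
            out.append(LeafPath(leaf_id=ident, steps=steps))
            return
        node = tree.nodes[ident]
        walk(node.if_true,
             steps + (PathStep(node.node_id, node.predicate, True),))
        walk(node.if_false,
             steps + (PathStep(node.node_id, node.predicate, False),))

    walk(tree.root, ())
    return out


def paths_to_markdown(tree: RuleTree) -> str:
    lines = ["| leaf | candidates | decision path |",
             "| --- | --- | --- |"]
    for path in enumerate_paths(tree):
        leaf = tree.leaves[path.leaf_id]
        chain = " AND ".join(
            ("" if s.taken else "NOT ") + s.predicate.describe()
            for s in path.steps) or "(root)"
        lines.append(
            f"| {path.leaf_id} | {', '.join(leaf.candidates)} | {chain} |")
    return "\n".join(lines)


def paths_to_dot(tree: RuleTree) -> str:
    """Graph description (DOT) for visualization."""
    lines = ["digraph charon {", "  rankdir=TB;"]
    for node in tree.nodes.values():
        label = node.predicate.describe().replace('"', "'")
        lines.append(f'  "{node.node_id}" [shape=box, label="{label}"];')
    for leaf in tree.leaves.values():
        label = f"{leaf.leaf_id}\\n{', '.join(leaf.candidates)}"
        lines.append(f'  "{leaf.leaf_id}" '
                     f'[shape=ellipse, label="{label}"];')
    for node in tree.nodes.values():
        for ref, polarity in ((node.if_true, "yes"), (node.if_false, "no")):
            lines.append(f'  "{node.node_id}" -> "{ref[1]}" '
                         f'[label="{polarity}"];')
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# structural metrics (used for documentation and acceptance checks)
# ---------------------------------------------------------------------------

def top_level_branches(tree: RuleTree) -> tuple[ChildRef, ...]:
    """The subtrees hanging off the root split (the major classes)."""
    kind, ident = tree.root
    if kind == "leaf":
        return ()
    node = tree.nodes[ident]
    return (node.if_true, node.if_false)


def _iter_subtree(tree: RuleTree, ref: ChildRef) -> Iterator[ChildRef]:
    yield ref
    kind, ident = ref
    if kind == "node":
        node = tree.nodes[ident]
        yield from _iter_subtree(tree, node.if_true)
        yield from _iter_subtree(tree, node.if_false)


def group_a_t2_node(tree: RuleTree) -> DecisionNode:
    """First node testing any-infratentorial-T2-change in the global-atrophy
    subtree (the split that opens the signal-change pattern branches)."""
    kind, ident = tree.root
    if kind != "node":
        raise KBError("degenerate tree has no group A subtree")
    for ref in _iter_subtree(tree, tree.nodes[ident].if_true):
        if ref[0] == "node":
            node = tree.nodes[ref[1]]
            if node.predicate.feature == ANY_T2_FEATURE:
                return node
    raise KBError("no infratentorial T2-change split found in group A")


def signal_pattern_branches(tree: RuleTree) -> tuple[str, ...]:
    """Distinct signal-change pattern labels under the group A T2 split."""
    node = group_a_t2_node(tree)
    labels = {
        tree.leaves[ref[1]].pattern
        for ref in _iter_subtree(tree, node.if_true)
        if ref[0] == "leaf" and tree.leaves[ref[1]].pattern
    }
    return tuple(sorted(labels))


def onset_split_decade(tree: RuleTree) -> int:
    """Decade ordinal encoded by the onset-age splits (end-of-decade cut).

    All onset predicates in the tree must agree on a single year
    boundary that is a whole number of decades.
    """
    thresholds = {
        node.predicate.threshold
        for node in tree.nodes.values()
        if node.predicate.feature == "onset_age_years"
    }
    if len(thresholds) != 1:
        raise KBError(f"inconsistent onset boundaries: {sorted(thresholds)}")
    (boundary,) = thresholds
    if boundary is None or boundary % 10 != 0:
        raise KBError(f"onset boundary {boundary!r} is not a whole decade")
    return int(boundary // 10)
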