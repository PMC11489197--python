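"""Independent brute-force path evaluator used to cross-check traversal.

Semantics asserted: the leaves reached for a partial record are exactly
the leaves reached by walking each *fully-resolved* variant of the
record (every unknown tri-state feature the tree can test set to
present/absent in all combinations) down the tree; a leaf is strict iff
every resolution lands on exactly that one leaf.

Everything here is written from scratch (including predicate
evaluation) so it shares no code path with the engine under test.
"""

from dataclasses import replace
from itertools import product

from charon.findings import FIELD_SPECS, PatientFindings, TriState


def _pattern_of(f: PatientFindings) -> str:
    sup = f.mri_vermis_superior_atrophy
    inf = f.mri_vermis_inferior_atrophy
    hemi = f.mri_hemispheric_atrophy
    vermian = TriState.PRESENT in (sup, inf)
    if hemi is TriState.PRESENT and vermian:
        return "global"
    if hemi is TriState.ABSENT and vermian:
        return "selective_vermian"
    if (sup, inf, hemi) == (TriState.ABSENT,) * 3:
        return "none"
    return "indeterminate"


_T2 = ("mri_dn_t2_hyperintensity", "mri_hcb_sign", "mri_mcp_wm_lesions",
       "mri_splenium_wm_lesions", "mri_lateral_pons_lesions")


def _eval(pred, f: PatientFindings) -> str:
    """'true' / 'false' / 'unknown' on an (ideally resolved) record."""
    c = pred.comparator.value
    if pred.feature == "atrophy_pattern":
        pattern = _pattern_of(f)
        if pattern == "indeterminate":
            return "unknown"
        return "true" if pattern == pred.state else "false"
    if pred.feature == "mri_any_infratentorial_t2_change":
        values = [getattr(f, g) for g in _T2]
        if TriState.PRESENT in values:
            hit = True
        elif TriState.UNKNOWN in values:
            return "unknown"
        else:
            hit = False
        return "true" if hit == (c == "is_present") else "false"
    value = getattr(f, pred.feature)
    kind = FIELD_SPECS[pred.feature].kind
    if kind == "tristate":
        if value is TriState.UNKNOWN:
            return "unknown"
        hit = (value is TriState.PRESENT) == (c == "is_present")
        return "true" if hit else "false"
    if kind == "number":
        if value is None:
            return "unknown"
        hit = {"lt": value < pred.threshold, "le": value <= pred.threshold,
               "gt": value > pred.threshold, "ge": value >= pred.threshold}[c]
        return "true" if hit else "false"
    if value.value == "unknown":
        return "unknown"
    return "true" if value.value == pred.state else "false"


def _walk(tree, f: PatientFindings) -> frozenset[str]:
    """Leaves reached by one record, following both branches only where
    a predicate is irreducibly unresolvable (e.g. unknown numerics or an
    unassignable atrophy combination)."""
    reached: set[str] = set()
    stack = [tree.root]
    while stack:
        kind, ident = stack.pop()
        if kind == "leaf":
            reached.add(ident)
            continue
        node = tree.nodes[ident]
        outcome = _eval(node.predicate, f)
        if outcome == "true":
            stack.append(node.if_true)
        elif outcome == "false":
            stack.append(node.if_false)
        else:
            stack.append(node.if_true)
            stack.append(node.if_false)
    return frozenset(reached)


def brute_force_traverse(tree, f: PatientFindings) -> dict[str, str]:
    """leaf_id -> 'strict' | 'indeterminate' by exhaustive resolution."""
    testable = sorted({
        base for node in tree.nodes.values()
        for base in node.predicate.base_features()
        if FIELD_SPECS[base].kind == "tristate"
        and getattr(f, base) is TriState.UNKNOWN
    })
    leaf_sets = []
    for combo in product((TriState.PRESENT, TriState.ABSENT),
                         repeat=len(testable)):
        resolved = replace(f, **dict(zip(testable, combo)))
        leaf_sets.append(_walk(tree, resolved))
    union = frozenset().union(*leaf_sets)
    return {
        leaf: ("strict" if all(ls == {leaf} for ls in leaf_sets)
               else "indeterminate")
        for leaf in union
    }
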