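"""Inference engine: three-valued evaluation, traversal, ranking, probing."""

from dataclasses import replace
from itertools import product

import numpy as np
import pytest

from _oracle import brute_force_traverse
from conftest import GLOBAL_ATROPHY, NO_SIGNAL_CHANGES, random_findings

from charon.engine import (
    EngineError,
    ProbeError,
    ScoredCandidate,
    Tier,
    Truth,
    evaluate_predicate,
    probe_decision_boundary,
    rank_candidates,
    run_charon,
    score_leaf,
    traverse,
)
from charon.findings import PatientFindings, TriState, parse_findings
from charon.knowledge import (
    Comparator,
    Predicate,
    load_knowledge_base,
)
from charon.vignettes import canonical_vignette

AFP_LT_15 = Predicate(feature="lab_afp_ug_per_L",
                      comparator=Comparator.LT, threshold=15)


class TestEvaluatePredicate:
    def test_afp_below_cutoff_is_true(self):
        f = parse_findings({"lab_afp_ug_per_L": 10})
        assert evaluate_predicate(AFP_LT_15, f) is Truth.TRUE

    def test_boundary_is_strict(self):
        f = parse_findings({"lab_afp_ug_per_L": 15})
        assert evaluate_predicate(AFP_LT_15, f) is Truth.FALSE

    def test_unknown_value_gives_unknown(self):
        assert evaluate_predicate(AFP_LT_15, PatientFindings()) \
            is Truth.UNKNOWN
        tri = Predicate(feature="mri_hcb_sign",
                        comparator=Comparator.IS_PRESENT)
        assert evaluate_predicate(tri, PatientFindings()) is Truth.UNKNOWN

    @pytest.mark.parametrize("state,expected", [
        ("present", Truth.TRUE), ("absent", Truth.FALSE)])
    def test_tristate_mapping(self, state, expected):
        tri = Predicate(feature="mri_hcb_sign",
                        comparator=Comparator.IS_PRESENT)
        f = parse_findings({"mri_hcb_sign": state})
        assert evaluate_predicate(tri, f) is expected

    def test_any_t2_is_three_valued_or(self):
        pred = Predicate(feature="mri_any_infratentorial_t2_change",
                         comparator=Comparator.IS_PRESENT)
        one_present = parse_findings({"mri_splenium_wm_lesions": "present"})
        assert evaluate_predicate(pred, one_present) is Truth.TRUE
        all_absent = parse_findings(dict(NO_SIGNAL_CHANGES))
        assert evaluate_predicate(pred, all_absent) is Truth.FALSE
        partial = parse_findings({"mri_dn_t2_hyperintensity": "absent"})
        assert evaluate_predicate(pred, partial) is Truth.UNKNOWN

    def test_atrophy_pattern_respects_possible_resolutions(self):
        pred = Predicate(feature="atrophy_pattern",
                         comparator=Comparator.EQUALS_STATE, state="none")
        # superior vermis atrophic, hemispheres unknown: the pattern may
        # be global or selective, but it cannot be "none"
        f = parse_findings({"mri_vermis_superior_atrophy": "present",
                            "mri_vermis_inferior_atrophy": "absent"})
        assert evaluate_predicate(pred, f) is Truth.FALSE
        as_global = Predicate(feature="atrophy_pattern",
                              comparator=Comparator.EQUALS_STATE,
                              state="global")
        assert evaluate_predicate(as_global, f) is Truth.UNKNOWN


class TestTraverse:
    def test_resolved_dentate_case_hits_single_strict_leaf(self, tree):
        f = parse_findings({**GLOBAL_ATROPHY, **NO_SIGNAL_CHANGES,
                            "mri_dn_t2_hyperintensity": "present",
                            "mri_swi_low_signal_around_dn": "absent",
                            "onset_age_years": 70})
        hits, trace = traverse(tree, f)
        assert hits == {"a_dn_adult": Tier.STRICT}
        assert [s.node_id for s in trace][0] == "atrophy_global"
        assert all(s.outcome is not Truth.UNKNOWN for s in trace)

    def test_all_unknown_reaches_every_leaf_indeterminate(self, tree):
        hits, _ = traverse(tree, PatientFindings())
        assert set(hits) == set(tree.leaves)
        assert set(hits.values()) == {Tier.INDETERMINATE}

    def test_unknown_fork_equals_union_of_resolutions(self, tree):
        base = {**GLOBAL_ATROPHY, **NO_SIGNAL_CHANGES,
                "onset_age_years": 45,
                "mri_swi_low_signal_around_dn": "absent"}
        masked = dict(base)
        masked["mri_dn_t2_hyperintensity"] = "unknown"
        hits_masked, _ = traverse(tree, parse_findings(masked))
        union = set()
        for state in ("present", "absent"):
            resolved = dict(base)
            resolved["mri_dn_t2_hyperintensity"] = state
            hits, _ = traverse(tree, parse_findings(resolved))
            union |= set(hits)
        assert set(hits_masked) == union

    def test_trace_records_both_branches_on_fork(self, tree):
        f = parse_findings({**GLOBAL_ATROPHY, "onset_age_years": 45})
        _, trace = traverse(tree, f)
        t2_step = next(s for s in trace if s.node_id == "a_any_t2")
        assert t2_step.outcome is Truth.UNKNOWN
        assert t2_step.branches == ("true", "false")


# reduced tree over four plain tri-state splits, for oracle comparison
REDUCED_KB = {
    "version": "reduced",
    "entities": [
        {"code": "SCA2", "full_name": "SCA2", "prevalence_rank": 1},
        {"code": "SCA7", "full_name": "SCA7", "prevalence_rank": 2},
        {"code": "SCA8", "full_name": "SCA8", "prevalence_rank": 3},
        {"code": "SPG7", "full_name": "SPG7", "prevalence_rank": 4},
        {"code": "SCAR10", "full_name": "SCAR10", "prevalence_rank": 5},
    ],
    "root": {"node": "n_dn"},
    "nodes": [
        {"id": "n_dn", "feature": "mri_dn_t2_hyperintensity",
         "comparator": "is_present",
         "if_true": {"node": "n_hcb"}, "if_false": {"node": "n_spastic"}},
        {"id": "n_hcb", "feature": "mri_hcb_sign",
         "comparator": "is_present",
         "if_true": {"leaf": "l_sca2"}, "if_false": {"node": "n_pons"}},
        {"id": "n_pons", "feature": "mri_pons_atrophy",
         "comparator": "is_present",
         "if_true": {"leaf": "l_sca7"}, "if_false": {"leaf": "l_sca8"}},
        {"id": "n_spastic", "feature": "clin_spastic_paraplegia",
         "comparator": "is_present",
         "if_true": {"leaf": "l_spg7"}, "if_false": {"leaf": "l_scar10"}},
    ],
    "leaves": [
        {"id": "l_sca2", "candidates": ["SCA2"]},
        {"id": "l_sca7", "candidates": ["SCA7"]},
        {"id": "l_sca8", "candidates": ["SCA8"]},
        {"id": "l_spg7", "candidates": ["SPG7"]},
        {"id": "l_scar10", "candidates": ["SCAR10"]},
    ],
}

# reduced tree exercising the two derived features
DERIVED_KB = {
    "version": "derived",
    "entities": [
        {"code": "FRDA", "full_name": "FRDA", "prevalence_rank": 1},
        {"code": "SPG7", "full_name": "SPG7", "prevalence_rank": 2},
        {"code": "SCA6", "full_name": "SCA6", "prevalence_rank": 3},
    ],
    "root": {"node": "m_pattern"},
    "nodes": [
        {"id": "m_pattern", "feature": "atrophy_pattern",
         "comparator": "equals_state", "state": "global",
         "if_true": {"node": "m_t2"}, "if_false": {"node": "m_none"}},
        {"id": "m_t2", "feature": "mri_any_infratentorial_t2_change",
         "comparator": "is_present",
         "if_true": {"leaf": "m_spg7"}, "if_false": {"leaf": "m_sca6"}},
        {"id": "m_none", "feature": "atrophy_pattern",
         "comparator": "equals_state", "state": "none",
         "if_true": {"leaf": "m_frda"}, "if_false": {"leaf": "m_mixed"}},
    ],
    "leaves": [
        {"id": "m_spg7", "candidates": ["SPG7"]},
        {"id": "m_sca6", "candidates": ["SCA6"]},
        {"id": "m_frda", "candidates": ["FRDA"]},
        {"id": "m_mixed", "candidates": ["SPG7", "FRDA"]},
    ],
}


class TestOracleEquivalence:
    def test_reduced_kb_exhaustive(self):
        tiny = load_knowledge_base(REDUCED_KB)
        features = ("mri_dn_t2_hyperintensity", "mri_hcb_sign",
                    "mri_pons_atrophy", "clin_spastic_paraplegia")
        for combo in product(("present", "absent", "unknown"), repeat=4):
            f = parse_findings(dict(zip(features, combo)))
            hits, _ = traverse(tiny, f)
            expected = brute_force_traverse(tiny, f)
            assert {k: v.value for k, v in hits.items()} == expected, combo

    def test_derived_features_exhaustive(self):
        tiny = load_knowledge_base(DERIVED_KB)
        features = ("mri_vermis_superior_atrophy",
                    "mri_vermis_inferior_atrophy",
                    "mri_hemispheric_atrophy",
                    "mri_dn_t2_hyperintensity", "mri_hcb_sign")
        base = {"mri_mcp_wm_lesions": "absent",
                "mri_splenium_wm_lesions": "absent",
                "mri_lateral_pons_lesions": "absent"}
        for combo in product(("present", "absent", "unknown"), repeat=5):
            f = parse_findings({**base, **dict(zip(features, combo))})
            hits, _ = traverse(tiny, f)
            expected = brute_force_traverse(tiny, f)
            assert {k: v.value for k, v in hits.items()} == expected, combo

    def test_full_kb_random_records(self, tree):
        rng = np.random.default_rng(42)
        for _ in range(25):
            f = random_findings(rng)
            hits, _ = traverse(tree, f)
            expected = brute_force_traverse(tree, f)
            assert {k: v.value for k, v in hits.items()} == expected


class TestScoringAndRanking:
    def test_spasticity_separates_spg7_from_scar10(self, tree):
        leaf = tree.leaves["a_dn_adult"]
        f = parse_findings({"clin_spastic_paraplegia": "present",
                            "lab_coq10": "normal", "onset_age_years": 50})
        scored = {c.entity: c for c in score_leaf(leaf, f)}
        assert scored["SPG7"].supports == 1
        assert scored["SCAR10"].supports == 0

    def test_swi_rim_fires_for_ctx(self, tree):
        leaf = tree.leaves["a_dn_ctx"]
        f = parse_findings({"mri_swi_low_signal_around_dn": "present"})
        (ctx,) = score_leaf(leaf, f)
        assert ctx.supports == 1 and any("SWI" in note for note in ctx.fired)

    def test_unknown_discriminators_count_for_neither(self, tree):
        leaf = tree.leaves["a_dn_juvenile"]
        scored = {c.entity: c for c in score_leaf(leaf, PatientFindings())}
        assert all(c.supports == 0 and c.contradictions == 0
                   for c in scored.values())

    def _cand(self, entity, tier=Tier.STRICT, s=0, c=0):
        return ScoredCandidate(entity=entity, tier=tier, supports=s,
                               contradictions=c, leaf_ids=("x",))

    def test_supports_rank_above(self, tree):
        diff = rank_candidates(
            [self._cand("SCAR10"), self._cand("SPG7", s=2)], tree)
        assert diff.top(2) == ("SPG7", "SCAR10")

    def test_prevalence_breaks_ties(self, tree):
        diff = rank_candidates(
            [self._cand("AVED"), self._cand("FRDA")], tree)
        assert diff.top(2) == ("FRDA", "AVED")

    def test_strict_tier_ranks_first(self, tree):
        diff = rank_candidates(
            [self._cand("FRDA", tier=Tier.INDETERMINATE, s=3),
             self._cand("AVED")], tree)
        assert diff.top(1) == ("AVED",)

    def test_lexicographic_final_tiebreak(self, tree):
        # candidates outside the registry share the fallback prevalence,
        # leaving the entity code as the only remaining tie-break
        diff = rank_candidates(
            [self._cand("ZZZ"), self._cand("YYY")], tree)
        assert diff.top(2) == ("YYY", "ZZZ")

    def test_empty_candidate_list_is_engine_error(self, tree):
        with pytest.raises(EngineError):
            rank_candidates([], tree)


class TestRunCharon:
    def test_canonical_sca6_vignette(self, tree):
        diff = run_charon(canonical_vignette("SCA6"), tree)
        assert diff.candidates[0].entity == "SCA6"
        assert diff.candidates[0].tier is Tier.STRICT

    def test_canonical_aved_vignette(self, tree):
        diff = run_charon(canonical_vignette("AVED"), tree)
        assert diff.candidates[0].entity == "AVED"

    def test_canonical_sca2_vignette_keeps_cluster(self, tree):
        diff = run_charon(canonical_vignette("SCA2"), tree)
        assert diff.candidates[0].entity == "SCA2"
        assert {"SCA1", "SCA3"} <= diff.entity_set()

    def test_multi_leaf_merge_keeps_best_tier(self, tree):
        # dentate hyperintensity with unknown atrophy: SPG7 is reachable
        # through both groups, merged into a single candidate
        f = parse_findings({"mri_dn_t2_hyperintensity": "present",
                            "onset_age_years": 70})
        diff = run_charon(f, tree)
        (spg7,) = [c for c in diff.candidates if c.entity == "SPG7"]
        assert len(spg7.leaf_ids) >= 2
        assert len([c.entity for c in diff.candidates]) == \
            len({c.entity for c in diff.candidates})

    def test_determinism_byte_identical(self, tree):
        f = parse_findings({"mri_hcb_sign": "present"})
        assert run_charon(f, tree).to_json() == run_charon(f, tree).to_json()


class TestSupportMonotonicity:
    """Switching a pure (non-routing) SUPPORTS discriminator from absent
    to present never worsens that entity's rank."""

    @pytest.mark.parametrize("template_entity,feature,entity", [
        ("SCAR10", "clin_spastic_paraplegia", "SPG7"),
        ("SCA6", "clin_cognitive_psychiatric", "SCA17"),
        ("SCA6", "clin_fasciculations", "SCAR10"),
        ("SCA3", "clin_pyramidal_signs", "SCA1"),
        ("SCA1", "clin_ankle_reflex_alteration", "SCA3"),
        ("SCA17", "clin_downbeat_nystagmus", "SCA6"),
    ])
    def test_rank_never_drops(self, tree, template_entity, feature, entity):
        template = canonical_vignette(template_entity)

        def rank_of(state):
            f = replace(template, **{feature: state})
            return run_charon(f, tree).top(20).index(entity)

        assert rank_of(TriState.PRESENT) <= rank_of(TriState.ABSENT)


class TestProbe:
    def juvenile_dn_template(self):
        return parse_findings({
            **GLOBAL_ATROPHY, **NO_SIGNAL_CHANGES,
            "mri_dn_t2_hyperintensity": "present",
            "mri_swi_low_signal_around_dn": "absent",
            "onset_age_years": 12, "lab_afp_ug_per_L": 1,
            "lab_coq10": "normal",
        })

    def test_finds_aoa_boundary(self, tree):
        boundary = probe_decision_boundary(
            tree, self.juvenile_dn_template(),
            "lab_afp_ug_per_L", 0, 60, tol=0.001)
        assert boundary == pytest.approx(15, abs=0.001)

    def test_top1_constant_below_boundary(self, tree):
        template = self.juvenile_dn_template()
        tops = {
            run_charon(replace(template, lab_afp_ug_per_L=v),
                       tree).candidates[0].entity
            for v in np.linspace(0, 14.9, 30)
        }
        assert tops == {"AOA1"}

    def test_untested_feature_raises_probe_error(self, tree):
        # Hot Cross Bun route never consults AFP
        template = canonical_vignette("SCA2")
        with pytest.raises(ProbeError, match="does not switch"):
            probe_decision_boundary(tree, template,
                                    "lab_afp_ug_per_L", 0, 60)

    def test_rejects_bad_interval_and_feature(self, tree):
        template = self.juvenile_dn_template()
        with pytest.raises(ProbeError):
            probe_decision_boundary(tree, template,
                                    "lab_afp_ug_per_L", 60, 0)
        with pytest.raises(ProbeError):
            probe_decision_boundary(tree, template,
                                    "mri_hcb_sign", 0, 1)
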