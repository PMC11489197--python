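# Methods

This note documents the model behind `charon-ataxia`: what the engine
assumes, the parameters that matter, what the simulator does and does
not emulate, and the design choices taken where the published clinical
reasoning left the mechanism open.

## Input model

The engine consumes a closed-vocabulary findings record: 27 tri-state
imaging/clinical features, two non-negative scalars (onset age in
years, serum alpha-fetoprotein in μg/L), and two categorical labs
(vitamin E: reduced/normal; coenzyme Q10: low/normal).  Tri-state
semantics distinguish "assessed and absent" from "not assessed"
(`unknown`); a record with every field unknown is valid (the worst-case
referral).  Missing keys default to unknown rather than erroring —
referrals routinely omit findings — and the defaulting is recorded in a
provenance note on the parsed record.  There is deliberately no
free-text pathway: determinism and auditability require a closed
vocabulary.

The schema requires *bilateral* dentate hyperintensity; no unilateral
state exists, because the branch-defining sign is defined bilaterally.

## Atrophy-pattern classification

The top-level classification over (superior vermis, inferior vermis,
hemispheres) is:

* `global` — hemispheres present **and** at least one vermian component
  present.  "Global" is operationalized permissively because worked
  cases of "pure" cerebellar atrophy show hemispheric plus vermian
  involvement with the inferior vermis sometimes only mildly affected.
* `selective_vermian` — a vermian component present, hemispheres
  explicitly absent.
* `none` — all three explicitly absent.
* `indeterminate` — everything else.  This includes isolated
  hemispheric atrophy with spared vermis: no branch of the tree is
  defined for it, so rather than silently routing it to either group
  the engine warns and explores both groups.

The function is total over all 3^3 tri-state combinations and is
verified against a hand-written truth table by exhaustive enumeration.

## Knowledge base

The decision tree is data, not code: YAML with `entities`, `nodes`
(binary predicate splits), and `leaves` (candidate clusters with
per-entity support/contradict discriminators).  Loading validates
schema and structure (rooted binary tree, single parent, no cycles, no
dangling references, discriminators confined to their leaf's
candidates, type-checked predicates with unit-checked thresholds);
`validate_tree` additionally reports reachability and entity coverage.
Every node and discriminator carries a citation string so a rendered
differential can be audited line by line.

Decision constants: AFP 15 μg/L (below: AOA1 over AOA2), AFP 65 μg/L
(above: ataxia-telangiectasia), onset boundary at the end of the 2nd
decade.  The onset boundary is stored both as a decade ordinal and an
explicit year value (20); "before the 2nd decade" is read as the whole
of it because AOA2 onset typically falls *within* the second decade — a
strict <10 reading would misroute it.  Boundary semantics are strict:
"below 15" is `<`, "more than 65" is `>`, onset "before" is `<`.  The
comparator vocabulary therefore includes `lt/le/gt/ge` on numerics: the
composed AFP regimes need both open and closed interval ends (values in
(15, 65] support AOA2 and *contradict* ataxia-telangiectasia).

Two derived features may appear in predicates: the atrophy pattern
(above) and `mri_any_infratentorial_t2_change`, a three-valued OR over
the five T2-signal features.  The "brainstem involvement" split in the
Hot-Cross-Bun branch is operationalized as: pons absent → SCA8; pons
present, medulla absent ("selective pontine atrophy") → SCA7; pons and
medulla present → {SCA1, SCA2, SCA3}.

The SCA1/SCA2/SCA3 clinical discriminators (pyramidal signs → SCA1,
oculomotor deficits → SCA2, ankle-reflex alteration → SCA3) are a
literature-derived mapping, not an imaging assertion; they ship as
editable KB data and are flagged as such in their citations.

Prevalence ranks are ordinal and serve **only** as a late tie-break.
FRDA's first place is a firm literature claim; the rest of the ordering
is an explicit editorial choice recorded in the KB file.  Degree-of-
atrophy observations (e.g. milder cerebellar atrophy in SCA3 than in
SCA1/2) are not encoded as predicates — they would require volumetry —
and survive only as KB comments.

## Traversal under unknowns

A predicate evaluates to true/false/unknown (Kleene logic; numeric
comparisons on an unknown value are unknown).  On an unknown outcome
the engine enumerates the present/absent resolutions of the predicate's
unknown *base* features, substitutes each resolution into the record,
and continues down the indicated branch with the substituted record.
Substitution persists, so no path can assume "DN present" at one node
and "DN absent" at a later one.  Leaves reached through any fork carry
the `indeterminate` tier; a leaf reached without forks is `strict`.

This yields the union law the test suite enforces: for any record, the
entity set returned with one tri-state feature masked equals the union
of the entity sets of the two resolved variants.  Traversal is also
checked exhaustively against an independently written brute-force
resolution-enumeration evaluator on reduced trees, and on random
records against the full tree.  Numeric unknowns (onset, AFP) cannot be
finitely enumerated and fork both branches directly; this is exact
here because no root-to-leaf path tests the same numeric feature twice.

Scoring counts each satisfied discriminator as exactly 1 — the source
reasoning provides no weights, and inventing them would fabricate
evidence.  Unknown discriminator evidence counts for neither polarity.
An entity reached through several leaves is merged keeping the best
tier, the maximum supports and the minimum contradictions: an entity
strictly reachable on one path should not be demoted by an
indeterminate duplicate.  The final order (strict tier, supports desc,
contradictions asc, prevalence rank, code) is total, making the whole
pipeline deterministic and byte-stable.

A consequence worth noting: support monotonicity (asserting a SUPPORTS
feature can only improve an entity's rank) is guaranteed for features
that act purely as discriminators; features that *also* route the
descent (e.g. dentate hyperintensity, a vermian component) can move the
record to a different leaf, where the comparison set changes.  The
property test is scoped accordingly.

## Vignettes and simulation

Each of the 17 entities has a canonical prototype: a complete tri-state
assignment, an onset range, and lab rules anchored to the decision
constants rather than to literature reference distributions (e.g. AOA1
AFP uniform on [2, 14] μg/L, strictly below the 15 μg/L cut; AOA2 on
[20, 60]; ataxia-telangiectasia on [70, 260], i.e. above 65; all others
on a normal-range [1, 9]).  Onset ranges reflect typical presentations
(juvenile < 20 years for AOA1, AOA2, AT, ARSACS, FRDA, AVED; adult
otherwise); midpoints instantiate the deterministic canonical
vignettes, and every canonical vignette self-classifies as a unique
strict top-1 — asserted in the suite as a build invariant.

The simulator perturbs prototype instantiations with (i) symmetric
present↔absent flips at rate ε on tri-state features, then (ii) masking
to unknown at rate μ, then (iii) masking of scalars (onset and labs) at
a separate rate.  Labs are never flipped: a sign flip on a
concentration has no defined magnitude.  All randomness flows from one
seeded generator; identical seeds give identical cohorts, and every
perturbation is logged so that the clean record is exactly
reconstructable.

What the simulator emulates is *imperfect reading and reporting* of a
textbook case.  What it does not emulate: within-entity phenotypic
heterogeneity (each entity has a single prototype), correlated reader
errors, atypical or mixed presentations, longitudinal change, or
population prevalence (entities are sampled uniformly).  Perfect
noiseless recovery therefore shows the tree is *consistent* with the
canonical phenotypes, not that real-world sensitivity is high; the
noise sweeps measure robustness of the ranking, not clinical accuracy.
A real-world validation would require case-level data that does not
exist in this form.

## Evaluation and problem sizes

The evaluation harness reports a true-by-top-1 confusion matrix,
per-entity top-1 recall, truth-in-top-3 rate (the clinically relevant
target is a *short list*, not a single answer), truth-in-differential
rate, and mean differential length.  Invalid batch records are excluded
and listed rather than aborting the run.

Default problem sizes were chosen to keep every check comfortably
desk-scale while statistically meaningful: noise sweeps use 204 records
per setting (12 per entity); the union-law check uses 500 random
records × all 27 tri-state maskings; oracle comparisons are exhaustive
(3^4 and 3^5 combinations) on reduced trees plus 25 random records on
the full tree.  Decision-boundary probes bisect to 0.01 μg/L.

## Known limitations

* Covers only the 17 encoded entities; a record from any other disease
  will still be forced into this differential.
* Outputs are ordinal, not probabilistic: tiers and counts, no
  calibrated posteriors.
* The tree assumes the radiologist's assertions are correct; flip noise
  in the simulation shows that wrong (as opposed to missing) assertions
  can exclude the truth — `absent` is a strong statement.
* Selective *hemispheric* atrophy has no defined branch and is handled
  by exploring both groups with a warning.
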