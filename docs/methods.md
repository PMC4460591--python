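# Methods

## Model

A knowledge base (KB) is a typed network: *feature items* are instances of
declared feature types, each type belonging to one of two categories —
biomolecular entities (DNA sequences, genes, transcripts, proteins) or
biomedical-molecular characteristics (biological functions, pathways,
enzymes, genetic disorders). Directed *associations* connect items with one
of five semantic types: `ENCODES` and `INTERACT_WITH` (specific
entity–entity), `RELATED_TO` (generic entity–entity), `ANNOTATED_TO`
(entity–characteristic) and `ASSOCIATED_WITH`
(characteristic–characteristic). `INTERACT_WITH` is symmetric and stored
once with canonically ordered endpoints. Ontology-typed characteristics
carry a rooted is_a DAG over their items. Every association records its
evidence codes (GO/GOA style; an empty set means the source provides none,
as with OMIM-style gene–disorder rows), its provenance source, an
`inferred` status (`SOURCE`, `SOURCE_COMPUTATIONAL`, or
`TRANSITIVE_RELATIONSHIP` for anything this package derived) and an
obsolete flag.

## Transfer by transitive relationship

From A → B and B → C the engine derives A → C, restricted to *admissible*
patterns. Admissibility is cardinality reasoning: a relationship may be
walked only in a direction whose cardinality is 1:1 or 1:n. The
gene→protein `ENCODES` map is 1:1 from the protein side (1:n from the gene
side under alternative splicing), so protein annotations flow up to the
encoding gene unconditionally, while gene annotations flow down to encoded
proteins only as *candidates* — and only for genetic disorders, where the
suggestion value justifies the risk. Characteristic–characteristic
relationships are n:n and are never walked; no admissible pattern has a
characteristic as its middle item. Path length is fixed at two: no
transitive closure, no iterated rounds (derived annotations are never
re-used as supports).

Rules are data, not code. A rule names the three item patterns (a concrete
feature-type name or a category wildcard), the two support semantic types
and traversal directions (`REVERSE` walks a stored edge backwards; `EITHER`
is reserved for the symmetric `INTERACT_WITH`), the derived semantic type
and the candidate flag. The construction-time invariant `candidate_only ⇔
the pattern walks ENCODES in reverse` is enforced, as is pattern
uniqueness, and a ruleset is validated against the KB's schema (unknown
type names, or derivable edges illegal for their endpoint categories, fail
before any transfer). The shipped default (`data/default_rules.yaml`)
reproduces the four-rule system in the README table.

## Error-propagation controls

A support edge is disqualified when:

* it, or either endpoint item, is obsolete (`exclude_obsolete`, default on);
* its non-empty evidence set falls inside an excluded profile — default
  profile `{IEA}`, so IEA-only annotations are dropped while mixed sets
  like `{IEA, NAS}` survive; edges without evidence information are never
  evidence-filtered, and the check applies only to `ANNOTATED_TO` supports
  (evidence codes are an annotation concept);
* it is marked `SOURCE_COMPUTATIONAL` (default on);
* it is itself a transferred annotation — this control is structural and
  cannot be switched off, which is what prevents recursive closure.

Derived edges are additionally suppressed when the triple already exists as
a non-obsolete association (including one applied by a previous transfer
run — required for idempotence), when the subject is a pseudogene and the
target type is functional (default: every ontology-typed characteristic
plus `enzyme`; configurable, since reasonable readings differ on whether
pathways count as functional), and — for ontology targets — when the term
equals or is an ancestor of a term already annotated to the subject
(true-path redundancy). The same dominance argument is applied *within* a
run: if one run would emit both a term and its strict ancestor for the same
subject, only the most specific is kept; terms applied by earlier runs
dominate as well, making repeated runs idempotent.

Each admissible path is accounted for exactly once in the run statistics
(first failing predicate wins), so
`matched = Σ rejections + emitted paths` holds exactly and runs are
auditable from the logs.

Every emitted record carries the ordered pair(s) of support edges
(deduplicated on the derived triple, all provenance pairs retained, sorted
deterministically), the union of support evidence codes, and a source
string naming the two support sources.

## Candidate detection

Protein–disorder: one candidate per (protein, disorder) with at least one
eligible encoding gene annotated to the disorder. PPI–disorder: one
candidate per (PPI, disorder) where **both** interacting proteins have such
support for the same disorder (a self-interaction needs only its one
protein). "Same disorder for both endpoints" is the strict reading of the
rule; a `require_both_endpoints=False` switch gives the laxer one-endpoint
variant for sensitivity analyses. Candidates are permanently flagged and
never fed back as supports. Candidate detection does not suppress pairs
whose annotation already exists — it reports support, not novelty — which
keeps the internal invariant that every PPI candidate implies both protein
candidates.

## Leave-out evaluation

Recall and precision are estimated by hiding *all* known gene annotations
of the requested target types from a copy of the KB, re-deriving gene
annotations from protein annotations and ENCODES edges alone, and comparing
exactly on (gene, term) pairs. Hidden computationally-derived annotations
stay in the denominator: their misses are genuine recall losses, since the
engine refuses their supports on purpose. Hiding the gene annotations also
disables the ancestor-redundancy suppression they would cause, so the
identified set is a superset of a production run's output. Counts are
pooled (micro-averaged) for the overall figure; a type with no known
annotations reports recall as undefined rather than raising. Genes carrying
known annotations but no usable ENCODES edge are kept as legitimate misses
and their count is reported for transparency. Because available
annotations are incomplete by definition, the precision figure is an
approximation: an identified-but-unknown annotation may simply be missing
from the sources (on synthetic KBs with a positive holdout fraction this is
literally true — the planted annotations depress measured precision while
being correct by construction).

## Co-functional assessment

For a gene g annotated (transferred or known) to pathway P, and each
partner gene G *known* in P (g excluded from its own partner set for the
known role): MaxL(g–G) is the maximum ontology level over all lowest common
ancestors (LCAs) of all pairs of their usable functional annotations; per
gene, `max_level` is the maximum and `avg_level` the mean of the MaxL(g–G)
over partners that have annotations (unannotated partners are skipped, not
scored 0, because the pairwise statistic is undefined for them). A gene
with no usable annotation, or no annotated partner, falls into category N.
Usable known annotations follow the global evidence policy (IEA-only
excluded); the `KNOWN_PLUS_TRANSFERRED` scope additionally counts
transferred functional annotations, which can only raise `max_level` and
shrink N — the monotonicity the test-suite asserts. Histograms bin
`avg_level` by floor and clip values beyond the requested cap into the top
bin; raw values are retained in the per-record output.

**Level convention.** A term's level is the length of the *longest* is_a
path from any root (roots at 0). Where a term is reachable at several
depths, the deeper one defines its level ("take the higher level"), scoring
a shared annotation at its most specific placement. Multiple roots are
allowed. `lca_set` is reflexive (`lca_set(t, t) = {t}`), so identical
annotations score at the term's own level. Obsolete terms stay in the DAG —
they shape levels and ancestor sets — but are excluded as annotation
targets by the filters.

## Synthetic data

The generator builds KBs with the structure the method assumes: genes
encoding proteins (one gene per protein; a configurable fraction of genes
encodes several — alternative splicing), protein annotations to ontology
terms/pathways/enzymes with mixed evidence, protein–transcript
`RELATED_TO` edges, evidence-free gene–disorder annotations and PPIs. The
ontology grows by preferential attachment with occasional second parents,
giving realistic level spread and diamond LCAs. Decoys — obsolete
items/edges/terms, IEA-only evidence, computational sources, pre-existing
transferred annotations, pseudogenes with their own exclusively-encoded
annotated proteins — are injected with configurable probabilities and
recorded in a ground-truth ledger. For IEA-only and computational decoys
the corresponding gene annotation is added as known data (sources do carry
such annotations), creating honest recall misses in the leave-out
evaluation.

Derivable gene annotations are computed by construction (eligible supports
only, dominated ancestor terms dropped), then a `holdout_fraction` of them
is withheld into `planted_holdout`; on decoy-free configurations the
engine must recover the planted set exactly, at any holdout fraction.
All construction-derivable protein–disorder pairs are materialised as known
associations, so a zero-holdout decoy-free KB transfers nothing. A fraction
of PPIs (`p_ppi_disease_module`, default 0.3) is drawn between proteins
whose genes share a disorder, modelling disease-module enrichment —
uniformly random pairs essentially never share one. Generation consumes a
single seeded stream in fixed order; identical (config, seed) gives
byte-identical serialized bundles, across processes.

What the generator does **not** emulate: real identifier grammars, sequence
data, evidence-code co-occurrence statistics, ontology namespace semantics
(`part_of`/`regulates` are out of scope), or the cross-database
reconciliation that precedes integration in real pipelines. Passing tests
therefore demonstrate the correctness of the transfer logic and filters,
not the biological accuracy that depends on source data quality.

Defaults (60 genes, 80 proteins, 60 terms, 12 pathways, 8 disorders,
40 PPIs, 3 annotations per protein on average, 25 % of genes
disorder-annotated, holdout 0.5, decoy rates ~5–15 %) are desk-scale
stand-ins for an integrated annotation warehouse; the scale smoke test runs
10⁴ genes / 2×10⁴ proteins / 5×10³ terms / ~10⁵ annotations, which the
engine handles in seconds.

## Numerical and design choices

* Deterministic output ordering everywhere (records by subject/object id,
  provenance pairs by edge sort keys) so serialized results are
  reproducible byte-for-byte.
* Self-transfers (A = C) are forbidden.
* Obsolete existing associations do not block re-derivation (obsolete data
  is "not current"); non-obsolete ones of any inferred status do.
* Identifiers are opaque, case-sensitive strings; no namespace
  normalization.
* The OBO reader handles the 1.2 subset (`[Term]`, `id`, `name`, `is_a`,
  `is_obsolete`) via obonet; the GAF 2.x reader uses columns 2/4/5/7,
  skips `NOT`-qualified rows and merges duplicate (object, term) rows'
  evidence codes.
* ROC/k-fold machinery is deliberately absent: the method gives discrete,
  not probabilistic, answers, so recall/precision of the leave-out
  comparison is the appropriate instrument.

## Known limitations

* Path length is fixed at 2; chains of three or more supports are out of
  scope by design.
* Pattern matching treats rule cardinality as declared per relationship
  type, not inferred from the data; a mis-declared schema yields
  mis-derived edges.
* The evaluation's precision is an under-estimate on any KB whose sources
  are incomplete (which is all of them; the synthetic holdout makes the
  effect explicit and quantifiable).
* LCA computation is exact but quadratic in the annotation sets per gene
  pair; co-functional scoring of very densely annotated KBs is the slowest
  path in the package.
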