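# Methods

This note documents the statistical model behind golink, the choices
made where the design was genuinely open, what the synthetic benchmark
does and does not emulate, and the package's known limitations.

## Co-occurrence model

The unit of evidence is one abstract.  A corpus is reduced to four
counts: `n..` (abstracts mentioning at least one gene or GO term), the
margins `ni.` and `n.j`, and the joint counts `nij`.  Abstracts
mentioning nothing are ignored entirely, so `n..` is a property of the
corpus *and* the dictionaries used to scan it.  Joint counts of zero are
never stored: "no abstract mentions this pair" is a first-class missing
value, distinct from a measured weak association, and every downstream
rule says explicitly how it treats missingness (weight 0 in profiles,
p = 1 in enrichment means and averages, blank cells in matrix exports).

### Dictionary filtering and matching

Surface names shorter than 3 characters or equal (case-insensitively) to
a stop-word are removed before scanning; both parameters are exposed
(`min_len`, any word list).  The bundled list of ~280 common English
words stands in for a full lexical database and mixes function words
with everyday nouns that collide with gene symbols and GO term names
("learning", "growth", "memory").  Terms that lose every name are kept
in the dictionary with an empty name set — identifier spaces stay stable
across filtering choices — and logged, since they can never match.

Text matching is deliberately simple and fully specified: text is
lower-cased and split on runs of non-alphanumeric characters, and a name
matches iff its own token sequence occurs as consecutive tokens.  This
is a deterministic, testable rule, not an attempt at biomedical named
entity recognition; no disambiguation or negation handling is done.  The
pipeline equally accepts pre-extracted mention tables and skips scanning
altogether — mention events, not raw text, are its real input.

## The mid-p hypergeometric score

For each observed pair the association score is
`P(X > nij) + 1/2 P(X = nij)` with `X ~ HG(n.., n.j, ni.)`.  The mid-p
correction halves the observed outcome's probability mass, which
de-biases the conservatism of discrete tail tests; the identity
`upper(k) + lower(k) = 1` (with the analogous lower tail) characterises
the correction and is asserted exhaustively in the tests.

Numerically the tail is assembled in log space from
`scipy.stats.hypergeom.logpmf` terms with a grouped log-sum-exp, so the
score is exact to floating precision at small margins (validated to
≤ 1e-12 against an integer-arithmetic enumeration over every valid
margin combination with `n.. <= 60`) and stable at literature scale —
margins in the thousands against totals of 10^7 yield tails below
1e-300 that are still returned as positive numbers rather than
underflowing to zero.  Degenerate margins (`ni. = 0` or `n.j = 0`) give
exactly 0.5: a point mass at zero with half its mass counted, i.e. "no
evidence either way".

## Profiles and cosine similarity

Profiles use `w = -log max(p, 1e-6)`.  The floor stops a handful of
astronomically small p-values (common for famous gene–term pairs) from
dominating the geometry; 1e-6 is the package default and configurable.
Natural log is the default base; the cosine depends only on weight
ratios, so the base provably cancels (asserted under base e vs base 10)
and matters only for exported weight tables.  The sum runs over the
union of the two profiles' supports — coordinates outside it are zero in
both vectors and cannot contribute.

A gene whose profile is all-zero (observed in abstracts, but never with
any GO term) has no direction in profile space.  Its similarities are
*undefined*: they are stored as 0 and flagged, so thresholding at any
cutoff — including 0 — never invents edges for unstudied genes, and the
percentile machinery excludes these placeholder zeros by default.  The
diagonal is 1 for defined genes and 0 for undefined ones.

The direct co-occurrence baseline is the cosine of the genes' 0/1
abstract-incidence vectors, which closes to `nii' / sqrt(ni. ni'.)`.
It uses the same tally and the same network machinery, differing only in
what it measures — that is what makes edge-count comparisons between the
two approaches meaningful.

## Networks, communities, enrichment

An edge exists iff `gamma >= c` (boundary included).  All genes remain
as nodes; at high-confidence cutoffs most genes are isolated, and that
is reported rather than hidden — isolated genes become singleton
communities.  Cutoffs are best chosen as percentiles of the similarity
distribution at hand; the CLI presets `median` / `moderate` / `high`
compute the 50th / 95th / 99th percentile of the user's own data.
(At full-literature scale these percentiles have been observed around
0.054, 0.288 and 0.492, but percentiles are corpus-specific and are
always recomputed, never hard-coded.)  The percentile rule is linear
interpolation between order statistics (numpy's default, the classical
type-7 estimator), configurable via any `numpy.quantile` method.

Asynchronous label propagation starts every node with a unique label;
each sweep visits the nodes in a freshly shuffled seeded order and gives
each node a label drawn uniformly (seeded) from the most frequent labels
among its neighbours.  Termination is the classical fixed-point
condition — every node's label already maximal among its neighbours —
checked before each sweep; after `max_iter` sweeps (default 100)
non-convergence is a warning, not an error, because bipartite-like
structures can oscillate between tied labelings.  Neighbour frequencies
are unweighted, matching the cited algorithm family; edge weights decide
only which edges exist.  Labels are densified by ordering communities by
their smallest member, so output is reproducible given the seed.

Community GO enrichment is the mean of the members' p-values per term
with missing pairs as 1 — a deliberately conservative rule under which a
community can only look enriched for terms its members were actually
observed with.  Bonferroni adjustment (`min(1, m·p)`) is offered in the
query tables; the family size defaults to the full GO index for gene
queries and the full gene index for GO queries, and is overridable since
the "right" family is a judgment call.

Gene-set term selection (`select_top_go`) ranks GO terms by mean p over
the gene set, missing = 1, ties broken lexicographically.  Because a
term specific to a subgroup is "missing" for every other gene, selection
should be run per signature and the selected terms pooled afterwards
(as in `examples/04`); averaging over an eclectic gene set favours
diffusely co-mentioned terms, which is a property of the averaging rule,
not a bug.

The probit transform maps p (clamped to `[1e-6, 1 - 1e-6]`, missing → 1)
through the standard-normal quantile, giving roughly normal, unbounded
scores suitable for k-means, hierarchical clustering or PCA with stock
implementations; golink exposes the transform and leaves the clustering
to scikit-learn/scipy.

The Fruchterman–Reingold layout (networkx's implementation) is exposed
with its spacing parameter `k`, a seed, and an iteration count.
Coordinates are returned unrescaled so that `k` keeps its documented
meaning — doubling it genuinely spreads the drawing — which the tests
check as a statistical property over seeds.

## The synthetic benchmark

`SyntheticCorpusConfig` defaults describe the reference conditions used
by the test suite and the acceptance script: 40 genes, 80 GO terms,
2000 abstracts, four disjoint modules of 5 genes and 8 GO terms,
`p_signal_go = 0.6`, `p_direct_cooccurrence = 0.05`,
`p_background = 0.01`.  Each abstract draws a topic — background with
probability `background_share` (default 0.2), otherwise a module
uniformly.  A module abstract mentions one focal module gene (with
probability `p_signal_gene`, default 1), every other module gene with
the small direct-co-occurrence probability, and each module GO term with
`p_signal_go`; background mentions of every gene and term are then
superimposed.  The 0.2 background share makes the five topics
(four modules + background) uniform under the defaults.

This emulates the one statistical regime the method is built for —
module genes share GO vocabulary but rarely co-occur directly — and
nothing else: no realistic text, no synonymy or ambiguity, no citation
or temporal structure, no heavy-tailed gene popularity.  Passing the
recovery tests therefore shows that the statistics compose correctly in
that regime, not that the matcher or dictionaries would perform well on
real PubMed text.

Two quantitative consequences of the default sizing are worth stating.
First, the 40 within-module pairs are 5.1% of the 780 gene pairs, so the
95th percentile of the similarity distribution is the cutoff that
matches the planted edge density: there the pipeline recovers the four
modules exactly (ARI 1.0 in 20/20 seeds).  A 99th-percentile cutoff
retains only the top ~8 pairs of 780 and so cannot reconnect four
five-gene modules on this problem size, whatever the method's quality;
the suite measures recovery at both cutoffs and the acceptance script
reports both.  Second, the edge-richness comparison against the direct
co-occurrence baseline follows the standard signature design: each
method's cutoff is a percentile of its own full-corpus distribution, and
edges are counted among the signature (planted) genes.  Counting edges
over the same pair set that defines the percentiles would force both
counts to ~(1 − q)·780 and reduce the comparison to tie-breaking noise.

## Problem sizes

The test suite simulates twenty 2000-abstract corpora once per session
(shared fixture, ~15 s) and validates the mid-p statistic on the
exhaustive `n.. <= 60` grid (~635k margin combinations, ~10 s); the
acceptance script repeats both from scratch in about half a minute.
These sizes were chosen so that every property is checked end to end on
one CPU while the statistics operate far from small-sample edge cases.

## Known limitations

- Matching is exact token-sequence lookup; misspellings, plural forms,
  and ambiguous symbols (e.g. "AN", "CAT") are handled only insofar as
  filtering removes them.
- The hypergeometric model treats abstracts as exchangeable; review
  articles and topic bursts violate that silently.
- Only Bonferroni adjustment is offered; no FDR machinery.
- GO structure (term ancestry, semantic similarity) is not used; terms
  are independent symbols.
- Label propagation is non-deterministic across seeds by nature; only
  the seeded result is reproducible, and near-tied community structures
  genuinely differ between seeds.
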