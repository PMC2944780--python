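# Methods

## Concept tagging

Thesauri map biological items (genes, diseases, drugs, pathways, biological
processes, liver pathologies) to typed keywords: a full name, symbols and
aliases. Catalogued full names are unusable as literal search strings, so
they are normalized before matching: parenthesized annotations are deleted
(innermost-out until none remain), commas become spaces, and whitespace
runs collapse. Gene symbols and aliases shorter than three characters are
removed outright, and the survivors are screened case-insensitively against
a pinned English word list (shipped with the package, configurable by path)
so that symbols like "AND" or "CELL" cannot flood the concordance. The word
list is deliberately small and versioned: reproducibility of the filter
matters more than lexicographic completeness, and a larger lexicon can be
supplied without code changes. Single-character symbols are treated like
two-letter ones; they share the same drop-reason code because the closed
reason vocabulary has no finer distinction.

Matching uses a boundary contract rather than generic word boundaries: an
occurrence counts when the characters flanking the keyword are one of
`] [ . - ) ( , : ;`, a space, or the string edge, an optional trailing "s"
is absorbed, and inside full names each single space may match whitespace
or a dash ("cell death" also hits "cell-death"). Full names and non-gene
phrase descriptions match case-insensitively; gene symbols match
case-sensitively as written, since case-folding symbols would re-introduce
the English-word collisions the cleaning removed. The optional plural "s"
is not applied to symbols (plural symbol forms are not conventional); both
choices are configurable. Titles, abstract bodies and substance terms are
searched as one uniformly treated text.

A gene hit supported only by symbol or alias matches is ambiguous. It is
retained only when at least one informative word of the gene's full name
also occurs in the document — informative meaning at least four characters,
not a stopword (generic tokens like "receptor", "protein", "factor"), and
not containing a digit. The four-character guard and the stopword list keep
trivial words from vouching for a symbol; both are configurable. Hits
supported by a full-name match bypass the check, as do gene concepts that
carry no full name at all (nothing to check against). Per document, hits
are deduplicated to concept level, producing a non-redundant
document-to-concept concordance that retains every document — including
hit-free ones — so that the total document count N below is the corpus
size, not the number of documents with hits.

## Association scoring

For concepts A, B occurring in `n_A`, `n_B` of `N` documents and
co-occurring in `n_AB`, the mutual-information ratio is
`S = (n_AB/N) / ((n_A/N)(n_B/N))`, `R = log10 S`, and the R-scaled score is
the affine map `R' = 1 + 99 (R − Rmin)/(Rmax − Rmin)` onto [1, 100], with
`Rmin`/`Rmax` the extremes over the scored co-publication list. Pairs that
never co-occur are unscored rather than scored low (S would be zero and R
undefined); "no direct relationship" checks therefore consult the raw
co-occurrence counts, which the score table retains even for pairs removed
by a minimum co-publication filter. The scale is global by default, with a
per-category-pair option for sensitivity analysis. A degenerate scale (one
distinct R) maps everything to 100. Scores above 40 are flagged
significant; the threshold is configurable.

Two numerical details: exact endpoint identities (`R = Rmin → 1`,
`R = Rmax → 100`) are enforced rather than left to floating-point rounding,
and values within a 1e-9 relative margin outside the scale are clamped
before the affine map; anything further out is a domain error.

## Hidden-relationship discovery

An intermediate B qualifies for the pair (A, C) when it belongs to an
allowed category — genes and biological processes by default, which keeps
uninformative bridges out — and both links (A,B) and (B,C) appear in the
score table with at least `min_copubs_link` co-publications (default 3) and
R-scaled at least `min_rscaled_link` (default 20). The inferred score is
`Ri = Σ min(R'_AB, R'_BC) / k` over the k qualifying intermediates; the
weakest link limits how much an intermediate can vouch for the connection.
Two alternative aggregations are provided for sensitivity analysis: the
mean of both link scores, and the mean of only the top-k weakest-link
scores (default k = 5). For fixed links, min-link Ri never exceeds
mean-link Ri, and adding an intermediate whose weakest link is below the
current Ri dilutes it — both properties are asserted in the test suite.

Closed discovery scores one hypothesized pair and returns nothing when the
pair co-occurs directly (any shared abstract, not merely a sub-threshold
score: the strict reading of "hidden") or when fewer than
`min_intermediates` qualify. Open discovery enumerates every known concept
of a target category with zero direct co-occurrence with A and returns
relationships at or above the Ri cutoff, sorted by Ri descending with ties
broken by intermediate count descending, then concept id — a total order,
so output is reproducible.

## Validation by literature partitioning

A dated corpus is split at a cutoff date: background (strictly before) and
test (from the split up to an end date, half-open). Candidate pairs are
drawn from the background under three criteria: the members never co-occur
there, each occurs in at least 10 distinct abstracts, and they share at
least 5 qualifying intermediates. Each candidate's Ri comes from the
background; its label comes from the test slice — true positive iff it
gains at least 3 co-occurrences there with a test-slice R-scaled score
strictly above 40, computed against the test slice's own scale. Both
slices' score tables are restricted to pairs with at least 3
co-publications: the same minimum the link criteria impose, and it keeps
the scale extremes off one-off chance pairs, whose extreme-value noise
would otherwise shift every R-scaled score between runs.

The ROC curve sweeps every distinct Ri value (plus sentinels) from high to
low, calling a pair positive when its Ri meets the threshold; the trapezoid
area equals the rank statistic (probability that a random true pair
outranks a random false one, ties counting half), which the tests verify
against an independent rank-counting oracle and scikit-learn. The
significance cutoff is the smallest threshold whose FPR stays within a
bound (0.1 by default), maximizing TPR subject to it; the lower sentinel is
excluded as it is not an applicable score, and a bound of exactly 1 is
permitted and returns the smallest observed score.

The time-lag statistic measures how far prediction precedes assertion: the
date of the first document co-mentioning A and C anywhere in the corpus,
minus the mean publication date over all documents supporting the A–B and
B–C links. A document is counted once per link side it appears in, so
evidence used by several links weighs accordingly. Dates carry at least
year precision; year-only dates enter date arithmetic as July 1 (month-only
as the 15th), the unbiased midpoint.

## Synthetic corpora

The generator emulates the statistical skeleton of an abstract database,
not its language: documents are filler-word text with unambiguous keyword
tokens embedded under the tagger's boundary contract, so the realized
document-to-concept matrix is exact ground truth for the full pipeline.
Filler vocabulary, keywords and the English filter list are checked for
mutual disjointness at generation time. Dates are uniform over the
configured year span; the same seed reproduces the corpus byte-for-byte.

Planted joint events are carved out of each concept's base rate: per
document, pair and link events fire first, and a residual solo rate (base
rate minus the concept's total planted rate, clipped at zero) tops the
marginal up to its base. Realized marginals therefore track the configured
base rates instead of inflating with every planted link — essential here,
because the mutual-information score normalizes by the marginals and would
otherwise cancel additive co-occurrence boosts. The per-pair feasibility
invariant (joint rate not exceeding either member's base rate) follows
from this carve-out semantics. A concept whose links exhaust its base rate
is a specialist that only appears alongside its partners.

Hiddenness is enforced per document: while a forbidden pair is co-present
(always, or before its assertion date), one member is removed — the one
whose removal destroys the fewest planted co-mentions in that document,
with a stable checksum parity breaking ties so the loss splits evenly
between the two sides. Planted post-split assertions are protected from
this pass. The pass iterates to a fixpoint; it only ever shrinks the
membership set, so it terminates.

### The partitioning benchmark

`validation_benchmark()` builds the standard evaluation scenario: 2,000
documents dated 1988 to May 2007 over 60 concepts — 14 disease and 14 gene
endpoints (never co-mentioned before 2000), 6 promiscuous biological
processes linked to every endpoint (the shared-intermediate background that
makes every endpoint pair a candidate; their links score near or below
chance, as promiscuous terms do under mutual information), 22 dedicated
specialist intermediates dealt round-robin to the 20 planted true pairs
(exclusive links, hence high S — the signal the weakest-link score
rewards), and 4 high-frequency generic terms forming two calibration
pairs whose co-mention only emerges in 1999. These last pin the scale's
Rmin at a stable, far-below-independence value; without them Rmin is set
by whichever link happens to fluctuate lowest, and the whole R-scaled
scale — including the hub links' position relative to the inclusion
threshold of 20 — drifts from run to run. True pairs gain direct
co-mentions after the 2000 split at a rate yielding a handful of test-slice
co-occurrences; all other endpoint pairs never co-occur anywhere. Rates
(endpoints 0.07, hub links 0.007, dedicated links 0.008 per document) were
chosen so that planted links comfortably clear the 3-co-publication and
R'≥20 inclusion criteria in a background of ~1,250 documents while chance
co-occurrences between endpoints and dedicated intermediates rarely do.

What the generator does not emulate — and what passing tests therefore do
not show about real literature: linguistic ambiguity beyond the dedicated
symbol fixtures, correlated topic drift over time, citation structure,
heavy-tailed concept frequencies, and thesaurus incompleteness. The
benchmark demonstrates that the statistical machinery recovers a planted
signal of realistic shape at desk scale, not that any particular corpus
yields any particular AUC.

At this corpus density (60 concepts in 2,000 documents, far denser than
real literature), occasional chance co-occurrences reach three documents
and let a dedicated intermediate of one pair leak weak evidence into a
neighboring false pair; this is the main source of high-scoring false
positives and is left in deliberately — sparser, cleaner corpora would
overstate the method.

One caveat on the held-out cutoff check: the FPR-bounded cutoff is by
construction an upper order statistic of the false-positive score
distribution, so a replicate corpus's empirical FPR at that cutoff is
expected to land near the bound itself, and whether it falls just below or
just above is dominated by sampling noise rather than signal strength.

## Pipeline defaults

Link criteria 3 co-publications and R' ≥ 20; intermediates genes and
biological processes; aggregation min-link with top-k default 5;
significance 40; candidate criteria 10 abstracts per member and 5 shared
intermediates; partition split 2000-01-01, test end 2007-05-01 (half-open);
FPR bound 0.1. Every threshold is a parameter; the CLI records all of them,
with input hashes and the package version, in a run manifest from which a
run can be reproduced exactly.
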