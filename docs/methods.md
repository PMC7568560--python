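# Methods

## Scope and data model

`trialnet` analyses a corpus of clinical-trial manuscripts, one
`PublicationRecord` each: calendar year, journal tier (a small integer
category with a user-supplied tier → median-citation table), a randomized
flag, an update index (0 = primary publication of a trial, k = k-th
follow-up, with optional pooled indices for manuscripts pooling updates of
several trials), a citation-count snapshot, a subspecialty weight map
summing to one, and the ordered author list with equal-contribution flags.
Two stable file dialects (JSON-lines; a per-author-slot TSV) round-trip
bit-for-bit, and records are always processed in `(year, record_id)` order
so every cumulative computation is order-deterministic.

Author names use the MEDLINE `Surname_Given` convention; a given block of
1–3 uppercase letters is treated as initials. The journal-tier taxonomy is
deliberately config-defined: tiers are opaque categories whose only semantic
content is the median-citation table supplied alongside the corpus.

## Identity resolution

Canonicalization applies an explicit alias table (closed transitively, with
cycle detection) and then one conservative automatic rule: an initials-only
form merges into a full-name form iff exactly one full form in the corpus
shares the surname and first initial. Anything more aggressive (career name
changes, misspellings, nationality-dependent given names) must come through
the alias/override tables; no probabilistic record linkage is attempted.

Gender is assigned per given name from lookup tables with fixed precedence:
override table, then a frequency table using a *strictly greater than* 0.9
one-gender ratio, then a dictionary table, else `ambiguous`. Initials-only
authors are always `unknown_initials`. The four categories partition the
author set.

## Impact scoring

Per manuscript and author, `score = role × trial × citation × update` with
role ∈ {3, 1} (first/last/equal-contributor vs middle), trial ∈ {2, 1}
(any randomized design vs none), update = 0.5^k (pooled updates use the
smallest pooled k — the most favourable generation), and citation = count
normalized by the single corpus-wide maximum count. For 2009–2018
manuscripts the numerator is blended: `citations + w(year) · tier_median`
with `w(year) = (year − 2008)/10` ramping linearly to 1 at 2018. The ramp is
a documented default (the phase-in schedule is genuinely open); both
endpoints are configurable, and blended scores are allowed to exceed 1 since
the normalization constant stays the raw corpus maximum. All coefficients
sit in `ImpactConfig` so the sensitivity analysis can rescale them.

Scores split across subspecialties by the record's weight map and accumulate
in an `ImpactLedger` keyed by (author, year, subspecialty); cumulative
totals are non-decreasing in time by construction.

## Networks

Every manuscript adds one multigraph edge per unordered author pair with
weight `score_i · score_j / n_authors`; dividing by team size damps single
links on large trials while the total neighbourhood weight still grows
linearly with team size ((n−1)s²/2 for equal scores s). Parallel edges are
retained for provenance and endpoint counting; all global metrics run on the
weight-summed simple view, because the modularity and assortativity
definitions used are simple-graph formulations. Self-loops cannot arise
(slots merged to one canonical author contribute no pair).

Metric conventions, each validated against a brute-force oracle on small
graphs:

* **density** — distinct co-author pairs over n(n−1)/2. This choice is
  pinned down by the published arithmetic it must reproduce (12 authors with
  30 links → 45.5%; 29,197 with 697,084 → 0.16%).
* **modularity / assortativity** — weighted, over the primary-subspecialty
  partition (equal-split assignments contribute their first tied label;
  unassigned authors form their own `"None"` community). Assortativity uses
  the weighted categorical mixing-matrix formula and is signalled as
  degenerate when fewer than two categories carry edge mass.
* **betweenness** — weighted shortest paths with distance = 1/(summed edge
  weight): stronger collaborations are shorter bridges. Unweighted mode is
  provided because the original convention is not fully determined; the
  default is weighted. A normalized-to-max variant supports "share of the
  top score" reporting.
* **PageRank** — damping 0.85, weights as transition propensities, sums
  to 1. "Median PageRank" is the median of this probability vector.
* **homophily** — per author, the share of distinct co-authors (or, in
  outlink mode, of incident edge weight) with a matching attribute; authors
  with no label or no co-authors are excluded as incalculable.
* **concentration** — top ceil(f·n) authors by impact (ties broken by key):
  their share of multigraph edge endpoints and of total impact.

Yearly series are built incrementally (adding each year's records to a
persistent builder); tests pin incremental construction to batch rebuilds.
Node attributes (impact, gender, subspecialty-in-force) are refreshed at
each yearly snapshot. Final networks export to GraphML; no layout is
computed.

## Careers

Eligibility for a subspecialty in a year: ever first/last author there, or
cumulative impact ≥ (mean − 1·SD) of all authors with positive impact in
that subspecialty that year (population SD). Reading the criterion as a
floor is the only interpretation that makes it an inclusion rule; with
heavy-tailed impact the floor is often negative, making any positive impact
eligible, which is accepted behaviour. Among eligible subspecialties the
primary is the impact-majority one; exact ties assign the tied set equally;
otherwise-ineligible authors are `"None"`. Assignment is recomputed only in
years the author publishes, and an incumbent is displaced only by an
eligible subspecialty with strictly higher impact.

Longevity = last − first publication year, with final years 2016–2017
extended to 2018 when the career began before 2016 (publication lag
truncation). The subspecialty-change flag compares only single-label years,
ignoring `"None"` and tie states — moving through an equal split is not
counted as a change unless the dominant label itself changes.

## Statistics

* **Rank-sum comparisons** are exact (full enumeration of C(n+m, n) mid-rank
  assignments, two-sided p = share of assignments at least as deviant from
  the null mean) when both groups have ≤ 10 observations, else the
  tie-corrected normal approximation via the equivalent Mann–Whitney U.
  Quartiles use linear interpolation. P-values are stored at full precision;
  "< 0.001" is formatting only.
* **LOESS** is locally weighted quadratic regression with tricube weights
  and span 0.75 (nearest ceil(span·n) points per evaluation); a degree-2
  local fit reproduces noiseless quadratics exactly, which the tests use as
  the correctness anchor.
* **Parity year**: ordinary least squares on the most recent 30 years
  (configurable) of new-author woman proportions, reporting the first
  calendar year the line reaches 0.5; the exact estimator behind such
  extrapolations is an open choice, so the window is exposed and recorded in
  the output.
* **Sensitivity analysis**: five coefficient settings — baseline, role
  ×(1±0.67), trial ×(1±0.5). Each variant rebuilds the ledger and the yearly
  assortativity/modularity series and reports Pearson correlations against
  baseline (exactly 1 at baseline by construction) plus the variant's
  max-normalized score distribution. Correlations on series shorter than 3
  points or with zero variance are flagged as degenerate rather than
  reported.

## Synthetic corpus generator

The generator emulates the structural conditions the analysis assumes, at
roughly 1/50 of the scale of a real seven-decade corpus (defaults: ~110
manuscripts, ~600–800 authors, 1946–2018) so that the full pipeline runs in
seconds; all parameters are on `SimulationConfig`:

* yearly manuscript rate: geometric ramp 0.32 → 4.5 expected papers
  (Poisson draws, at least one paper in the first year);
* team size: log-normal around a geometric median ramp 6 → 20 with σ = 0.33,
  putting the final-year IQR near 16–25;
* 13 subspecialties drawn uniformly per paper; each team slot belongs to the
  paper's subspecialty with probability 0.88, else a random other — applied
  identically to veterans and new entrants, which realizes a median
  neighbour homophily of ~0.84–0.88 after multi-subspecialty papers (10%)
  and cross-community picks dilute it;
* veteran recruitment weight 1 + strength·(papers authored) (preferential
  attachment, default strength 1); 45% of slots are new entrants, keeping
  the median career at a single year;
* women's entry share 15% before 1980 rising linearly to 40% at 2018; men
  get a ×2 weight in first/last-author selection (the only gendered
  mechanism — citations are gender-blind, so disparity metrics under that
  null are testable);
* citations log-normal (σ = 1.3) around the journal-tier median scaled by a
  10-year accrual factor; 4 tiers with medians 200/80/30/12;
* updates (probability 0.2) pick an earlier same-subspecialty parent,
  inherit its weights and design, reuse parent authors for half their slots,
  and occasionally (0.05) form pooled updates; a per-manuscript randomized
  probability of 0.65 yields ~78% of authors touching at least one
  randomized trial once update inheritance is included;
* names are surname-like unique tokens with a controlled gendered given-name
  vocabulary (95:5 frequency split for gendered tokens, 50:50 for ambiguous
  ones, ~9% initials-only authors), and the matching frequency table is
  emitted so identity resolution can be scored against truth.

What the generator does **not** emulate: real name collisions and
misspellings (surnames are unique, so canonicalization on synthetic data is
near-trivial), institutional or geographic structure, gendered citation or
team-size effects, seminal-event bursts within subspecialties, and calendar
non-stationarities beyond the smooth ramps. Passing recovery tests therefore
demonstrates that the pipeline measures what the generator encodes — not
that real corpora satisfy these assumptions.

## Numerical choices and degenerate inputs

Subspecialty weight sums are validated to 1 ± 1e-9. Ties in primary
subspecialty use a relative tolerance of 1e-12. PageRank runs to tolerance
1e-12 (cap 1000 iterations, convergence failure raised). Metrics undefined
on a given graph (density with < 2 nodes, modularity without edges,
assortativity with one category, empty networks) raise a dedicated
degenerate-graph error instead of returning sentinels. File outputs use
fixed key order and `%.10g` float formatting so identical runs are
byte-identical; every CLI bundle includes a manifest of SHA-256 checksums.

## Problem sizes

Tests and the acceptance surface run the generator at its default 1/50
scale (and a smaller two-decade corpus for fast unit tests); oracle
equivalence suites use 200 random graphs of ≤ 8 nodes and exhaustive
rank-sum enumeration up to 8 observations per group — sizes at which
brute-force evaluation of the defining formulas is itself exact.

## Known limitations

Citation snapshots are static per-record integers; no retrieval is
performed. The identity stage cannot resolve ambiguity the tables do not
encode, and gender categories are name-based proxies, with all the caveats
that implies. The careers floor interpretation (mean − 1·SD over positive
contributors) and the blend ramp are documented choices among defensible
readings; both are configurable. Homophily and partition metrics exclude
`"None"`-labelled authors, so their medians describe the subspecialized
population only.
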