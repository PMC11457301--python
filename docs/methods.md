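# Methods

This note documents the models and procedures implemented in
`lditrends`, the parameter choices that matter, what the synthetic
corpus generator does and does not emulate, and the package's known
limitations.

## Query semantics

Queries are boolean trees over quoted phrases with an optional
`METHODS:` field restriction. Precedence is `NOT` > `AND` > `OR`;
keywords are case-insensitive; both straight and typographic double
quotes delimit phrases.

Matching is defined by one tokenizer, used everywhere: text is
lower-cased and split on every non-ASCII-alphanumeric character, and a
phrase matches iff its token sequence occurs contiguously within one
field. Consequences, chosen deliberately and treated as a dialect knob:

- hyphens and slashes are token boundaries, so `MALDI` matches
  "MALDI-TOF" and `"laser desorption/ionization"` matches both the
  slashed and the spaced spelling;
- `MS` matches only as a whole token, never as a substring;
- a `METHODS:` term fails on publications with no methods text — there
  is no silent fallback to the abstract;
- unprefixed terms search title, abstract and methods text, and a
  phrase cannot span field boundaries.

The upstream literature search engine this dialect approximates may
apply stemming or section heuristics we do not model; no claim of
identical behaviour is made. The shipped technique query set (17 named
queries) is conjoined at load time with the
`(METHODS:"mass spectrometry" OR METHODS:"MS")` guard.

## Enrichment statistics

For substance *s* with synonym set *S* (searched as an unrestricted OR
— matrix names appear in titles and abstracts, not only methods), we
count `total` (publications matching *S*), `with_technique`
(additionally matching the technique query), and the joint counts with
the three analyte contexts: SM = `"small molecule" OR "small
molecules"`, PP = `peptide OR peptides OR protein OR proteins`,
OP = `oligomer OR oligomers OR polymer OR polymers`.

- **Background rate**: mean and sample standard deviation (ddof = 1) of
  `100 · with_technique/total` over common non-matrix chemicals
  (adenosine, alanine, ascorbic acid, chlorophyll, cholesterol,
  cisplatin, cocaine, glucose, nicotine, water). Chemicals with
  `total = 0` are excluded with a warning; at least two must remain.
- **Enrichment rule**: `with_technique/total ≥ fold × background mean`
  (default fold 5) **and** `with_technique ≥ 10`. The fraction is taken
  over the substance's own publications (the substance marginal), not
  over the technique corpus.
- **Ratios**: any ratio with a zero denominator is `None` (undefined),
  carried through sorting and output as `NA` — never coerced to zero
  and never an exception. Table output rounds ratios to 2 decimals in
  the published-table style, 3 decimals by default.
- **Weighted average** of SM/PP (or SM/OP) over a table: the pooled
  ratio Σ with_sm / Σ with_pp over rows with a nonzero denominator.
  This equals a per-row-ratio mean weighted by denominator counts, so
  it reduces to the row ratio for a single row and always lies within
  the range of the defined per-row ratios. Because the weighting behind
  a pooled literature average is a genuine modelling choice, an
  alternative mode weighting per-row ratios by `with_technique` is also
  provided; the pooled form is the default. Splitting a row into two
  rows with the same summed counts leaves the pooled value unchanged
  provided both halves keep a nonzero denominator (a half with
  numerator but zero denominator becomes an undefined-ratio row and is
  excluded from pooling).
- **Expected ratio**: the corpus-size ratio n_SM/n_PP reported to three
  decimals, the value expected if matrix mentions were independent of
  analyte context; `excess_over_expected` reports the percent excess of
  the observed pooled average over it.

## VOSviewer export

VOSviewer rejects missing values, so exports impute:

- **Year**: first present field of pubYear, journal year of
  publication, first publication date, electronic publication date,
  first index date (dates contribute their year component; an
  unparseable value is treated as absent with a warning); if all five
  are absent, 2006 — the median publication year of the source
  database — with provenance `imputed_median`.
- **Citations**: missing counts become 0.
- **Citations per age**: `citations / max(reference_year − year, 1)`.
  The clamp defines an age for same-year publications; integer years
  are used throughout (fractional ages from full dates would be a
  refinement the record model does not require). The reference year
  defaults to 2023, the archival query date of the corpora this
  package is designed to reproduce, and is configurable.

The corpus file (title TAB abstract, tabs/newlines inside fields
flattened to spaces) is written row-aligned with the scores file and
the alignment is verified. The thesaurus file maps excluded terms
(shipped list: month and country names; editable resource) to empty
replacements. The minimum term-occurrence threshold for a corpus of
*n* publications is `round(base_threshold · n / base_n)` (half-up,
floor 1), scaling the base threshold of 10 defined on a base corpus.

## Property landscapes

Annotated entities of a corpus slice are placed at (logP, MW):

- **MW**: explicit entity value, else computed from the Hill-notation
  formula with standard atomic weights (trailing charges ignored,
  dot-separated components summed), to 3 decimals.
- **logP**: explicit entity value, else the Wildman–Crippen
  atomic-contribution estimate computed from SMILES with RDKit. The
  precedence makes ingestion of precomputed property tables possible.
  Entities with neither are excluded with a warning.
- Entities carrying the ChEBI role "MALDI matrix material" are removed
  before visualization — they co-occur with the technique terms by
  construction, not because they are analytes.

The grid defaults to logP ∈ [−10, 15] in steps of 0.5 (x) and MW ∈
[0, 1500] Da in steps of 25 (y), covering the ranges where text-mined
small-molecule literature concentrates; a compound class with shared
logP and varying mass forms a vertical line. Cell weights count either
publication–entity pairs (default: one per annotating publication) or
total named-entity recognitions; both totals are reported. Out-of-range
points are counted and reported, never silently clipped. `property_
summary` returns the weighted mean MW and logP under the same two
modes — occurrence-weighted and recognition-weighted averages answer
slightly different questions and neither is canonical.

The test suite cross-checks the RDKit-based logP against OpenBabel's
independent Wildman–Crippen implementation on a 50-molecule fixture of
neutral organics (hydrocarbons, O-functional groups, nitriles, azo
compounds, pyridine/thiophene/furan heteroaromatics). That fixture
deliberately spans the region where the published atom-typing rules are
unambiguous; for H on amine/amide nitrogen, sp3 amine nitrogen,
hypervalent sulfur and bare water, independent implementations of the
method legitimately differ in typing, so agreement there is a property
of toolkit conventions rather than of correctness.

## Synthetic corpus generator

The generator produces corpora whose latent state is recorded exactly,
so every pipeline stage can be validated end to end:

- **Techniques**: per publication, each technique label fires
  independently with its configured prevalence (default: MALDI at
  0.08). A fired label injects the technique phrase plus the "mass
  spectrometry" guard phrase into the methods text only.
- **Matrix substances**: mentioned with probability
  `P(s | technique)` when a relevant label fired (defaults 0.005–0.35
  across five substances), else a small base rate — giving substances
  that range from almost-always-MALDI to background-level, like the
  real matrix spectrum.
- **Non-matrix chemicals**: the ten baseline chemicals are mentioned
  with configured marginal rates (0.02–0.15, so each exceeds 100
  publications at n = 10 000), with conditional rates derived by Bayes'
  rule so that `P(technique | chemical) = background_rate` exactly
  (default 0.01, i.e. a ~1% background co-occurrence).
- **Contexts**: the SM/PP/OP context phrases are injected into
  abstracts at one rate given the focal technique and a lower base rate
  otherwise.
- **Annotations**: analyte classes (defaults: small metabolites,
  lipids, oligosaccharides) have lognormal MW and normal logP entity
  distributions and per-publication mention rates; annotation counts
  are 1 + Poisson. Matrix and baseline chemicals also get entities, the
  matrices carrying the "MALDI matrix material" role so the landscape
  filter is exercised.
- **Metadata**: the year is uniform over 1990–2023; with probability
  0.05 all five year fields are absent, otherwise one source field is
  drawn (weights 0.70/0.10/0.10/0.05/0.05 down the fallback chain) and
  populated together with the fields after it, so the resolver's
  provenance is recoverable exactly. Citations are negative binomial
  with mean 0.8 per year of age and dispersion 1.2 (overdispersed, like
  real citation counts), missing with probability 0.02; the
  age-proportional mean makes the citations-per-age score flat in age
  by construction.

Losslessness is enforced, not hoped for: filler text comes from a fixed
vocabulary disjoint from every query token, and configuration
validation rejects any pair of injected phrases (across techniques,
contexts, substances and synonyms) where one is a token-subsequence of
the other. Under these conditions the query engine's counts equal the
recorded truth exactly, which the tests assert.

One global seed drives counter-derived per-publication substreams
(`default_rng([seed, i])`), so corpora are byte-identical across runs
and stable under partial regeneration.

**What the generator does not emulate**: linguistically realistic
prose, named-entity-recognition errors, acronym ambiguity (e.g. FAB the
technique versus Fab the antibody fragment), correlated technique
labels, preprint/journal duplicates, or the true marginal distributions
of the live literature. Passing tests therefore demonstrate that the
pipeline measures what the corpus contains — not that a live corpus
would yield any particular published value.

## Problem sizes and numerical choices

The statistical acceptance checks run on a 10 000-publication corpus
(seed fixed in the tests), where every baseline chemical exceeds 100
publications and binomial standard errors are small enough for 3-SE
checks to be informative; unit tests use 2 000. Recovery checks compare
at 3 standard errors with the correct clustering: class property means
use entity-level cluster SEs (each entity's property value is a single
draw reused across its annotating papers), and conditional
co-occurrence checks use binomial SEs at the substance's realized
publication count. Ties in the co-occurrence table sort break by total
count, then substance name. Rounding is half-up for the occurrence
threshold; ratio rounding happens only at the reporting boundary.

## Known limitations

- The engine is a deliberate approximation of the upstream search
  dialect; counts on live corpora will differ where stemming or section
  parsing differ.
- No deduplication of multi-version records (preprint + journal
  article) is performed.
- Published weighted averages depend on unpublished per-row context
  counts and on the live corpus state at the archival query date;
  the package reproduces the arithmetic and the procedure, not those
  specific values.
- The landscape averages depend on which logP predictor generated a
  precomputed table; when computing from structure this package uses
  Wildman–Crippen exclusively.
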