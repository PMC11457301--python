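# lditrends

Text-mining analysis of trends in laser desorption/ionization mass
spectrometry (LDI-MS), focused on which matrix substances are used for
small-molecule versus peptide/protein and polymer applications.

Soft LDI techniques such as MALDI co-crystallize the analyte with a
UV-absorbing matrix compound, and matrix choice is strongly
analyte-dependent. This package mines a literature corpus for those
preferences instead of relying on a manually curated reading list. It
provides, as a library and a `lditrends` command line:

- **Corpus model** — line-delimited publication records using Europe PMC
  core field names (`pubYear`, `citedByCount`, `firstPublicationDate`,
  `electronicPublicationDate`, `firstIndexDate`,
  `journalInfo.yearOfPublication`), plus ChEBI-style annotation and
  chemical-entity tables (TSV).
- **Query engine** — boolean phrase queries with `AND`/`OR`/`NOT`,
  parentheses and a `METHODS:` field restriction; ships the named
  technique query set (APCI, EI, ESI, DART, DIOS, FAB, LDI, NALDI,
  MALDI, NIMS, SALDI, SELDI, SIMS, …), each conjoined with the
  `(METHODS:"mass spectrometry" OR METHODS:"MS")` guard.
- **Enrichment statistics** — per-substance co-occurrence counts with a
  technique query; a background rate from 10 common non-matrix
  chemicals; the enrichment rule *fraction ≥ 5 × background and ≥ 10
  co-occurring publications*; SM/PP and SM/OP context ratios (how often
  a matrix co-occurs with "small molecule(s)" versus "peptide(s)/
  protein(s)" or "oligomer(s)/polymer(s)"), pooled weighted averages
  Σ num / Σ den, and naïvely expected ratios from corpus sizes.
- **VOSviewer export** — corpus, scores and thesaurus files, with the
  publication-year fallback chain (pubYear → journal year → first
  publication date → electronic publication date → first index date →
  imputed 2006), zero-imputed citations, a citations-per-age "hot
  topic" score, and the corpus-size-normalized minimum term-occurrence
  threshold round(10 · n/n₀).
- **Property landscapes** — SCOPE-style 2D density of text-mined
  compounds in (logP, molecular weight) space, with Wildman–Crippen
  logP, formula-based molecular weights, and removal of entities
  carrying the ChEBI role "MALDI matrix material".
- **Synthetic corpus generator** — seeded corpora with exact ground
  truth for every quantity above, used by the test suite and for
  end-to-end pipeline validation.

## Worked example

```python
from lditrends import (GeneratorConfig, generate_corpus, truth_summary,
                       build_cooccurrence_table, background_rate,
                       flag_enriched, parse_query)
from lditrends.synthetic_corpus import config_substances

config = GeneratorConfig(n_publications=10_000, seed=101)
corpus, truth = generate_corpus(config)

matrices, nonmatrix = config_substances(config)
technique = parse_query(config.focal_technique)   # "MALDI"
rows = flag_enriched(
    build_cooccurrence_table(corpus, matrices, technique),
    background_rate(corpus, nonmatrix, technique),
)
for r in rows:
    print(f"{r.substance:24s} {r.with_technique:4d}/{r.total:4d} "
          f"enriched={r.enriched}")
```

prints

```
hydroxycinnamic acid      311/ 315 enriched=True
dihydroxybenzoic acid     203/ 225 enriched=True
sinapic acid               81/ 111 enriched=True
aminoacridine              47/  71 enriched=True
diphenylanthracene          2/  43 enriched=False
```

Each line is one candidate matrix: how many of its publications also
mention MALDI, and whether that passes the 5×-background / ≥10-count
enrichment rule (the background over the ten non-matrix chemicals in
this corpus is ≈1%). The counts equal the generator's ground truth
(`truth_summary(truth)`) exactly — phrase injection is lossless, which
is what makes the synthetic corpus a meaningful end-to-end check.

The same pipeline runs from the shell:

```sh
lditrends simulate --n 10000 --seed 101 --out-dir demo
lditrends query --corpus demo/corpus.jsonl --query-name MALDI
lditrends enrich --corpus demo/corpus.jsonl --out demo/table.tsv
lditrends vos-export --corpus demo/corpus.jsonl --out-prefix demo/maldi
lditrends landscape --corpus demo/corpus.jsonl \
    --annotations demo/annotations.tsv --entities demo/entities.tsv \
    --technique MALDI --out-prefix demo/maldi
lditrends run-all --out-dir demo_all --seed 101
```

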