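# scatbarcode

A toolkit for mitochondrial *ATP6* mini-barcode species identification from
non-invasive (scat) samples, aimed at wildlife-survey practitioners and
conservation-genetics labs working with degraded faecal DNA.

The marker is a 172 bp amplicon — a 21 nt forward primer site (ATP6-DF3,
`AACGAAAATCTATTCGCCTCT`), a 126 bp species-diagnostic insert, and a 25 nt
reverse primer site (ATP6-DR1, `CCAGTATTTGTTTTGATGTTAGTTG`). The package
covers the full desk-side workflow around this marker:

- **In silico PCR** (`primer_eval`): locate the amplicon on reference
  mitochondrial sequences (either strand), tally primer–template mismatches
  over the full primer and over the 3′ pentamer (the five bases nearest the
  3′ terminus, where mismatches most disrupt extension), and classify
  expected amplification success: ≤1 pentamer mismatch per primer is
  *assumed successful*, 2 in the same primer is *potentially problematic*.
- **Reference database curation** (`refdb`): provenance-driven filtering
  (reviewed entries dropped in favour of originals; historical/withdrawn
  removed; captive/non-native/unknown-origin kept only as a last resort),
  species-wise haplotype deduplication, and deterministic export of a
  representative identification panel.
- **Species assignment** (`assigner`): a query insert is assigned to the
  species whose haplotype it matches within a mismatch threshold
  (default 2, strict Hamming), with regional-reference preference, explicit
  tie (ambiguity) handling, and cohort summaries.
- **Monophyly verification** (`phylo`): p-distance matrices with pairwise
  deletion, Saitou–Nei neighbour joining, nonparametric bootstrap (default
  500 replicates), and per-species monophyly scoring with newick export.
- **Survey statistics** (`surveystats`): incidence-based sample coverage

  C&#770; = 1 − (Q₁/U) · (T−1)Q₁ / [(T−1)Q₁ + 2Q₂],

  coverage rarefaction C(m) = 1 − Σᵢ (Yᵢ/U)·C(T−Yᵢ, m)/C(T−1, m) in exact
  integer arithmetic, Chao2 asymptotic richness
  S&#770; = S_obs + ((T−1)/T)·Q₁²/(2Q₂), attempt-ledger accounting for
  multi-extraction retry workflows, χ² goodness of fit and Fisher's exact
  test.
- **Synthetic data** (`synth`): seeded generator of reference panels and
  error-bearing query cohorts with full ground truth, for testing the whole
  pipeline without any downloads.

## Worked example

Simulate a six-species panel (two haplotypes per species, between-species
p-distance 0.10, within-species 0.01) with 25 queries per species carrying
~1 substitution and ~1.3 `N` base calls per 126 nt, then identify them:

```console
$ scatbarcode simulate --seed 12 --n-queries 25 --out demo
panel: 12 records, 9 haplotypes; 150 queries

$ scatbarcode identify --query demo/queries.fasta --db demo/references.fasta \
    --db-meta demo/references.tsv --out demo_id
assigned 87/150 (58.0%)

$ scatbarcode identify --query demo/queries.fasta --db demo/references.fasta \
    --db-meta demo/references.tsv --ambiguity-policy compatible --out demo_id2
assigned 134/150 (89.3%)
```

Under strict counting every `N` consumes mismatch budget, so queries with
noise plus masking exceed the 2-mismatch threshold and only 58% resolve;
treating `N` as compatible with any base recovers 89%, in line with the
binomial expectation P(substitutions ≤ 2) ≈ 0.92 at this error rate. Every
assigned call matches the generator's truth table.

Survey-side, given per-species identified-sample counts:

```console
$ scatbarcode survey-coverage --incidence counts.tsv -m 9 --out cov
{"T": 149, "S_obs": 6, "Q1": 2, "Q2": 1, "coverage_percent": 98.67,
 "S_asymptotic": 7.99, "coverage_percent_at_m9": 91.68}
```

i.e. a survey of 149 identified scats from six species (130/12/3/2/1/1)
covers an estimated 98.67% of the community's incidence probability, nine
samples already cover ~92%, and the Chao2 estimate of 7.99 species suggests
about two species went undetected.

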