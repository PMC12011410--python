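# Methods

## The marker and its coordinate frame

The *ATP6* mini-barcode is a 172 bp amplicon composed of a 21 nt forward
primer site, a 126 bp diagnostic insert, and a 25 nt reverse primer site.
All coordinates in this package are 1-based and inclusive on the amplicon
sense strand: forward primer 1–21 (3′ pentamer 17–21), insert 22–147,
reverse primer 148–172 (3′ pentamer 148–152). The reverse primer is written
5′→3′; since it anneals to the sense strand, its 3′-terminal base maps to
amplicon position 148 and its bases are compared against the reverse
complement of sense positions 148–172.

Mismatch cells are reported primer base first, then the base the primer
would need to equal on its annealing-equivalent strand (sense strand for
the forward primer, antisense for the reverse). Published mismatch tables
for this marker do not state which strand their X–Y cells refer to; the
annealing-equivalent convention is the one that reproduces the published
wild-dog (T–G at the 3rd, G–T at the 4th pentamer position) and
white-tailed-mongoose patterns, and is adopted here as an interpretation.

## Amplifiability classification

A species is *assumed successful* when neither primer carries more than one
mismatch in its 3′ pentamer, and *potentially problematic* when either
primer carries two. The rule is per primer, not summed across primers: one
mismatch in each primer's pentamer is still assumed successful. Three or
more pentamer mismatches in one primer fall outside the range observed in
the carnivore panels this rule was calibrated on; they are conservatively
folded into the problematic class (a severity the two-level scheme cannot
express is never allowed to look *better* than two mismatches).
Amplicon location uses exhaustive sliding comparison of both primer sites
on both strands (templates are short; correctness over speed), with a
default cap of 6 mismatches per primer — the largest full-primer tally seen
in practice for this marker. Ambiguity codes in templates count as
mismatches under the strict policy used for report tables.

## Curation and haplotype reduction

Provenance is metadata, not inference: historical, withdrawn, captive,
non-native and unknown-origin judgments are human annotations supplied in a
TSV sidecar. The only auto-flag is `reviewed_refseq` from the `NC_` prefix,
which is purely syntactic. Filtering drops reviewed entries when an
original submission of the same species exists, drops historical/withdrawn
records unconditionally, keeps last-resort provenance only when a species
has no cleaner record, and moves records with incomplete insert coverage to
a binding-assessment-only set. Haplotype identity is exact string equality
within species (no ambiguity folding: a record with an `N` either resolves
against a conspecific or stands as its own haplotype with a warning). The
representative of a haplotype is the lexicographically smallest member id —
the choice is not scientifically meaningful and is fixed only for
determinism.

## Assignment rule

A query insert is assigned to the species minimising strict Hamming
distance over the species' haplotypes, subject to a threshold (default 2
mismatches per 126 nt). Ties between species at the minimum distance within
the threshold are reported as *ambiguous* — no arbitrary winner. "Same
area" preference is an optional region tag: regional references are
searched first, and the global set is consulted only when no regional hit
falls within the threshold. This reflects deep intraspecific geographic
divergence (a local reference can match a query exactly while repository
references from elsewhere sit ~10 mismatches away, as seen for banded
mongoose). Distances are computed on the 126 nt insert only; primer-binding
segments carry no assignment information. Queries with IUPAC ambiguities
use strict counting by default (conservative: an `N` spends mismatch
budget); a `compatible` mode treating intersecting IUPAC sets as matches is
available for noisy Sanger calls.

## Phylogenetic verification

Species-level monophyly on a neighbour-joining tree is the marker's
diagnostic criterion. With only 126 characters there is too little signal
to estimate a probabilistic substitution model reliably, so the simple
p-distance is used (proportion of differing sites, pairwise deletion of
gap/`N` sites, per-pair denominators recorded; a pair with zero comparable
sites is an error). NJ is the classic Saitou–Nei algorithm with
deterministic lowest-index tie-breaking in the Q-matrix; negative branch
lengths are clamped to zero with the deficit transferred to the sister
branch, preserving path lengths. On additive matrices the generating tree
is recovered exactly (verified against an independent random-additive-tree
oracle in the test suite). Bootstrap supports (default 500 column-resampling
replicates, explicit seed, no global state) are mapped onto the all-data
reference tree rather than a majority-rule consensus, mirroring how
per-node support figures are usually produced; the denominator is the
number of retained replicates (a replicate is dropped, counted and warned
about if resampling leaves some pair with no comparable sites). An
alignment with no variable sites is flagged `no_signal` and supports are
n/a rather than a meaningless 100.

## Survey statistics

The sampling unit is one identified scat sample; incidence frequency Yᵢ is
the number of samples assigned to species i, U = ΣYᵢ, and Q₁/Q₂ count
species seen in exactly one/two samples. Estimators follow the
incidence-frequency branch of the Chao-style coverage framework:

- coverage at T: C&#770; = 1 − (Q₁/U)·(T−1)Q₁/[(T−1)Q₁ + 2Q₂]
- rarefied coverage: C(m) = 1 − Σᵢ (Yᵢ/U)·C(T−Yᵢ, m)/C(T−1, m), evaluated
  with exact integer binomial coefficients (`math.comb` + `Fraction`), so
  no overflow or log-space approximation is involved at any survey size
- asymptotic richness: Chao2, S_obs + ((T−1)/T)·Q₁²/(2Q₂), with the
  bias-corrected fallback S_obs + ((T−1)/T)·Q₁(Q₁−1)/2 when Q₂ = 0
- extrapolation beyond T (coverage and richness) is provided but always
  flagged as extrapolation; nothing downstream depends on it.

χ² goodness of fit uses the asymptotic upper-tail p with no continuity
correction; Fisher's exact test is the standard two-sided sum of
hypergeometric probabilities no larger than the observed table's, with
p = 1 by convention (and a warning) for a zero margin. Both delegate to
scipy behind the module surface; the test suite checks Fisher against a
full hypergeometric enumeration oracle. Attempt-ledger percentages are
reported to one decimal, coverage to two, matching how such tables are
conventionally printed.

Two spatial statistics often reported alongside such surveys (χ² against
road-length proportions, Fisher on border/non-border splits) require the
underlying road lengths and split counts, which are survey-specific inputs;
the functions accept them but the package ships no defaults for them.

## Synthetic data: what it emulates, what it does not

`synth.generate_panel` builds a random ancestral amplicon with exact primer
sites and derives species by planting substitutions: each species founder
differs from the ancestor at Binomial(126, inter/2) sites so that pairwise
between-species distances centre on inter·126; within-species haplotypes
differ from the founder at Binomial(126, intra) sites. Defaults are a
six-species guild (the size detected in a typical small scat survey), two
haplotypes per species, inter = 0.10 versus intra = 0.01 — a clearly
separable regime, which is the premise of the marker — a query error rate
of 1/126 (about one substitution per insert, plausible for degraded
template) and an `N` rate of 0.01 per base. Queries are a sampled haplotype
plus independent per-base substitution noise and `N`-masking.

The generator is deliberately idealised: substitutions only (no indels — the
assignment rule is substitution-based), no coalescent structure within
species, no chromatogram artefacts, no contamination or mixed-species
scats, and species divergences are independent rather than tree-shaped.
Passing tests therefore demonstrate the correctness of the algorithms under
the marker's stated premise (inter ≫ intra divergence), not robustness to
taxon sampling gaps, shared haplotypes between recently diverged species,
or mixture — all of which the curation warnings and the ambiguity status
are designed to surface rather than hide.

At the default error rate the binomial tail P(errors > 2) ≈ 0.079 puts a
hard ceiling of ~92% on the fraction of noisy queries that can clear a
2-mismatch threshold; accuracy of the method is therefore judged on the
correctness of the calls it makes (which is 100% in the separable regime),
with the unassigned fraction tracking the binomial tail.

## Numerical and interface choices

- Hamming distance: a gap (`-`) always counts as a mismatch, including
  gap-vs-gap; gaps are legal only in alignment containers, never in curated
  inserts.
- `U` (RNA) input is folded to `T` with a warning; all storage is uppercase.
- Problem sizes in tests are chosen so the full suite runs in seconds:
  oracle sweeps use exhaustive enumeration at small margins plus seeded
  random instances at larger ones, the bootstrap convergence check compares
  500 against 2,000 replicates on a 4-taxon alignment, and the
  rarefaction Monte-Carlo oracle uses 100,000 draws (standard error well
  under the 0.005 agreement bound).
- Every CLI run writes a JSON manifest (tool version, subcommand, merged
  configuration, seed) next to its outputs; re-running with the same
  manifest reproduces outputs byte-identically.
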