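# Methods

This note documents the models, rules and numerical choices behind
`gwaskit`, and what the synthetic-data tests do and do not demonstrate.

## Scope: harmonization, not quality control

The pipeline validates and harmonizes; it deliberately does not filter on
strand-ambiguity (A/T, C/G pairs), minor-allele frequency or imputation
INFO. Those are analysis-specific QC decisions; applying them here would
force re-harmonization for every downstream use. The only removals are rows
that are *unusable* (missing identity or alleles, out-of-domain values,
duplicates) or *unidentifiable* (no reference entry, incompatible alleles).
Every removal is counted per filter in the cleaning report, and
removed + surviving = input rows is asserted throughout.

## Column mapping

Headers are mapped case-insensitively through a fixed alias dictionary
(`gwaskit.ingest._ALIASES`). The dictionary is a pragmatic union of the
dialects of common tools (PLINK, GWAS catalog, METAL, BOLT-LMM, SAIGE);
because there is no published standard, the dictionary is part of this
package's contract and is easy to extend. Two deliberate choices:

* `MAF` is accepted as `EAF` only when nothing else claims `EAF`, and the
  fallback is logged — minor-allele frequency equals effect-allele frequency
  only when the effect allele is minor.
* An explicit user mapping always wins over guessing.

Cells are read as text; numeric coercion happens during validation so that a
mis-mapped column fails loudly (a column in which more than half of the
non-missing values fail coercion is a fatal error) instead of silently
becoming NaN.

## Reference panel and curation

The reference is a curated extract of a dbSNP-style catalogue: one record
per variant with the rsID number, chromosome, 1-based positions on both
GRCh37 and GRCh38, reference allele and alternate-allele list, stored as
hive-partitioned Parquet (`CHR=<label>/`), with indels kept in a separate
partition in left-aligned, trimmed (minimal) representation, plus a
merged-rsID table mapping retired identifiers to current ones.

Curation applies four filters in a fixed order, reporting counts per filter:
(1) drop rsIDs mapping to more than one position on either build; (2) at
each chromosome+position (per build) keep the smallest rsID *number* (rs45
before rs123 — numeric, not lexicographic, order) and drop the rest; (3)
drop records whose chromosome differs between builds; (4) keep only records
with positions on both builds. The order matters for the counts; filters are
idempotent as a set (re-curating curated data removes nothing). After
curation, (chromosome, position) is a key within each build and rsID numbers
are unique panel-wide. Multiallelic sites are stored as one record with
several alternate alleles.

Merged-rsID chains (a → b → c across releases) are resolved transitively to
the terminal identifier at load time; self-maps and cycles are rejected.

## Cleaning rules

Validation rules, chosen as the minimal widely defensible set:

| column | rule |
|---|---|
| P | in (0, 1]; literal 0 replaced by the smallest positive normal double (≈2.2e−308) and logged, since P = 0 is an underflow artifact at genome-wide hits, not evidence the row is bad |
| EAF | in (0, 1), exclusive |
| SE | > 0 and finite |
| INFO | in [0, 1.1] (some imputation dialects slightly exceed 1) |
| N, CaseN, ControlN | > 0; N ≥ CaseN + ControlN is logged if violated, not enforced |
| POS | integer in [1, 3×10⁸] |
| CHR | in {1..22, X, Y, MT} after normalization (`chr1`/`ch1`/`CHR1` → `1`; PLINK numerics 23/24/25 → X/Y/MT) |
| B, Z | finite |
| alleles | uppercased; characters outside {A,C,G,T} allowed only as the legacy single-character indel codes D/I/R; EffectAllele ≠ OtherAllele |

Missing values never fail validation — a missing statistics column is
normal; only present-but-invalid values remove a row. Deduplication keys on
chromosome:position (or rsID when positions are absent) plus the *unordered*
allele pair, so (A,G) and (G,A) at one site are one variant; the first
occurrence survives (deterministic and order-independent in count).

## Identity repair

Genome build is inferred from the first 10,000 cleaned rows with complete
CHR+POS (first rather than random: deterministic, and summary statistics are
not ordered by anything that correlates with build). Rows are matched
against both builds' positions; the build with more matches wins, ties break
to GRCh38 with a warning, and zero matches on both builds is fatal.

Compound identifiers in the rsID column (`1:12345:A:G`, `chr2:555`,
underscore-separated variants) are split into CHR and POS; alleles embedded
in the identifier are ignored in favor of the allele columns, which went
through validation.

Matching prefers CHR:POS (on the inferred build) and falls back to rsID for
rows without positions; with the synthetic panels both routes provably
return the same variant set. Input rsIDs are dropped wholesale whenever
CHR+POS are also available, because reference-derived rsIDs are strictly
more trustworthy than those shipped in the file. Indel rows are matched
against the indel partition (strategy `qc`), passed through unmatched
(`keep`) or dropped (`drop`).

Allele compatibility: the unordered pair {EffectAllele, OtherAllele} must be
a subset of {ref} ∪ alts with one member equal to ref; failing that, the
base-complemented pair may satisfy the same condition, which is accepted as
a strand flip and flagged `strand_flipped` rather than removed (downstream
QC can drop flips if it wishes; removing them here would silently discard
valid data from chips reporting the opposite strand). Palindromic pairs
match in their original orientation and are never resolved or removed here.
When several alternate alleles are compatible the row is kept once; the
`multi_allelic` flag (set on every row sharing an rsID) carries the
ambiguity.

## Statistics imputation

Missing cells of B, SE, Z, P and N are filled from the closed-form
identities listed in the README, in a fixed order, with two passes so a fill
can enable a later one (the dependency graph needs no more; a fixpoint is
reached). Existing values are never overwritten — on a fully populated table
the step is the identity. Choices worth recording:

* MAF in the N identity is min(EAF, 1−EAF), the standard meaning.
* The factor 4 in `N = 4/(2·MAF·(1−MAF)·SE²)` is the effective-sample-size
  convention for case-control designs (N_eff = 4/(1/N_cases+1/N_controls)).
  It is *not* the algebraic inverse of the SE identity at Z = 0 (factor 1);
  the two conventions coexist in the field and the effective-N form is
  implemented as stated. Consequently N is the one column whose
  deletion-then-imputation does not reproduce a quantitative-trait ground
  truth.
* Two-sided P uses `scipy.stats.norm.sf`, which is accurate deep into the
  tail; P underflows to zero only beyond |Z| ≈ 38.6, the double-precision
  limit. The Z-from-P route uses the upper-tail χ²₁ quantile, matching the
  numerically robust convention, and the round trip Z → P → Z is exact to
  better than 1e−12 relative over |Z| ≤ 37.
* Rows where a formula is undefined (EAF exactly 0/1, N ≤ 0) skip that
  imputation and are logged; nothing is removed.

Reference allele frequencies (per-population table keyed by rsID, storing
the alternate-allele frequency) are oriented to the effect allele —
complemented alleles included — giving `EAF_ref`; a missing study EAF is
filled from it and flagged `eaf_imputed`. `freq_diff` is |EAF − EAF_ref| >
0.2, missing (not false) when either side is unavailable.

## Storage and meta-analysis

Output is hive-partitioned Parquet by chromosome with deterministic file
names, JSON sidecars (cleaning report, run metadata), and native nulls — the
round trip is bit-exact for every numeric column. The TSV alternative writes
`%.17g` floats and reads them back with round-trip parsing, so values
survive to the last ulp. Region queries (1-based closed intervals, matching
VCF/dbSNP conventions) prune to the single chromosome partition and accept
any number of datasets, tagging rows with their source.

Meta-analysis pools per variant with inverse-variance weights on (B, SE) —
the canonical fixed-effects estimator when effects and standard errors are
available (the alternative, sample-size-weighted Z, uses strictly less
information). Grouping is by rsID; the first study's allele orientation is
canonical, swapped alleles contribute −B, and studies whose allele set does
not match are excluded with "?" in the direction string. Heterogeneity:
Cochran's Q, P_het from the upper tail of χ² with k−1 degrees of freedom,
I² = max(0, (Q−(k−1))/Q)·100, with Q = 0 defining I² = 0 and k = 1 leaving
all three missing. Variants with fewer than `min_k` usable studies (default
2) are omitted. Processing is per chromosome partition, bounding memory by
one chromosome of the stacked studies.

## Synthetic data

The generators emulate: a curated dual-build panel (constant per-chromosome
GRCh37→GRCh38 offset, 10 kb by default; ~10% indels in minimal
representation; ~5% multiallelic sites; a merged-rsID map including one
two-hop chain), and summary statistics drawn from it with EAF ~ U(0.05,
0.95), true effects β ~ N(0, 0.02²), N = 50,000 per study and unit sampling
noise on the Z scale — magnitudes typical of a well-powered quantitative
GWAS. Statistics are generated self-consistently with the imputation
identities (SE = 1/√(2·EAF·(1−EAF)·(N+Z²)), B = Z·SE, P = 2Φ(−|Z|)), so
deleting any of Z, B, SE or P and re-imputing recovers ground truth; this is
what makes the formula-recovery tests sharp. Corruptions (missing alleles,
duplicates, invalid P/EAF/SE, off-panel positions, incompatible alleles,
compound ids, `chr` prefixes, swapped-allele/negated-B rows) are planted on
disjoint rows by default so each filter's count is attributable exactly; an
overlap mode exists for order-of-filters experiments. A single integer seed
drives everything; equal seeds give byte-identical files.

What the fixtures do *not* model: linkage disequilibrium, real allele
frequency spectra, genuine strand mix-ups at palindromic SNPs, per-variant
sample-size variation, or badly malformed files (ragged rows, mixed
encodings). Passing tests therefore demonstrate correctness of the
*mechanics* — parsing, matching, accounting, algebra — not robustness to
every real-world pathology.

Default problem sizes — panels of 300–1,000 variants over 3 chromosomes,
1,000 variants × 10 studies for the meta-analysis oracle and 10,000 variants
for its calibration, 100 tables for build-inference accuracy — are small
enough to run anywhere in seconds while leaving each check statistically
meaningful (e.g. the calibration variance estimate has standard error
≈ 0.014 at 10,000 variants, against a ±0.05 acceptance band).

## Known limitations

* Positions on both builds always come from the panel; there is no chain-file
  liftover, so variants absent from the panel cannot be rescued.
* Build inference assumes positional overlap with the panel; a table of
  panel-absent variants fails fatally rather than guessing.
* The alias dictionary cannot anticipate every header dialect; unmapped
  columns are dropped with a log line, and the explicit mapping is the
  escape hatch.
* Meta-analysis assumes independent studies (no sample-overlap correction)
  and a fixed-effects model; heterogeneity is reported, not modeled.
* Indel matching requires the reference's minimal representation; alternative
  representations in the input are matched only after the panel's own
  left-align/trim normalization, which does not renormalize input alleles.
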