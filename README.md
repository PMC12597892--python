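# gwaskit

Validation, harmonization and meta-analysis of GWAS summary statistics.

Published GWAS summary statistics arrive in dozens of dialects: inconsistent
column names, chromosome labels (`chr1` vs `1` vs `23`), genome builds,
missing statistics columns, retired rsIDs, and assorted encoding artifacts.
Before any downstream analysis (polygenic scores, heritability, credible
sets, meta-analysis) this "munging" has to happen, and it is error-prone when
done ad hoc. `gwaskit` does it once, reproducibly, and deliberately stops
short of quality control: strand-ambiguity, MAF or INFO filtering are
downstream decisions, so the harmonized output can be reused across analyses
with different QC requirements.

## What it does

Given a summary-statistics file and a curated dual-build variant reference
(rsID, chromosome, GRCh37 + GRCh38 positions, ref/alt alleles, merged-rsID
map), `gwaskit`:

1. parses any tab/comma/semicolon/whitespace-delimited file (optionally
   gzipped) and maps heterogeneous headers to canonical names;
2. removes rows missing critical identity columns, deduplicates on
   chromosome:position:{allele pair}, flags indels, validates every column
   (e.g. P ∈ (0,1], SE > 0) and harmonizes chromosome labels;
3. infers the genome build by matching up to 10,000 rows against both builds
   of the reference and keeping the build with more matches;
4. merges with the reference by CHR:POS (or by rsID, after updating retired
   identifiers), restoring rsIDs and positions on *both* builds, dropping
   variants absent from the reference or with incompatible alleles
   (strand-complement matches are accepted and flagged);
5. imputes missing statistics columns from closed-form identities, e.g.

   ```
   Z = B / SE                   P = 2 Φ(−|Z|)
   B = Z / √(2·EAF·(1−EAF)·(N+Z²))      SE = 1 / √(2·EAF·(1−EAF)·(N+Z²))
   Z = sign(B) · √(χ²₁⁻¹(1−P))          N = 4 / (2·MAF·(1−MAF)·SE²)
   ```

   filling only missing cells, never overwriting;
6. writes chromosome-partitioned Parquet (hive layout, `CHR=<label>/`) with a
   JSON cleaning report, and can query many datasets as one logical dataset;
7. runs fixed-effects inverse-variance meta-analysis directly on those
   partitioned outputs, with Cochran's Q, I² and METAL-style direction
   strings:

   ```
   w_i = 1/SE_i²,  B_meta = Σ w_i B_i / Σ w_i,  SE_meta = 1/√(Σ w_i)
   Q = Σ w_i (B_i − B_meta)²,  I² = max(0, (Q − (k−1))/Q) · 100%
   ```

A synthetic-data module generates reference panels and messy sumstats files
with exactly known ground truth, so the entire pipeline is testable offline.

## Worked example

```python
from gwaskit.fixtures import FixtureSpec, CorruptionPlan, make_reference, make_sumstats
from gwaskit import harmonize, meta_analyse

spec = FixtureSpec(seed=1, n_variants=1000,
                   plan=CorruptionPlan(na_rows=5, duplicate_rows=7, invalid_p=3,
                                       off_panel=4, allele_incompatible=2))
panel = make_reference(spec, "panel")
fx = make_sumstats(spec, panel, build=37, out_path="sumstats.tsv.gz", gz=True)

res = harmonize(fx.raw_path, panel, output="study1")
print(res.report.to_dict()["removed"])
print(res.build)
```

prints the per-filter removal counts — exactly the planted corruption plan —
and the build call:

```
{'missing_critical': 5, 'duplicates': 7, 'indel_dropped': 0, 'validation': 3,
 'no_dbsnp_match': 4, 'allele_incompatible': 2}
BuildCall(build='GRCh37', n_sampled=1037, matches_37=1033, matches_38=0)
```

Five rows lacked an effect allele, seven were duplicated variants, three had
P outside (0,1], four sat at positions unknown to the reference, and two had
alleles incompatible with the reference ref/alt set; 1,033 of the 1,037
sampled rows matched GRCh37 positions, so the table is called GRCh37 and both
builds' coordinates are attached to every surviving row. Meta-analysing two
harmonized studies:

```python
pooled = meta_analyse(["study1", "study2"], min_k=2)
print(pooled.head(3))
```

```
     RSID CHR   POS_38  k    B_meta  SE_meta   P_meta        Q        I2 direction
rs1005390   1 14236633  2 -0.015908 0.004623 0.000580 1.613599 38.026737        --
rs1033310   1 14278173  2  0.016340 0.006547 0.012565 5.337974 81.266299        +-
 rs104932   1  1238429  2  0.008722 0.005382 0.105107 2.642026 62.150259        ++
```

Each row pools the per-study effects with inverse-variance weights: `B_meta`
and `SE_meta` are the pooled effect and its standard error, `Q`/`I2` quantify
between-study heterogeneity, and `direction` gives each study's effect sign
in input order.

The same workflow is available from the shell:

```bash
gwaskit make-fixtures demo --seed 1
gwaskit clean demo/sumstats.tsv demo/panel -o demo/ds1
gwaskit query "1:1000000-2000000" demo/ds1 --build 38
gwaskit meta demo/ds1 demo/ds2 -o demo/meta
```

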