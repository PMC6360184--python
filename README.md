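# famvar

Family-exome rare-variant discovery: a tested, reusable implementation of
the workflow used when a multiplex disease family is exome-sequenced
alongside a sporadic case cohort and in-house control exomes.

It is written for statistical/medical geneticists who need the classic
dominant-model discovery recipe as composable, auditable code rather than a
one-off script pile:

* **Filtering cascade** — from raw coding variants to prioritized
  candidates: consequence filter (keep NSVs, SSVs and coding indels),
  nested public-database filters (dbSNP 135, 1000 Genomes, NHLBI ESP,
  non-psychiatric ExAC), dominant cosegregation filter (heterozygous in
  all affected, absent from all unaffected), in-house control-frequency
  filter (MAF ≤ 1% by default, absence tracked separately), PROVEAN + SIFT
  + PolyPhen-2 consensus, and linkage-region intersection — with per-stage
  counts and a complete audit trail.
* **Pedigree genetics** — obligate-carrier genotype inference for untyped
  (e.g. deceased) relatives from spouse and children, under explicit
  no-de-novo and rare-allele assumptions, and a full-penetrance dominant
  cosegregation verdict.
* **Allelic association** — Fisher's exact test from genotype count tables.
  For genotype counts (n_MM, n_Mm, n_mm), minor-allele count is
  a = n_Mm + 2·n_mm out of 2N alleles; the two-sided p-value sums
  hypergeometric point probabilities P(X = k) ≤ P(X = a) over all tables
  with the observed margins.
* **Domain burden** — HGVS p.-string mapping onto protein domain
  architecture and a carrier-level Fisher exact burden test restricted to a
  region class (e.g. the teneurin YD repeats).
* **Expression specificity** — per-species FPKM normalization by the
  maximal tissue and a cross-species brain-specificity report.
* **Synthetic data** — seeded, byte-deterministic generators for every
  input (family VCF/PED with a planted fully penetrant dominant causal
  variant, Table-style cohort genotype counts, FPKM matrices), so the
  whole pipeline is testable end to end with known ground truth.

## Worked example

Simulate a family exome study and run the full analysis:

```bash
famvar simulate --seed 3 --out-dir sim --n-background 300
famvar run-all \
    --vcf sim/family.vcf --ped sim/family.ped \
    --ann sim/annotations.tsv --regions sim/linkage.bed \
    --case-counts sim/case_counts.tsv --control-counts sim/control_counts.tsv \
    --fpkm sim/fpkm.tsv --out-dir run \
    --affected III-2 --affected III-4 --unaffected II-1 --unaffected III-1
```

`run/stage_counts.tsv` shows the cascade collapsing 300-odd variants to
the single planted candidate:

```
stage	variants	carried_III-2	carried_III-4	shared_affected	het_shared_maf_pass	het_shared_absent_controls
consequence	177	16	18	10	1	1
not_in_dbsnp	9	1	1	1	1	1
not_in_dbsnp_1000g	9	1	1	1	1	1
not_in_dbsnp_1000g_esp	9	1	1	1	1	1
not_in_plus_exac	9	1	1	1	1	1
segregation	1	1	1	1	1	1
control_maf	1	1	1	1	1	1
predictor_consensus	1	1	1	1	1	1
linkage	1	1	1	1	1	1
```

Row by row: 177 variants have coding impact; 9 are absent from every public
database; exactly 1 is heterozygous in both affected exomes and absent from
both unaffected; it is unseen in controls, called deleterious by all three
predictors, and falls inside the linkage region. `run/summary.json` names
it as the unique prioritized candidate, with cosegregation verdict `true`
(the untyped founder-spouse II-2 is inferred an obligate heterozygote from
her three heterozygous children and homozygous-reference spouse).

The statistics are usable directly from Python as well:

```python
>>> from famvar.association import ContingencyTable2x2, fisher_exact_two_sided
>>> fisher_exact_two_sided(ContingencyTable2x2(2, 238, 8, 2264))
0.24656851163500243        # 2/240 case vs 8/2272 control alleles
>>> from famvar.burden import BurdenInput, burden_test
>>> burden_test(BurdenInput(3, 121, 0, 1136))
0.0008720571251630408      # 3 YD-region carriers in cases, 0 in controls
```

The first value is the two-sided allelic p for a variant seen in 2 of 240
case alleles versus 8 of 2272 control alleles (no association); the second
shows that 3 qualifying-variant carriers among 121 cases against 0 of 1136
controls is significant at p < 0.001.

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

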