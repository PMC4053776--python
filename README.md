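# incismir

Integrative detection of **in-cis miRNA dysregulation** in tumor cohorts:
miRNAs whose expression change is statistically tied to a DNA-level
aberration at their own genomic locus — a copy-number gain or loss, an
aberration of promoter methylation, or both.

The package is aimed at cancer genomics analysts who have, for one cohort
of tumors (plus a normal-tissue methylation reference): a miRNA expression
matrix, CpG methylation β values with probe annotation, and copy-number
log-ratios with probe positions. It implements the full analysis chain and
a synthetic-cohort generator with planted ground truth so every stage is
testable without any data download.

## Method

For each miRNA genomic locus *g* and tumor *i*:

1. **Expression**: log2 array intensities are filtered (miRNAs detected in
   < 10 % of samples removed), normalized per sample by subtracting the
   90th percentile across miRNAs, and expanded from mature miRNAs to all of
   their genomic loci (a mature miRNA encoded at *k* loci contributes *k*
   identical rows).
2. **Copy number**: per-sample log2 ratios are median-centered and
   segmented by exact piecewise-constant fitting (PCF), minimizing
   SSE + γ·(number of breakpoints) by dynamic programming (γ = 40 by
   default, in units of the sample's robust noise variance). The covering
   segment's mean is the locus copy number; values > 0.1 are **gains**,
   < −0.1 **losses** (strict).
3. **Methylation**: promoter probes are tied to loci by a three-tier rule
   (designated probes → host-gene promoter probes for intronic loci →
   nearest probe), summarized per locus by the median β. With *m* and SD
   the median and standard deviation of β in normals, a tumor is
   **hypermethylated** when β > m + 2·SD and **hypomethylated** when
   β < m − 2·SD; a cutoff outside [0, 1] disables that call.
4. **Detection**: under two scenarios (activating: gain/hypomethylation;
   silencing: loss/hypermethylation) and three categories (copy number,
   methylation, combined), patients are split into altered vs non-altered
   groups and expression compared by a Wilcoxon rank-sum test, with
   Benjamini–Hochberg adjustment per (scenario, category) family. A locus
   is **in-cis** when q < 0.05 and the correlation sign is as expected
   (ρ(copy number, expression) > 0 or ρ(methylation, expression) < 0).
5. **Replication**: candidates are re-tested in an independent cohort at
   uncorrected p < 0.05 with the matching aberration type; when two CpG
   assays cover one promoter, each is tested separately and the larger p is
   reported.
6. **Downstream**: seed-family complementarity (identical nucleotides 2–8;
   the family is "altered" in a patient when any member is gained or
   hypomethylated), clinical subgroup scans (Wilcoxon / Kruskal–Wallis,
   per-variable FDR), median-split log-rank survival, miRNA–mRNA Spearman
   screening (|ρ| > 0.3, sign-consistent across cohorts), and functional
   screen hit calling (|log2 viability| > 0.2; lysate |z| > 1.96).

## Worked example

```python
from collections import Counter
from incismir import SimulationConfig, generate_cohort_pair, run_pipeline

disc, repl = generate_cohort_pair(SimulationConfig(seed=1))
result = run_pipeline(disc, replication_bundle=repl)

print(f"in-cis loci: {len(result.incis)}")
print("driver classes:", dict(Counter(m.driver_class for m in result.incis)))
print("effects:", dict(Counter(m.effect for m in result.incis)))
print(f"replicated: {len(result.replicated_loci)}")
for p in result.profiles[:2]:
    print(f"family {p.family_id}: members={len(p.locus_ids)}, "
          f"fraction of tumors with an activating aberration={p.fraction_altered:.2f}")
```

prints

```
in-cis loci: 51
driver classes: {'methylation': 20, 'copy_number': 21, 'combination': 10}
effects: {'silencing': 21, 'activating': 30}
replicated: 49
family AAAGGCU/mir-2: members=2, fraction of tumors with an activating aberration=0.62
family CAAGGUC/mir-1: members=2, fraction of tumors with an activating aberration=0.61
```

The default synthetic pair plants 50 in-cis loci (10 per mechanism: gain,
loss, hypomethylation, hypermethylation, combined) among 500 loci in 100
tumors; here the pipeline recovers all 50 (one false positive), attributes
each to the correct driver, and replicates 49 in the twin cohort. The two
family profiles show the complementary pattern: ~60 % of tumors carry an
activating aberration in at least one family member, although each member
alone is altered in only 30 %.

The same stages are scriptable from the shell:

```bash
incismir simulate --seed 1 --outdir scratch/pair
incismir run-all scratch/pair/discovery --replication scratch/pair/replication --out scratch/run
```

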