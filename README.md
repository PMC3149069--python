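# cnastats

Statistics for genome-wide somatic copy-number alterations (CNAs) in
tumor cohorts profiled on dense SNP arrays. The package answers three
questions about a cohort's CNA landscape:

1. **Where do CNAs recur?** Per-locus prevalence is tested against an
   empirical genome-wide null with exact binomial tails and FDR control,
   then collapsed to genes (*positional* clustering).
2. **Do two groups differ genome-wide?** A permutation global test
   compares whole CNA profiles between groups (germline vs tumor, early
   vs late stage, histological subtypes), accounting for the correlation
   of copy numbers along the genome and for multiplicity.
3. **Are CNAs shaped by selection and function?** Per-sample G/T ratios
   measure whether events avoid gene locations, and a gene-label
   permutation variant of GSEA finds biological gene sets enriched for
   high-prevalence CNA genes (*functional* clustering), confirmed through
   a discovery/validation cohort split.

It is aimed at statistical-genomics practitioners who have per-sample
inferred copy numbers on an ordered probe map (plus sample metadata, gene
annotation, and gene sets in GMT format) and want a tested, scriptable
reimplementation of this analysis — including a synthetic cohort
generator that makes every stage verifiable without access to patient
data.

## The statistics in brief

* **Calling.** CN = 2·signal/reference mean, median-smoothed over 11
  probes within chromosomes; gain ⇔ CN ≥ 2.7, loss ⇔ CN ≤ 1.3 (the
  thresholds detect CN ≥ 3 / ≤ 1 under up to 30% normal contamination).
* **Locus tests.** k events among n patients ~ Binomial(n, π₀), with
  π₀ = total event probe-cells / (probes × samples); exact upper-tail p,
  Benjamini–Hochberg q across the genome; per gene, the probe with the
  highest prevalence represents the gene (2 kb flank, inclusive).
* **Global test.** d_i = (p₁ᵢ − p₂ᵢ)/√(p₁ᵢ(1−p₁ᵢ)/n₁ + p₂ᵢ(1−p₂ᵢ)/n₂)
  with p_ji = (x_ji + 0.5)/n_j; D = Σ d_i²; p by permuting group labels
  (10,000 draws, add-one rule). Matched-pairs variant with within-pair
  swaps; pack-year-based greedy matching included.
* **Selection.** TP / GP = per-sample event probes total / within genes;
  G/T = GP/TP compared to the array's in-gene fraction (40.64% for the
  250K array) by one-sample t; group contrasts by Welch's t.
* **GSEA.** Weighted KS enrichment score on the prevalence ranking; null
  by permuting gene labels (20,000 draws; sets with ≥ 15 members); sets
  must be significant (p < 0.05) in both halves of a random
  discovery/validation split to be reported.

## Worked example

```python
import cnastats as cna

cfg = cna.SimulationConfig(
    seed=11, n_probes=4000, n_chromosomes=4, noise_sd=0.1,
    hotspot_loci=(("3", 500, 8.0),),           # a recurrent region on chr3
    group_specs=(
        cna.GroupSpec("blood", "blood", "none", 25, 0.4, 0.5),
        cna.GroupSpec("early", "tumor", "early", 40, 7.0, 1.2),
        cna.GroupSpec("late", "tumor", "late", 10, 20.0, 2.0),
    ),
)
probe_map, genes = cna.simulate_probe_map_and_genes(cfg)
cn, design = cna.simulate_cohort(cfg, probe_map, genes)
calls = cna.call_cnas(cna.median_smooth(cn))

tumors = design.tumors
null = cna.estimate_empirical_null(calls, tumors, "gain")
print(f"empirical null pi0(gain) = {null.pi0:.4f}")

res = cna.locus_prevalence_tests(calls, tumors, "gain", null)
print(f"loci with q < 0.05: {(res['q_value'] < 0.05).sum()} of {len(res)}")
gene_res = cna.collapse_to_genes(res, probe_map, genes)
top = gene_res.nsmallest(1, "p_value").iloc[0]
print(f"top gene {top.gene_id}: prevalence {top.prevalence:.2%}, "
      f"p = {top.p_value:.3g}, q = {top.q_value:.3g}")

g = cna.global_cna_test(calls, design.select(tissue="blood"), tumors,
                        "gain", B=2000, seed=1)
print(g.summary())

metrics = cna.compute_gt_metrics(calls, probe_map, genes, "gain",
                                 sample_subset=tumors)
r0 = cna.null_gt_ratio(probe_map, genes)
print(f"mean G/T = {metrics['gt_ratio'].dropna().mean():.4f} "
      f"vs null {r0:.4f}; {cna.test_gt_vs_null(metrics, r0).summary()}")
```

Output:

```
empirical null pi0(gain) = 0.0961
loci with q < 0.05: 97 of 4000
top gene g00101: prevalence 44.00%, p = 2.5e-10, q = 7.15e-08
global CNA test (gain): A (n=25) vs B (n=50); D = 1.117e+04, p = 0.0004998 (permutation, B = 2000)
mean G/T = 0.4016 vs null 0.4065; one_sample_vs_null: samples vs null; statistic = -1.332, p = 0.1891
```

Reading the numbers: about 10% of probe-cells in the tumors carry a gain
(the empirical binomial null); 97 loci — the planted chr3 hotspot region —
recur more often than that background after FDR control, with the top
gene gained in 44% of tumors; the genome-wide gain profile of tumors
differs from germline at the smallest achievable permutation p
(1/(B+1) ≈ 5·10⁻⁴); and with the generator's default mild placement
selection (strength 1.5 against in-gene starts) the mean G/T ratio sits
slightly below the 40.65% in-gene probe fraction but not significantly so
at this sample size — long segments dilute start-placement selection, as
discussed in `docs/methods.md`.

The same workflow is scriptable from the shell:

```bash
cnastats simulate --config sim.yaml --out-dir cohort/
cnastats run-all --config run.yaml     # call → locus tests → collapse →
                                       # global tests → G/T → GSEA + manifest
```

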