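# methsilence

Tools for classifying transcriptional-silencing pathways in plant genomes
from whole-genome bisulfite, RNA, and small-RNA sequencing summaries. The
motivating biology: in *Arabidopsis*, RNA-directed DNA methylation (RdDM)
silences transposable elements through Pol IV/Pol V-dependent 24-nt siRNAs
and DRM2-mediated methylation, while MORC-family ATPases silence an
overlapping set of loci largely *without* changing DNA methylation.
Distinguishing the two regimes requires comparing, across mutant genotypes,
(1) where methylation is lost, (2) where silencing is released, and (3)
which siRNA classes persist — this package implements that comparison as a
tested, reusable pipeline.

Intended users: computational biologists working downstream of Bismark-style
cytosine reports, feature count tables, and small-RNA length profiles.

## The statistics at the core

* **DMR calling.** Weighted methylation per 50-bp window,
  level = Σm / (Σm + Σu) over sites with ≥ 5× coverage; windows with
  |Δ| ≥ 0.10 and two-sided Fisher exact p < 0.01 between genotypes; merged
  into DMRs when gaps ≤ 50 bp, hypo and hyper chains kept separate.
* **DMR-set comparison.** Two regions overlap only when the shared span
  strictly exceeds 50 bp; enrichment of the overlap count k between sets of
  sizes K and n in a universe of N units is the hypergeometric upper tail
  P(X ≥ k).
* **Differential expression.** Per feature, fold change of
  library-normalized counts (pseudocount 0.5) combined with a Fisher exact
  test of (count, library − count) across genotypes: up requires fold > 2
  and p < 0.01.
* **Feature methylation classes.** Pooled levels over TE bodies and 1-kb
  promoters; methylated classes at > 20% (TE) and > 5% (promoter) total-C
  methylation; Welch t-tests between genotype groups.
* **siRNA dependence.** RPTM = count × 10⁷ / library total; a feature's
  24-nt siRNAs are Pol IV-dependent when (RPTM_nrpd1 + 1)/(RPTM_WT + 1) <
  0.5, and Pol V-independent when the nrpe1 fold change is ≥ 0.5.

A seeded synthetic-data generator plants hypo-DMRs, up-regulated features,
and siRNA dependence labels with known ground truth, so every decision rule
is validated end to end by recovery statistics. See `docs/methods.md` for
models, parameter defaults, and limitations.

## Worked example

Call DMRs in two mutants against wild type on simulated data and classify
the shared/specific partition:

```python
from methsilence import (
    SimulationConfig, simulate_annotation, plant_ground_truth, simulate_methylome,
    compute_window_methylation, call_differential_windows, merge_windows,
    classify_overlap, hypergeometric_upper_tail,
)

cfg = SimulationConfig(seed=1)
annotation = simulate_annotation(cfg)
truth = plant_ground_truth(cfg, annotation)
windows_wt = compute_window_methylation(
    simulate_methylome(cfg, annotation, truth, "WT"), window_size=50, min_coverage=5
)

dmrs = {}
for name in ("suvh29", "morc6"):
    wb = compute_window_methylation(
        simulate_methylome(cfg, annotation, truth, name), window_size=50, min_coverage=5
    )
    diff = call_differential_windows(windows_wt, wb, delta_min=0.10, alpha=0.01)
    dmrs[name] = [d for d in merge_windows(diff, max_gap=50) if d.direction == "hypo"]
    print(f"{name}: {len(dmrs[name])} hypo-DMRs (planted: {len(truth.dmrs_for(name))})")

part = classify_overlap(dmrs["suvh29"], dmrs["morc6"], min_overlap=50)
p = hypergeometric_upper_tail(
    len(part.shared_b), len(dmrs["suvh29"]), len(dmrs["morc6"]), 8000
)
print(f"shared (morc6 side): {len(part.shared_b)}, "
      f"morc6-specific: {len(part.specific_b)}, p = {p:.3g}")
```

Output:

```
suvh29: 61 hypo-DMRs (planted: 60)
morc6: 29 hypo-DMRs (planted: 21)
shared (morc6 side): 15, morc6-specific: 14, p = 1.91e-25
```

Reading the numbers: the caller recovers all 60 DMRs planted in the
suvh2/9-like genotype (one extra single-window call is Fisher-null noise at
p < 0.01 over 8,000 windows); of the morc6-like genotype's calls, exactly
the 15 planted shared loci overlap the suvh2/9 set by more than 50 bp — the
synthetic analogue of the shared "Class I" loci — and the overlap is far
beyond chance in a universe of 8,000 tested windows. The morc6-specific
side holds its 6 planted specific DMRs plus scattered single-window noise
calls, which can never satisfy the strict >50-bp overlap rule.

The same analysis runs from the shell:

```bash
methsilence simulate --seed 1 --outdir sim/
methsilence call-dmrs --treatment sim/meth_suvh29.tsv --control sim/meth_WT.tsv \
    --window 50 --min-coverage 5 --delta 0.10 --alpha 0.01 --gap 50 --out dmrs_suvh29.bed
methsilence pipeline run --seed 1 --outdir results/
methsilence pipeline evaluate --results results/
```

## Layout

```
src/methsilence/
  io.py          cytosine reports, GFF3/BED annotations, DMR BED output
  dmr.py         windowed methylation, Fisher exact test, DMR merging
  compare.py     overlap partition, hypergeometric enrichment, composition
  expression.py  fold-change + Fisher DE rule, target Venn partitions
  features.py    promoters, feature-level methylation, class filters, t-tests
  sirna.py       24-nt counts, RPTM, Pol IV/V dependence calls
  simulate.py    seeded generator with planted ground truth
  pipeline.py    file-isolated stages, manifest, truth evaluation
  cli.py         `methsilence` command-line interface
```
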