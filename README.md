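# cnvpopgen

Population genetics of copy number variation (CNV) from SNP-array
log R ratio (LRR) data, for geneticists studying structured livestock or
wildlife cohorts. The package takes a probe-by-sample LRR matrix and
carries it through the full analysis a CNV population survey needs:

1. **Preprocess** — autosome filtering and removal of the GC-content
   intensity wave by per-sample regression on a probe GC track.
2. **Segment** — multi-sample (shared-breakpoint) least-squares
   segmentation: recursive binary splits maximizing the pooled SSE
   reduction, accepted by a max-statistic permutation test
   (p ≤ 0.01, n = 1,000 permutations by default), with a
   circular-binary-segmentation-style double-cut rescue for compact
   mid-block events.
3. **Call** — three-state genotyping of segment means at ±0.3
   (loss / neutral / gain), union of overlapping candidates into
   non-redundant regions, a strict > 1% frequency filter, and recoding of
   deletion regions as biallelic markers ("12" = loss event, "22" =
   neutral) for SNP-style analyses.
4. **Structure** — method-of-moments relatedness (pi-hat) with greedy
   relative removal (> 0.4), identity-by-state distance
   D = 1 − (IBS2 + 0.5·IBS1)/N, classical multidimensional scaling,
   neighbor-joining trees (Newick), hierarchical clustering of mean-LRR
   profiles, and maximum-likelihood admixture (EM on the standard
   mixture likelihood with K ancestral clusters).
5. **Differentiate** — per-region V_ST = (V_T − V_S)/V_T between group
   pairs, where V_T is the total variance of segment mean LRRs and V_S
   the size-weighted within-group variance; regions above 0.4 / 0.6 are
   flagged as lineage-differentiated, and gene overlaps (≥ 1 bp,
   half-open coordinates) with a Welch length/frequency contrast complete
   the picture.

A synthetic-cohort generator (`cnvpopgen.synthetic`) produces multi-group
cohorts with hierarchically diverged allele frequencies
(Balding–Nichols), admixed hybrids, Hardy–Weinberg genotypes at planted
deletion/duplication loci, Gaussian probe noise and GC waves — with a
recorded truth set, so every stage of the pipeline is validated against
known answers. `docs/methods.md` documents the model and every numerical
convention.

## Worked example

```python
import cnvpopgen as c
from cnvpopgen.segmentation import SegConfig
from cnvpopgen.evaluate import score_recovery

cfg = c.SimConfig(seed=0)                      # 52 samples, 800 probes, 12 CNV loci
lrr, sheet, truth = c.simulate_cohort(cfg)
m = c.gc_correct(lrr, mode="trimmed")
segset = c.segment_lrr(m, SegConfig(n_perm=300, seed=1))
regions = c.filter_frequency(c.merge_regions(segset))
print(score_recovery(regions, truth, cfg))
```

Running `python examples/01_simulate_and_call.py` prints:

```
cohort: 52 samples x 800 probes, 12 true CNV loci

called 12 regions (frequency > 1%):
  CNV1: chr2:94000-114000 loss  frequency=0.96
  CNV2: chr2:28000-54000 loss  frequency=0.88
  ...

state accuracy      : 100.0%
boundary hit rate   : 100.0%
false regions       : 0
```

Every planted locus is recovered: region ids are sorted by descending
carrier frequency, all per-sample loss/neutral/gain calls match the
simulated copy numbers, and every region boundary lands within two probes
of the true locus edge. `examples/02_population_structure.py` continues
into distance/MDS/NJ/admixture (the first MDS axis separates the most
diverged group; ancestry is recovered with mean absolute error 0.03 at
200 markers), `examples/03_vst_scan.py` shows a V_ST scan flagging all
ten planted differentiated loci (top regions reach V_ST ≈ 0.93) with no
background region above 0.4, and `examples/04_gene_overlap.py`
demonstrates gene annotation and the Welch contrast.

The same pipeline is scriptable from the shell:

```bash
cnvpopgen simulate --out run/
cnvpopgen preprocess --in run/
cnvpopgen call --in run/ --nperm 300
cnvpopgen structure --in run/ --admix-k 3
cnvpopgen vst --in run/ --groups G1:G2 --groups G1:G3 --groups G2:G3
```

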