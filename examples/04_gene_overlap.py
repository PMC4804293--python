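"""Annotate called CNV regions with gene overlaps and contrast classes.

Writes a toy gene BED, intersects it with the regions called from the
standard cohort (>= 1 bp overlap, half-open coordinates), and runs the
Welch t-test contrast between gene-overlapping and non-overlapping
regions for length and carrier frequency.
"""

import tempfile
from pathlib import Path

import cnvpopgen as c
from cnvpopgen.calling import regions_to_bed
from cnvpopgen.differentiation import annotate_overlap, gene_overlap_contrast, read_genes_bed
from cnvpopgen.segmentation import SegConfig

cfg = c.SimConfig(seed=0)
lrr, sheet, truth = c.simulate_cohort(cfg)
segset = c.segment_lrr(c.gc_correct(lrr, mode="trimmed"), SegConfig(n_perm=300, seed=1))
regions = c.filter_frequency(c.merge_regions(segset))
bed = regions_to_bed(regions)

# toy annotation: one gene over every other region midpoint, plus one far away
rows = []
for i, (_, r) in enumerate(bed.iloc[::2].iterrows()):
    mid = (r.start + r.end) // 2
    rows.append(f"{r.chrom}\t{mid}\t{mid + 5000}\tgene{i + 1}")
rows.append("1\t900000\t905000\tfar_gene")
genes_path = Path(tempfile.mkdtemp()) / "genes.bed"
genes_path.write_text("\n".join(rows) + "\n")

genes = read_genes_bed(genes_path)
overlaps = annotate_overlap(bed.rename(columns={"name": "region_id"}), genes)
print(f"{len(overlaps)} region-gene overlaps (>= 1 bp):")
print(overlaps.head().to_string(index=False))

res = gene_overlap_contrast(regions, overlaps)
for cls in ("overlapping", "non_overlapping"):
    s = res[cls]
    print(f"\n{cls}: N={s.n} mean length={s.mean_length:.0f} bp "
          f"(SEM {s.sem_length:.0f}), mean frequency={s.mean_freq:.3f}")
t = res["length_test"]
print(f"\nWelch t-test on length: t={t['t']:.2f}, df={t['df']:.1f}, p={t['p']:.3f}")
# p is the two-sided probability of a length difference this large if the
# two classes had equal means
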