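"""Scoring pipeline output against synthetic truth.

Used by the test suite and the reproduction script to measure how well
segmentation + calling recover the simulated copy-number loci, and how
well the admixture fit recovers simulated ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import CNVRegion, GAIN, LOSS, NEUTRAL
from .synthetic import SimConfig, TruthSet


def truth_state(copies: int) -> int:
    """Expected three-state call for a true integer copy number."""
    if copies <= 1:
        return LOSS
    if copies >= 3:
        return GAIN
    return NEUTRAL


@dataclass
class RecoveryReport:
    """Per-cohort truth-recovery metrics.

    ``state_accuracy``: fraction of (sample, true locus) pairs whose called
    state matches the state implied by the true copy number (loci with no
    overlapping called region count every carrier as a miss).
    ``boundary_hit_rate``: fraction of true loci recovered by a region whose
    probe-index boundaries both fall within ``boundary_tol`` probes of
    truth. ``n_false_regions``: called regions overlapping no true locus.
    """

    state_accuracy: float
    boundary_hit_rate: float
    n_true_loci: int
    n_regions: int
    n_false_regions: int


def score_recovery(regions: list[CNVRegion], truth: TruthSet, cfg: SimConfig,
                   boundary_tol: int = 2) -> RecoveryReport:
    """Score called regions against the simulated loci."""
    n_samples = truth.genotypes.shape[0]
    matched_region_idx: set[int] = set()
    state_hits = 0
    state_total = 0
    boundary_hits = 0

    for j, locus in enumerate(truth.cnv_loci):
        # region with the largest probe overlap on this locus
        best, best_ov = None, 0
        for k, r in enumerate(regions):
            if r.chrom != locus.chrom or r.start_idx is None:
                continue
            ov = min(r.end_idx - 1, locus.last_probe) - max(r.start_idx, locus.first_probe) + 1
            if ov > best_ov:
                best, best_ov = k, ov
        expected = np.array([truth_state(c) for c in truth.genotypes[:, j]])
        state_total += n_samples
        if best is None:
            state_hits += int(np.sum(expected == NEUTRAL))
            continue
        matched_region_idx.add(best)
        r = regions[best]
        state_hits += int(np.sum(r.states == expected))
        if (abs(r.start_idx - locus.first_probe) <= boundary_tol
                and abs((r.end_idx - 1) - locus.last_probe) <= boundary_tol):
            boundary_hits += 1

    return RecoveryReport(
        state_accuracy=state_hits / state_total if state_total else 1.0,
        boundary_hit_rate=boundary_hits / len(truth.cnv_loci) if truth.cnv_loci else 1.0,
        n_true_loci=len(truth.cnv_loci),
        n_regions=len(regions),
        n_false_regions=len(regions) - len(matched_region_idx),
    )


def truth_region_labels(truth: TruthSet, regions: list[CNVRegion]) -> dict[str, int | None]:
    """Map each region id to the index of the true locus it best overlaps."""
    out: dict[str, int | None] = {}
    for r in regions:
        best, best_ov = None, 0
        for j, locus in enumerate(truth.cnv_loci):
            if r.chrom != locus.chrom or r.start_idx is None:
                continue
            ov = min(r.end_idx - 1, locus.last_probe) - max(r.start_idx, locus.first_probe) + 1
            if ov > best_ov:
                best, best_ov = j, ov
        out[r.region_id] = best
    return out
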