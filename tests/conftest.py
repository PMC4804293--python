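"""Shared fixtures: the standard synthetic cohort and its pipeline products."""

import dataclasses

import numpy as np
import pytest

import cnvpopgen as c


@pytest.fixture(scope="session")
def standard_cohort():
    """Default-configuration cohort: 52 samples, 2 chromosomes, 12 CNV loci."""
    cfg = c.SimConfig()
    lrr, sheet, truth = c.simulate_cohort(cfg)
    return cfg, lrr, sheet, truth


@pytest.fixture(scope="session")
def standard_pipeline(standard_cohort):
    """GC-corrected, segmented, called regions for the standard cohort."""
    cfg, lrr, sheet, truth = standard_cohort
    m = c.gc_correct(lrr, mode="trimmed")
    segset = c.segment_lrr(m, c.SegConfig(n_perm=300, seed=1))
    regions = c.filter_frequency(c.merge_regions(segset))
    return cfg, sheet, truth, segset, regions


@pytest.fixture(scope="session")
def admixture_cohort():
    """Marker-level 3-group cohort with 10 hybrids and 200 deletion markers."""
    from cnvpopgen.synthetic import simulate_deletion_markers

    cfg = dataclasses.replace(c.SimConfig(), n_hybrids=10, n_differentiated_loci=0)
    g, sheet, ancestry = simulate_deletion_markers(cfg, 200, seed=3)
    return g, sheet, ancestry


def make_region(freq, *, chrom="1", start=1000, end=2000, kind="loss",
                n_samples=100, region_id="", means=None):
    """Construct a CNVRegion with a given carrier frequency for unit tests."""
    n_carriers = int(round(freq * n_samples))
    states = np.zeros(n_samples, dtype=np.int8)
    sval = c.calling.LOSS if kind == "loss" else c.calling.GAIN
    states[:n_carriers] = sval
    if means is None:
        means = np.where(states == 0, 0.0, -1.0 if kind == "loss" else 0.5)
    return c.CNVRegion(
        region_id=region_id, chrom=chrom, start_bp=start, end_bp=end,
        kind=kind, states=states, means=np.asarray(means, float),
        frequency=n_carriers / n_samples,
    )
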