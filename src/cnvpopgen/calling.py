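"""Three-state CNV genotyping, region merging, filtering, and recoding.

Per-sample segment mean LRRs are thresholded at +/- ``state_threshold``
(default 0.3, boundary inclusive) into loss / neutral / gain states.
Segments carrying at least one non-neutral sample become candidate
regions; candidates that overlap (or are adjacent in probe coordinates —
with shared breakpoints segments tile the chromosome, so adjacency is the
only way two candidate segments can abut) are unioned into non-redundant
regions. Regions are filtered to population frequency strictly above
``min_freq`` (default 1%) and renamed CNV1..CNVn by descending frequency.
Deletion (loss-type) regions are finally recoded as biallelic markers:
"12" for a loss event, "22" for neutral — the coding used downstream for
distance, MDS, trees and admixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .segmentation import Segment, SegmentSet

__all__ = [
    "CallConfig", "CNVRegion", "GenotypeMatrix",
    "call_state", "call_states", "merge_regions", "filter_frequency",
    "recode_deletions", "region_frequency_by_group", "region_mean_matrix",
    "regions_to_bed", "write_regions_bed", "write_state_matrix",
    "write_ped_map", "read_ped_map",
]

LOSS, NEUTRAL, GAIN = -1, 0, 1
_STATE_NAME = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain"}


@dataclass(frozen=True)
class CallConfig:
    """Thresholds for state calling and frequency filtering."""

    state_threshold: float = 0.3
    min_freq: float = 0.01

    def __post_init__(self):
        if not self.state_threshold > 0:
            raise ConfigError(f"state_threshold must be > 0, got {self.state_threshold}")
        if not 0 <= self.min_freq < 1:
            raise ConfigError(f"min_freq must lie in [0, 1), got {self.min_freq}")


@dataclass
class CNVRegion:
    """A non-redundant copy-number-variable region with per-sample states.

    ``states`` holds -1/0/+1 (loss/neutral/gain) per sample; ``means`` the
    representative segment-mean LRR per sample (from the constituent
    segment where that sample is most extreme). ``frequency`` is the
    fraction of samples with a non-neutral state.
    """

    region_id: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    kind: str  # "loss" | "gain" | "mixed"
    states: np.ndarray  # (n_samples,) int8
    means: np.ndarray  # (n_samples,) float
    frequency: float
    start_idx: int | None = None  # chromosome-local probe index span, half-open
    end_idx: int | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def state_names(self) -> list[str]:
        return [_STATE_NAME[int(s)] for s in self.states]


@dataclass
class GenotypeMatrix:
    """Deletion CNVs recoded as biallelic markers.

    ``codes[i, j]`` is "12" (deletion event) or "22" (neutral) for sample i
    at marker j; the dosage view maps "12" -> 1, "22" -> 0.
    """

    samples: list[str]
    markers: list[str]
    codes: np.ndarray  # (n_samples, n_markers) of "12"/"22"
    positions: pd.DataFrame | None = None  # marker map: chrom, midpoint bp

    def __post_init__(self):
        allowed = {"12", "22"}
        found = set(np.unique(self.codes).tolist())
        if not found <= allowed:
            raise InputError(f"genotype codes must be '12'/'22', found {found - allowed}")

    @property
    def dosage(self) -> np.ndarray:
        """Deletion-presence indicator (1 = loss event)."""
        return (self.codes == "12").astype(np.int8)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


# ---------------------------------------------------------------------------
# state calling


def call_state(segment_mean: float, cfg: CallConfig | None = None) -> str:
    """Three-state call of one segment mean: <= -t -> loss, >= +t -> gain.

    The boundary is inclusive: a mean of exactly -t is a loss.
    """
    cfg = cfg or CallConfig()
    if not np.isfinite(segment_mean):
        raise InputError(f"segment mean must be finite, got {segment_mean}")
    t = cfg.state_threshold
    if segment_mean <= -t:
        return "loss"
    if segment_mean >= t:
        return "gain"
    return "neutral"


def call_states(means: np.ndarray, cfg: CallConfig | None = None) -> np.ndarray:
    """Vectorized three-state calling; returns int8 codes -1/0/+1."""
    cfg = cfg or CallConfig()
    means = np.asarray(means, dtype=float)
    if not np.all(np.isfinite(means)):
        raise InputError("segment means must be finite")
    out = np.zeros(means.shape, dtype=np.int8)
    out[means <= -cfg.state_threshold] = LOSS
    out[means >= cfg.state_threshold] = GAIN
    return out


# ---------------------------------------------------------------------------
# merging


def _region_kind(states: np.ndarray) -> str:
    has_loss = np.any(states == LOSS)
    has_gain = np.any(states == GAIN)
    if has_loss and has_gain:
        return "mixed"
    return "loss" if has_loss else "gain"


def _finalize(chrom, segs: list[Segment], cfg: CallConfig) -> CNVRegion:
    """Union a run of candidate segments into one region.

    Each sample's representative mean comes from the constituent segment
    where its |mean| is largest; the state is re-called from that mean.
    """
    mean_stack = np.stack([s.means for s in segs], axis=1)  # (n_samples, n_segs)
    pick = np.argmax(np.abs(mean_stack), axis=1)
    means = mean_stack[np.arange(mean_stack.shape[0]), pick]
    states = call_states(means, cfg)
    freq = float(np.mean(states != NEUTRAL))
    return CNVRegion(
        region_id="",
        chrom=chrom,
        start_bp=min(s.start_bp for s in segs),
        end_bp=max(s.end_bp for s in segs),
        kind=_region_kind(states),
        states=states,
        means=means,
        frequency=freq,
        start_idx=min(s.start_idx for s in segs),
        end_idx=max(s.end_idx for s in segs),
    )


def merge_candidates(candidates: list[Segment], cfg: CallConfig | None = None) -> list[CNVRegion]:
    """Union overlapping/adjacent candidate segments into regions.

    Candidates are sorted by (chrom, start); two candidates on the same
    chromosome merge when their bp spans overlap by >= 1 bp or their
    probe-index spans touch (consecutive segments share a breakpoint).
    """
    cfg = cfg or CallConfig()
    ordered = sorted(candidates, key=lambda s: (s.chrom, s.start_bp, s.end_bp))
    regions: list[CNVRegion] = []
    run: list[Segment] = []
    run_end_bp = run_end_idx = None
    for seg in ordered:
        touches = False
        if run and seg.chrom == run[0].chrom:
            if seg.start_bp <= run_end_bp:
                touches = True
            elif seg.start_idx is not None and run_end_idx is not None and seg.start_idx <= run_end_idx:
                touches = True
        if touches:
            run.append(seg)
            run_end_bp = max(run_end_bp, seg.end_bp)
            if run_end_idx is not None:
                run_end_idx = max(run_end_idx, seg.end_idx)
        else:
            if run:
                regions.append(_finalize(run[0].chrom, run, cfg))
            run = [seg]
            run_end_bp = seg.end_bp
            run_end_idx = seg.end_idx
    if run:
        regions.append(_finalize(run[0].chrom, run, cfg))
    return regions


def merge_regions(segset: SegmentSet, calls: list[np.ndarray] | None = None,
                  cfg: CallConfig | None = None) -> list[CNVRegion]:
    """Merge candidate segments of a segmentation into non-redundant regions.

    A segment is a candidate when >= 1 sample is non-neutral. Candidates on
    different chromosomes never merge.
    """
    cfg = cfg or CallConfig()
    segs = segset.segments()
    if calls is None:
        calls = [call_states(s.means, cfg) for s in segs]
    candidates = [seg for seg, st in zip(segs, calls) if np.any(st != NEUTRAL)]
    return merge_candidates(candidates, cfg)


def filter_frequency(regions: list[CNVRegion], cfg: CallConfig | None = None) -> list[CNVRegion]:
    """Retain regions with frequency strictly above ``min_freq``; re-id.

    Region ids CNV1..CNVn are re-assigned by descending frequency, ties
    broken by (chrom, start_bp).
    """
    cfg = cfg or CallConfig()
    kept = [r for r in regions if r.frequency > cfg.min_freq]
    kept.sort(key=lambda r: (-r.frequency, r.chrom, r.start_bp))
    for i, r in enumerate(kept):
        r.region_id = f"CNV{i + 1}"
    return kept


# ---------------------------------------------------------------------------
# recoding & summaries


def recode_deletions(regions: list[CNVRegion], samples: list[str] | None = None) -> GenotypeMatrix:
    """Recode loss-type regions as biallelic markers ("12" loss / "22" else).

    Mixed- and gain-type regions are excluded. An empty result (no loss
    regions) is returned with a warning rather than raising.
    """
    losses = [r for r in regions if r.kind == "loss"]
    if not losses:
        import warnings

        warnings.warn("no loss-type regions; genotype matrix is empty")
    n = len(losses[0].states) if losses else (len(samples) if samples else 0)
    codes = np.full((n, len(losses)), "22", dtype=object)
    for j, r in enumerate(losses):
        codes[r.states == LOSS, j] = "12"
    pos = pd.DataFrame(
        {
            "marker": [r.region_id for r in losses],
            "chrom": [r.chrom for r in losses],
            "position": [(r.start_bp + r.end_bp) // 2 for r in losses],
        }
    )
    return GenotypeMatrix(
        samples=list(samples) if samples is not None else [f"S{i}" for i in range(n)],
        markers=[r.region_id for r in losses],
        codes=codes,
        positions=pos,
    )


def region_frequency_by_group(regions: list[CNVRegion], samplesheet: pd.DataFrame,
                              group: str, column: str = "group") -> pd.Series:
    """Per-region carrier frequency within one group of samples."""
    if column not in samplesheet.columns:
        raise InputError(f"sample sheet has no column {column!r}")
    mask = (samplesheet[column] == group).to_numpy()
    if not mask.any():
        raise InputError(f"group {group!r} matches no samples")
    out = {r.region_id: float(np.mean(r.states[mask] != NEUTRAL)) for r in regions}
    return pd.Series(out, name=group)


def region_mean_matrix(regions: list[CNVRegion]) -> pd.DataFrame:
    """Sample-by-region matrix of representative segment mean LRRs."""
    data = np.column_stack([r.means for r in regions])
    return pd.DataFrame(data, columns=[r.region_id for r in regions])


# ---------------------------------------------------------------------------
# text output


def regions_to_bed(regions: list[CNVRegion]) -> pd.DataFrame:
    """BED view of regions: 0-based half-open, score = frequency * 1000."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start_bp - 1 for r in regions],
            "end": [r.end_bp for r in regions],
            "name": [r.region_id for r in regions],
            "score": [int(round(r.frequency * 1000)) for r in regions],
            "strand": ["." for _ in regions],
        }
    )


def write_regions_bed(regions: list[CNVRegion], path):
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False)


def write_state_matrix(regions: list[CNVRegion], samples: list[str], path):
    df = pd.DataFrame(
        {r.region_id: r.state_names() for r in regions}, index=samples
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_ped_map(g: GenotypeMatrix, samplesheet: pd.DataFrame, prefix):
    """Write PLINK-style PED/MAP text files for the recoded deletion markers.

    PED: FID IID PAT MAT SEX PHENO then two allele columns per marker
    ("1 2" for a deletion event, "2 2" for neutral). MAP: chrom, marker id,
    0, region-midpoint position.
    """
    prefix = Path(prefix)
    sheet = samplesheet.set_index("sample")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(samplesheet["sample"]):
            fam = sheet.loc[s, "breed"]
            alleles = []
            for j in range(g.n_markers):
                code = g.codes[i, j]
                alleles.extend([code[0], code[1]])
            fh.write(" ".join([str(fam), str(s), "0", "0", "0", "-9"] + alleles) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, m in enumerate(g.markers):
            chrom = g.positions["chrom"].iloc[j] if g.positions is not None else "0"
            pos = g.positions["position"].iloc[j] if g.positions is not None else j + 1
            fh.write(f"{chrom}\t{m}\t0\t{pos}\n")


def read_ped_map(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PED/MAP pair written by :func:`write_ped_map`."""
    prefix = Path(prefix)
    markers = []
    chroms, positions = [], []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            c, m, _, p = line.split()
            markers.append(m)
            chroms.append(c)
            positions.append(int(p))
    samples, fams, rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(markers):
                raise InputError(f"PED line {ln} has {len(parts)} fields, expected {6 + 2 * len(markers)}")
            fams.append(parts[0])
            samples.append(parts[1])
            alleles = parts[6:]
            rows.append(["".join(sorted(alleles[2 * j:2 * j + 2])) for j in range(len(markers))])
    codes = np.array(rows, dtype=object)
    sheet = pd.DataFrame({"sample": samples, "breed": fams, "group": fams})
    g = GenotypeMatrix(
        samples=samples,
        markers=markers,
        codes=codes,
        positions=pd.DataFrame({"marker": markers, "chrom": chroms, "position": positions}),
    )
    return g, sheet
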