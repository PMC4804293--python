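"""Multi-sample least-squares segmentation with permutation-tested splits.

Each chromosome is partitioned into segments with breakpoints shared
across all samples (a "multivariate" segmentation: copy-number events that
recur at the same position in several individuals reinforce each other).
The procedure is recursive binary splitting: at each step the candidate
breakpoint maximizing the reduction in within-segment sum of squared
deviations, pooled over samples, is tested against a max-statistic
permutation null (probe order shuffled identically across samples, which
preserves the per-probe cross-sample covariance) and accepted when
p <= ``p_threshold`` (default 0.01, with ``n_perm`` = 1000 permutations).
Accepted splits recurse into both halves.

The output :class:`SegmentSet` carries, per chromosome, the shared
breakpoints and each sample's mean LRR over each segment — the quantity
later thresholded at +/-0.3 for three-state calling and used in V_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .preprocess import LRRMatrix

__all__ = ["SegConfig", "Segment", "SegmentSet", "best_split", "permutation_p",
           "segment_chromosome", "segment_lrr"]


@dataclass(frozen=True)
class SegConfig:
    """Segmentation tuning parameters.

    ``p_threshold`` and ``n_perm`` default to the conventional 0.01 /
    1,000-permutation pairwise test; ``min_probes`` is the smallest segment
    admitted on either side of a split; ``max_depth`` bounds the recursion
    (each accepted split increases depth by one along its path).
    Setting ``p_threshold`` = 1 disables the permutation test so that every
    SSE-reducing split is accepted (useful for oracle comparisons).
    """

    p_threshold: float = 0.01
    n_perm: int = 1000
    min_probes: int = 3
    max_depth: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_threshold <= 1:
            raise ConfigError(f"p_threshold must lie in (0, 1], got {self.p_threshold}")
        if self.n_perm < 100:
            raise ConfigError(f"n_perm must be >= 100, got {self.n_perm}")
        if self.min_probes < 1:
            raise ConfigError(f"min_probes must be >= 1, got {self.min_probes}")
        if self.max_depth < 1:
            raise ConfigError(f"max_depth must be >= 1, got {self.max_depth}")


@dataclass(frozen=True)
class Segment:
    """One segment: a half-open probe-index span with per-sample mean LRRs."""

    chrom: str
    start_idx: int  # chromosome-local probe index, half-open [start_idx, end_idx)
    end_idx: int
    start_bp: int  # position of first probe (1-based inclusive)
    end_bp: int  # position of last probe (inclusive)
    means: np.ndarray  # (n_samples,)

    @property
    def n_probes(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class SegmentSet:
    """Shared per-chromosome breakpoints plus per-sample segment means."""

    samples: list[str]
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)  # incl. 0 and n
    means: dict[str, np.ndarray] = field(default_factory=dict)  # (n_samples, n_seg)
    positions: dict[str, np.ndarray] = field(default_factory=dict)  # probe bp per chrom

    def segments(self) -> list[Segment]:
        out = []
        for chrom, bounds in self.boundaries.items():
            pos = self.positions[chrom]
            for s in range(len(bounds) - 1):
                lo, hi = int(bounds[s]), int(bounds[s + 1])
                out.append(
                    Segment(chrom, lo, hi, int(pos[lo]), int(pos[hi - 1]),
                            self.means[chrom][:, s])
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments():
            row = {
                "chrom": seg.chrom,
                "start_bp": seg.start_bp,
                "end_bp": seg.end_bp,
                "n_probes": seg.n_probes,
            }
            row.update({s: m for s, m in zip(self.samples, seg.means)})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split statistic


def _split_stats(values: np.ndarray, min_probes: int):
    """SSE reduction for every admissible split of a (samples x probes) block.

    Returns (ks, stats): left-segment sizes and the pooled SSE drop
    SSE(block) - [SSE(left) + SSE(right)] for each.
    """
    s, p = values.shape
    if p < 2 * min_probes:
        return np.empty(0, dtype=int), np.empty(0)
    c = np.cumsum(values, axis=1)
    sq = np.cumsum(values * values, axis=1)
    tot_c = c[:, -1][:, None]
    tot_sq = sq[:, -1][:, None]
    ks = np.arange(min_probes, p - min_probes + 1)
    cl = c[:, ks - 1]
    sql = sq[:, ks - 1]
    left = sql - cl * cl / ks
    right = (tot_sq - sql) - (tot_c - cl) ** 2 / (p - ks)
    full = (tot_sq - tot_c * tot_c / p).sum()
    stats = full - (left + right).sum(axis=0)
    return ks, stats


def best_split(values: np.ndarray, min_probes: int = 3):
    """Best shared breakpoint of a block, by pooled SSE reduction.

    Returns ``(split_index, statistic)`` where ``split_index`` is the size
    of the left segment (probes ``[:split_index]`` / ``[split_index:]``).
    Ties break toward the smallest index. Blocks too short for any
    admissible split return ``(None, 0.0)``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ks, stats = _split_stats(values, min_probes)
    if ks.size == 0:
        return None, 0.0
    i = int(np.argmax(stats))  # argmax takes the first maximum: smallest index
    stat = float(stats[i])
    if stat <= 0:
        return None, 0.0
    return int(ks[i]), stat


def _max_island_stat(values: np.ndarray, min_probes: int):
    """Best double-cut (island) statistic of a block.

    A compact copy-number event in the middle of a long block is weakly
    captured by any single split (its contrast is diluted over one long
    side), so blocks are additionally tested for the best interior island
    [i, j): pooled SSE(block) - SSE(island) - SSE(complement), maximized
    over i, j with all three resulting parts >= min_probes (the
    circular-binary-segmentation move). Returns ((i, j), statistic) or
    ((None, None), 0.0).
    """
    s, p = values.shape
    if p < 3 * min_probes:
        return (None, None), 0.0
    c = np.concatenate([np.zeros((s, 1)), np.cumsum(values, axis=1)], axis=1)
    sq = np.concatenate([np.zeros((s, 1)), np.cumsum(values * values, axis=1)], axis=1)
    tot_c = c[:, -1:]
    tot_sq = sq[:, -1:]
    full = float((tot_sq - tot_c * tot_c / p).sum())
    best_stat, best_ij = 0.0, (None, None)
    for L in range(min_probes, p - 2 * min_probes + 1):
        i = np.arange(min_probes, p - min_probes - L + 1)
        if i.size == 0:
            continue
        S = c[:, i + L] - c[:, i]
        Q = sq[:, i + L] - sq[:, i]
        sse_isl = (Q - S * S / L).sum(axis=0)
        Sc = tot_c - S
        Qc = tot_sq - Q
        sse_comp = (Qc - Sc * Sc / (p - L)).sum(axis=0)
        stats = full - sse_isl - sse_comp
        k = int(np.argmax(stats))
        if stats[k] > best_stat + 1e-15:
            best_stat = float(stats[k])
            best_ij = (int(i[k]), int(i[k]) + L)
    return best_ij, best_stat


def permutation_p(values: np.ndarray, split_statistic: float, cfg: SegConfig,
                  rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for an observed best-split statistic.

    Each permutation shuffles the probe order identically across samples
    and recomputes the maximal split statistic; the p-value is
    ``(1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    count = 0
    for _ in range(cfg.n_perm):
        perm = rng.permutation(values.shape[1])
        _, stats = _split_stats(values[:, perm], cfg.min_probes)
        if stats.size and stats.max() >= split_statistic:
            count += 1
    return (1 + count) / (1 + cfg.n_perm)


def _significant(values: np.ndarray, observed: float, stat_fn, cfg: SegConfig,
                 rng: np.random.Generator) -> bool:
    """Permutation accept/reject with early stopping.

    Identical decision to thresholding the exact permutation p-value at
    ``p_threshold``: stops as soon as enough permuted maxima reach the
    observed statistic to make p > p_threshold inevitable.
    """
    allowed = int(np.floor(cfg.p_threshold * (1 + cfg.n_perm))) - 1
    if allowed < 0:
        return False
    count = 0
    for _ in range(cfg.n_perm):
        perm = rng.permutation(values.shape[1])
        if stat_fn(values[:, perm]) >= observed:
            count += 1
            if count > allowed:
                return False
    return True


def segment_chromosome(m: LRRMatrix, chrom: str, cfg: SegConfig,
                       rng: np.random.Generator | None = None):
    """Segment one chromosome by recursive permutation-tested splits.

    Each block is first tested for its best single shared breakpoint
    (accepted when the max-statistic permutation p-value is at most
    ``p_threshold``); a block whose single split is not significant is
    re-tested for its best interior double cut (island), which rescues
    compact events sitting mid-block. Accepted cuts recurse into the
    resulting sub-blocks.

    Returns ``(boundaries, means)``: boundary probe indices (including 0 and
    n_probes) and the (n_samples x n_segments) matrix of segment mean LRRs.
    """
    values = m.chrom_block(chrom)
    if rng is None:
        import zlib

        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(chrom.encode()) % (2**31)])
        )
    breaks: list[int] = []

    def max_split_stat(block):
        _, stats = _split_stats(block, cfg.min_probes)
        return stats.max() if stats.size else 0.0

    def max_island_stat(block):
        _, stat = _max_island_stat(block, cfg.min_probes)
        return stat

    def recurse(lo: int, hi: int, depth: int):
        if depth >= cfg.max_depth:
            return
        block = values[:, lo:hi]
        k, stat = best_split(block, cfg.min_probes)
        if k is not None and (
            cfg.p_threshold >= 1.0
            or _significant(block, stat, max_split_stat, cfg, rng)
        ):
            breaks.append(lo + k)
            recurse(lo, lo + k, depth + 1)
            recurse(lo + k, hi, depth + 1)
            return
        if cfg.p_threshold >= 1.0:
            return
        (i, j), isl_stat = _max_island_stat(block, cfg.min_probes)
        if i is not None and isl_stat > 0 and _significant(
            block, isl_stat, max_island_stat, cfg, rng
        ):
            breaks.extend([lo + i, lo + j])
            recurse(lo, lo + i, depth + 1)
            recurse(lo + i, lo + j, depth + 1)
            recurse(lo + j, hi, depth + 1)

    recurse(0, values.shape[1], 0)
    bounds = np.array([0] + sorted(breaks) + [values.shape[1]], dtype=int)
    means = np.empty((values.shape[0], len(bounds) - 1))
    for s in range(len(bounds) - 1):
        means[:, s] = values[:, bounds[s]:bounds[s + 1]].mean(axis=1)
    return bounds, means


def segment_lrr(m: LRRMatrix, cfg: SegConfig | None = None) -> SegmentSet:
    """Segment every chromosome of an LRR matrix into a :class:`SegmentSet`."""
    cfg = cfg or SegConfig()
    out = SegmentSet(samples=list(m.samples))
    for i, chrom in enumerate(m.panel.chroms()):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, i]))
        bounds, means = segment_chromosome(m, chrom, cfg, rng)
        out.boundaries[chrom] = bounds
        out.means[chrom] = means
        out.positions[chrom] = m.panel.position[m.panel.chrom_slice(chrom)]
    return out
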