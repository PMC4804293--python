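"""V_ST lineage-differentiation scans and gene-overlap annotation.

V_ST is the copy-number analogue of F_ST: for one CNV region and two
population groups, V_ST = (V_T - V_S)/V_T where V_T is the total variance
of per-individual segment mean LRRs pooled over both groups and V_S is
the average within-group variance. With population variances (denominator
n) and a size-weighted V_S this is exactly the between-group share of the
total variance (law of total variance), so V_ST lies in [0, 1]:
0 = no differentiation, 1 = complete differentiation. Regions are flagged
at the conventional strict thresholds V_ST > 0.4 and > 0.6.

Gene annotation reports every (region, gene) pair overlapping by at least
1 bp under 0-based half-open coordinates; a Welch two-sample t-test
contrasts length and frequency of gene-overlapping vs non-overlapping
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .calling import CNVRegion
from .errors import InputError, ParseError

__all__ = [
    "vst", "vst_scan", "unique_differentiated",
    "read_genes_bed", "read_genes_gff3", "annotate_overlap",
    "gene_overlap_contrast", "manhattan_table",
]


def _group_var(x: np.ndarray, unbiased: bool) -> float:
    ddof = 1 if unbiased else 0
    if len(x) <= ddof:
        return 0.0
    return float(np.var(x, ddof=ddof))


def vst(values: np.ndarray, labels: np.ndarray, unbiased: bool = False) -> float:
    """V_ST = (V_T - V_S)/V_T for one region and two groups.

    ``values`` are per-individual segment mean LRRs; ``labels`` assigns each
    to one of exactly two groups. By default V_T is the population variance
    (denominator n) of the pooled values and V_S the size-weighted mean of
    the two within-group population variances, which guarantees
    V_ST in [0, 1]. ``unbiased=True`` switches to (n-1) variances with an
    unweighted group mean; the result is reported unclamped and may fall
    slightly below 0. A region with V_T = 0 is degenerate and returns 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise InputError(f"vst needs exactly two groups, got {list(groups)}")
    parts = [values[labels == g] for g in groups]
    if any(len(p) == 0 for p in parts):
        raise InputError("both groups must be non-empty")
    ddof = 1 if unbiased else 0
    n = len(values)
    if (unbiased and n < 2) or np.ptp(values) == 0:
        return 0.0
    v_t = float(np.var(values, ddof=ddof))
    if v_t == 0:
        return 0.0
    if unbiased:
        v_s = float(np.mean([_group_var(p, True) for p in parts]))
    else:
        v_s = float(sum(len(p) * _group_var(p, False) for p in parts) / n)
    return (v_t - v_s) / v_t


def vst_scan(regions: list[CNVRegion], samplesheet: pd.DataFrame,
             comparisons: list[tuple[str, str]],
             thresholds: tuple[float, float] = (0.4, 0.6),
             unbiased: bool = False) -> pd.DataFrame:
    """Per-region V_ST for each group comparison.

    Each comparison is a pair of labels resolved against the sample sheet's
    ``group`` column first, then ``breed`` (so both group-level contrasts
    like G1 vs G2 and breed-level ones like HOL vs ANG work). Returns one
    row per region per comparison with V_T, V_S, V_ST, a degenerate flag,
    and strict-inequality flags at the two thresholds.
    """
    lo_t, hi_t = thresholds
    rows = []
    for a, b in comparisons:
        mask_a = _resolve_label(samplesheet, a)
        mask_b = _resolve_label(samplesheet, b)
        labels = np.where(mask_a, a, np.where(mask_b, b, None))
        sel = mask_a | mask_b
        for r in regions:
            vals = r.means[sel]
            labs = labels[sel]
            n = len(vals)
            ddof = 1 if unbiased else 0
            v_t = float(np.var(vals, ddof=ddof)) if n > ddof else 0.0
            degenerate = v_t == 0
            v = 0.0 if degenerate else vst(vals, labs, unbiased=unbiased)
            if degenerate:
                v_s = 0.0
            elif unbiased:
                v_s = v_t * (1 - v) if v_t else 0.0
            else:
                v_s = v_t * (1 - v)
            rows.append(
                {
                    "region_id": r.region_id,
                    "chrom": r.chrom,
                    "midpoint_bp": (r.start_bp + r.end_bp) // 2,
                    "comparison": f"{a}_vs_{b}",
                    "V_T": v_t,
                    "V_S": v_s,
                    "V_ST": v,
                    "degenerate": degenerate,
                    f"above_{lo_t}": (not degenerate) and v > lo_t,
                    f"above_{hi_t}": (not degenerate) and v > hi_t,
                }
            )
    return pd.DataFrame(rows)


def _resolve_label(samplesheet: pd.DataFrame, label: str) -> np.ndarray:
    for col in ("group", "breed"):
        if col in samplesheet.columns:
            mask = (samplesheet[col] == label).to_numpy()
            if mask.any():
                return mask
    raise InputError(f"label {label!r} matches no group or breed in the sample sheet")


def unique_differentiated(tables: list[pd.DataFrame], threshold: float = 0.4) -> set[str]:
    """Union of region ids flagged above ``threshold`` across comparisons."""
    out: set[str] = set()
    for t in tables:
        flagged = t.loc[(~t["degenerate"]) & (t["V_ST"] > threshold), "region_id"]
        out |= set(flagged)
    return out


def manhattan_table(vst_table: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Plot-ready (chrom, midpoint_bp, V_ST) slice for one comparison."""
    sub = vst_table[vst_table["comparison"] == comparison]
    if sub.empty:
        raise InputError(f"comparison {comparison!r} not present in table")
    return sub[["chrom", "midpoint_bp", "V_ST"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene overlap


def read_genes_bed(path) -> pd.DataFrame:
    """Read a gene BED file (chrom, start, end, name); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"],
                     dtype={0: str})
    _check_intervals(df)
    return df


def read_genes_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Extract gene features from GFF3 into 0-based half-open intervals.

    GFF3 is 1-based inclusive; starts are shifted by -1. The gene id is
    taken from the ID= attribute (falling back to Name=).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError("GFF3 record has fewer than 9 fields", line=ln)
            chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ftype not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("Name", f"feature_{ln}"))
            rows.append({"chrom": chrom, "start": int(start) - 1, "end": int(end), "gene_id": gid})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    _check_intervals(df)
    return df


def _check_intervals(df: pd.DataFrame):
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise InputError(f"malformed interval (start > end) at record {int(bad[0]) + 1}")


def annotate_overlap(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """All (region, gene) pairs overlapping by >= 1 bp.

    Both inputs are BED-like frames with 0-based half-open ``start``/``end``
    columns (regions additionally carry ``name`` or ``region_id``). Returns
    a table with region_id, gene_id and the overlap length in bp.
    """
    rid_col = "region_id" if "region_id" in regions.columns else "name"
    _check_intervals(regions)
    _check_intervals(genes)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for _, g in sub.iterrows():
            if g["end"] > g["start"]:
                t.addi(int(g["start"]), int(g["end"]), g["gene_id"])
        trees[str(chrom)] = t
    rows = []
    for _, r in regions.iterrows():
        t = trees.get(str(r["chrom"]))
        if t is None:
            continue
        for iv in sorted(t.overlap(int(r["start"]), int(r["end"]))):
            ov = min(iv.end, int(r["end"])) - max(iv.begin, int(r["start"]))
            if ov >= 1:
                rows.append({"region_id": r[rid_col], "gene_id": iv.data, "overlap_bp": int(ov)})
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "overlap_bp"])


# ---------------------------------------------------------------------------
# contrast


@dataclass
class ClassSummary:
    n: int
    mean_length: float
    sem_length: float
    mean_freq: float
    sem_freq: float


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _welch(a: np.ndarray, b: np.ndarray):
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    if va + vb == 0:
        return 0.0, float(len(a) + len(b) - 2), 1.0
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(t), float(df), float(p)


def gene_overlap_contrast(regions: list[CNVRegion], overlaps: pd.DataFrame) -> dict:
    """Length/frequency contrast of gene-overlapping vs non-overlapping regions.

    Returns per-class N, mean and SEM of region length (bp) and carrier
    frequency, plus Welch two-sample t-tests (t, Welch-Satterthwaite df,
    two-sided p) for both quantities. Classes with N < 2 skip the tests
    with a warning.
    """
    with_genes = set(overlaps["region_id"]) if len(overlaps) else set()
    cls = {True: [], False: []}
    for r in regions:
        cls[r.region_id in with_genes].append(r)
    out = {}
    data = {}
    for key, name in ((True, "overlapping"), (False, "non_overlapping")):
        lens = np.array([r.length_bp for r in cls[key]], dtype=float)
        freqs = np.array([r.frequency for r in cls[key]], dtype=float)
        data[name] = (lens, freqs)
        out[name] = ClassSummary(
            n=len(lens),
            mean_length=float(lens.mean()) if len(lens) else float("nan"),
            sem_length=_sem(lens),
            mean_freq=float(freqs.mean()) if len(freqs) else float("nan"),
            sem_freq=_sem(freqs),
        )
    if min(out["overlapping"].n, out["non_overlapping"].n) < 2:
        warnings.warn("a class has N < 2; Welch tests skipped")
    else:
        la, fa = data["overlapping"]
        lb, fb = data["non_overlapping"]
        for label, a, b in (("length", la, lb), ("frequency", fa, fb)):
            if np.array_equal(np.sort(a), np.sort(b)):
                out[f"{label}_test"] = {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0}
            else:
                t, df, p = _welch(a, b)
                out[f"{label}_test"] = {"t": t, "df": df, "p": p}
    return out
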