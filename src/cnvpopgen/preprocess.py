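"""Reading LRR matrices and removing GC-content intensity waves.

The raw observable of the pipeline is the log R ratio (LRR): a normalized
log2 intensity ratio per array probe that sits near 0 at two copies, drops
under deletion and rises under duplication. This module loads a
probe-by-sample LRR matrix (GenomeStudio-final-report-like tab-delimited
text), restricts it to autosomes, and removes the slowly varying
"GC wave" — a spurious intensity component correlated with local GC
content — by per-sample regression of LRR on the probe GC fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InputError, ParseError

#: Default autosome labels (cattle: 29 autosomes). Chromosome labels are
#: opaque tokens; pass a different list for another species.
DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 30))

_NA_TOKENS = {"", "NA", "NaN", "nan", ".", "NULL"}


@dataclass(frozen=True)
class ProbePanel:
    """Ordered probe coordinate system: id, chromosome, position, GC fraction.

    Probes are strictly sorted by (chromosome, position); positions are
    1-based and unique within a chromosome; ``gc`` is the local GC fraction
    in [0, 1] used by :func:`gc_correct`.
    """

    probe_id: np.ndarray  # str
    chrom: np.ndarray  # str
    position: np.ndarray  # int64, 1-based bp
    gc: np.ndarray  # float64 in [0, 1]

    def __post_init__(self):
        n = len(self.probe_id)
        if not (len(self.chrom) == len(self.position) == len(self.gc) == n):
            raise InputError("panel arrays must have equal length")
        for c in self.chroms():
            pos = self.position[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise InputError(
                    f"panel positions on chromosome {c} are not strictly increasing"
                )
        finite = np.isfinite(self.gc)
        if np.any((self.gc[finite] < 0) | (self.gc[finite] > 1)):
            raise InputError("panel GC fractions must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    def chroms(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous probe-index slice covering one chromosome."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise InputError(f"chromosome {chrom!r} not present in panel")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, mask: np.ndarray) -> "ProbePanel":
        return ProbePanel(
            self.probe_id[mask], self.chrom[mask], self.position[mask], self.gc[mask]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "chrom": self.chrom,
                "position": self.position,
                "gc": self.gc,
            }
        )


@dataclass
class LRRMatrix:
    """Sample-by-probe LRR values tied to a :class:`ProbePanel`.

    ``values[i, j]`` is sample ``samples[i]`` at probe ``panel.probe_id[j]``.
    After loading, no missing-value sentinel remains (missing cells are
    median-imputed or the probe is dropped; see :func:`read_lrr`).
    """

    samples: list[str]
    values: np.ndarray  # (n_samples, n_probes) float64
    panel: ProbePanel
    n_dropped_probes: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), self.panel.n_probes):
            raise InputError(
                f"LRR matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {self.panel.n_probes} probes"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_block(self, chrom: str) -> np.ndarray:
        """View of the value matrix restricted to one chromosome."""
        return self.values[:, self.panel.chrom_slice(chrom)]


def read_samplesheet(path) -> pd.DataFrame:
    """Read a tab-delimited sample sheet with columns sample, breed, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "breed", "group"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise InputError(f"duplicate sample ids in sample sheet: {dups}")
    return df


def read_panel(path) -> ProbePanel:
    """Read a probe map (probe_id, chrom, position[, gc]); gc defaults to NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str},
                     float_precision="round_trip")
    required = {"probe_id", "chrom", "position"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"panel file missing columns: {sorted(missing)}")
    gc = df["gc"].to_numpy(float) if "gc" in df.columns else np.full(len(df), np.nan)
    return ProbePanel(
        df["probe_id"].to_numpy(dtype=object),
        df["chrom"].to_numpy(dtype=object),
        df["position"].to_numpy(np.int64),
        gc,
    )


def read_lrr(
    matrix_path,
    panel_path,
    samplesheet_path,
    autosomes: tuple[str, ...] | None = None,
    max_missing_frac: float = 0.05,
) -> LRRMatrix:
    """Load an LRR matrix, restrict to autosomes, resolve missing cells.

    The matrix file is tab-delimited with columns ``Name``, ``Chr``,
    ``Position`` followed by one LRR column per sample. Probes whose ``Chr``
    is not in ``autosomes`` are dropped (the count is recorded on
    ``n_dropped_probes``). Missing cells are imputed with the per-probe
    median across samples when fewer than ``max_missing_frac`` of a probe's
    values are missing; otherwise the probe is dropped. Any cell that is
    neither numeric nor a recognized missing token raises :class:`ParseError`
    with its line number.
    """
    autosomes = tuple(autosomes) if autosomes is not None else DEFAULT_AUTOSOMES
    panel = read_panel(panel_path)
    sheet = read_samplesheet(samplesheet_path)

    df = pd.read_csv(matrix_path, sep="\t", dtype={"Name": str, "Chr": str},
                     float_precision="round_trip")
    for col in ("Name", "Chr", "Position"):
        if col not in df.columns:
            raise InputError(f"LRR matrix missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("Name", "Chr", "Position")]

    expected = set(sheet["sample"])
    got = set(sample_cols)
    if expected != got:
        offenders = sorted(expected.symmetric_difference(got))
        raise InputError(
            "sample ids in LRR header do not match the sample sheet; "
            f"offending ids: {offenders}"
        )
    # keep the sample sheet's ordering
    sample_cols = list(sheet["sample"])

    raw = df[sample_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.astype(str).apply(
        lambda col: col.str.strip().isin(_NA_TOKENS) | col.isin(["nan"])
    ) & raw.notna()
    if bad.to_numpy().any():
        row = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
        col = bad.columns[int(np.flatnonzero(bad.iloc[row].to_numpy())[0])]
        raise ParseError(
            f"non-numeric LRR value {raw.iloc[row][col]!r} for sample {col!r}",
            line=row + 2,  # header is line 1
        )

    # autosome restriction
    keep = df["Chr"].isin(autosomes).to_numpy()
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    numeric = numeric.loc[keep].reset_index(drop=True)

    # align to panel order via probe id; probes absent from the panel are dropped
    panel_order = {pid: i for i, pid in enumerate(panel.probe_id)}
    in_panel = df["Name"].map(panel_order).notna().to_numpy()
    df = df.loc[in_panel].reset_index(drop=True)
    numeric = numeric.loc[in_panel].reset_index(drop=True)
    order = np.argsort(df["Name"].map(panel_order).to_numpy())
    df = df.iloc[order].reset_index(drop=True)
    numeric = numeric.iloc[order].reset_index(drop=True)

    panel_mask = np.isin(panel.probe_id, df["Name"].to_numpy())
    panel = panel.subset(panel_mask)

    values = numeric.to_numpy(float).T  # samples x probes
    miss = ~np.isfinite(values)
    if miss.any():
        frac = miss.mean(axis=0)
        drop = frac >= max_missing_frac
        for j in np.flatnonzero(~drop & miss.any(axis=0)):
            col = values[:, j]
            med = np.nanmedian(col)
            col[~np.isfinite(col)] = med
        if drop.any():
            values = values[:, ~drop]
            panel = panel.subset(~drop)
            n_dropped += int(drop.sum())

    return LRRMatrix(sample_cols, values, panel, n_dropped_probes=n_dropped)


def gc_correct(m: LRRMatrix, mode: str = "linear", loess_frac: float = 0.3,
               trim_mads: float = 4.0) -> LRRMatrix:
    """Remove the GC-correlated intensity wave from each sample.

    For ``mode='linear'``, each sample's LRR vector is regressed (ordinary
    least squares with intercept) on the panel GC fraction and the fit is
    subtracted; the sample mean LRR is retained. OLS residuals are exactly
    orthogonal to the GC track, so a second application is a no-op.

    ``mode='trimmed'`` fits the same regression on the probes within
    ``trim_mads`` scaled median absolute deviations of the sample median
    before subtracting the fit from all probes. This shields the wave
    estimate from leverage by genuine copy-number spans, which otherwise
    attenuates segment means whenever CNVs cover a non-negligible fraction
    of the panel; it is the pipeline default.

    ``mode='loess'`` substitutes a lowess local-linear fit of LRR on GC.
    """
    gc = np.asarray(m.panel.gc, dtype=float)
    if not np.all(np.isfinite(gc)):
        raise InputError("panel carries no finite GC track; cannot GC-correct")
    if np.ptp(gc) == 0:
        raise DegenerateDesignError("GC track is constant; regression design is degenerate")
    if mode not in ("linear", "trimmed", "loess"):
        raise InputError(f"unknown gc_correct mode {mode!r}")

    out = np.empty_like(m.values)
    if mode == "linear":
        X = np.column_stack([np.ones_like(gc), gc])
        # one shared pseudo-inverse: the design is identical for all samples
        pinv = np.linalg.pinv(X)
        beta = pinv @ m.values.T  # (2, n_samples)
        fit = (X @ beta).T
        resid = m.values - fit
        out = resid + m.values.mean(axis=1, keepdims=True)
    elif mode == "trimmed":
        X = np.column_stack([np.ones_like(gc), gc])
        for i in range(m.n_samples):
            y = m.values[i]
            med = np.median(y)
            mad = np.median(np.abs(y - med)) * 1.4826
            keep = np.abs(y - med) <= trim_mads * max(mad, 1e-12)
            if keep.sum() < 2 or np.ptp(gc[keep]) == 0:
                keep = np.ones_like(keep)
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            resid = y - X @ beta
            out[i] = resid - resid.mean() + y.mean()
    else:
        from scipy.interpolate import interp1d
        from statsmodels.nonparametric.smoothers_lowess import lowess  # optional path

        for i in range(m.n_samples):
            sm = lowess(m.values[i], gc, frac=loess_frac, return_sorted=True)
            f = interp1d(sm[:, 0], sm[:, 1], bounds_error=False,
                         fill_value=(sm[0, 1], sm[-1, 1]))
            resid = m.values[i] - f(gc)
            out[i] = resid - resid.mean() + m.values[i].mean()

    return LRRMatrix(list(m.samples), out, m.panel,
                     n_dropped_probes=m.n_dropped_probes, meta=dict(m.meta))
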