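"""Synthetic SNP-array cohorts with known copy-number truth.

Emulates the structure of a multi-breed cattle cohort genotyped on a dense
SNP array: several ancestral groups each split into breeds, plus admixed
(hybrid) individuals; multi-probe deletion/duplication loci whose allele
frequencies diverge hierarchically between groups and breeds under a
Balding-Nichols model; Hardy-Weinberg genotype sampling at each locus;
per-probe Gaussian LRR noise; and a GC-correlated intensity wave. A
:class:`TruthSet` records the locus placements, per-sample copy states,
breed allele frequencies, and ancestry proportions so that every
downstream stage (segmentation, calling, structure, differentiation) can
be scored against known truth.

Every draw is controlled by ``SimConfig.seed``; identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, CnvPopGenError
from .preprocess import LRRMatrix, ProbePanel

__all__ = [
    "SimConfig",
    "CnvLocus",
    "TruthSet",
    "simulate_panel",
    "simulate_freqs",
    "simulate_cohort",
    "write_cohort",
    "read_truth",
]

#: LRR means per copy state. Two copies sit at 0; a hemizygous deletion near
#: -0.5; a homozygous deletion near -1.2; a single-copy duplication near +0.4.
#: Chosen so that every non-neutral state mean clears the +/-0.3 segment-mean
#: calling threshold with margin: a state mean exactly at the threshold would
#: be missed ~half the time under any symmetric noise.
DEFAULT_LRR_MEANS = {0: -1.2, 1: -0.5, 2: 0.0, 3: 0.4}

_HYBRID_GROUP = "HYB"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults define the standard desk-scale cohort used throughout the test
    suite: 3 ancestral groups x 2 breeds x 8 individuals plus 4 hybrids on
    2 chromosomes of 400 probes, with 12 copy-number loci of which 3 carry
    strongly group-differentiated deletion frequencies.
    """

    n_groups: int = 3
    breeds_per_group: int = 2
    n_per_breed: int = 8
    n_hybrids: int = 4
    n_chrom: int = 2
    probes_per_chrom: int = 400
    probe_spacing: int = 2000  # bp between consecutive probes
    n_cnv_loci: int = 12
    cnv_span_probes: tuple[int, int] = (10, 25)
    divergence_F: tuple[float, float] = (0.2, 0.05)  # (group level, breed level)
    base_freq_range: tuple[float, float] = (0.2, 0.8)
    n_differentiated_loci: int = 3
    diff_freq_pair: tuple[float, float] = (0.9, 0.05)
    gain_fraction: float = 0.3  # share of non-differentiated loci that duplicate
    lrr_means: dict = field(default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    noise_sd: float = 0.12
    gc_wave_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_groups": self.n_groups,
            "breeds_per_group": self.breeds_per_group,
            "n_per_breed": self.n_per_breed,
            "n_chrom": self.n_chrom,
            "probes_per_chrom": self.probes_per_chrom,
            "probe_spacing": self.probe_spacing,
            "n_cnv_loci": self.n_cnv_loci,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.n_hybrids < 0:
            raise ConfigError(f"n_hybrids must be >= 0, got {self.n_hybrids}")
        if not self.noise_sd > 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.gc_wave_amplitude < 0:
            raise ConfigError("gc_wave_amplitude must be >= 0")
        for f in self.divergence_F:
            if not 0 < f < 1:
                raise ConfigError(f"divergence_F entries must lie in (0,1), got {f}")
        lo, hi = self.base_freq_range
        if not (0 < lo <= hi < 1):
            raise ConfigError(f"base_freq_range must satisfy 0<lo<=hi<1, got {self.base_freq_range}")
        for f in self.diff_freq_pair:
            if not 0 <= f <= 1:
                raise ConfigError(f"diff_freq_pair entries must lie in [0,1], got {f}")
        s_lo, s_hi = self.cnv_span_probes
        if not (1 <= s_lo <= s_hi):
            raise ConfigError(f"cnv_span_probes must be an increasing range >= 1, got {self.cnv_span_probes}")
        if s_hi > self.probes_per_chrom:
            raise ConfigError("cnv_span_probes upper bound exceeds probes_per_chrom")
        if self.n_differentiated_loci > self.n_cnv_loci:
            raise ConfigError("n_differentiated_loci cannot exceed n_cnv_loci")
        if not 0 <= self.gain_fraction <= 1:
            raise ConfigError("gain_fraction must lie in [0,1]")
        if set(self.lrr_means) < {0, 1, 2, 3}:
            raise ConfigError("lrr_means must map copy states 0..3")

    # -- derived layout -----------------------------------------------------
    @property
    def breeds(self) -> list[str]:
        return [
            f"G{g + 1}B{b + 1}"
            for g in range(self.n_groups)
            for b in range(self.breeds_per_group)
        ]

    @property
    def groups(self) -> list[str]:
        return [f"G{g + 1}" for g in range(self.n_groups)]

    def breed_group(self, breed: str) -> str:
        return breed.split("B")[0]


@dataclass(frozen=True)
class CnvLocus:
    """One simulated copy-number locus: a contiguous probe span on a chromosome."""

    chrom: str
    first_probe: int  # chromosome-local probe index, inclusive
    last_probe: int  # inclusive
    kind: str  # "loss" | "gain"

    @property
    def n_probes(self) -> int:
        return self.last_probe - self.first_probe + 1


@dataclass
class TruthSet:
    """Ground truth for a simulated cohort."""

    cnv_loci: list[CnvLocus]
    genotypes: np.ndarray  # (n_samples, n_loci) integer copy state
    breed_freqs: pd.DataFrame  # loci x breeds, CNV-allele frequency
    group_freqs: pd.DataFrame  # loci x groups (parent level of the hierarchy)
    ancestry_Q: pd.DataFrame  # samples x groups, rows sum to 1

    def __post_init__(self):
        rows = self.ancestry_Q.to_numpy(float).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise CnvPopGenError("ancestry_Q rows must sum to 1")
        for j, locus in enumerate(self.cnv_loci):
            states = set(np.unique(self.genotypes[:, j]).tolist())
            allowed = {0, 1, 2} if locus.kind == "loss" else {2, 3}
            if not states <= allowed:
                raise CnvPopGenError(
                    f"locus {j} has copy states {states} inconsistent with kind {locus.kind}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "cnv_loci": [dataclasses.asdict(l) for l in self.cnv_loci],
                "genotypes": self.genotypes.tolist(),
                "breed_freqs": self.breed_freqs.to_dict(orient="split"),
                "group_freqs": self.group_freqs.to_dict(orient="split"),
                "ancestry_Q": self.ancestry_Q.to_dict(orient="split"),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)

        def frame(spl):
            return pd.DataFrame(spl["data"], index=spl["index"], columns=spl["columns"])

        return cls(
            cnv_loci=[CnvLocus(**l) for l in d["cnv_loci"]],
            genotypes=np.asarray(d["genotypes"], dtype=int),
            breed_freqs=frame(d["breed_freqs"]),
            group_freqs=frame(d["group_freqs"]),
            ancestry_Q=frame(d["ancestry_Q"]),
        )


# ---------------------------------------------------------------------------
# panel


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed), stream]))


def simulate_panel(cfg: SimConfig) -> ProbePanel:
    """Lay out an evenly spaced probe panel with a smooth GC track.

    Positions on each chromosome are ``probe_spacing * (i + 1)`` for probe
    index i, so the last probe sits at ``probes_per_chrom * probe_spacing``.
    The GC fraction is a smooth sinusoid of position (phase drawn per
    chromosome) bounded well inside [0, 1], so that a GC-correlated
    intensity wave can be injected and later regressed out.
    """
    rng = _rng(cfg.seed, 0)
    ids, chroms, poss, gcs = [], [], [], []
    for c in range(cfg.n_chrom):
        phase = rng.uniform(0, 2 * np.pi)
        i = np.arange(cfg.probes_per_chrom)
        pos = (i + 1) * cfg.probe_spacing
        gc = 0.45 + 0.12 * np.sin(2 * np.pi * i / 173.0 + phase)
        ids.extend(f"chr{c + 1}_p{j + 1}" for j in i)
        chroms.extend([str(c + 1)] * cfg.probes_per_chrom)
        poss.append(pos)
        gcs.append(gc)
    return ProbePanel(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=object),
        np.concatenate(poss).astype(np.int64),
        np.clip(np.concatenate(gcs), 0.0, 1.0),
    )


# ---------------------------------------------------------------------------
# allele frequencies


def _balding_nichols(rng, parent: np.ndarray, F: float) -> np.ndarray:
    """Draw child frequencies around ``parent`` with divergence F.

    Beta distribution with mean = parent and shape scaled by (1-F)/F; as
    F -> 0 the child concentrates on the parent frequency.
    """
    scale = (1.0 - F) / F
    a = np.clip(parent * scale, 1e-6, None)
    b = np.clip((1.0 - parent) * scale, 1e-6, None)
    return np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)


def simulate_freqs(cfg: SimConfig, seed: int | None = None):
    """Hierarchical CNV-allele frequencies per breed.

    For each locus an ancestral frequency is drawn uniformly from
    ``base_freq_range``; group frequencies are Balding-Nichols draws around
    it at divergence ``divergence_F[0]`` and breed frequencies around their
    group at ``divergence_F[1]``. The first ``n_differentiated_loci`` loci
    instead get fixed frequencies: group G1 receives ``diff_freq_pair[0]``
    and every other group ``diff_freq_pair[1]`` (breeds inherit their group
    value exactly), guaranteeing a large between-group frequency contrast.

    Returns ``(breed_freqs, group_freqs)`` as loci x breed / loci x group
    DataFrames.
    """
    rng = _rng(cfg.seed if seed is None else seed, 1)
    L, G = cfg.n_cnv_loci, cfg.n_groups
    lo, hi = cfg.base_freq_range
    ancestral = rng.uniform(lo, hi, size=L)
    gF, bF = cfg.divergence_F

    group = np.empty((L, G))
    for g in range(G):
        group[:, g] = _balding_nichols(rng, ancestral, gF)
    breed = np.empty((L, G * cfg.breeds_per_group))
    for g in range(G):
        for b in range(cfg.breeds_per_group):
            breed[:, g * cfg.breeds_per_group + b] = _balding_nichols(rng, group[:, g], bF)

    hi_f, lo_f = cfg.diff_freq_pair
    for l in range(cfg.n_differentiated_loci):
        group[l, :] = lo_f
        group[l, 0] = hi_f
        for g in range(G):
            breed[l, g * cfg.breeds_per_group:(g + 1) * cfg.breeds_per_group] = group[l, g]

    loci = [f"locus{j + 1}" for j in range(L)]
    return (
        pd.DataFrame(breed, index=loci, columns=cfg.breeds),
        pd.DataFrame(group, index=loci, columns=cfg.groups),
    )


# ---------------------------------------------------------------------------
# cohort


def _place_loci(cfg: SimConfig, rng: np.random.Generator, min_gap: int = 5) -> list[CnvLocus]:
    """Place non-overlapping loci (>= min_gap probes apart) on random chromosomes."""
    placed: dict[str, list[tuple[int, int]]] = {str(c + 1): [] for c in range(cfg.n_chrom)}
    loci: list[CnvLocus] = []
    s_lo, s_hi = cfg.cnv_span_probes
    for j in range(cfg.n_cnv_loci):
        if j < cfg.n_differentiated_loci:
            kind = "loss"  # differentiated loci are deletions: they feed the marker recoding
        else:
            kind = "gain" if rng.random() < cfg.gain_fraction else "loss"
        for _ in range(1000):
            span = int(rng.integers(s_lo, s_hi + 1))
            chrom = str(int(rng.integers(cfg.n_chrom)) + 1)
            start = int(rng.integers(0, cfg.probes_per_chrom - span + 1))
            end = start + span - 1
            if all(
                end + min_gap < a or start - min_gap > b for a, b in placed[chrom]
            ):
                placed[chrom].append((start, end))
                loci.append(CnvLocus(chrom, start, end, kind))
                break
        else:
            raise CnvPopGenError(
                "could not place non-overlapping CNV loci; reduce n_cnv_loci or spans"
            )
    return loci


def simulate_cohort(cfg: SimConfig):
    """Simulate one cohort: returns ``(LRRMatrix, samplesheet, TruthSet)``.

    Copy states at deletion loci follow Hardy-Weinberg sampling at the
    breed's deletion-allele frequency (0/1/2 deletion alleles -> 2/1/0
    copies); at duplication loci carriers of >= 1 duplication allele get 3
    copies. Hybrid individuals draw ancestry proportions from a flat
    Dirichlet over the groups and use the ancestry-weighted mixture of
    group frequencies. The LRR of a probe inside a locus span is
    ``lrr_means[copy state] + N(0, noise_sd)``; off-locus probes are pure
    noise; the wave ``gc_wave_amplitude * (gc - mean gc)`` is added to
    every probe of every sample.
    """
    panel = simulate_panel(cfg)
    breed_freqs, group_freqs = simulate_freqs(cfg)
    rng = _rng(cfg.seed, 2)

    loci = _place_loci(cfg, rng)

    # samples ---------------------------------------------------------------
    records = []
    for breed in cfg.breeds:
        for k in range(cfg.n_per_breed):
            records.append(
                {"sample": f"{breed}_{k + 1:03d}", "breed": breed, "group": cfg.breed_group(breed)}
            )
    for k in range(cfg.n_hybrids):
        records.append({"sample": f"HYB_{k + 1:03d}", "breed": "SHK", "group": _HYBRID_GROUP})
    sheet = pd.DataFrame(records)
    n = len(sheet)

    Q = np.zeros((n, cfg.n_groups))
    for i, rec in enumerate(records):
        if rec["group"] == _HYBRID_GROUP:
            Q[i] = rng.dirichlet(np.ones(cfg.n_groups))
        else:
            Q[i, cfg.groups.index(rec["group"])] = 1.0

    # genotypes -------------------------------------------------------------
    L = cfg.n_cnv_loci
    geno = np.full((n, L), 2, dtype=int)
    gf = group_freqs.to_numpy()
    bf = breed_freqs.to_numpy()
    for i, rec in enumerate(records):
        if rec["group"] == _HYBRID_GROUP:
            f = gf @ Q[i]
        else:
            f = bf[:, cfg.breeds.index(rec["breed"])]
        n_alleles = rng.binomial(2, f)
        for j, locus in enumerate(loci):
            if locus.kind == "loss":
                geno[i, j] = 2 - n_alleles[j]
            else:
                geno[i, j] = 2 + (1 if n_alleles[j] > 0 else 0)

    # LRR values ------------------------------------------------------------
    values = rng.normal(0.0, cfg.noise_sd, size=(n, panel.n_probes))
    chrom_offset = {str(c + 1): c * cfg.probes_per_chrom for c in range(cfg.n_chrom)}
    for j, locus in enumerate(loci):
        off = chrom_offset[locus.chrom]
        sl = slice(off + locus.first_probe, off + locus.last_probe + 1)
        shift = np.array([cfg.lrr_means[s] for s in geno[:, j]])
        values[:, sl] += shift[:, None]
    values += cfg.gc_wave_amplitude * (panel.gc - panel.gc.mean())

    truth = TruthSet(
        cnv_loci=loci,
        genotypes=geno,
        breed_freqs=breed_freqs,
        group_freqs=group_freqs,
        ancestry_Q=pd.DataFrame(Q, index=sheet["sample"], columns=cfg.groups),
    )
    lrr = LRRMatrix(list(sheet["sample"]), values, panel)
    return lrr, sheet, truth


def simulate_deletion_markers(cfg: SimConfig, n_markers: int, seed: int | None = None):
    """Draw biallelic deletion markers directly, skipping the intensity level.

    Convenience for testing marker-level methods (relatedness, distance,
    MDS, admixture) at marker counts larger than a probe panel can host:
    hierarchical breed frequencies are drawn as in :func:`simulate_freqs`
    (with ``n_markers`` loci, the first ``n_differentiated_loci`` fixed to
    ``diff_freq_pair``), Hardy-Weinberg genotypes are sampled per breed
    (hybrids at ancestry-mixed group frequencies), and carriers of >= 1
    deletion allele are coded "12" (matching the dominant one-state calling
    of the intensity pipeline).

    Returns ``(GenotypeMatrix, samplesheet, ancestry_Q)``.
    """
    from .calling import GenotypeMatrix

    cfg = dataclasses.replace(cfg, n_cnv_loci=n_markers)
    breed_freqs, group_freqs = simulate_freqs(cfg, seed=seed)
    rng = _rng(cfg.seed if seed is None else seed, 4)

    records = []
    for breed in cfg.breeds:
        for k in range(cfg.n_per_breed):
            records.append({"sample": f"{breed}_{k + 1:03d}", "breed": breed,
                            "group": cfg.breed_group(breed)})
    for k in range(cfg.n_hybrids):
        records.append({"sample": f"HYB_{k + 1:03d}", "breed": "SHK", "group": _HYBRID_GROUP})
    sheet = pd.DataFrame(records)
    n = len(sheet)

    Q = np.zeros((n, cfg.n_groups))
    gf, bf = group_freqs.to_numpy(), breed_freqs.to_numpy()
    codes = np.full((n, n_markers), "22", dtype=object)
    for i, rec in enumerate(records):
        if rec["group"] == _HYBRID_GROUP:
            Q[i] = rng.dirichlet(np.ones(cfg.n_groups))
            f = gf @ Q[i]
        else:
            Q[i, cfg.groups.index(rec["group"])] = 1.0
            f = bf[:, cfg.breeds.index(rec["breed"])]
        carrier = rng.binomial(2, f) > 0
        codes[i, carrier] = "12"

    g = GenotypeMatrix(
        samples=list(sheet["sample"]),
        markers=[f"locus{j + 1}" for j in range(n_markers)],
        codes=codes,
    )
    ancestry = pd.DataFrame(Q, index=sheet["sample"], columns=cfg.groups)
    return g, sheet, ancestry


# ---------------------------------------------------------------------------
# text round-trip


def write_cohort(outdir, lrr: LRRMatrix, sheet: pd.DataFrame, truth: TruthSet | None = None):
    """Write a cohort as plain text: lrr.tsv, panel.tsv, samples.tsv, truth.json.

    The LRR matrix layout matches a GenomeStudio-style final report: one row
    per probe with Name/Chr/Position, then one LRR column per sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "Name": lrr.panel.probe_id,
            "Chr": lrr.panel.chrom,
            "Position": lrr.panel.position,
        }
    )
    for i, s in enumerate(lrr.samples):
        df[s] = lrr.values[i]
    # 17 significant digits: a re-read reproduces the matrix bit-exactly
    df.to_csv(outdir / "lrr.tsv", sep="\t", index=False, float_format="%.17g")
    lrr.panel.to_frame().to_csv(outdir / "panel.tsv", sep="\t", index=False,
                                float_format="%.17g")
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
    return outdir


def read_truth(path) -> TruthSet:
    return TruthSet.from_json(Path(path).read_text())
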