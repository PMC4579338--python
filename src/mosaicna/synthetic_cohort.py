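"""Synthetic paired control/UM/PT SNP-array cohorts with known ground truth.

The generator emulates the study design this package analyses: for each
subject, one constitutional control profile (blood/skin), one or more
uninvolved-margin (UM) samples from macroscopically normal breast tissue
carrying mosaic aberrations, and 0-3 primary-tumor (PT) samples into which
UM aberrations propagate at a higher cell fraction.

Signal model (shared with the caller through :mod:`mosaicna.mosaic_model`):
germline genotypes are drawn once per subject under Hardy-Weinberg
proportions from per-probe population allele frequencies ~ Uniform(0.05,
0.95); outside aberrations, LRR is centred at 0 and BAF at {0, 0.5, 1} by
genotype; inside an aberration carried by a fraction ``f`` of cells, LRR is
shifted by ``expected_lrr_shift`` and each heterozygous probe's BAF sits on
one of the two branches ``0.5 +/- expected_baf_split`` (an independent fair
coin per probe, since phase is unobserved on arrays).  Gaussian noise is
added per probe and BAF is clipped to [0, 1].

Defaults mirror the study conditions: 4-kb probe spacing (OmniExpress-like
density), LRR sd 0.15 (inside the < 0.2 array-noise inclusion bound),
het-BAF sd 0.03, hom-BAF sd 0.01, missing-genotype rate 0.5 % (call rate
99.5 %, inside the > 98 % bound).

Randomness is fully deterministic: one global seed is expanded into
per-sample child seeds by hashing the subject and sample ids (CRC-32) into
a ``numpy`` ``SeedSequence``, so cohorts are stable under subject
reordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_io import Manifest, ProbeSeries
from .mosaic_model import AberrationClass, expected_baf_split, expected_lrr_shift

__all__ = [
    "GenomeModel",
    "NoiseModel",
    "SimAberrationSpec",
    "CohortSimConfig",
    "CohortResult",
    "simulate_genotypes",
    "simulate_sample",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def child_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-entity generator: seed + CRC-32 of each token."""
    entropy = [int(seed)] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# genome model

# GRCh37 chromosome lengths (bp), 22 autosomes + X
_GRCH37_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths and a regular probe grid.

    The default is a human-reference-like genome (22 autosomes + X) with
    4-kb probe spacing, giving ~770k probes genome-wide — the density order
    of an OmniExpress-class array.  Smaller genomes (fewer/shorter
    chromosomes) are used to scale simulations down without changing probe
    density or noise.
    """

    lengths: dict[str, int] = field(default_factory=lambda: dict(_GRCH37_LENGTHS))
    spacing: int = 4_000

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths.values()):
            raise ConfigError("chromosome lengths must be positive")
        if self.spacing <= 0:
            raise ConfigError("probe spacing must be positive")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_autosomal_bp(self) -> int:
        return sum(v for k, v in self.lengths.items() if k not in ("X", "Y"))

    def probe_grid(self) -> pd.DataFrame:
        """Probe id / chrom / position table (positions strictly increasing)."""
        frames = []
        for chrom, length in self.lengths.items():
            pos = np.arange(self.spacing, length + 1, self.spacing, dtype=np.int64)
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"p{chrom}_{i}" for i in range(len(pos))],
                        "chrom": chrom,
                        "pos": pos,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def n_probes(self) -> int:
        return int(sum(length // self.spacing for length in self.lengths.values()))


def small_genome(n_chroms: int = 3, chrom_mb: float = 120.0, spacing: int = 4_000) -> GenomeModel:
    """Reduced genome for fast simulations at unchanged probe density."""
    return GenomeModel(
        lengths={str(i + 1): int(chrom_mb * 1e6) for i in range(n_chroms)},
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# noise and aberration specs

@dataclass(frozen=True)
class NoiseModel:
    """Per-probe Gaussian noise and missing-call rate."""

    lrr_sd: float = 0.15
    het_baf_sd: float = 0.03
    hom_baf_sd: float = 0.01
    missing_rate: float = 0.005

    def __post_init__(self) -> None:
        if min(self.lrr_sd, self.het_baf_sd, self.hom_baf_sd, self.missing_rate) < 0:
            raise ConfigError("noise rates must be >= 0")
        if self.missing_rate >= 1:
            raise ConfigError("missing_rate must be < 1")


NOISELESS = NoiseModel(lrr_sd=0.0, het_baf_sd=0.0, hom_baf_sd=0.0, missing_rate=0.0)


@dataclass(frozen=True)
class SimAberrationSpec:
    """One injected aberration: interval, class, cell fraction, germline flag."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    cls: AberrationClass
    f: float
    germline: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"spec start {self.start} > end {self.end}")
        if not 0.0 < self.f <= 1.0:
            raise ConfigError(f"spec fraction f={self.f} outside (0, 1]")
        object.__setattr__(self, "cls", AberrationClass(self.cls))

    def overlaps(self, other: "SimAberrationSpec") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def _check_non_overlapping(specs: list[SimAberrationSpec]) -> None:
    by_chrom: dict[str, list[SimAberrationSpec]] = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if a.end >= b.start:
                raise ConfigError(
                    f"overlapping aberration specs on chrom {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


# ---------------------------------------------------------------------------
# single-sample simulation

def simulate_genotypes(
    allele_freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw germline genotypes under Hardy-Weinberg proportions.

    ``allele_freqs`` is the per-probe population B-allele frequency; returns
    an array of ``AA``/``AB``/``BB`` strings.
    """
    p = np.asarray(allele_freqs, dtype=float)
    u = rng.random(p.size)
    gt = np.full(p.size, "AA", dtype="<U2")
    het = (u >= (1 - p) ** 2) & (u < (1 - p) ** 2 + 2 * p * (1 - p))
    gt[het] = "AB"
    gt[u >= (1 - p) ** 2 + 2 * p * (1 - p)] = "BB"
    return gt


def simulate_sample(
    genome: GenomeModel,
    genotypes: np.ndarray,
    specs: list[SimAberrationSpec],
    noise: NoiseModel,
    rng: np.random.Generator,
    sample_id: str = "sample",
    c: float = 1.0,
    grid: pd.DataFrame | None = None,
) -> ProbeSeries:
    """Simulate one sample's probe series from germline genotypes + events.

    Inside each aberration, heterozygous probes sit on one of the two BAF
    branches ``0.5 +/- delta`` (fair coin per probe) and all probes take the
    class's expected LRR shift; homozygous BAF is unaffected (A- and B-only
    signals stay at the rails).  ``specs`` must be non-overlapping.
    """
    _check_non_overlapping(specs)
    if grid is None:
        grid = genome.probe_grid()
    n = len(grid)
    if len(genotypes) != n:
        raise ConfigError(f"genotypes length {len(genotypes)} != grid size {n}")
    chrom = grid["chrom"].to_numpy()
    pos = grid["pos"].to_numpy()

    lrr = rng.normal(0.0, noise.lrr_sd, n) if noise.lrr_sd > 0 else np.zeros(n)
    baf = np.empty(n)
    het = genotypes == "AB"
    baf[genotypes == "AA"] = 0.0
    baf[genotypes == "BB"] = 1.0
    baf[het] = 0.5
    if noise.hom_baf_sd > 0:
        hom = ~het
        baf[hom] = baf[hom] + rng.normal(0.0, noise.hom_baf_sd, int(hom.sum()))
    if noise.het_baf_sd > 0:
        baf[het] = baf[het] + rng.normal(0.0, noise.het_baf_sd, int(het.sum()))

    for spec in specs:
        mask = (chrom == spec.chrom) & (pos >= spec.start) & (pos <= spec.end)
        if not mask.any():
            continue
        lrr[mask] += expected_lrr_shift(spec.cls, spec.f, c)
        hmask = mask & het
        nh = int(hmask.sum())
        if nh:
            delta = expected_baf_split(spec.cls, spec.f)
            branch = np.where(rng.random(nh) < 0.5, 1.0, -1.0)
            baf[hmask] += branch * delta

    np.clip(baf, 0.0, 1.0, out=baf)

    gtype = genotypes.astype("<U2").copy()
    if noise.missing_rate > 0:
        nc = rng.random(n) < noise.missing_rate
        gtype[nc] = "NC"
        baf[nc] = np.nan

    probes = grid.copy()
    probes["lrr"] = lrr
    probes["baf"] = baf
    probes["gtype"] = gtype
    return ProbeSeries(sample_id=sample_id, probes=probes)


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class CohortSimConfig:
    """Study-condition parameters for a simulated cohort.

    Defaults emulate the cohort structure of the breast-margin study: 1-3
    UMs per subject, up to three tumor foci for multifocal cases, gains as
    the predominant aberration class, mosaic fractions spanning the low-
    mosaicism range the arrays can detect, and near-universal propagation
    of UM events into PTs at a considerably higher cell fraction.
    """

    n_subjects: int = 5
    genome: GenomeModel = field(default_factory=GenomeModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    um_range: tuple[int, int] = (1, 3)
    pt_range: tuple[int, int] = (1, 3)
    #: probability a UM carries any somatic aberration at all
    p_aberrant_um: float = 0.6
    #: number of aberrations in an aberrant UM: 1 + Poisson(rate)
    aberrations_per_um: float = 1.0
    #: event size: log-uniform between these bounds (Mb)
    size_mb_range: tuple[float, float] = (0.5, 50.0)
    #: carrier cell fraction: uniform between these bounds
    fraction_range: tuple[float, float] = (0.05, 0.9)
    #: class mix (GAIN, DEL, CNNLOH); gains predominate in margins
    class_probs: tuple[float, float, float] = (0.7, 0.15, 0.15)
    #: expected constitutional CNVs per subject (shared by all samples, f=1)
    germline_cnv_rate: float = 0.0
    germline_size_mb_range: tuple[float, float] = (0.2, 2.0)
    #: probability a UM event reappears in each PT of the subject
    propagation_prob: float = 0.9
    #: propagated fraction: f_PT = f_UM + (1 - f_UM) * U(boost_lo, boost_hi)
    propagation_boost: tuple[float, float] = (0.3, 0.7)
    #: UM-to-nearest-tumor edge-to-edge distance ~ U(0, max) cm
    max_distance_cm: float = 24.0
    lrr_response: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        for name in ("p_aberrant_um", "propagation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.germline_cnv_rate < 0 or self.aberrations_per_um < 0:
            raise ConfigError("rates must be >= 0")
        if not (1 <= self.pt_range[0] <= self.pt_range[1] <= 3):
            raise ConfigError("pt_range must lie within 1..3")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ConfigError("class_probs must sum to 1")


@dataclass
class CohortResult:
    """In-memory result of a cohort simulation."""

    manifest: Manifest
    truth: pd.DataFrame  # subject, sample, chrom, start, end, class, f, germline
    series: dict[str, ProbeSeries]  # empty when probes were not synthesised


TRUTH_COLUMNS = ["subject", "sample", "chrom", "start", "end", "class", "f", "germline"]


def _draw_event(
    cfg: CohortSimConfig,
    rng: np.random.Generator,
    existing: list[SimAberrationSpec],
    size_range: tuple[float, float],
    germline: bool,
    max_tries: int = 50,
) -> SimAberrationSpec | None:
    """Place one event uniformly (length-weighted chromosome) avoiding overlap."""
    chroms = cfg.genome.chroms
    lengths = np.array([cfg.genome.lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    lo, hi = size_range
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        size = int(np.exp(rng.uniform(np.log(lo * 1e6), np.log(hi * 1e6))))
        clen = cfg.genome.lengths[chrom]
        if size >= clen:
            size = clen // 2
        start = int(rng.integers(1, clen - size + 1))
        if germline:
            cls = AberrationClass.GAIN if rng.random() < 0.5 else AberrationClass.DEL
            f = 1.0
        else:
            cls = [AberrationClass.GAIN, AberrationClass.DEL, AberrationClass.CNNLOH][
                int(rng.choice(3, p=list(cfg.class_probs)))
            ]
            f = float(rng.uniform(*cfg.fraction_range))
        cand = SimAberrationSpec(chrom, start, start + size - 1, cls, f, germline)
        if not any(cand.overlaps(e) for e in existing):
            return cand
    return None


def simulate_cohort(cfg: CohortSimConfig, synthesize_probes: bool = True) -> CohortResult:
    """Generate manifest, per-sample probe series and a ground-truth table.

    Germline events appear identically (f=1) in every sample of their
    subject; each UM's somatic events reappear in each of the subject's PTs
    with probability ``propagation_prob`` at a strictly higher cell
    fraction.  With ``synthesize_probes=False`` only the manifest and truth
    table are produced (for cohort-statistics work at truth level).

    Identical config + seed gives identical output.
    """
    grid = cfg.genome.probe_grid() if synthesize_probes else None

    manifest_rows = []
    truth_rows: list[tuple] = []
    series: dict[str, ProbeSeries] = {}

    for si in range(cfg.n_subjects):
        subject = f"S{si + 1:03d}"
        rng_subj = child_rng(cfg.seed, "subject", subject)
        n_um = int(rng_subj.integers(cfg.um_range[0], cfg.um_range[1] + 1))
        n_pt = int(rng_subj.integers(cfg.pt_range[0], cfg.pt_range[1] + 1))

        germline_specs: list[SimAberrationSpec] = []
        n_germ = int(rng_subj.poisson(cfg.germline_cnv_rate))
        for _ in range(n_germ):
            ev = _draw_event(
                cfg, rng_subj, germline_specs, cfg.germline_size_mb_range, True
            )
            if ev is not None:
                germline_specs.append(ev)

        sample_specs: dict[str, list[SimAberrationSpec]] = {}
        control_id = f"{subject}_CTRL"
        manifest_rows.append((subject, control_id, "CONTROL", "blood", np.nan, np.nan))
        sample_specs[control_id] = list(germline_specs)

        pt_ids = [f"{subject}_PT{j + 1}" for j in range(n_pt)]
        pt_specs: dict[str, list[SimAberrationSpec]] = {
            p: list(germline_specs) for p in pt_ids
        }

        for j in range(n_um):
            um_id = f"{subject}_UM{j + 1}"
            rng_um = child_rng(cfg.seed, "events", um_id)
            specs = list(germline_specs)
            if rng_um.random() < cfg.p_aberrant_um:
                n_ev = 1 + int(rng_um.poisson(cfg.aberrations_per_um))
                for _ in range(n_ev):
                    ev = _draw_event(cfg, rng_um, specs, cfg.size_mb_range, False)
                    if ev is not None:
                        specs.append(ev)
            distance = float(rng_um.uniform(0.0, cfg.max_distance_cm))
            manifest_rows.append(
                (subject, um_id, "UM", "breast", round(distance, 2), np.nan)
            )
            sample_specs[um_id] = specs
            # propagation into each PT at a strictly higher fraction
            for pt in pt_ids:
                rng_prop = child_rng(cfg.seed, "prop", um_id, pt)
                for ev in specs:
                    if ev.germline:
                        continue
                    if rng_prop.random() >= cfg.propagation_prob:
                        continue
                    lo, hi = cfg.propagation_boost
                    f_pt = min(1.0, ev.f + (1.0 - ev.f) * float(rng_prop.uniform(lo, hi)))
                    prop = replace(ev, f=max(f_pt, ev.f))
                    if not any(prop.overlaps(e) for e in pt_specs[pt]):
                        pt_specs[pt].append(prop)

        for pt in pt_ids:
            manifest_rows.append((subject, pt, "PT", "tumor", np.nan, np.nan))
            sample_specs[pt] = pt_specs[pt]

        for sample_id, specs in sample_specs.items():
            for ev in specs:
                truth_rows.append(
                    (
                        subject,
                        sample_id,
                        ev.chrom,
                        ev.start,
                        ev.end,
                        ev.cls.value,
                        ev.f,
                        ev.germline,
                    )
                )

        if synthesize_probes:
            rng_gt = child_rng(cfg.seed, "genotypes", subject)
            freqs = rng_gt.uniform(0.05, 0.95, len(grid))
            genotypes = simulate_genotypes(freqs, rng_gt)
            for sample_id, specs in sample_specs.items():
                rng_s = child_rng(cfg.seed, "sample", sample_id)
                series[sample_id] = simulate_sample(
                    cfg.genome,
                    genotypes,
                    specs,
                    cfg.noise,
                    rng_s,
                    sample_id=sample_id,
                    c=cfg.lrr_response,
                    grid=grid,
                )

    manifest = Manifest(
        pd.DataFrame(
            manifest_rows,
            columns=["subject", "sample", "role", "tissue", "distance_cm", "subtype"],
        )
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return CohortResult(manifest=manifest, truth=truth, series=series)
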