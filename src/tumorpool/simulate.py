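"""Synthetic multi-region tumor sequencing data with known clonal truth.

The generator emulates a multi-region exome design: one patient, a matched
normal plus ``n_regions`` tumor regions sequenced at ~100x, with a somatic
mutation catalogue split into trunk mutations (in every region), branch
mutations (a proper subset of >= 2 regions) and private mutations (one
region). Each region has its own tumor purity; the observed alt fraction
of a mutation is its true cancer-cell VAF diluted by purity, plus a
per-base sequencing error floor. A hypermutator preset reproduces the
regime where one region carries hundreds of low-VAF private mutations.

Germline heterozygous sites, copy-number segments with and without
B-allele loss, and the resulting tumor allele-fraction shifts are
generated separately for the LOH pipeline.

All randomness flows from ``SimConfig.seed``: each output (truth, counts,
flanks, LOH data) draws from its own fixed sub-stream, so outputs are
byte-identical across runs and individually reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CLONAL,
    SUBCLONAL,
    BRANCH,
    PRIVATE,
    TRUNK,
    ConfigError,
    SampleMeta,
)
from .loh import GermlineHetSite, Segment
from .pooling import KEY, ReadPool, thin_counts

__all__ = [
    "SimConfig",
    "ClonalTruth",
    "simulate_truth",
    "simulate_counts",
    "simulate_flanks",
    "make_global_pool",
    "simulate_loh_data",
    "region_pool",
]

_BASES = np.array(list("ACGT"))

# sub-stream indices for SeedSequence([seed, index])
_STREAM_TRUTH = 0
_STREAM_COUNTS = 1
_STREAM_FLANKS = 2
_STREAM_LOH = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated patient.

    Defaults mirror the study design: three tumor regions plus one normal,
    ~100x exome coverage, purity 0.7, clonal founder VAFs in 0.2-0.5, and
    a per-base sequencing error rate of 1e-3.
    """

    n_regions: int = 3
    n_trunk: int = 90
    n_branch: int = 30
    n_private: int = 30
    clonal_vaf_range: tuple[float, float] = (0.2, 0.5)
    subclonal_vaf_range: tuple[float, float] = (0.02, 0.08)
    private_subclonal_fraction: float = 0.0
    private_region: int | None = None
    coverage_mean: float = 100.0
    purity_per_region: tuple[float, ...] | None = None
    error_rate: float = 1e-3
    n_germline_het: int = 400
    n_loh_segments: int = 4
    loh_total_copies: int = 1
    hypermutator: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ConfigError("n_regions must be >= 2")
        if min(self.n_trunk, self.n_branch, self.n_private) < 0:
            raise ConfigError("mutation counts must be >= 0")
        if self.n_branch > 0 and self.n_regions < 3:
            raise ConfigError(
                "branch mutations need a proper subset of >= 2 regions; "
                "impossible with fewer than 3 regions"
            )
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be > 0")
        for name in ("clonal_vaf_range", "subclonal_vaf_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 1.0):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.private_subclonal_fraction <= 1.0:
            raise ConfigError("private_subclonal_fraction must lie in [0, 1]")
        if self.private_region is not None and not (
            0 <= self.private_region < self.n_regions
        ):
            raise ConfigError("private_region must index an existing region")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must lie in [0, 0.5)")
        for p in self.purities:
            if not 0.0 < p <= 1.0:
                raise ConfigError("purity values must lie in (0, 1]")
        if self.n_loh_segments > self.n_germline_het:
            raise ConfigError("n_loh_segments cannot exceed n_germline_het")

    @property
    def purities(self) -> tuple[float, ...]:
        if self.purity_per_region is None:
            return (0.7,) * self.n_regions
        if len(self.purity_per_region) != self.n_regions:
            raise ConfigError("purity_per_region length must equal n_regions")
        return tuple(self.purity_per_region)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1}" for i in range(self.n_regions))

    @classmethod
    def hypermutator_preset(cls, **overrides) -> "SimConfig":
        """A hypermutating-tumor configuration: one region flooded with
        low-VAF private mutations (all drawn from 0.10-0.15), so that
        pooling regions dilutes them below detection thresholds."""
        params = dict(
            n_trunk=90,
            n_branch=30,
            n_private=500,
            subclonal_vaf_range=(0.10, 0.15),
            private_subclonal_fraction=1.0,
            private_region=0,
            hypermutator=True,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class ClonalTruth:
    """Simulator ground truth for one patient.

    ``table`` has one row per mutation: site key columns, ``topology``,
    ``origin`` ('+'-joined carrying regions), one ``vaf_<region>`` column
    per region with the true cancer-cell VAF (0 where absent), and one
    ``clonality_<region>`` column with the clonal/sub-clonal label of the
    *expected observed* (purity-diluted) VAF, missing where absent.
    """

    table: pd.DataFrame
    regions: tuple[str, ...]

    def presence(self) -> pd.DataFrame:
        """True presence matrix (sites x regions)."""
        return pd.DataFrame(
            {r: self.table[f"vaf_{r}"] > 0 for r in self.regions},
            index=self.table.index,
        )

    def sweep_truth(self, region_as_origin: bool = True) -> pd.DataFrame:
        """Truth table for the detection sweeps (site key, origin,
        clonality). The clonality of a mutation is taken in its carrying
        region(s): the maximum expected observed VAF decides."""
        t = self.table
        clon = []
        for _, row in t.iterrows():
            labels = [
                row[f"clonality_{r}"]
                for r in self.regions
                if isinstance(row[f"clonality_{r}"], str)
            ]
            clon.append(CLONAL if CLONAL in labels else SUBCLONAL)
        out = t[KEY].copy()
        out["origin"] = t["origin"] if region_as_origin else "all"
        out["clonality"] = clon
        return out


def _random_sites(rng: np.random.Generator, n: int, chrom: str, start_pos: int):
    pos = start_pos + 1000 * np.arange(n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    return pos, ref, alt


def simulate_truth(cfg: SimConfig) -> ClonalTruth:
    """Draw the clonal architecture: topology, carriers and true VAFs."""
    rng = _rng(cfg.seed, _STREAM_TRUTH)
    regions = cfg.regions
    n_total = cfg.n_trunk + cfg.n_branch + cfg.n_private
    pos, ref, alt = _random_sites(rng, n_total, "chr1", 10_000)

    topology = (
        [TRUNK] * cfg.n_trunk + [BRANCH] * cfg.n_branch + [PRIVATE] * cfg.n_private
    )
    vafs = np.zeros((n_total, cfg.n_regions))
    origins: list[str] = []
    lo_c, hi_c = cfg.clonal_vaf_range
    lo_s, hi_s = cfg.subclonal_vaf_range

    proper_subsets = [
        subset
        for size in range(2, cfg.n_regions)
        for subset in itertools.combinations(range(cfg.n_regions), size)
    ]
    for i in range(n_total):
        if topology[i] == TRUNK:
            carriers = tuple(range(cfg.n_regions))
            v = rng.uniform(lo_c, hi_c)
        elif topology[i] == BRANCH:
            carriers = proper_subsets[rng.integers(0, len(proper_subsets))]
            v = rng.uniform(lo_c, hi_c)
        else:
            if cfg.private_region is not None:
                carriers = (cfg.private_region,)
            else:
                carriers = (int(rng.integers(0, cfg.n_regions)),)
            if rng.random() < cfg.private_subclonal_fraction:
                v = rng.uniform(lo_s, hi_s)
            else:
                v = rng.uniform(lo_c, hi_c)
        vafs[i, list(carriers)] = v
        origins.append("+".join(regions[j] for j in carriers))

    table = pd.DataFrame(
        {
            "mut_id": [f"m{i:05d}" for i in range(n_total)],
            "chrom": "chr1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "topology": topology,
            "origin": origins,
        }
    )
    purities = cfg.purities
    for j, r in enumerate(regions):
        table[f"vaf_{r}"] = vafs[:, j]
        expected_obs = purities[j] * vafs[:, j]
        label = np.where(expected_obs >= 0.10, CLONAL, SUBCLONAL)
        table[f"clonality_{r}"] = np.where(vafs[:, j] > 0, label, None)
    return ClonalTruth(table=table, regions=regions)


def simulate_counts(
    truth: ClonalTruth, cfg: SimConfig
) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """Observed read counts for every region and the matched normal.

    Depth is Poisson around ``coverage_mean``; mutant reads are Binomial
    with success probability ``purity * true_vaf + error_rate`` (clamped),
    so absent sites and the normal still collect error-rate mutant reads.
    Returns a long count table (``chrom pos ref alt sample depth
    alt_count``) and the sample metadata.
    """
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    t = truth.table
    n = len(t)
    purities = cfg.purities
    frames = []
    meta = [SampleMeta("N", "normal", 1.0)]
    for j, r in enumerate(truth.regions):
        depth = rng.poisson(cfg.coverage_mean, size=n)
        p = np.minimum(1.0, purities[j] * t[f"vaf_{r}"].to_numpy() + cfg.error_rate)
        alt = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t["chrom"],
                    "pos": t["pos"],
                    "ref": t["ref"],
                    "alt": t["alt"],
                    "sample": r,
                    "depth": depth,
                    "alt_count": alt,
                }
            )
        )
        meta.append(SampleMeta(r, "region", purities[j]))
    depth_n = rng.poisson(cfg.coverage_mean, size=n)
    alt_n = rng.binomial(depth_n, cfg.error_rate)
    frames.append(
        pd.DataFrame(
            {
                "chrom": t["chrom"],
                "pos": t["pos"],
                "ref": t["ref"],
                "alt": t["alt"],
                "sample": "N",
                "depth": depth_n,
                "alt_count": alt_n,
            }
        )
    )
    counts = pd.concat(frames, ignore_index=True)
    return counts, meta


def simulate_flanks(
    truth: ClonalTruth, cfg: SimConfig, offsets: Sequence[int] = (-50, 50)
) -> pd.DataFrame:
    """Non-variant flanking positions for background-rate estimation.

    Each variant contributes one flank position per offset per sample,
    with ``nonref_count ~ Binomial(depth, error_rate)``.
    """
    rng = _rng(cfg.seed, _STREAM_FLANKS)
    t = truth.table
    samples = list(truth.regions) + ["N"]
    frames = []
    for sample in samples:
        for off in offsets:
            depth = rng.poisson(cfg.coverage_mean, size=len(t))
            nonref = rng.binomial(depth, cfg.error_rate)
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chrom": t["chrom"],
                        "pos": t["pos"] + off,
                        "depth": depth,
                        "nonref_count": nonref,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def region_pool(counts: pd.DataFrame, sample: str) -> ReadPool:
    """Extract one sample's rows of a long count table as a ReadPool."""
    sel = counts[counts["sample"] == sample]
    if len(sel) == 0:
        raise KeyError(f"sample {sample!r} not present in count table")
    pool = sel[KEY + ["depth", "alt_count"]].reset_index(drop=True)
    return ReadPool(pool, label=sample)


def make_global_pool(
    regions: Sequence[ReadPool],
    weights: Sequence[float] | None = None,
    seed=None,
) -> ReadPool:
    """Equal-mass (or weighted) in-silico mix of region pools.

    Models the global specimen, where DNA from several distinct regions is
    combined before sequencing: each region's reads are thinned to its
    weight and summed per site, so a region-private mutation's VAF is
    diluted by the region's weight while shared clones keep theirs.
    """
    if len(regions) == 0:
        raise ConfigError("need at least one region pool")
    if weights is None:
        weights = [1.0 / len(regions)] * len(regions)
    if len(weights) != len(regions):
        raise ConfigError("one weight per region is required")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError(f"weights must sum to 1, got {sum(weights)!r}")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(0 if seed is None else seed)
    if len(regions) == 1:
        return ReadPool(regions[0].sites.copy(), label="global")

    acc: pd.DataFrame | None = None
    for pool, w in zip(regions, weights):
        if w == 0:
            continue
        part = thin_counts(pool, w, seed=rng).sites
        if acc is None:
            acc = part
        else:
            acc = (
                acc.merge(part, on=KEY, how="outer", suffixes=("", "_y"))
                .fillna(0)
            )
            acc["depth"] = (acc["depth"] + acc["depth_y"]).astype(np.int64)
            acc["alt_count"] = (acc["alt_count"] + acc["alt_count_y"]).astype(
                np.int64
            )
            acc = acc[KEY + ["depth", "alt_count"]]
    assert acc is not None
    acc = acc.sort_values(KEY, kind="mergesort").reset_index(drop=True)
    return ReadPool(acc, label="global")


def simulate_paired_pools(
    n_shared: int = 100,
    n_private_each: int = 300,
    n_subclonal_shared: int = 0,
    clonal_vaf_range: tuple[float, float] = (0.2, 0.5),
    subclonal_vaf: float = 0.03,
    coverage_mean: float = 70.0,
    error_rate: float = 1e-3,
    seed: int = 0,
) -> tuple[ReadPool, ReadPool, pd.DataFrame]:
    """Two single-sample read pools emulating a primary tumor and a
    metastatic site, plus the truth table the detection sweeps consume.

    Site classes: ``n_shared`` clonal mutations carried by both pools at
    the same VAF (the shared trunk of the two sites); ``n_private_each``
    clonal mutations private to each pool; optionally
    ``n_subclonal_shared`` sites at a fixed sub-clonal VAF in both pools.
    Depth is Poisson around ``coverage_mean`` per pool; mutant reads are
    Binomial at the site's VAF plus the error floor (absent sites collect
    error-rate reads only, but are not listed in the truth of the other
    origin). Truth origins are ``shared``, ``primary`` and ``metastasis``.
    """
    rng = _rng(seed, 4)
    n_total = n_shared + 2 * n_private_each + n_subclonal_shared
    pos, ref, alt = _random_sites(rng, n_total, "chr1", 10_000)
    lo, hi = clonal_vaf_range
    vaf_a = np.zeros(n_total)
    vaf_b = np.zeros(n_total)
    origin = np.empty(n_total, dtype=object)
    s0, s1 = 0, n_shared
    shared_vaf = rng.uniform(lo, hi, size=n_shared)
    vaf_a[s0:s1] = shared_vaf
    vaf_b[s0:s1] = shared_vaf
    origin[s0:s1] = "shared"
    p0, p1 = s1, s1 + n_private_each
    vaf_a[p0:p1] = rng.uniform(lo, hi, size=n_private_each)
    origin[p0:p1] = "primary"
    q0, q1 = p1, p1 + n_private_each
    vaf_b[q0:q1] = rng.uniform(lo, hi, size=n_private_each)
    origin[q0:q1] = "metastasis"
    vaf_a[q1:] = subclonal_vaf
    vaf_b[q1:] = subclonal_vaf
    origin[q1:] = "shared"

    def _pool(vaf, label):
        depth = rng.poisson(coverage_mean, size=n_total)
        altc = rng.binomial(depth, np.minimum(1.0, vaf + error_rate))
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "depth": depth,
                "alt_count": altc,
            }
        )
        return ReadPool(df, label=label)

    truth = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "origin": origin,
            "clonality": np.where(
                np.maximum(vaf_a, vaf_b) >= 0.10, CLONAL, SUBCLONAL
            ),
        }
    )
    return _pool(vaf_a, "primary"), _pool(vaf_b, "metastasis"), truth


def simulate_loh_data(
    cfg: SimConfig,
    null: bool = False,
) -> tuple[list[GermlineHetSite], list[Segment], np.ndarray]:
    """Germline heterozygous sites, copy segments, and LOH truth flags.

    With ``null=True`` the tumor allele fractions stay balanced even
    inside the loss-annotated segments (a copy-number annotation without a
    real event), which calibrates the caller's false-positive rate on
    informative sites; the returned truth flags are then all False.

    Half of the sites sit inside B-allele-loss segments (split across
    ``n_loh_segments`` intervals); there the tumor's expected alt fraction
    is ``(1 - purity) / ((1 - purity) * 2 + purity * C)`` with ``C`` the
    tumor copy number of the segment — the residual B-allele signal of the
    contaminating normal cells. A neutral segment (minor copy 1) covers
    part of the remaining balanced sites to exercise the informativeness
    gate. Purity of the first region is used.
    """
    rng = _rng(cfg.seed, _STREAM_LOH)
    n = cfg.n_germline_het
    purity = cfg.purities[0]
    C = cfg.loh_total_copies
    spacing = 1000
    pos = spacing * (1 + np.arange(n))  # 1-based

    n_loh = n // 2
    flags = np.zeros(n, dtype=bool)
    flags[:n_loh] = True

    segments: list[Segment] = []
    if cfg.n_loh_segments > 0 and n_loh > 0:
        bounds = np.linspace(0, n_loh, cfg.n_loh_segments + 1).astype(int)
        for k in range(cfg.n_loh_segments):
            i, j = bounds[k], bounds[k + 1]
            if j <= i:
                continue
            segments.append(
                Segment(
                    chrom="chr2",
                    start=int(pos[i] - 1 - spacing // 4),
                    end=int(pos[j - 1] + spacing // 4),
                    total_copies=C,
                    minor_copies=0,
                )
            )
    # a neutral segment over the first quarter of the balanced sites
    n_neutral = (n - n_loh) // 2
    if n_neutral > 0:
        segments.append(
            Segment(
                chrom="chr2",
                start=int(pos[n_loh] - 1 - spacing // 4),
                end=int(pos[n_loh + n_neutral - 1] + spacing // 4),
                total_copies=2,
                minor_copies=1,
            )
        )

    denom = (1 - purity) * 2 + purity * C
    shifted_baf = (1 - purity) / denom if denom > 0 else 0.0
    sites: list[GermlineHetSite] = []
    for i in range(n):
        nd = int(rng.poisson(cfg.coverage_mean))
        td = int(rng.poisson(cfg.coverage_mean))
        na = int(rng.binomial(nd, 0.5)) if nd else 0
        baf = shifted_baf if (flags[i] and not null) else 0.5
        ta = int(rng.binomial(td, baf)) if td else 0
        sites.append(
            GermlineHetSite(
                chrom="chr2",
                pos=int(pos[i]),
                normal_ref=nd - na,
                normal_alt=na,
                tumor_ref=td - ta,
                tumor_alt=ta,
            )
        )
    if null:
        flags = np.zeros(n, dtype=bool)
    return sites, segments, flags
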