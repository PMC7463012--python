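"""Shared domain types and deterministic classifiers.

This module holds the atoms the whole pipeline operates on — per-site,
per-sample read counts (:class:`SiteCounts`), the named thresholds that
drive every deterministic decision (:class:`FilterConfig`) — together with
the purity-corrected variant allele frequency, the hard site filters, and
the trunk/branch/private and clonal/sub-clonal classifiers.

Conventions
-----------
* Positions are 1-based inclusive everywhere in this module (VCF-style).
* A *tumor* sample is any sample whose role is not ``"normal"``.
* VAF (variant allele frequency) is ``alt_count / depth``; the purity
  correction divides by the tumor-cell fraction of the specimen and clamps
  at 1, the standard cellularity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRUNK",
    "BRANCH",
    "PRIVATE",
    "CLONAL",
    "SUBCLONAL",
    "ROLE_NORMAL",
    "VALID_ROLES",
    "ConfigError",
    "UndefinedInputError",
    "NotPresentError",
    "FilterConfig",
    "SampleMeta",
    "SiteCounts",
    "purity_corrected_vaf",
    "passes_site_filters",
    "apply_site_filters",
    "classify_topology",
    "classify_clonality",
    "trunk_proportion",
    "presence_proportions",
]

TRUNK = "trunk"
BRANCH = "branch"
PRIVATE = "private"
TOPOLOGY_LABELS = (TRUNK, BRANCH, PRIVATE)

CLONAL = "clonal"
SUBCLONAL = "subclonal"

ROLE_NORMAL = "normal"
VALID_ROLES = frozenset({"normal", "biopsy", "local", "global", "region"})


class ConfigError(ValueError):
    """A threshold, purity or other configuration value is invalid or missing."""


class UndefinedInputError(ValueError):
    """An operation was asked for a quantity that is undefined for its input."""


class NotPresentError(ValueError):
    """A site absent from every tumor sample has no topology label."""


@dataclass(frozen=True)
class FilterConfig:
    """Named thresholds driving every deterministic decision in the pipeline.

    Parameters
    ----------
    min_depth
        Minimum per-sample sequencing depth (reads) for a site to be
        evaluable in that sample. Default 50.
    min_alt
        Minimum mutant-read count required in at least one tumor sample for
        the site to be kept at all. Default 5.
    min_corrected_vaf
        Minimum purity-corrected VAF for a per-sample pass. Default 0.05.
    clonal_vaf_threshold
        VAF at or above which a mutation is called clonal. Default 0.10.
    genotype_alpha
        Significance level of the Poisson background test in the joint
        genotyper. Default 0.01.
    loh_alpha
        Significance level of the Fisher allele-shift test for LOH calls.
        Default 0.05.
    """

    min_depth: int = 50
    min_alt: int = 5
    min_corrected_vaf: float = 0.05
    clonal_vaf_threshold: float = 0.10
    genotype_alpha: float = 0.01
    loh_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_alt < 0:
            raise ConfigError("integer thresholds must be >= 0")
        if int(self.min_depth) != self.min_depth or int(self.min_alt) != self.min_alt:
            raise ConfigError("min_depth and min_alt must be integers")
        for name in ("min_corrected_vaf", "clonal_vaf_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("genotype_alpha", "loh_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced specimen: identifier, sampling role and tumor purity.

    ``purity`` is the tumor-cell fraction of the specimen (cellularity),
    in (0, 1]. For the matched normal it is irrelevant and fixed at 1.
    """

    sample_id: str
    role: str
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ConfigError(
                f"unknown sample role {self.role!r}; expected one of {sorted(VALID_ROLES)}"
            )
        if not 0.0 < self.purity <= 1.0:
            raise ConfigError(f"purity must lie in (0, 1], got {self.purity!r}")

    @property
    def is_tumor(self) -> bool:
        return self.role != ROLE_NORMAL


def validate_sample_set(meta: Sequence[SampleMeta]) -> None:
    """Check the one-normal-per-patient and unique-id invariants."""
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sample_id in sample metadata")
    n_normal = sum(not m.is_tumor for m in meta)
    if n_normal != 1:
        raise ConfigError(f"expected exactly one normal sample, found {n_normal}")


@dataclass
class SiteCounts:
    """One candidate variant site with per-sample depth and mutant reads.

    ``per_sample`` is an ordered list of ``(sample_id, depth, alt_count)``
    tuples; ``alt_count <= depth`` for every sample and sample ids are
    unique within a site.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    per_sample: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        seen: set[str] = set()
        for sample_id, depth, alt in self.per_sample:
            if sample_id in seen:
                raise ValueError(f"duplicate sample {sample_id!r} at {self.key}")
            seen.add(sample_id)
            if depth < 0 or alt < 0:
                raise ValueError(f"negative counts at {self.key} / {sample_id}")
            if alt > depth:
                raise ValueError(
                    f"alt_count {alt} exceeds depth {depth} at {self.key} / {sample_id}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def counts_for(self, sample_id: str) -> tuple[int, int]:
        for sid, depth, alt in self.per_sample:
            if sid == sample_id:
                return depth, alt
        raise KeyError(f"sample {sample_id!r} not recorded at {self.key}")


# ---------------------------------------------------------------------------
# operations


def purity_corrected_vaf(alt_count: int, depth: int, purity: float) -> float:
    """VAF corrected for tumor purity: ``min(1, (alt/depth) / purity)``.

    Dividing the observed allele fraction by the tumor-cell fraction
    rescales it to the tumor-cell population; values above 1 (possible for
    mutations in amplified regions or noisy purity estimates) are clamped.
    """
    if not 0.0 < purity <= 1.0:
        raise ConfigError(f"purity must lie in (0, 1], got {purity!r}")
    if depth <= 0:
        raise UndefinedInputError("VAF is undefined at zero depth")
    if alt_count < 0 or alt_count > depth:
        raise UndefinedInputError(
            f"alt_count must lie in [0, depth], got alt={alt_count}, depth={depth}"
        )
    return min(1.0, (alt_count / depth) / purity)


def passes_site_filters(
    site: SiteCounts,
    meta: Sequence[SampleMeta],
    cfg: FilterConfig,
) -> tuple[dict[str, bool], bool]:
    """Apply the hard filters to one site.

    Per-sample pass: depth >= ``min_depth`` and purity-corrected VAF >=
    ``min_corrected_vaf``. Site-level pass additionally requires at least
    ``min_alt`` mutant reads in at least one tumor sample.

    Returns ``(per_sample_pass, site_pass)`` where ``per_sample_pass`` maps
    tumor sample ids to booleans (the matched normal is not scored).
    """
    by_id = {m.sample_id: m for m in meta}
    per_sample: dict[str, bool] = {}
    any_min_alt = False
    for sample_id, depth, alt in site.per_sample:
        m = by_id.get(sample_id)
        if m is None:
            raise ConfigError(f"no metadata for sample {sample_id!r}")
        if not m.is_tumor:
            continue
        if depth > 0:
            vaf = purity_corrected_vaf(alt, depth, m.purity)
            ok = depth >= cfg.min_depth and vaf >= cfg.min_corrected_vaf
        else:
            ok = False
        per_sample[sample_id] = ok
        if alt >= cfg.min_alt:
            any_min_alt = True
    if not per_sample:
        raise ConfigError(f"site {site.key} has no tumor samples")
    site_pass = any(per_sample.values()) and any_min_alt
    return per_sample, site_pass


def apply_site_filters(
    counts: pd.DataFrame,
    meta: Sequence[SampleMeta],
    cfg: FilterConfig,
) -> pd.DataFrame:
    """Vectorised hard filters over a long-format count table.

    ``counts`` has columns ``chrom pos ref alt sample depth alt_count``
    (one row per site x sample). Returns a copy restricted to tumor samples
    with added columns ``corrected_vaf``, ``sample_pass`` and ``site_pass``
    (the site-level verdict broadcast to every row of the site).
    """
    purity = {m.sample_id: m.purity for m in meta if m.is_tumor}
    missing = set(counts["sample"].unique()) - set(
        m.sample_id for m in meta
    )
    if missing:
        raise ConfigError(f"no metadata for samples {sorted(missing)}")
    tumor_ids = set(purity)
    df = counts[counts["sample"].isin(tumor_ids)].copy()
    pur = df["sample"].map(purity).to_numpy(dtype=float)
    depth = df["depth"].to_numpy(dtype=float)
    alt = df["alt_count"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvaf = np.where(depth > 0, np.minimum(1.0, (alt / depth) / pur), 0.0)
    df["corrected_vaf"] = cvaf
    df["sample_pass"] = (
        (depth >= cfg.min_depth) & (cvaf >= cfg.min_corrected_vaf) & (depth > 0)
    )
    key = ["chrom", "pos", "ref", "alt"]
    has_alt = pd.Series(alt >= cfg.min_alt, index=df.index)
    site_alt = has_alt.groupby([df[k] for k in key]).transform("any")
    site_any_pass = df.groupby(key)["sample_pass"].transform("any")
    df["site_pass"] = site_alt & site_any_pass
    return df


def classify_topology(presence: Sequence[bool]) -> str:
    """Trunk / branch / private from a presence vector over tumor samples.

    trunk: present in every sample; private: present in exactly one;
    branch: any other non-empty pattern.
    """
    presence = [bool(p) for p in presence]
    if len(presence) < 2:
        raise ValueError("topology needs at least 2 tumor samples")
    n = sum(presence)
    if n == 0:
        raise NotPresentError("site absent from every sample has no topology")
    if n == len(presence):
        return TRUNK
    if n == 1:
        return PRIVATE
    return BRANCH


def classify_clonality(vaf: float, cfg: FilterConfig) -> str:
    """Clonal / sub-clonal by VAF against ``clonal_vaf_threshold``.

    The threshold itself (default 10%) is assigned to the clonal class so
    the two labels are exhaustive.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must lie in [0, 1], got {vaf!r}")
    return CLONAL if vaf >= cfg.clonal_vaf_threshold else SUBCLONAL


def _as_presence_frame(presence) -> pd.DataFrame:
    if isinstance(presence, pd.DataFrame):
        return presence.astype(bool)
    arr = np.asarray(presence, dtype=bool)
    if arr.ndim != 2:
        raise ValueError("presence matrix must be 2-D (sites x samples)")
    return pd.DataFrame(arr)


def topology_labels(presence) -> pd.Series:
    """Topology label per row of a sites-by-samples presence matrix.

    Rows absent everywhere get a missing label (they carry no topology).
    """
    df = _as_presence_frame(presence)
    n = df.sum(axis=1)
    out = pd.Series(pd.NA, index=df.index, dtype="object")
    out[n == df.shape[1]] = TRUNK
    out[(n > 1) & (n < df.shape[1])] = BRANCH
    out[n == 1] = PRIVATE
    return out


def trunk_proportion(presence) -> pd.Series:
    """Per-sample fraction of present sites that are trunk mutations.

    For each sample: (trunk sites present in that sample) / (all sites
    present in that sample). A sample with zero present sites gets NaN.
    """
    df = _as_presence_frame(presence)
    if df.size == 0:
        raise ValueError("presence matrix is empty")
    labels = topology_labels(df)
    present_per_sample = df.sum(axis=0).astype(float)
    trunk_rows = labels == TRUNK
    trunk_per_sample = df[trunk_rows].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = trunk_per_sample / present_per_sample
    frac[present_per_sample == 0] = np.nan
    return frac


def presence_proportions(presence, denominator: str = "union") -> pd.Series:
    """Fraction of a patient's mutations identified in each sample.

    ``denominator='union'`` (default) divides by the union of sites present
    in any sample; ``denominator='per_sample'`` returns the raw counts
    normalised by the largest per-sample count instead. Both readings of
    the combined-call denominator are exposed because the convention is not
    uniquely determined by the study design.
    """
    df = _as_presence_frame(presence)
    present_any = df.any(axis=1)
    counts = df.sum(axis=0).astype(float)
    if denominator == "union":
        denom = float(present_any.sum())
    elif denominator == "per_sample":
        denom = float(counts.max())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("no site is present in any sample")
    return counts / denom
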