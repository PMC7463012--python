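"""In-silico read pooling, coverage titration and detection sweeps.

The experiment these operations implement: take per-site read counts from
two tumor specimens (e.g. a primary tumor and a metastatic site), mix them
computationally at varying compositions, rescale coverage between 0.1- and
100-fold, and at every grid point measure what fraction of the known
clonal and sub-clonal mutations the standard detection rule still finds.

Resampling works at the count level: within a site, keeping a fraction
``f`` of ``depth`` reads of which ``alt`` are mutant is a draw
``depth' ~ Binomial(depth, f)`` followed by
``alt' | depth' ~ Hypergeometric(depth, alt, depth')`` — exactly the
distribution of sampling reads without replacement. This is
distributionally equivalent to subsampling a BAM for site-level detection
statistics, without touching reads. Coverage above the available reads is
reached by bootstrap (with-replacement) resampling, which preserves the
per-site expected VAF but not the read-level error correlations of a true
re-sequencing run; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CLONAL, SUBCLONAL, FilterConfig
from .genotyper import DEFAULT_MIN_ERROR_RATE, poisson_tail_array

__all__ = [
    "ReadPool",
    "DetectionSummary",
    "thin_counts",
    "iterative_subsample",
    "mix_pools",
    "upscale_pool",
    "scale_pool",
    "detect_mutations",
    "composition_sweep",
    "coverage_sweep",
    "make_summary_frame",
]

KEY = ["chrom", "pos", "ref", "alt"]

DEFAULT_DECILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
DEFAULT_FOLDS = (0.1, 0.25, 0.5, 1, 2, 5, 10, 30, 100)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ReadPool:
    """Per-site read counts of one (possibly mixed) specimen.

    ``sites`` is a DataFrame with columns ``chrom pos ref alt depth
    alt_count``, one row per site; ``label`` names the origin (primary,
    metastasis, a mix, ...).
    """

    sites: pd.DataFrame
    label: str = "pool"

    def __post_init__(self) -> None:
        required = set(KEY + ["depth", "alt_count"])
        if not required.issubset(self.sites.columns):
            raise ValueError(f"pool table must have columns {sorted(required)}")
        if (self.sites["alt_count"] > self.sites["depth"]).any():
            raise ValueError("alt_count exceeds depth in pool")
        if (self.sites[["depth", "alt_count"]] < 0).any().any():
            raise ValueError("negative counts in pool")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def total_reads(self) -> int:
        return int(self.sites["depth"].sum())

    def with_counts(self, depth: np.ndarray, alt: np.ndarray, label: str) -> "ReadPool":
        df = self.sites[KEY].copy()
        df["depth"] = np.asarray(depth, dtype=np.int64)
        df["alt_count"] = np.asarray(alt, dtype=np.int64)
        return ReadPool(df, label=label)


def _hypergeom_alt(
    rng: np.random.Generator,
    depth: np.ndarray,
    alt: np.ndarray,
    new_depth: np.ndarray,
) -> np.ndarray:
    """alt' ~ Hypergeometric(depth, alt, new_depth), elementwise, 0-safe."""
    depth = np.asarray(depth, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    new_depth = np.asarray(new_depth, dtype=np.int64)
    out = np.zeros_like(new_depth)
    mask = (new_depth > 0) & (alt > 0)
    if mask.any():
        out[mask] = rng.hypergeometric(
            alt[mask], depth[mask] - alt[mask], new_depth[mask]
        )
    return out


def thin_counts(pool: ReadPool, fraction: float, seed=None) -> ReadPool:
    """Keep each read independently with probability ``fraction``.

    Per site: ``depth' ~ Binomial(depth, fraction)`` and
    ``alt' | depth' ~ Hypergeometric(depth, alt, depth')`` — reads sampled
    without replacement within the site. ``fraction = 1`` returns the pool
    unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction!r}")
    if fraction == 1.0:
        return ReadPool(pool.sites.copy(), label=pool.label)
    rng = _rng(seed)
    depth = pool.sites["depth"].to_numpy(dtype=np.int64)
    alt = pool.sites["alt_count"].to_numpy(dtype=np.int64)
    new_depth = rng.binomial(depth, fraction)
    new_alt = _hypergeom_alt(rng, depth, alt, new_depth)
    return pool.with_counts(new_depth, new_alt, label=pool.label)


def iterative_subsample(
    pool: ReadPool,
    target_fraction: float,
    step: float = 0.1,
    seed=None,
) -> ReadPool:
    """Reach ``target_fraction`` by repeatedly extracting ``step``-sized
    tranches of reads without replacement.

    ``floor(target/step)`` tranches of ``step * total_reads`` reads each,
    plus one remainder tranche, are drawn successively from the not-yet-
    sampled reads of the whole pool (site allocation is multivariate
    hypergeometric, mutant reads within a site hypergeometric). The union
    of the tranches is returned; it is distributed as a single
    without-replacement draw of the target fraction.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step!r}")
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError(
            f"target_fraction must lie in (0, 1], got {target_fraction!r}"
        )
    rng = _rng(seed)
    depth0 = pool.sites["depth"].to_numpy(dtype=np.int64)
    alt0 = pool.sites["alt_count"].to_numpy(dtype=np.int64)
    total = int(depth0.sum())
    goal = int(round(target_fraction * total))

    n_full = int(math.floor(target_fraction / step + 1e-12))
    tranche = int(round(step * total))
    sizes = [tranche] * n_full
    drawn_total = sum(sizes)
    if drawn_total > goal:  # floating-point edge: target an exact multiple
        sizes = sizes[:-1]
        drawn_total = sum(sizes)
    if goal - drawn_total > 0:
        sizes.append(goal - drawn_total)

    rem_depth = depth0.copy()
    rem_alt = alt0.copy()
    acc_depth = np.zeros_like(depth0)
    acc_alt = np.zeros_like(alt0)
    for size in sizes:
        size = min(size, int(rem_depth.sum()))
        if size <= 0:
            continue
        take = rng.multivariate_hypergeometric(rem_depth, size, method="marginals")
        take_alt = _hypergeom_alt(rng, rem_depth, rem_alt, take)
        acc_depth += take
        acc_alt += take_alt
        rem_depth -= take
        rem_alt -= take_alt
    return pool.with_counts(acc_depth, acc_alt, label=pool.label)


def _aligned(a: ReadPool, b: ReadPool) -> pd.DataFrame:
    """Outer-join two pools on the site key; absent sites get depth 0."""
    merged = a.sites.merge(
        b.sites, on=KEY, how="outer", suffixes=("_a", "_b")
    ).fillna(0)
    for col in ("depth_a", "alt_count_a", "depth_b", "alt_count_b"):
        merged[col] = merged[col].astype(np.int64)
    return merged.sort_values(KEY, kind="mergesort").reset_index(drop=True)


def mix_pools(
    a: ReadPool,
    b: ReadPool,
    proportion_b: float,
    total_scale: float = 1.0,
    seed=None,
) -> ReadPool:
    """Combine two pools' reads at a given composition.

    The output is ``thin(a, (1 - proportion_b) * total_scale) +
    thin(b, proportion_b * total_scale)`` summed per site over the union
    of the two site universes. ``proportion_b = 0`` with ``total_scale = 1``
    returns ``a`` exactly.
    """
    if not 0.0 <= proportion_b <= 1.0:
        raise ValueError(f"proportion_b must lie in [0, 1], got {proportion_b!r}")
    if total_scale <= 0:
        raise ValueError(f"total_scale must be > 0, got {total_scale!r}")
    frac_a = (1.0 - proportion_b) * total_scale
    frac_b = proportion_b * total_scale
    if frac_a > 1.0 or frac_b > 1.0:
        raise ValueError(
            "requested composition needs more reads than a pool holds "
            f"(fractions {frac_a:.3g} / {frac_b:.3g})"
        )
    rng = _rng(seed)
    merged = _aligned(a, b)

    def _part(depth, alt, frac):
        if frac == 0.0:
            return np.zeros_like(depth), np.zeros_like(alt)
        if frac == 1.0:
            return depth.copy(), alt.copy()
        nd = rng.binomial(depth, frac)
        na = _hypergeom_alt(rng, depth, alt, nd)
        return nd, na

    da, aa = _part(
        merged["depth_a"].to_numpy(), merged["alt_count_a"].to_numpy(), frac_a
    )
    db, ab = _part(
        merged["depth_b"].to_numpy(), merged["alt_count_b"].to_numpy(), frac_b
    )
    out = merged[KEY].copy()
    out["depth"] = da + db
    out["alt_count"] = aa + ab
    return ReadPool(out, label=f"mix({a.label}:{1 - proportion_b:.2f},{b.label}:{proportion_b:.2f})")


def upscale_pool(pool: ReadPool, fold: float, seed=None) -> ReadPool:
    """Bootstrap a pool to ``fold``-times its coverage (``fold > 1``).

    Per site, ``depth' ~ Poisson(fold * depth)`` reads are drawn with
    replacement from the site's original reads, so
    ``alt' | depth' ~ Binomial(depth', alt/depth)``: the expected per-site
    VAF is preserved and a zero-alt site stays alt-free.
    """
    if fold <= 1:
        raise ValueError(
            f"fold must be > 1 (use thin_counts for fold <= 1), got {fold!r}"
        )
    rng = _rng(seed)
    depth = pool.sites["depth"].to_numpy(dtype=np.int64)
    alt = pool.sites["alt_count"].to_numpy(dtype=np.int64)
    new_depth = rng.poisson(fold * depth)
    vaf = np.divide(alt, depth, out=np.zeros(len(depth)), where=depth > 0)
    new_alt = rng.binomial(new_depth, vaf)
    return pool.with_counts(new_depth, new_alt, label=pool.label)


def scale_pool(pool: ReadPool, fold: float, seed=None) -> ReadPool:
    """Thin (fold < 1), pass through (fold == 1) or bootstrap (fold > 1)."""
    if fold <= 0:
        raise ValueError(f"fold must be > 0, got {fold!r}")
    if fold < 1:
        return thin_counts(pool, fold, seed=seed)
    if fold == 1:
        return ReadPool(pool.sites.copy(), label=pool.label)
    return upscale_pool(pool, fold, seed=seed)


# ---------------------------------------------------------------------------
# detection


def detect_mutations(
    pool: ReadPool,
    cfg: FilterConfig,
    error_rate: float,
    min_error_rate: float = DEFAULT_MIN_ERROR_RATE,
    use_genotyper: bool = True,
) -> np.ndarray:
    """Boolean detection verdict per site of a pool.

    A site is detected when its depth clears ``min_depth`` and its mutant
    reads either clear the hard ``min_alt`` threshold or are accepted by
    the Poisson background test at ``genotype_alpha`` (the genotyper-rescue
    path). The corrected-VAF filter is not applied: a pooled mixture has no
    single purity.
    """
    depth = pool.sites["depth"].to_numpy(dtype=float)
    alt = pool.sites["alt_count"].to_numpy(dtype=float)
    detected = alt >= cfg.min_alt
    if use_genotyper:
        lam = max(error_rate, min_error_rate) * depth
        p = poisson_tail_array(alt, lam)
        detected = detected | ((p <= cfg.genotype_alpha) & (alt >= 1))
    return detected & (depth >= cfg.min_depth)


@dataclass
class DetectionSummary:
    """Detection-fraction grid from a composition or coverage sweep.

    ``table`` is long-format with columns ``axis_value replicate clonality
    origin detected_fraction n_sites``; ``origin`` includes the pseudo-
    origin ``"combined"`` aggregating all origins of a clonality class.
    """

    axis: str
    table: pd.DataFrame
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        bad = ~self.table["detected_fraction"].between(0, 1)
        if bad.any():
            raise ValueError("detected fractions must lie in [0, 1]")

    def mean_detection(self, clonality: str, origin: str = "combined") -> pd.Series:
        """Mean detected fraction over replicates, indexed by axis value."""
        t = self.table
        sel = t[(t["clonality"] == clonality) & (t["origin"] == origin)]
        return sel.groupby("axis_value")["detected_fraction"].mean()


def make_summary_frame(summary: "DetectionSummary") -> pd.DataFrame:
    """Long-format sweep output with the axis named in its own column."""
    out = summary.table.copy()
    out.insert(0, "axis", summary.axis)
    return out


def _detection_rows(
    pool: ReadPool,
    truth: pd.DataFrame,
    detected: np.ndarray,
    axis_value: float,
    replicate: int,
) -> list[dict]:
    hit = pool.sites[KEY].copy()
    hit["detected"] = detected
    joined = truth.merge(hit, on=KEY, how="left")
    joined["detected"] = (
        joined["detected"].astype("boolean").fillna(False).astype(bool)
    )
    rows = []
    for clonality, cgrp in joined.groupby("clonality"):
        groups = [("combined", cgrp)] + list(cgrp.groupby("origin"))
        for origin, grp in groups:
            rows.append(
                {
                    "axis_value": axis_value,
                    "replicate": replicate,
                    "clonality": clonality,
                    "origin": origin,
                    "detected_fraction": float(grp["detected"].mean()),
                    "n_sites": int(len(grp)),
                }
            )
    return rows


def _check_truth(truth: pd.DataFrame) -> pd.DataFrame:
    required = set(KEY + ["origin", "clonality"])
    if not required.issubset(truth.columns):
        raise ValueError(f"truth table must have columns {sorted(required)}")
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    bad = set(truth["clonality"]) - {CLONAL, SUBCLONAL}
    if bad:
        raise ValueError(f"unknown clonality labels {sorted(bad)}")
    return truth.reset_index(drop=True)


def composition_sweep(
    a: ReadPool,
    b: ReadPool,
    truth: pd.DataFrame,
    cfg: FilterConfig | None = None,
    deciles: Sequence[float] = DEFAULT_DECILES,
    replicates: int = 10,
    seed: int = 0,
    error_rate: float = 1e-3,
    total_scale: float = 1.0,
    use_genotyper: bool = True,
) -> DetectionSummary:
    """Mix two pools at each composition and measure detection per class.

    For every composition in ``deciles`` and every replicate, pool ``a``
    and ``b`` at that proportion (replicate ``r`` reuses seed
    ``seed + r``), apply the detection rule, and record the detected
    fraction of each (clonality, origin) truth class.
    """
    cfg = cfg or FilterConfig()
    truth = _check_truth(truth)
    rows: list[dict] = []
    for prop_b in deciles:
        for rep in range(replicates):
            rng = np.random.default_rng(seed + rep)
            mixed = mix_pools(a, b, prop_b, total_scale=total_scale, seed=rng)
            detected = detect_mutations(
                mixed, cfg, error_rate, use_genotyper=use_genotyper
            )
            rows.extend(_detection_rows(mixed, truth, detected, float(prop_b), rep))
    return DetectionSummary(
        axis="composition",
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
    )


def coverage_sweep(
    pooled: ReadPool,
    truth: pd.DataFrame,
    cfg: FilterConfig | None = None,
    folds: Sequence[float] = DEFAULT_FOLDS,
    replicates: int = 10,
    seed: int = 0,
    error_rate: float = 1e-3,
    use_genotyper: bool = True,
) -> DetectionSummary:
    """Titrate a pool's coverage and measure detection per class.

    ``fold = 1`` is the pooled input's own coverage; smaller folds thin the
    reads without replacement, larger folds bootstrap them.

    Note that with the Poisson-rescue path enabled the effective
    mutant-read threshold is depth-dependent (it steps up wherever the
    background mean crosses the alpha boundary), so detection can dip
    slightly between neighbouring folds even though it rises over any
    larger span; the hard-filter rule alone is monotone in expectation.
    """
    cfg = cfg or FilterConfig()
    truth = _check_truth(truth)
    if any(f <= 0 for f in folds):
        raise ValueError("coverage folds must be positive")
    rows: list[dict] = []
    for fold in folds:
        for rep in range(replicates):
            rng = np.random.default_rng(seed + rep)
            scaled = scale_pool(pooled, fold, seed=rng)
            detected = detect_mutations(
                scaled, cfg, error_rate, use_genotyper=use_genotyper
            )
            rows.extend(_detection_rows(scaled, truth, detected, float(fold), rep))
    return DetectionSummary(
        axis="coverage_fold",
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
    )
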