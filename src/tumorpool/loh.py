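"""Loss-of-heterozygosity detection at germline heterozygous sites.

A germline heterozygous site is *informative* for LOH when it falls inside
a copy-number segment with B-allele loss (minor copy number zero): there
the tumor-cell population carries only one parental allele, so the alt
(B-allele) fraction in the tumor shifts away from the ~0.5 seen in the
matched normal, attenuated by normal-cell contamination. The shift is
tested per site with a two-sided Fisher exact test on the 2x2 table of
(ref, alt) reads in normal vs tumor.

Coordinates: segments use 0-based half-open intervals (BED convention);
site positions are 1-based (VCF convention). A 1-based position ``p`` lies
in segment ``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core import ConfigError, FilterConfig, UndefinedInputError

__all__ = [
    "Segment",
    "GermlineHetSite",
    "LOHCall",
    "select_informative_sites",
    "fisher_shift_test",
    "call_loh",
    "LOHCaller",
    "ALT_LOSS",
    "REF_LOSS",
]

ALT_LOSS = "alt-loss"
REF_LOSS = "ref-loss"


@dataclass(frozen=True)
class Segment:
    """A genomic interval with total/minor copy state (0-based half-open)."""

    chrom: str
    start: int
    end: int
    total_copies: int
    minor_copies: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.total_copies < 0 or self.minor_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.minor_copies > self.total_copies:
            raise ValueError("minor_copies cannot exceed total_copies")

    @property
    def b_allele_loss(self) -> bool:
        return self.minor_copies == 0 and self.total_copies >= 1

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class GermlineHetSite:
    """A germline heterozygous position with normal and tumor allele counts."""

    chrom: str
    pos: int
    normal_ref: int
    normal_alt: int
    tumor_ref: int
    tumor_alt: int

    def __post_init__(self) -> None:
        for name in ("normal_ref", "normal_alt", "tumor_ref", "tumor_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")


@dataclass(frozen=True)
class LOHCall:
    site: GermlineHetSite
    p_value: float
    loh: bool
    direction: str | None


def _check_non_overlapping(segments: Sequence[Segment]) -> None:
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def select_informative_sites(
    sites: Iterable[GermlineHetSite],
    segments: Sequence[Segment],
) -> list[GermlineHetSite]:
    """Sites whose position falls inside a B-allele-loss segment."""
    _check_non_overlapping(segments)
    loss = [s for s in segments if s.b_allele_loss]
    out = []
    for site in sites:
        if any(seg.chrom == site.chrom and seg.contains(site.pos) for seg in loss):
            out.append(site)
    return out


def fisher_shift_test(
    normal_ref: int,
    normal_alt: int,
    tumor_ref: int,
    tumor_alt: int,
) -> float:
    """Two-sided Fisher exact p-value for an allele-fraction shift.

    Tests the 2x2 table ``[[normal_ref, normal_alt], [tumor_ref,
    tumor_alt]]`` under the minimum-likelihood two-sided convention (the
    p-value sums the probabilities of all tables, at fixed margins, no more
    likely than the observed one).
    """
    table = np.array(
        [[normal_ref, normal_alt], [tumor_ref, tumor_alt]], dtype=np.int64
    )
    if np.any(table < 0):
        raise ValueError("counts must be >= 0")
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise UndefinedInputError(
            "Fisher shift test undefined when a sample has zero reads"
        )
    p = stats.fisher_exact(table, alternative="two-sided").pvalue
    return float(min(1.0, p))


class LOHCaller(BaseEstimator):
    """LOH caller over germline heterozygous sites.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level on the Fisher shift p-value.
    bh_correct : bool, default False
        Apply Benjamini-Hochberg correction across the informative sites
        before thresholding. Off by default; single-site raw p-values are
        the convention the per-gene LOH reports follow.
    het_low, het_high : float, defaults 0.3 and 0.7
        Normal B-allele-fraction window used to keep only credibly
        heterozygous sites in real-data mode (where no germline genotype
        accompanies the counts). Set to 0 and 1 to disable.
    min_depth : int, default 0
        Minimum normal depth for the heterozygosity gate.

    Attributes
    ----------
    segments_ : list[Segment]
        Segments retained by :meth:`fit`.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        bh_correct: bool = False,
        het_low: float = 0.3,
        het_high: float = 0.7,
        min_depth: int = 0,
    ):
        self.alpha = alpha
        self.bh_correct = bh_correct
        self.het_low = het_low
        self.het_high = het_high
        self.min_depth = min_depth

    def fit(self, segments: Sequence[Segment]):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        _check_non_overlapping(segments)
        self.segments_ = list(segments)
        return self

    def _is_het(self, site: GermlineHetSite) -> bool:
        depth = site.normal_ref + site.normal_alt
        if depth == 0 or depth < self.min_depth:
            return False
        baf = site.normal_alt / depth
        return self.het_low <= baf <= self.het_high

    def predict(self, sites: Iterable[GermlineHetSite]) -> list[LOHCall]:
        """Fisher-test every informative heterozygous site.

        Returns one :class:`LOHCall` per informative site; non-informative
        sites (outside B-allele-loss segments, or failing the
        heterozygosity gate) are excluded from the output entirely.
        """
        if not hasattr(self, "segments_"):
            raise ConfigError("LOH caller is not fitted; call fit() first")
        informative = [
            s
            for s in select_informative_sites(sites, self.segments_)
            if self._is_het(s)
        ]
        pvals = np.array(
            [
                fisher_shift_test(
                    s.normal_ref, s.normal_alt, s.tumor_ref, s.tumor_alt
                )
                for s in informative
            ]
        )
        if self.bh_correct and len(pvals):
            adj = stats.false_discovery_control(pvals, method="bh")
        else:
            adj = pvals
        calls = []
        for site, p_raw, p_adj in zip(informative, pvals, adj):
            n_baf = site.normal_alt / (site.normal_ref + site.normal_alt)
            t_depth = site.tumor_ref + site.tumor_alt
            t_baf = site.tumor_alt / t_depth if t_depth else n_baf
            shifted = t_baf != n_baf
            loh = bool(p_adj <= self.alpha and shifted)
            direction = None
            if shifted:
                direction = ALT_LOSS if t_baf < n_baf else REF_LOSS
            calls.append(LOHCall(site, float(p_raw), loh, direction))
        return calls


def call_loh(
    sites: Iterable[GermlineHetSite],
    segments: Sequence[Segment],
    cfg: FilterConfig,
    bh_correct: bool = False,
) -> list[LOHCall]:
    """Select informative sites, Fisher-test each, and threshold at
    ``cfg.loh_alpha``. Functional wrapper over :class:`LOHCaller` with the
    heterozygosity gate disabled (synthetic truth guarantees het normals).
    """
    caller = LOHCaller(
        alpha=cfg.loh_alpha, bh_correct=bh_correct, het_low=0.0, het_high=1.0
    )
    return caller.fit(segments).predict(sites)


def loh_calls_to_frame(calls: Sequence[LOHCall]) -> pd.DataFrame:
    """Long-format table of LOH calls for TSV output."""
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in calls],
            "pos": [c.site.pos for c in calls],
            "normal_ref": [c.site.normal_ref for c in calls],
            "normal_alt": [c.site.normal_alt for c in calls],
            "tumor_ref": [c.site.tumor_ref for c in calls],
            "tumor_alt": [c.site.tumor_alt for c in calls],
            "p_value": [c.p_value for c in calls],
            "loh": [c.loh for c in calls],
            "direction": [c.direction if c.direction else "none" for c in calls],
        }
    )
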