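"""Joint genotyping against a Poisson sequencing-noise background.

Once a candidate somatic mutation has been called in any sample of a
patient, every other sample of that patient is re-tested at the same
position: the observed mutant-read count ``k`` at depth ``d`` is compared
with the background noise rate ``e`` (non-reference bases per sequenced
base, estimated from non-variant positions flanking the candidates) using
the upper tail of a Poisson distribution with mean ``lambda = e * d``. A
genotype is accepted when ``P(X >= k) <= alpha`` and at least one mutant
read was seen. This rescues genuine low-evidence genotypes that a somatic
caller run per sample would miss, and is deliberately permissive: the sites
are already candidates, so no genome-wide multiple-testing burden applies
(an optional Bonferroni correction is available).

The background can be estimated locally (flanking positions within a
window of each candidate), falling back to a pooled per-sample rate, and
finally to a configured default rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.base import BaseEstimator

from .core import ConfigError, FilterConfig, SiteCounts

__all__ = [
    "BackgroundModel",
    "GenotypeCall",
    "estimate_background_rate",
    "poisson_tail",
    "joint_genotype",
    "PoissonBackgroundGenotyper",
]

#: floor on the background rate so a pristine flank (rate 0) cannot make a
#: single stray read at any depth look significant
DEFAULT_MIN_ERROR_RATE = 1e-4
DEFAULT_FALLBACK_RATE = 1e-3
DEFAULT_WINDOW = 100


@dataclass(frozen=True)
class BackgroundModel:
    """Per-sample sequencing-noise rate and the evidence behind it."""

    sample_id: str
    error_rate: float
    n_observed_bases: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError(
                f"error_rate must lie in [0, 0.5), got {self.error_rate!r}"
            )
        if self.n_observed_bases < 0:
            raise ConfigError("n_observed_bases must be >= 0")


@dataclass(frozen=True)
class GenotypeCall:
    """Accept/reject verdict for one site x sample."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_id: str
    p_value: float
    accepted: bool


def poisson_tail(k: int, lam: float) -> float:
    """Upper tail ``P(X >= k)`` of a Poisson(`lam`) variable.

    Computed through the regularized lower incomplete gamma function,
    ``P(X >= k) = gammainc(k, lam)`` for integer ``k >= 1``, which is
    numerically stable for large means. ``P(X >= 0)`` is exactly 1.
    """
    if k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam!r}")
    if k == 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    return float(special.gammainc(k, lam))


def poisson_tail_array(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Vectorised :func:`poisson_tail` over aligned arrays."""
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(k < 0) or np.any(lam < 0):
        raise ValueError("k and lam must be non-negative")
    out = special.gammainc(np.maximum(k, 1.0), lam)
    out = np.where(lam == 0.0, 0.0, out)
    return np.where(k == 0, 1.0, out)


def estimate_background_rate(
    flank_counts: Iterable[tuple[int, int]],
    fallback_rate: float = DEFAULT_FALLBACK_RATE,
    sample_id: str = "",
) -> BackgroundModel:
    """Pooled noise rate from flanking non-variant positions.

    ``error_rate = sum(nonref) / sum(depth)`` over the supplied
    ``(depth, nonref_count)`` pairs; when no bases were observed the
    configured ``fallback_rate`` is used instead.
    """
    if not 0.0 <= fallback_rate < 0.5:
        raise ConfigError(
            f"fallback_rate must lie in [0, 0.5), got {fallback_rate!r}"
        )
    total_depth = 0
    total_nonref = 0
    for depth, nonref in flank_counts:
        if nonref > depth:
            raise ValueError("nonref_count exceeds depth in flank counts")
        total_depth += int(depth)
        total_nonref += int(nonref)
    if total_depth == 0:
        return BackgroundModel(sample_id, fallback_rate, 0)
    return BackgroundModel(sample_id, total_nonref / total_depth, total_depth)


class PoissonBackgroundGenotyper(BaseEstimator):
    """Joint genotyper testing mutant reads against Poisson background noise.

    Parameters
    ----------
    alpha : float, default 0.01
        Acceptance significance level on the Poisson upper-tail p-value.
    fallback_rate : float, default 1e-3
        Background rate used for a sample with no flank evidence at all.
    min_error_rate : float, default 1e-4
        Floor applied to any estimated rate before computing the Poisson
        mean, so a perfectly clean flank cannot make one read significant.
    window : int, default 100
        Half-width (bp) of the local window around each candidate within
        which flank positions inform a site-specific rate; outside evidence
        contributes only to the pooled per-sample rate.
    bonferroni : bool, default False
        Divide ``alpha`` by the number of tests performed in one
        :meth:`predict` call. Off by default: the genotyper re-tests known
        candidates rather than discovering new ones.

    Attributes
    ----------
    background_ : dict[str, BackgroundModel]
        Pooled per-sample background models, set by :meth:`fit`.
    flanks_ : pandas.DataFrame or None
        Flank table retained for local-window estimation.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        fallback_rate: float = DEFAULT_FALLBACK_RATE,
        min_error_rate: float = DEFAULT_MIN_ERROR_RATE,
        window: int = DEFAULT_WINDOW,
        bonferroni: bool = False,
    ):
        self.alpha = alpha
        self.fallback_rate = fallback_rate
        self.min_error_rate = min_error_rate
        self.window = window
        self.bonferroni = bonferroni

    # -- fitting ------------------------------------------------------

    def fit(self, flanks: pd.DataFrame | None = None, samples: Sequence[str] = ()):
        """Estimate per-sample background rates.

        ``flanks`` is a long table with columns
        ``sample chrom pos depth nonref_count`` (non-candidate positions);
        pass ``None`` to fall back to ``fallback_rate`` for every sample
        named in ``samples``.
        """
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not 0.0 <= self.fallback_rate < 0.5:
            raise ConfigError(
                f"fallback_rate must lie in [0, 0.5), got {self.fallback_rate!r}"
            )
        background: dict[str, BackgroundModel] = {}
        if flanks is not None and len(flanks) > 0:
            required = {"sample", "chrom", "pos", "depth", "nonref_count"}
            if not required.issubset(flanks.columns):
                raise ConfigError(
                    f"flank table must have columns {sorted(required)}"
                )
            for sid, grp in flanks.groupby("sample"):
                background[sid] = estimate_background_rate(
                    zip(grp["depth"], grp["nonref_count"]),
                    fallback_rate=self.fallback_rate,
                    sample_id=str(sid),
                )
            self.flanks_ = flanks.reset_index(drop=True)
        else:
            self.flanks_ = None
        for sid in samples:
            background.setdefault(
                sid, BackgroundModel(sid, self.fallback_rate, 0)
            )
        self.background_ = background
        return self

    # -- prediction ---------------------------------------------------

    def _rate_for(self, sample: str, chrom: str, pos: int) -> float:
        """Local-window rate if flank evidence exists nearby, else pooled."""
        if self.flanks_ is not None:
            f = self.flanks_
            near = f[
                (f["sample"] == sample)
                & (f["chrom"] == chrom)
                & ((f["pos"] - pos).abs() <= self.window)
            ]
            d = int(near["depth"].sum())
            if d > 0:
                return float(near["nonref_count"].sum()) / d
        model = self.background_.get(sample)
        if model is None:
            raise ConfigError(f"no background model for sample {sample!r}")
        return model.error_rate

    def predict(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Test every site x sample row of a long count table.

        Returns a table ``chrom pos ref alt sample p_value accepted``. The
        joint aspect is structural: the input table carries *every* sample
        of the patient at every candidate site, so a site called in one
        sample is automatically tested in all the others.
        """
        if not hasattr(self, "background_"):
            raise ConfigError("genotyper is not fitted; call fit() first")
        df = counts.reset_index(drop=True)
        rates = np.empty(len(df))
        # local-window estimation only kicks in when flank evidence exists
        if self.flanks_ is None:
            rate_by_sample = {
                sid: m.error_rate for sid, m in self.background_.items()
            }
            try:
                rates[:] = df["sample"].map(rate_by_sample).to_numpy(dtype=float)
            except (ValueError, TypeError):
                missing = set(df["sample"]) - set(rate_by_sample)
                raise ConfigError(f"no background model for samples {sorted(missing)}")
            if np.any(np.isnan(rates)):
                missing = sorted(set(df.loc[np.isnan(rates), "sample"]))
                raise ConfigError(f"no background model for samples {missing}")
        else:
            for i, row in enumerate(
                df[["sample", "chrom", "pos"]].itertuples(index=False)
            ):
                rates[i] = self._rate_for(row.sample, row.chrom, row.pos)
        lam = np.maximum(rates, self.min_error_rate) * df["depth"].to_numpy(
            dtype=float
        )
        alt = df["alt_count"].to_numpy(dtype=float)
        p = poisson_tail_array(alt, lam)
        alpha = self.alpha / len(df) if self.bonferroni and len(df) else self.alpha
        out = df[["chrom", "pos", "ref", "alt", "sample"]].copy()
        out["p_value"] = p
        out["accepted"] = (p <= alpha) & (alt >= 1)
        return out


def joint_genotype(
    sites: Sequence[SiteCounts],
    background: Mapping[str, BackgroundModel],
    cfg: FilterConfig,
    min_error_rate: float = DEFAULT_MIN_ERROR_RATE,
) -> list[GenotypeCall]:
    """Functional wrapper over :class:`PoissonBackgroundGenotyper`.

    Tests every sample of every site against its sample's pooled
    background model at significance ``cfg.genotype_alpha``.
    """
    calls: list[GenotypeCall] = []
    for site in sites:
        for sample_id, depth, alt in site.per_sample:
            model = background.get(sample_id)
            if model is None:
                raise ConfigError(f"no background model for sample {sample_id!r}")
            lam = max(model.error_rate, min_error_rate) * depth
            p = poisson_tail(alt, lam)
            calls.append(
                GenotypeCall(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref_allele=site.ref_allele,
                    alt_allele=site.alt_allele,
                    sample_id=sample_id,
                    p_value=p,
                    accepted=p <= cfg.genotype_alpha and alt >= 1,
                )
            )
    return calls
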