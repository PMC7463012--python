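"""Count-level read resampling: thinning, mixing, bootstrap upscaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tumorpool.core import FilterConfig
from tumorpool.pooling import (
    DetectionSummary,
    ReadPool,
    composition_sweep,
    coverage_sweep,
    detect_mutations,
    iterative_subsample,
    mix_pools,
    scale_pool,
    thin_counts,
    upscale_pool,
)


def make_pool(depths, alts, label="p", start=1):
    n = len(depths)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(start, start + n),
            "ref": "A",
            "alt": "T",
            "depth": depths,
            "alt_count": alts,
        }
    )
    return ReadPool(df, label=label)


class TestThinCounts:
    def test_fraction_one_is_identity(self):
        pool = make_pool([100, 50], [40, 0])
        out = thin_counts(pool, 1.0, seed=0)
        pd.testing.assert_frame_equal(out.sites, pool.sites)

    def test_mean_alt_matches_expectation(self):
        # site (1000, 400) at fraction 0.5: E[alt'] = 200
        pool = make_pool([1000], [400])
        alts = np.array(
            [
                thin_counts(pool, 0.5, seed=s).sites["alt_count"].iloc[0]
                for s in range(1000)
            ],
            dtype=float,
        )
        se = alts.std(ddof=1) / np.sqrt(len(alts))
        assert abs(alts.mean() - 200.0) < 3 * se

    def test_zero_alt_stays_zero(self):
        pool = make_pool([10], [0])
        for s in range(20):
            assert thin_counts(pool, 0.3, seed=s).sites["alt_count"].iloc[0] == 0

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_domain(self, fraction):
        with pytest.raises(ValueError):
            thin_counts(make_pool([10], [1]), fraction)

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=60, derandomize=True)
    def test_conservation(self, seed, fraction):
        pool = make_pool([120, 80, 5, 0], [50, 0, 5, 0])
        out = thin_counts(pool, fraction, seed=seed)
        assert (out.sites["alt_count"] <= out.sites["depth"]).all()
        assert (out.sites["depth"] <= pool.sites["depth"]).all()
        assert (out.sites["alt_count"] <= pool.sites["alt_count"]).all()

    def test_reproducible_per_seed(self):
        pool = make_pool([100, 200], [30, 60])
        a = thin_counts(pool, 0.4, seed=42).sites
        b = thin_counts(pool, 0.4, seed=42).sites
        pd.testing.assert_frame_equal(a, b)


class TestIterativeSubsample:
    def test_target_one_returns_everything(self):
        pool = make_pool([100, 60], [10, 6])
        out = iterative_subsample(pool, 1.0, seed=0)
        assert out.total_reads == pool.total_reads
        assert out.sites["alt_count"].sum() == 16

    def test_tranche_bookkeeping(self):
        pool = make_pool([1000] * 10, [100] * 10)
        out = iterative_subsample(pool, 0.3, step=0.1, seed=1)
        assert out.total_reads == round(0.3 * pool.total_reads)

    def test_remainder_tranche(self):
        pool = make_pool([1000] * 4, [0] * 4)
        out = iterative_subsample(pool, 0.25, step=0.1, seed=2)
        assert out.total_reads == round(0.25 * pool.total_reads)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            iterative_subsample(make_pool([10], [1]), 0.5, step=0.0)

    def test_distributionally_matches_one_shot_thinning(self):
        # per-site alt counts from 10%-tranche accumulation vs a single
        # binomial/hypergeometric thin at the same fraction
        from scipy.stats import ks_2samp

        pool = make_pool([100] * 200, [40] * 200)
        it_alt, th_alt = [], []
        for s in range(500):
            it_alt.append(
                iterative_subsample(pool, 0.3, seed=s).sites["alt_count"].iloc[0]
            )
            th_alt.append(
                thin_counts(pool, 0.3, seed=10_000 + s).sites["alt_count"].iloc[0]
            )
        assert ks_2samp(it_alt, th_alt).pvalue > 0.01


class TestMixPools:
    def test_degenerate_mix_returns_a(self):
        a = make_pool([100, 50], [40, 5], "a")
        b = make_pool([80, 80], [0, 8], "b", start=1)
        out = mix_pools(a, b, 0.0, seed=0)
        merged = out.sites.set_index("pos")
        orig = a.sites.set_index("pos")
        assert (merged.loc[orig.index, "depth"] == orig["depth"]).all()
        assert (merged.loc[orig.index, "alt_count"] == orig["alt_count"]).all()

    def test_private_site_vaf_dilution(self):
        # b-private VAF 0.4 mixed 50:50 with equal depths -> expected 0.2
        a = make_pool([2000], [0], "a")
        b = make_pool([2000], [800], "b")
        vafs = []
        for s in range(300):
            out = mix_pools(a, b, 0.5, seed=s).sites
            vafs.append(out["alt_count"].iloc[0] / out["depth"].iloc[0])
        assert np.mean(vafs) == pytest.approx(0.2, abs=0.005)

    def test_expected_depth_is_mean_of_inputs(self):
        a = make_pool([1000] * 5, [0] * 5, "a")
        b = make_pool([500] * 5, [0] * 5, "b")
        depths = [
            mix_pools(a, b, 0.5, seed=s).sites["depth"].mean() for s in range(200)
        ]
        assert np.mean(depths) == pytest.approx(750, rel=0.01)

    def test_union_of_site_universes(self):
        a = make_pool([100], [10], "a", start=1)
        b = make_pool([100], [10], "b", start=5)
        out = mix_pools(a, b, 0.5, seed=0)
        assert len(out.sites) == 2

    def test_proportion_domain(self):
        a = make_pool([10], [0])
        with pytest.raises(ValueError):
            mix_pools(a, a, 1.2)


class TestUpscale:
    def test_expectations(self):
        pool = make_pool([100], [40])
        d, a = [], []
        for s in range(400):
            out = upscale_pool(pool, 2.0, seed=s).sites
            d.append(out["depth"].iloc[0])
            a.append(out["alt_count"].iloc[0])
        assert np.mean(d) == pytest.approx(200, rel=0.02)
        assert np.mean(a) == pytest.approx(80, rel=0.03)

    def test_zero_alt_site_stays_clean(self):
        pool = make_pool([100], [0])
        for s in range(20):
            assert upscale_pool(pool, 100.0, seed=s).sites["alt_count"].iloc[0] == 0

    def test_vaf_preserved_at_high_fold(self):
        pool = make_pool([100] * 50, [40] * 50)
        errs = []
        for s in range(200):
            out = upscale_pool(pool, 10.0, seed=s).sites
            vaf = out["alt_count"] / out["depth"]
            errs.append(np.abs(vaf - 0.4).mean())
        assert np.mean(errs) < 0.02

    def test_fold_guard(self):
        with pytest.raises(ValueError):
            upscale_pool(make_pool([10], [1]), 0.5)
        # scale_pool routes small folds to thinning instead
        out = scale_pool(make_pool([1000], [10]), 0.5, seed=0)
        assert out.sites["depth"].iloc[0] < 1000


def _sweep_truth(pool, clonality="clonal", origin="a"):
    t = pool.sites[["chrom", "pos", "ref", "alt"]].copy()
    t["origin"] = origin
    t["clonality"] = clonality
    return t


class TestSweeps:
    def test_high_vaf_trunk_always_detected(self):
        # VAF 0.45 at depth 150 in both pools: expected alt >> thresholds
        a = make_pool([150] * 30, [68] * 30, "a")
        b = make_pool([150] * 30, [68] * 30, "b")
        truth = _sweep_truth(a, origin="shared")
        s = composition_sweep(a, b, truth, FilterConfig(), replicates=3, seed=0)
        assert (s.table["detected_fraction"] == 1.0).all()

    def test_absent_class_never_detected(self):
        # b-private sites cannot appear in an a-only mix
        a = make_pool([100] * 10, [0] * 10, "a")
        b = make_pool([100] * 10, [40] * 10, "b")
        truth = _sweep_truth(b, origin="b")
        s = composition_sweep(
            a, b, truth, FilterConfig(), deciles=[0.0], replicates=3, seed=0
        )
        assert (s.table["detected_fraction"] == 0.0).all()

    def test_depth_gate_kills_low_fold(self):
        pool = make_pool([100] * 20, [40] * 20)
        truth = _sweep_truth(pool)
        s = coverage_sweep(
            pool, truth, FilterConfig(), folds=[0.1], replicates=3, seed=0
        )
        assert (s.table["detected_fraction"] == 0.0).all()

    def test_detection_monotone_in_coverage(self):
        # subclonal VAF 0.03 sites at ~100x: mean detection over replicates
        # must rise with coverage fold (1-SE tolerance on each step)
        rng = np.random.default_rng(3)
        depths = rng.poisson(100, size=300)
        alts = rng.binomial(depths, 0.03)
        pool = make_pool(depths, alts)
        truth = _sweep_truth(pool, clonality="subclonal")
        s = coverage_sweep(
            pool,
            truth,
            FilterConfig(),
            folds=[1, 2, 5, 10],
            replicates=10,
            seed=0,
            use_genotyper=False,
        )
        t = s.table[(s.table["origin"] == "combined")]
        by_fold = t.groupby("axis_value")["detected_fraction"]
        means = by_fold.mean()
        ses = by_fold.std(ddof=1) / np.sqrt(s.replicates)
        for (f1, m1), (f2, m2) in zip(means.items(), means.iloc[1:].items()):
            tol = max(ses.loc[f1], ses.loc[f2], 1e-12)
            assert m2 >= m1 - tol, (f1, m1, f2, m2)

    def test_empty_truth_rejected(self):
        pool = make_pool([100], [10])
        with pytest.raises(ValueError):
            coverage_sweep(pool, _sweep_truth(pool).iloc[:0], FilterConfig())

    def test_summary_invariants(self):
        with pytest.raises(ValueError):
            DetectionSummary(
                axis="composition",
                table=pd.DataFrame(
                    {
                        "axis_value": [0.1],
                        "replicate": [0],
                        "clonality": ["clonal"],
                        "origin": ["combined"],
                        "detected_fraction": [1.2],
                        "n_sites": [10],
                    }
                ),
                replicates=1,
                seed=0,
            )

    def test_detect_rule_requires_depth(self):
        cfg = FilterConfig()
        pool = make_pool([40, 100, 100], [20, 6, 2])
        det = detect_mutations(pool, cfg, error_rate=1e-3)
        # shallow site fails, hard-filter site passes, 2-read site passes
        # only through the Poisson rescue
        assert det.tolist() == [False, True, True]
        det_no_gt = detect_mutations(pool, cfg, error_rate=1e-3, use_genotyper=False)
        assert det_no_gt.tolist() == [False, True, False]
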