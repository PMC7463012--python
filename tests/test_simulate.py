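"""Synthetic-data generator: truth structure, noise model, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from tumorpool.core import BRANCH, TRUNK, ConfigError
from tumorpool.loh import call_loh
from tumorpool.core import FilterConfig
from tumorpool.simulate import (
    SimConfig,
    make_global_pool,
    region_pool,
    simulate_counts,
    simulate_flanks,
    simulate_loh_data,
    simulate_paired_pools,
    simulate_truth,
)


class TestSimConfig:
    def test_defaults_are_valid(self):
        cfg = SimConfig()
        assert cfg.regions == ("R1", "R2", "R3")
        assert cfg.purities == (0.7, 0.7, 0.7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_regions=1),
            dict(n_regions=2, n_branch=5),
            dict(coverage_mean=0),
            dict(clonal_vaf_range=(0.5, 0.2)),
            dict(error_rate=0.7),
            dict(purity_per_region=(0.5, 0.5, 1.5)),
            dict(n_germline_het=2, n_loh_segments=5),
            dict(private_region=7),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)

    def test_hypermutator_preset(self):
        cfg = SimConfig.hypermutator_preset(seed=3)
        assert cfg.hypermutator and cfg.n_private == 500
        assert cfg.private_region == 0 and cfg.seed == 3


class TestSimulateTruth:
    def test_all_trunk_configuration(self):
        cfg = SimConfig(n_trunk=80, n_branch=0, n_private=0, seed=1)
        truth = simulate_truth(cfg)
        assert (truth.table["topology"] == TRUNK).all()
        assert truth.presence().all(axis=None)

    def test_private_confined_to_one_region(self):
        cfg = SimConfig(n_trunk=0, n_branch=0, n_private=30, seed=2)
        truth = simulate_truth(cfg)
        assert (truth.presence().sum(axis=1) == 1).all()

    def test_branch_is_proper_subset(self):
        cfg = SimConfig(n_trunk=0, n_branch=40, n_private=0, n_regions=4, seed=3)
        truth = simulate_truth(cfg)
        n = truth.presence().sum(axis=1)
        assert ((n >= 2) & (n < 4)).all()
        assert (truth.table["topology"] == BRANCH).all()

    def test_trunk_present_everywhere(self):
        truth = simulate_truth(SimConfig(seed=4))
        trunk = truth.table["topology"] == TRUNK
        assert truth.presence()[trunk.to_numpy()].all(axis=None)

    def test_deterministic_given_seed(self):
        a = simulate_truth(SimConfig(seed=5)).table
        b = simulate_truth(SimConfig(seed=5)).table
        pd.testing.assert_frame_equal(a, b)
        c = simulate_truth(SimConfig(seed=6)).table
        assert not a.equals(c)


class TestSimulateCounts:
    def test_counts_satisfy_invariants(self):
        cfg = SimConfig(seed=7)
        counts, meta = simulate_counts(simulate_truth(cfg), cfg)
        assert (counts["alt_count"] <= counts["depth"]).all()
        assert (counts[["depth", "alt_count"]] >= 0).all(axis=None)
        assert set(counts["sample"]) == {"R1", "R2", "R3", "N"}
        assert len(meta) == 4

    def test_observed_vaf_concentrates_at_high_depth(self):
        cfg = SimConfig(
            n_trunk=300,
            n_branch=0,
            n_private=0,
            clonal_vaf_range=(0.5, 0.5),
            purity_per_region=(1.0, 1.0, 1.0),
            coverage_mean=10_000,
            error_rate=0.0,
            seed=8,
        )
        counts, _ = simulate_counts(simulate_truth(cfg), cfg)
        r1 = counts[counts["sample"] == "R1"]
        vaf = r1["alt_count"] / r1["depth"]
        assert (vaf.between(0.48, 0.52)).mean() >= 0.99

    def test_purity_dilutes_expected_vaf(self):
        cfg = SimConfig(
            n_trunk=2000,
            n_branch=0,
            n_private=0,
            clonal_vaf_range=(0.4, 0.4),
            purity_per_region=(0.5, 0.5, 0.5),
            error_rate=0.0,
            seed=9,
        )
        counts, _ = simulate_counts(simulate_truth(cfg), cfg)
        r1 = counts[counts["sample"] == "R1"]
        assert (r1["alt_count"] / r1["depth"]).mean() == pytest.approx(0.2, abs=0.005)

    def test_no_error_no_signal_means_zero_alt(self):
        cfg = SimConfig(
            n_trunk=0, n_branch=0, n_private=50, error_rate=0.0, seed=10
        )
        truth = simulate_truth(cfg)
        counts, _ = simulate_counts(truth, cfg)
        normal = counts[counts["sample"] == "N"]
        assert (normal["alt_count"] == 0).all()

    def test_byte_identical_tables_per_seed(self, tmp_path):
        cfg = SimConfig(seed=11)
        paths = []
        for run in range(2):
            truth = simulate_truth(cfg)
            counts, _ = simulate_counts(truth, cfg)
            p = tmp_path / f"counts{run}.tsv"
            counts.to_csv(p, sep="\t", index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestGlobalPool:
    def test_single_region_identity(self):
        cfg = SimConfig(seed=12)
        counts, _ = simulate_counts(simulate_truth(cfg), cfg)
        p = region_pool(counts, "R1")
        out = make_global_pool([p], weights=[1.0])
        pd.testing.assert_frame_equal(out.sites, p.sites)

    def test_trunk_vaf_invariant_and_private_diluted(self):
        cfg = SimConfig(
            n_trunk=400,
            n_branch=0,
            n_private=900,
            clonal_vaf_range=(0.4, 0.4),
            purity_per_region=(1.0, 1.0, 1.0),
            coverage_mean=300,
            error_rate=0.0,
            seed=13,
        )
        truth = simulate_truth(cfg)
        counts, _ = simulate_counts(truth, cfg)
        pools = [region_pool(counts, r) for r in truth.regions]
        g = make_global_pool(pools, seed=0)
        merged = g.sites.merge(truth.table, on=["chrom", "pos", "ref", "alt"])
        vaf = merged["alt_count"] / merged["depth"]
        trunk = merged["topology"] == TRUNK
        assert vaf[trunk].mean() == pytest.approx(0.4, abs=0.01)
        assert vaf[~trunk].mean() == pytest.approx(0.4 / 3, abs=0.01)

    def test_weights_must_sum_to_one(self):
        cfg = SimConfig(seed=14)
        counts, _ = simulate_counts(simulate_truth(cfg), cfg)
        p = region_pool(counts, "R1")
        with pytest.raises(ConfigError):
            make_global_pool([p, p], weights=[0.5, 0.6])


class TestLohSimulation:
    def test_pure_tumor_full_loss_has_no_b_allele(self):
        cfg = SimConfig(
            seed=15, purity_per_region=(1.0, 1.0, 1.0), n_germline_het=100
        )
        sites, segments, flags = simulate_loh_data(cfg)
        shifted = [s for s, f in zip(sites, flags) if f]
        assert all(s.tumor_alt == 0 for s in shifted)

    def test_null_mode_is_balanced(self):
        cfg = SimConfig(seed=16, n_germline_het=600)
        sites, segments, flags = simulate_loh_data(cfg, null=True)
        assert not flags.any()
        calls = call_loh(sites, segments, FilterConfig())
        assert len(calls) == 300  # informative half still tested
        fpr = np.mean([c.loh for c in calls])
        se = np.sqrt(0.05 * 0.95 / len(calls))
        assert fpr <= 0.05 + 3 * se

    def test_flanks_shape_and_rate(self):
        cfg = SimConfig(seed=17, error_rate=5e-3)
        truth = simulate_truth(cfg)
        flanks = simulate_flanks(truth, cfg)
        assert set(flanks["sample"]) == {"R1", "R2", "R3", "N"}
        rate = flanks["nonref_count"].sum() / flanks["depth"].sum()
        assert rate == pytest.approx(5e-3, rel=0.15)


class TestPairedPools:
    def test_truth_partition_and_shapes(self):
        a, b, truth = simulate_paired_pools(
            n_shared=50, n_private_each=20, n_subclonal_shared=10, seed=18
        )
        assert len(truth) == 100 and len(a.sites) == 100
        assert truth["origin"].value_counts()["shared"] == 60
        assert (truth["clonality"] == "subclonal").sum() == 10

    def test_private_sites_carry_no_signal_in_other_pool(self):
        a, b, truth = simulate_paired_pools(
            n_shared=0, n_private_each=200, error_rate=0.0, seed=19
        )
        met = truth["origin"] == "metastasis"
        assert (a.sites.loc[met.to_numpy(), "alt_count"] == 0).all()
        assert (b.sites.loc[met.to_numpy(), "alt_count"] > 0).mean() > 0.99
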