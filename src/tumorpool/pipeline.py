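"""End-to-end pipeline driver: simulate -> genotype -> classify -> LOH -> sweeps.

Every stage writes its table under the output directory; a run log records
the seed and the full configuration so a run can be reproduced exactly.
Stage randomness is derived from the single top-level seed through fixed
sub-stream indices (see :mod:`tumorpool.simulate`), so re-running with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .core import (
    FilterConfig,
    SampleMeta,
    apply_site_filters,
    topology_labels,
    trunk_proportion,
    presence_proportions,
)
from .genotyper import PoissonBackgroundGenotyper
from .loh import call_loh, loh_calls_to_frame
from .pooling import KEY, composition_sweep, coverage_sweep, make_summary_frame
from .simulate import (
    make_global_pool,
    region_pool,
    simulate_counts,
    simulate_flanks,
    simulate_loh_data,
    simulate_truth,
)

__all__ = ["run_pipeline", "classify_calls", "write_presence_heatmap_table"]


def classify_calls(
    counts: pd.DataFrame,
    meta: list[SampleMeta],
    cfg: FilterConfig,
    genotype_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Presence, VAF, topology and clonality per site x tumor sample.

    A mutation is *present* in a sample when it passes the per-sample hard
    filters or is rescued by the joint genotyper; sites passing nowhere are
    dropped. Returns a long table ``site sample present vaf topology
    clonality`` — the data behind a presence/VAF heatmap.
    """
    filt = apply_site_filters(counts, meta, cfg)
    if genotype_calls is not None:
        acc = genotype_calls[KEY + ["sample", "accepted"]]
        filt = filt.merge(acc, on=KEY + ["sample"], how="left")
        filt["accepted"] = (
            filt["accepted"].astype("boolean").fillna(False).astype(bool)
        )
    else:
        filt["accepted"] = False
    filt["present"] = filt["sample_pass"] | filt["accepted"]

    presence = filt.pivot_table(
        index=KEY, columns="sample", values="present", aggfunc="any"
    ).fillna(False)
    keep = presence.any(axis=1)
    presence = presence[keep]
    topo = topology_labels(presence)

    depth = filt["depth"].to_numpy(dtype=float)
    alt = filt["alt_count"].to_numpy(dtype=float)
    filt["vaf"] = np.divide(alt, depth, out=np.zeros(len(filt)), where=depth > 0)
    filt["vaf"] = filt["vaf"].where(filt["present"], 0.0)

    out = filt.merge(
        topo.rename("topology").reset_index(), on=KEY, how="inner"
    )
    out["clonality"] = np.where(
        out["vaf"] >= cfg.clonal_vaf_threshold, "clonal", "subclonal"
    )
    out.loc[~out["present"], "clonality"] = "absent"
    return out[
        KEY
        + [
            "sample",
            "depth",
            "alt_count",
            "vaf",
            "corrected_vaf",
            "present",
            "topology",
            "clonality",
        ]
    ].sort_values(KEY + ["sample"], kind="mergesort").reset_index(drop=True)


def write_presence_heatmap_table(classified: pd.DataFrame, path) -> None:
    """Write the long-format presence/VAF table behind the heatmap."""
    cols = KEY + ["sample", "present", "vaf", "topology", "clonality"]
    classified[cols].to_csv(path, sep="\t", index=False)


def _presence_matrix(classified: pd.DataFrame) -> pd.DataFrame:
    return (
        classified.pivot_table(
            index=KEY, columns="sample", values="present", aggfunc="any"
        )
        .fillna(False)
        .astype(bool)
    )


def run_pipeline(config: tio.PipelineConfig, out_dir) -> Path:
    """Run every configured stage and write all outputs under ``out_dir``.

    Stages: synthetic-data generation, joint genotyping, presence
    classification (heatmap table, trunk proportions), LOH calling, and the
    composition/coverage sweeps. Returns the output directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}", "config:"]
    log_lines.append(json.dumps(dataclasses.asdict(config), indent=2, default=str))

    # --- stage: simulate -------------------------------------------------
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    truth = simulate_truth(sim_cfg)
    counts, meta = simulate_counts(truth, sim_cfg)
    flanks = simulate_flanks(truth, sim_cfg)
    truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    tio.write_counts_tsv(counts, out / "counts.tsv")
    tio.write_sample_meta(meta, out / "samples.tsv")
    flanks.to_csv(out / "flanks.tsv", sep="\t", index=False)
    if config.emit_vcf:
        tio.write_vcf(counts, out / "counts.vcf")
    log_lines.append(f"simulate: {len(truth.table)} mutations, "
                     f"{len(meta)} samples")

    # --- stage: joint genotyping ----------------------------------------
    genotyper = PoissonBackgroundGenotyper(
        alpha=config.filters.genotype_alpha,
        fallback_rate=config.genotyper_fallback_rate,
        window=config.genotyper_window,
    )
    genotyper.fit(flanks, samples=[m.sample_id for m in meta])
    tumor_counts = counts[counts["sample"] != "N"].reset_index(drop=True)
    calls = genotyper.predict(tumor_counts)
    calls.to_csv(out / "genotype_calls.tsv", sep="\t", index=False)
    log_lines.append(f"genotype: {int(calls['accepted'].sum())} accepted "
                     f"of {len(calls)} tests")

    # --- stage: classification ------------------------------------------
    classified = classify_calls(counts, meta, config.filters, calls)
    write_presence_heatmap_table(classified, out / "heatmap.tsv")
    presence = _presence_matrix(classified)
    trunk = trunk_proportion(presence)
    ident = presence_proportions(presence, denominator="union")
    summary_df = pd.DataFrame(
        {"trunk_proportion": trunk, "identified_fraction": ident}
    )
    summary_df.index.name = "sample"
    summary_df.to_csv(out / "sample_summary.tsv", sep="\t")
    log_lines.append(
        "classify: trunk proportions "
        + ", ".join(f"{s}={v:.3f}" for s, v in trunk.items())
    )

    # --- stage: LOH ------------------------------------------------------
    het_sites, segments, _ = simulate_loh_data(sim_cfg)
    tio.write_segments(segments, out / "segments.tsv")
    loh_calls = call_loh(het_sites, segments, config.filters)
    loh_calls_to_frame(loh_calls).to_csv(out / "loh_calls.tsv", sep="\t", index=False)
    log_lines.append(
        f"loh: {sum(c.loh for c in loh_calls)} LOH of "
        f"{len(loh_calls)} informative sites"
    )

    # --- stage: sweeps ---------------------------------------------------
    sweeps = config.sweeps
    regions = truth.regions
    if sweeps.run_composition or sweeps.run_coverage:
        pools = [region_pool(counts, r) for r in regions]
        sweep_truth = truth.sweep_truth()
    if sweeps.run_composition:
        summ = composition_sweep(
            pools[0],
            pools[1],
            sweep_truth,
            cfg=config.filters,
            deciles=sweeps.deciles,
            replicates=sweeps.replicates,
            seed=config.seed,
            error_rate=sim_cfg.error_rate,
        )
        make_summary_frame(summ).to_csv(
            out / "composition_sweep.tsv", sep="\t", index=False
        )
        log_lines.append("sweep: composition written")
    if sweeps.run_coverage:
        global_pool = make_global_pool(
            pools, seed=np.random.default_rng(config.seed)
        )
        summ = coverage_sweep(
            global_pool,
            sweep_truth,
            cfg=config.filters,
            folds=sweeps.folds,
            replicates=sweeps.replicates,
            seed=config.seed,
            error_rate=sim_cfg.error_rate,
        )
        make_summary_frame(summ).to_csv(
            out / "coverage_sweep.tsv", sep="\t", index=False
        )
        log_lines.append("sweep: coverage written")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
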