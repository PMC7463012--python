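"""Readers and writers for the pipeline's exchange formats.

Formats
-------
* Count table TSV (native exchange format): ``chrom pos ref alt sample
  depth alt_count``, one row per site x sample, positions 1-based.
* Sample metadata TSV: ``sample role purity``.
* Segment TSV (BED-like, 0-based half-open): ``chrom start end
  total_copies minor_copies``.
* Truth TSV: ``chrom pos ref alt origin clonality`` (plus topology/VAF
  columns when written from a :class:`~tumorpool.simulate.ClonalTruth`).
* VCF 4.2 with per-sample ``DP``/``AD`` FORMAT fields (pysam for writing,
  cyvcf2 for reading); multi-allelic records are split per alternate.
* Pipeline configuration as YAML with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from .core import ConfigError, FilterConfig, SampleMeta, SiteCounts
from .loh import GermlineHetSite, Segment
from .simulate import SimConfig

__all__ = [
    "FormatError",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_meta",
    "write_sample_meta",
    "read_segments",
    "write_segments",
    "read_vcf_counts",
    "write_vcf",
    "sites_to_frame",
    "frame_to_sites",
    "counts_to_het_sites",
    "SweepSettings",
    "PipelineConfig",
    "load_pipeline_config",
]

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "depth", "alt_count"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "total_copies", "minor_copies"]


class FormatError(ValueError):
    """An input file does not carry the fields the pipeline needs."""


# ---------------------------------------------------------------------------
# TSV


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing count columns {sorted(missing)}")
    return df[COUNT_COLUMNS + [c for c in df.columns if c not in COUNT_COLUMNS]]


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "role": str})
    missing = {"sample", "role", "purity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    return [
        SampleMeta(row["sample"], row["role"], float(row["purity"]))
        for _, row in df.iterrows()
    ]


def write_sample_meta(meta: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample": [m.sample_id for m in meta],
            "role": [m.role for m in meta],
            "purity": [m.purity for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing segment columns {sorted(missing)}")
    return [
        Segment(
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            total_copies=int(row["total_copies"]),
            minor_copies=int(row["minor_copies"]),
        )
        for _, row in df.iterrows()
    ]


def write_segments(segments: Sequence[Segment], path) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "total_copies": [s.total_copies for s in segments],
            "minor_copies": [s.minor_copies for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SiteCounts <-> long frame


def frame_to_sites(df: pd.DataFrame) -> list[SiteCounts]:
    """Group a long count table into per-site :class:`SiteCounts` atoms."""
    sites = []
    for (chrom, pos, ref, alt), grp in df.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        sites.append(
            SiteCounts(
                chrom=str(chrom),
                pos=int(pos),
                ref_allele=str(ref),
                alt_allele=str(alt),
                per_sample=[
                    (str(r["sample"]), int(r["depth"]), int(r["alt_count"]))
                    for _, r in grp.iterrows()
                ],
            )
        )
    return sites


def sites_to_frame(sites: Sequence[SiteCounts]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref_allele,
            "alt": s.alt_allele,
            "sample": sid,
            "depth": depth,
            "alt_count": alt,
        }
        for s in sites
        for sid, depth, alt in s.per_sample
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def counts_to_het_sites(
    df: pd.DataFrame, normal: str, tumor: str
) -> list[GermlineHetSite]:
    """Pair one normal and one tumor sample of a count table into
    germline-heterozygous-site records (``ref_count = depth - alt_count``)."""
    piv = df[df["sample"].isin([normal, tumor])]
    sites = []
    for (chrom, pos, _, _), grp in piv.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        by = {r["sample"]: r for _, r in grp.iterrows()}
        if normal not in by or tumor not in by:
            raise FormatError(
                f"site {chrom}:{pos} lacks counts for {normal!r} or {tumor!r}"
            )
        n, t = by[normal], by[tumor]
        sites.append(
            GermlineHetSite(
                chrom=str(chrom),
                pos=int(pos),
                normal_ref=int(n["depth"]) - int(n["alt_count"]),
                normal_alt=int(n["alt_count"]),
                tumor_ref=int(t["depth"]) - int(t["alt_count"]),
                tumor_alt=int(t["alt_count"]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# VCF


def read_vcf_counts(path, sample_ids: Sequence[str] | None = None) -> list[SiteCounts]:
    """Per-sample depth/alt counts from a VCF with allele-depth fields.

    ``depth`` is the sum of the allelic depths (falling back to the
    per-sample DP field when AD is absent for a record), ``alt_count`` the
    AD entry of the named alternate. Multi-allelic records are split into
    one site per alternate. A record without usable per-sample depth
    information raises :class:`FormatError` naming the record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_ids is not None:
        missing = set(sample_ids) - set(samples)
        if missing:
            raise FormatError(f"{path}: samples {sorted(missing)} not in VCF")
        keep = [samples.index(s) for s in sample_ids]
        names = list(sample_ids)
    else:
        keep = list(range(len(samples)))
        names = samples
    sites: list[SiteCounts] = []
    for rec in vcf:
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} has no AD field"
            )
        for alt_i, alt_allele in enumerate(rec.ALT):
            per_sample = []
            for name, si in zip(names, keep):
                row = ad[si]
                if row is None or len(row) <= alt_i + 1 or row[0] < 0:
                    raise FormatError(
                        f"{path}: record {rec.CHROM}:{rec.POS} lacks AD for "
                        f"sample {name!r}"
                    )
                depths = [int(x) for x in row if x >= 0]
                depth = sum(depths)
                alt_count = int(row[alt_i + 1])
                per_sample.append((name, depth, alt_count))
            sites.append(
                SiteCounts(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt_allele,
                    per_sample=per_sample,
                )
            )
    return sites


def write_vcf(df: pd.DataFrame, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Emit a long count table as a VCF 4.2 with per-sample DP/AD fields.

    One record per site, samples as columns; AD carries
    ``(depth - alt_count, alt_count)``.
    """
    import pysam

    samples = sorted(df["sample"].unique())
    chroms = list(dict.fromkeys(df["chrom"]))
    header = pysam.VariantHeader()
    header.add_meta("source", "tumorpool")
    for chrom in chroms:
        length = (contig_lengths or {}).get(chrom, 2_000_000_000)
        header.contigs.add(chrom, length=length)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), grp in df.groupby(
            ["chrom", "pos", "ref", "alt"], sort=True
        ):
            rec = out.new_record(
                contig=str(chrom), start=int(pos) - 1, alleles=(str(ref), str(alt))
            )
            by = {r["sample"]: r for _, r in grp.iterrows()}
            for s in samples:
                if s in by:
                    depth = int(by[s]["depth"])
                    altc = int(by[s]["alt_count"])
                else:
                    depth, altc = 0, 0
                rec.samples[s]["DP"] = depth
                rec.samples[s]["AD"] = (depth - altc, altc)
            out.write(rec)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class SweepSettings:
    """Composition/coverage sweep switches for the pipeline driver."""

    run_composition: bool = True
    run_coverage: bool = True
    replicates: int = 10
    deciles: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(1, 10))
    folds: tuple[float, ...] = (0.1, 0.25, 0.5, 1, 2, 5, 10, 30, 100)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    sweeps: SweepSettings = field(default_factory=SweepSettings)
    genotyper_fallback_rate: float = 1e-3
    genotyper_window: int = 100
    emit_vcf: bool = False


def _build(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where} config")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_pipeline_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML configuration.

    Unknown keys at any level are rejected so typos cannot silently fall
    back to defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in pipeline config")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "filters" in data:
        kwargs["filters"] = _build(FilterConfig, data["filters"] or {}, "filters")
    if "sim" in data:
        sim_data = dict(data["sim"] or {})
        sim_data.setdefault("seed", kwargs.get("seed", 0))
        kwargs["sim"] = _build(SimConfig, sim_data, "sim")
    if "sweeps" in data:
        kwargs["sweeps"] = _build(SweepSettings, data["sweeps"] or {}, "sweeps")
    for key in ("genotyper_fallback_rate", "genotyper_window", "emit_vcf"):
        if key in data:
            kwargs[key] = data[key]
    cfg = PipelineConfig(**kwargs)
    if "sim" not in data:
        cfg = dataclasses.replace(cfg, sim=dataclasses.replace(cfg.sim, seed=cfg.seed))
    return cfg
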