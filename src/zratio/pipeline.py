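"""End-to-end orchestration: load, filter, stratify, score, report.

The pipeline reads a series-matrix file (plus optional metadata and
probe-annotation TSVs), applies the presence filter, computes per-sample
Z-scores over the filtered gene universe, and emits Z-ratio and dosage
reports per stratum — the whole brain, each region with both groups
present, and each age rank.

Report layout mirrors the field's result tables: a wide gene × stratum
matrix with values rounded to two decimals for display and an ``*`` mark
on cells whose full-precision Z-ratio exceeds 1.96, plus a long-format
table carrying full precision and p-values.  Flags are always computed on
full precision; rounding is display-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .dosage import DEFAULT_BINS, DosageBins, dosage_records
from .geo_io import (
    ExpressionMatrix,
    SampleMetadata,
    map_probes_to_genes,
    parse_series_matrix,
    read_annotation_tsv,
    read_metadata_tsv,
)
from .preprocess import (
    DEFAULT_AGE_RANKS,
    EmptyStratumError,
    Stratum,
    age_rank_strata,
    filter_present,
    region_strata,
    split_by_stratum,
    to_linear,
    whole_brain_stratum,
)
from .zratio_core import OVEREXPRESSION_CUTOFF, zratio, zscore_per_sample

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs with documented defaults.

    The ``paper`` profile (see :meth:`with_profile`) turns Z-score
    clipping on at ±3.0 and uses the full filtered gene universe for the
    Z-ratio denominator.
    """

    input: str | Path = ""
    metadata: str | Path | None = None
    annotation: str | Path | None = None
    outdir: str | Path = "."
    universe: str = "all_filtered"  # all_filtered | listed_genes
    genes: tuple[str, ...] = ()  # rows to report; Z-ratio universe when listed_genes
    collapse: str = "mean"
    presence_threshold: float = 100.0
    presence_min_fraction: float = 0.5
    apply_presence_filter: bool = True
    clip: bool = False
    clip_bound: float = 3.0
    sd_convention: str = "sample"  # sample (n-1) | population (n)
    dosage_bins: DosageBins = field(default_factory=lambda: DEFAULT_BINS)
    brain_pooling: str = "all_samples"  # all_samples | mean_of_regions
    include_age_ranks: bool = True
    seed: int = 0
    log_level: str = "WARNING"

    @property
    def ddof(self) -> int:
        if self.sd_convention not in ("sample", "population"):
            raise ValueError(f"sd_convention must be sample/population, got {self.sd_convention!r}")
        return 1 if self.sd_convention == "sample" else 0

    def with_profile(self, profile: str) -> "RunConfig":
        if profile == "default":
            return self
        if profile == "paper":
            return replace(self, clip=True, clip_bound=3.0, universe="all_filtered")
        raise ValueError(f"unknown profile {profile!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "genes" in raw:
            raw["genes"] = tuple(raw["genes"])
        if "dosage_bins" in raw:
            raw["dosage_bins"] = DosageBins(**raw["dosage_bins"])
        return cls(**raw)


def load_inputs(cfg: RunConfig) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Parse, annotate, and presence-filter the input matrix."""
    matrix, meta = parse_series_matrix(cfg.input)
    if cfg.metadata is not None:
        meta = read_metadata_tsv(cfg.metadata)
        matrix.check_join(meta)
    if cfg.annotation is not None:
        matrix = map_probes_to_genes(matrix, read_annotation_tsv(cfg.annotation), cfg.collapse)
    if cfg.apply_presence_filter:
        kept = filter_present(
            to_linear(matrix), cfg.presence_threshold, cfg.presence_min_fraction
        ).probe_ids
        matrix = ExpressionMatrix(matrix.values.loc[kept], scale_tag=matrix.scale_tag)
    return matrix, meta


def default_strata(
    metadata: Sequence[SampleMetadata], include_age_ranks: bool = True
) -> list[Stratum]:
    """Whole brain, each region present in the metadata, each age rank."""
    present = sorted({m.region for m in metadata if m.region != "unknown"})
    strata: list[Stratum] = [whole_brain_stratum()]
    strata += region_strata([r for r in present])
    if include_age_ranks:
        strata += age_rank_strata(DEFAULT_AGE_RANKS)
    return strata


def _per_stratum(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    strata: Sequence[Stratum],
    compute,
) -> list[pd.DataFrame]:
    frames = []
    for stratum in strata:
        try:
            ds, ctrl = split_by_stratum(matrix, metadata, stratum)
        except EmptyStratumError as exc:
            logger.warning("skipping stratum: %s", exc)
            continue
        frames.append(compute(ds, ctrl, stratum))
    return frames


def zratio_table(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    cfg: RunConfig,
    strata: Sequence[Stratum] | None = None,
) -> pd.DataFrame:
    """Long-format Z-ratio records over all computable strata.

    Z-scores are standardized per sample over the full filtered gene
    universe; with ``universe="listed_genes"`` the Z-ratio denominator
    (SD of differences) then runs over ``cfg.genes`` only.
    """
    strata = list(strata) if strata is not None else default_strata(metadata, cfg.include_age_ranks)

    def compute(ds: ExpressionMatrix, ctrl: ExpressionMatrix, stratum: Stratum) -> pd.DataFrame:
        zds = zscore_per_sample(ds, clip=cfg.clip, clip_bound=cfg.clip_bound, ddof=cfg.ddof)
        zctrl = zscore_per_sample(ctrl, clip=cfg.clip, clip_bound=cfg.clip_bound, ddof=cfg.ddof)
        if cfg.universe == "listed_genes":
            if not cfg.genes:
                raise ValueError("universe='listed_genes' requires a nonempty gene list")
            keep = [g for g in zds.z.index if g in set(cfg.genes)]
            zds.z, zctrl.z = zds.z.loc[keep], zctrl.z.loc[keep]
        return zratio(zds, zctrl, stratum.name, ddof=cfg.ddof, bh_column=True)

    frames = _per_stratum(matrix, metadata, strata, compute)
    if not frames:
        raise ValueError("no stratum had both DS and control samples")
    long = pd.concat(frames).reset_index()

    if cfg.brain_pooling == "mean_of_regions":
        regions = [s.name for s in strata if s.kind == "region"]
        per_region = long[long["stratum"].isin(regions)]
        pooled = per_region.groupby("gene_id", sort=False)["z_ratio"].mean()
        long.loc[long["stratum"] == "Brain", "z_ratio"] = (
            long.loc[long["stratum"] == "Brain", "gene_id"].map(pooled).to_numpy()
        )
        brain = long["stratum"] == "Brain"
        from .zratio_core import p_from_z

        long.loc[brain, "p_two_tailed"] = p_from_z(long.loc[brain, "z_ratio"].to_numpy())
        long.loc[brain, "overexpressed"] = long.loc[brain, "z_ratio"] > OVEREXPRESSION_CUTOFF
    return long


def dosage_table(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    cfg: RunConfig,
    strata: Sequence[Stratum] | None = None,
) -> pd.DataFrame:
    """Long-format dosage (M, R, category) records over all computable strata."""
    strata = list(strata) if strata is not None else default_strata(metadata, cfg.include_age_ranks)
    frames = _per_stratum(
        matrix,
        metadata,
        strata,
        lambda ds, ctrl, st: dosage_records(ds, ctrl, st.name, cfg.dosage_bins),
    )
    if not frames:
        raise ValueError("no stratum had both DS and control samples")
    return pd.concat(frames).reset_index()


def _select_report_genes(long: pd.DataFrame, cfg: RunConfig) -> list[str]:
    available = list(dict.fromkeys(long["gene_id"]))
    if not cfg.genes:
        return available
    selected = [g for g in cfg.genes if g in set(available)]
    if not selected:
        raise ValueError("none of the requested genes survived filtering")
    return selected


def _stratum_order(long: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(long["stratum"]))


def run_zratio_report(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the wide flagged Z-ratio report and the long p-value table.

    Returns (wide display frame, long full-precision frame); files
    ``zratio_wide.tsv`` and ``zratio_long.tsv`` go to ``cfg.outdir``.
    """
    matrix, meta = load_inputs(cfg)
    long = zratio_table(matrix, meta, cfg)
    genes = _select_report_genes(long, cfg)
    long = long[long["gene_id"].isin(genes)]

    full = long.pivot(index="gene_id", columns="stratum", values="z_ratio")
    full = full.reindex(index=genes, columns=_stratum_order(long))
    flagged = long.pivot(index="gene_id", columns="stratum", values="overexpressed")
    flagged = flagged.reindex(index=genes, columns=full.columns)
    wide = pd.DataFrame(
        {
            col: [
                ("" if pd.isna(v) else f"{v:.2f}" + ("*" if bool(f) else ""))
                for v, f in zip(full[col], flagged[col].fillna(False))
            ]
            for col in full.columns
        },
        index=full.index,
    )
    wide.index.name = "gene_id"

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wide.to_csv(outdir / "zratio_wide.tsv", sep="\t")
    long.to_csv(outdir / "zratio_long.tsv", sep="\t", index=False, float_format="%.6g")
    return wide, long


def run_dosage_report(cfg: RunConfig) -> pd.DataFrame:
    """Write the long dosage report and a wide R-ratio matrix."""
    matrix, meta = load_inputs(cfg)
    long = dosage_table(matrix, meta, cfg)
    genes = _select_report_genes(long, cfg)
    long = long[long["gene_id"].isin(genes)]
    wide_r = long.pivot(index="gene_id", columns="stratum", values="r_ratio")
    wide_r = wide_r.reindex(index=genes, columns=_stratum_order(long))

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long.to_csv(outdir / "dosage_long.tsv", sep="\t", index=False, float_format="%.6g")
    wide_r.round(2).to_csv(outdir / "dosage_wide_r.tsv", sep="\t", float_format="%.2f")
    return long
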