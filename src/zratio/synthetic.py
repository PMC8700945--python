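"""Synthetic expression data with planted trisomy-like fold changes.

The generator emulates the design of a stratified brain microarray
study: log2 intensities over up to 11 brain regions, a trisomic (DS) and
a euploid (control) group per region, and ages spanning prenatal weeks of
gestation to adult years.  The model per gene g and sample s is

    log2 x_gs = mu_g + delta_gs + e_gs

with mu_g ~ Normal(baseline_mean, gene_sd) drawn once per gene,
delta_gs = log2(fold_change) iff s is DS and one of the effect's strata
contains s (by region, age rank, or the whole brain), and
e_gs ~ Normal(0, noise_sd).  Gaussian log2 noise is used because
RMA-style processed microarray data are approximately Gaussian on the
log2 scale; the generator aims at structural fidelity to the analysis
model, not array physics.

A single seed governs gene means, sample ages/sexes and noise, so the
full output stream — including fixture files on disk — is reproducible
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geo_io import (
    REGIONS,
    ExpressionMatrix,
    SampleMetadata,
    write_metadata_tsv,
    write_series_matrix,
)
from .preprocess import DEFAULT_AGE_RANKS, AgeRank, assign_age_rank


@dataclass(frozen=True)
class PlantedEffect:
    """A known fold change planted in one gene, restricted to given strata.

    ``strata`` may name region codes, age-rank labels, or ``"Brain"`` for
    a brain-wide effect.
    """

    gene_id: str
    fold_change: float
    strata: tuple[str, ...] = ("Brain",)

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror a stratified brain study: all 11 regions with a
    handful of DS and control samples each (about 55 per group in total),
    ages spread uniformly over the six default prenatal-to-adult ranks,
    log2 baselines around 8.0 with between-gene spread 1.5 and residual
    array noise 0.2 log2 units.
    """

    n_genes: int = 17000
    n_samples_per_group_per_region: int = 5
    regions: tuple[str, ...] = REGIONS
    age_ranks: tuple[AgeRank, ...] = DEFAULT_AGE_RANKS
    age_rank_proportions: tuple[float, ...] | None = None  # uniform when None
    baseline_mean: float = 8.0
    gene_sd: float = 1.5
    noise_sd: float = 0.2
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.gene_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region code(s): {sorted(unknown)}")
        if self.age_rank_proportions is not None and len(self.age_rank_proportions) != len(
            self.age_ranks
        ):
            raise ValueError("age_rank_proportions must match age_ranks in length")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids must have length n_genes")

    def resolved_gene_ids(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        width = len(str(self.n_genes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genes))


def _sample_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    props = cfg.age_rank_proportions
    p = (
        np.asarray(props, dtype=float) / np.sum(props)
        if props is not None
        else np.full(len(cfg.age_ranks), 1.0 / len(cfg.age_ranks))
    )
    records = []
    for region in cfg.regions:
        for group, tag in (("DS", "DS"), ("control", "CT")):
            for i in range(cfg.n_samples_per_group_per_region):
                rank = cfg.age_ranks[int(rng.choice(len(cfg.age_ranks), p=p))]
                age = float(rng.uniform(rank.low, rank.high))
                sex = "F" if rng.random() < 0.5 else "M"
                records.append(
                    SampleMetadata(
                        sample_id=f"{tag}_{region}_{i + 1:02d}",
                        group=group,
                        region=region,
                        age_value=max(round(age, 2), 0.01),
                        age_unit=rank.unit,
                        sex=sex,
                    )
                )
    return records


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleMetadata], pd.DataFrame]:
    """Generate (log2 expression matrix, sample metadata, truth table).

    The truth table lists every planted (gene_id, stratum, fold_change)
    row, so downstream detection can be scored against ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = cfg.resolved_gene_ids()
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for eff in cfg.planted_effects:
        if eff.gene_id not in gene_index:
            raise ValueError(f"planted gene {eff.gene_id!r} not in the simulated gene set")

    mu = rng.normal(cfg.baseline_mean, cfg.gene_sd, cfg.n_genes)
    metadata = _sample_metadata(cfg, rng)
    n_samples = len(metadata)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    delta = np.zeros((cfg.n_genes, n_samples))
    for eff in cfg.planted_effects:
        gi = gene_index[eff.gene_id]
        shift = np.log2(eff.fold_change)
        for si, meta in enumerate(metadata):
            if meta.group != "DS":
                continue
            rank = assign_age_rank(meta, cfg.age_ranks)
            labels = {"Brain", meta.region} | ({rank.label} if rank else set())
            if labels & set(eff.strata):
                delta[gi, si] += shift

    values = pd.DataFrame(
        mu[:, None] + delta + noise,
        index=list(gene_ids),
        columns=[m.sample_id for m in metadata],
    )
    truth = pd.DataFrame(
        [
            {"gene_id": e.gene_id, "stratum": s, "fold_change": e.fold_change}
            for e in cfg.planted_effects
            for s in e.strata
        ],
        columns=["gene_id", "stratum", "fold_change"],
    )
    return ExpressionMatrix(values, scale_tag="log2"), metadata, truth


#: Fixture probe → gene map: two probes for HMGN1, one for each other gene.
_FIXTURE_PROBES = (
    ("200943_at", "HMGN1", 3150),
    ("200944_s_at", "HMGN1", 3150),
    ("208668_x_at", "HMGN2", 3151),
    ("209377_s_at", "HMGN3", 9324),
    ("219062_s_at", "HMGN4", 10473),
    ("1553055_a_at", "HMGN5", 79366),
)

_TABLE1_ROWS = (
    ("HMGN1", 3150, "21q22.2"),
    ("HMGN2", 3151, "1p36.11"),
    ("HMGN3", 9324, "6q14.1"),
    ("HMGN4", 10473, "6p22.2"),
    ("HMGN5", 79366, "Xq21.1"),
)


def make_fixture_files(outdir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write the small fixed-seed fixtures used by the I/O and pipeline tests.

    Emits a 6-probe × 4-sample series-matrix file (two probes for HMGN1,
    one per other HMGN gene; 2 DS and 2 control hippocampus samples with
    a 1.5-fold shift planted in the HMGN1 probes of the DS samples), the
    matching metadata TSV, a probe annotation TSV, a five-gene annotation
    TSV with Entrez ids and cytoband loci, and the truth table.
    Regeneration with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    probes = [p for p, _, _ in _FIXTURE_PROBES]
    metadata = [
        SampleMetadata("DS_HIP_01", "DS", "HIP", 18.0, "WG", "F"),
        SampleMetadata("DS_HIP_02", "DS", "HIP", 35.0, "Y", "M"),
        SampleMetadata("CT_HIP_01", "control", "HIP", 20.0, "WG", "F"),
        SampleMetadata("CT_HIP_02", "control", "HIP", 33.0, "Y", "M"),
    ]
    mu = rng.normal(8.0, 1.5, len(probes))
    noise = rng.normal(0.0, 0.2, (len(probes), len(metadata)))
    values = mu[:, None] + noise
    shift = np.log2(1.5)
    for pi, (_, gene, _) in enumerate(_FIXTURE_PROBES):
        if gene == "HMGN1":
            values[pi, :2] += shift  # the two DS columns
    matrix = ExpressionMatrix(
        pd.DataFrame(np.round(values, 6), index=probes, columns=[m.sample_id for m in metadata]),
        scale_tag="log2",
    )

    paths = {
        "series_matrix": outdir / "series_matrix.txt",
        "metadata": outdir / "metadata.tsv",
        "probe_annotation": outdir / "probe_annotation.tsv",
        "gene_annotation": outdir / "gene_annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_series_matrix(matrix, metadata, paths["series_matrix"])
    write_metadata_tsv(metadata, paths["metadata"])
    pd.DataFrame(
        [{"probe_id": p, "gene_symbol": g, "entrez_id": e} for p, g, e in _FIXTURE_PROBES]
    ).to_csv(paths["probe_annotation"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_symbol": g, "entrez_id": e, "locus": l} for g, e, l in _TABLE1_ROWS]
    ).to_csv(paths["gene_annotation"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": "HMGN1", "stratum": "HIP", "fold_change": 1.5}]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
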