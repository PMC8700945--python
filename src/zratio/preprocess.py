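"""Presence filtering and stratification of samples by region and age rank.

The presence filter keeps a probe only when its linear-scale signal
exceeds an intensity threshold (default 100, the conventional PLIER
presence cut-off) in at least a given fraction of samples (default one
half, read literally: on an even number of samples, exactly n/2
qualifying samples is enough).

Strata are either the whole brain, a single region, or an age rank.  The
default age ranks span prenatal (weeks of gestation) to adult ages in six
disjoint bins; ages falling in a gap between bins are left unassigned
rather than snapped to the nearest bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geo_io import REGIONS, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


class EmptyStratumError(ValueError):
    """Signal that a stratum has no DS or no control samples (skip it)."""


@dataclass(frozen=True)
class AgeRank:
    """A closed age interval with its unit (WG weeks gestation, M months, Y years)."""

    label: str
    low: float
    high: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("WG", "M", "Y"):
            raise ValueError(f"age-rank unit must be WG/M/Y, got {self.unit!r}")
        if self.low > self.high:
            raise ValueError(f"age rank {self.label!r}: low > high")

    def contains(self, value: float, unit: str) -> bool:
        """Membership after unit normalization.

        WG ages only match WG bins; months of 24 or more are converted to
        years, years under 2 to months, so infant and adult ages land in
        the unit their bin is defined in.
        """
        if unit == "WG" or self.unit == "WG":
            if unit != self.unit:
                return False
        elif unit == "M" and self.unit == "Y":
            if value < 24:
                return False
            value = value / 12.0
        elif unit == "Y" and self.unit == "M":
            if value >= 2:
                return False
            value = value * 12.0
        return self.low <= value <= self.high


#: The six default age ranks, prenatal to adult.
DEFAULT_AGE_RANKS: tuple[AgeRank, ...] = (
    AgeRank("16-22 WG", 16, 22, "WG"),
    AgeRank("0-12 M", 0, 12, "M"),
    AgeRank("2-10 Y", 2, 10, "Y"),
    AgeRank("12-22 Y", 12, 22, "Y"),
    AgeRank("30-39 Y", 30, 39, "Y"),
    AgeRank("40-42 Y", 40, 42, "Y"),
)


@dataclass(frozen=True)
class Stratum:
    """A sample stratum: the whole brain, one region, or one age rank."""

    name: str
    kind: str  # whole_brain | region | age_rank
    region: str | None = None
    age_rank: AgeRank | None = None

    def __post_init__(self) -> None:
        if self.kind == "whole_brain":
            if self.region is not None or self.age_rank is not None:
                raise ValueError("whole_brain stratum must not set region or age_rank")
        elif self.kind == "region":
            if self.region is None or self.age_rank is not None:
                raise ValueError("region stratum must set region only")
            if self.region not in REGIONS:
                raise ValueError(f"unknown region code {self.region!r}")
        elif self.kind == "age_rank":
            if self.age_rank is None or self.region is not None:
                raise ValueError("age_rank stratum must set age_rank only")
        else:
            raise ValueError(f"unknown stratum kind {self.kind!r}")

    def members(
        self, metadata: Sequence[SampleMetadata], ranks: Sequence[AgeRank] = DEFAULT_AGE_RANKS
    ) -> list[str]:
        if self.kind == "whole_brain":
            return [m.sample_id for m in metadata]
        if self.kind == "region":
            return [m.sample_id for m in metadata if m.region == self.region]
        return [
            m.sample_id for m in metadata if assign_age_rank(m, ranks) == self.age_rank
        ]


def whole_brain_stratum() -> Stratum:
    return Stratum("Brain", "whole_brain")


def region_strata(regions: Sequence[str] = REGIONS) -> list[Stratum]:
    return [Stratum(r, "region", region=r) for r in regions]


def age_rank_strata(ranks: Sequence[AgeRank] = DEFAULT_AGE_RANKS) -> list[Stratum]:
    _check_rank_overlap(ranks)
    return [Stratum(r.label, "age_rank", age_rank=r) for r in ranks]


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reconstruct linear intensities as 2^log2 (identity if already linear)."""
    if matrix.scale_tag == "linear":
        return matrix
    return ExpressionMatrix(np.exp2(matrix.values), scale_tag="linear")


def filter_present(
    matrix: ExpressionMatrix,
    threshold: float = 100.0,
    min_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Keep probes whose linear intensity is strictly above ``threshold``
    in at least ``min_fraction`` of samples.

    The matrix must be on the linear scale (use :func:`to_linear` first).
    The fraction comparison is a plain ``>=``: with four samples and the
    default fraction, two qualifying samples keep the probe.
    """
    if matrix.scale_tag != "linear":
        raise ValueError("filter_present requires linear-scale intensities; use to_linear()")
    n = matrix.values.shape[1]
    if n == 0:
        raise ValueError("cannot apply presence filter with zero samples")
    n_above = (matrix.values > threshold).sum(axis=1)
    keep = n_above >= min_fraction * n
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_present: dropped %d of %d probes", n_dropped, len(keep))
    return ExpressionMatrix(matrix.values.loc[keep], scale_tag="linear")


def _check_rank_overlap(ranks: Sequence[AgeRank]) -> None:
    for i, a in enumerate(ranks):
        for b in ranks[i + 1 :]:
            if a.unit == b.unit and a.low <= b.high and b.low <= a.high:
                raise ValueError(f"overlapping age ranks: {a.label!r} and {b.label!r}")


def assign_age_rank(
    meta: SampleMetadata, ranks: Sequence[AgeRank] = DEFAULT_AGE_RANKS
) -> AgeRank | None:
    """Assign a sample to the unique matching age rank, or ``None``.

    Samples whose age falls in a gap between bins (e.g. 25 Y between the
    12–22 Y and 30–39 Y bins) are unassigned; callers count and report
    them.  Overlapping rank definitions are a configuration error.
    """
    if meta.age_value is None or meta.age_unit is None:
        return None
    _check_rank_overlap(ranks)
    matches = [r for r in ranks if r.contains(meta.age_value, meta.age_unit)]
    if len(matches) > 1:  # defensive: overlap check above should prevent this
        raise ValueError(f"sample {meta.sample_id} matches multiple age ranks")
    if not matches:
        logger.warning(
            "sample %s (age %s %s) falls outside all age ranks",
            meta.sample_id, meta.age_value, meta.age_unit,
        )
        return None
    return matches[0]


def split_by_stratum(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    stratum: Stratum,
    ranks: Sequence[AgeRank] = DEFAULT_AGE_RANKS,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a stratum's sample columns into (DS, control) submatrices.

    Raises :class:`EmptyStratumError` when either group is empty in the
    stratum; pipeline callers catch it and skip the stratum with a logged
    warning instead of crashing.
    """
    matrix.check_join(metadata)
    member_ids = set(stratum.members(metadata, ranks))
    by_id = {m.sample_id: m for m in metadata}
    ds_cols = [s for s in matrix.sample_ids if s in member_ids and by_id[s].group == "DS"]
    ctrl_cols = [s for s in matrix.sample_ids if s in member_ids and by_id[s].group == "control"]
    if not ds_cols or not ctrl_cols:
        raise EmptyStratumError(
            f"stratum {stratum.name!r}: DS n={len(ds_cols)}, control n={len(ctrl_cols)}"
        )
    return (
        ExpressionMatrix(matrix.values[ds_cols], scale_tag=matrix.scale_tag),
        ExpressionMatrix(matrix.values[ctrl_cols], scale_tag=matrix.scale_tag),
    )
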