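"""Gene-dosage imbalance scoring and copy-number-style classification.

For a gene in one stratum, M is the difference of group mean log2
intensities (DS minus control, on raw log2 values, never Z-scores) and
R = 2^M is the corresponding fold ratio.  R is interpreted on a
copy-dosage scale: a balanced two-copy gene sits near 1.0, a triplicated
gene near 1.5 (three copies / two copies), and higher ratios indicate
amplification beyond a third copy.

The classification bins are: R in [0.80, 1.30] balanced, [1.4, 1.7]
triplicated, and strictly above 1.8 amplified.  The ranges between the
named bins are reported explicitly as ``gap_low`` (1.30, 1.4) and
``gap_high`` (1.7, 1.8], and R below 0.80 as ``reduced`` — a ratio
falling between bins is never silently snapped to a neighboring call.
All bin edges are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geo_io import ExpressionMatrix

#: Dosage categories in increasing order of R.
CATEGORY_ORDER = ("reduced", "balanced", "gap_low", "triplicated", "gap_high", "amplified")


@dataclass(frozen=True)
class DosageBins:
    """Closed [low, high] bins for balanced/triplicated and the amplified cut."""

    balanced_low: float = 0.80
    balanced_high: float = 1.30
    triplicated_low: float = 1.4
    triplicated_high: float = 1.7
    amplified_above: float = 1.8

    def __post_init__(self) -> None:
        edges = (
            self.balanced_low,
            self.balanced_high,
            self.triplicated_low,
            self.triplicated_high,
            self.amplified_above,
        )
        if any(e <= 0 for e in edges) or list(edges) != sorted(edges):
            raise ValueError(f"dosage bin edges must be positive and increasing: {edges}")


DEFAULT_BINS = DosageBins()


def m_value(ds_values: Sequence[float], ctrl_values: Sequence[float]) -> float:
    """M = mean(DS log2) − mean(control log2), on unstandardized log2 intensities."""
    ds = np.asarray(ds_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if ds.size == 0 or ctrl.size == 0:
        raise ValueError("m_value requires nonempty DS and control groups")
    return float(ds.mean() - ctrl.mean())


def r_ratio(m: float) -> float:
    """R = 2^M, the dosage fold ratio."""
    if not np.isfinite(m):
        raise ValueError(f"non-finite M value: {m}")
    return float(2.0 ** m)


def classify_dosage(r: float, bins: DosageBins = DEFAULT_BINS) -> str:
    """Map a dosage ratio to its category.

    Boundaries are closed as stated by the bin definitions: 0.80 and 1.30
    are balanced, 1.4 and 1.7 triplicated; "amplified" is strictly above
    1.8, so (1.7, 1.8] is ``gap_high``.
    """
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"dosage ratio must be finite and positive, got {r}")
    if r < bins.balanced_low:
        return "reduced"
    if r <= bins.balanced_high:
        return "balanced"
    if r < bins.triplicated_low:
        return "gap_low"
    if r <= bins.triplicated_high:
        return "triplicated"
    if r <= bins.amplified_above:
        return "gap_high"
    return "amplified"


def dosage_records(
    ds: ExpressionMatrix,
    ctrl: ExpressionMatrix,
    stratum_name: str = "Brain",
    bins: DosageBins = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-gene dosage table for one stratum.

    Both matrices must be log2-scale with identical gene sets.  Returns a
    DataFrame indexed by gene with columns ``stratum``, ``m_value``,
    ``r_ratio`` and ``category``.
    """
    if ds.scale_tag != "log2" or ctrl.scale_tag != "log2":
        raise ValueError("dosage scoring requires log2-scale matrices")
    if list(ds.values.index) != list(ctrl.values.index):
        raise ValueError("gene sets of DS and control matrices differ")
    m = ds.values.mean(axis=1) - ctrl.values.mean(axis=1)
    r = np.exp2(m)
    out = pd.DataFrame(
        {
            "stratum": stratum_name,
            "m_value": m,
            "r_ratio": r,
            "category": [classify_dosage(v, bins) for v in r],
        }
    )
    out.index.name = "gene_id"
    return out
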