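"""The Z-score / Z-ratio differential-expression statistic.

Each sample (array) is standardized across its genes:

    z_gs = (x_gs - mean_g' x_g's) / sd_g' x_g's

so that every array has mean-zero, unit-variance expression regardless of
its overall intensity — this removes array-level location/scale effects.
Optionally Z-scores are winsorized to [-3, +3] to bound the influence of
extreme probes.

For a stratum with groups DS and control, the per-gene difference of
group-mean Z-scores is scaled by the standard deviation of those
differences over all analyzed genes:

    Z-ratio_g = (mean_z_DS,g - mean_z_ctrl,g) / sd_g'(diff_g')

A gene with Z-ratio strictly greater than 1.96 (the two-tailed 5% normal
critical value) is called overexpressed.  Two-tailed p-values are
computed from the standard normal distribution; a Benjamini–Hochberg
q-value column is available for rigor but never gates the overexpression
flag, which follows the fixed 1.96 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo_io import ExpressionMatrix

#: Two-tailed 5% critical value of the standard normal distribution.
OVEREXPRESSION_CUTOFF = 1.96


class ZeroVarianceError(ValueError):
    """A standard deviation needed for standardization is zero."""


@dataclass
class ZScoreMatrix:
    """Gene × sample matrix of per-sample standardized expression."""

    z: pd.DataFrame
    clipped: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def zscore_per_sample(
    matrix: ExpressionMatrix,
    clip: bool = False,
    clip_bound: float = 3.0,
    ddof: int = 1,
) -> ZScoreMatrix:
    """Standardize each sample column across its genes.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population convention.  With ``clip`` set, values
    are winsorized to ``[-clip_bound, +clip_bound]`` after
    standardization.
    """
    x = matrix.values
    if x.shape[0] < 2:
        raise ValueError("per-sample standardization needs at least 2 genes")
    sd = x.std(axis=0, ddof=ddof)
    zero = sd[sd == 0]
    if len(zero):
        raise ZeroVarianceError(
            f"zero within-sample standard deviation for sample(s): {list(zero.index)}"
        )
    z = (x - x.mean(axis=0)) / sd
    if clip:
        z = z.clip(lower=-clip_bound, upper=clip_bound)
    return ZScoreMatrix(z, clipped=clip)


def p_from_z(z):
    """Two-tailed normal p-value, 2·(1 − Φ(|z|)).  Accepts scalars or arrays."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z value")
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def zratio(
    ds: ZScoreMatrix,
    ctrl: ZScoreMatrix,
    stratum_name: str = "Brain",
    ddof: int = 1,
    cutoff: float = OVEREXPRESSION_CUTOFF,
    bh_column: bool = False,
) -> pd.DataFrame:
    """Compute per-gene Z-ratios for one stratum.

    Both matrices must carry the same gene set (the analyzed universe —
    the denominator's standard deviation runs over exactly these genes).
    Returns a DataFrame indexed by gene with columns ``stratum``,
    ``mean_z_ds``, ``mean_z_control``, ``z_ratio``, ``p_two_tailed`` and
    ``overexpressed`` (strictly greater than ``cutoff``); with
    ``bh_column``, a ``q_bh`` Benjamini–Hochberg column is added that
    never affects the flag.
    """
    if list(ds.z.index) != list(ctrl.z.index):
        raise ValueError("gene sets of DS and control matrices differ")
    if ds.z.shape[0] < 2:
        raise ValueError("Z-ratio needs at least 2 genes (SD of differences)")
    mean_ds = ds.z.mean(axis=1)
    mean_ctrl = ctrl.z.mean(axis=1)
    diffs = mean_ds - mean_ctrl
    sd_diffs = float(diffs.std(ddof=ddof))
    if sd_diffs == 0:
        raise ZeroVarianceError("standard deviation of Z-score differences is zero")
    zr = diffs / sd_diffs
    out = pd.DataFrame(
        {
            "stratum": stratum_name,
            "mean_z_ds": mean_ds,
            "mean_z_control": mean_ctrl,
            "z_ratio": zr,
            "p_two_tailed": p_from_z(zr.to_numpy()),
            "overexpressed": zr > cutoff,
        }
    )
    out.index.name = "gene_id"
    if bh_column:
        out["q_bh"] = stats.false_discovery_control(out["p_two_tailed"].to_numpy(), method="bh")
    return out
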