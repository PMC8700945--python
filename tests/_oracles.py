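"""Independent literal re-implementations used as oracles in tests.

These are deliberately loop-based and depend only on ``math`` so they
share no code path with the package implementation.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_sd(xs):
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def zscores_per_sample(rows):
    """rows: list of gene rows (each a list over samples) -> same shape z."""
    n_genes, n_samples = len(rows), len(rows[0])
    z = [[0.0] * n_samples for _ in range(n_genes)]
    for s in range(n_samples):
        col = [rows[g][s] for g in range(n_genes)]
        m, sd = mean(col), sample_sd(col)
        for g in range(n_genes):
            z[g][s] = (rows[g][s] - m) / sd
    return z


def zratios(ds_rows, ctrl_rows):
    """Literal Z-ratio: per-gene diff of group-mean Z-scores over SD of diffs."""
    zds = zscores_per_sample(ds_rows)
    zctrl = zscores_per_sample(ctrl_rows)
    diffs = [mean(zds[g]) - mean(zctrl[g]) for g in range(len(ds_rows))]
    sd = sample_sd(diffs)
    return [d / sd for d in diffs]


def m_and_r(ds_values, ctrl_values):
    m = mean(ds_values) - mean(ctrl_values)
    return m, math.exp(m * math.log(2.0))


def normal_two_tailed_p(z):
    """2·(1 − Φ(|z|)) via the complementary error function."""
    return math.erfc(abs(z) / math.sqrt(2.0))
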