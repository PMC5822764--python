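"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's extraction path: MTT and AUC are
computed by dense Riemann summation of the *model function itself* on a
fine grid, with the true baseline subtracted analytically — no baseline
estimation, no smoothing, no clipping logic shared with the code under
test.
"""

import numpy as np

from icgflow.simulate import model_intensity


def fine_grid_moments(p, window_end, dt=0.001):
    """(mtt, auc) of the noiseless model curve by dense midpoint summation
    over [0, window_end], time measured from acquisition start."""
    t = np.arange(0.0, window_end, dt) + dt / 2.0
    net = (
        model_intensity(
            t, p.baseline, p.arrival, p.amplitude, p.rise_time,
            p.washout_tau, p.plateau_fraction,
        )
        - p.baseline
    )
    mass = net.sum() * dt
    mtt = (t * net).sum() * dt / mass
    return mtt, mass


def summary_anova_f(means, sds, ns):
    """Closed-form one-way ANOVA F from group summary statistics."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    grand = (ns * means).sum() / ns.sum()
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    dfb = len(means) - 1
    dfw = ns.sum() - len(means)
    return (ssb / dfb) / (ssw / dfw)


def pearson_chi2(table):
    """Direct-formula Pearson chi-square statistic."""
    table = np.asarray(table, float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return ((table - expected) ** 2 / expected).sum()
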