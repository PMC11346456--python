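"""Independent Monte-Carlo oracle for the discovery/resistance dynamics.

A flat-numpy batch simulator of the full generative process, written
separately from abxdyn.simulate (continuous time, no tables) so that
analytic-curve checks compare two independent routes.
"""

import numpy as np

LN2 = np.log(2.0)


def mc_curves(k, n, t_lag, t0, half_life, checkpoints, n_rep, seed):
    """Monte-Carlo means and standard errors of D(t) and R(t).

    Draws arrive as a rate-``n`` Poisson process after ``t0 + t_lag``,
    land uniformly on ``k`` classes, and each discovered class becomes
    resistant after an exponential delay with median ``half_life``.
    Returns (D_mean, D_se, R_mean, R_se), each an array over checkpoints.
    """
    rng = np.random.default_rng(seed)
    onset = t0 + t_lag
    span = float(max(checkpoints) - onset)
    m = rng.poisson(n * span, size=n_rep)
    total = int(m.sum())
    rep = np.repeat(np.arange(n_rep, dtype=np.int64), m)
    times = rng.random(total) * span
    cls = rng.integers(0, k, size=total)
    key = rep * k + cls
    order = np.lexsort((times, key))
    key_sorted = key[order]
    times_sorted = times[order]
    uniq, first_idx = np.unique(key_sorted, return_index=True)
    disc = np.full(n_rep * k, np.inf)
    disc[uniq] = times_sorted[first_idx]
    res = disc + rng.exponential(half_life / LN2, size=n_rep * k)
    disc = disc.reshape(n_rep, k)
    res = res.reshape(n_rep, k)
    d_mean, d_se, r_mean, r_se = [], [], [], []
    for tc in checkpoints:
        tau = tc - onset
        d_counts = (disc <= tau).sum(axis=1)
        r_counts = (res <= tau).sum(axis=1)
        d_mean.append(d_counts.mean())
        d_se.append(d_counts.std(ddof=1) / np.sqrt(n_rep))
        r_mean.append(r_counts.mean())
        r_se.append(r_counts.std(ddof=1) / np.sqrt(n_rep))
    return (np.array(d_mean), np.array(d_se), np.array(r_mean), np.array(r_se))
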