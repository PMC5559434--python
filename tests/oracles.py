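"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive (enumeration, literal window scans)
and shares no code path with the implementation it checks.
"""

import itertools

import numpy as np


def enum_path_probs(y, x, params):
    """All 2^T hidden paths of one couple with their joint probabilities.

    Returns (paths, probs): paths as tuples of 0/1 state indices, probs as
    the joint probability of (path, y).
    """
    T = len(y)
    paths, probs = [], []
    for path in itertools.product([0, 1], repeat=T):
        pr = params.pi[path[0]]
        for t in range(T):
            z = params.mu + (params.alpha2 if path[t] == 1 else 0.0) \
                + float(np.dot(x, params.beta))
            p1 = 1.0 / (1.0 + np.exp(-z))
            pr *= p1 if y[t] == 1 else (1.0 - p1)
        for t in range(1, T):
            pr *= params.Pi[path[t - 1], path[t]]
        paths.append(path)
        probs.append(pr)
    return paths, np.asarray(probs)


def enum_loglik(panel, params):
    """Manifest log-likelihood by explicit path enumeration."""
    total = 0.0
    for i in range(panel.n):
        T = int(panel.lengths[i])
        x = panel.xmat(0)[i] if not panel.time_varying() else None
        if panel.time_varying():
            raise NotImplementedError("oracle assumes time-fixed covariates")
        _, probs = enum_path_probs(panel.Y[i, :T], x, params)
        total += np.log(probs.sum())
    return total


def enum_posteriors(panel, params):
    """Smoothed state posteriors gamma[i, t, u] by enumeration."""
    gamma = np.zeros((panel.n, panel.T_max, 2))
    for i in range(panel.n):
        T = int(panel.lengths[i])
        x = panel.xmat(0)[i]
        paths, probs = enum_path_probs(panel.Y[i, :T], x, params)
        z = probs.sum()
        for path, pr in zip(paths, probs):
            for t in range(T):
                gamma[i, t, path[t]] += pr / z
    return gamma


def brute_force_shift(days, bbt, disturbance=None, after_day=None,
                      max_gap_days=1):
    """Literal scan of all (six-before, three-after) windows over the
    usable (recorded, non-disturbed) temperatures."""
    days = np.asarray(days, dtype=int)
    bbt = np.asarray(bbt, dtype=float)
    ok = ~np.isnan(bbt)
    if disturbance is not None:
        ok &= np.asarray(disturbance, dtype=int) == 0
    d, v = days[ok], bbt[ok]
    if d.size < 9:
        return None
    best = None
    for j in range(len(d)):
        if j < 6 or j + 2 >= len(d):
            continue
        if after_day is not None and d[j] <= after_day:
            continue
        if d[j + 1] - d[j] > 1 + max_gap_days:
            continue
        if d[j + 2] - d[j + 1] > 1 + max_gap_days:
            continue
        six = [v[j - k] for k in range(1, 7)]
        three = [v[j], v[j + 1], v[j + 2]]
        if all(h > max(six) for h in three):
            if best is None or d[j] < best:
                best = int(d[j])
    return best
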