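"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written in the most literal way possible
(loops, explicit formulas) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def km_oracle(times, events):
    """Product-limit estimator by explicit sequential accumulation.

    Returns (event_times, survival) at distinct event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_oracle(times1, events1, times2, events2):
    """Two-group log-rank chi-square by 2x2 hypergeometric accumulation."""
    t = np.concatenate([times1, times2]).astype(float)
    e = np.concatenate([events1, events2]).astype(int)
    g = np.concatenate([np.zeros(len(times1)), np.ones(len(times2))]).astype(int)
    obs_minus_exp = 0.0
    var = 0.0
    for tau in sorted(set(t[e == 1])):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & (g == 0)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var


def cox_partial_loglik(beta, x, times, events):
    """Breslow partial log-likelihood for a single covariate, literal form."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def cox_grid_oracle(x, times, events, lo=-5.0, hi=5.0, tol=1e-6):
    """Maximize the single-covariate partial likelihood by grid refinement."""
    while hi - lo > tol:
        grid = np.linspace(lo, hi, 41)
        lls = [cox_partial_loglik(b, x, times, events) for b in grid]
        k = int(np.argmax(lls))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
    return (lo + hi) / 2.0


def roc_points_oracle(scores, outcome, threshold):
    """Sensitivity and specificity at a threshold by explicit counting."""
    tp = sum(1 for s, y in zip(scores, outcome) if y == 1 and s >= threshold)
    fn = sum(1 for s, y in zip(scores, outcome) if y == 1 and s < threshold)
    tn = sum(1 for s, y in zip(scores, outcome) if y == 0 and s < threshold)
    fp = sum(1 for s, y in zip(scores, outcome) if y == 0 and s >= threshold)
    return tp / (tp + fn), tn / (tn + fp)
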