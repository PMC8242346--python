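"""Independent reference implementations used only by the test suite.

These are deliberately written in the most literal way possible
(explicit per-time tabulation, exhaustive enumeration) so they share no
code with the package implementations they check.
"""

import numpy as np
from scipy import stats


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Hypergeometric-table log-rank: loop over every distinct event
    time, count at-risk/event numbers per group by brute force."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    event_times = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        n = n_a + n_b
        d_a = int(np.sum((ta == t) & (ea == 1)))
        d_b = int(np.sum((tb == t) & (eb == 1)))
        d = d_a + d_b
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return stat, float(stats.chi2.sf(stat, df=1))


def cutpoint_scan_oracle(values, times, events, lower=0.10, upper=0.90):
    """Exhaustive brute force over every admissible split: returns the
    (cut_value, p) pair with the smallest p, ties broken toward the
    median."""
    values = np.asarray(values, float)
    n = values.size
    median = np.median(values)
    best = None
    for cut in sorted(set(values)):
        low = values <= cut
        n_low = int(low.sum())
        if n_low < lower * n or n_low > upper * n or n_low == n:
            continue
        if events[low].sum() + events[~low].sum() == 0:
            continue
        _, p = logrank_oracle(times[low], events[low], times[~low], events[~low])
        if (
            best is None
            or p < best[1] - 1e-15
            or (abs(p - best[1]) <= 1e-15
                and abs(cut - median) < abs(best[0] - median))
        ):
            best = (float(cut), p)
    return best


def auc_pair_counting(scores, outcome):
    """AUC by explicit concordant-pair counting with 0.5 tie credit."""
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome, int)
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
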