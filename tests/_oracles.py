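"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates label assignments directly, and the ROC oracle scans every
candidate cutoff with explicit loops.
"""

from itertools import combinations

import numpy as np


def mann_whitney_exact_p(a, b):
    """Two-sided exact p by full enumeration of label assignments (no ties)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n_a = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n_a):
        r_sum = sum(i + 1 for i in idx)
        us.append(r_sum - n_a * (n_a + 1) / 2)
    us = np.array(us, dtype=float)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def roc_youden_bruteforce(values, labels):
    """Best Youden J over all observed cutoffs; ties -> larger cutoff."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best = None
    for cutoff in sorted(set(values.tolist())):
        tp = fn = tn = fp = 0
        for v, y in zip(values, labels):
            call_pos = v > cutoff
            if y == 1 and call_pos:
                tp += 1
            elif y == 1:
                fn += 1
            elif call_pos:
                fp += 1
            else:
                tn += 1
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or cutoff > best[1]:
                best = (j, cutoff, sens, spec)
    return best  # (j, cutoff, sensitivity, specificity)
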