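"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition (all-pairs
scans, transitive closure, explicit product-limit arithmetic) and share no
code with the implementation they check.
"""

import numpy as np


def count_below_line_cutoff(signals):
    """O(N^2) hockey-stick scan: for each candidate rank, draw the line of
    slope (max-min)/N through that point and count points on or below it;
    the cutoff is the candidate with the fewest, ties to the largest rank.
    Returns (cutoff_signal, cutoff_rank 1-based)."""
    y = np.sort(np.clip(np.asarray(signals, dtype=float), 0.0, None))
    n = y.size
    if y[-1] == y[0]:
        return float(y[-1]), n
    slope = (y[-1] - y[0]) / n
    tol = 1e-9 * (y[-1] - y[0])  # guards one-ULP misses at the tangent point
    best_rank, best_count = None, None
    for i in range(n):
        intercept = y[i] - slope * i
        line = slope * np.arange(n) + intercept
        count = int((y <= line + tol).sum())
        if best_count is None or count < best_count or count == best_count:
            if best_count is None or count < best_count:
                best_rank, best_count = i, count
            elif count == best_count:
                best_rank = i  # ties resolve to the largest rank
    return float(y[best_rank]), best_rank + 1


def transitive_merge(intervals, gap):
    """Brute-force transitive interval merge: repeatedly fuse any two
    same-chromosome intervals whose edge-to-edge distance is <= gap until
    no pair qualifies. Returns a sorted list of (chrom, start, end)."""
    regions = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                if a[0] != b[0]:
                    continue
                dist = max(a[1], b[1]) - min(a[2], b[2])
                if dist <= gap:
                    merged = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    regions = [r for k, r in enumerate(regions) if k not in (i, j)]
                    regions.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(r) for r in regions)


def km_product_limit(times, events):
    """Explicit product-limit estimator over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - deaths) / at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_statistic(times_a, events_a, times_b, events_b):
    """Mantel-Cox chi-square from the O-E / hypergeometric-variance sums."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def gsea_running_sum(metric_sorted, in_set_mask, weight_p=1.0):
    """Step-by-step weighted Kolmogorov-Smirnov walk; returns the signed
    deviation of maximal magnitude."""
    w = np.abs(metric_sorted) ** weight_p
    n = len(metric_sorted)
    k = int(in_set_mask.sum())
    total = w[in_set_mask].sum()
    if total == 0:
        total = 1.0
    walk, value = [], 0.0
    for i in range(n):
        if in_set_mask[i]:
            value += w[i] / total
        else:
            value -= 1.0 / (n - k)
        walk.append(value)
    walk = np.array(walk)
    return walk.max() if walk.max() >= -walk.min() else walk.min()
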