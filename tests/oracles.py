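"""Independent brute-force oracles used to cross-check the reference-interval
machinery.  Deliberately naive implementations, kept separate from the code
paths they verify."""

import math


def oracle_limits(values, coverage=0.95):
    """Hand-rolled sort-and-interpolate with ranks r = p(n+1), clamped."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def at_rank(p):
        r = p * (n + 1)
        r = min(max(r, 1.0), float(n))
        k = int(math.floor(r))
        frac = r - k
        if k >= n:
            return xs[n - 1]
        return xs[k - 1] + frac * (xs[k] - xs[k - 1])

    tail = (1 - coverage) / 2
    return at_rank(tail), at_rank(1 - tail)


def oracle_dr_filter(values):
    """Naive re-implementation of the D/R rule: repeated passes testing both
    extremes against the range of the original sample."""
    remaining = list(values)
    removed = []
    r = max(values) - min(values)
    while len(remaining) >= 3 and r > 0:
        xs = sorted(remaining)
        to_remove = []
        if (xs[-1] - xs[-2]) / r > 1 / 3:
            to_remove.append(xs[-1])
        if (xs[1] - xs[0]) / r > 1 / 3 and len(remaining) - len(to_remove) >= 3:
            to_remove.append(xs[0])
        if not to_remove:
            break
        for v in to_remove:
            remaining.remove(v)
            removed.append(v)
    return remaining, removed


def oracle_ci_ranks(n, p, conf):
    """Exhaustive rank-pair search using math.comb binomial probabilities."""
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    best = None
    for l in range(1, n):
        for u in range(l + 1, n + 1):
            cov = sum(pmf[l:u])
            if cov >= conf:
                width = u - l
                centrality = abs((l + u) / 2 - p * (n + 1))
                key = (width, centrality, l)
                if best is None or key < best[0]:
                    best = (key, (l, u))
    return None if best is None else best[1]
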