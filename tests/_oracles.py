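"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by brute force or first principles, never
by calling the implementation it checks.
"""

import math

import numpy as np


def permutation_anova_p(groups: list[np.ndarray], n_perm: int = 100_000,
                        seed: int = 0) -> float:
    """One-way ANOVA p-value from the permutation null of the F statistic.

    With fixed group sizes, F is a monotone function of the between-group sum
    of squares, so the permutation tail of SSB equals the tail of F.
    """
    sizes = [len(g) for g in groups]
    values = np.concatenate(groups)
    grand = values.mean()

    def ssb(v: np.ndarray) -> float:
        total, start = 0.0, 0
        for size in sizes:
            total += size * (v[start:start + size].mean() - grand) ** 2
            start += size
        return total

    observed = ssb(values)
    rng = np.random.default_rng(seed)
    count = 0
    # vectorised permutations in chunks
    chunk = 2000
    done = 0
    n = len(values)
    starts = np.cumsum([0] + sizes)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)
        permuted = values[perm]
        ssb_perm = np.zeros(m)
        for i, size in enumerate(sizes):
            seg = permuted[:, starts[i]:starts[i + 1]]
            ssb_perm += size * (seg.mean(axis=1) - grand) ** 2
        count += int(np.sum(ssb_perm >= observed - 1e-12))
        done += m
    return count / n_perm


def brute_force_vector(bg, cbh, nag, lap, ue, ap):
    """Symbol-by-symbol evaluation of the vector formulas with math.*."""
    x = math.log(bg + cbh) / math.log(ap)
    y = math.log(bg + cbh) / math.log(nag + lap + ue)
    angle = math.degrees(math.atan2(x, y))
    length = math.sqrt(x * x + y * y)
    strict_length = math.sqrt(y * y + (math.log(bg) / math.log(ap)) ** 2)
    return x, y, angle, length, strict_length


def pearson_by_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance formula for Pearson r."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))
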