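"""Two-sided Fisher exact test on 2x2 tables, vectorized.

The test statistic is the hypergeometric probability of the observed
table; the two-sided p-value sums the probabilities of every table with
the same margins whose probability does not exceed the observed one
(the standard "sum of small p" rule, as in ``scipy.stats.fisher_exact``).

Probabilities are evaluated through a cached log-factorial table so that
hundreds of thousands of sites can be tested in a few numpy passes; the
scalar entry point wraps the vectorized one.
"""

from __future__ import annotations

import numpy as np

# Relative slack when comparing table probabilities, to keep exact ties
# (equal up to float rounding) inside the tail sum.
_REL_TOL = 1.0 + 1e-7

_log_fact = np.zeros(1)


def _logfact(n_max: int) -> np.ndarray:
    """Return log(k!) for k = 0..n_max, growing the module cache as needed."""
    global _log_fact
    if n_max >= _log_fact.size:
        new = np.zeros(n_max + 1)
        new[1:] = np.cumsum(np.log(np.arange(1, n_max + 1, dtype=float)))
        _log_fact = new
    return _log_fact


def fisher_exact_two_sided_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    chunk_cells: int = 5_000_000,
) -> np.ndarray:
    """Two-sided Fisher p-values for tables ``[[a, b], [c, d]]`` (elementwise).

    All four arguments are broadcastable integer arrays of cell counts.
    """
    a, b, c, d = np.broadcast_arrays(
        *(np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    )
    a, b, c, d = (x.ravel() for x in (a, b, c, d))
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("negative cell count in 2x2 table")
    r1 = a + b
    r2 = c + d
    k = a + c
    m = r1 + r2
    lf = _logfact(int(m.max(initial=0)))

    lo = np.maximum(0, k - r2)
    hi = np.minimum(r1, k)
    width = hi - lo + 1
    out = np.empty(a.size, dtype=float)

    start = 0
    n = a.size
    while start < n:
        maxw = 1
        stop = start
        # grow the chunk while the padded support matrix stays bounded
        while stop < n:
            w = max(maxw, int(width[stop]))
            if (stop - start + 1) * w > chunk_cells and stop > start:
                break
            maxw = w
            stop += 1
        sl = slice(start, stop)
        r1c, r2c, kc, mc = r1[sl, None], r2[sl, None], k[sl, None], m[sl, None]
        loc, hic = lo[sl, None], hi[sl, None]
        x = loc + np.arange(maxw, dtype=np.int64)[None, :]
        valid = x <= hic
        xs = np.where(valid, x, loc)

        log_denom = lf[mc] - lf[kc] - lf[mc - kc]

        def logpmf(xx):
            return (
                lf[r1c] - lf[xx] - lf[r1c - xx]
                + lf[r2c] - lf[kc - xx] - lf[r2c - kc + xx]
                - log_denom
            )

        pmf = np.exp(logpmf(xs))
        p_obs = np.exp(logpmf(a[sl, None]))
        tail = np.where(valid & (pmf <= p_obs * _REL_TOL), pmf, 0.0).sum(axis=1)
        out[sl] = np.minimum(tail, 1.0)
        start = stop
    return out


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for a single 2x2 table."""
    return float(
        fisher_exact_two_sided_many(
            np.array([a]), np.array([b]), np.array([c]), np.array([d])
        )[0]
    )
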