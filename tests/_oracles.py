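"""Independently coded reference implementations used as test oracles."""
import numpy as np
from scipy import optimize, special, stats


def medpolish_oracle(M, tol=1e-4, max_iter=100):
    """Plain alternating median subtraction, coded with explicit loops."""
    z = np.array(M, dtype=float)
    nr, nc = z.shape
    overall, row, col = 0.0, np.zeros(nr), np.zeros(nc)
    last = 0.0
    for _ in range(max_iter):
        for i in range(nr):
            m = np.nanmedian(z[i])
            z[i] -= m
            row[i] += m
        m = np.nanmedian(col)
        col -= m
        overall += m
        for j in range(nc):
            m = np.nanmedian(z[:, j])
            z[:, j] -= m
            col[j] += m
        m = np.nanmedian(row)
        row -= m
        overall += m
        s = np.nansum(np.abs(z))
        if s == 0 or abs(s - last) < tol * s:
            break
        last = s
    return overall, row, col, z


def moderated_t_oracle(X, d0=None, s0sq=None):
    """Closed-form moderated one-sample t with the prior fitted by root
    finding (brentq on trigamma) rather than Newton iteration."""
    X = np.asarray(X, float)
    n, R = X.shape
    d = R - 1
    mean = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    if d0 is None:
        e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
        target = np.var(e, ddof=1) - special.polygamma(1, d / 2)
        assert target > 0, "oracle expects a non-degenerate prior"
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - target, 1e-6, 1e8, xtol=1e-12
        )
        d0 = 2 * half_d0
        s0sq = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
    s2_post = (d0 * s0sq + d * s2) / (d0 + d)
    t = mean / np.sqrt(s2_post / R)
    df = min(d0 + d, n * d)
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, d0, s0sq
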