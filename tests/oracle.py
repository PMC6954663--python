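"""Naive reference implementations used as independent oracles.

Everything here is deliberately written with plain Python loops over
``None``-marked series, sharing no code with the package internals.
"""

from __future__ import annotations

import math


def oracle_smooth(series, w):
    """Centered truncated-window moving average; None splits runs."""
    n = len(series)
    out = [None] * n
    runs = []
    cur = []
    for i, v in enumerate(series):
        if v is None:
            if cur:
                runs.append(cur)
            cur = []
        else:
            cur.append(i)
    if cur:
        runs.append(cur)
    half = w // 2
    for run in runs:
        lo_run, hi_run = run[0], run[-1]
        for i in run:
            window = [
                series[k]
                for k in range(max(i - half, lo_run), min(i + half, hi_run) + 1)
            ]
            out[i] = sum(window) / len(window)
    return out


def oracle_signals(series, w, i_length, eps=1e-6):
    """(smoothed, baseline, proportional, integral, relative) per index."""
    n = len(series)
    s = oracle_smooth(series, w)
    b = [None] * n
    e = [None] * n
    g = [None] * n
    rel = [None] * n
    for t in range(n):
        if s[t] is None:
            continue
        window = []
        ok = True
        for k in range(t - i_length, t):
            if k < 0 or s[k] is None:
                ok = False
                break
            window.append(s[k])
        if not ok:
            continue
        b[t] = sum(window) / i_length
        e[t] = s[t] - b[t]
        rel[t] = s[t] / max(b[t], eps)
    for t in range(n):
        if e[t] is None:
            continue
        addends = []
        ok = True
        for k in range(t - i_length + 1, t + 1):
            if k < 0 or e[k] is None:
                ok = False
                break
            addends.append(e[k])
        if ok:
            g[t] = sum(addends)
    return s, b, e, g, rel


def oracle_flags(series, ts):
    """(up, down) boolean flag lists for one column under threshold set ts."""
    _, _, e, g, rel = oracle_signals(series, ts.w_smooth, ts.i_length)
    n = len(series)
    up = [False] * n
    down = [False] * n
    for t in range(n):
        if e[t] is None or g[t] is None or rel[t] is None:
            continue
        if e[t] >= ts.p_up and g[t] >= ts.i_up and rel[t] >= 1.0 + ts.r_up:
            up[t] = True
        if -e[t] >= ts.p_down and -g[t] >= ts.i_down and rel[t] <= 1.0 / (1.0 + ts.r_down):
            down[t] = True
    return up, down


def oracle_ols(xs, ys):
    """Closed-form simple linear regression slope and R^2."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if syy == 0:
        return 0.0, 0.0
    slope = sxy / sxx
    r2 = sxy * sxy / (sxx * syy)
    return slope, r2


def oracle_closest_to_origin(alphas, counts):
    """Brute-force normalized distance minimization with smaller-alpha ties."""

    def norm(xs):
        lo, hi = min(xs), max(xs)
        if hi == lo:
            return [0.0] * len(xs)
        return [(x - lo) / (hi - lo) for x in xs]

    na, nc = norm(list(alphas)), norm(list(counts))
    best, best_d = 0, math.inf
    for i in range(len(alphas)):
        d = math.hypot(na[i], nc[i])
        if d < best_d - 1e-15:
            best, best_d = i, d
    return best
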