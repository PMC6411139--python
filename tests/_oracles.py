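"""Independent brute-force reference implementations used to check the package.

Everything here is deliberately written as plain loops / textbook formulas,
sharing no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sp_stats


def ramp_brute(pixels, p: int, normalize: bool) -> float:
    """Sum of |I(x,y) - I(x,y-p)| over x in {0,p,...}, y in {p,2p,...}."""
    h = len(pixels)
    w = len(pixels[0])
    total = 0
    count = 0
    y = p
    while y < h:
        x = 0
        while x < w:
            total += abs(int(pixels[y][x]) - int(pixels[y - p][x]))
            count += 1
            x += p
        y += p
    return total / count if normalize else float(total)


def sid_brute(pixels, p: int, rows: int, cols: int, normalize: bool) -> float:
    """Population std of per-segment sampled sums (remainder joins the last segment)."""
    h = len(pixels)
    w = len(pixels[0])
    row_edges = [i * (h // rows) for i in range(rows)] + [h]
    col_edges = [j * (w // cols) for j in range(cols)] + [w]
    sums = [[0.0] * cols for _ in range(rows)]
    counts = [[0] * cols for _ in range(rows)]
    y = p
    while y < h:
        x = 0
        while x < w:
            si = max(i for i in range(rows) if row_edges[i] <= y)
            sj = max(j for j in range(cols) if col_edges[j] <= x)
            sums[si][sj] += int(pixels[y][x])
            counts[si][sj] += 1
            x += p
        y += p
    flat = []
    for i in range(rows):
        for j in range(cols):
            v = sums[i][j] / counts[i][j] if normalize else sums[i][j]
            flat.append(v)
    m = sum(flat) / len(flat)
    return float(np.sqrt(sum((v - m) ** 2 for v in flat) / len(flat)))


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Textbook OLS with intercept: coefficients, standard errors, p-values, adj R^2."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    xtx_inv = np.linalg.inv(A.T @ A)
    beta = xtx_inv @ A.T @ y
    resid = y - A @ beta
    dof = n - k - 1
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(xtx_inv) * s2)
    t = beta / se
    p = 2 * sp_stats.t.sf(np.abs(t), dof)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - (resid @ resid) / ss_tot
    adj_r2 = 1 - (1 - r2) * (n - 1) / dof
    return beta, se, p, adj_r2


def window_select_brute(values, window: int) -> list[int]:
    """Positions of the per-window maxima (first maximum wins)."""
    out = []
    for start in range(0, len(values), window):
        chunk = list(values[start : start + window])
        best = start + chunk.index(max(chunk))
        out.append(best)
    return out


def minimum_window_brute(values, target: float):
    """Smallest n <= floor(0.25 N) whose every window holds a value >= target."""
    n_frames = len(values)
    for n in range(1, max(1, int(0.25 * n_frames)) + 1):
        ok = True
        for start in range(0, n_frames, n):
            if not any(v >= target for v in values[start : start + n]):
                ok = False
                break
        if ok:
            return n
    return None


def pearson_textbook(a, b) -> float:
    """Covariance over product of standard deviations, from the definition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a.mean(), b.mean()
    cov = np.mean((a - am) * (b - bm))
    return float(cov / (np.sqrt(np.mean((a - am) ** 2)) * np.sqrt(np.mean((b - bm) ** 2))))
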